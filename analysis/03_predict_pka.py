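"""Close the thermodynamic cycles and convert ddG to pKa predictions.

Reads the leg estimates from 02, forms ddG = dG(protein) - dG(peptide)
per residue with quadrature error propagation, and applies the reference
constants (ASP 3.94, GLU 4.25, LYS 10.4) with the acid/base sign
convention. Only bootstrap uncertainties are propagated here, matching how
the leg errors were produced.

Writes results/pka_predictions.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from neqpka.constants import DEFAULT_TEMPERATURE
from neqpka.cycle import DEFAULT_REFERENCES, ddg_from_legs, pka_from_ddg
from neqpka.estimators import FreeEnergyEstimate


def leg_estimate(row) -> FreeEnergyEstimate:
    return FreeEnergyEstimate(
        value=row["dg_kjmol"], se=row["se_kjmol"],
        n_forward=int(row["n_forward"]), n_reverse=int(row["n_reverse"]),
        estimator="BAR",
    )


def main() -> None:
    legs = pd.read_csv(RESULTS / "leg_estimates.csv")
    rows = []
    for residue, grp in legs.groupby("residue", sort=False):
        by_leg = {r["leg"]: r for _, r in grp.iterrows()}
        cyc = ddg_from_legs(
            leg_estimate(by_leg["protein"]), leg_estimate(by_leg["peptide"]),
            DEFAULT_TEMPERATURE,
        )
        cls = by_leg["protein"]["class"]
        pred = pka_from_ddg(
            cyc, DEFAULT_REFERENCES[cls], include_ref_error=False,
            protein="SYNTH", residue=residue, source="neq",
        )
        rows.append(
            {
                "protein": "SYNTH", "residue": residue, "class": cls,
                "ddg_kjmol": cyc.ddg, "ddg_se_kjmol": cyc.se,
                "pred_neq": pred.pka, "se_neq": pred.se,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "pka_predictions.csv", index=False)

    ex = table.iloc[0]
    print(f"predicted pKa for {len(table)} residues")
    print(f"example {ex['residue']}: ddG = {ex['ddg_kjmol']:.2f} +/- {ex['ddg_se_kjmol']:.2f} "
          f"kJ/mol -> pKa = {ex['pred_neq']:.2f} +/- {ex['se_neq']:.2f}")
    print(f"median pKa SE: {table['se_neq'].median():.3f} pK")
    print(f"wrote {RESULTS / 'pka_predictions.csv'}")


if __name__ == "__main__":
    main()
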