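"""Build the synthetic pKa benchmark that stands in for the MD campaign.

144 residues (ASP/GLU/LYS at the 57:48:39 composition of the experimental
benchmark), true pKa shifts ~ truncated Normal(0, 1.5 pK) within +/-5 pK,
and for every residue two alchemical legs (protein, peptide) of 200
forward + 200 reverse Crooks-consistent work values at sigma = 5 kJ/mol.

Writes the ground-truth residue table to results/synthetic_residues.csv.
Downstream steps regenerate the same dataset deterministically from SEED.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import N_RES, N_TRANSITIONS, RESULTS, SEED, SIGMA

from neqpka.synthetic import synthetic_residue_dataset


def main() -> None:
    residues, worksets, truth = synthetic_residue_dataset(
        n_res=N_RES, sigma=SIGMA, n_transitions=N_TRANSITIONS, seed=SEED
    )
    RESULTS.mkdir(exist_ok=True)
    truth.to_csv(RESULTS / "synthetic_residues.csv", index=False)

    counts = truth["class"].value_counts()
    print(f"synthetic benchmark: {len(truth)} residues "
          f"({counts.get('ASP', 0)} ASP, {counts.get('GLU', 0)} GLU, {counts.get('LYS', 0)} LYS)")
    print(f"true shifts: mean {truth['true_shift'].mean():+.3f} pK, "
          f"sd {truth['true_shift'].std():.3f}, "
          f"range [{truth['true_shift'].min():+.2f}, {truth['true_shift'].max():+.2f}]")
    n_works = sum(ws.n_forward + ws.n_reverse for ws in worksets.values())
    print(f"work samples generated: {n_works} "
          f"({N_TRANSITIONS} transitions/direction x 2 legs x {N_RES} residues)")
    print(f"wrote {RESULTS / 'synthetic_residues.csv'}")


if __name__ == "__main__":
    main()
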