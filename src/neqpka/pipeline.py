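"""End-to-end glue: synthetic residues -> leg estimates -> pKa -> records.

Thin composition of the module-level operations, used by the analysis
drivers, the acceptance script, and the recovery tests.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkRecord
from .cycle import DEFAULT_REFERENCES, ddg_from_legs, pka_from_ddg
from .estimators import bar_estimate
from .synthetic import SyntheticResidue
from .work_ingest import WorkSet

__all__ = ["predict_residue", "predict_dataset", "records_from_predictions"]


def predict_residue(
    res: SyntheticResidue,
    worksets: Mapping[tuple[str, str], WorkSet],
    n_boot: int = 0,
    seed: int = 0,
    source: str = "neq",
):
    """BAR both legs of one residue's cycle and convert to a pKa prediction."""
    ws_p = worksets[(res.residue, "protein")]
    ws_s = worksets[(res.residue, "peptide")]
    leg_p = bar_estimate(ws_p, n_boot=n_boot, seed=seed, warn_on_low_overlap=False)
    leg_s = bar_estimate(ws_s, n_boot=n_boot, seed=seed + 1, warn_on_low_overlap=False)
    cyc = ddg_from_legs(leg_p, leg_s, temperature=ws_p.temperature)
    return pka_from_ddg(
        cyc,
        DEFAULT_REFERENCES[res.res_class],
        include_ref_error=False,
        protein=res.protein,
        residue=res.residue,
        source=source,
    )


def predict_dataset(
    residues: Sequence[SyntheticResidue],
    worksets: Mapping[tuple[str, str], WorkSet],
    n_boot: int = 0,
    seed: int = 0,
    source: str = "neq",
) -> list[BenchmarkRecord]:
    """Run the full cycle pipeline over a synthetic dataset.

    Returns one BenchmarkRecord per residue, with the residue's true pKa as
    the "experimental" value, ready for the benchmark module.
    """
    records = []
    for i, res in enumerate(residues):
        pred = predict_residue(res, worksets, n_boot=n_boot, seed=seed + 2 * i, source=source)
        records.append(
            BenchmarkRecord(
                protein=res.protein,
                residue=res.residue,
                res_class=res.res_class,
                experimental_pka=res.true_pka,
                predictions={source: pred},
            )
        )
    return records


def records_from_predictions(records: Sequence[BenchmarkRecord], source: str) -> pd.DataFrame:
    """Flatten records into a tidy table (one row per residue)."""
    rows = []
    for r in records:
        p = r.predictions[source]
        rows.append(
            {
                "protein": r.protein,
                "residue": r.residue,
                "class": r.res_class,
                "expt_pka": r.experimental_pka,
                f"pred_{source}": p.pka,
                f"se_{source}": p.se,
                "kind": p.kind,
            }
        )
    return pd.DataFrame(rows)
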