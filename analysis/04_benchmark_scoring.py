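"""Score the pKa predictions against the (synthetic) experimental values.

Joins the predictions from 03 with the ground truth from 01 and computes
AUE and Pearson r with residue-resampling bootstrap SEs, per class and
overall (overall AUE = mean of the class AUEs), plus the null model that
predicts the class reference pKa for every residue.

Writes results/benchmark_report.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from neqpka.benchmark import BenchmarkRecord, aue, class_breakdown, null_model
from neqpka.cycle import PkaPrediction

N_BOOT = 2000


def main() -> None:
    truth = pd.read_csv(RESULTS / "synthetic_residues.csv")
    preds = pd.read_csv(RESULTS / "pka_predictions.csv")
    merged = preds.merge(truth[["residue", "true_pka"]], on="residue", validate="1:1")

    records = []
    for _, row in merged.iterrows():
        pred = PkaPrediction(
            pka=row["pred_neq"], se=row["se_neq"], protein=row["protein"],
            residue=row["residue"], res_class=row["class"], source="neq",
        )
        records.append(
            BenchmarkRecord(
                protein=row["protein"], residue=row["residue"], res_class=row["class"],
                experimental_pka=row["true_pka"], predictions={"neq": pred},
            )
        )

    reports = class_breakdown(records, "neq", n_boot=N_BOOT, seed=SEED)
    nulls = null_model(records)
    null_aue = aue(
        [nulls[r.key].pka for r in records], [r.experimental_pka for r in records]
    )

    payload = {
        name: {
            "aue": rep.aue, "aue_se": rep.aue_se,
            "pearson": rep.pearson, "pearson_se": rep.pearson_se, "n": rep.n,
        }
        for name, rep in reports.items()
    }
    payload["null_model"] = {"aue": null_aue, "n": len(records)}
    (RESULTS / "benchmark_report.json").write_text(json.dumps(payload, indent=2) + "\n")

    for name in ("ASP", "GLU", "LYS", "overall"):
        rep = reports[name]
        print(f"{name:>8}: AUE {rep.aue:.3f} +/- {rep.aue_se:.3f} pK, "
              f"r {rep.pearson:.3f} +/- {rep.pearson_se:.3f} (n={rep.n})")
    print(f"    null: AUE {null_aue:.3f} pK (predicting the class reference everywhere)")
    print(f"wrote {RESULTS / 'benchmark_report.json'}")


if __name__ == "__main__":
    main()
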