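"""Scoring predicted against experimental pKa values.

Metrics follow the conventions of pKa benchmark studies: average unsigned
error (AUE), Pearson correlation, residue-resampling bootstrap standard
errors, per-class breakdowns whose overall AUE is the mean of the per-class
AUEs, and a null model that predicts the class reference pKa° for every
residue (the zero-shift baseline any predictor must beat). A convergence
curve utility subsamples a WorkSet to show how the free-energy estimate
stabilizes with the number of transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cycle import DEFAULT_REFERENCES, PkaPrediction, ResidueClassRef
from .estimators import _bar_root
from .work_ingest import WorkSet

__all__ = [
    "BenchmarkRecord",
    "MetricReport",
    "aue",
    "pearson",
    "metric_bootstrap",
    "null_model",
    "class_breakdown",
    "convergence_curve",
]


@dataclass
class BenchmarkRecord:
    """One residue's experimental pKa and its predictions by source tag."""

    protein: str
    residue: str
    res_class: str
    experimental_pka: float
    predictions: dict[str, PkaPrediction] = field(default_factory=dict)
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.experimental_pka):
            raise ValueError("experimental pKa must be finite")
        if self.res_class not in DEFAULT_REFERENCES:
            raise ValueError(f"unknown residue class {self.res_class!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein, self.residue)


@dataclass(frozen=True)
class MetricReport:
    """AUE and Pearson r with bootstrap SEs for one prediction source."""

    aue: float
    aue_se: float
    pearson: float
    pearson_se: float
    n: int


def aue(pred: Sequence[float], expt: Sequence[float]) -> float:
    """Average unsigned error, mean |pred - expt|."""
    p = np.asarray(pred, dtype=float)
    e = np.asarray(expt, dtype=float)
    if p.size != e.size:
        raise ValueError(f"length mismatch: {p.size} vs {e.size}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(p - e)))


def pearson(pred: Sequence[float], expt: Sequence[float]) -> float:
    """Sample Pearson correlation; zero variance on either side is an error."""
    p = np.asarray(pred, dtype=float)
    e = np.asarray(expt, dtype=float)
    if p.size != e.size:
        raise ValueError(f"length mismatch: {p.size} vs {e.size}")
    if p.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(p) == 0 or np.ptp(e) == 0:
        raise ValueError("zero variance; Pearson correlation undefined")
    return float(stats.pearsonr(p, e).statistic)


def _extract(
    records: Sequence[BenchmarkRecord],
    source: str,
    allow_mixed_kinds: bool,
) -> tuple[np.ndarray, np.ndarray]:
    preds, expts, kinds = [], [], set()
    for r in records:
        if source not in r.predictions:
            raise KeyError(f"record {r.key} has no prediction from source {source!r}")
        p = r.predictions[source]
        kinds.add(p.kind)
        preds.append(p.pka)
        expts.append(r.experimental_pka)
    if len(kinds) > 1 and not allow_mixed_kinds:
        raise ValueError(
            f"records mix prediction kinds {sorted(kinds)}; pass allow_mixed_kinds=True "
            "to average standard and conditional estimates deliberately"
        )
    return np.asarray(preds), np.asarray(expts)


def metric_bootstrap(
    records: Sequence[BenchmarkRecord],
    source: str,
    n_boot: int = 1000,
    seed: int = 0,
    allow_mixed_kinds: bool = False,
) -> MetricReport:
    """AUE and Pearson r with residue-resampling bootstrap SEs.

    Records are resampled with replacement ``n_boot`` times; the SEs are the
    SDs of each metric over the resamples. Resamples with zero variance on
    either side (Pearson undefined) are skipped and counted; if every
    resample is degenerate an error is raised. Deterministic given ``seed``.
    """
    preds, expts = _extract(records, source, allow_mixed_kinds)
    n = preds.size
    if n < 2:
        raise ValueError("need at least 2 records")
    point_aue = aue(preds, expts)
    point_r = pearson(preds, expts)
    rng = np.random.default_rng(seed)
    aues = np.empty(n_boot)
    rs = []
    skipped = 0
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        aues[k] = np.mean(np.abs(preds[idx] - expts[idx]))
        if np.ptp(preds[idx]) == 0 or np.ptp(expts[idx]) == 0:
            skipped += 1
            continue
        rs.append(stats.pearsonr(preds[idx], expts[idx]).statistic)
    if not rs:
        raise ValueError("all bootstrap resamples degenerate; cannot estimate Pearson SE")
    if skipped:
        warnings.warn(f"{skipped} degenerate resamples skipped for Pearson", stacklevel=2)
    return MetricReport(
        aue=point_aue,
        aue_se=float(np.std(aues, ddof=1)),
        pearson=point_r,
        pearson_se=float(np.std(rs, ddof=1)),
        n=n,
    )


def null_model(
    records: Sequence[BenchmarkRecord],
    references: Mapping[str, ResidueClassRef] = DEFAULT_REFERENCES,
) -> dict[tuple[str, str], PkaPrediction]:
    """Zero-shift baseline: predict the class reference pKa° for every residue."""
    out: dict[tuple[str, str], PkaPrediction] = {}
    for r in records:
        if r.res_class not in references:
            raise ValueError(f"unknown residue class {r.res_class!r}")
        ref = references[r.res_class]
        out[r.key] = PkaPrediction(
            pka=ref.ref_pka, se=ref.ref_pka_se,
            protein=r.protein, residue=r.residue, res_class=r.res_class,
            kind="standard", source="null",
        )
    return out


def class_breakdown(
    records: Sequence[BenchmarkRecord],
    source: str,
    n_boot: int = 1000,
    seed: int = 0,
    residue_weighted: bool = False,
    allow_mixed_kinds: bool = False,
) -> dict[str, MetricReport]:
    """Per-class metric reports plus an ``"overall"`` summary.

    The overall AUE is the unweighted mean of the per-class AUEs (its SE the
    quadrature mean of the class SEs), matching the convention of averaging
    over residue classes; ``residue_weighted=True`` pools all residues
    instead. The overall Pearson is always computed on the pooled residues,
    since within-class and cross-class correlation are different quantities.
    """
    classes = sorted({r.res_class for r in records})
    out: dict[str, MetricReport] = {}
    for i, cls in enumerate(classes):
        sub = [r for r in records if r.res_class == cls]
        if len(sub) < 2:
            warnings.warn(f"class {cls} has <2 records; skipped", stacklevel=2)
            continue
        out[cls] = metric_bootstrap(
            sub, source, n_boot=n_boot, seed=seed + i, allow_mixed_kinds=allow_mixed_kinds
        )
    pooled = metric_bootstrap(
        records, source, n_boot=n_boot, seed=seed + len(classes),
        allow_mixed_kinds=allow_mixed_kinds,
    )
    if residue_weighted or not out:
        out["overall"] = pooled
    else:
        class_reports = [out[c] for c in out]
        k = len(class_reports)
        out["overall"] = MetricReport(
            aue=float(np.mean([m.aue for m in class_reports])),
            aue_se=float(np.sqrt(np.sum([m.aue_se**2 for m in class_reports])) / k),
            pearson=pooled.pearson,
            pearson_se=pooled.pearson_se,
            n=pooled.n,
        )
    return out


def convergence_curve(
    ws: WorkSet,
    n_grid: Sequence[int],
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """BAR estimate vs number of transitions, by repeated subsampling.

    For each n in ``n_grid``, draws ``reps`` subsamples of n forward and n
    reverse works without replacement and re-runs BAR; reports the mean and
    SD per n. The SD shrinking (to exactly 0 at the full set size, where
    only one subsample exists) is the convergence diagnostic.
    """
    n_grid = sorted(int(n) for n in n_grid)
    if n_grid[0] < 2:
        raise ValueError("subsample sizes must be >= 2")
    if n_grid[-1] > min(ws.n_forward, ws.n_reverse):
        raise ValueError("subsample size exceeds available transitions")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        vals = np.empty(reps)
        for k in range(reps):
            wf = rng.choice(ws.forward_works, size=n, replace=False)
            wr = rng.choice(ws.reverse_works, size=n, replace=False)
            vals[k] = _bar_root(wf, wr, ws.temperature)
        rows.append({"n": n, "mean_dg": float(np.mean(vals)), "sd_dg": float(np.std(vals, ddof=0))})
    return pd.DataFrame(rows)
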