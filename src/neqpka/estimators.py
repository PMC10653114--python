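"""Free-energy estimation from two-sided nonequilibrium work data.

The primary estimator is Bennett's acceptance ratio (BAR), implemented as
the maximum-likelihood estimator that follows from the Crooks fluctuation
theorem for pooled forward/reverse work samples. With
``M = ln(n_F / n_R) / beta`` the log-likelihood of the pooled sample is

    L(dG) = sum_F ln f(-beta (M + W_F - dG)) + sum_R ln f(beta (M - W_R - dG))

where ``f(x) = 1 / (1 + exp(x))`` and reverse works follow the
reverse-direction convention of :mod:`neqpka.work_ingest`. Its stationary
point is the Bennett self-consistency condition

    sum_F f(beta (M + W_F - dG)) = sum_R f(beta (W_R + dG - M)),

equivalent to Bennett's original ``dG = C + ln(n_F/n_R)/beta`` with C the
acceptance-ratio crossing point. This form is antisymmetric under swapping
the forward and reverse sets, invariant under duplicating every sample, and
exact (dG = c) in the dissipation-free limit W_F = {c}, W_R = {-c}.

Uncertainties are obtained by bootstrap, resampling the forward and reverse
sets independently with replacement, which is how the original analysis
propagated errors into the cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .constants import beta as _beta
from .work_ingest import WorkSet

__all__ = [
    "FreeEnergyEstimate",
    "bar_estimate",
    "bar_loglikelihood",
    "jarzynski_estimate",
    "bootstrap_se",
    "overlap_diagnostic",
    "LowOverlapWarning",
]

#: Overlap below this triggers a LowOverlapWarning on bar_estimate.
OVERLAP_WARN_THRESHOLD = 0.03

#: Absolute tolerance (kJ/mol) of the BAR root solve.
BAR_XTOL = 1e-8


class LowOverlapWarning(UserWarning):
    """Forward/reverse work distributions barely overlap; BAR may be unreliable."""


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG estimate (kJ/mol) for one alchemical leg, with provenance."""

    value: float
    se: float
    n_forward: int
    n_reverse: int
    estimator: str
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("non-finite free energy estimate")
        if self.se < 0 or not np.isfinite(self.se):
            raise ValueError("standard error must be finite and >= 0")


def _bar_imbalance(dg: float, wf: np.ndarray, wr: np.ndarray, b: float, m: float) -> float:
    # f(x) = 1/(1+e^x) = expit(-x); increasing in dg, so brentq brackets cleanly
    return float(expit(-b * (m + wf - dg)).sum() - expit(-b * (wr + dg - m)).sum())


def _bar_root(wf: np.ndarray, wr: np.ndarray, temperature: float) -> float:
    b = _beta(temperature)
    m = np.log(wf.size / wr.size) / b
    span = float(max(np.max(np.abs(wf)), np.max(np.abs(wr)))) + 50.0 / b
    lo, hi = -span, span
    flo = _bar_imbalance(lo, wf, wr, b, m)
    fhi = _bar_imbalance(hi, wf, wr, b, m)
    # widen if works are extreme enough to push the root outside the heuristic bracket
    while flo * fhi > 0 and span < 1e8:
        span *= 4.0
        lo, hi = -span, span
        flo = _bar_imbalance(lo, wf, wr, b, m)
        fhi = _bar_imbalance(hi, wf, wr, b, m)
    return float(brentq(_bar_imbalance, lo, hi, args=(wf, wr, b, m), xtol=BAR_XTOL))


def bar_estimate(
    ws: WorkSet,
    n_boot: int = 0,
    seed: int = 0,
    warn_on_low_overlap: bool = True,
) -> FreeEnergyEstimate:
    """BAR estimate of ΔG from a :class:`WorkSet`.

    Solves the Bennett self-consistency equation by bracketed Brent root
    finding to 1e-8 kJ/mol. If ``n_boot >= 2`` the standard error is the
    bootstrap SD over that many resamples (seeded); otherwise ``se = 0`` and
    a separate :func:`bootstrap_se` call can supply it.

    A :class:`LowOverlapWarning` (not an error) is attached when the
    forward/reverse work histograms barely overlap.
    """
    wf, wr = ws.forward_works, ws.reverse_works
    if warn_on_low_overlap and overlap_diagnostic(ws) < OVERLAP_WARN_THRESHOLD:
        warnings.warn(
            f"forward/reverse work overlap below {OVERLAP_WARN_THRESHOLD}; "
            "the BAR estimate may be dominated by tail samples",
            LowOverlapWarning,
            stacklevel=2,
        )
    value = _bar_root(wf, wr, ws.temperature)
    se = 0.0
    if n_boot >= 2:
        se = bootstrap_se(ws, "bar", n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(
        value=value,
        se=se,
        n_forward=ws.n_forward,
        n_reverse=ws.n_reverse,
        estimator="BAR",
        n_boot=n_boot,
        seed=seed,
    )


def bar_loglikelihood(ws: WorkSet, dg: float) -> float:
    """Crooks maximum-likelihood objective for BAR at a trial ΔG.

    Computed with an overflow-safe ``log(1+e^x)`` formulation; its argmax
    over dg coincides with the :func:`bar_estimate` root.
    """
    b = _beta(ws.temperature)
    m = np.log(ws.n_forward / ws.n_reverse) / b
    # ln f(x) = -log(1 + e^x) = -logaddexp(0, x)
    fwd = -np.logaddexp(0.0, -b * (m + ws.forward_works - dg))
    rev = -np.logaddexp(0.0, b * (m - ws.reverse_works - dg))
    return float(fwd.sum() + rev.sum())


def jarzynski_estimate(
    works: np.ndarray,
    temperature: float,
    direction: str = "forward",
) -> FreeEnergyEstimate:
    """One-sided exponential-average (Jarzynski) estimate of ΔG.

    ``dG = -ln<exp(-beta W)>/beta`` for forward works; for reverse works
    (reverse-direction convention) the same average estimates −ΔG and the
    sign is flipped. Computed via log-sum-exp. Used as a cross-check; the
    pipeline's production estimator is BAR.
    """
    w = np.asarray(works, dtype=float)
    if w.size == 0:
        raise ValueError("empty work list")
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite work values")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    b = _beta(temperature)
    dg = -(logsumexp(-b * w) - np.log(w.size)) / b
    tag = "JARZYNSKI_F"
    if direction == "reverse":
        dg = -dg
        tag = "JARZYNSKI_R"
    nf = w.size if direction == "forward" else 0
    nr = w.size if direction == "reverse" else 0
    return FreeEnergyEstimate(float(dg), 0.0, nf, nr, estimator=tag)


_POINT_ESTIMATORS: dict[str, Callable[[WorkSet], float]] = {
    "bar": lambda ws: _bar_root(ws.forward_works, ws.reverse_works, ws.temperature),
    "jarzynski_f": lambda ws: jarzynski_estimate(ws.forward_works, ws.temperature, "forward").value,
    "jarzynski_r": lambda ws: jarzynski_estimate(ws.reverse_works, ws.temperature, "reverse").value,
}


def bootstrap_se(
    ws: WorkSet,
    estimator: str | Callable[[WorkSet], float] = "bar",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a work-based ΔG estimator.

    Forward and reverse lists are resampled independently with replacement
    at their original sizes; the SE is the SD of the estimator over
    ``n_boot`` resamples. Deterministic given ``seed``. A resample on which
    the estimator fails is redrawn; if more than 1% fail a warning is
    emitted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = _POINT_ESTIMATORS[estimator] if isinstance(estimator, str) else estimator
    rng = np.random.default_rng(seed)
    wf, wr = ws.forward_works, ws.reverse_works
    values = np.empty(n_boot)
    failures = 0
    for k in range(n_boot):
        while True:
            sub = WorkSet(
                rng.choice(wf, size=wf.size, replace=True),
                rng.choice(wr, size=wr.size, replace=True),
                temperature=ws.temperature,
                label=ws.label,
            )
            try:
                values[k] = est(sub)
                break
            except Exception:
                failures += 1
                if failures > max(10, n_boot):
                    raise
    if failures > 0.01 * n_boot:
        warnings.warn(
            f"{failures} bootstrap resamples failed and were redrawn",
            UserWarning,
            stacklevel=2,
        )
    if np.ptp(values) == 0:  # degenerate limit: no resampling variance at all
        return 0.0
    return float(np.std(values, ddof=1))


def overlap_diagnostic(ws: WorkSet, n_bins: int = 50) -> float:
    """Histogram overlap of forward works and negated reverse works in [0, 1].

    Both samples are binned on a common grid spanning their pooled range;
    the overlap is the summed bin-wise minimum of the two probability
    masses: 0 for disjoint supports, approaching 1 for identical
    distributions.
    """
    wf = ws.forward_works
    wr = -ws.reverse_works  # map reverse works into the forward frame
    pooled = np.concatenate([wf, wr])
    lo, hi = float(np.min(pooled)), float(np.max(pooled))
    if lo == hi:  # all mass at a point: identical degenerate distributions
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pf, _ = np.histogram(wf, bins=edges)
    pr, _ = np.histogram(wr, bins=edges)
    return float(np.minimum(pf / wf.size, pr / wr.size).sum())
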