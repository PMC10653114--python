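"""pH-dependent treatment of interacting titratable sites.

When two titratable residues sit close together (e.g. an acidic dyad within
0.5 nm), the deprotonation of one shifts the free energy of deprotonating
the other, and a single intrinsic pKa no longer describes either site. This
module implements a grand-canonical microstate model for such a pair: with
intrinsic pKas ``pk_a``/``pk_b`` (each defined with the partner protonated)
and an interaction free energy ``w`` between the two deprotonated forms,
the four microstates have relative free energies

    G(HH) = 0
    G(H-) = g_b          (B deprotonated)
    G(-H) = g_a          (A deprotonated)
    G(--) = g_a + g_b + w

with ``g_x(pH) = R T ln10 * (pk_x - pH)``, so deprotonation of x is
favorable once pH exceeds its intrinsic pKa. Boltzmann-weighting the four
states gives each site's protonated-fraction marginal; ``w = 0`` recovers
the one-site Henderson-Hasselbalch curve exactly, and ``w > 0`` (mutually
disfavored deprotonations, the usual case for two acids) splits the proton
release into two separated apparent transitions.

Triads are reduced to dyads by fixing the site with the lowest intrinsic
pKa as the first deprotonation event and shifting the remaining intrinsic
pKas by their coupling to that now-deprotonated site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

from .constants import DEFAULT_TEMPERATURE, beta as _beta, rt_ln10
from .cycle import CycleResult, PkaPrediction, ResidueClassRef, _pka_arithmetic

__all__ = [
    "CoupledDyad",
    "TitrationCurve",
    "dyad_titration",
    "protonation_fractions",
    "apparent_pka",
    "reduce_triad",
    "hh_curve",
    "hh_fit",
    "conditional_pka",
    "interaction_energy",
]


@dataclass(frozen=True)
class CoupledDyad:
    """Two coupled titratable sites.

    ``pk_a``/``pk_b`` are intrinsic pKas referenced to the partner's
    protonated state; ``w`` (kJ/mol) is the extra free energy of the doubly
    deprotonated microstate (w > 0 = the two deprotonations disfavor each
    other).
    """

    pk_a: float
    pk_b: float
    w: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        vals = (self.pk_a, self.pk_b, self.w, self.temperature)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite dyad parameters")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class TitrationCurve:
    """Per-site protonated fractions over an ascending pH grid."""

    ph: np.ndarray
    frac_a: np.ndarray
    frac_b: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        fa = np.asarray(self.frac_a, dtype=float)
        fb = np.asarray(self.frac_b, dtype=float)
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "frac_a", fa)
        object.__setattr__(self, "frac_b", fb)
        if ph.size < 2 or fa.size != ph.size or fb.size != ph.size:
            raise ValueError("grid needs >= 2 points and matching fraction arrays")
        if not np.all(np.diff(ph) > 0):
            raise ValueError("pH grid must be strictly ascending")

    def fraction(self, site: str) -> np.ndarray:
        if site not in ("a", "b"):
            raise ValueError("site must be 'a' or 'b'")
        return self.frac_a if site == "a" else self.frac_b


def protonation_fractions(d: CoupledDyad, ph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann marginals of the 4-state dyad at each pH.

    Returns (frac_a_protonated, frac_b_protonated). Weights are computed
    relative to the minimum microstate free energy so normalization is exact
    at any coupling strength.
    """
    ph = np.atleast_1d(np.asarray(ph, dtype=float))
    scale = rt_ln10(d.temperature)
    g_a = scale * (d.pk_a - ph)
    g_b = scale * (d.pk_b - ph)
    # microstate order: HH, H- (B deprot), -H (A deprot), --
    g = np.stack([np.zeros_like(ph), g_b, g_a, g_a + g_b + d.w])
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite microstate free energies")
    b = _beta(d.temperature)
    g -= g.min(axis=0, keepdims=True)
    wts = np.exp(-b * g)
    z = wts.sum(axis=0)
    frac_a = (wts[0] + wts[1]) / z
    frac_b = (wts[0] + wts[2]) / z
    return frac_a, frac_b


def dyad_titration(d: CoupledDyad, ph_grid: np.ndarray) -> TitrationCurve:
    """Titration curve of a coupled dyad over a pH grid."""
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size < 2:
        raise ValueError("pH grid needs at least 2 points")
    frac_a, frac_b = protonation_fractions(d, ph)
    return TitrationCurve(ph, frac_a, frac_b)


def apparent_pka(curve: TitrationCurve, site: str = "a") -> float:
    """Half-protonation pH of one site's marginal titration curve.

    Located by monotone (PCHIP) interpolation of the marginal followed by
    Brent root refinement; raises if the fraction never crosses 0.5 within
    the grid, in which case a wider grid is needed.
    """
    frac = curve.fraction(site)
    resid = frac - 0.5
    sign_change = np.nonzero(resid[:-1] * resid[1:] <= 0)[0]
    exact = np.nonzero(resid == 0)[0]
    if exact.size:
        return float(curve.ph[exact[0]])
    if not sign_change.size:
        raise ValueError(
            "protonated fraction does not cross 0.5 within the pH grid; widen the grid"
        )
    interp = PchipInterpolator(curve.ph, resid)
    i = int(sign_change[0])
    return float(brentq(interp, curve.ph[i], curve.ph[i + 1], xtol=1e-8))


def reduce_triad(
    sites: Sequence[tuple[str, float]],
    couplings: Mapping[frozenset | tuple, float],
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[str, CoupledDyad]:
    """Reduce three coupled sites to a dyad via the most probable first
    deprotonation.

    The site with the lowest intrinsic pKa is taken to deprotonate first and
    is fixed in its deprotonated state; the remaining two sites form a
    :class:`CoupledDyad` whose intrinsic pKas are shifted by
    ``w(site, fixed) / (R T ln10)`` and whose coupling is the remaining pair
    interaction. A tie for the lowest pKa is an error requiring an explicit
    choice.
    """
    if len(sites) != 3:
        raise ValueError("reduce_triad requires exactly three sites")
    cmap = {frozenset(k): float(v) for k, v in couplings.items()}
    ids = [s[0] for s in sites]
    for i in range(3):
        for j in range(i + 1, 3):
            if frozenset((ids[i], ids[j])) not in cmap:
                raise ValueError(f"missing coupling for pair ({ids[i]}, {ids[j]})")
    pks = [s[1] for s in sites]
    lowest = min(pks)
    if sum(1 for p in pks if p == lowest) > 1:
        raise ValueError(
            "tie for the lowest intrinsic pKa; specify the first deprotonation explicitly"
        )
    order = sorted(range(3), key=lambda i: pks[i])
    fixed_id = ids[order[0]]
    scale = rt_ln10(temperature)
    (id_a, pk_a), (id_b, pk_b) = (sites[order[1]], sites[order[2]])
    pk_a += cmap[frozenset((id_a, fixed_id))] / scale
    pk_b += cmap[frozenset((id_b, fixed_id))] / scale
    dyad = CoupledDyad(pk_a, pk_b, cmap[frozenset((id_a, id_b))], temperature=temperature)
    return fixed_id, dyad


def hh_curve(ph: np.ndarray, pka: float) -> np.ndarray:
    """One-site Henderson-Hasselbalch protonated fraction."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - pka))


def hh_fit(ph: Sequence[float], fraction: Sequence[float]) -> tuple[float, float]:
    """Least-squares Henderson-Hasselbalch fit of a titration curve.

    Fits ``f(pH) = 1/(1 + 10^(pH - pKa))`` over the single parameter pKa and
    returns ``(pka, rss)``. Mirrors how NMR chemical-shift titrations are
    reduced to a pKa at the inflection point.
    """
    ph = np.asarray(ph, dtype=float)
    frac = np.asarray(fraction, dtype=float)
    if ph.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(frac) == 0:
        raise ValueError("all fractions equal; no titration information")
    p0 = float(ph[np.argmin(np.abs(frac - 0.5))])
    popt, _ = curve_fit(hh_curve, ph, frac, p0=[p0], maxfev=10000)
    pka = float(popt[0])
    rss = float(np.sum((hh_curve(ph, pka) - frac) ** 2))
    return pka, rss


def conditional_pka(
    cycle: CycleResult,
    ref: ResidueClassRef,
    condition: str,
    *,
    include_ref_error: bool = True,
    protein: str = "",
    residue: str = "",
    source: str = "",
) -> PkaPrediction:
    """pKa computed with a named neighbor state clamped (e.g. "HIS+ neighbor").

    Same arithmetic as the standard conversion; the ``conditional`` kind and
    the verbatim condition string keep such estimates from being silently
    averaged with standard ones downstream.
    """
    if not condition:
        raise ValueError("a conditional prediction requires a non-empty condition")
    pka, se = _pka_arithmetic(cycle, ref, include_ref_error)
    return PkaPrediction(
        pka=pka, se=se, protein=protein, residue=residue,
        res_class=ref.name, kind="conditional", condition=condition, source=source,
    )


def interaction_energy(dg_neighbor_protonated: float, dg_neighbor_deprotonated: float) -> float:
    """Pair interaction w from two conditional deprotonation free energies.

    Given the deprotonation free energy of a site with its neighbor clamped
    protonated and clamped deprotonated (each itself a cycle double
    difference), ``w = dG(neighbor deprotonated) - dG(neighbor protonated)``
    — the second difference G(--) - G(-H) - G(H-) + G(HH).
    """
    return dg_neighbor_deprotonated - dg_neighbor_protonated
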