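"""Thermodynamic cycle: from leg free energies to pKa predictions.

The cycle compares deprotonation of a residue in the protein against the
same residue in a capped reference peptide (the model compound whose pKa°
is known). The double difference

    ddG = dG_deprot(protein) - dG_deprot(peptide)

converts to a pKa shift through R*T*ln(10):

    pKa = pKa° + s * ddG / (R T ln 10)

with s = +1 for acids (ASP, GLU) and s = -1 for the base class (LYS). The
sign handling lives here so that WorkSets always describe the deprotonation
direction regardless of residue class. Leg uncertainties propagate in
quadrature; the reference constant's uncertainty is included by default and
can be dropped to mirror analyses that propagate only the bootstrap errors.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .constants import rt_ln10
from .estimators import FreeEnergyEstimate

__all__ = [
    "ResidueClassRef",
    "CycleResult",
    "PkaPrediction",
    "DEFAULT_REFERENCES",
    "ACID_CLASSES",
    "BASE_CLASSES",
    "class_sign",
    "ddg_from_legs",
    "pka_from_ddg",
    "pk_int_from_ddg",
    "ddg_from_pka",
    "consensus",
    "load_references",
]


@dataclass(frozen=True)
class ResidueClassRef:
    """Reference (model-compound) pKa° of a titratable residue class."""

    name: str
    ref_pka: float
    ref_pka_se: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_pka_se < 0:
            raise ValueError("ref_pka_se must be >= 0")


#: Model-compound constants for the three probed classes (overridable).
DEFAULT_REFERENCES: dict[str, ResidueClassRef] = {
    "ASP": ResidueClassRef("ASP", 3.94, 0.03),
    "GLU": ResidueClassRef("GLU", 4.25, 0.05),
    "LYS": ResidueClassRef("LYS", 10.4, 0.08),
}

ACID_CLASSES = frozenset({"ASP", "GLU"})
BASE_CLASSES = frozenset({"LYS"})


def class_sign(res_class: str) -> int:
    """+1 for acid classes, -1 for base classes (deprotonation convention)."""
    if res_class in ACID_CLASSES:
        return 1
    if res_class in BASE_CLASSES:
        return -1
    raise ValueError(f"unknown residue class {res_class!r}")


@dataclass(frozen=True)
class CycleResult:
    """ΔΔG (protein leg minus peptide leg) with quadrature-propagated SE."""

    ddg: float
    se: float
    protein_leg: FreeEnergyEstimate
    peptide_leg: FreeEnergyEstimate
    temperature: float


@dataclass(frozen=True)
class PkaPrediction:
    """A pKa value with uncertainty and its conditioning metadata.

    ``kind`` distinguishes standard predictions, intrinsic pKas (environment
    fixed, pH-independent), conditional predictions (a named neighbor state)
    and coupled-apparent values from titration-curve marginals, so the
    benchmark never silently mixes them.
    """

    pka: float
    se: float
    protein: str = ""
    residue: str = ""
    res_class: str = ""
    kind: str = "standard"
    condition: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pka) and np.isfinite(self.se)):
            raise ValueError("non-finite pKa prediction")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def ddg_from_legs(
    protein: FreeEnergyEstimate,
    peptide: FreeEnergyEstimate,
    temperature: float,
    *,
    leg_temperatures: tuple[float, float] | None = None,
) -> CycleResult:
    """Close the cycle: ΔΔG = protein ΔG − peptide ΔG, SEs in quadrature."""
    if leg_temperatures is not None:
        tp, ts = leg_temperatures
        if not math.isclose(tp, ts, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError(f"leg temperatures differ: {tp} K vs {ts} K")
        if not math.isclose(tp, temperature, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError("cycle temperature does not match leg temperature")
    ddg = protein.value - peptide.value
    se = math.hypot(protein.se, peptide.se)
    return CycleResult(ddg=ddg, se=se, protein_leg=protein, peptide_leg=peptide, temperature=temperature)


def _pka_arithmetic(
    cycle: CycleResult,
    ref: ResidueClassRef,
    include_ref_error: bool,
) -> tuple[float, float]:
    s = class_sign(ref.name)
    scale = rt_ln10(cycle.temperature)
    pka = ref.ref_pka + s * cycle.ddg / scale
    var = (cycle.se / scale) ** 2
    if include_ref_error:
        var += ref.ref_pka_se**2
    return pka, math.sqrt(var)


def pka_from_ddg(
    cycle: CycleResult,
    ref: ResidueClassRef,
    *,
    include_ref_error: bool = True,
    protein: str = "",
    residue: str = "",
    source: str = "",
) -> PkaPrediction:
    """Convert a cycle ΔΔG to a standard pKa prediction.

    ``include_ref_error=False`` reproduces pipelines that propagate only the
    bootstrap leg uncertainties and treat pKa° as exact.
    """
    pka, se = _pka_arithmetic(cycle, ref, include_ref_error)
    return PkaPrediction(
        pka=pka, se=se, protein=protein, residue=residue,
        res_class=ref.name, kind="standard", source=source,
    )


def pk_int_from_ddg(
    cycle: CycleResult,
    ref: ResidueClassRef,
    *,
    include_ref_error: bool = True,
    protein: str = "",
    residue: str = "",
    source: str = "",
) -> PkaPrediction:
    """Intrinsic pKa (pK_int) from a cycle computed with the neighborhood
    protonation states fixed, so the environment term is pH independent.

    The arithmetic is identical to :func:`pka_from_ddg`; only the ``kind``
    tag differs, which downstream averaging respects.
    """
    pka, se = _pka_arithmetic(cycle, ref, include_ref_error)
    return PkaPrediction(
        pka=pka, se=se, protein=protein, residue=residue,
        res_class=ref.name, kind="intrinsic", source=source,
    )


def ddg_from_pka(pka: float, ref: ResidueClassRef, temperature: float) -> float:
    """Invert the pKa relation back to a cycle ΔΔG in kJ/mol."""
    return class_sign(ref.name) * (pka - ref.ref_pka) * rt_ln10(temperature)


def consensus(
    predictions: Sequence[PkaPrediction],
    *,
    inverse_variance: bool = False,
) -> PkaPrediction:
    """Combine per-force-field predictions of one residue into a consensus.

    Default is the unweighted mean of the pKa values with
    ``se = sqrt(sum se_i^2) / k``; ``inverse_variance=True`` switches to
    precision weighting (requires strictly positive SEs).
    """
    if len(predictions) == 0:
        raise ValueError("need at least one prediction")
    first = predictions[0]
    for p in predictions[1:]:
        if (p.protein, p.residue, p.res_class) != (first.protein, first.residue, first.res_class):
            raise ValueError("consensus inputs must describe the same residue")
        if p.kind != first.kind:
            raise ValueError("consensus inputs must share the same kind")
    vals = np.array([p.pka for p in predictions])
    ses = np.array([p.se for p in predictions])
    if inverse_variance:
        if np.any(ses <= 0):
            raise ValueError("inverse-variance weighting requires positive SEs")
        w = 1.0 / ses**2
        pka = float(np.sum(w * vals) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
    else:
        pka = float(np.mean(vals))
        se = float(np.sqrt(np.sum(ses**2)) / len(predictions))
    return replace(first, pka=pka, se=se, source="consensus")


def load_references(path: str | os.PathLike) -> dict[str, ResidueClassRef]:
    """Load reference pKa° overrides from a YAML or JSON config.

    Expected mapping: ``{CLASS: {ref_pka: float, ref_pka_se: float}}``;
    classes not listed keep their defaults.
    """
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    refs = dict(DEFAULT_REFERENCES)
    for name, entry in data.items():
        name = name.upper()
        refs[name] = ResidueClassRef(
            name, float(entry["ref_pka"]), float(entry.get("ref_pka_se", 0.0))
        )
    return refs
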