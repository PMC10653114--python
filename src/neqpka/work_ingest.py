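"""Ingestion of nonequilibrium work data.

Two entry formats are supported:

* GROMACS XVG text files holding one dH/dλ curve per alchemical transition;
  the work of the transition is obtained by thermodynamic integration
  (trapezoidal rule over λ).
* CSV tables of pre-integrated work values, one row per transition, with
  header ``transition,work_kjmol``.

Sign convention
---------------
Forward works are recorded along the forward transition (λ: 0 → 1, e.g.
protonated → deprotonated). Each reverse work is recorded as the work done
along the reverse transition *in its own direction* (λ: 1 → 0), so that the
Crooks fluctuation theorem reads ``P_F(W) / P_R(-W) = exp(beta * (W - dG))``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import KCAL_TO_KJ

__all__ = [
    "DhdlCurve",
    "WorkSet",
    "read_xvg",
    "integrate_dhdl",
    "load_workset",
    "write_workset",
]

_XVG_COMMENT = ("#", "@")


@dataclass(frozen=True)
class DhdlCurve:
    """A single dH/dλ curve from one alchemical transition.

    Parameters
    ----------
    lambdas : array-like
        Strictly monotone coupling-parameter values in [0, 1]; ascending
        (0 → 1) for a forward transition, descending (1 → 0) for a reverse
        one.
    dhdl : array-like
        dH/dλ in kJ/mol at each λ.
    direction : {"forward", "reverse"}
    """

    lambdas: np.ndarray
    dhdl: np.ndarray
    direction: str = "forward"

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        dh = np.asarray(self.dhdl, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "dhdl", dh)
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if lam.ndim != 1 or dh.ndim != 1 or lam.size != dh.size:
            raise ValueError("lambdas and dhdl must be 1-D and equal length")
        if lam.size < 2:
            raise ValueError("a dH/dl curve needs at least 2 points")
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(dh))):
            raise ValueError("non-finite values in dH/dl curve")
        dlam = np.diff(lam)
        if self.direction == "forward":
            if not np.all(dlam > 0):
                raise ValueError("forward curve requires strictly increasing lambda")
            lo, hi = lam[0], lam[-1]
        else:
            if not np.all(dlam < 0):
                raise ValueError("reverse curve requires strictly decreasing lambda")
            lo, hi = lam[-1], lam[0]
        if not (math.isclose(lo, 0.0, abs_tol=1e-9) and math.isclose(hi, 1.0, abs_tol=1e-9)):
            raise ValueError("lambda endpoints must be 0 and 1")

    def __len__(self) -> int:
        return int(self.lambdas.size)


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse nonequilibrium work samples for one alchemical leg.

    Reverse works follow the reverse-direction convention documented in the
    module docstring; both lists must be non-empty and finite so a two-sided
    (BAR) estimate is always possible.
    """

    forward_works: np.ndarray
    reverse_works: np.ndarray
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        fw = np.asarray(self.forward_works, dtype=float)
        rv = np.asarray(self.reverse_works, dtype=float)
        object.__setattr__(self, "forward_works", fw)
        object.__setattr__(self, "reverse_works", rv)
        if fw.size == 0 or rv.size == 0:
            raise ValueError("both forward and reverse work lists must be non-empty")
        if not (np.all(np.isfinite(fw)) and np.all(np.isfinite(rv))):
            raise ValueError("non-finite work values")
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def n_forward(self) -> int:
        return int(self.forward_works.size)

    @property
    def n_reverse(self) -> int:
        return int(self.reverse_works.size)


def read_xvg(
    path: str | os.PathLike,
    direction: str = "forward",
    time_as_lambda: bool = False,
) -> DhdlCurve:
    """Parse a GROMACS XVG file into a :class:`DhdlCurve`.

    Lines beginning with ``#`` or ``@`` are comments/legends and are ignored
    wherever they appear. Data lines are whitespace-separated pairs; the
    first column is λ, or — with ``time_as_lambda=True`` — a time stamp that
    is mapped linearly onto λ ∈ [0, 1] (reversed for reverse transitions).

    Raises
    ------
    ValueError
        On a non-numeric data line (the message names the line number) or
        fewer than two data rows.
    """
    path = Path(path)
    lambdas: list[float] = []
    dhdl: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_XVG_COMMENT):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric data {line!r}") from exc
            lambdas.append(x)
            dhdl.append(y)
    if len(lambdas) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    lam = np.asarray(lambdas, dtype=float)
    if time_as_lambda:
        span = lam[-1] - lam[0]
        if span == 0:
            raise ValueError(f"{path}: zero time span, cannot map onto lambda")
        lam = (lam - lam[0]) / span
        if direction == "reverse":
            lam = 1.0 - lam
    return DhdlCurve(lam, np.asarray(dhdl), direction=direction)


def integrate_dhdl(curve: DhdlCurve) -> float:
    """Work of one transition by thermodynamic integration.

    The trapezoidal rule is applied along the curve's own λ path, so a
    reverse curve (λ descending 1 → 0) yields the reverse-direction work
    directly, consistent with the package-wide sign convention.
    """
    return float(np.trapezoid(curve.dhdl, curve.lambdas))


def _works_from_source(
    source: str | os.PathLike | Sequence[float],
    direction: str,
    time_as_lambda: bool,
    unit: str,
) -> np.ndarray:
    """Collect work values from a directory of XVGs, a CSV file, or a sequence."""
    if isinstance(source, (str, os.PathLike)):
        p = Path(source)
        if p.is_dir():
            files = sorted(p.glob("*.xvg"))
            if not files:
                raise ValueError(f"no .xvg files in {p}")
            works = np.array(
                [
                    integrate_dhdl(read_xvg(f, direction=direction, time_as_lambda=time_as_lambda))
                    for f in files
                ]
            )
        elif p.is_file():
            table = pd.read_csv(p, float_precision="round_trip")
            if "work_kjmol" not in table.columns:
                raise ValueError(f"{p}: expected a 'work_kjmol' column, got {list(table.columns)}")
            if len(table) == 0:
                raise ValueError(f"{p}: empty work table")
            works = table["work_kjmol"].to_numpy(dtype=float)
        else:
            raise ValueError(f"source {p} is neither a directory nor a file")
    else:
        works = np.asarray(list(source), dtype=float)
        if works.size == 0:
            raise ValueError("empty work sequence")
    if unit == "kcal/mol":
        works = works * KCAL_TO_KJ
    elif unit != "kJ/mol":
        raise ValueError(f"unknown unit {unit!r}; use 'kJ/mol' or 'kcal/mol'")
    return works


def load_workset(
    forward_source: str | os.PathLike | Sequence[float],
    reverse_source: str | os.PathLike | Sequence[float],
    temperature: float,
    label: str = "",
    time_as_lambda: bool = False,
    unit: str = "kJ/mol",
) -> WorkSet:
    """Assemble a :class:`WorkSet` from XVG directories, CSV tables, or values.

    Both sources must use the same unit; pass ``unit="kcal/mol"`` to convert
    kcal input explicitly (×4.184).
    """
    fw = _works_from_source(forward_source, "forward", time_as_lambda, unit)
    rv = _works_from_source(reverse_source, "reverse", time_as_lambda, unit)
    return WorkSet(fw, rv, temperature=temperature, label=label)


def write_workset(ws: WorkSet, forward_csv: str | os.PathLike, reverse_csv: str | os.PathLike) -> None:
    """Write forward/reverse works to two CSV tables.

    Values are written with ``repr`` (shortest round-tripping decimal), so a
    write → read cycle reproduces the floats bit-for-bit.
    """
    for path, works in ((forward_csv, ws.forward_works), (reverse_csv, ws.reverse_works)):
        with open(path, "w") as fh:
            fh.write("transition,work_kjmol\n")
            for i, w in enumerate(works):
                fh.write(f"{i},{float(w)!r}\n")
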