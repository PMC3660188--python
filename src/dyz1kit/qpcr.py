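"""Absolute quantification by real-time PCR standard curves.

A dilution series of a plasmid standard with known copy numbers gives
quantification cycles (Ct) that are linear in log10(copies) under
constant amplification efficiency:

    ct = intercept + slope * log10(copies)

The curve is fitted by ordinary least squares of Ct on log10(copies)
(replicates enter as individual points).  Amplification efficiency
follows from the slope as ``10**(-1/slope) - 1``; a ten-fold series at
100% efficiency has slope -1/log10(2) = -3.3219... (prints as -3.32).
Unknowns are quantified by inverting the line, and copy counts are
normalised to copies per genome-equivalent input mass (3.3 pg, one
haploid human genome, by default).

Ct values are inputs; no fluorescence-trace processing is done here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import read_table

GENOME_EQUIVALENT_PG = 3.3

__all__ = [
    "GENOME_EQUIVALENT_PG",
    "DilutionPoint",
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "efficiency",
    "quantify",
    "copies_per_genome",
    "quantify_samples",
    "read_dilution_table",
    "read_unknowns_table",
]


@dataclasses.dataclass(frozen=True)
class DilutionPoint:
    """One well of the standard dilution series."""

    known_copies: float
    ct: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if not self.known_copies > 0:
            raise ValueError(f"known_copies must be > 0, got {self.known_copies}")
        if not np.isfinite(self.ct):
            raise ValueError(f"ct must be finite, got {self.ct}")


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct = intercept + slope * log10(copies) line.

    ``efficiency`` is the per-cycle amplification fraction implied by
    the slope; ``warnings`` flags curves of unacceptable quality
    (r^2 < 0.99 or slope outside [-3.6, -3.1], i.e. efficiency roughly
    outside 90-110%).
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int
    warnings: tuple[str, ...] = ()


def efficiency(slope: float) -> float:
    """Amplification efficiency implied by a standard-curve slope:
    10**(-1/slope) - 1 (1.0 == 100% doubling per cycle)."""
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10 ** (-1.0 / slope) - 1.0


def fit_standard_curve(points: Iterable[DilutionPoint]) -> StandardCurve:
    """Least-squares fit of Ct on log10(known copies).

    Requires at least three distinct copy levels.
    """
    points = list(points)
    levels = sorted({p.known_copies for p in points})
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct copy levels, got {len(levels)}"
        )
    x = np.log10([p.known_copies for p in points])
    y = np.array([p.ct for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in copy numbers")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    warns = []
    if r2 < 0.99:
        warns.append(f"r_squared {r2:.4f} < 0.99")
    if not (-3.6 <= fit.slope <= -3.1):
        warns.append(f"slope {fit.slope:.3f} outside [-3.6, -3.1]")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency=efficiency(float(fit.slope)) if fit.slope < 0 else float("nan"),
        n_points=len(points),
        warnings=tuple(warns),
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Copies per reaction for an observed Ct, by inverting the curve:
    copies = 10**((ct - intercept) / slope)."""
    if not isinstance(curve, StandardCurve):
        raise TypeError("quantify requires a fitted StandardCurve")
    return float(10 ** ((ct - curve.intercept) / curve.slope))


def copies_per_genome(
    copies: float, input_mass_pg: float, genome_mass_pg: float = GENOME_EQUIVALENT_PG
) -> float:
    """Normalise copies per reaction to copies per genome-equivalent
    mass of input DNA (default 3.3 pg)."""
    if input_mass_pg <= 0:
        raise ValueError(f"input mass must be positive, got {input_mass_pg}")
    if genome_mass_pg <= 0:
        raise ValueError(f"genome mass must be positive, got {genome_mass_pg}")
    return copies * genome_mass_pg / input_mass_pg


@dataclasses.dataclass(frozen=True)
class QuantResult:
    """Absolute quantification of one unknown reaction."""

    sample: str
    ct: float
    copies_per_reaction: float
    input_mass_pg: float
    copies_per_genome_equivalent: float


def quantify_samples(
    unknowns: pd.DataFrame,
    curve: StandardCurve,
    genome_mass_pg: float = GENOME_EQUIVALENT_PG,
) -> list[QuantResult]:
    """Quantify an unknowns table (columns sample, ct, input_mass_pg)."""
    required = {"sample", "ct", "input_mass_pg"}
    if not required <= set(unknowns.columns):
        raise ValueError(f"unknowns table missing columns {sorted(required - set(unknowns.columns))}")
    out = []
    for row in unknowns.itertuples(index=False):
        ct = float(row.ct)
        mass = float(row.input_mass_pg)
        copies = quantify(ct, curve)
        out.append(
            QuantResult(
                sample=str(row.sample),
                ct=ct,
                copies_per_reaction=copies,
                input_mass_pg=mass,
                copies_per_genome_equivalent=copies_per_genome(copies, mass, genome_mass_pg),
            )
        )
    return out


def read_dilution_table(path: str | Path) -> list[DilutionPoint]:
    """Read a dilution TSV: known_copies, ct, replicate."""
    df = read_table(path)
    required = {"known_copies", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"dilution table missing columns {sorted(required - set(df.columns))}")
    return [
        DilutionPoint(
            known_copies=float(row.known_copies),
            ct=float(row.ct),
            replicate=str(getattr(row, "replicate", "")),
        )
        for row in df.itertuples(index=False)
    ]


def read_unknowns_table(path: str | Path) -> pd.DataFrame:
    """Read an unknowns TSV: sample, ct, input_mass_pg."""
    return read_table(path)
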