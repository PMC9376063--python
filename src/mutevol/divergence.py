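"""Genomic divergence and the rate of genomic evolution.

Divergence at a timepoint is the sum of derived allele frequencies of all
detected mutations; the evolution rate is the slope of a zero-intercept
least-squares regression of divergence on generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import DivergenceSeries

__all__ = [
    "DivergenceSeries",
    "EvolutionRate",
    "divergence_at_timepoint",
    "evolution_rate",
]


def divergence_at_timepoint(allele_frequencies: Sequence[float]) -> float:
    """Sum of derived allele frequencies at one timepoint."""
    freqs = np.asarray(allele_frequencies, dtype=float)
    if freqs.size and ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(freqs.sum())


@dataclass(frozen=True)
class EvolutionRate:
    """Zero-intercept regression slope with its standard error."""

    slope: float  # divergence per generation
    stderr: float
    n_points: int


def evolution_rate(series: DivergenceSeries) -> EvolutionRate:
    """Rate of genomic evolution: divergence ~ generations + 0.

    slope = sum(x*y) / sum(x^2); the slope standard error uses n - 1
    residual degrees of freedom (the no-intercept model class).
    """
    x = np.asarray(series.generations, dtype=float)
    y = np.asarray(series.divergence, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two timepoints")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("all generation values are zero")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    dof = x.size - 1
    sigma2 = float(np.dot(resid, resid)) / dof if dof > 0 else 0.0
    return EvolutionRate(
        slope=slope, stderr=math.sqrt(sigma2 / sxx), n_points=x.size
    )
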