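"""Serial-transfer demography: census trajectories, harmonic-mean effective
population size, and generations per day."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class TransferScheme:
    """A serial-dilution regime.

    dilution_factor: fraction of the culture carried over at each transfer.
    period_days: days between transfers.
    carrying_capacity: cells per culture at saturation.
    """

    dilution_factor: float
    period_days: int = 1
    carrying_capacity: float = 1e10

    def __post_init__(self):
        if not 0 < self.dilution_factor < 1:
            raise ValueError("dilution factor must be in (0, 1)")
        if self.period_days < 1:
            raise ValueError("transfer period must be >= 1 day")
        if self.carrying_capacity * self.dilution_factor < 1:
            raise ValueError("bottleneck must hold at least one cell")


def census_trajectory(scheme: TransferScheme) -> list[float]:
    """Census snapshots through one growth cycle.

    Starting from the bottleneck N0 = K*D, the population doubles until it
    saturates: the snapshots are N0 * 2^i for every doubling strictly below
    the carrying capacity, followed by the carrying capacity itself.
    """
    n0 = scheme.carrying_capacity * scheme.dilution_factor
    sizes: list[float] = []
    n = n0
    while n < scheme.carrying_capacity:
        sizes.append(n)
        n *= 2
    sizes.append(scheme.carrying_capacity)
    return sizes


def harmonic_ne(trajectory: Sequence[float]) -> float:
    """Harmonic mean of census population sizes (the serial-transfer Ne)."""
    if len(trajectory) == 0:
        raise ValueError("empty census trajectory")
    if any(n < 1 for n in trajectory):
        raise ValueError("census sizes must be >= 1")
    return len(trajectory) / sum(1.0 / n for n in trajectory)


def effective_size(scheme: TransferScheme) -> float:
    """Ne of a transfer scheme: harmonic mean over its census trajectory."""
    return harmonic_ne(census_trajectory(scheme))


def generations_per_day(scheme: TransferScheme) -> float:
    """Doublings needed to recover the dilution, averaged over the period.

    A dilution by D requires log2(1/D) doublings to restore the carrying
    capacity, so the per-day rate is log2(1/D) / period.
    """
    return math.log2(1.0 / scheme.dilution_factor) / scheme.period_days
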