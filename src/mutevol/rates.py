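"""Mutation-rate estimation for mutation-accumulation (MA) lines.

Per-line rates are simple quotients: per-site-per-generation rates for SNMs
and small indels (m / (G * n)) and per-genome-per-generation rates for
structural variants (m / G).  Lines with outlying rates are excluded by a
single-pass Z-score cutoff computed within each progenitor group, and groups
are compared by fold change plus a two-tailed unpaired t-test.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationCall, log_stage


@dataclass
class MALine:
    """One bottlenecked MA lineage."""

    line_id: str
    progenitor_id: str
    generations: float  # total generations elapsed (G)
    covered_sites: int  # ancestral sites covered at high quality (n)
    excluded: dict = field(default_factory=dict)  # per-mclass exclusion flags

    def __post_init__(self):
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        if self.covered_sites <= 0:
            raise ValueError("covered_sites must be > 0")


@dataclass(frozen=True)
class PassageRecord:
    """Generations-per-passage measurements at days 0, 30, and the last day."""

    g0: float
    g30: float
    g_final: float
    n_days: int

    def __post_init__(self):
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if min(self.g0, self.g30, self.g_final) <= 0:
            raise ValueError("generation estimates must be positive")


def passage_generations(rec: PassageRecord) -> float:
    """Weighted mean generations per passage over an MA experiment.

    The early (day 0-30) estimate gets weight a = 15 and the late estimate
    weight b = N/2 - 15, each applied to the mean of its bracketing
    measurements:

        G = ((G0 + G30) * a + (G30 + GN) * b) / N,   a = 15, b = N/2 - 15
    """
    if rec.n_days < 30:
        raise ValueError("weighting undefined for experiments shorter than 30 days")
    a = 15.0
    b = rec.n_days / 2.0 - 15.0
    return ((rec.g0 + rec.g30) * a + (rec.g30 + rec.g_final) * b) / rec.n_days


def site_rate(m: int, generations: float, sites: int) -> float:
    """Per-site per-generation mutation rate: u = m / (G * n)."""
    if generations <= 0 or sites <= 0:
        raise ValueError("generations and sites must be positive")
    if m < 0:
        raise ValueError("mutation count must be non-negative")
    return m / (generations * sites)


def genome_rate(m: int, generations: float) -> float:
    """Per-genome per-generation mutation rate: u = m / G."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    if m < 0:
        raise ValueError("mutation count must be non-negative")
    return m / generations


def zscore_exclude(
    rates: Sequence[float], cutoff: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier exclusion within one progenitor group.

    Z = (u - U) / S with U the mean and S the sample (n-1) standard
    deviation over ALL lines of the progenitor; a line is excluded iff
    |Z| > cutoff.  Returns boolean masks (kept, excluded).  With zero
    spread all Z are defined as 0, so nothing is excluded.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least two lines for outlier exclusion")
    mean = rates.mean()
    sd = rates.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(rates)
    else:
        z = (rates - mean) / sd
    excluded = np.abs(z) > cutoff
    log_stage("zscore_exclude", rates.size, int((~excluded).sum()))
    return ~excluded, excluded


@dataclass
class RateComparison:
    """Fold change and unpaired t-test between two groups of line rates."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change: float
    t_stat: float
    p_value: float
    direction: str  # "increase" if mean_a > mean_b else "decrease"
    n_a: int
    n_b: int


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def compare_groups(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = True,
) -> RateComparison:
    """Compare mean rates of two groups of MA lines.

    fold_change = mean_a / mean_b; the p-value comes from a two-tailed
    unpaired t-test (Welch unequal-variance by default, Student's by flag).
    Two degenerate equal constant groups give t = 0, p = 1.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two lines")
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=not welch)
    if math.isnan(t_stat):
        # both groups constant: equal means -> no evidence of difference
        if a.mean() == b.mean():
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = math.inf * math.copysign(1, a.mean() - b.mean()), 0.0
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_a / mean_b if mean_b != 0 else math.nan
    return RateComparison(
        group_a=label_a,
        group_b=label_b,
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=_sem(a),
        sem_b=_sem(b),
        fold_change=fold,
        t_stat=float(t_stat),
        p_value=float(p_value),
        direction="increase" if mean_a > mean_b else "decrease",
        n_a=a.size,
        n_b=b.size,
    )


def rate_table(
    calls: Iterable[MutationCall],
    lines: Sequence[MALine],
    zscore_cutoff: Optional[float] = 2.5,
) -> pd.DataFrame:
    """Per-line mutation counts and rates, one row per (line, class).

    SNM/SIM rates are per site per generation (u = m/(G*n)); SV rates are
    per genome per generation (u = m/G).  When ``zscore_cutoff`` is given,
    the Z-score exclusion is applied per progenitor and per mutation class
    independently, and flagged in the ``excluded`` column.
    """
    counts: Counter = Counter()
    for call in calls:
        counts[(call.line_id, call.mclass)] += 1
    rows = []
    for line in lines:
        for mclass in ("SNM", "SIM", "SV"):
            m = counts.get((line.line_id, mclass), 0)
            if mclass == "SV":
                u = genome_rate(m, line.generations)
            else:
                u = site_rate(m, line.generations, line.covered_sites)
            rows.append(
                {
                    "line_id": line.line_id,
                    "progenitor_id": line.progenitor_id,
                    "mclass": mclass,
                    "m": m,
                    "generations": line.generations,
                    "covered_sites": line.covered_sites,
                    "u": u,
                    "excluded": False,
                }
            )
    table = pd.DataFrame(rows)
    if zscore_cutoff is not None and not table.empty:
        for (_, _), idx in table.groupby(["progenitor_id", "mclass"]).groups.items():
            sub = table.loc[idx]
            if len(sub) < 2:
                continue
            _, excl = zscore_exclude(sub["u"].to_numpy(), cutoff=zscore_cutoff)
            table.loc[idx, "excluded"] = excl
    return table


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and line count per (progenitor, class), excluded lines dropped."""
    kept = table[~table["excluded"]]
    rows = []
    for (prog, mclass), sub in kept.groupby(["progenitor_id", "mclass"]):
        u = sub["u"].to_numpy()
        rows.append(
            {
                "progenitor_id": prog,
                "mclass": mclass,
                "mean_u": u.mean(),
                "sem_u": _sem(u),
                "n_lines": len(u),
            }
        )
    return pd.DataFrame(rows)
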