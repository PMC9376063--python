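"""Mutation patterns by non-negative matrix factorization of 96-class spectra.

The 96 x samples count matrix is factorized as V ~ W @ H (patterns x
exposures) under the generalized Kullback-Leibler divergence with
multiplicative updates, keeping the best of several random restarts.  The
number of patterns is chosen where the cophenetic correlation coefficient of
restart-consensus clustering starts to decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

MAX_ITER = 10_000
TOL = 1e-8


def _gkl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH)."""
    mask = V > 0
    WH = np.maximum(WH, 1e-300)
    return float(
        (V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum()
    )


@dataclass
class PatternModel:
    """NMF factorization of a 96 x samples matrix."""

    patterns: np.ndarray  # W, 96 x k, columns sum to 1
    exposures: np.ndarray  # H, k x samples
    rank: int
    objective: float  # generalized KL divergence at the optimum
    restarts: int
    seed: int
    sample_names: list = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        return self.patterns @ self.exposures


@dataclass
class RankSelection:
    """Cophenetic coefficients per candidate rank and the chosen rank."""

    ranks: list
    coefficients: list
    chosen: int
    no_decrease: bool = False  # no rank showed a decrease; largest returned


def _check_matrix(V: np.ndarray, sample_names: Optional[Sequence[str]]):
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("count matrix must be 2-D (classes x samples)")
    if (V < 0).any():
        raise ValueError("count matrix must be non-negative")
    zero = np.nonzero(V.sum(axis=0) == 0)[0]
    if zero.size:
        names = (
            [sample_names[i] for i in zero] if sample_names else list(zero)
        )
        raise ValueError(f"all-zero sample(s): {names}")
    return V


def _fit_once(V: np.ndarray, rank: int, random_state: int,
              max_iter: int = MAX_ITER, beta_loss: str = "kullback-leibler"
              ) -> tuple[np.ndarray, np.ndarray, float]:
    model = NMF(
        n_components=rank,
        init="random",
        solver="mu",
        beta_loss=beta_loss,
        max_iter=max_iter,
        tol=TOL,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(V)
    H = model.components_
    return W, H, _gkl_divergence(V, W @ H)


def nmf(
    count_matrix,
    rank: int,
    restarts: int = 10,
    seed: int = 0,
    beta_loss: str = "kullback-leibler",
    sample_names: Optional[Sequence[str]] = None,
) -> PatternModel:
    """Factorize a classes x samples count matrix into ``rank`` patterns.

    Multiplicative updates minimize the generalized KL divergence (Frobenius
    available via ``beta_loss='frobenius'``); the best of ``restarts``
    random initializations is kept.  Pattern columns are renormalized to sum
    to 1 with the compensating scale moved into the exposures.  Fully
    deterministic given (matrix, rank, restarts, seed).
    """
    if isinstance(count_matrix, pd.DataFrame):
        sample_names = list(count_matrix.columns)
        count_matrix = count_matrix.to_numpy()
    V = _check_matrix(count_matrix, sample_names)
    n_samples = V.shape[1]
    if rank < 1 or rank >= n_samples:
        raise ValueError(
            f"rank must satisfy 1 <= rank < n_samples ({n_samples})"
        )
    best = None
    for r in range(restarts):
        W, H, obj = _fit_once(V, rank, seed + r, beta_loss=beta_loss)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, obj = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return PatternModel(
        patterns=W,
        exposures=H,
        rank=rank,
        objective=obj,
        restarts=restarts,
        seed=seed,
        sample_names=list(sample_names) if sample_names else [],
    )


def _consensus_matrix(V: np.ndarray, rank: int, restarts: int, seed: int,
                      max_iter: int) -> np.ndarray:
    """Sample-pair co-cluster frequency by dominant exposure over restarts."""
    n = V.shape[1]
    C = np.zeros((n, n))
    for r in range(restarts):
        _, H, _ = _fit_once(V, rank, seed + r, max_iter=max_iter)
        labels = H.argmax(axis=0)
        C += labels[:, None] == labels[None, :]
    return C / restarts


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - consensus."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        # no structure to correlate (e.g. perfect co-clustering throughout)
        return 1.0
    Z = hierarchy.average(condensed)
    coeff, _ = hierarchy.cophenet(Z, condensed)
    return float(coeff)


def select_rank(
    count_matrix,
    rank_range: Sequence[int],
    restarts: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
) -> RankSelection:
    """Choose the number of patterns by consensus cophenetic correlation.

    For each candidate rank a consensus matrix over random restarts is
    clustered hierarchically; the chosen rank is the smallest whose
    cophenetic coefficient exceeds the next rank's (the first point where
    the coefficient starts decreasing).  Ties count as not decreasing.  If
    no decrease occurs the largest rank is returned with a warning flag.
    """
    if isinstance(count_matrix, pd.DataFrame):
        count_matrix = count_matrix.to_numpy()
    V = _check_matrix(count_matrix, None)
    ranks = sorted(rank_range)
    if len(ranks) < 2:
        raise ValueError("rank_range must contain at least two ranks")
    if ranks[0] < 2:
        raise ValueError("minimum candidate rank is 2")
    if ranks != list(range(ranks[0], ranks[-1] + 1)):
        raise ValueError("rank_range must be contiguous")
    profiles = V / V.sum(axis=0, keepdims=True)
    if np.allclose(profiles, profiles[:, [0]]):
        # identical samples: restart consensus is arbitrary, rank meaningless
        warnings.warn(
            "all samples have identical profiles; no clustering structure "
            "to select a rank from"
        )
        return RankSelection(
            ranks=ranks, coefficients=[1.0] * len(ranks), chosen=ranks[-1],
            no_decrease=True,
        )
    coeffs = []
    for k in ranks:
        C = _consensus_matrix(V, k, restarts, seed + 1000 * k, max_iter)
        coeffs.append(_cophenetic_coefficient(C))
    chosen = None
    for i in range(len(ranks) - 1):
        if coeffs[i] > coeffs[i + 1]:
            chosen = ranks[i]
            break
    no_decrease = chosen is None
    if no_decrease:
        chosen = ranks[-1]
        warnings.warn(
            "cophenetic coefficient never decreased over the rank range; "
            "returning the largest candidate rank"
        )
    return RankSelection(
        ranks=ranks, coefficients=coeffs, chosen=chosen,
        no_decrease=no_decrease,
    )


def correlate_signatures(
    model: PatternModel,
    references: Mapping[str, np.ndarray],
    display_threshold: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each pattern with each reference signature.

    Returns (r matrix, display mask of r >= threshold); zero-variance
    vectors give missing (NaN) correlations.
    """
    rows = {}
    for i in range(model.rank):
        w = model.patterns[:, i]
        row = {}
        for name, ref in references.items():
            ref = np.asarray(ref, dtype=float)
            if ref.shape != w.shape:
                raise ValueError(
                    f"reference {name!r} has wrong length {ref.shape}"
                )
            if w.std() == 0 or ref.std() == 0:
                row[name] = np.nan
            else:
                row[name] = float(np.corrcoef(w, ref)[0, 1])
        rows[f"MP{i + 1}"] = row
    r = pd.DataFrame(rows).T
    mask = r >= display_threshold
    return r, mask


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def match_patterns(
    recovered: np.ndarray, truth: np.ndarray
) -> tuple[list[int], list[float]]:
    """Greedy best-cosine assignment of truth columns to recovered columns."""
    k = truth.shape[1]
    sims = np.array(
        [
            [cosine_similarity(truth[:, i], recovered[:, j])
             for j in range(recovered.shape[1])]
            for i in range(k)
        ]
    )
    assignment = [-1] * k
    scores = [0.0] * k
    taken: set[int] = set()
    for _ in range(k):
        i, j = np.unravel_index(
            np.nanargmax(np.where(np.isnan(sims), -np.inf, sims)), sims.shape
        )
        assignment[i] = int(j)
        scores[i] = float(sims[i, j])
        sims[i, :] = np.nan
        sims[:, j] = np.nan
        taken.add(int(j))
    return assignment, scores
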