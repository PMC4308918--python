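"""NMF consensus clustering of miRNA expression.

Non-negative matrix factorization with the Brunet multiplicative updates for
the KL (generalized Kullback-Leibler) divergence; samples are assigned to the
metagene with the largest coefficient.  Stability is assessed by consensus
clustering over repeated randomly initialized runs, summarized by the
cophenetic correlation of the consensus matrix, surveyed over a range of
ranks (k = 2..8 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .diffexp import DEResult, differential_expression
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).tiny


@dataclass
class ConsensusClustering:
    k: int
    consensus: np.ndarray  # samples x samples, in [0, 1]
    cophenetic: float
    assignments: pd.Series  # per-sample cluster label (1..k)
    n_runs: int
    seed: int | None = None
    n_degenerate_runs: int = 0


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum(V log(V/WH) - V + WH)."""
    WH = W @ H
    mask = V > 0
    div = np.sum(WH) - np.sum(V[mask])
    div += np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div)


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Brunet multiplicative-update NMF minimizing KL divergence.

    Random uniform initialization from ``seed``; stops when the relative
    objective change over a check interval falls below ``tol`` or at
    ``max_iter``.  Returns (W, H, objective history).  The multiplicative
    updates guarantee a non-increasing objective.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    n, m = V.shape
    if not (1 <= k <= min(n, m)):
        raise ValueError(f"rank k={k} out of range for a {n}x{m} matrix")
    if (V.sum(axis=1) == 0).any() or (V.sum(axis=0) == 0).any():
        raise ValueError("V has an all-zero row or column")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale
    history = [kl_divergence(V, W, H)]
    for it in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            obj = kl_divergence(V, W, H)
            prev = history[-1]
            history.append(obj)
            if prev > 0 and (prev - obj) / max(prev, _EPS) < tol:
                break
    return W, H, history


def _run_assignments(V: np.ndarray, k: int, seed, max_iter: int, tol: float) -> np.ndarray:
    _W, H, _ = nmf_factorize(V, k, seed=seed, max_iter=max_iter, tol=tol)
    return np.argmax(H, axis=0)


def consensus_cluster(
    V: np.ndarray,
    k: int,
    n_runs: int = 100,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    sample_ids=None,
) -> ConsensusClustering:
    """Consensus over ``n_runs`` randomly initialized NMF runs.

    consensus[i, j] is the fraction of runs placing samples i and j in the
    same metagene cluster; final assignments cut the average-linkage
    dendrogram of (1 - consensus) at k.  Runs yielding an empty cluster are
    logged and still counted.
    """
    V = np.asarray(V, dtype=float)
    m = V.shape[1]
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    together = np.zeros((m, m))
    n_degenerate = 0
    for run_seed in child_seeds:
        labels = _run_assignments(V, k, np.random.default_rng(run_seed), max_iter, tol)
        if len(np.unique(labels)) < k:
            n_degenerate += 1
            logger.debug("degenerate NMF run: %d of %d clusters used", len(np.unique(labels)), k)
        together += (labels[:, None] == labels[None, :]).astype(float)
    consensus = together / n_runs
    np.fill_diagonal(consensus, 1.0)
    coph, assignments = _cut_consensus(consensus, k)
    if sample_ids is None:
        sample_ids = list(range(m))
    return ConsensusClustering(
        k=k,
        consensus=consensus,
        cophenetic=coph,
        assignments=pd.Series(assignments, index=list(sample_ids)),
        n_runs=n_runs,
        seed=seed,
        n_degenerate_runs=n_degenerate,
    )


def _cut_consensus(consensus: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    coph = cophenetic_score(consensus)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return coph, labels


def cophenetic_score(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Pearson correlation between the off-diagonal (1 - consensus) distances and
    the cophenetic distances of their average-linkage dendrogram.  A constant
    distance matrix has no defined correlation; NaN is returned as sentinel.
    """
    consensus = np.asarray(consensus, dtype=float)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        return float("nan")
    Z = average(condensed)
    c, _d = cophenet(Z, condensed)
    return float(c)


def rank_survey(
    V: np.ndarray,
    k_range=range(2, 9),
    n_runs: int = 100,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    sample_ids=None,
) -> tuple[list[ConsensusClustering], pd.DataFrame]:
    """Consensus clustering at each rank in ``k_range`` (2..8 by default).

    Returns the per-k results and a cophenetic profile report.  Selecting the
    preferred k from the profile is a judgment call left to the caller; the
    report only presents the scores.
    """
    ks = list(k_range)
    k_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(ks))
    results = [
        consensus_cluster(
            V, k, n_runs=n_runs, seed=int(kseed), max_iter=max_iter, tol=tol,
            sample_ids=sample_ids,
        )
        for k, kseed in zip(ks, k_seeds)
    ]
    report = pd.DataFrame(
        {
            "k": [r.k for r in results],
            "cophenetic": [r.cophenetic for r in results],
            "n_degenerate_runs": [r.n_degenerate_runs for r in results],
        }
    )
    return results, report


def characterize_clusters(
    assignments: pd.Series,
    m: ExpressionMatrix,
    q_max: float = 0.05,
    abs_m_min: float = 0.0,
    pseudocount: float = 1.0,
) -> list[DEResult]:
    """Differential expression between the two clusters (Wilcoxon + BH)."""
    labels = assignments.loc[[s for s in m.sample_ids if s in assignments.index]]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(uniq)}")
    group_a = [s for s in labels.index if labels[s] == uniq[0]]
    group_b = [s for s in labels.index if labels[s] == uniq[1]]
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("cluster of size < 2")
    sub = m.subset_samples(group_a + group_b)
    return differential_expression(
        sub, group_a, group_b, pseudocount=pseudocount, q_max=q_max, abs_m_min=abs_m_min
    )
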