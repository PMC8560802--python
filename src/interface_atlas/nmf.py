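"""Non-negative matrix factorization of microenvironment spots.

The factorization minimizes the generalized Kullback-Leibler divergence
with Lee-Seung multiplicative updates and uniform random initialization —
the classic Brunet-style setup.  Rank is chosen by consensus clustering
across random restarts: for each candidate rank, spots are hard-assigned
to their argmax factor in every run, the run-averaged co-assignment
matrix is hierarchically clustered, and the cophenetic correlation
between consensus distances and the tree's cophenetic distances measures
stability.  The suggested rank is the first whose cophenetic correlation
exceeds the next rank's (the "first rank where cophenetic starts
decreasing").  The residual sum of squares per rank is also surveyed so
the full curve can be inspected; no automatic inflection detection is
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NMFResult",
    "RankSurvey",
    "clamp_negatives",
    "nmf_fit",
    "estimate_rank",
    "factor_spot_scores",
    "top_factor_genes",
]

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray  # spots x rank loadings
    H: np.ndarray  # rank x genes basis
    rank: int
    objective_trace: list[float]
    seed: int
    spot_ids: np.ndarray | None = None
    gene_ids: np.ndarray | None = None


@dataclass
class RankSurvey:
    table: pd.DataFrame  # index rank; columns cophenetic, rss, n_runs
    suggested_rank: int
    consensus: dict[int, np.ndarray] = field(default_factory=dict)


def clamp_negatives(matrix: np.ndarray) -> np.ndarray:
    """Zero out negative entries (for matrices arriving from integration
    workflows that can produce negative 'expression')."""
    out = np.asarray(matrix, dtype=float).copy()
    out[out < 0] = 0.0
    return out


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    mask = X > 0
    div = np.sum(X[mask] * np.log(X[mask] / np.maximum(WH[mask], _EPS)))
    return float(div - X.sum() + WH.sum())


def nmf_fit(
    matrix: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    spot_ids=None,
    gene_ids=None,
    n_restarts: int = 1,
) -> NMFResult:
    """KL-divergence NMF by multiplicative updates.

    ``matrix`` must be nonnegative (use :func:`clamp_negatives` first if
    needed).  Initialization is uniform random, scaled to the data's mean;
    iteration stops when the relative objective change drops below ``tol``
    or after ``max_iter`` iterations.  Deterministic given ``seed``.

    ``n_restarts > 1`` runs that many fits from different random
    initializations (seeds derived from ``seed``) and returns the one with
    the lowest final objective — multiplicative updates only find local
    optima, so a handful of restarts is standard practice.
    """
    if n_restarts > 1:
        seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
        best = None
        for s in seeds:
            fit = nmf_fit(
                matrix,
                rank,
                seed=int(s),
                max_iter=max_iter,
                tol=tol,
                spot_ids=spot_ids,
                gene_ids=gene_ids,
            )
            if best is None or fit.objective_trace[-1] < best.objective_trace[-1]:
                best = fit
        return best
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be nonnegative; use clamp_negatives first")
    if X.sum() == 0:
        raise ValueError("cannot factorize an all-zero matrix")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    n, m = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / rank)
    W = rng.uniform(_EPS, 1.0, size=(n, rank)) * scale
    H = rng.uniform(_EPS, 1.0, size=(rank, m)) * scale

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H
        W *= (X / np.maximum(WH, _EPS)) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = W @ H
        H *= W.T @ (X / np.maximum(WH, _EPS)) / np.maximum(W.sum(axis=0), _EPS)[:, None]
        obj = _kl_divergence(X, W @ H)
        trace.append(obj)
        if prev < np.inf and abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return NMFResult(
        W=W,
        H=H,
        rank=rank,
        objective_trace=trace,
        seed=seed,
        spot_ids=None if spot_ids is None else np.asarray(spot_ids, dtype=object),
        gene_ids=None if gene_ids is None else np.asarray(gene_ids, dtype=object),
    )


def _consensus_matrix(assignments: list[np.ndarray]) -> np.ndarray:
    n = len(assignments[0])
    C = np.zeros((n, n))
    for a in assignments:
        C += a[:, None] == a[None, :]
    return C / len(assignments)


def _cophenetic_correlation(consensus: np.ndarray) -> float:
    d = squareform(1.0 - consensus, checks=False)
    if np.allclose(d, d[0]):
        return 1.0  # perfectly stable (all-equal distances)
    Z = linkage(d, method="average")
    coph, _ = cophenet(Z, d)
    return float(coph)


def estimate_rank(
    matrix: np.ndarray,
    rank_range,
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> RankSurvey:
    """Survey candidate ranks by consensus stability across random restarts.

    For each rank: ``n_runs`` fits from different random initializations;
    cophenetic correlation of the consensus co-assignment matrix; RSS of
    the best (lowest-KL) run.  The suggested rank is the smallest r in the
    range with cophenetic(r) > cophenetic(r+1); if the curve never
    decreases, the largest surveyed rank is returned with a warning.
    """
    ranks = list(rank_range)
    if len(ranks) < 2:
        raise ValueError("rank_range must contain at least two ranks")
    if sorted(ranks) != ranks:
        raise ValueError("rank_range must be ascending")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")

    X = np.asarray(matrix, dtype=float)
    rows = []
    consensus_by_rank: dict[int, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(len(ranks) * n_runs) % (2**31)
    for i, r in enumerate(ranks):
        assignments = []
        best_obj, best_fit = np.inf, None
        for j in range(n_runs):
            fit = nmf_fit(
                X, r, seed=int(run_seeds[i * n_runs + j]), max_iter=max_iter, tol=tol
            )
            assignments.append(np.argmax(fit.W, axis=1))
            if fit.objective_trace[-1] < best_obj:
                best_obj, best_fit = fit.objective_trace[-1], fit
        C = _consensus_matrix(assignments)
        consensus_by_rank[r] = C
        rss = float(np.sum((X - best_fit.W @ best_fit.H) ** 2))
        rows.append(
            {"rank": r, "cophenetic": _cophenetic_correlation(C), "rss": rss, "n_runs": n_runs}
        )
    table = pd.DataFrame(rows).set_index("rank")

    suggested = None
    coph = table["cophenetic"]
    for r_cur, r_next in zip(ranks[:-1], ranks[1:]):
        if coph[r_cur] > coph[r_next]:
            suggested = r_cur
            break
    if suggested is None:
        suggested = ranks[-1]
        warnings.warn(
            "cophenetic correlation never decreased over the surveyed range; "
            "returning the largest rank",
            stacklevel=2,
        )
    return RankSurvey(table=table, suggested_rank=suggested, consensus=consensus_by_rank)


def factor_spot_scores(result: NMFResult) -> np.ndarray:
    """Z-score each spot's loading vector across factors (mean 0, SD 1 per
    spot, SD with n-1 denominator).  Spots with constant loadings map to
    all-zero scores."""
    if result.rank < 2:
        raise ValueError("z-scoring across factors requires rank >= 2")
    W = result.W
    mean = W.mean(axis=1, keepdims=True)
    sd = W.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(W)
    ok = sd[:, 0] > 0
    out[ok] = (W[ok] - mean[ok]) / sd[ok]
    return out


def top_factor_genes(result: NMFResult, factor: int, n: int = 150) -> list[str]:
    """Genes ranked by their weight in one basis row (descending), ties
    broken lexicographically by gene id; first ``n`` returned."""
    if not (0 <= factor < result.rank):
        raise ValueError(f"factor {factor} out of range for rank {result.rank}")
    if result.gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(result.H.shape[1])], dtype=object)
    else:
        gene_ids = result.gene_ids
    if n > len(gene_ids):
        warnings.warn("n exceeds the gene count; returning the full ranking", stacklevel=2)
        n = len(gene_ids)
    weights = result.H[factor]
    order = sorted(range(len(gene_ids)), key=lambda i: (-weights[i], str(gene_ids[i])))
    return [str(gene_ids[i]) for i in order[:n]]
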