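"""Spatially coherent gene-set testing.

The statistic asks whether the spots that highly express a gene set lie
closer together on the array than random spots would.  For each gene set:

1. score every spot by the mean normalized expression of the set's genes;
2. call a spot "high" if its score exceeds mean + 2 SD of the scores
   (at least ``min_spots`` high spots are required to proceed);
3. collect all pairwise Euclidean distances among the high spots;
4. build a null by drawing the same number of spots uniformly without
   replacement ``n_reps`` times (100 by default) and pooling their pairwise
   distances;
5. compare observed vs null distances with a two-sided rank-sum statistic.

Two p-value methods are offered.  ``method='studentized'`` (default) ranks
all distances jointly, computes the mean rank of each group (observed and
each null repetition), and studentizes the observed mean rank against the
across-repetition distribution of the same statistic (t reference with
n_reps - 1 df).  This keeps the rank-sum form of the comparison while
respecting the fact that the C(n, 2) pairwise distances among n spots are
statistically dependent: treating them as independent (as the plain
two-group rank-sum normal approximation does) inflates the type-I error
roughly sevenfold in simulation.  ``method='ranksum'`` is that plain
pooled two-group Wilcoxon comparison, provided for compatibility with the
classical description of the procedure.

Because only distance ranks enter the test, the p-value is invariant to
any global scaling, translation, or rotation of the coordinates.  Region
restriction (e.g. testing within the tumor only) is performed by the
caller subsetting spots before calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata
from scipy.stats import t as t_dist

from .datatypes import GeneSetCollection, NormalizedMatrix

__all__ = [
    "CoherenceResult",
    "set_mean_expression",
    "select_high_spots",
    "coherence_test",
    "coherence_screen",
]


@dataclass
class CoherenceResult:
    set_name: str
    n_high_spots: int
    evaluated: bool
    p_value: float = float("nan")
    median_observed: float = float("nan")
    median_null: float = float("nan")
    observed_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_distances: np.ndarray = field(default_factory=lambda: np.empty(0))


def set_mean_expression(norm: NormalizedMatrix, gene_set, set_name: str = "") -> np.ndarray:
    """Per-spot arithmetic mean of normalized expression over a gene set.

    Only the set's measured genes contribute; an empty intersection with
    the measured genes is an error naming the set.
    """
    idx = np.sort(norm.gene_index(gene_set))  # order-independent summation
    if len(idx) == 0:
        raise ValueError(
            f"gene set {set_name or '<unnamed>'!r} shares no genes with the matrix"
        )
    return norm.values[:, idx].mean(axis=1)


def select_high_spots(score: np.ndarray, min_spots: int = 5) -> np.ndarray:
    """Indices of spots scoring above mean + 2 SD (SD with n-1 denominator).

    A constant score vector selects nothing.  The returned list may be
    shorter than ``min_spots``; evaluability is the caller's decision.
    """
    score = np.asarray(score, dtype=float)
    if len(score) < min_spots:
        raise ValueError(f"need at least {min_spots} spots, got {len(score)}")
    sd = score.std(ddof=1)
    if sd == 0:
        return np.empty(0, dtype=int)
    return np.flatnonzero(score > score.mean() + 2.0 * sd)


def _studentized_rank_p(observed: np.ndarray, null_parts: list[np.ndarray]) -> float:
    """Two-sided p for the observed mean pooled rank, studentized against
    the across-repetition distribution of the same statistic."""
    sizes = [len(observed)] + [len(g) for g in null_parts]
    ranks = rankdata(np.concatenate([observed, *null_parts]))
    bounds = np.cumsum([0] + sizes)
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(sizes))]
    )
    s_obs, s_null = mean_ranks[0], mean_ranks[1:]
    sd = s_null.std(ddof=1)
    if sd == 0:
        return 1.0
    z = (s_obs - s_null.mean()) / sd
    return float(min(1.0, 2.0 * t_dist.sf(abs(z), df=len(s_null) - 1)))


def coherence_test(
    norm: NormalizedMatrix,
    coords: np.ndarray,
    gene_set,
    n_reps: int = 100,
    min_spots: int = 5,
    seed: int = 0,
    set_name: str = "",
    keep_distances: bool = True,
    method: str = "studentized",
) -> CoherenceResult:
    """Test one gene set for spatial coherence among its high spots.

    The spot universe is exactly the rows of ``norm``/``coords`` supplied;
    restrict to a region by subsetting beforehand.  Deterministic for a
    given seed.  When fewer than ``min_spots`` spots are high, the result
    has ``evaluated=False`` and no p-value.

    ``method`` selects the p-value computation: ``'studentized'`` (default,
    calibrated under spatially random sets; see module docstring) or
    ``'ranksum'`` (plain pooled two-group rank-sum with tie-corrected
    normal approximation; anti-conservative because pairwise distances are
    dependent).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != norm.n_obs:
        raise ValueError("coords are not aligned to the normalized matrix rows")
    if norm.n_obs < min_spots:
        raise ValueError(f"need at least {min_spots} spots, got {norm.n_obs}")
    if method not in ("studentized", "ranksum"):
        raise ValueError(f"unknown method: {method!r}")

    score = set_mean_expression(norm, gene_set, set_name=set_name)
    high = select_high_spots(score, min_spots=min_spots)
    if len(high) < min_spots:
        return CoherenceResult(set_name=set_name, n_high_spots=len(high), evaluated=False)

    observed = pdist(coords[high])
    rng = np.random.default_rng(seed)
    n = len(high)
    null_parts = []
    for _ in range(n_reps):
        pick = rng.choice(norm.n_obs, size=n, replace=False)
        null_parts.append(pdist(coords[pick]))
    null = np.concatenate(null_parts)

    if method == "studentized":
        p = _studentized_rank_p(observed, null_parts)
    else:
        p = float(
            mannwhitneyu(observed, null, alternative="two-sided", method="asymptotic").pvalue
        )
    return CoherenceResult(
        set_name=set_name,
        n_high_spots=n,
        evaluated=True,
        p_value=p,
        median_observed=float(np.median(observed)),
        median_null=float(np.median(null)),
        observed_distances=observed if keep_distances else np.empty(0),
        null_distances=null if keep_distances else np.empty(0),
    )


def coherence_screen(
    norm: NormalizedMatrix,
    coords: np.ndarray,
    collection: GeneSetCollection,
    n_reps: int = 100,
    min_spots: int = 5,
    seed: int = 0,
    bh_correct: bool = False,
    method: str = "studentized",
) -> pd.DataFrame:
    """Run the coherence test over every set in a collection.

    Returns a table (set, n_high, median_obs, median_null, p, evaluated),
    optionally with a Benjamini-Hochberg column (off by default; raw
    p-values are the primary output).
    """
    rows = []
    for i, name in enumerate(collection.names()):
        res = coherence_test(
            norm,
            coords,
            collection[name],
            n_reps=n_reps,
            min_spots=min_spots,
            seed=seed + i,
            set_name=name,
            keep_distances=False,
            method=method,
        )
        rows.append(
            {
                "set": name,
                "n_high": res.n_high_spots,
                "median_obs": res.median_observed,
                "median_null": res.median_null,
                "p": res.p_value,
                "evaluated": res.evaluated,
            }
        )
    df = pd.DataFrame(rows).set_index("set")
    if bh_correct:
        mask = df["evaluated"].to_numpy()
        q = np.full(len(df), np.nan)
        if mask.any():
            q[mask] = false_discovery_control(df.loc[mask, "p"].to_numpy(), method="bh")
        df["q_bh"] = q
    return df
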