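"""Module scoring, cross-dataset signature construction, and
signature-based classification.

The module score of a gene set in one observation is the mean normalized
expression of the set's genes minus the mean expression of control genes
drawn from the same expression strata: genes are binned into equal-count
bins by their mean expression across observations, and each set gene
contributes ``n_ctrl`` controls sampled from its own bin (excluding set
genes).  Subtracting bin-matched controls centers the score at zero for a
random gene set regardless of overall expression level, so scores are
comparable across sets and datasets.

An interface signature is built by intersecting the significantly
upregulated genes of the interface cluster across several datasets
(spatial, cell, nucleus), after removing ribosomal genes (prefixes
"rps"/"rpl"), mirroring how a shared tumor-boundary program is defined
from multiple modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import MarkerTable, NormalizedMatrix

__all__ = [
    "ModuleScore",
    "SignatureDefinition",
    "module_score",
    "build_interface_signature",
    "score_correlation",
    "classify_by_signature",
]


@dataclass
class ModuleScore:
    scores: pd.Series  # indexed by observation id
    set_name: str
    n_bins: int
    n_ctrl: int
    seed: int

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


@dataclass
class SignatureDefinition:
    genes: list[str]
    source_contrasts: list[tuple[str, str]] = field(default_factory=list)
    fc_threshold: float = 0.0
    ribo_prefixes: tuple[str, ...] = ("rps", "rpl")


def module_score(
    norm: NormalizedMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    set_name: str = "",
    control_exclude=None,
) -> ModuleScore:
    """Binned-control module score per observation.

    score(obs) = mean over set genes of norm(obs, g)
               - mean over all sampled control genes of norm(obs, c)

    Controls are sampled per set gene from its mean-expression bin,
    excluding set genes, with replacement when the eligible bin is smaller
    than ``n_ctrl``.  Deterministic given ``seed``.

    ``control_exclude`` removes additional genes from the control pools.
    When two scores will be correlated against each other (e.g. a
    transcription-factor set against its target set), exclude the union of
    both sets from each score's controls — otherwise genes of one set leak
    into the other's controls and induce a spurious negative correlation.
    """
    set_idx = norm.gene_index(gene_set)
    if len(set_idx) == 0:
        raise ValueError(f"gene set {set_name or '<unnamed>'!r} has no measured genes")
    values = norm.values
    n_genes = values.shape[1]
    means = values.mean(axis=0)

    # equal-count bins on the mean-expression ranks
    order_key = pd.Series(means).rank(method="first")
    bins = pd.qcut(order_key, q=min(n_bins, n_genes), labels=False, duplicates="drop").to_numpy()

    rng = np.random.default_rng(seed)
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_idx] = True
    if control_exclude is not None:
        in_set[norm.gene_index(control_exclude)] = True
    control_idx: list[np.ndarray] = []
    for g in set_idx:
        pool = np.flatnonzero((bins == bins[g]) & ~in_set)
        if len(pool) == 0:
            # degenerate universe: the set exhausts its bin; controls are
            # the set genes themselves, making the contribution self-cancelling
            pool = np.flatnonzero(bins == bins[g])
        replace = len(pool) < n_ctrl
        control_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    controls = np.concatenate(control_idx)

    set_mean = values[:, set_idx].mean(axis=1)
    ctrl_mean = values[:, controls].mean(axis=1)
    scores = pd.Series(set_mean - ctrl_mean, index=norm.obs_ids.astype(str))
    return ModuleScore(
        scores=scores, set_name=set_name, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    )


def build_interface_signature(
    marker_tables: list[MarkerTable],
    alpha: float = 0.05,
    fc_threshold: float = 0.0,
    ribo_prefixes=("rps", "rpl"),
) -> SignatureDefinition:
    """Intersect significantly upregulated genes across datasets.

    Per table: keep genes with adjusted p < ``alpha`` and log2 fold change
    > ``fc_threshold``; drop genes whose name starts (case-insensitively)
    with any ribosomal prefix; the signature is the intersection across all
    tables.  An empty intersection yields an empty signature with a
    warning, not an error.
    """
    if len(marker_tables) < 2:
        raise ValueError("need at least two marker tables to intersect")
    prefixes = tuple(p.lower() for p in ribo_prefixes)

    def _upregulated(mt: MarkerTable) -> set[str]:
        t = mt.table
        genes = t.index[(t["p_adj"] < alpha) & (t["log2fc"] > fc_threshold)]
        return {g for g in genes if not str(g).lower().startswith(prefixes)}

    sets = [_upregulated(mt) for mt in marker_tables]
    common = set.intersection(*sets)
    if not common:
        warnings.warn("interface signature is empty after intersection", stacklevel=2)
    return SignatureDefinition(
        genes=sorted(common),
        source_contrasts=[(mt.group, mt.reference) for mt in marker_tables],
        fc_threshold=fc_threshold,
        ribo_prefixes=prefixes,
    )


def score_correlation(
    scores_a: ModuleScore, scores_b: ModuleScore, subset=None
) -> tuple[float, float]:
    """Pearson correlation of two module scores over an observation subset.

    Returns ``(r, p)`` with the two-sided p-value from the t-distribution
    with n-2 degrees of freedom.  Zero variance in either score yields
    ``(nan, nan)``.
    """
    a = scores_a.scores
    b = scores_b.scores
    if subset is not None:
        subset = [str(s) for s in subset]
        a = a.loc[subset]
        b = b.loc[subset]
    else:
        b = b.loc[a.index]
    if len(a) < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        warnings.warn("zero variance in module scores: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = pearsonr(a.to_numpy(float), b.to_numpy(float))
    return float(res.statistic), float(res.pvalue)


def classify_by_signature(
    scores: ModuleScore, threshold: float | None = None
) -> pd.Series:
    """Boolean interface-like call per observation: score > threshold.

    When ``threshold`` is None it defaults to mean + 2 SD of the scores
    across observations (SD with n-1 denominator) — a conservative outlier
    rule; pass an explicit value to use a fixed cutoff.
    """
    vals = scores.values()
    if not np.isfinite(vals).all():
        raise ValueError("module scores must be finite")
    if threshold is None:
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        threshold = float(vals.mean() + 2.0 * sd)
    return pd.Series(vals > threshold, index=scores.scores.index)
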