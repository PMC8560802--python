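"""Rank-sum marker detection, the interface-enrichment rule, and
cluster-correlation analysis.

Marker p-values come from the two-sided Wilcoxon rank-sum test on
normalized expression: exact enumeration of the rank-sum null (with
midranks for ties) when the combined sample size is at most
``EXACT_MAX_N``, and the tie-corrected normal approximation with
continuity correction otherwise.  The fold change follows the common
single-cell convention: ``log2(mean(expm1(x_in)) + 1) -
log2(mean(expm1(x_out)) + 1)``, i.e. means are taken on the de-logged
scale with a pseudocount of one.

The interface-enrichment rule addresses the admixture problem at a
tumor boundary: a gene counts as interface-enriched only if its fold
change in the interface (versus everything else) exceeds the fold change
the same gene shows in the pure tumor and in the pure muscle clusters —
otherwise its apparent enrichment could simply reflect a mixture of the
two flanking tissues.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import norm as normal_dist
from scipy.stats import pearsonr, rankdata

from .datatypes import InterfaceGeneCall, MarkerTable, NormalizedMatrix

__all__ = [
    "ranksum_p",
    "ranksum_markers",
    "interface_enriched_genes",
    "cluster_correlation",
]

#: largest combined sample size for which the exact rank-sum null is enumerated
EXACT_MAX_N = 12


def _exact_two_sided_p(ranks: np.ndarray, n_in: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all group assignments of the ranks."""
    n = len(ranks)
    combos = np.array(list(combinations(range(n), n_in)))
    w_null = ranks[combos].sum(axis=1)
    eps = 1e-9
    p_ge = np.mean(w_null >= w_obs - eps)
    p_le = np.mean(w_null <= w_obs + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def _asymptotic_two_sided_p(ranks: np.ndarray, n_in: int, w_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(ranks)
    n_out = n - n_in
    mu = n_in * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n_in * n_out / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * normal_dist.sf(max(z, 0.0))))


def ranksum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[: len(x)].sum())
    if len(x) + len(y) <= EXACT_MAX_N:
        return _exact_two_sided_p(ranks, len(x), w)
    return _asymptotic_two_sided_p(ranks, len(x), w)


def _log2fc(values_in: np.ndarray, values_out: np.ndarray) -> np.ndarray:
    """Seurat-style log2 fold change on de-logged means, pseudocount 1."""
    mean_in = np.expm1(values_in).mean(axis=0)
    mean_out = np.expm1(values_out).mean(axis=0)
    return np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)


def ranksum_markers(
    norm: NormalizedMatrix,
    labels,
    group: str,
    reference: str = "rest",
    min_pct: float = 0.0,
    correction: str = "bonferroni",
) -> MarkerTable:
    """Per-gene rank-sum differential expression of ``group`` vs ``reference``.

    ``reference='rest'`` contrasts against all other observations.  Genes
    expressed (value > 0) in fewer than ``min_pct`` of observations in
    *both* groups are skipped.  Adjusted p-values use Bonferroni over the
    tested genes by default (``correction='bh'`` for Benjamini-Hochberg).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != norm.n_obs:
        raise ValueError("labels are not aligned to the normalized matrix")
    in_mask = labels == group
    if not in_mask.any():
        raise ValueError(f"unknown or empty group label: {group!r}")
    if reference == "rest":
        out_mask = ~in_mask
    else:
        out_mask = labels == reference
        if not out_mask.any():
            raise ValueError(f"unknown or empty reference label: {reference!r}")
    if not out_mask.any():
        raise ValueError("reference group is empty")

    vals_in = norm.values[in_mask]
    vals_out = norm.values[out_mask]
    n_in, n_out = vals_in.shape[0], vals_out.shape[0]

    pct_in = (vals_in > 0).mean(axis=0)
    pct_out = (vals_out > 0).mean(axis=0)
    tested = ~((pct_in < min_pct) & (pct_out < min_pct)) if min_pct > 0 else np.ones(
        norm.values.shape[1], dtype=bool
    )

    pooled = np.vstack([vals_in, vals_out])
    ranks = rankdata(pooled, axis=0)
    w = ranks[:n_in].sum(axis=0)

    tested_idx = np.flatnonzero(tested)
    p = np.full(norm.values.shape[1], np.nan)
    if n_in + n_out <= EXACT_MAX_N:
        for j in tested_idx:
            p[j] = _exact_two_sided_p(ranks[:, j], n_in, w[j])
    else:
        for j in tested_idx:
            p[j] = _asymptotic_two_sided_p(ranks[:, j], n_in, w[j])

    fc = _log2fc(vals_in, vals_out)
    n_tested = len(tested_idx)
    p_adj = np.full_like(p, np.nan)
    if correction == "bonferroni":
        p_adj[tested_idx] = np.minimum(1.0, p[tested_idx] * n_tested)
    elif correction == "bh":
        from scipy.stats import false_discovery_control

        p_adj[tested_idx] = false_discovery_control(p[tested_idx], method="bh")
    else:
        raise ValueError(f"unknown correction: {correction!r}")

    table = pd.DataFrame(
        {
            "log2fc": fc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": pct_in,
            "pct_out": pct_out,
        },
        index=pd.Index(norm.gene_ids.astype(str), name="gene"),
    ).loc[norm.gene_ids.astype(str)[tested]]
    return MarkerTable(table=table, group=group, reference=reference)


def interface_enriched_genes(
    table_vs_all: MarkerTable,
    table_tumor: MarkerTable,
    table_muscle: MarkerTable,
    alpha: float = 0.05,
) -> list[InterfaceGeneCall]:
    """Apply the interface-enrichment rule across three contrasts.

    Up-calls require log2FC(interface) > 0, greater than both
    log2FC(tumor) and log2FC(muscle), and adjusted p < alpha in the
    interface-vs-all contrast; down-calls reverse all three fold-change
    inequalities.  The three tables must share one gene universe.
    """
    sets = [set(t.genes) for t in (table_vs_all, table_tumor, table_muscle)]
    common = sets[0] & sets[1] & sets[2]
    union = sets[0] | sets[1] | sets[2]
    if common != union:
        diff = sorted(union - common)
        raise ValueError(f"marker tables cover different gene universes: {diff[:20]}")

    ti = table_vs_all.table
    tt = table_tumor.table
    tm = table_muscle.table
    calls: list[InterfaceGeneCall] = []
    for gene in ti.index:
        fc_i = float(ti.at[gene, "log2fc"])
        fc_t = float(tt.at[gene, "log2fc"])
        fc_m = float(tm.at[gene, "log2fc"])
        p_adj = float(ti.at[gene, "p_adj"])
        if not (p_adj < alpha):
            continue
        if fc_i > 0 and fc_i > fc_t and fc_i > fc_m:
            direction = "up"
        elif fc_i < 0 and fc_i < fc_t and fc_i < fc_m:
            direction = "down"
        else:
            continue
        calls.append(
            InterfaceGeneCall(
                gene=str(gene),
                direction=direction,
                fc_interface=fc_i,
                fc_tumor=fc_t,
                fc_muscle=fc_m,
                p_adj=p_adj,
            )
        )
    return calls


def cluster_correlation(
    norm_per_dataset,
    labels_per_dataset,
    n_var: int = 1000,
):
    """Pearson correlation matrix between cluster mean expression profiles.

    Per dataset, the top ``n_var`` variable genes are selected and their
    union taken; cluster mean profiles are computed over all observations
    (pooled across datasets) restricted to that union.  Returns
    ``(r_matrix, p_matrix, leaf_order)`` where the leaf order comes from
    average-linkage hierarchical clustering of distance 1 - r.  Pairs with
    a constant profile have missing (NaN) r and p.
    """
    from .preprocess import select_variable_genes

    if not isinstance(norm_per_dataset, (list, tuple)):
        norm_per_dataset = [norm_per_dataset]
        labels_per_dataset = [labels_per_dataset]
    if len(norm_per_dataset) != len(labels_per_dataset):
        raise ValueError("need one label vector per dataset")
    gene_ids = norm_per_dataset[0].gene_ids
    for nm in norm_per_dataset[1:]:
        if not np.array_equal(nm.gene_ids, gene_ids):
            raise ValueError("datasets must share one gene universe")

    union: set[str] = set()
    for nm in norm_per_dataset:
        union |= set(select_variable_genes(nm, min(n_var, len(gene_ids))))
    var_genes = sorted(union)
    col = norm_per_dataset[0].gene_index(var_genes)

    all_values = np.vstack([nm.values[:, col] for nm in norm_per_dataset])
    all_labels = np.concatenate([np.asarray(l, dtype=object) for l in labels_per_dataset])
    clusters = sorted(set(all_labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    profiles = np.vstack([all_values[all_labels == c].mean(axis=0) for c in clusters])

    k = len(clusters)
    r = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        pmat[i, i] = 0.0
        for j in range(i + 1, k):
            if profiles[i].std() == 0 or profiles[j].std() == 0:
                continue  # constant profile: correlation undefined
            res = pearsonr(profiles[i], profiles[j])
            r[i, j] = r[j, i] = float(res.statistic)
            pmat[i, j] = pmat[j, i] = float(res.pvalue)

    dist = 1.0 - r
    dist[np.isnan(dist)] = 2.0  # undefined pairs treated as maximally distant
    iu = np.triu_indices(k, 1)
    order = leaves_list(linkage(dist[iu], method="average"))
    r_df = pd.DataFrame(r, index=clusters, columns=clusters)
    p_df = pd.DataFrame(pmat, index=clusters, columns=clusters)
    leaf_order = [clusters[i] for i in order]
    return r_df, p_df, leaf_order
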