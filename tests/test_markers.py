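"""Rank-sum markers, the interface-enrichment rule, cluster correlation."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from interface_atlas.datatypes import NormalizedMatrix
from interface_atlas.markers import (
    cluster_correlation,
    interface_enriched_genes,
    ranksum_markers,
    ranksum_p,
)


def _norm_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    if genes is None:
        genes = [f"g{i:03d}" for i in range(g)]
    return NormalizedMatrix(
        values=values,
        gene_ids=np.array(genes, dtype=object),
        obs_ids=np.array([f"o{i}" for i in range(n)], dtype=object),
    )


def brute_force_ranksum_p(x, y):
    """Independent exact oracle: enumerate all assignments of the pooled
    midranks to the first group; two-sided by tail doubling."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(pooled)
    w_obs = ranks[: len(x)].sum()
    w_all = [sum(ranks[list(c)]) for c in combinations(range(n), len(x))]
    w_all = np.asarray(w_all)
    ge = np.mean(w_all >= w_obs - 1e-9)
    le = np.mean(w_all <= w_obs + 1e-9)
    return min(1.0, 2 * min(ge, le))


class TestRanksumP:
    def test_three_vs_three_exact(self):
        # {5,6,7} vs {1,2,3}: W = 15 (U = 9, the maximum); exact two-sided
        # p = 2 * 1/20 = 0.1
        assert ranksum_p([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert ranksum_p([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0
        assert ranksum_p(np.ones(50), np.ones(80)) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        y = rng.integers(0, 6, size=n2).astype(float)
        assert ranksum_p(x, y) == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_asymptotic_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.3, 1, 80)
        ours = ranksum_p(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_asymptotic_with_ties_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, 40).astype(float)
        y = rng.integers(0, 5, 50).astype(float)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ranksum_p(x, y) == pytest.approx(ref, rel=1e-9)


class TestRanksumMarkers:
    def test_identically_distributed_gene(self):
        values = np.zeros((8, 2))
        values[:, 0] = [1, 2, 3, 4, 1, 2, 3, 4]
        values[:, 1] = 1.0
        norm = _norm_from(values)
        labels = ["a"] * 4 + ["b"] * 4
        t = ranksum_markers(norm, labels, "a", "b").table
        assert t.loc["g000", "p"] == pytest.approx(1.0)
        assert t.loc["g000", "log2fc"] == pytest.approx(0.0)

    def test_all_zero_reference_fc_formula(self):
        # log2fc = log2(mean(expm1(x_in)) + 1) with a silent reference
        values = np.zeros((6, 1))
        values[:3, 0] = np.log1p(3.0)  # expm1 -> 3
        norm = _norm_from(values)
        t = ranksum_markers(norm, ["a"] * 3 + ["b"] * 3, "a", "b").table
        assert t.loc["g000", "log2fc"] == pytest.approx(np.log2(4.0))

    def test_swap_groups_flips_log2fc(self, norm_spots, spatial_data):
        spots, _ = spatial_data
        ab = ranksum_markers(norm_spots, spots.cluster_of_spot, "tumor", "muscle").table
        ba = ranksum_markers(norm_spots, spots.cluster_of_spot, "muscle", "tumor").table
        assert np.allclose(ab["log2fc"], -ba["log2fc"])

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(0)
        norm = _norm_from(rng.gamma(2, 1, size=(30, 10)))
        t = ranksum_markers(norm, ["a"] * 15 + ["b"] * 15, "a", "b").table
        assert np.allclose(t["p_adj"], np.minimum(1.0, t["p"] * len(t)))

    def test_unknown_label_rejected(self, norm_spots, spatial_data):
        spots, _ = spatial_data
        with pytest.raises(ValueError):
            ranksum_markers(norm_spots, spots.cluster_of_spot, "no_such_cluster")

    def test_planted_markers_detected(self, norm_spots, spatial_data):
        spots, truth = spatial_data
        t = ranksum_markers(norm_spots, spots.cluster_of_spot, "tumor", "rest")
        up = set(t.significant_up(0.05))
        markers = set(truth.marker_genes["tumor"])
        assert len(up & markers) / len(markers) >= 0.9


def _table_from(fc_p):  # {gene: (log2fc, p_adj)}
    import pandas as pd

    from interface_atlas.datatypes import MarkerTable

    genes = sorted(fc_p)
    df = pd.DataFrame(
        {
            "log2fc": [fc_p[g][0] for g in genes],
            "p": [fc_p[g][1] for g in genes],
            "p_adj": [fc_p[g][1] for g in genes],
            "pct_in": 1.0,
            "pct_out": 1.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return MarkerTable(table=df, group="interface", reference="rest")


class TestInterfaceRule:
    def test_clear_up_call(self):
        ti = _table_from({"a": (1.0, 1e-6)})
        tt = _table_from({"a": (0.2, 0.5)})
        tm = _table_from({"a": (-0.5, 0.5)})
        calls = interface_enriched_genes(ti, tt, tm)
        assert len(calls) == 1 and calls[0].direction == "up"

    def test_tumor_fold_change_dominance_blocks_call(self):
        ti = _table_from({"a": (1.0, 1e-9)})
        tt = _table_from({"a": (1.5, 1e-9)})
        tm = _table_from({"a": (-0.5, 1e-9)})
        assert interface_enriched_genes(ti, tt, tm) == []

    def test_down_call_requires_all_reversed(self):
        ti = _table_from({"a": (-1.0, 1e-6), "b": (-1.0, 1e-6)})
        tt = _table_from({"a": (-0.2, 0.5), "b": (-2.0, 0.5)})
        tm = _table_from({"a": (-0.1, 0.5), "b": (-0.2, 0.5)})
        calls = interface_enriched_genes(ti, tt, tm)
        assert [c.gene for c in calls] == ["a"]
        assert calls[0].direction == "down"

    def test_mismatched_universes_rejected(self):
        ti = _table_from({"a": (1.0, 1e-6), "b": (1.0, 1e-6)})
        tt = _table_from({"a": (0.0, 0.5)})
        tm = _table_from({"a": (0.0, 0.5)})
        with pytest.raises(ValueError, match="b"):
            interface_enriched_genes(ti, tt, tm)

    def test_alpha_cut_monotone_transform_invariant(self):
        # any strictly monotone transform of p_adj preserving the 0.05 cut
        # leaves the call set unchanged
        base = {"a": (1.0, 0.01), "b": (1.0, 0.2), "c": (2.0, 0.04)}
        flat = {"x": (0.0, 0.5)}
        ti = _table_from({**base, **flat})
        tt = _table_from({g: (0.0, 0.5) for g in list(base) + list(flat)})
        tm = _table_from({g: (0.0, 0.5) for g in list(base) + list(flat)})
        calls1 = {c.gene for c in interface_enriched_genes(ti, tt, tm)}
        squeezed = {g: (fc, p**2 * (0.05 ** -1)) for g, (fc, p) in base.items()}
        # p -> p^2/0.05 is strictly monotone and fixes the 0.05 threshold
        ti2 = _table_from({**squeezed, **flat})
        calls2 = {c.gene for c in interface_enriched_genes(ti2, tt, tm)}
        assert calls1 == calls2

    def test_planted_program_recovered(self, norm_spots, spatial_data):
        spots, truth = spatial_data
        labels = spots.cluster_of_spot
        ti = ranksum_markers(norm_spots, labels, "interface", "rest")
        tt = ranksum_markers(norm_spots, labels, "tumor", "rest")
        tm = ranksum_markers(norm_spots, labels, "muscle", "rest")
        calls = interface_enriched_genes(ti, tt, tm)
        up = {c.gene for c in calls if c.direction == "up"}
        program = set(truth.interface_program)
        assert len(up & program) / len(program) >= 0.9
        pure = set(truth.marker_genes["tumor"]) | set(truth.marker_genes["muscle"])
        assert not (up & pure)


class TestClusterCorrelation:
    def test_three_cluster_toy_closed_form(self):
        # profiles a=(1,2,3,4), b=2a, c=reverse(a): r(a,b)=1, r(a,c)=-1
        values = np.vstack(
            [
                np.tile([1.0, 2.0, 3.0, 4.0], (3, 1)),
                np.tile([2.0, 4.0, 6.0, 8.0], (3, 1)),
                np.tile([4.0, 3.0, 2.0, 1.0], (3, 1)),
            ]
        )
        rng = np.random.default_rng(0)
        values = values + rng.normal(0, 1e-9, values.shape)  # break constancy
        norm = _norm_from(values)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r, p, order = cluster_correlation(norm, labels, n_var=4)
        assert r.loc["a", "b"] == pytest.approx(1.0, abs=1e-6)
        assert r.loc["a", "c"] == pytest.approx(-1.0, abs=1e-6)
        assert np.allclose(np.diag(r), 1.0)

    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(1)
        profile = rng.gamma(2, 1, 50)
        values = np.tile(profile, (8, 1)) + rng.normal(0, 1e-12, (8, 50))
        norm = _norm_from(values)
        r, p, _ = cluster_correlation(norm, ["a"] * 4 + ["b"] * 4, n_var=50)
        assert r.loc["a", "b"] == pytest.approx(1.0, abs=1e-6)
        assert p.loc["a", "b"] < 1e-10

    def test_dendrogram_groups_interface_with_its_neighbors(
        self, norm_spots, spatial_data
    ):
        spots, _ = spatial_data
        r, p, order = cluster_correlation(norm_spots, spots.cluster_of_spot, n_var=500)
        assert set(order) == {"tumor", "interface", "muscle"}
        assert r.shape == (3, 3)
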