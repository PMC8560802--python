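"""Module scoring, signature intersection, score correlation, classification."""

import numpy as np
import pandas as pd
import pytest

from interface_atlas.datatypes import MarkerTable, NormalizedMatrix
from interface_atlas.signatures import (
    build_interface_signature,
    classify_by_signature,
    module_score,
    score_correlation,
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


def _marker_table(up_genes, universe, group="interface"):
    df = pd.DataFrame(
        {
            "log2fc": [1.0 if g in up_genes else -0.2 for g in universe],
            "p": [1e-8 if g in up_genes else 0.9 for g in universe],
            "p_adj": [1e-6 if g in up_genes else 1.0 for g in universe],
            "pct_in": 1.0,
            "pct_out": 1.0,
        },
        index=pd.Index(universe, name="gene"),
    )
    return MarkerTable(table=df, group=group, reference="rest")


class TestModuleScore:
    def test_degenerate_identical_universe_scores_zero(self):
        # every gene identical: controls equal the set, score collapses to 0
        values = np.tile(np.linspace(1, 2, 8)[:, None], (1, 10))
        norm = _norm_from(values)
        ms = module_score(norm, ["g000", "g001"], n_bins=1, seed=0)
        assert np.allclose(ms.values(), 0.0)

    def test_random_set_centered_on_null_data(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            norm = _norm_from(np.log1p(rng.gamma(2.0, 1.0, size=(300, 400))))
            genes = [f"g{i:03d}" for i in rng.choice(400, 30, replace=False)]
            ms = module_score(norm, genes, seed=seed)
            means.append(ms.values().mean())
        assert np.all(np.abs(means) < 0.05)

    def test_interface_program_separates_planted_states(self, cell_data, norm_cells):
        from interface_atlas.markers import ranksum_p

        cells, truth = cell_data
        ms = module_score(norm_cells, truth.interface_program, seed=0)
        is_iface = np.array(
            [str(s).startswith("interface") for s in cells.cluster_of_cell]
        )
        p = ranksum_p(ms.values()[is_iface], ms.values()[~is_iface])
        assert p < 1e-6
        assert ms.values()[is_iface].mean() > ms.values()[~is_iface].mean()

    def test_deterministic_given_seed(self, norm_cells, cell_data):
        _, truth = cell_data
        a = module_score(norm_cells, truth.interface_program, seed=3)
        b = module_score(norm_cells, truth.interface_program, seed=3)
        assert np.array_equal(a.values(), b.values())

    def test_empty_measured_set_rejected(self, norm_cells):
        with pytest.raises(ValueError):
            module_score(norm_cells, ["not_a_gene"])

    def test_agrees_with_scanpy_scoring(self, norm_cells, cell_data):
        # independent implementation of the same binned-control scheme;
        # control draws differ, so agreement is checked by correlation
        import anndata as ad
        import scanpy as sc

        cells, truth = cell_data
        adata = ad.AnnData(
            X=norm_cells.values.copy(),
            obs=pd.DataFrame(index=norm_cells.obs_ids.astype(str)),
            var=pd.DataFrame(index=norm_cells.gene_ids.astype(str)),
        )
        sc.tl.score_genes(
            adata, truth.interface_program, score_name="ref", ctrl_size=100, random_state=0
        )
        ours = module_score(norm_cells, truth.interface_program, seed=0)
        r = np.corrcoef(ours.values(), adata.obs["ref"].to_numpy())[0, 1]
        assert r > 0.95


class TestBuildSignature:
    universe = ["a", "b", "c", "rps1", "rpl7", "d"]

    def test_intersection_minus_ribosomal(self):
        tables = [
            _marker_table({"a", "b", "rps1"}, self.universe),
            _marker_table({"a", "b", "c"}, self.universe),
            _marker_table({"a", "b"}, self.universe),
        ]
        sig = build_interface_signature(tables)
        assert sig.genes == ["a", "b"]

    def test_ribosomal_prefix_case_insensitive(self):
        tables = [
            _marker_table({"a", "RPS1".lower(), "rpl7"}, self.universe),
            _marker_table({"a", "rps1", "rpl7"}, self.universe),
        ]
        sig = build_interface_signature(tables)
        assert sig.genes == ["a"]

    def test_empty_table_gives_empty_signature_with_warning(self):
        tables = [
            _marker_table({"a"}, self.universe),
            _marker_table(set(), self.universe),
        ]
        with pytest.warns(UserWarning):
            sig = build_interface_signature(tables)
        assert sig.genes == []

    def test_table_order_invariance(self):
        t1 = _marker_table({"a", "b", "d"}, self.universe)
        t2 = _marker_table({"b", "d"}, self.universe)
        t3 = _marker_table({"a", "b", "c", "d"}, self.universe)
        assert (
            build_interface_signature([t1, t2, t3]).genes
            == build_interface_signature([t3, t1, t2]).genes
        )

    def test_single_table_rejected(self):
        with pytest.raises(ValueError):
            build_interface_signature([_marker_table({"a"}, self.universe)])

    def test_planted_program_recovered_across_modalities(self):
        from interface_atlas.markers import ranksum_markers
        from interface_atlas.preprocess import normalize_dataset
        from interface_atlas.synthio import SynthConfig, generate_cells, generate_spatial

        cfg = SynthConfig(seed=17)
        spots, truth = generate_spatial(cfg)
        cells, _ = generate_cells(cfg, "cell")
        nuclei, _ = generate_cells(cfg, "nucleus")

        def merge(labels):
            return np.array(
                ["interface" if str(l).startswith("interface") else str(l) for l in labels],
                dtype=object,
            )

        tables = [
            ranksum_markers(normalize_dataset(spots), spots.cluster_of_spot, "interface"),
            ranksum_markers(normalize_dataset(cells), merge(cells.cluster_of_cell), "interface"),
            ranksum_markers(normalize_dataset(nuclei), merge(nuclei.cluster_of_cell), "interface"),
        ]
        sig = set(build_interface_signature(tables).genes)
        program = set(truth.interface_program)
        # the shared planted program is recovered nearly exactly
        assert len(sig & program) / len(program) >= 0.9
        # and nothing planted as tumor-only or muscle-only leaks in
        assert not (sig & (set(truth.marker_genes["tumor"]) | set(truth.marker_genes["muscle"])))


class TestScoreCorrelation:
    def _scores(self, a, b):
        idx = [f"o{i}" for i in range(len(a))]
        from interface_atlas.signatures import ModuleScore

        return (
            ModuleScore(pd.Series(a, index=idx), "a", 24, 100, 0),
            ModuleScore(pd.Series(b, index=idx), "b", 24, 100, 0),
        )

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        sa, sb = self._scores(a, -a)
        r, p = score_correlation(sa, sb)
        assert r == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        # x=(1,2,3,4), y=(1,3,2,4): r = 0.8, matches hand Pearson
        sa, sb = self._scores([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0])
        r, p = score_correlation(sa, sb)
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_independent_scores_near_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sa, sb = self._scores(rng.normal(0, 1, 300), rng.normal(0, 1, 300))
            r, _ = score_correlation(sa, sb)
            hits += abs(r) < 0.15
        assert hits >= 19

    def test_zero_variance_reported_missing(self):
        sa, sb = self._scores([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            r, p = score_correlation(sa, sb)
        assert np.isnan(r) and np.isnan(p)

    def test_subset_restriction(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 100)
        b = np.concatenate([-a[:50], rng.normal(0, 1, 50)])
        sa, sb = self._scores(a, b)
        r_sub, _ = score_correlation(sa, sb, subset=[f"o{i}" for i in range(50)])
        assert r_sub == pytest.approx(-1.0)


class TestClassify:
    def _ms(self, values):
        from interface_atlas.signatures import ModuleScore

        return ModuleScore(
            pd.Series(values, index=[f"o{i}" for i in range(len(values))]),
            "sig", 24, 100, 0,
        )

    def test_all_equal_none_classified(self):
        out = classify_by_signature(self._ms(np.full(20, 0.3)))
        assert not out.any()

    def test_single_outlier_only_classified(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.01, 1000)
        vals[123] = 5.0
        out = classify_by_signature(self._ms(vals))
        assert out.sum() == 1 and out.iloc[123]

    def test_explicit_threshold(self):
        out = classify_by_signature(self._ms(np.array([0.1, 0.6, 0.4])), threshold=0.5)
        assert out.tolist() == [False, True, False]

    def test_planted_interface_cells_detected(self, cell_data, norm_cells):
        cells, truth = cell_data
        ms = module_score(norm_cells, truth.interface_program, seed=0)
        is_iface = np.array(
            [str(s).startswith("interface") for s in cells.cluster_of_cell]
        )
        # threshold chosen per the signature-score distribution of
        # non-interface cells (mean + 2 sd), as when screening a new dataset
        bg = ms.values()[~is_iface]
        thr = bg.mean() + 2 * bg.std(ddof=1)
        calls = classify_by_signature(ms, threshold=thr).to_numpy()
        sensitivity = calls[is_iface].mean()
        fpr = calls[~is_iface].mean()
        assert sensitivity >= 0.8
        assert fpr <= 0.05
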