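"""Dataset masking, strand-bias exclusion, rate filtering and PCA."""

from __future__ import annotations

import numpy as np
import pytest

from mitocomparator.phylo_prep import (build_concat_dataset, composition_pca,
                                       site_rates, slowfast_filter,
                                       strand_bias_filter)


def genes_of(widths, taxa=("t1", "t2", "t3", "t4")):
    rng = np.random.default_rng(0)
    out = {}
    for gi, w in enumerate(widths):
        out[f"gene{gi}"] = {t: "".join(rng.choice(list("ACDEFGHIK"), size=w))
                            for t in taxa}
    return out


class TestConcatenation:
    def test_score_mask_keeps_high_confidence_columns(self):
        aln = {"nad2": {"a": "MKLV", "b": "MKIV"}}
        d = build_concat_dataset(aln, {"nad2": "9562"}, score_threshold=5)
        assert d.matrix == ("ML", "MI")   # columns scoring 9 and 6 retained
        assert d.gene_partitions == {"nad2": (1, 2)}
        assert d.column_scores == (9, 6)

    def test_threshold_zero_keeps_all_scored_columns(self):
        aln = {"nad2": {"a": "MKLV", "b": "MKIV"}}
        d = build_concat_dataset(aln, {"nad2": "1111"}, score_threshold=0)
        assert d.n_columns == 4

    def test_partitions_tile_concatenation(self):
        genes = genes_of([10, 15])
        d = build_concat_dataset(genes, exclude_genes=())
        assert d.gene_partitions == {"gene0": (1, 10), "gene1": (11, 25)}

    def test_atp8_excluded_by_default(self):
        genes = genes_of([6])
        genes["atp8"] = {t: "MMMMMM" for t in ("t1", "t2", "t3", "t4")}
        d = build_concat_dataset(genes)
        assert "atp8" not in d.gene_partitions

    def test_missing_taxa_padded_and_recorded(self):
        aln = {"nad2": {"a": "MK", "b": "MK"}, "cox1": {"a": "LV"}}
        d = build_concat_dataset(aln, exclude_genes=())
        assert d.row("b")[d.gene_partitions["cox1"][0] - 1:] == "--"
        assert d.padded_taxa == {"cox1": ("b",)}

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_concat_dataset({"nad2": {"a": "MK"}},
                                 {"nad2": [3, 12]})

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            build_concat_dataset({"nad2": {"a": "MK", "b": "MK"}},
                                 {"nad2": "11"}, score_threshold=5)

    def test_masking_commutes_with_concatenation(self):
        """Masking per gene then concatenating equals concatenating all
        columns then selecting the same columns."""
        aln = {"g1": {"a": "MKLV", "b": "MRLV"},
               "g2": {"a": "AADE", "b": "ACDE"}}
        scores = {"g1": "9268", "g2": "7193"}
        masked = build_concat_dataset(aln, scores, exclude_genes=())
        unmasked = build_concat_dataset(aln, exclude_genes=())
        keep = [i for i, s in enumerate("92687193") if int(s) > 5]
        assert masked.matrix == unmasked.select_columns(keep).matrix


class TestStrandBias:
    taxa = ("t1", "t2", "t3")

    def _dataset(self, genes):
        return build_concat_dataset(
            {g: {t: "M" * 5 for t in self.taxa} for g in genes},
            exclude_genes=())

    def test_balanced_gene_retained(self):
        # GGG/GGC alternating: equal G and C bases at fourfold third sites
        cds = {"t1": "GGGGGC" * 20, "t2": "GGCGGG" * 20, "t3": "GGGGGC" * 20}
        d = self._dataset(["g1"])
        filtered, decisions = strand_bias_filter(d, {"g1": cds})
        assert decisions[0].excluded is False
        assert "g1" in filtered.gene_partitions

    def test_heavily_skewed_gene_excluded(self):
        # fourfold third positions 90% G, 10% C
        cds = {t: "GGG" * 90 + "GGC" * 10 for t in self.taxa}
        d = self._dataset(["g1"])
        filtered, decisions = strand_bias_filter(d, {"g1": cds})
        assert decisions[0].excluded is True
        assert decisions[0].n_biased == 3
        assert "g1" not in filtered.gene_partitions
        assert filtered.n_columns == 0

    def test_gene_without_degenerate_sites_flagged_retained(self):
        cds = {t: "TTTAAA" * 10 for t in self.taxa}  # Phe/Lys: no 4-fold sites
        d = self._dataset(["g1"])
        filtered, decisions = strand_bias_filter(d, {"g1": cds})
        assert decisions[0].flagged_no_degenerate_sites
        assert not decisions[0].excluded

    def test_alpha_one_boundary(self):
        # p-values are never < 1 for perfectly balanced counts: p == 1 ties
        cds = {t: "GGGGGC" * 10 for t in self.taxa}
        d = self._dataset(["g1"])
        _, decisions = strand_bias_filter(d, {"g1": cds}, alpha=1.0)
        assert decisions[0].excluded is False


class TestSlowFast:
    def test_invariant_column_has_rate_zero(self):
        d = build_concat_dataset(
            {"g": {"a": "M", "b": "M", "c": "M", "d": "M"}}, exclude_genes=())
        assert site_rates(d, {"a": "x", "b": "x", "c": "y", "d": "y"}) == (0,)

    def test_hand_counted_rates(self):
        # column 1: groups {A,A} and {B,B} -> 0 steps;
        # column 2: groups {A,C} and {B,D} -> 1 + 1 = 2 steps
        d = build_concat_dataset(
            {"g": {"a": "AA", "b": "AC", "c": "BB", "d": "BD"}},
            exclude_genes=())
        assert site_rates(d, {"a": "x", "b": "x", "c": "y", "d": "y"}) == (0, 2)

    def test_quartile_selection_on_distinct_ranks(self):
        """8 columns with rates 0..7: the internal quartiles keep exactly
        the sites ranked 3-6 (rates 2..5)."""
        taxa = [f"x{i}" for i in range(5)] + [f"y{i}" for i in range(5)]
        groups = {t: t[0] for t in taxa}
        letters = "CDEFGHIKLM"   # never the background state A
        matrix_cols = []
        for rate in range(8):
            gx = min(rate, 4)        # steps in group x (max 4)
            gy = rate - gx
            col = []
            for i in range(5):
                col.append(letters[i] if i < gx else "A")
            for i in range(5):
                col.append(letters[5 + i] if i < gy else "A")
            matrix_cols.append("".join(col))
        aln = {"g": {t: "".join(matrix_cols[c][j] for c in range(8))
                     for j, t in enumerate(taxa)}}
        d = build_concat_dataset(aln, exclude_genes=())
        filtered, vec = slowfast_filter(d, groups)
        assert vec.rates == tuple(range(8))
        assert vec.retained_mask() == [False, False, True, True,
                                       True, True, False, False]
        assert filtered.n_columns == 4

    def test_tied_boundary_sites_all_retained(self):
        d = build_concat_dataset(
            {"g": {"a": "MMMM", "b": "MMMM", "c": "MMMM", "d": "MMMM"}},
            exclude_genes=())
        filtered, vec = slowfast_filter(d, {"a": "x", "b": "x",
                                            "c": "y", "d": "y"})
        assert filtered.n_columns == 4       # degenerate quartiles keep all
        assert set(vec.quartile_labels) == {"Q2"}

    def test_rates_invariant_under_within_group_reordering(self):
        aln = {"g": {"a": "AC", "b": "CC", "c": "DD", "d": "DE"}}
        groups = {"a": "x", "b": "x", "c": "y", "d": "y"}
        d1 = build_concat_dataset(aln, exclude_genes=())
        swapped = {"g": {"a": aln["g"]["b"], "b": aln["g"]["a"],
                         "c": aln["g"]["d"], "d": aln["g"]["c"]}}
        d2 = build_concat_dataset(swapped, exclude_genes=())
        assert site_rates(d1, groups) == site_rates(d2, groups)

    def test_small_group_rejected(self):
        d = build_concat_dataset({"g": {"a": "M", "b": "M"}}, exclude_genes=())
        with pytest.raises(ValueError):
            site_rates(d, {"a": "x", "b": "y"})

    def test_spread_rates_retain_about_half(self):
        """With rates spread nearly uniformly over a wide range, the two
        internal quartiles plus small boundary tie-blocks keep 40-60% of
        columns."""
        from mitocomparator.synthetic_data import (RateClassConfig,
                                                   gen_rate_class_alignment)
        cfg = RateClassConfig(group_sizes=(11, 11),
                              class_rates=tuple(range(21)),
                              sites_per_class=19)
        aln, groups, _ = gen_rate_class_alignment(cfg, seed=4)
        d = build_concat_dataset({"g": aln}, exclude_genes=())
        filtered, _ = slowfast_filter(d, groups)
        assert 0.4 <= filtered.n_columns / d.n_columns <= 0.6


class TestCompositionPca:
    def test_single_axis_variation(self):
        comps = {f"t{i}": [0.25 + 0.02 * i, 0.25 - 0.02 * i, 0.25, 0.25]
                 for i in range(5)}
        r = composition_pca(comps)
        assert r.variance_explained[0] == pytest.approx(1.0)

    def test_identical_compositions_flagged(self):
        comps = {f"t{i}": [0.3, 0.2, 0.2, 0.3] for i in range(4)}
        r = composition_pca(comps)
        assert r.degenerate

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(6)
        raw = rng.dirichlet([5, 3, 3, 5], size=10)
        comps = {f"t{i}": raw[i] for i in range(10)}
        r = composition_pca(comps)
        X = np.array([comps[t] for t in r.taxa])
        centred = X - X.mean(axis=0)
        assert np.allclose(r.scores @ r.loadings, centred, atol=1e-10)
        assert np.all(r.variance_explained >= -1e-12)
        assert r.variance_explained.sum() <= 1 + 1e-9

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            composition_pca({"a": [0.25] * 4, "b": [0.25] * 4})
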