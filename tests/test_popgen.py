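"""Population analysis: MAF filtering, distances, NJ trees, PCA, the
Fisher's-exact enrichment scan, and the core-variant paired comparison."""

import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_two_sided, paired_t, random_additive_tree
from tipscan.popgen import (
    cds_length_contrast,
    core_variant_comparison,
    enrichment_scan,
    fisher_exact_2x2,
    maf_filter,
    minor_allele_frequency,
    nj_tree,
    pairwise_distance,
    pca,
)
from tipscan.synthetic import simulate_population_matrix


def _matrix(rows: dict[str, str]) -> pd.DataFrame:
    data = {lid: list(codes.split()) for lid, codes in rows.items()}
    n = len(next(iter(data.values())))
    return pd.DataFrame.from_dict(data, orient="index", columns=[f"a{i}" for i in range(n)])


class TestMAF:
    def test_rare_locus_removed(self):
        codes = pd.DataFrame([["CC"] * 3 + ["GG"] * 97], index=["L1"],
                             columns=[f"a{i}" for i in range(100)])
        with pytest.warns(UserWarning):
            assert len(maf_filter(codes)) == 0

    def test_common_locus_kept(self):
        codes = pd.DataFrame([["CC"] * 10 + ["GG"] * 90], index=["L1"],
                             columns=[f"a{i}" for i in range(100)])
        assert len(maf_filter(codes)) == 1

    def test_nn_excluded_from_denominator(self):
        # 5 CC / 90 GG / 5 NN: MAF = 5/95 ~ 0.0526 > 0.05 -> kept
        codes = pd.DataFrame([["CC"] * 5 + ["GG"] * 90 + ["NN"] * 5], index=["L1"],
                             columns=[f"a{i}" for i in range(100)])
        maf = minor_allele_frequency(codes)
        assert maf["L1"] == pytest.approx(5 / 95)
        assert len(maf_filter(codes)) == 1

    def test_cg_contributes_one_allele_of_each(self):
        codes = pd.DataFrame([["CG"] * 10], index=["L1"], columns=[f"a{i}" for i in range(10)])
        assert minor_allele_frequency(codes)["L1"] == pytest.approx(0.5)

    def test_monotone_in_threshold(self):
        codes, _, _ = simulate_population_matrix(100, [("a", 60)], neutral_freq_range=(0.0, 0.3), seed=3)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            survivors = [set(maf_filter(codes, t).index) for t in (0.02, 0.05, 0.10)]
        assert survivors[2] <= survivors[1] <= survivors[0]


class TestDistance:
    def test_identical_accessions_distance_zero(self):
        codes = _matrix({"L1": "CC CC", "L2": "GG GG"})
        d = pairwise_distance(codes)
        assert d.iloc[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        codes = pd.DataFrame({"a0": ["CC"] * 10, "a1": ["GG"] * 10},
                             index=[f"L{i}" for i in range(10)])
        assert pairwise_distance(codes).iloc[0, 1] == 1.0

    def test_fractional_mismatch(self):
        codes = pd.DataFrame({"a0": ["CC"] * 10, "a1": ["GG"] * 2 + ["CC"] * 8},
                             index=[f"L{i}" for i in range(10)])
        assert pairwise_distance(codes).iloc[0, 1] == pytest.approx(0.2)

    def test_het_counts_half(self):
        codes = _matrix({"L1": "CC CG", "L2": "GG GG"})
        assert pairwise_distance(codes).iloc[0, 1] == pytest.approx(0.25)

    def test_all_nn_accession_rejected(self):
        codes = _matrix({"L1": "CC NN", "L2": "GG NN"})
        with pytest.raises(ValueError, match="all-NN"):
            pairwise_distance(codes)

    def test_symmetry_and_zero_diagonal(self):
        codes, _, _ = simulate_population_matrix(50, [("a", 8)], seed=4, nn_rate=0.05)
        d = pairwise_distance(codes).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC"))
        nwk = nj_tree(d)
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError):
            nj_tree(d)

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_additive_distances_recover_tree(self, n_taxa, rng):
        """NJ on distances that are exactly additive on a tree reproduces the
        tree's topology and path lengths."""
        import dendropy

        _, labels, dist = random_additive_tree(rng, n_taxa)
        D = pd.DataFrame([[dist[a][b] for b in labels] for a in labels],
                         index=labels, columns=labels)
        nwk = nj_tree(D)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a in labels:
            for b in labels:
                if a < b:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        dist[a][b], abs=1e-9
                    )

    def test_agrees_with_skbio_on_additive_input(self, rng):
        import dendropy
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        _, labels, dist = random_additive_tree(rng, 7)
        D = pd.DataFrame([[dist[a][b] for b in labels] for a in labels],
                         index=labels, columns=labels)
        D = (D + D.T) / 2  # remove float asymmetry from path summation order
        ours = dendropy.Tree.get(data=nj_tree(D), schema="newick",
                                 taxon_namespace=dendropy.TaxonNamespace(labels))
        theirs = dendropy.Tree.get(
            data=str(skbio_nj(DistanceMatrix(D.to_numpy(), ids=labels))),
            schema="newick", taxon_namespace=ours.taxon_namespace,
        )
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0

    def test_two_groups_form_clades(self):
        """A population with group-disjoint carrier loci yields a tree in
        which each group is monophyletic."""
        import dendropy

        codes, groups, _ = simulate_population_matrix(
            60, [("g1", 6), ("g2", 6)],
            enriched={i: ((0.95, 0.02) if i < 30 else (0.02, 0.95)) for i in range(60)},
            seed=5,
        )
        tree = dendropy.Tree.get(data=nj_tree(pairwise_distance(codes)), schema="newick")
        tree.encode_bipartitions()
        g1 = [t for t in tree.taxon_namespace if t.label.startswith("g1")]
        mrca = tree.mrca(taxa=g1)
        assert {l.taxon.label for l in mrca.leaf_iter()} == {t.label for t in g1}


class TestPCA:
    def test_two_groups_separate_on_pc1(self):
        codes, groups, _ = simulate_population_matrix(
            80, [("g1", 10), ("g2", 10)],
            enriched={i: ((0.9, 0.05) if i < 40 else (0.05, 0.9)) for i in range(80)},
            seed=6,
        )
        res = pca(codes, k=3)
        pc1 = res.coordinates["PC1"]
        s1 = np.sign(pc1[groups[groups == "g1"].index])
        s2 = np.sign(pc1[groups[groups == "g2"].index])
        assert len(set(s1)) == 1 and len(set(s2)) == 1 and s1.iloc[0] != s2.iloc[0]

    def test_identical_accessions_zero_variance(self):
        codes = pd.DataFrame({f"a{i}": ["CC", "GG"] for i in range(5)}, index=["L1", "L2"])
        res = pca(codes, k=2)
        assert np.allclose(res.explained_variance, 0)

    def test_eigenvalues_nonincreasing_and_bounded(self):
        codes, _, _ = simulate_population_matrix(60, [("a", 15)], seed=7)
        res = pca(codes, k=10)
        ev = res.explained_variance
        assert all(ev[i] >= ev[i + 1] - 1e-12 for i in range(len(ev) - 1))
        assert res.explained_ratio.sum() <= 1.0 + 1e-12

    def test_k_truncated_with_warning(self):
        codes, _, _ = simulate_population_matrix(20, [("a", 5)], seed=8)
        with pytest.warns(UserWarning, match="truncating"):
            res = pca(codes, k=10)
        assert res.coordinates.shape[1] == 4


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_small_table_brute_force_value(self):
        # margins (4,4,4,4): enumeration gives 34/70
        assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70, rel=1e-9)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_two_sided(a, b, c, d), rel=1e-7
            )


class TestScan:
    def test_equal_frequencies_give_p_one(self):
        codes = _matrix({"L1": "CC GG CC GG"})
        scan = enrichment_scan(codes, ["a0", "a1"], ["a2", "a3"])
        row = scan.iloc[0]
        assert row.p == 1.0 and row.neg_log10_p == 0.0

    def test_counts_exclude_nn_and_count_cg_as_carrier(self):
        codes = _matrix({"L1": "CC CG NN GG GG NN"})
        scan = enrichment_scan(codes, ["a0", "a1", "a2"], ["a3", "a4", "a5"])
        row = scan.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (2, 0, 0, 2)

    def test_planted_enriched_loci_rank_smallest_p(self):
        codes, groups, enriched_ids = simulate_population_matrix(
            500, [("derived", 329), ("control", 195)],
            enriched={i: (0.8, 0.02) for i in range(5)}, seed=9,
        )
        scan = enrichment_scan(
            codes, list(groups[groups == "derived"].index), list(groups[groups == "control"].index)
        )
        assert set(scan.head(5).locus_id) == set(enriched_ids)

    def test_z_scores_standardized(self):
        codes, groups, _ = simulate_population_matrix(200, [("d", 60), ("c", 40)], seed=10)
        scan = enrichment_scan(
            codes, list(groups[groups == "d"].index), list(groups[groups == "c"].index)
        )
        assert scan.z.mean() == pytest.approx(0.0, abs=1e-12)
        assert scan.z.std(ddof=0) == pytest.approx(1.0, rel=1e-12)

    def test_overlapping_groups_rejected(self):
        codes = _matrix({"L1": "CC GG"})
        with pytest.raises(ValueError):
            enrichment_scan(codes, ["a0"], ["a0", "a1"])


class TestCoreVariants:
    def test_identical_columns_give_t_zero(self):
        tip = {f"g{i}": [0.2] for i in range(5)}
        snp = {f"g{i}": [0.2] for i in range(5)}
        res, recs = core_variant_comparison(tip, snp)
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_nonzero_diffs_flagged_degenerate(self):
        tip = {f"g{i}": [0.1] for i in range(4)}
        snp = {f"g{i}": [0.2] for i in range(4)}
        res, _ = core_variant_comparison(tip, snp)
        assert res.degenerate and res.p == 0.0 and res.t < 0

    def test_core_is_min_p_and_missing_snp_reported_separately(self):
        tip = {"g1": [0.5, 0.01], "g2": [0.3], "g3": [0.2], "g4": [0.4]}
        snp = {"g1": [0.6, 0.2], "g2": [0.9], "g3": [0.1]}
        res, recs = core_variant_comparison(tip, snp)
        by_gene = {r.gene_id: r for r in recs}
        assert by_gene["g1"].core_tip_p == 0.01
        assert by_gene["g1"].core_snp_p == 0.2
        assert by_gene["g4"].core_snp_p is None
        assert res.n_pairs == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            core_variant_comparison({"g1": [0.1], "g2": [0.2]}, {"g1": [0.3], "g2": [0.4]})

    def test_matches_closed_form_paired_t(self, rng):
        diffs = rng.normal(0.05, 0.02, size=20)
        snp_ps = rng.uniform(0.2, 0.8, size=20)
        tip = {f"g{i}": [float(snp_ps[i] - diffs[i])] for i in range(20)}
        snp = {f"g{i}": [float(snp_ps[i])] for i in range(20)}
        res, _ = core_variant_comparison(tip, snp)
        t, df, p = paired_t([tip[f"g{i}"][0] for i in range(20)], [snp[f"g{i}"][0] for i in range(20)])
        assert res.t == pytest.approx(t)
        assert res.df == df
        assert res.p == pytest.approx(p)


class TestCDSContrast:
    def test_equal_proportions_p_one(self):
        assert cds_length_contrast(10, 10, 100, 100) == 1.0

    def test_matches_fisher(self):
        assert cds_length_contrast(14, 8, 317, 327) == pytest.approx(
            fisher_exact_2x2(14, 8, 317, 327)
        )
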