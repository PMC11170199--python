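"""Spatial mapping: each stage against an oracle, plus end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

from tomomap import (
    CorrelationMap,
    SimulationConfig,
    assign_cluster_position,
    cluster_fold_changes,
    filter_reference_genes,
    generate_cell_matrix,
    generate_section_reference,
    map_clusters_to_sections,
    match_genes,
    pseudobulk_profile,
    quality_proxy,
    section_fold_changes,
    spatial_correlation,
    subcluster_concordance,
)


def _df(data, genes=None, cols=None):
    data = np.asarray(data, dtype=float)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    cols = cols if cols is not None else list(range(1, data.shape[1] + 1))
    return pd.DataFrame(data, index=genes, columns=cols)


class TestReferenceFilter:
    def test_boundary_less_than_20_removed_20_retained(self):
        ref = _df([[19] * 5, [0, 0, 20, 0, 0]])
        out = filter_reference_genes(ref)
        assert list(out.index) == ["g1"]

    def test_zero_threshold_is_identity(self):
        ref = _df([[1, 2], [0, 0]])
        assert filter_reference_genes(ref, 0).equals(ref)

    def test_matches_row_max_scan_oracle(self):
        rng = np.random.default_rng(1)
        ref = _df(rng.integers(0, 60, size=(200, 12)))
        out = filter_reference_genes(ref)
        expected = [g for g in ref.index
                    if max(ref.loc[g].tolist()) >= 20]  # brute-force scan
        assert list(out.index) == expected

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_reference_genes(_df([[1, 2, 3]]))


class TestFoldChanges:
    def test_section_fc_arithmetic(self):
        fc = section_fold_changes(_df([[2, 4, 6]]))
        np.testing.assert_allclose(fc.to_numpy()[0], [0.5, 1.0, 1.5])

    def test_constant_row_gives_ones(self):
        fc = section_fold_changes(_df([[5, 5, 5, 5]]))
        np.testing.assert_allclose(fc.to_numpy(), 1.0)

    def test_mean_of_fc_is_one_for_every_retained_gene(self):
        rng = np.random.default_rng(2)
        smoothed = _df(rng.uniform(0, 100, size=(300, 40)))
        fc = section_fold_changes(smoothed)
        np.testing.assert_allclose(fc.mean(axis=1), 1.0, atol=1e-9)

    def test_zero_mean_row_yields_zeros(self):
        fc = section_fold_changes(_df([[0, 0, 0]]))
        np.testing.assert_allclose(fc.to_numpy(), 0.0)

    def test_cluster_fc_is_power_of_two(self):
        s = pd.Series([0.0, 1.0, -2.0], index=["a", "b", "c"])
        fc = cluster_fold_changes(s)
        np.testing.assert_allclose(fc.to_numpy(), [1.0, 2.0, 0.25])
        np.testing.assert_allclose(np.log2(fc), s, atol=1e-12)

    def test_cluster_fc_skips_missing(self):
        s = pd.Series([1.0, np.nan], index=["a", "b"])
        assert list(cluster_fold_changes(s).index) == ["a"]


class TestMatching:
    def test_zero_drop_rule(self):
        cluster = pd.Series({"g1": 2.0, "g2": 0.0, "g3": 1.0})
        section = _df([[1.0], [3.0], [2.0]], genes=["g1", "g2", "g4"])
        cv, sv, n = match_genes(cluster, section, 1)
        assert n == 1
        assert (cv[0], sv[0]) == (2.0, 1.0)

    def test_disjoint_ids(self):
        cluster = pd.Series({"a": 1.0})
        section = _df([[1.0]], genes=["b"])
        assert match_genes(cluster, section, 1)[2] == 0

    def test_matches_dictionary_join_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in rng.choice(800, 500, replace=False)]
        cluster = pd.Series(rng.choice([0.0, 1.5, 2.0], 500), index=genes)
        sgenes = [f"g{i}" for i in rng.choice(800, 500, replace=False)]
        section = _df(rng.choice([0.0, 0.5, 3.0], (500, 1)), genes=sgenes)
        cv, sv, n = match_genes(cluster, section, 1)
        cdict = cluster.to_dict()
        sdict = section[1].to_dict()
        expected = sorted((cdict[g], sdict[g]) for g in cdict
                          if g in sdict and cdict[g] != 0 and sdict[g] != 0)
        assert sorted(zip(cv, sv)) == expected
        assert n == len(expected)


class TestCorrelation:
    def test_perfect_linear_pairs(self):
        cfc = pd.Series([1.0, 2, 3], index=list("abc"), name="X")
        up = _df([[2.0], [4], [6]], genes=list("abc"))
        down = _df([[3.0], [2], [1]], genes=list("abc"))
        assert spatial_correlation(cfc, up).rho.iloc[0, 0] == pytest.approx(1.0)
        assert spatial_correlation(cfc, down).rho.iloc[0, 0] == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(0.1, 5, 20), rng.uniform(0.1, 5, 20)
        cfc = pd.Series(x, index=[f"g{i}" for i in range(20)])
        sfc = _df(y[:, None], genes=list(cfc.index))
        rho = spatial_correlation(cfc, sfc).rho.iloc[0, 0]
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_missing_below_min_matched_and_constant(self):
        cfc = pd.Series([1.0, 2.0], index=["a", "b"])
        sfc = _df([[1.0], [2.0]], genes=["a", "b"])
        assert np.isnan(spatial_correlation(cfc, sfc, min_matched=3).rho.iloc[0, 0])
        const = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        sfc3 = _df([[1.0], [2.0], [3.0]], genes=list("abc"))
        assert np.isnan(spatial_correlation(const, sfc3).rho.iloc[0, 0])

    def test_invariant_to_gene_and_cluster_ordering(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        cfc = pd.DataFrame(rng.uniform(0.1, 4, (50, 3)), index=genes,
                           columns=["A", "B", "C"])
        sfc = _df(rng.uniform(0.1, 4, (50, 6)), genes=genes)
        base = spatial_correlation(cfc, sfc)
        perm = rng.permutation(genes)
        shuffled = spatial_correlation(cfc.loc[perm, ["C", "A", "B"]],
                                       sfc.loc[perm])
        np.testing.assert_allclose(
            base.rho.loc[["A", "B", "C"]].to_numpy(),
            shuffled.rho.loc[["A", "B", "C"]].to_numpy(), atol=1e-12)


class TestQualityAndAssignment:
    def _cmap(self, counts, rho=None):
        counts = np.asarray(counts)[None, :]
        rho = (np.asarray(rho)[None, :] if rho is not None
               else np.zeros_like(counts, dtype=float))
        sections = list(range(1, counts.shape[1] + 1))
        return CorrelationMap(
            rho=pd.DataFrame(rho, index=["c"], columns=sections),
            n_compared=pd.DataFrame(counts, index=["c"], columns=sections))

    def test_uniform_counts_no_flags(self):
        cmap = quality_proxy(self._cmap([100, 100, 100]))
        np.testing.assert_allclose(cmap.section_quality_ratio, 1.0)
        assert not cmap.low_support.any()

    def test_ratio_arithmetic_and_flag(self):
        cmap = quality_proxy(self._cmap([200, 200, 40]))
        assert cmap.avg_compared == pytest.approx(146.667, abs=1e-3)
        np.testing.assert_allclose(cmap.section_quality_ratio,
                                   [1.3636, 1.3636, 0.2727], atol=1e-4)
        assert list(cmap.low_support) == [False, False, True]

    def test_flags_follow_section_permutation(self):
        a = quality_proxy(self._cmap([200, 40, 200]))
        b = quality_proxy(self._cmap([40, 200, 200]))
        assert list(a.low_support) == [False, True, False]
        assert list(b.low_support) == [True, False, False]

    def test_argmax_assignment_and_tiebreak(self):
        cmap = self._cmap([9, 9, 9], rho=[0.1, 0.9, 0.3])
        assert assign_cluster_position(cmap)["c"] == 2
        tie = self._cmap([9, 9], rho=[0.5, 0.5])
        assert assign_cluster_position(tie)["c"] == 1

    def test_all_missing_rho_unassigned(self):
        cmap = self._cmap([0, 0], rho=[np.nan, np.nan])
        assert assign_cluster_position(cmap).isna().all()

    def test_low_support_sections_excluded_from_argmax(self):
        cmap = quality_proxy(self._cmap([100, 100, 5],
                                        rho=[0.2, 0.5, 0.99]))
        assert assign_cluster_position(cmap)["c"] == 2


class TestSubclusterConcordance:
    def test_identical_subcluster_fully_concordant(self):
        genes = list("abcd")
        fc = pd.Series([1.0, 2, 3, 4], index=genes)
        rho = pd.Series([0.1, 0.5, 0.9], index=[1, 2, 3])
        out = subcluster_concordance(
            fc, fc.to_frame("s1"), rho,
            pd.DataFrame([rho.to_numpy()], index=["s1"], columns=rho.index))
        assert out.loc["s1", "gene_corr"] == pytest.approx(1.0)
        assert out.loc["s1", "spatial_corr"] == pytest.approx(1.0)
        assert bool(out.loc["s1", "homogeneous"])

    def test_reversed_spatial_profile_anticorrelated(self):
        genes = list("abcd")
        fc = pd.Series([1.0, 2, 3, 4], index=genes)
        rho = pd.Series([-0.8, 0.0, 0.8], index=[1, 2, 3])
        sub_rho = pd.DataFrame([rho.to_numpy()[::-1]], index=["s1"],
                               columns=rho.index)
        out = subcluster_concordance(fc, fc.to_frame("s1"), rho, sub_rho)
        assert out.loc["s1", "spatial_corr"] == pytest.approx(-1.0)
        assert not bool(out.loc["s1", "homogeneous"])

    def test_too_few_shared_genes_missing(self):
        fc = pd.Series([1.0, 2], index=["a", "b"])
        rho = pd.Series([0.1, 0.5, 0.9], index=[1, 2, 3])
        sub_rho = pd.DataFrame([[0.1, 0.5, 0.9]], index=["s1"],
                               columns=[1, 2, 3])
        out = subcluster_concordance(fc, fc.to_frame("s1"), rho, sub_rho)
        assert np.isnan(out.loc["s1", "gene_corr"])
        assert not bool(out.loc["s1", "homogeneous"])

    def test_split_cluster_flagged_heterogeneous(self):
        """A parent merging anchored subclusters at distant sections is
        heterogeneous: the anterior minority deviates from the
        posterior-dominated parent, while a random split of a genuine
        cluster stays homogeneous."""
        cfg = SimulationConfig(n_genes=600, n_sections=40, n_cells=600,
                               n_clusters=8, count_noise=10.0, seed=31)
        ref, st = generate_section_reference(cfg)
        adata, _ = generate_cell_matrix(cfg, st)
        labels = adata.obs["cluster"].copy()
        # artificial parent: one anterior cluster merged with two
        # posterior ones
        subs = ["cluster00", "cluster06", "cluster07"]
        parent_labels = labels.where(~labels.isin(subs), "parent")
        prof_parent = pseudobulk_profile(adata, parent_labels)
        prof_sub = pseudobulk_profile(adata, labels)
        cmap_parent = map_clusters_to_sections(ref, prof_parent.log2fc)
        cmap_sub = map_clusters_to_sections(ref, prof_sub.log2fc)
        out = subcluster_concordance(
            prof_parent.log2fc["parent"].pipe(np.exp2),
            prof_sub.log2fc[subs].pipe(np.exp2),
            cmap_parent.rho.loc["parent"],
            cmap_sub.rho.loc[subs])
        assert not out["homogeneous"].all()
        assert not out.loc["cluster00", "homogeneous"]  # distant minority

        # control: an arbitrary split of one real cluster is concordant
        rng = np.random.default_rng(0)
        labels2 = adata.obs["cluster"].copy()
        in_c3 = labels2 == "cluster03"
        labels2.loc[in_c3] = np.where(rng.random(in_c3.sum()) < 0.5,
                                      "c03a", "c03b")
        prof_split = pseudobulk_profile(adata, labels2)
        prof_main = pseudobulk_profile(adata, adata.obs["cluster"])
        cmap_split = map_clusters_to_sections(ref, prof_split.log2fc)
        cmap_main = map_clusters_to_sections(ref, prof_main.log2fc)
        control = subcluster_concordance(
            prof_main.log2fc["cluster03"].pipe(np.exp2),
            prof_split.log2fc[["c03a", "c03b"]].pipe(np.exp2),
            cmap_main.rho.loc["cluster03"],
            cmap_split.rho.loc[["c03a", "c03b"]])
        assert control["homogeneous"].all()


class TestEndToEndRecovery:
    def test_anchored_clusters_recovered_within_two_sections(self):
        cfg = SimulationConfig(n_genes=800, n_sections=40, n_cells=1000,
                               n_clusters=8, count_noise=5.0, seed=13)
        ref, st = generate_section_reference(cfg)
        adata, _ = generate_cell_matrix(cfg, st)
        prof = pseudobulk_profile(adata, adata.obs["cluster"])
        cmap = map_clusters_to_sections(ref, prof.log2fc)
        anchors = adata.uns["cluster_anchor_sections"]
        errors = {c: abs(int(cmap.assigned_section[c]) - a)
                  for c, a in anchors.items()}
        assert sum(e <= 2 for e in errors.values()) >= 7

    def test_assignment_error_non_decreasing_with_noise(self):
        """Mean |assignment - anchor| averaged over seeds grows (weakly)
        as NB dispersion drops (more noise)."""
        grid = [200.0, 5.0, 0.4]  # decreasing dispersion = increasing noise
        mean_errors = []
        for disp in grid:
            errs = []
            for seed in range(20):
                cfg = SimulationConfig(n_genes=300, n_sections=30,
                                       n_cells=240, n_clusters=6,
                                       count_noise=disp, seed=100 + seed)
                ref, st = generate_section_reference(cfg)
                adata, _ = generate_cell_matrix(cfg, st)
                prof = pseudobulk_profile(adata, adata.obs["cluster"])
                cmap = map_clusters_to_sections(ref, prof.log2fc)
                anchors = adata.uns["cluster_anchor_sections"]
                for c, a in anchors.items():
                    pos = cmap.assigned_section[c]
                    if not pd.isna(pos):
                        errs.append(abs(int(pos) - a))
            mean_errors.append(np.mean(errs))
        assert mean_errors[0] <= mean_errors[1] <= mean_errors[2]
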