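import itertools

import numpy as np
import pandas as pd
import pytest

from e3ome.expression import (
    CapacityError,
    CountMatrix,
    LayerError,
    SampleMetadata,
    auc_scale,
    cp10k_normalize,
    de_call,
    filter_classes,
    log1p_transform,
    rank_sum_exact_p,
    rank_sum_normal_p,
    restrict_panel,
    rowwise_zscore,
    sample_donors,
    wilcoxon_ovr,
)


def make_metadata(n_tissues, donors_per_tissue, samples_per_donor=1):
    out = []
    d = 0
    for t in range(n_tissues):
        for _ in range(donors_per_tissue):
            d += 1
            for s in range(samples_per_donor):
                out.append(
                    SampleMetadata(f"D{d:03d}-S{s}", f"D{d:03d}", f"tis{t:02d}")
                )
    return out


class TestSampleDonors:
    def test_31_tissues_yield_279_samples(self):
        metadata = make_metadata(31, 12, samples_per_donor=2)
        retained = sample_donors(metadata, per_tissue=9, seed=42)
        assert len(retained) == 279
        per_tissue = pd.Series([m.tissue for m in retained]).value_counts()
        assert (per_tissue == 9).all()

    def test_one_sample_per_donor_and_disjoint_donors(self):
        metadata = make_metadata(4, 10, samples_per_donor=3)
        retained = sample_donors(metadata, per_tissue=9, seed=1)
        donors = [m.donor for m in retained]
        assert len(donors) == len(set(donors))
        donor_tissue = {}
        for m in retained:
            assert donor_tissue.setdefault(m.donor, m.tissue) == m.tissue

    def test_exact_capacity_keeps_all(self):
        metadata = make_metadata(1, 9)
        retained = sample_donors(metadata, per_tissue=9, seed=0)
        assert {m.donor for m in retained} == {m.donor for m in metadata}

    def test_deterministic_for_fixed_seed(self):
        metadata = make_metadata(5, 15, samples_per_donor=2)
        a = sample_donors(metadata, per_tissue=9, seed=42)
        b = sample_donors(metadata, per_tissue=9, seed=42)
        assert a == b
        c = sample_donors(metadata, per_tissue=9, seed=43)
        assert a != c

    def test_capacity_error_names_tissue(self):
        metadata = make_metadata(1, 8)
        with pytest.raises(CapacityError, match="tis00"):
            sample_donors(metadata, per_tissue=9)

    def test_multi_tissue_donor_assigned_once(self):
        metadata = make_metadata(2, 10) + [
            SampleMetadata("D001-X", "D001", "tis01")  # D001 also in tis00
        ]
        retained = sample_donors(metadata, per_tissue=9, seed=0)
        tissues = {m.tissue for m in retained if m.donor == "D001"}
        assert tissues <= {"tis00"}  # home tissue is the sorted-first one


class TestScalingAndPanels:
    def _matrix(self, values, layer="raw"):
        values = np.asarray(values, dtype=float)
        genes = [f"g{i}" for i in range(values.shape[0])]
        cols = [f"s{i}" for i in range(values.shape[1])]
        return CountMatrix(genes, cols, values, layer)

    def test_auc_scale_ratios(self):
        m = self._matrix([[1, 2], [3, 4]])
        scaled = auc_scale(m, {"s0": 2e7, "s1": 4e7}, target=4e7)
        assert scaled.layer == "auc_scaled"
        np.testing.assert_allclose(scaled.values[:, 0], [2, 6])  # doubled
        np.testing.assert_allclose(scaled.values[:, 1], [2, 4])  # identity

    def test_auc_scale_column_sums(self):
        rng = np.random.default_rng(5)
        m = self._matrix(rng.poisson(10, size=(20, 4)))
        auc = {f"s{i}": float(a) for i, a in enumerate(rng.uniform(1e6, 1e8, 4))}
        scaled = auc_scale(m, auc, target=4e7)
        for i in range(4):
            expected = m.values[:, i].sum() * 4e7 / auc[f"s{i}"]
            assert scaled.values[:, i].sum() == pytest.approx(expected)

    def test_auc_scale_rejects_nonpositive(self):
        m = self._matrix([[1]])
        with pytest.raises(ValueError):
            auc_scale(m, {"s0": 0.0})

    def test_auc_scale_layer_discipline(self):
        m = self._matrix([[1]], layer="cp10k")
        with pytest.raises(LayerError):
            auc_scale(m, {"s0": 1e7})

    def test_restrict_panel_subset_and_missing_report(self):
        m = self._matrix(np.arange(20).reshape(10, 2))
        panel = ["g3", "g1", "g7", "gX"]
        sub, missing = restrict_panel(m, panel)
        assert sub.genes == ["g3", "g1", "g7"]  # panel order preserved
        assert missing == ["gX"]
        np.testing.assert_array_equal(sub.values[0], m.values[3])

    def test_restrict_panel_identity_and_disjoint(self):
        m = self._matrix(np.ones((3, 2)))
        sub, missing = restrict_panel(m, m.genes)
        assert sub.genes == m.genes and missing == []
        with pytest.raises(ValueError):
            restrict_panel(m, ["nope"])


class TestCp10kAndLog1p:
    def test_cp10k_arithmetic(self):
        m = CountMatrix(["a", "b", "c"], ["cell"], [[1], [1], [2]], "raw")
        norm = cp10k_normalize(m)
        np.testing.assert_allclose(norm.values[:, 0], [2500, 2500, 5000])

    def test_all_zero_cell_clips_not_crashes(self):
        m = CountMatrix(["a"], ["c1", "c2"], [[0, 4]], "raw")
        norm = cp10k_normalize(m)
        assert norm.values[0, 0] == 0.0
        assert norm.values[0, 1] == 1e4

    def test_nonfinite_replaced_with_zero(self):
        m = CountMatrix(["a", "b"], ["c"], [[np.nan], [4]], "raw")
        norm = cp10k_normalize(m)
        assert norm.values[0, 0] == 0.0
        assert norm.values[1, 0] == 1e4

    def test_column_sums_ten_thousand(self):
        rng = np.random.default_rng(0)
        m = CountMatrix(
            [f"g{i}" for i in range(50)],
            [f"c{i}" for i in range(10)],
            rng.poisson(3, size=(50, 10)).astype(float),
            "raw",
        )
        norm = cp10k_normalize(m)
        np.testing.assert_allclose(norm.values.sum(axis=0), 1e4)

    def test_log1p_values_and_layer(self):
        m = CountMatrix(["a", "b"], ["c"], [[0], [np.e - 1]], "cp10k")
        out = log1p_transform(m)
        assert out.layer == "log1p"
        np.testing.assert_allclose(out.values[:, 0], [0.0, 1.0])

    def test_log1p_requires_cp10k_layer(self):
        m = CountMatrix(["a"], ["c"], [[1]], "raw")
        with pytest.raises(LayerError):
            log1p_transform(m)


class TestFilterClasses:
    def test_inclusive_threshold(self):
        labels = {}
        for cls, n in (("big", 25), ("small", 19), ("edge", 20)):
            for i in range(n):
                labels[f"{cls}{i}"] = cls
        assert filter_classes(labels, 20) == ["big", "edge"]

    def test_all_survive_cases(self):
        labels = {f"c{i}": "x" for i in range(30)}
        assert filter_classes(labels, 20) == ["x"]
        assert filter_classes({"c": "y"}, 1) == ["y"]

    def test_no_survivor_raises(self):
        with pytest.raises(CapacityError):
            filter_classes({"c1": "x"}, 20)


def exhaustive_two_sided_p(x, y):
    """Independent permutation oracle over all C(n, n1) group splits."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, n1 = len(pooled), len(x)
    mu = n1 * (n + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = sum(
        abs(ranks[list(combo)].sum() - mu) >= obs - 1e-12
        for combo in itertools.combinations(range(n), n1)
    )
    from math import comb

    return hits / comb(n, n1)


class TestRankSum:
    def test_most_extreme_split(self):
        # {1,2,3} vs {4,5,6}: 2 of C(6,3)=20 splits are as extreme
        assert rank_sum_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=n2).astype(float)
        assert rank_sum_exact_p(x, y) == pytest.approx(
            exhaustive_two_sided_p(x, y), abs=1e-10
        )

    def test_normal_approx_matches_scipy_tie_corrected(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        x = rng.poisson(3, 40).astype(float)
        y = rng.poisson(4, 60).astype(float)
        _, p = rank_sum_normal_p(x, y)
        expected = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert p == pytest.approx(expected, rel=1e-9)

    def test_zero_variance_gives_p_one(self):
        _, p = rank_sum_normal_p([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0


class TestWilcoxonOvr:
    def _toy(self, values, labels_list, layer="cp10k"):
        cols = [f"c{i}" for i in range(len(labels_list))]
        m = CountMatrix(
            [f"g{i}" for i in range(np.asarray(values).shape[0])],
            cols, values, layer,
        )
        return m, dict(zip(cols, labels_list))

    def test_exact_mode_on_tiny_input(self):
        m, labels = self._toy(
            [[1, 2, 3, 4, 5, 6]], ["a"] * 3 + ["b"] * 3
        )
        results = wilcoxon_ovr(m, labels)
        by_group = {r.group: r for r in results}
        assert by_group["a"].p == pytest.approx(0.1)
        assert by_group["b"].p == pytest.approx(0.1)

    def test_constant_gene_p_one(self):
        m, labels = self._toy(
            [[5.0] * 6, [1, 2, 3, 4, 5, 6]], ["a"] * 3 + ["b"] * 3
        )
        results = [r for r in wilcoxon_ovr(m, labels) if r.gene == "g0"]
        assert all(r.p == 1.0 for r in results)

    def test_bh_within_class_and_significance_flag(self):
        rng = np.random.default_rng(2)
        values = rng.poisson(5, size=(30, 80)).astype(float)
        values[0, :40] += 50  # strong marker for class a
        m, labels = self._toy(values, ["a"] * 40 + ["b"] * 40)
        results = wilcoxon_ovr(m, labels, alpha=0.05)
        from e3ome.enrichment import bh_adjust

        for group in ("a", "b"):
            sub = [r for r in results if r.group == group]
            assert [r.p_adj for r in sub] == pytest.approx(
                bh_adjust([r.p for r in sub])
            )
            for r in sub:
                assert r.significant == (r.p_adj < 0.05)
        marker = next(r for r in results if r.gene == "g0" and r.group == "a")
        assert marker.significant and marker.log2fc > 0

    def test_layer_discipline(self):
        m, labels = self._toy([[1, 2, 3, 4]], ["a", "a", "b", "b"], layer="raw")
        with pytest.raises(LayerError):
            wilcoxon_ovr(m, labels)

    def test_requires_two_classes(self):
        m, labels = self._toy([[1, 2, 3]], ["a", "a", "a"])
        with pytest.raises(ValueError):
            wilcoxon_ovr(m, labels)


class TestDECall:
    @pytest.mark.parametrize(
        "fdr, lfc, expected",
        [
            (0.049, 1.0, True),    # both boundaries satisfied
            (0.05, 3.0, False),    # fdr strict
            (0.001, 0.99, False),  # lfc gate inclusive at 1
            (0.01, -1.5, True),    # absolute fold change
        ],
    )
    def test_boundary_semantics(self, fdr, lfc, expected):
        table = pd.DataFrame(
            {"gene": ["g"], "tissue": ["liver"], "log2fc": [lfc], "fdr": [fdr]}
        )
        [call] = de_call(table)
        assert call.significant is expected

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="fdr"):
            de_call(pd.DataFrame({"gene": [], "tissue": [], "log2fc": []}))


class TestRowwiseZscore:
    def test_unit_spaced_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(rowwise_zscore(df).to_numpy(), [[-1, 0, 1]])

    def test_constant_row_zeros(self):
        df = pd.DataFrame([[4.0, 4.0, 4.0]])
        np.testing.assert_allclose(rowwise_zscore(df).to_numpy(), 0.0)

    def test_moments(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(5, 12)))
        z = rowwise_zscore(df).to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            rowwise_zscore(pd.DataFrame([[1.0]]))
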