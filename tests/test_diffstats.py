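"""Normalization, multiple testing, differential and category statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from prernaseq.diffstats import (
    CountTable,
    ProteinTable,
    bh_adjust,
    category_stats,
    detection_by_class,
    detection_summary,
    diff_test,
    size_factors,
    volcano_classify,
)
from prernaseq.simulate import (
    GROUP_NEURITE,
    GROUP_SOMA,
    simulate_count_table,
    simulate_protein_table,
)


def _meta(replicates=5):
    names = [f"{g}_r{r}" for g in (GROUP_SOMA, GROUP_NEURITE) for r in range(1, replicates + 1)]
    return pd.DataFrame(
        [(g, r) for g in (GROUP_SOMA, GROUP_NEURITE) for r in range(1, replicates + 1)],
        columns=["group", "replicate"], index=names,
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_gets_factor_two(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_bruteforce_median_of_ratios(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = size_factors(counts)
        # independent recomputation: per-feature geometric mean, then the
        # median ratio per sample
        gm = np.exp(np.mean(np.log(counts.to_numpy(float)), axis=1))
        expected = np.median(counts.to_numpy(float) / gm[:, None], axis=0)
        assert np.allclose(sf.to_numpy(), expected)

    def test_no_all_nonzero_feature_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(counts)


class TestBH:
    def test_closed_form_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_is_monotone(self, p):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(ours[order]) >= -1e-12)


class TestDiffTest:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        half = rng.integers(10, 1000, size=(100, 5))
        counts = pd.DataFrame(np.hstack([half, half]), columns=_meta().index)
        table = CountTable(counts=counts, sample_meta=_meta(),
                           feature_meta=pd.DataFrame(index=counts.index))
        res = diff_test(table)
        assert res["significant"].sum() == 0

    def test_sign_convention_neurite_minus_soma(self):
        table = simulate_count_table(n_features=100, n_nuclear=20, n_pre=0, seed=2)
        res = diff_test(table)
        nuclear = (table.feature_meta.feature_class == "nuclear_control").values
        assert (res["log2FC"][nuclear] < 0).all()  # depleted in neurites

    def test_adjusted_p_at_least_raw_p(self):
        table = simulate_count_table(n_features=300, seed=5)
        res = diff_test(table)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_feature_order_invariance(self):
        table = simulate_count_table(n_features=80, seed=6)
        res = diff_test(table)
        perm = np.random.default_rng(0).permutation(80)
        shuffled = CountTable(
            counts=table.counts.iloc[perm],
            sample_meta=table.sample_meta,
            feature_meta=table.feature_meta.iloc[perm],
        )
        res2 = diff_test(shuffled).loc[res.index]
        pd.testing.assert_frame_equal(res, res2)

    def test_single_replicate_group_rejected(self):
        meta = _meta(2).iloc[[0, 2, 3]]
        counts = pd.DataFrame(np.ones((5, 3)), columns=meta.index)
        table = CountTable(counts=counts, sample_meta=meta,
                           feature_meta=pd.DataFrame(index=counts.index))
        with pytest.raises(ValueError, match="fewer than 2"):
            diff_test(table)


def _protein_design(rows):
    return pd.DataFrame(
        rows, columns=["protein", "category", "true_shift",
                       "release_site", "interaction", "moonlighting"],
    ).set_index("protein")


class TestVolcano:
    def test_fold_change_gate_blocks_small_effects(self):
        # strong significance but |log2FC| ~ 0.4 < 0.5: must stay ns
        design = _protein_design(
            [(f"p{i}", "X", 0.4 if i == 0 else 0.0, None, None, False) for i in range(50)]
        )
        pt = simulate_protein_table(design, noise_sd=0.05, seed=0)
        res = volcano_classify(pt)
        assert res["p_adj"].iloc[0] < 0.001
        assert res["class"].iloc[0] == "ns"

    def test_large_shift_classified_up_neurite(self):
        design = _protein_design(
            [(f"p{i}", "X", 2.0 if i < 5 else 0.0, None, None, False) for i in range(100)]
        )
        pt = simulate_protein_table(design, noise_sd=0.3, seed=1)
        res = volcano_classify(pt)
        assert (res["class"].iloc[:5] == "up_neurite").all()

    def test_degenerate_variance_gets_p_one(self):
        intens = pd.DataFrame(np.full((3, 10), 20.0), columns=_meta().index,
                              index=["a", "b", "c"])
        pt = ProteinTable(intensities=intens, sample_meta=_meta(),
                          protein_meta=pd.DataFrame(index=intens.index))
        res = volcano_classify(pt)
        assert (res["p"] == 1.0).all()


class TestCategoryStats:
    def test_label_permutation_within_category_invariant(self):
        rng = np.random.default_rng(2)
        lfc = pd.Series(rng.normal(size=60))
        cats = pd.Series(["a"] * 30 + ["b"] * 30)
        res1 = category_stats(lfc, cats, pairs=[("a", "b")])
        perm = np.concatenate([rng.permutation(30), 30 + rng.permutation(30)])
        res2 = category_stats(lfc.iloc[perm].reset_index(drop=True),
                              cats, pairs=[("a", "b")])
        assert res1["kw_p"] == pytest.approx(res2["kw_p"])
        assert res1["pairwise"]["p"][0] == pytest.approx(res2["pairwise"]["p"][0])

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            category_stats(np.arange(10.0), ["x"] * 10)

    def test_shifted_category_detected(self):
        """One category shifted by 3 sd among three: Kruskal-Wallis p < 0.001
        in at least 99 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lfc = np.concatenate([rng.normal(3, 1, 30), rng.normal(0, 1, 30),
                                  rng.normal(0, 1, 30)])
            cats = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
            hits += category_stats(lfc, cats)["kw_p"] < 0.001
        assert hits >= 99

    def test_null_kw_p_uniform(self):
        """Under exchangeable categories the omnibus p value is uniform:
        a KS test over 100 seeded runs must not reject."""
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            lfc = rng.normal(size=90)
            cats = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
            ps.append(category_stats(lfc, cats)["kw_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestDetection:
    def test_full_and_partial_presence(self):
        intens = pd.DataFrame(20.0, index=["a", "b"], columns=_meta().index)
        intens.iloc[1, 0] = np.nan  # protein b missing in one soma replicate
        pt = ProteinTable(intensities=intens, sample_meta=_meta(),
                          protein_meta=pd.DataFrame({"release_site": ["nucleus", "cytosol"]},
                                                    index=intens.index))
        det = detection_summary(pt, min_replicates=5)
        assert bool(det.loc["a"].all())
        assert not det.loc["b", f"detected_{GROUP_SOMA}"]
        assert det.loc["b", f"detected_{GROUP_NEURITE}"]

    def test_planted_missingness_pattern_recovered(self):
        rng = np.random.default_rng(4)
        design_rows = [(f"p{i}", "RBF", 0.0, "nucleus" if i % 2 else "cytosol",
                        None, False) for i in range(20)]
        design = _protein_design(design_rows)
        mask = pd.DataFrame(False, index=design.index, columns=_meta().index)
        planted_absent = design.index[:6]
        mask.loc[planted_absent, [c for c in mask.columns if c.startswith(GROUP_NEURITE)]] = True
        pt = simulate_protein_table(design, missing_mask=mask, seed=4)
        det = detection_summary(pt, min_replicates=5)
        assert set(det.index[~det[f"detected_{GROUP_NEURITE}"]]) == set(planted_absent)
        by_class = detection_by_class(det, pt.protein_meta)
        assert by_class.loc["cytosol", f"detected_{GROUP_SOMA}"] == 10
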