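"""ddCt fold changes, intensity ratios, EASE enrichment, and group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendroquant.cohort_stats import (
    benjamini_hochberg,
    ddct_fold_change,
    ease_enrichment,
    ease_p,
    fisher_right_tail_p,
    group_tests,
    intensity_ratio,
    normalized_intensity,
)
from dendroquant.synthetic import generate_qpcr, generate_roi_table


def ct_table(gene_case, gene_ctrl, ref_case, ref_ctrl):
    rows = []
    for cond, g, r in [("case", gene_case, ref_case), ("control", gene_ctrl, ref_ctrl)]:
        rows.append({"gene": "bdwf", "condition": cond, "ct": g})
        rows.append({"gene": "RpL32", "condition": cond, "ct": r})
    return pd.DataFrame(rows)


class TestDdct:
    def test_two_cycle_shift_is_fourfold(self):
        fc = ddct_fold_change(ct_table(20, 22, 16, 16), "bdwf", "case", "control", "RpL32")
        assert fc.delta_delta_ct == pytest.approx(-2.0)
        assert fc.fold == pytest.approx(4.0)

    def test_identical_conditions_fold_one(self):
        fc = ddct_fold_change(ct_table(22, 22, 16, 16), "bdwf", "case", "control", "RpL32")
        assert fc.fold == pytest.approx(1.0)

    def test_reference_shift_cancels(self):
        fc = ddct_fold_change(ct_table(23, 22, 17, 16), "bdwf", "case", "control", "RpL32")
        assert fc.fold == pytest.approx(1.0)

    def test_reference_equal_to_target_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(ct_table(20, 22, 16, 16), "RpL32", "case", "control", "RpL32")

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="no Ct rows"):
            ddct_fold_change(ct_table(20, 22, 16, 16), "bdwf", "nope", "control", "RpL32")

    @settings(max_examples=50, deadline=None)
    @given(
        offset=st.floats(-10, 10, allow_nan=False),
        gene_case=st.floats(15, 30),
        gene_ctrl=st.floats(15, 30),
        ref=st.floats(10, 20),
    )
    def test_plate_offset_invariance(self, offset, gene_case, gene_ctrl, ref):
        base = ct_table(gene_case, gene_ctrl, ref, ref)
        shifted = base.assign(ct=base["ct"] + offset)
        a = ddct_fold_change(base, "bdwf", "case", "control", "RpL32")
        b = ddct_fold_change(shifted, "bdwf", "case", "control", "RpL32")
        assert b.fold == pytest.approx(a.fold, rel=1e-9)


class TestRatios:
    @pytest.mark.parametrize("a, b, expected", [(50, 100, 0.5), (7.3, 7.3, 1.0)])
    def test_forced_arithmetic(self, a, b, expected):
        assert intensity_ratio(a, b) == pytest.approx(expected)
        assert normalized_intensity(a, b) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            intensity_ratio(1.0, 0.0)

    def test_generator_enrichment_recovered(self):
        tbl = generate_roi_table({"ct-OE": 2.1}, noise_sd=0.05, seed=0, n_animals=200)
        ratios = tbl["region_a_mean"] / tbl["region_b_mean"]
        assert ratios.mean() == pytest.approx(2.1, rel=0.02)


def brute_force_right_tail(k, N, K, n):
    """Independent tail sum over the hypergeometric support using comb."""
    lo, hi = max(0, K + n - N), min(K, n)
    if k <= lo:
        return 1.0
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(max(k, lo), hi + 1)
    ) / denom


class TestEase:
    def test_single_hit_annihilates(self):
        res = ease_enrichment(
            {f"g{i}" for i in range(10)} | set(),
            {"cat": {"g0"} | {f"x{i}" for i in range(9)}},
            {f"g{i}" for i in range(10)} | {f"x{i}" for i in range(90)},
        )
        assert res[0].hits_in_category == 1
        assert res[0].ease_p == pytest.approx(1.0)

    def test_saturated_table(self):
        bg = {f"g{i}" for i in range(12)}
        res = ease_enrichment(bg, {"all": bg}, bg)
        assert res[0].fold_enrichment == pytest.approx(1.0)
        assert res[0].fisher_p == pytest.approx(1.0)

    def test_ease_never_below_fisher(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(5, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            assert ease_p(k, N, K, n) >= fisher_right_tail_p(k, N, K, n) - 1e-12

    def test_tail_sums_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            N = int(rng.integers(3, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert fisher_right_tail_p(k, N, K, n) == pytest.approx(
                brute_force_right_tail(k, N, K, n), abs=1e-10
            )
            assert ease_p(k, N, K, n) == pytest.approx(
                brute_force_right_tail(k - 1, N, K, n), abs=1e-10
            )

    def test_fold_enrichment_scale_free(self):
        hits = {"a", "b"}
        cats = {"cat": {"a", "c"}}
        bg = {"a", "b", "c", "d", "e", "f"}
        base = ease_enrichment(hits, cats, bg)[0].fold_enrichment
        # duplicate every element under new names
        dup = lambda s: s | {x + "_2" for x in s}
        doubled = ease_enrichment(
            dup(hits), {"cat": dup(cats["cat"])}, dup(bg)
        )[0].fold_enrichment
        assert doubled == pytest.approx(base)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ease_enrichment(set(), {"c": {"a"}}, {"a"})
        with pytest.raises(ValueError):
            ease_enrichment({"a"}, {"c": {"a"}}, set())


class TestBH:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.8, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 1, size=30)
        tbl = pd.DataFrame(
            {"value": np.concatenate([v, v]), "g": ["control"] * 30 + ["case"] * 30}
        )
        res = group_tests(tbl, "value", "g", "control", method="ttest")
        assert res["p"].iloc[0] > 0.9

    def test_large_shift_flagged_by_dunnett(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(0, 1, 15)
        case = rng.normal(5, 1, 15)  # 5 SD shift
        tbl = pd.DataFrame(
            {
                "value": np.concatenate([ctrl, case]),
                "g": ["control"] * 15 + ["case"] * 15,
            }
        )
        res = group_tests(tbl, "value", "g", "control", method="anova_dunnett")
        dunnett = res[res["test"] == "dunnett"]
        assert bool(dunnett["significant"].iloc[0])

    def test_constant_groups_flagged_not_crashing(self):
        tbl = pd.DataFrame({"value": [3.0] * 10, "g": ["control"] * 5 + ["case"] * 5})
        for method in ("anova_dunnett", "ttest", "mannwhitney", "kruskal_dunn"):
            res = group_tests(tbl, "value", "g", "control", method=method)
            assert (res["note"] != "").any()

    def test_kruskal_dunn_reports_omnibus_and_posthoc(self):
        rng = np.random.default_rng(2)
        tbl = pd.DataFrame(
            {
                "value": np.concatenate(
                    [rng.normal(0, 1, 12), rng.normal(3, 1, 12), rng.normal(0, 1, 12)]
                ),
                "g": ["control"] * 12 + ["a"] * 12 + ["b"] * 12,
            }
        )
        res = group_tests(tbl, "value", "g", "control", method="kruskal_dunn")
        assert set(res["test"]) == {"kruskal", "dunn"}
        assert res.loc[res["comparison"] == "a vs control", "significant"].iloc[0]


class TestQpcrGenerator:
    def test_noiseless_recovery_exact(self):
        for fold in (1.0, 0.35, 4.0, 14.0):
            tbl = generate_qpcr({"g": fold}, noise_sd=0.0, seed=0)
            fc = ddct_fold_change(tbl, "g", "case", "control", "RpL32")
            assert fc.fold == pytest.approx(fold, rel=1e-12)

    def test_ddct_estimate_unbiased_under_noise(self):
        """Across many seeds the mean recovered ddCt equals the encoded
        value within Monte-Carlo error (the estimator is unbiased on the
        cycle scale)."""
        true_ddct = -math.log2(4.0)
        est = []
        for seed in range(400):
            tbl = generate_qpcr({"g": 4.0}, noise_sd=0.2, seed=seed, replicates=3)
            est.append(
                ddct_fold_change(tbl, "g", "case", "control", "RpL32").delta_delta_ct
            )
        se = np.std(est) / math.sqrt(len(est))
        assert abs(np.mean(est) - true_ddct) < 4 * se + 1e-6
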