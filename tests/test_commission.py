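import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hnplan.commission import (
    CommissionCase,
    assign_group,
    bonferroni,
    build_report,
    dvh_bands,
    paired_wilcoxon,
    synthetic_commissioning_cases,
)
from hnplan.evaluate import DVHCurve, STANDARD_ENDPOINTS


def enumeration_wilcoxon_p(diffs):
    """Independent oracle: literal enumeration of all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(diffs))
    n = len(diffs)
    w_obs = ranks[diffs > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    n_tot = len(ws)
    cdf = (ws <= w_obs + 1e-9).sum() / n_tot
    sf = (ws >= w_obs - 1e-9).sum() / n_tot
    return min(1.0, 2.0 * min(cdf, sf))


class TestPairedWilcoxon:
    def test_equal_samples_give_p_one_with_warning(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        with pytest.warns(UserWarning, match="zero"):
            assert paired_wilcoxon(x, x) == 1.0

    def test_six_positive_differences_exact_p(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x - np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        # all 6 differences positive: two-sided exact p = 2/2^6 = 0.03125
        assert paired_wilcoxon(x, y) == pytest.approx(0.03125)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_random_n10(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0.2, 1, 10)
        assert paired_wilcoxon(x, y) == pytest.approx(
            enumeration_wilcoxon_p(x - y), abs=1e-12
        )

    @pytest.mark.parametrize("n", range(5, 13))
    def test_matches_enumeration_for_all_small_n(self, n):
        rng = np.random.default_rng(n)
        diffs = rng.normal(0.3, 1.0, n)
        diffs[diffs == 0] = 0.1
        p = paired_wilcoxon(diffs, np.zeros(n))
        assert p == pytest.approx(enumeration_wilcoxon_p(diffs), abs=1e-12)

    def test_handles_midrank_ties_exactly(self):
        diffs = np.array([1.0, 1.0, -1.0, 2.0, 3.0, 3.0])
        p = paired_wilcoxon(diffs, np.zeros(6))
        assert p == pytest.approx(enumeration_wilcoxon_p(diffs), abs=1e-12)

    def test_cross_check_scipy_exact_no_ties(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0.5, 1, 12)
        ours = paired_wilcoxon(x, y)
        ref = stats.wilcoxon(x, y, method="exact").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.4, 1, 40)
        ours = paired_wilcoxon(x, y)
        ref = stats.wilcoxon(x, y, correction=True, method="approx").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            paired_wilcoxon([1, 2, 3], [0, 0, 0])


class TestBonferroni:
    def test_single_comparison_threshold_alpha(self):
        flags, adj = bonferroni([0.04], alpha=0.05)
        assert flags[0]
        assert adj[0] == pytest.approx(0.04)

    def test_family_of_13_threshold(self):
        flags, _ = bonferroni([0.004], alpha=0.05, m=13)
        assert not flags[0]  # 0.004 > 0.05/13 = 0.00385
        flags2, _ = bonferroni([0.003], alpha=0.05, m=13)
        assert flags2[0]

    def test_flags_equal_adjusted_p_formulation(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 0.2, 20)
        flags, adj = bonferroni(ps, alpha=0.05)
        assert np.array_equal(flags, adj <= 0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestAssignGroup:
    def test_equal_doses_bilateral(self):
        ep = {"parotid_l_dmedian_gy": 14.0, "parotid_r_dmedian_gy": 14.0}
        assert assign_group(ep) == "bilateral"

    def test_lower_left_goes_to_left_group(self):
        ep = {"parotid_l_dmedian_gy": 10.0, "parotid_r_dmedian_gy": 20.0}
        assert assign_group(ep, tau_gy=3.0) == "left"

    def test_lower_right_goes_to_right_group(self):
        ep = {"parotid_l_dmedian_gy": 20.0, "parotid_r_dmedian_gy": 10.0}
        assert assign_group(ep, tau_gy=3.0) == "right"

    def test_tau_sweep_changes_only_boundary_cases(self):
        rng = np.random.default_rng(1)
        deltas = rng.uniform(-8, 8, 50)
        for tau_small, tau_big in ((2.0, 5.0),):
            for d in deltas:
                ep = {"parotid_l_dmedian_gy": 15.0 + d, "parotid_r_dmedian_gy": 15.0}
                g_small = assign_group(ep, tau_gy=tau_small)
                g_big = assign_group(ep, tau_gy=tau_big)
                if abs(d) <= tau_small or abs(d) > tau_big:
                    assert g_small == g_big or abs(d) <= tau_big
                if g_small != g_big:
                    assert tau_small < abs(d) <= tau_big  # only boundary flips

    def test_missing_parotid_is_error(self):
        with pytest.raises(ValueError, match="parotid"):
            assign_group({"parotid_l_dmedian_gy": 10.0})

    def test_partition_no_case_lost(self):
        cases = synthetic_commissioning_cases(n_cases=9, group="bilateral", seed=2)
        groups = [assign_group(c.clinical) for c in cases]
        assert len(groups) == 9
        assert all(g in ("bilateral", "left", "right") for g in groups)


class TestDvhBands:
    def _curve(self, scale):
        dose = np.linspace(0, 60, 61)
        vol = 100.0 * np.clip(1 - dose / (40.0 * scale), 0, 1)
        return DVHCurve(dose, vol)

    def test_identical_cases_zero_width_band(self):
        curves = [self._curve(1.0) for _ in range(5)]
        bands = dvh_bands(curves)
        assert np.allclose(bands["p25_pct"], bands["p75_pct"])
        assert np.allclose(bands["median_pct"], bands["p25_pct"])

    def test_three_cases_median_is_middle(self):
        curves = [self._curve(s) for s in (0.8, 1.0, 1.2)]
        bands = dvh_bands(curves, dose_axis=np.array([0.0, 10.0, 20.0, 30.0]))
        mid = self._curve(1.0).resample(bands["dose_gy"].to_numpy()).volume_pct
        assert np.allclose(bands["median_pct"], mid)

    def test_bands_non_increasing_in_dose(self):
        rng = np.random.default_rng(3)
        curves = [self._curve(s) for s in rng.uniform(0.7, 1.3, 8)]
        bands = dvh_bands(curves)
        for col in ("median_pct", "p25_pct", "p75_pct"):
            assert np.all(np.diff(bands[col]) <= 1e-9)


class TestBuildReport:
    def test_ai_identical_to_clinical_all_p_one(self):
        cases = synthetic_commissioning_cases(n_cases=8, seed=4)
        for c in cases:
            c.ai = {k: c.clinical.copy() for k in c.ai}
        with pytest.warns(UserWarning):
            report = build_report(cases)
        table = report["bilateral"]
        assert np.all(table["p1"] == 1.0)
        assert np.all(table["p2"] == 1.0)
        assert not table["p1_significant"].any()
        assert table["clinical"].equals(table["ai_BP"])

    def test_injected_shift_flagged_at_stated_n(self):
        # shifts several times the pair-noise SD so the test is well powered
        shifted = {"parotid_l_dmedian_gy": 4.0, "hi": 3.0}
        cases = synthetic_commissioning_cases(
            n_cases=18, group="bilateral", shifts=shifted, noise_sd=0.3, seed=5
        )
        report = build_report(cases)
        table = report["bilateral"]
        flagged = set(table.index[table["p1_significant"]])
        assert flagged == set(shifted)
        # p3 compares the shifted *P plan against the unshifted *O plan
        flagged_p3 = set(table.index[table["p3_significant"]])
        assert set(shifted) <= flagged_p3

    def test_report_schema(self):
        cases = synthetic_commissioning_cases(n_cases=6, seed=6)
        report = build_report(cases)
        table = report["bilateral"]
        assert list(table.index) == list(STANDARD_ENDPOINTS)
        for col in ("clinical", "ai_BP", "ai_BO", "p1", "p2", "p3",
                    "p1_significant", "p2_significant", "p3_significant"):
            assert col in table.columns
        assert table.attrs["n_cases"] == 6
        assert table.attrs["bonferroni_m"] == len(STANDARD_ENDPOINTS)

    def test_groups_partition_cases(self):
        all_cases = (
            synthetic_commissioning_cases(5, "bilateral", seed=7)
            + synthetic_commissioning_cases(5, "left", seed=8)
            + synthetic_commissioning_cases(5, "right", seed=9)
        )
        report = build_report(all_cases)
        total = sum(t.attrs["n_cases"] for t in report.values())
        assert total == 15
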