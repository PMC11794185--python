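"""Signed-rank machinery, TOST verdicts, and the comparison roster."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctisim import tost_equivalence, wilcoxon_signed_rank
from ctisim.equivalence import (
    DEFAULT_ROSTER,
    DegenerateSampleError,
    PairingError,
    RosterError,
    results_frame,
    run_comparison_roster,
)


def enumeration_oracle(d, shift=0.0):
    """Exact signed-rank tails by brute force over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float) - shift
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    totals = np.array(
        [ranks[np.array(signs, bool)].sum() for signs in product([0, 1], repeat=d.size)]
    )
    p_g = (totals >= w_obs - 1e-9).mean()
    p_l = (totals <= w_obs + 1e-9).mean()
    return p_g, p_l, min(1.0, 2 * min(p_g, p_l))


class TestWilcoxonSignedRank:
    def test_exact_matches_enumeration_on_reference_vector(self):
        d = [1.1, -0.3, 0.7, 2.0, -0.2, 0.9, 1.4, 0.5]
        r = wilcoxon_signed_rank(d)
        pg, pl, p2 = enumeration_oracle(d)
        assert r.p_greater == pytest.approx(pg)
        assert r.p_less == pytest.approx(pl)
        assert r.p_two_sided == pytest.approx(p2)

    def test_exact_matches_enumeration_randomized(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 11))
            d = rng.normal(0, 1, n)
            if rng.random() < 0.3:  # force ties in |d| sometimes
                d[1] = -d[0]
            shift = float(rng.normal(0, 0.5))
            d = d[np.abs(d - shift) > 1e-12]
            if d.size < 5:
                continue
            r = wilcoxon_signed_rank(d, shift)
            pg, pl, p2 = enumeration_oracle(d, shift)
            assert r.p_greater == pytest.approx(pg, abs=1e-12)
            assert r.p_less == pytest.approx(pl, abs=1e-12)
            assert r.p_two_sided == pytest.approx(p2, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            d = rng.normal(0.2, 1, 12)
            r = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(d, alternative="greater", method="exact")
            assert r.p_greater == pytest.approx(float(ref.pvalue))

    def test_approx_close_to_scipy_large_n(self, rng):
        d = rng.normal(0.1, 1, 60)
        r = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
        assert r.method == "approx"
        assert r.p_two_sided == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_all_positive_is_smallest_attainable_p(self):
        r = wilcoxon_signed_rank(np.full(20, 1.0), shift=0.0)
        assert r.p_greater == pytest.approx(2.0**-20)

    def test_null_uniformity_of_p_values(self):
        """Under a symmetric null the rejection rate stays near alpha."""
        rej = 0
        n_seeds = 500
        for seed in range(n_seeds):
            d = np.random.default_rng(seed).normal(0, 1, 40)
            rej += wilcoxon_signed_rank(d).p_two_sided < 0.05
        assert rej / n_seeds == pytest.approx(0.05, abs=0.03)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank(np.full(10, 0.3), shift=0.3)

    def test_too_few_nonzero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.1, -0.2, 0.3, 0.0])


class TestTostEquivalence:
    def test_tiny_offset_is_equivalent(self):
        a = np.linspace(0.30, 0.35, 50)
        r = tost_equivalence(a + 0.001, a)
        assert r.equivalent
        assert r.median_diff == pytest.approx(0.001)

    def test_large_offset_is_different_not_equivalent(self):
        a = np.linspace(0.30, 0.35, 50)
        r = tost_equivalence(a + 0.2, a)
        assert not r.equivalent and r.different

    def test_small_consistent_offset_can_be_both(self, rng):
        a = rng.normal(0.4, 0.005, 100)
        r = tost_equivalence(a + 0.01, a)
        assert r.equivalent and r.different

    def test_power_at_cohort_scale(self):
        """i.i.d. N(0, 0.01^2) differences at n=199: equivalence nearly always."""
        wins = 0
        for seed in range(200):
            g = np.random.default_rng(seed)
            b = g.normal(0.4, 0.02, 199)
            a = b + g.normal(0, 0.01, 199)
            wins += tost_equivalence(a, b).equivalent
        assert wins / 200 > 0.95

    def test_type_one_error_at_bound(self):
        """True offset at the upper bound: false equivalence claims <= alpha."""
        claims = 0
        reps = 1000
        for seed in range(reps):
            g = np.random.default_rng(seed)
            d = g.normal(0.05, 0.02, 50)
            claims += tost_equivalence(d, np.zeros(50)).equivalent
        assert claims / reps <= 0.05 + 0.02

    def test_monotone_in_bounds(self, rng):
        a = rng.normal(0.4, 0.02, 60)
        b = a + rng.normal(0.02, 0.01, 60)
        narrow = tost_equivalence(a, b, bounds=(-0.03, 0.03))
        wide = tost_equivalence(a, b, bounds=(-0.10, 0.10))
        if narrow.equivalent:
            assert wide.equivalent

    def test_pooled_mode_runs_on_unequal_groups(self, rng):
        a = rng.normal(0.4, 0.01, 40)
        b = rng.normal(0.4, 0.01, 30)
        r = tost_equivalence(a, b, mode="pooled")
        assert r.equivalent

    def test_paired_mode_rejects_unequal_lengths(self):
        with pytest.raises(PairingError):
            tost_equivalence(np.zeros(5) + 0.1, np.ones(6))

    def test_agrees_with_two_scipy_one_sided_tests(self, rng):
        a = rng.normal(0.40, 0.02, 20)
        b = rng.normal(0.41, 0.02, 20)
        r = tost_equivalence(a, b)
        lo = stats.wilcoxon(a - b + 0.05, alternative="greater", method="exact")
        hi = stats.wilcoxon(a - b - 0.05, alternative="less", method="exact")
        assert r.p_lower == pytest.approx(float(lo.pvalue))
        assert r.p_upper == pytest.approx(float(hi.pvalue))


def _table(medians_by_roi, n=20, model="smt", sd=0.002, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for roi, mu in medians_by_roi.items():
        for k in range(n):
            rows.append({"subject": k, "roi": roi, "model": model,
                         "median": float(rng.normal(mu, sd))})
    return pd.DataFrame(rows)


class TestRoster:
    def test_empty_roster_empty_result(self, rng):
        t = _table({"cc_body": 0.28})
        assert run_comparison_roster(t, roster=()) == []

    def test_missing_roi_raises_with_name(self):
        t = _table({"cc_body": 0.28})
        with pytest.raises(RosterError, match="cc_genu"):
            run_comparison_roster(t, roster=(("cc_body", "cc_genu"),))

    def test_one_result_per_pair_per_model(self):
        rois = {r for pair in DEFAULT_ROSTER for r in pair}
        frames = [
            _table({r: 0.3 for r in rois}, model=m, seed=i)
            for i, m in enumerate(["noddi", "sandi", "smt"])
        ]
        t = pd.concat(frames, ignore_index=True)
        res = run_comparison_roster(t)
        assert len(res) == 3 * len(DEFAULT_ROSTER)
        frame = results_frame(res)
        assert frame["equivalent"].all()

    def test_offset_pair_flagged(self):
        t = _table({"putamen_left": 0.45, "putamen_right": 0.30, "cc_body": 0.28,
                    "cc_genu": 0.28})
        res = run_comparison_roster(
            t, roster=(("putamen_left", "putamen_right"), ("cc_body", "cc_genu"))
        )
        by_pair = {r.roi_pair: r for r in res}
        assert not by_pair[("putamen_left", "putamen_right")].equivalent
        assert by_pair[("putamen_left", "putamen_right")].different
        assert by_pair[("cc_body", "cc_genu")].equivalent
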