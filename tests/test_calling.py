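"""ASE engines: binomial and conditional-NB exact tests, dispersion, BH-FDR,
and the reference-bias diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from asekit.calling import (
    bh_adjust,
    bias_diagnostics,
    binomial_ase_test,
    call_ase,
    estimate_dispersion,
    nb_exact_ase_test,
    ref_ratio,
    skew_from_counts,
)

from .oracles import binom_two_sided_oracle, nb_conditional_oracle


class TestRefRatio:
    @pytest.mark.parametrize("ref,alt,expected", [
        (1, 19, 0.05), (33, 67, 0.33), (5, 5, 0.5), (123, 123, 0.5),
    ])
    def test_values(self, ref, alt, expected):
        assert ref_ratio(ref, alt) == pytest.approx(expected)

    def test_no_reads_undefined(self):
        with pytest.raises(ValueError):
            ref_ratio(0, 0)


class TestBinomial:
    def test_balanced_counts_are_null(self):
        assert binomial_ase_test(5, 5) == 1.0

    def test_closed_form_one_sided_extreme(self):
        assert binomial_ase_test(15, 0) == pytest.approx(2 * 0.5**15)

    def test_cohortwide_skew_is_significant(self):
        # pooled above/below-0.5 counts of the scale seen in heart cohorts
        assert binomial_ase_test(3383, 2305) < 0.001

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60))
    def test_symmetric_in_ref_alt(self, a, b):
        if a + b == 0:
            return
        assert binomial_ase_test(a, b) == pytest.approx(binomial_ase_test(b, a))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(1, 200))
    def test_matches_direct_pmf_summation(self, k, extra):
        n = k + extra
        assert binomial_ase_test(k, n - k) == pytest.approx(
            binom_two_sided_oracle(k, n, 0.5), abs=1e-10
        )


class TestDispersion:
    def test_identical_counts_have_zero_dispersion(self):
        ref = np.full(5, 10)
        alt = np.full(5, 10)
        phi, fallback = estimate_dispersion(ref, alt)
        assert phi == 0.0 and not fallback

    def test_single_individual_uses_fallback(self):
        phi, fallback = estimate_dispersion(np.array([10]), np.array([5]))
        assert phi == 0.1 and fallback

    def test_recovers_simulated_dispersion(self):
        # NB counts at true phi = 0.1, n = 200: moment estimate lands in a
        # factor-two band across seeds
        phi_true, n, mu = 0.1, 200, 50.0
        ests = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            r = 1 / phi_true
            ref = rng.negative_binomial(r, r / (r + mu), size=n)
            alt = rng.negative_binomial(r, r / (r + mu), size=n)
            keep = (ref + alt) > 0
            phi, _ = estimate_dispersion(ref[keep], alt[keep])
            ests.append(phi)
        ests = np.array(ests)
        assert ((ests >= 0.05) & (ests <= 0.2)).mean() >= 0.9


class TestNbExact:
    def test_balanced_split_is_modal(self):
        p = nb_exact_ase_test(np.array([20, 20]), np.array([20, 20]), 0.05)
        assert p == pytest.approx(1.0)

    def test_zero_dispersion_limit_is_binomial(self):
        p_nb = nb_exact_ase_test(np.array([30]), np.array([10]), 1e-8)
        p_bin = binomial_ase_test(30, 10)
        assert p_nb == pytest.approx(p_bin, abs=1e-3)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            nb_exact_ase_test(np.array([0]), np.array([0]), 0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 50), st.integers(0, 49), st.integers(1, 5),
           st.floats(0.01, 1.0))
    def test_matches_enumeration_oracle(self, total, s_ref_raw, n, phi):
        s_ref = min(s_ref_raw, total)
        # split the sums across n individuals arbitrarily; only sums matter
        ref = np.zeros(n, dtype=int)
        ref[0] = s_ref
        alt = np.zeros(n, dtype=int)
        alt[0] = total - s_ref
        assert nb_exact_ase_test(ref, alt, phi) == pytest.approx(
            nb_conditional_oracle(s_ref, total, n, phi), abs=1e-10
        )

    def test_p_decreases_away_from_balance(self):
        total, phi = 60, 0.2
        ps = [nb_exact_ase_test(np.array([k]), np.array([total - k]), phi)
              for k in range(30, total + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestBh:
    def test_small_closed_forms(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        assert bh_adjust([]).size == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_step_up(self, pvals):
        mine = bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert mine == pytest.approx(theirs, abs=1e-12)
        assert (mine >= np.asarray(pvals) - 1e-15).all()

    def test_threshold_selects_step_up_set(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 1e-4, 20), rng.uniform(0, 1, 200)])
        alpha = 0.05
        adj = bh_adjust(p)
        # classic step-up: largest k with p_(k) <= k/m * alpha
        order = np.sort(p)
        m = len(p)
        ks = np.nonzero(order <= (np.arange(1, m + 1) / m) * alpha)[0]
        n_sig = (ks[-1] + 1) if len(ks) else 0
        assert (adj < alpha).sum() == n_sig


class TestCallAse:
    def test_unknown_engine_rejected(self, small_study):
        with pytest.raises(ValueError):
            call_ase(small_study.counts, engine="bogus")

    def test_large_effect_is_called(self):
        # true ratio 0.95, 20 heterozygotes at depth ~50: far beyond the
        # detection threshold for every engine
        rng = np.random.default_rng(42)
        depth = rng.poisson(50, size=20) + 1
        ref = rng.binomial(depth, 0.95)
        counts = pd.DataFrame({
            "snp_id": "hot", "individual_id": [f"i{k}" for k in range(20)],
            "ref_count": ref, "alt_count": depth - ref, "other_count": 0,
        })
        for engine in ("binomial", "nb_aggregate", "nb_individual"):
            res = call_ase(counts, engine=engine)
            assert res["p_fdr"].iloc[0] < 0.05

    def test_engines_agree_when_dispersion_is_zero(self):
        # identical per-individual counts force the moment estimate to 0,
        # where the conditional NB test is exactly the binomial test
        counts = pd.DataFrame({
            "snp_id": "s", "individual_id": [f"i{k}" for k in range(6)],
            "ref_count": 14, "alt_count": 6, "other_count": 0,
        })
        p_bin = call_ase(counts, engine="binomial")["p_raw"].iloc[0]
        p_nb = call_ase(counts, engine="nb_individual")["p_raw"].iloc[0]
        assert p_nb == pytest.approx(p_bin)

    def test_null_pvalues_roughly_uniform(self):
        # pooled-depth >= 500 null: KS distance of raw binomial p-values
        # from uniform stays small
        rng = np.random.default_rng(7)
        rows = []
        for s in range(1000):
            depth = rng.poisson(80, size=15) + 1
            ref = rng.binomial(depth, 0.5)
            for i, (d, r) in enumerate(zip(depth, ref)):
                rows.append((f"s{s:04d}", f"i{i}", r, d - r, 0))
        counts = pd.DataFrame(rows, columns=["snp_id", "individual_id",
                                             "ref_count", "alt_count",
                                             "other_count"])
        res = call_ase(counts, engine="binomial")
        from scipy.stats import kstest
        ks = kstest(res["p_raw"], "uniform").statistic
        assert ks < 0.05


class TestBiasDiagnostics:
    def test_reported_skew_proportions(self):
        pct_la, p_la = skew_from_counts(3383, 2305)
        pct_lv, p_lv = skew_from_counts(5539, 3103)
        assert round(pct_la) == 59 and p_la < 0.001
        assert round(pct_lv) == 64 and p_lv < 0.001

    def test_ties_at_half_belong_to_neither_side(self):
        res = pd.DataFrame({
            "snp_id": list("abc"), "n_reads": [100, 100, 100],
            "ref_ratio": [0.6, 0.5, 0.4], "p_raw": [1e-6] * 3,
            "p_fdr": [1e-5] * 3,
        })
        d = bias_diagnostics(res)
        assert (d.n_above_half, d.n_below_half) == (1, 1)

    def test_unbiased_data_shows_no_skew(self, small_study):
        la = small_study.counts[small_study.counts["tissue"] == "LA"]
        res = call_ase(la, engine="binomial")
        d = bias_diagnostics(res)
        if d.skew_p is not None:
            assert d.skew_p > 0.05 or abs(d.percent_above - 50) < 25
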