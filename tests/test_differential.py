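"""Beta-binomial likelihood, MLE fitting, and the group/paired LRTs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, chi2

from asekit.differential import (
    betabinom_loglik,
    differential_table,
    fit_betabinom,
    lrt_group_differential,
    lrt_paired_differential,
)

from .oracles import betabinom_pmf_oracle, two_prop_lrt_oracle


class TestLoglik:
    def test_reduces_to_binomial_at_zero_rho(self):
        ref = np.array([3, 7, 2])
        total = np.array([10, 12, 9])
        mine = betabinom_loglik(ref, total, 0.37, 0.0)
        assert mine == pytest.approx(binom.logpmf(ref, total, 0.37).sum(), abs=1e-12)

    def test_degenerate_limit_perfect_fit(self):
        # a single all-REF record at mu -> 1 has log-likelihood -> 0
        ll = betabinom_loglik([10], [10], 1 - 1e-9, 0.0)
        assert -1e-6 < ll <= 0

    def test_closed_boundaries_rejected(self):
        with pytest.raises(ValueError):
            betabinom_loglik([1], [2], 0.0, 0.1)
        with pytest.raises(ValueError):
            betabinom_loglik([1], [2], 1.0, 0.1)
        with pytest.raises(ValueError):
            betabinom_loglik([1], [2], 0.5, 1.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 30),
           st.floats(0.05, 0.95), st.floats(0.01, 0.9))
    def test_matches_pmf_product_oracle(self, total, ref_raw, mu, rho):
        ref = min(ref_raw, total)
        conc = (1 - rho) / rho
        expected = np.log(betabinom_pmf_oracle(ref, total, mu * conc,
                                               (1 - mu) * conc))
        assert betabinom_loglik([ref], [total], mu, rho) == pytest.approx(
            expected, abs=1e-10
        )


class TestFit:
    def test_no_between_individual_variance(self):
        model = fit_betabinom([5] * 8, [10] * 8)
        assert model.mu == pytest.approx(0.5, abs=1e-3)
        assert model.rho < 1e-4

    def test_single_record_pins_rho(self):
        model = fit_betabinom([7], [10])
        assert model.rho == 0.0 and model.rho_pinned

    def test_parameter_recovery(self):
        # mu = 0.7, rho = 0.05, n = 200 at depth ~80: MLE lands within
        # +-0.03 of both truths for every seed
        for seed in range(50):
            rng = np.random.default_rng(3000 + seed)
            n = 200
            t = rng.poisson(80, size=n) + 1
            conc = 0.95 / 0.05
            p = rng.beta(0.7 * conc, 0.3 * conc, size=n)
            ref = rng.binomial(t, p)
            model = fit_betabinom(ref, t)
            assert abs(model.mu - 0.7) < 0.03
            assert abs(model.rho - 0.05) < 0.03

    def test_mle_consistency_bias_shrinks_with_n(self):
        grid = [(0.5, 0.0), (0.7, 0.05), (0.9, 0.2)]
        bias = {50: [], 500: []}
        for n in bias:
            for mu, rho in grid:
                for seed in range(5):
                    rng = np.random.default_rng(seed + int(mu * 100) + n)
                    t = rng.poisson(60, size=n) + 1
                    if rho > 0:
                        conc = (1 - rho) / rho
                        p = rng.beta(mu * conc, (1 - mu) * conc, size=n)
                    else:
                        p = mu
                    ref = rng.binomial(t, p)
                    m = fit_betabinom(ref, t)
                    bias[n].append(abs(m.mu - mu) + abs(m.rho - rho))
        assert np.mean(bias[500]) < np.mean(bias[50])


class TestGroupLrt:
    def _records(self, ref1, tot1, ref2, tot2):
        n1, n2 = len(ref1), len(ref2)
        return pd.DataFrame({
            "ref_count": list(ref1) + list(ref2),
            "alt_count": [t - r for r, t in zip(ref1, tot1)]
            + [t - r for r, t in zip(ref2, tot2)],
            "group": ["g1"] * n1 + ["g2"] * n2,
        })

    def test_identical_groups_are_null(self):
        rec = self._records([5, 6, 7], [10, 12, 14], [5, 6, 7], [10, 12, 14])
        res = lrt_group_differential(rec)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-4)
        assert res.p_raw > 0.97

    def test_monoallelic_versus_balanced_pattern(self):
        # one group fully reference-expressed (ratio 1.00), the other
        # balanced (0.50) at high depth: decisively significant
        rec = self._records([500], [500], [251, 249], [500, 500])
        res = lrt_group_differential(rec)
        assert res.ratio_group1 == pytest.approx(1.0)
        assert res.ratio_group2 == pytest.approx(0.5, abs=0.01)
        # the shared-rho null absorbs part of a single-outlier signal,
        # so the p-value is decisive but far milder than a binomial contrast
        assert res.p_raw < 1e-3
        assert res.low_confidence  # single heterozygote in one group

    def test_relabeling_and_allele_swap_invariance(self):
        rec = self._records([8, 9], [20, 25], [3, 2], [15, 10])
        res = lrt_group_differential(rec)
        swapped = rec.copy()
        swapped["group"] = swapped["group"].map({"g1": "g2", "g2": "g1"})
        res2 = lrt_group_differential(swapped)
        assert res.lrt_stat == pytest.approx(res2.lrt_stat, abs=1e-5)
        mirrored = rec.rename(columns={"ref_count": "alt_count",
                                       "alt_count": "ref_count"})
        res3 = lrt_group_differential(mirrored)
        assert res.lrt_stat == pytest.approx(res3.lrt_stat, abs=1e-4)

    def test_binomial_limit_matches_two_proportion_oracle(self):
        rec = self._records([30], [40], [10], [40])
        res = lrt_group_differential(rec, rho_fixed=0.0)
        stat = two_prop_lrt_oracle(30, 40, 10, 40)
        assert res.lrt_stat == pytest.approx(stat, abs=1e-8)
        assert res.p_raw == pytest.approx(float(chi2.sf(stat, 1)), abs=1e-8)

    def test_single_group_rejected(self):
        rec = self._records([5], [10], [], [])
        with pytest.raises(ValueError):
            lrt_group_differential(rec)


class TestPairedLrt:
    def _paired(self, base, post, depth=200):
        rows = []
        for i, (b, p) in enumerate(zip(base, post)):
            rows.append((f"i{i}", "baseline", b, depth - b))
            rows.append((f"i{i}", "post", p, depth - p))
        return pd.DataFrame(rows, columns=["individual_id", "timepoint",
                                           "ref_count", "alt_count"])

    def test_identical_timepoints_are_null(self):
        rec = self._paired([100, 110], [100, 110])
        res = lrt_paired_differential(rec)
        assert res.p_raw > 0.97

    def test_ischemia_scale_shift_detected(self):
        # ratio 0.35 pre vs 0.64 post in two individuals at depth ~220
        rec = self._paired([77, 77], [141, 141], depth=220)
        res = lrt_paired_differential(rec)
        assert res.ratio_group1 == pytest.approx(0.35, abs=0.01)
        assert res.ratio_group2 == pytest.approx(0.64, abs=0.01)
        assert res.p_raw < 0.05

    def test_timepoint_swap_symmetry(self):
        rec = self._paired([60, 70], [90, 95])
        res = lrt_paired_differential(rec)
        swapped = rec.copy()
        swapped["timepoint"] = swapped["timepoint"].map(
            {"baseline": "post", "post": "baseline"})
        res2 = lrt_paired_differential(swapped)
        assert res.p_raw == pytest.approx(res2.p_raw, abs=1e-6)

    def test_incomplete_individuals_dropped(self):
        rec = self._paired([60, 70], [90, 95])
        rec = pd.concat([rec, pd.DataFrame([{"individual_id": "lone",
                                             "timepoint": "baseline",
                                             "ref_count": 5,
                                             "alt_count": 5}])],
                        ignore_index=True)
        res = lrt_paired_differential(rec)
        assert res.n_het_group1 == 2  # the unpaired individual is excluded


def test_differential_table_flags_injected_effect(small_study):
    study = small_study
    la = study.counts[study.counts["tissue"] == "LA"].copy()
    labels = study.design.samples.set_index("individual_id")["group"].to_dict()
    la["group"] = la["individual_id"].map(labels)
    out = differential_table(la, label_column="group")
    truth = study.differential_truth
    hit = truth.loc[truth["kind"] == "group", "snp_id"].iloc[0]
    top = out.iloc[0]
    assert top["snp_id"] == hit
    assert top["p_fdr"] < 0.05
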