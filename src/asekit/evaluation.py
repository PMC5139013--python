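"""Calibration, power and recovery experiments on synthetic data.

These routines quantify the statistical behaviour of the pipeline under the
generator's study conditions: type-I error of the ASE engines and the
differential LRTs under a null configuration, beta-binomial parameter
recovery, detection power for a clinical-group effect, and the permutation
overlap machinery against its hypergeometric expectation.  They are used by
the test suite and the reproduction script; all randomness flows from the
``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import call_ase
from .cross_tissue import permutation_overlap_test
from .differential import differential_table, fit_betabinom, lrt_group_differential
from .simulate import SimulationConfig, simulate_allele_counts, simulate_genotypes

__all__ = [
    "null_config",
    "null_calibration",
    "betabinom_recovery",
    "group_differential_power",
    "permutation_benchmark",
]


def null_config(seed: int, n_snps: int = 1000) -> SimulationConfig:
    """Null study conditions: balanced true ratios everywhere, no reference
    bias, no sequencing error, binomial splits (rho = 0), and enough
    heterozygotes x depth for a pooled depth in the low thousands."""
    return SimulationConfig(
        n_individuals=50,
        n_snps=n_snps,
        maf_range=(0.3, 0.5),
        genotyping_rate=1.0,
        depth_mean=70.0,
        depth_shape=5.0,
        error_rate=0.0,
        ref_bias=0.0,
        overdispersion_rho=0.0,
        ase_fraction=0.0,
        seed=seed,
    )


def null_calibration(seed: int, n_snps: int = 1000) -> dict:
    """Raw p < 0.05 rates under the null for the two ASE engines and the two
    differential LRTs; all four should sit near the nominal 5%."""
    cfg = null_config(seed, n_snps)
    geno, _ = simulate_genotypes(cfg)
    ratios = pd.Series(0.5, index=geno.index)
    counts = simulate_allele_counts(geno, cfg, ratios, seed=cfg.seed)

    res_bin = call_ase(counts, engine="binomial")
    res_nb = call_ase(counts, engine="nb_individual")

    inds = list(geno.columns)
    case = set(inds[: len(inds) // 2])
    grouped = counts.copy()
    grouped["group"] = np.where(grouped["individual_id"].isin(case),
                                "case", "control")
    diff_g = differential_table(grouped, label_column="group")

    base = counts.copy()
    base["timepoint"] = "baseline"
    post = simulate_allele_counts(geno, cfg, ratios, seed=cfg.seed + 7777)
    post["timepoint"] = "post"
    paired = pd.concat([base, post], ignore_index=True)
    diff_p = differential_table(paired, label_column="timepoint", paired=True)

    return {
        "binomial": float((res_bin["p_raw"] < 0.05).mean()),
        "nb_individual": float((res_nb["p_raw"] < 0.05).mean()),
        "group_lrt": float((diff_g["p_raw"] < 0.05).mean()),
        "paired_lrt": float((diff_p["p_raw"] < 0.05).mean()),
        "n_snps": int(len(res_bin)),
        "median_pooled_depth": float(res_bin["n_reads"].median()),
    }


def betabinom_recovery(
    seed: int,
    n_seeds: int = 50,
    n: int = 200,
    mu: float = 0.7,
    rho: float = 0.05,
    depth: float = 80.0,
) -> dict:
    """Maximum-likelihood recovery of (mu, rho) across seeded replicates."""
    err_mu, err_rho = [], []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 101 * k)
        t = rng.poisson(depth, size=n) + 1
        conc = (1 - rho) / rho
        p = rng.beta(mu * conc, (1 - mu) * conc, size=n)
        ref = rng.binomial(t, p)
        model = fit_betabinom(ref, t)
        err_mu.append(abs(model.mu - mu))
        err_rho.append(abs(model.rho - rho))
    return {
        "max_abs_err_mu": float(np.max(err_mu)),
        "max_abs_err_rho": float(np.max(err_rho)),
        "mean_abs_err_mu": float(np.mean(err_mu)),
        "mean_abs_err_rho": float(np.mean(err_rho)),
        "n_seeds": n_seeds,
        "n": n,
    }


def group_differential_power(
    seed: int,
    n_reps: int = 50,
    n_het: int = 30,
    depth: float = 100.0,
    ratio_control: float = 0.5,
    ratio_case: float = 0.9,
    rho: float = 0.01,
    alpha: float = 0.05,
) -> dict:
    """Fraction of seeded replicates in which the group LRT flags a single
    SNP carrying a clinical-group allelic-ratio effect."""
    hits = 0
    conc = (1 - rho) / rho
    for k in range(n_reps):
        rng = np.random.default_rng(seed + 13 * k)
        rows = []
        for grp, ratio in (("case", ratio_case), ("control", ratio_control)):
            t = rng.poisson(depth, size=n_het) + 1
            p = rng.beta(ratio * conc, (1 - ratio) * conc, size=n_het)
            ref = rng.binomial(t, p)
            for r, tt in zip(ref, t):
                rows.append((int(r), int(tt - r), grp))
        rec = pd.DataFrame(rows, columns=["ref_count", "alt_count", "group"])
        res = lrt_group_differential(rec)
        # a single tested SNP: the BH-adjusted value equals the raw one
        if res.p_raw < alpha:
            hits += 1
    return {"power": hits / n_reps, "n_reps": n_reps}


def permutation_benchmark(seed: int, B: int = 10_000) -> dict:
    """Null-overlap mean for eligible = 1000, set sizes 100/100 (the
    hypergeometric expectation is 10), and the permutation-p floor reached
    by a fully overlapping observed set."""
    p_floor, null = permutation_overlap_test(1000, 100, 100, 100, B=B, seed=seed)
    return {
        "null_mean": float(null.mean()),
        "expected_mean": 10.0,
        "se": float(null.std(ddof=1) / np.sqrt(B)),
        "perm_p_full_overlap": float(p_floor),
        "B": B,
    }
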