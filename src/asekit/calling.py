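"""Per-SNP ASE calling and reference-bias diagnostics.

Three engines test the null of a balanced REF/(REF+ALT) ratio of 0.5:

``binomial``
    exact binomial test on REF and ALT counts pooled over individuals;
``nb_aggregate``
    exact conditional negative-binomial test on the pooled counts with a
    fixed dispersion of 0.1;
``nb_individual``
    the same conditional NB test on per-individual counts with a per-SNP
    moment estimate of the dispersion (the default engine).

The conditional NB test conditions the REF-group sum against the ALT-group
sum on their pooled total; as dispersion goes to zero it reduces to the
binomial test.  Multiplicity is handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binomtest

__all__ = [
    "ref_ratio",
    "binomial_ase_test",
    "estimate_dispersion",
    "nb_exact_ase_test",
    "bh_adjust",
    "call_ase",
    "bias_diagnostics",
    "skew_from_counts",
    "BiasDiagnostics",
    "ENGINES",
]

ENGINES = ("binomial", "nb_aggregate", "nb_individual")

_REL_TOL = 1 + 1e-7  # fp tolerance for "no more probable than observed"
DISPERSION_FALLBACK = 0.1  # used when a single individual precludes estimation
DEFAULT_DEPTH_BINS = (15, 30, 60, 120)


def ref_ratio(ref: int, alt: int) -> float:
    """Reference ratio REF/(REF+ALT); OTHER reads are excluded."""
    if ref + alt < 1:
        raise ValueError("ref + alt must be >= 1")
    return ref / (ref + alt)


def binomial_ase_test(pooled_ref: int, pooled_alt: int) -> float:
    """Two-sided exact binomial test of the pooled reference ratio against
    0.5 (minimum-likelihood two-sided convention)."""
    n = pooled_ref + pooled_alt
    if n < 1:
        raise ValueError("pooled_ref + pooled_alt must be >= 1")
    return float(binomtest(pooled_ref, n, 0.5, alternative="two-sided").pvalue)


def estimate_dispersion(
    ref: np.ndarray, alt: np.ndarray, fallback: float = DISPERSION_FALLBACK
) -> tuple[float, bool]:
    """Method-of-moments NB dispersion for one SNP's per-individual counts.

    The REF/ALT counts of each individual are a binomial split of that
    individual's total with intraclass correlation rho; the Pearson
    statistic against the fitted split proportion has expectation
    df + rho * sum(t - 1), giving rho = (chi2 - df) / sum(t - 1).  Two
    independent NB(mu, phi) groups conditioned on their total split with
    rho = phi / (2 + phi), so the NB dispersion consistent with the
    conditional exact test is phi = 2 rho / (1 - rho), clamped to [0, 10].
    With a single individual the dispersion is not estimable and
    ``fallback`` is returned with a flag.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    n = len(ref)
    if n < 2:
        return fallback, True
    t = ref + alt
    total = t.sum()
    if total == 0:
        raise ValueError("all counts zero")
    pi = ref.sum() / total
    if pi <= 0.0 or pi >= 1.0:
        return 0.0, False  # monoallelic: no within-split variance information
    denom = (t - 1).clip(min=0).sum()
    if denom <= 0:
        return 0.0, False
    chi2_stat = ((ref - pi * t) ** 2 / (pi * (1 - pi) * t)).sum()
    rho = np.clip((chi2_stat - (n - 1)) / denom, 0.0, 1.0 - 1e-9)
    phi = 2.0 * rho / (1.0 - rho)
    return float(np.clip(phi, 0.0, 10.0)), False


def _conditional_nb_logpmf(total: int, r: float) -> np.ndarray:
    """Log-pmf of the REF-group sum given the pooled total, for two NB groups
    with equal exposure and common size parameter r (independent of the mean)."""
    k = np.arange(total + 1)
    logw = (gammaln(k + r) - gammaln(k + 1)
            + gammaln(total - k + r) - gammaln(total - k + 1))
    return logw - logsumexp(logw)


def nb_exact_ase_test(ref: np.ndarray, alt: np.ndarray, phi: float) -> float:
    """Exact conditional test of equal REF/ALT negative-binomial means.

    ``ref`` and ``alt`` are per-individual counts for one SNP; the group sums
    are NB with size n/phi each, so conditioning on the pooled total gives a
    beta-binomial-shaped distribution free of the nuisance mean.  Two-sided p
    sums the probabilities of splits no more probable than the observed one;
    at phi = 0 this is exactly the binomial test.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    ref = np.atleast_1d(np.asarray(ref, dtype=int))
    alt = np.atleast_1d(np.asarray(alt, dtype=int))
    s_ref, s_alt = int(ref.sum()), int(alt.sum())
    total = s_ref + s_alt
    if total == 0:
        raise ValueError("pooled total must be >= 1")
    if phi < 1e-12:
        return binomial_ase_test(s_ref, s_alt)
    r = len(ref) / phi
    logp = _conditional_nb_logpmf(total, r)
    p = np.exp(logp)
    return float(min(1.0, p[p <= p[s_ref] * _REL_TOL].sum()))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_ase(
    counts: pd.DataFrame,
    engine: str = "nb_individual",
    fdr_alpha: float = 0.05,
    fixed_dispersion: float = DISPERSION_FALLBACK,
) -> pd.DataFrame:
    """One ASE result per SNP from a filtered count table.

    Returns a table sorted by raw p with columns snp_id, n_het, n_reads,
    ref_ratio, p_raw, p_fdr, engine, significant.  ``n_het`` counts the
    records (heterozygous samples) used; ``n_reads`` pools REF+ALT.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    rows = []
    for sid, grp in counts.groupby("snp_id", sort=True):
        ref = grp["ref_count"].to_numpy()
        alt = grp["alt_count"].to_numpy()
        s_ref, s_alt = int(ref.sum()), int(alt.sum())
        if s_ref + s_alt == 0:
            continue
        if engine == "binomial":
            p = binomial_ase_test(s_ref, s_alt)
        elif engine == "nb_aggregate":
            p = nb_exact_ase_test(np.array([s_ref]), np.array([s_alt]), fixed_dispersion)
        else:
            phi, _ = estimate_dispersion(ref, alt, fallback=fixed_dispersion)
            p = nb_exact_ase_test(ref, alt, phi)
        rows.append((sid, len(grp), s_ref + s_alt, ref_ratio(s_ref, s_alt), p))
    result = pd.DataFrame(rows, columns=["snp_id", "n_het", "n_reads", "ref_ratio", "p_raw"])
    result["p_fdr"] = bh_adjust(result["p_raw"].to_numpy())
    result["engine"] = engine
    result["significant"] = result["p_fdr"] < fdr_alpha
    return result.sort_values(["p_raw", "snp_id"], kind="mergesort").reset_index(drop=True)


@dataclass
class BiasDiagnostics:
    """Residual reference-genome-bias summary among ASE-significant SNPs."""

    overall_ref_ratio: float
    n_above_half: int
    n_below_half: int
    skew_p: float | None
    ratio_by_depth_bin: pd.DataFrame = field(repr=False, default=None)

    @property
    def percent_above(self) -> float | None:
        n = self.n_above_half + self.n_below_half
        return 100.0 * self.n_above_half / n if n else None


def skew_from_counts(n_above: int, n_below: int) -> tuple[float, float]:
    """Percent of SNPs above 0.5 and the two-sided binomial skew p-value."""
    n = n_above + n_below
    if n == 0:
        raise ValueError("no SNPs off 0.5")
    p = float(binomtest(n_above, n, 0.5, alternative="two-sided").pvalue)
    return 100.0 * n_above / n, p


def bias_diagnostics(
    results: pd.DataFrame,
    fdr_alpha: float = 0.05,
    depth_bins: tuple[int, ...] = DEFAULT_DEPTH_BINS,
) -> BiasDiagnostics:
    """Count significant SNPs above/below 0.5 (ties at exactly 0.5 in
    neither group), test the skew, and stratify the mean reference ratio by
    pooled read depth — unbiased data should sit at 0.5 in every stratum."""
    sig = results[results["p_fdr"] < fdr_alpha]
    n_above = int((sig["ref_ratio"] > 0.5).sum())
    n_below = int((sig["ref_ratio"] < 0.5).sum())
    skew_p = None
    if n_above + n_below > 0:
        _, skew_p = skew_from_counts(n_above, n_below)
    pooled_ratio = float("nan")
    tot = sig["n_reads"].sum()
    if tot > 0:
        pooled_ratio = float((sig["ref_ratio"] * sig["n_reads"]).sum() / tot)
    edges = [*depth_bins, np.inf]
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    binned = pd.cut(sig["n_reads"], bins=edges, labels=labels, right=False)
    by_bin = (
        sig.assign(depth_bin=binned)
        .groupby("depth_bin", observed=False)
        .agg(mean_ref_ratio=("ref_ratio", "mean"), n=("snp_id", "size"))
        .reset_index()
    )
    return BiasDiagnostics(
        overall_ref_ratio=pooled_ratio,
        n_above_half=n_above,
        n_below_half=n_below,
        skew_p=skew_p,
        ratio_by_depth_bin=by_bin,
    )
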