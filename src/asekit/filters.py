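"""SNP/read filter cascade producing the set eligible for ASE calling.

Stages, in order: (1) at least one heterozygous individual; (2) a minimum
number of RNA reads crossing the heterozygous SNP (default 15, inclusive,
applied per (SNP, individual) record); (3) Hardy-Weinberg equilibrium
(exact test, p > 1e-5); (4) genotyping rate > 95%; (5) mappability score
of 1; (6) a test that the rate of bases matching neither REF nor ALT equals
the overall genotyping error — SNPs rejecting that null at p < 0.05 look
like genotyping errors or random monoallelic expression and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binomtest, chi2

from .simulate import MISSING

__all__ = [
    "FilterConfig",
    "FilterStage",
    "FilterReport",
    "hwe_exact_test",
    "hwe_chisq_test",
    "estimate_error_rate",
    "genotyping_error_test",
    "apply_filters",
]

_REL_TOL = 1 + 1e-12  # minimum-likelihood two-sided tests: tolerate fp ties


@dataclass(frozen=True)
class FilterConfig:
    min_reads: int = 15
    hwe_alpha: float = 1e-5
    min_genotyping_rate: float = 0.95
    min_mappability: float = 1.0
    error_test_alpha: float = 0.05
    min_reads_scope: str = "record"  # or "pooled"
    hwe_method: str = "exact"  # or "chisq"

    def validate(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        for name, v in (("hwe_alpha", self.hwe_alpha),
                        ("min_genotyping_rate", self.min_genotyping_rate),
                        ("min_mappability", self.min_mappability),
                        ("error_test_alpha", self.error_test_alpha)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_reads_scope not in ("record", "pooled"):
            raise ValueError("min_reads_scope must be 'record' or 'pooled'")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")


@dataclass
class FilterStage:
    name: str
    snps_in: int
    snps_out: int
    reads_in: int
    reads_out: int


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)
    overall_error_rate: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.stages])

    def to_dict(self) -> dict:
        return {"stages": [asdict(s) for s in self.stages],
                "overall_error_rate": self.overall_error_rate}


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and enumerates every possible
    heterozygote count; each configuration has probability proportional to
    its multinomial weight times 2^het.  Two-sided p is the total probability
    of configurations no more probable than the observed one.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_hom_alt + n_het  # ALT allele count
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # multinomial weight x 2^het, in logs; constants in n cancel on normalisation
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logw = (hets * np.log(2)
            - gammaln(hom_common + 1) - gammaln(hets + 1) - gammaln(hom_rare + 1))
    logp = logw - logsumexp(logw)
    p_obs = np.exp(logp[np.searchsorted(hets, n_het)])
    return float(min(1.0, np.exp(logp)[np.exp(logp) <= p_obs * _REL_TOL].sum()))


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (no continuity correction); offered as an
    alternative to the exact test for large cohorts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    q = (2 * n_hom_alt + n_het) / (2 * n)
    exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    obs = np.array([n_hom_ref, n_het, n_hom_alt])
    mask = exp > 0
    stat = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(chi2.sf(stat, df=1))


def estimate_error_rate(counts: pd.DataFrame) -> float:
    """Overall genotyping error: OTHER reads over all reads in the table."""
    if counts.empty:
        raise ValueError("count table is empty")
    total = int(counts[["ref_count", "alt_count", "other_count"]].to_numpy().sum())
    if total == 0:
        raise ValueError("count table has zero total reads")
    return float(counts["other_count"].sum() / total)


def genotyping_error_test(other: int, total: int, e: float) -> float:
    """Exact binomial test of the observed OTHER-base count against the
    overall genotyping error rate ``e`` (two-sided, minimum-likelihood)."""
    if not (0 <= other <= total):
        raise ValueError("need 0 <= other <= total")
    if total < 1:
        raise ValueError("total must be >= 1")
    if e <= 0.0:
        return 1.0 if other == 0 else 0.0
    if e >= 1.0:
        return 1.0 if other == total else 0.0
    return float(binomtest(other, total, e, alternative="two-sided").pvalue)


def _stage_counts(counts: pd.DataFrame) -> tuple[int, int]:
    reads = int(counts[["ref_count", "alt_count", "other_count"]].to_numpy().sum())
    return counts["snp_id"].nunique(), reads


def apply_filters(
    counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade; returns the eligible count table and a
    stage-by-stage report.

    ``genotypes`` is the SNP x individual matrix from the genotyping assay of
    the whole cohort (HWE and genotyping rate are computed on it, not on
    RNA-derived calls); ``panel`` carries per-SNP mappability.
    """
    config = config or FilterConfig()
    config.validate()
    unknown = set(counts["snp_id"]) - set(genotypes.index)
    if unknown:
        raise ValueError(f"count table references SNPs absent from genotypes: "
                         f"{sorted(unknown)[:5]} ...")
    report = FilterReport()
    if not counts.empty:
        report.overall_error_rate = estimate_error_rate(counts)
    panel = panel.set_index("snp_id") if "snp_id" in panel.columns else panel
    cur = counts.copy()

    def record(name: str, nxt: pd.DataFrame):
        s_in, r_in = _stage_counts(cur)
        s_out, r_out = _stage_counts(nxt)
        report.stages.append(FilterStage(name, s_in, s_out, r_in, r_out))
        return nxt

    # 1. at least one heterozygous individual (on the genotyping assay)
    n_het = (genotypes == 1).sum(axis=1)
    ok = set(n_het.index[n_het >= 1])
    cur = record("het_individuals", cur[cur["snp_id"].isin(ok)])

    # 2. minimum reads crossing the heterozygous SNP (boundary inclusive)
    tot = cur[["ref_count", "alt_count", "other_count"]].sum(axis=1)
    if config.min_reads_scope == "record":
        nxt = cur[tot >= config.min_reads]
    else:
        pooled = tot.groupby(cur["snp_id"]).transform("sum")
        nxt = cur[pooled >= config.min_reads]
    cur = record("min_reads", nxt)

    # 3. Hardy-Weinberg equilibrium on the cohort genotypes
    hwe_fn = hwe_exact_test if config.hwe_method == "exact" else hwe_chisq_test
    keep = []
    for sid in cur["snp_id"].unique():
        g = genotypes.loc[sid]
        g = g[g != MISSING]
        p = hwe_fn(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        if p > config.hwe_alpha:
            keep.append(sid)
    cur = record("hwe", cur[cur["snp_id"].isin(set(keep))])

    # 4. genotyping rate across all genotyped individuals
    rate = (genotypes != MISSING).mean(axis=1)
    ok = set(rate.index[rate > config.min_genotyping_rate])
    cur = record("genotyping_rate", cur[cur["snp_id"].isin(ok)])

    # 5. mappability annotation
    mappable = set(panel.index[panel["mappability"] >= config.min_mappability])
    cur = record("mappability", cur[cur["snp_id"].isin(mappable)])

    # 6. genotyping-error test, pooled per SNP against the overall error rate
    e = report.overall_error_rate
    keep = []
    grouped = cur.groupby("snp_id")[["ref_count", "alt_count", "other_count"]].sum()
    for sid, row in grouped.iterrows():
        total = int(row.sum())
        p = genotyping_error_test(int(row["other_count"]), total, e) if total else 1.0
        if p >= config.error_test_alpha:
            keep.append(sid)
    cur = record("error_test", cur[cur["snp_id"].isin(set(keep))])

    return cur.reset_index(drop=True), report
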