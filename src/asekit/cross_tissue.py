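"""Shared vs tissue-specific ASE between two tissues.

Given per-tissue ASE result tables restricted to SNPs eligible in both
tissues, partitions the significant SNPs into both / A-only / B-only,
compares the observed overlap against a permutation null (random draws of
equally sized SNP sets from the eligible pool), measures direction
concordance of the reference ratio, and tests per-SNP differential ASE
between the tissues with the beta-binomial LRT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .differential import differential_table

log = logging.getLogger(__name__)

__all__ = [
    "SharingPartition",
    "SharingResult",
    "ConcordanceResult",
    "shared_ase",
    "permutation_overlap_test",
    "direction_concordance",
    "differential_ase_between_tissues",
]


@dataclass
class SharingPartition:
    both: set
    a_only: set
    b_only: set
    n_eligible_both: int

    @property
    def n_ase_either(self) -> int:
        return len(self.both) + len(self.a_only) + len(self.b_only)


@dataclass
class SharingResult:
    n_eligible_both: int
    n_ase_either: int
    n_ase_both: int
    n_a_only: int
    n_b_only: int
    perm_p: float
    perm_null: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_eligible_both": self.n_eligible_both,
            "n_ase_either": self.n_ase_either,
            "n_ase_both": self.n_ase_both,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "perm_p": self.perm_p,
            "perm_null_mean": float(np.mean(self.perm_null)),
        }


@dataclass
class ConcordanceResult:
    concordance_both: float | None
    concordance_a_only: float | None
    concordance_b_only: float | None
    pairwise_p: dict = field(default_factory=dict)


def shared_ase(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    scale: str = "fdr",
) -> SharingPartition:
    """Partition significant SNPs into both / A-only / B-only.

    Significance is p_fdr < alpha by default; ``scale="raw"`` uses p_raw
    instead (both scales are reported in the literature for sharing counts).
    Only SNPs present in both result tables are eligible.
    """
    col = {"fdr": "p_fdr", "raw": "p_raw"}[scale]
    eligible = set(results_a["snp_id"]) & set(results_b["snp_id"])
    if not eligible:
        raise ValueError("no SNPs eligible in both tissues")
    sig_a = set(results_a.loc[results_a[col] < alpha, "snp_id"]) & eligible
    sig_b = set(results_b.loc[results_b[col] < alpha, "snp_id"]) & eligible
    return SharingPartition(
        both=sig_a & sig_b,
        a_only=sig_a - sig_b,
        b_only=sig_b - sig_a,
        n_eligible_both=len(eligible),
    )


def permutation_overlap_test(
    n_eligible: int,
    size_a: int,
    size_b: int,
    observed_overlap: int,
    B: int = 10_000,
    seed: int = 0,
    mode: str = "both",
) -> tuple[float, np.ndarray]:
    """Permutation null for the shared-ASE count.

    Each of B permutations draws random SNP subsets of the observed sizes
    from the eligible pool (without replacement) and records their overlap;
    ``mode="both"`` redraws both sets each round (symmetric in the tissues),
    ``mode="single"`` holds one set fixed and redraws the other.  The p-value
    uses the (k+1)/(B+1) estimator so it is never exactly zero; its floor at
    B = 10,000 is about 1e-4.
    """
    if size_a > n_eligible or size_b > n_eligible:
        raise ValueError("set sizes cannot exceed the eligible pool")
    if observed_overlap > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller set size")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(B, dtype=int)
    fixed = np.zeros(n_eligible, dtype=bool)
    fixed[rng.choice(n_eligible, size=size_a, replace=False)] = True
    for i in range(B):
        if mode == "both":
            in_a = np.zeros(n_eligible, dtype=bool)
            in_a[rng.choice(n_eligible, size=size_a, replace=False)] = True
        elif mode == "single":
            in_a = fixed
        else:
            raise ValueError("mode must be 'both' or 'single'")
        idx_b = rng.choice(n_eligible, size=size_b, replace=False)
        null[i] = int(in_a[idx_b].sum())
    perm_p = (1 + int((null >= observed_overlap).sum())) / (B + 1)
    return perm_p, null


def direction_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    partition: SharingPartition,
) -> ConcordanceResult:
    """Fraction of SNPs whose reference ratio falls on the same side of 0.5
    in both tissues, per sharing group, with pairwise Fisher exact
    comparisons of the concordant/discordant splits between groups."""
    ra = results_a.set_index("snp_id")["ref_ratio"]
    rb = results_b.set_index("snp_id")["ref_ratio"]

    def tally(ids: set) -> tuple[int, int]:
        conc = disc = 0
        for sid in ids:
            a, b = ra.get(sid), rb.get(sid)
            if a is None or b is None or a == 0.5 or b == 0.5:
                continue  # ties at exactly 0.5 belong to neither side
            if (a > 0.5) == (b > 0.5):
                conc += 1
            else:
                disc += 1
        return conc, disc

    tallies = {
        "both": tally(partition.both),
        "a_only": tally(partition.a_only),
        "b_only": tally(partition.b_only),
    }
    fracs = {
        k: (c / (c + d) if (c + d) else None) for k, (c, d) in tallies.items()
    }
    pairwise = {}
    names = list(tallies)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            (c1, d1), (c2, d2) = tallies[names[i]], tallies[names[j]]
            if c1 + d1 == 0 or c2 + d2 == 0:
                pairwise[f"{names[i]}_vs_{names[j]}"] = None
                continue
            _, p = fisher_exact([[c1, d1], [c2, d2]])
            pairwise[f"{names[i]}_vs_{names[j]}"] = float(p)
    return ConcordanceResult(
        concordance_both=fracs["both"],
        concordance_a_only=fracs["a_only"],
        concordance_b_only=fracs["b_only"],
        pairwise_p=pairwise,
    )


def differential_ase_between_tissues(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    tissue_a: str = "A",
    tissue_b: str = "B",
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP beta-binomial LRT of the allelic ratio between two tissues
    sampled from distinct (unpaired) cohorts; BH-FDR across tested SNPs.
    SNPs heterozygous in only one cohort are skipped (logged)."""
    common = set(counts_a["snp_id"]) & set(counts_b["snp_id"])
    skipped = (set(counts_a["snp_id"]) | set(counts_b["snp_id"])) - common
    if skipped:
        log.info("%d SNPs heterozygous in one tissue only; skipped", len(skipped))
    merged = pd.concat(
        [
            counts_a[counts_a["snp_id"].isin(common)].assign(group=tissue_a),
            counts_b[counts_b["snp_id"].isin(common)].assign(group=tissue_b),
        ],
        ignore_index=True,
    )
    return differential_table(merged, label_column="group", fdr_alpha=fdr_alpha)
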