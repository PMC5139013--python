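"""Synthetic genotype / allele-count generator for ASE pipeline testing.

Emulates the data layout of a two-cohort cardiac ASE study: one cohort with a
binary clinical label (e.g. postoperative atrial fibrillation in left-atrium
samples) and one paired-timepoint cohort (baseline vs post-ischemia left
ventricle).  Genotypes are drawn from Hardy-Weinberg proportions, read depth
per heterozygote is negative-binomial, sequencing error produces OTHER bases,
and the REF/ALT split is beta-binomial so allelic counts can be overdispersed
relative to a binomial.  Every simulation emits a truth ledger next to the
data so downstream tests never re-derive ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SimulationConfig",
    "StudyDesign",
    "SyntheticStudy",
    "simulate_genotypes",
    "simulate_truth_ratios",
    "simulate_allele_counts",
    "simulate_study",
    "make_snp_panel",
]

#: genotype codes in the matrix: 0 hom-REF, 1 het, 2 hom-ALT, -1 missing call
MISSING = -1

_EPS = 1e-6  # clamp for REF probabilities near 0/1


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model.

    depth_mean/depth_shape parameterise the negative-binomial per-heterozygote
    coverage (variance = m + m^2/shape); error_rate is the probability an
    observed base is neither REF nor ALT; ref_bias shifts the REF-read
    probability additively (0 = unbiased); overdispersion_rho is the
    beta-binomial intraclass correlation of the REF/ALT split.
    """

    n_individuals: int = 62
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_rate: float = 0.99
    depth_mean: float = 40.0
    depth_shape: float = 5.0
    error_rate: float = 0.005
    ref_bias: float = 0.0
    overdispersion_rho: float = 0.01
    ase_fraction: float = 0.1
    ase_ratio_range: tuple[float, float] = (0.65, 0.95)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("genotyping_rate", "error_rate", "ase_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if self.depth_mean <= 0 or self.depth_shape <= 0:
            raise ValueError("depth_mean and depth_shape must be positive")
        rlo, rhi = self.ase_ratio_range
        if not (0.0 < rlo <= rhi < 1.0):
            raise ValueError("ase_ratio_range must lie within (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyDesign:
    """Sample sheet of a two-tissue study plus the cross-tissue sharing knob.

    ``samples`` has one row per RNA sample with columns sample_id,
    individual_id, tissue, group, timepoint.  Unpaired samples carry
    timepoint ``"none"``; paired samples come as baseline/post rows sharing an
    individual_id.
    """

    samples: pd.DataFrame
    shared_ase_fraction: float = 0.6

    REQUIRED = ("sample_id", "individual_id", "tissue", "group", "timepoint")

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.samples.columns]
        if missing:
            raise ValueError(f"design sample sheet missing columns {missing}")
        if not (0.0 <= self.shared_ase_fraction <= 1.0):
            raise ValueError("shared_ase_fraction must be in [0, 1]")
        paired = self.samples[self.samples["timepoint"].isin(["baseline", "post"])]
        for ind, grp in paired.groupby("individual_id"):
            tps = sorted(grp["timepoint"])
            if tps != ["baseline", "post"]:
                raise ValueError(
                    f"individual {ind} has timepoints {tps}; every post sample "
                    "needs exactly one baseline partner"
                )

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.samples["tissue"]))

    @classmethod
    def two_cohort(
        cls,
        n_group_a: int = 62,
        n_group_b: int = 76,
        tissue_a: str = "LA",
        tissue_b: str = "LV",
        group_positive_fraction: float = 21 / 62,
        shared_ase_fraction: float = 0.6,
    ) -> "StudyDesign":
        """Mirror of the study layout this generator emulates: an unpaired
        cohort with a binary clinical label and a distinct paired cohort
        sampled at baseline and post-ischemia."""
        rows = []
        n_pos = int(round(group_positive_fraction * n_group_a))
        for i in range(n_group_a):
            ind = f"A{i + 1:03d}"
            rows.append((f"{ind}_{tissue_a}", ind, tissue_a,
                         "case" if i < n_pos else "control", "none"))
        for i in range(n_group_b):
            ind = f"B{i + 1:03d}"
            for tp in ("baseline", "post"):
                rows.append((f"{ind}_{tissue_b}_{tp}", ind, tissue_b, "none", tp))
        samples = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        design = cls(samples=samples, shared_ase_fraction=shared_ase_fraction)
        design.validate()
        return design


@dataclass
class SyntheticStudy:
    """Bundle returned by :func:`simulate_study`."""

    config: SimulationConfig
    design: StudyDesign
    panel: pd.DataFrame                      # snp_id, chrom, pos, ref, alt, mappability
    genotypes: dict[str, pd.DataFrame]       # tissue -> SNP x individual matrix
    counts: pd.DataFrame                     # long table incl. tissue/timepoint
    truth: pd.DataFrame                      # per-SNP truth ledger
    differential_truth: pd.DataFrame         # one row per injected effect


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_snp_panel(n_snps: int, seed: int = 0, mappability: float = 1.0) -> pd.DataFrame:
    """Biallelic SNP panel spread over autosomes with distinct REF/ALT bases."""
    rng = _rng(seed)
    bases = np.array(list("ACGT"))
    chroms = [str(1 + i % 22) for i in range(n_snps)]
    pos = 1000 + 500 * (np.arange(n_snps) // 22 + 1)
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(n_snps)],
            "chrom": chroms,
            "pos": pos.astype(int),
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "mappability": mappability,
        }
    )


def simulate_genotypes(
    config: SimulationConfig, seed: int | None = None, individual_prefix: str = "I"
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a SNP x individual genotype matrix from Hardy-Weinberg proportions.

    Each SNP gets a minor-allele frequency uniform in ``maf_range``; genotypes
    are multinomial in HWE proportions ((1-q)^2, 2q(1-q), q^2) and each call is
    independently set missing with probability 1 - genotyping_rate.

    Returns (matrix, per-SNP MAF truth).  Matrix values: 0 hom-REF, 1 het,
    2 hom-ALT, -1 missing.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    n, m = config.n_individuals, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    u = rng.random(size=(m, n))
    p_hom_ref = (1 - maf) ** 2
    p_het = 2 * maf * (1 - maf)
    geno = np.where(
        u[:] < p_hom_ref[:, None], 0, np.where(u < (p_hom_ref + p_het)[:, None], 1, 2)
    ).astype(np.int8)
    if config.genotyping_rate < 1.0:
        miss = rng.random(size=(m, n)) > config.genotyping_rate
        geno[miss] = MISSING
    snp_ids = [f"snp{i + 1:05d}" for i in range(m)]
    ind_ids = [f"{individual_prefix}{j + 1:03d}" for j in range(n)]
    matrix = pd.DataFrame(geno, index=snp_ids, columns=ind_ids)
    matrix.index.name = "snp_id"
    return matrix, pd.Series(maf, index=snp_ids, name="maf")


def simulate_truth_ratios(config: SimulationConfig, seed: int | None = None) -> pd.Series:
    """True REF ratios per SNP: 0.5 for non-ASE SNPs, otherwise uniform in
    ``ase_ratio_range``, mirrored below 0.5 with probability 1/2 so the
    simulated ASE carries no net reference-allele preference."""
    config.validate()
    rng = _rng((config.seed if seed is None else seed) + 1)
    m = config.n_snps
    ratios = np.full(m, 0.5)
    n_ase = int(round(config.ase_fraction * m))
    if n_ase:
        idx = rng.choice(m, size=n_ase, replace=False)
        r = rng.uniform(config.ase_ratio_range[0], config.ase_ratio_range[1], size=n_ase)
        flip = rng.random(n_ase) < 0.5
        ratios[idx] = np.where(flip, 1.0 - r, r)
    snp_ids = [f"snp{i + 1:05d}" for i in range(m)]
    return pd.Series(ratios, index=snp_ids, name="true_ratio")


def simulate_allele_counts(
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    truth_ratios: pd.Series,
    seed: int | None = None,
    tissue: str = "LA",
    timepoint: str = "none",
    sample_suffix: str = "",
) -> pd.DataFrame:
    """Per-heterozygote REF/ALT/OTHER read counts.

    Depth ~ NB(depth_mean, depth_shape); OTHER ~ Binomial(depth, error_rate)
    drawn first so error_rate is a per-base error probability; the remaining
    reads split REF/ALT with mean clamp(true_ratio + ref_bias, eps, 1-eps) and
    beta-binomial correlation overdispersion_rho.  Only heterozygous cells
    receive counts; zero-depth draws emit no record.
    """
    config.validate()
    bad = truth_ratios[(truth_ratios <= 0) | (truth_ratios >= 1)]
    if len(bad):
        raise ValueError("truth ratios must lie strictly inside (0, 1)")
    rng = _rng((config.seed if seed is None else seed) + 2)

    het_snp, het_ind = np.nonzero(genotypes.to_numpy() == 1)
    k = len(het_snp)
    snp_ids = genotypes.index.to_numpy()[het_snp]
    ind_ids = genotypes.columns.to_numpy()[het_ind]

    p_nb = config.depth_shape / (config.depth_shape + config.depth_mean)
    depth = rng.negative_binomial(config.depth_shape, p_nb, size=k)
    other = rng.binomial(depth, config.error_rate)
    rem = depth - other
    p_ref = np.clip(truth_ratios.loc[snp_ids].to_numpy() + config.ref_bias, _EPS, 1 - _EPS)
    rho = config.overdispersion_rho
    if rho > 0:
        conc = (1 - rho) / rho
        p_draw = rng.beta(p_ref * conc, (1 - p_ref) * conc)
    else:
        p_draw = p_ref
    ref = rng.binomial(rem, p_draw)
    alt = rem - ref

    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "individual_id": ind_ids,
            "sample_id": np.char.add(ind_ids.astype(str), sample_suffix),
            "tissue": tissue,
            "timepoint": timepoint,
            "ref_count": ref,
            "alt_count": alt,
            "other_count": other,
        }
    )
    table = table[depth > 0].reset_index(drop=True)
    return table.sort_values(["snp_id", "individual_id"], kind="mergesort").reset_index(drop=True)


def _pick_effect_snps(effects, eligible: pd.Index, rng: np.random.Generator) -> list[dict]:
    """Resolve effect specs; effects without an snp_id get one drawn from the
    eligible panel (without replacement across effects)."""
    resolved, used = [], set()
    pool = [s for s in eligible]
    for eff in effects:
        eff = dict(eff)
        if eff.get("snp_id") is None:
            remaining = [s for s in pool if s not in used]
            if not remaining:
                raise ValueError("more effects than eligible SNPs")
            eff["snp_id"] = remaining[int(rng.integers(len(remaining)))]
        used.add(eff["snp_id"])
        resolved.append(eff)
    return resolved


def simulate_study(
    config: SimulationConfig,
    design: StudyDesign,
    effects: list[dict] | None = None,
) -> SyntheticStudy:
    """Full two-tissue synthetic study with truth ledger.

    ``effects`` is a list of dicts with keys ``kind`` ("group" or "paired"),
    ``ratio_baseline`` and ``ratio_affected`` (true REF ratios), and optional
    ``snp_id``.  Group effects apply in the unpaired tissue: samples with the
    affected group label express ratio_affected, the rest ratio_baseline.
    Paired effects apply in the paired tissue: baseline samples express
    ratio_baseline, post samples ratio_affected.  A
    ``shared_ase_fraction`` of ASE SNPs keeps the same true ratio in both
    tissues; the rest are active in one tissue only (ratio 0.5 in the other).
    """
    config.validate()
    design.validate()
    effects = list(effects or [])
    rng = _rng(config.seed + 10)

    tissues = design.tissues
    if len(tissues) != 2:
        raise ValueError(f"two-tissue design required, got tissues {tissues}")
    tis_a, tis_b = tissues
    panel = make_snp_panel(config.n_snps, seed=config.seed)

    # one genotype matrix per cohort (disjoint individuals)
    genotypes: dict[str, pd.DataFrame] = {}
    mafs: dict[str, pd.Series] = {}
    for t_idx, tis in enumerate(tissues):
        inds = design.samples.loc[design.samples["tissue"] == tis, "individual_id"].unique()
        cfg = replace(config, n_individuals=len(inds))
        g, maf = simulate_genotypes(cfg, seed=config.seed + 1000 * (t_idx + 1))
        g.columns = inds
        genotypes[tis] = g
        mafs[tis] = maf

    # base truth ratios, then carve shared vs tissue-specific ASE
    base = simulate_truth_ratios(config, seed=config.seed)
    ase_ids = base.index[base != 0.5].to_numpy()
    rng.shuffle(ase_ids)
    n_shared = int(round(design.shared_ase_fraction * len(ase_ids)))
    shared_ids = set(ase_ids[:n_shared])
    specific = ase_ids[n_shared:]
    a_only = set(specific[: len(specific) // 2])
    b_only = set(specific[len(specific) // 2:])

    ratios = {tis_a: base.copy(), tis_b: base.copy()}
    ratios[tis_a][list(b_only)] = 0.5
    ratios[tis_b][list(a_only)] = 0.5

    eligible = base.index[base == 0.5]
    effects = _pick_effect_snps(effects, eligible, rng)

    truth = pd.DataFrame(
        {
            "snp_id": base.index,
            "maf_" + tis_a: mafs[tis_a].to_numpy(),
            "maf_" + tis_b: mafs[tis_b].to_numpy(),
            "true_ratio_" + tis_a: ratios[tis_a].to_numpy(),
            "true_ratio_" + tis_b: ratios[tis_b].to_numpy(),
            "ase_shared": base.index.isin(shared_ids),
            "ase_" + tis_a + "_only": base.index.isin(a_only),
            "ase_" + tis_b + "_only": base.index.isin(b_only),
        }
    ).set_index("snp_id")

    # per-sample counts; effect SNPs get sample-set-specific ratios
    count_parts = []
    diff_rows = []
    sample_rows = design.samples
    for offset, (_, row) in enumerate(sample_rows.iterrows()):
        tis = row["tissue"]
        geno_col = genotypes[tis][[row["individual_id"]]]
        r = ratios[tis].copy()
        for eff in effects:
            sid = eff["snp_id"]
            if eff["kind"] == "group" and tis == tis_a:
                r[sid] = (
                    eff["ratio_affected"] if row["group"] == "case" else eff["ratio_baseline"]
                )
            elif eff["kind"] == "paired" and tis == tis_b:
                r[sid] = (
                    eff["ratio_affected"] if row["timepoint"] == "post" else eff["ratio_baseline"]
                )
        part = simulate_allele_counts(
            geno_col,
            config,
            r,
            seed=config.seed + 100 + offset,
            tissue=tis,
            timepoint=row["timepoint"],
        )
        part["sample_id"] = row["sample_id"]
        count_parts.append(part)
    counts = pd.concat(count_parts, ignore_index=True)
    counts = counts.sort_values(
        ["tissue", "snp_id", "individual_id", "timepoint"], kind="mergesort"
    ).reset_index(drop=True)

    for eff in effects:
        sid = eff["snp_id"]
        tis = tis_a if eff["kind"] == "group" else tis_b
        hets = (genotypes[tis].loc[sid] == 1).sum()
        untestable = False
        if eff["kind"] == "group":
            case_inds = set(
                sample_rows.loc[
                    (sample_rows["tissue"] == tis_a) & (sample_rows["group"] == "case"),
                    "individual_id",
                ]
            )
            het_inds = set(genotypes[tis_a].columns[(genotypes[tis_a].loc[sid] == 1)])
            if not (het_inds & case_inds) or not (het_inds - case_inds):
                untestable = True
        else:
            untestable = hets == 0
        if untestable:
            warnings.warn(
                f"differential effect on {sid} has no heterozygote in an affected "
                "group; kept in truth ledger as untestable",
                stacklevel=2,
            )
        diff_rows.append(
            {
                "snp_id": sid,
                "kind": eff["kind"],
                "tissue": tis,
                "ratio_baseline": eff["ratio_baseline"],
                "ratio_affected": eff["ratio_affected"],
                "n_het": int(hets),
                "untestable": untestable,
            }
        )
    differential_truth = pd.DataFrame(
        diff_rows,
        columns=[
            "snp_id", "kind", "tissue", "ratio_baseline", "ratio_affected",
            "n_het", "untestable",
        ],
    )

    return SyntheticStudy(
        config=config,
        design=design,
        panel=panel,
        genotypes=genotypes,
        counts=counts,
        truth=truth.reset_index(),
        differential_truth=differential_truth,
    )
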