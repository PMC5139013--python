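"""End-to-end orchestration: count -> filter -> call -> compare -> differential.

A :class:`PipelineConfig` names the inputs (either a long allele-count TSV or
per-individual SAM files referenced from the sample sheet, plus genotypes and
a SNP panel), the filter thresholds, the ASE engine and the seed.  Every run
echoes its configuration, writes a manifest with package versions and input
checksums, and is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as aio
from .calling import bias_diagnostics, call_ase
from .counting import build_count_table
from .cross_tissue import (
    differential_ase_between_tissues,
    direction_concordance,
    permutation_overlap_test,
    shared_ase,
)
from .differential import differential_table
from .filters import FilterConfig, apply_filters

log = logging.getLogger("asekit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "cohort_summary"]


@dataclass
class PipelineConfig:
    out_dir: str | Path
    counts: str | Path | None = None          # long count TSV; or SAM inputs below
    sam_dir: str | Path | None = None         # directory of <individual_id>.sam
    genotypes: dict[str, str | Path] = field(default_factory=dict)  # tissue -> TSV
    panel: str | Path | None = None
    samples: str | Path | None = None         # sample sheet TSV
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    engine: str = "nb_individual"
    fdr_alpha: float = 0.05
    B: int = 10_000
    seed: int = 0
    sharing_alpha_scale: str = "fdr"
    run_sharing: bool = True
    run_differential: bool = True

    def validate(self) -> None:
        if self.counts is None and self.sam_dir is None:
            raise ValueError("either a count table or SAM inputs must be given")
        for p in [self.counts, self.panel, self.samples,
                  *self.genotypes.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("out_dir", "counts", "sam_dir", "panel", "samples"):
            if d[k] is not None:
                d[k] = str(d[k])
        d["genotypes"] = {t: str(p) for t, p in d["genotypes"].items()}
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def cohort_summary(samples: pd.DataFrame) -> dict:
    """Per-tissue bookkeeping: individuals, samples, and the positive-label
    rate in percent (e.g. the fraction of a cohort with postoperative AF)."""
    out = {}
    for tis, grp in samples.groupby("tissue"):
        inds = grp["individual_id"].nunique()
        labelled = grp.drop_duplicates("individual_id")
        n_case = int((labelled["group"] == "case").sum())
        entry = {"n_individuals": int(inds), "n_samples": int(len(grp))}
        if n_case:
            entry["n_case"] = n_case
            entry["case_rate_percent"] = 100.0 * n_case / inds
        out[str(tis)] = entry
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the output bundle in memory
    and writes every table under ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")

    samples = aio.read_samples_tsv(config.samples) if config.samples else None
    panel = aio.read_panel_tsv(config.panel) if config.panel else None
    genotypes = {t: aio.read_genotypes_tsv(p) for t, p in config.genotypes.items()}

    if config.counts is not None:
        counts = aio.read_counts_tsv(config.counts)
    else:
        if samples is None or panel is None or not genotypes:
            raise ValueError("SAM input requires a sample sheet, panel and genotypes")
        parts = []
        for tis, grp in samples.groupby("tissue"):
            paths = {
                ind: Path(config.sam_dir) / f"{ind}.sam"
                for ind in grp["individual_id"].unique()
            }
            tab, stats = build_count_table(paths, genotypes[tis], panel)
            log.info("tissue %s: %d reads in, %d not uniquely mapped, %d retained",
                     tis, stats.total, stats.removed, stats.retained)
            tab["tissue"] = tis
            tab["timepoint"] = "none"
            parts.append(tab.drop(columns=["chrom", "pos"]))
        counts = pd.concat(parts, ignore_index=True)
    if "tissue" not in counts.columns:
        counts["tissue"] = "T1"
    if "timepoint" not in counts.columns:
        counts["timepoint"] = "none"

    if samples is not None:
        known = set(samples["individual_id"])
        stray = set(counts["individual_id"]) - known
        if stray:
            raise ValueError(f"count table names individuals absent from the "
                             f"sample sheet: {sorted(stray)[:5]}")

    bundle: dict = {"filter_reports": {}, "ase": {}, "bias": {}}
    eligible: dict[str, pd.DataFrame] = {}
    tissues = sorted(counts["tissue"].unique())
    for tis in tissues:
        sub = counts[counts["tissue"] == tis]
        if tis in genotypes and panel is not None:
            elig, report = apply_filters(sub, genotypes[tis], panel, config.filter_config)
            bundle["filter_reports"][tis] = report
            aio.write_json(report.to_dict(), out_dir / f"filter_report_{tis}.json")
            report.to_frame().to_csv(out_dir / f"filter_report_{tis}.tsv",
                                     sep="\t", index=False)
        else:
            log.warning("tissue %s: no genotypes/panel given, skipping filters", tis)
            elig = sub
        eligible[tis] = elig
        # paired tissues are called on baseline samples to keep one record
        # per heterozygous individual
        call_in = elig[elig["timepoint"].isin(["none", "baseline"])]
        res = call_ase(call_in, engine=config.engine, fdr_alpha=config.fdr_alpha)
        bundle["ase"][tis] = res
        res.to_csv(out_dir / f"ase_{tis}.tsv", sep="\t", index=False)
        diag = bias_diagnostics(res, fdr_alpha=config.fdr_alpha)
        bundle["bias"][tis] = diag
        aio.write_json(
            {"overall_ref_ratio": diag.overall_ref_ratio,
             "n_above_half": diag.n_above_half, "n_below_half": diag.n_below_half,
             "skew_p": diag.skew_p,
             "percent_above": diag.percent_above},
            out_dir / f"bias_{tis}.json",
        )
        log.info("tissue %s: %d SNPs called, %d significant at FDR %.2f",
                 tis, len(res), int(res["significant"].sum()), config.fdr_alpha)

    if config.run_sharing and len(tissues) == 2:
        a, b = tissues
        res_a = bundle["ase"][a]
        res_b = bundle["ase"][b]
        common = set(res_a["snp_id"]) & set(res_b["snp_id"])
        ra = res_a[res_a["snp_id"].isin(common)]
        rb = res_b[res_b["snp_id"].isin(common)]
        part = shared_ase(ra, rb, alpha=config.fdr_alpha,
                          scale=config.sharing_alpha_scale)
        perm_p, null = permutation_overlap_test(
            part.n_eligible_both,
            len(part.both) + len(part.a_only),
            len(part.both) + len(part.b_only),
            len(part.both), B=config.B, seed=config.seed,
        )
        conc = direction_concordance(ra, rb, part)
        sharing = {
            "tissues": [a, b],
            "n_eligible_both": part.n_eligible_both,
            "n_ase_either": part.n_ase_either,
            "n_ase_both": len(part.both),
            "n_a_only": len(part.a_only),
            "n_b_only": len(part.b_only),
            "perm_p": perm_p,
            "perm_null_mean": float(null.mean()),
            "concordance_both": conc.concordance_both,
            "concordance_a_only": conc.concordance_a_only,
            "concordance_b_only": conc.concordance_b_only,
            "concordance_pairwise_p": conc.pairwise_p,
        }
        bundle["sharing"] = sharing
        aio.write_json(sharing, out_dir / "sharing.json")

        base_b = eligible[b][eligible[b]["timepoint"].isin(["none", "baseline"])]
        diff_t = differential_ase_between_tissues(
            eligible[a][eligible[a]["timepoint"] == "none"], base_b,
            tissue_a=a, tissue_b=b, fdr_alpha=config.fdr_alpha)
        bundle["diff_tissue"] = diff_t
        diff_t.to_csv(out_dir / "diff_tissue.tsv", sep="\t", index=False)

    if config.run_differential and samples is not None:
        labels = samples.set_index("individual_id")["group"].to_dict()
        grouped = samples[samples["group"].isin(["case", "control"])]
        if not grouped.empty:
            tis = grouped["tissue"].iloc[0]
            sub = eligible[tis].copy()
            sub["group"] = sub["individual_id"].map(labels)
            sub = sub[sub["group"].isin(["case", "control"])]
            diff_g = differential_table(sub, label_column="group",
                                        fdr_alpha=config.fdr_alpha)
            bundle["diff_group"] = diff_g
            diff_g.to_csv(out_dir / "diff_group.tsv", sep="\t", index=False)
        paired = samples[samples["timepoint"].isin(["baseline", "post"])]
        if not paired.empty:
            tis = paired["tissue"].iloc[0]
            sub = eligible[tis]
            sub = sub[sub["timepoint"].isin(["baseline", "post"])]
            diff_p = differential_table(sub, label_column="timepoint", paired=True,
                                        fdr_alpha=config.fdr_alpha)
            bundle["diff_paired"] = diff_p
            diff_p.to_csv(out_dir / "diff_paired.tsv", sep="\t", index=False)
        bundle["cohorts"] = cohort_summary(samples)
        aio.write_json(bundle["cohorts"], out_dir / "cohorts.json")

    manifest = {
        "asekit_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict() | {"filter_config": dataclasses.asdict(config.filter_config)},
        "inputs": {
            str(p): _sha256(p)
            for p in [config.counts, config.panel, config.samples,
                      *config.genotypes.values()]
            if p is not None
        },
    }
    aio.write_json(manifest, out_dir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
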