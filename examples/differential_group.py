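"""Differential ASE between clinical groups (beta-binomial LRT).

Injects a strong allelic-ratio difference (0.5 vs 0.9) at one SNP between
the case and control subgroups of the unpaired cohort, then tests every
SNP with the shared-rho beta-binomial likelihood-ratio test and BH-FDR.
"""

from asekit.differential import differential_table
from asekit.simulate import SimulationConfig, StudyDesign, simulate_study

study = simulate_study(
    SimulationConfig(n_snps=300, seed=5),
    StudyDesign.two_cohort(n_group_a=62, n_group_b=76),
    effects=[{"kind": "group", "ratio_baseline": 0.5, "ratio_affected": 0.9}],
)
truth_snp = study.differential_truth["snp_id"].iloc[0]

la = study.counts[study.counts["tissue"] == "LA"].copy()
labels = study.design.samples.set_index("individual_id")["group"].to_dict()
la["group"] = la["individual_id"].map(labels)

out = differential_table(la, label_column="group", fdr_alpha=0.05)
print(f"SNPs tested: {len(out)}; significant at FDR < 0.05: "
      f"{int(out['significant'].sum())}")
print(out.head(3)[["snp_id", "n_het_group1", "n_het_group2",
                   "ratio_group1", "ratio_group2", "p_fdr",
                   "low_confidence"]].to_string(index=False))
print(f"\ninjected effect SNP: {truth_snp} "
      f"(rank {out.index[out['snp_id'] == truth_snp][0] + 1} by p-value)")
# ratio_group1/ratio_group2 are the pooled REF/(REF+ALT) ratios per group;
# low_confidence marks SNPs with a single heterozygote in one group, which
# a genotyping error could mimic.
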