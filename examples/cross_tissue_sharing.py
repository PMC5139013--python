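"""Quantify shared vs tissue-specific ASE between two tissues.

Calls ASE separately in both tissues, partitions significant SNPs into
both / A-only / B-only, compares the observed overlap with 10,000 random
draws from the eligible pool, and measures direction concordance of the
reference ratio.
"""

from asekit.calling import call_ase
from asekit.cross_tissue import (
    direction_concordance,
    permutation_overlap_test,
    shared_ase,
)
from asekit.simulate import SimulationConfig, StudyDesign, simulate_study

study = simulate_study(
    SimulationConfig(n_snps=400, seed=3, ase_fraction=0.15),
    StudyDesign.two_cohort(n_group_a=62, n_group_b=76,
                           shared_ase_fraction=0.6),
)
la = study.counts[study.counts["tissue"] == "LA"]
lv = study.counts[(study.counts["tissue"] == "LV")
                  & (study.counts["timepoint"] == "baseline")]

res_la = call_ase(la)
res_lv = call_ase(lv)
common = set(res_la["snp_id"]) & set(res_lv["snp_id"])
res_la = res_la[res_la["snp_id"].isin(common)]
res_lv = res_lv[res_lv["snp_id"].isin(common)]

part = shared_ase(res_la, res_lv, alpha=0.05)
perm_p, null = permutation_overlap_test(
    part.n_eligible_both,
    len(part.both) + len(part.a_only),
    len(part.both) + len(part.b_only),
    len(part.both), B=10_000, seed=3,
)
print(f"eligible in both tissues: {part.n_eligible_both}")
print(f"ASE in both: {len(part.both)}, LA only: {len(part.a_only)}, "
      f"LV only: {len(part.b_only)}")
print(f"random-draw overlap: mean {null.mean():.1f}; "
      f"observed {len(part.both)} -> permutation p = {perm_p:.2g}")

conc = direction_concordance(res_la, res_lv, part)
print(f"direction concordance: both={conc.concordance_both:.0%}, "
      f"LA-only={conc.concordance_a_only:.0%}, "
      f"LV-only={conc.concordance_b_only:.0%}")
# shared-ASE SNPs land on the same side of 0.5 in both tissues far more
# often than chance; a small permutation p says the overlap is not random.
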