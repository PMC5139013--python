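import warnings
from pathlib import Path

import pandas as pd
import pytest

from asekit.simulate import SimulationConfig, StudyDesign, simulate_study

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def sam_fixture():
    """Hand-written SAM fixture: two SNPs x two heterozygous individuals.

    Expected counts were tallied by hand from the read sequences: ind1 rs1
    has 4 REF / 2 ALT / 1 OTHER among its 12 uniquely mapped reads (one via a
    soft-clipped alignment, one read deleted across the SNP), ind1 rs2 has
    2/2/0, ind2 has 4/1/0 and 1/3/0.
    """
    panel = pd.read_csv(DATA / "panel.tsv", sep="\t", dtype={"chrom": str})
    genotypes = pd.read_csv(DATA / "genotypes.tsv", sep="\t", index_col="snp_id")
    paths = {"ind1": DATA / "ind1.sam", "ind2": DATA / "ind2.sam"}
    expected = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 100, 200, 200],
            "snp_id": ["rs1", "rs1", "rs2", "rs2"],
            "individual_id": ["ind1", "ind2", "ind1", "ind2"],
            "ref_count": [4, 4, 2, 1],
            "alt_count": [2, 1, 2, 3],
            "other_count": [1, 0, 0, 0],
        }
    )
    return panel, genotypes, paths, expected


@pytest.fixture(scope="session")
def small_study():
    """Seeded two-tissue study with one group effect and one paired effect."""
    cfg = SimulationConfig(n_snps=150, n_individuals=30, seed=11)
    design = StudyDesign.two_cohort(n_group_a=30, n_group_b=20,
                                    shared_ase_fraction=0.6)
    effects = [
        {"kind": "group", "ratio_baseline": 0.5, "ratio_affected": 0.9},
        {"kind": "paired", "ratio_baseline": 0.35, "ratio_affected": 0.64},
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg, design, effects)
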