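import pytest

from meiorec.parent_blocks import HaplotypeBlock, PhasedSite
from meiorec.pipeline import analyze_dataset
from meiorec.simulate import SimulationConfig, simulate_dataset


def make_block(
    positions,
    hap1_labels,
    chrom="Chr01",
    parent_id="P1",
    block_id="b1",
    source="phased_input",
):
    """A labelled haplotype block; hap1 carries 'A', hap2 carries 'C'."""
    sites = []
    for pos, lab in zip(positions, hap1_labels):
        other = "b" if lab == "a" else "a"
        sites.append(
            PhasedSite(
                chrom=chrom,
                pos=pos,
                hap1_allele="A",
                hap2_allele="C",
                ab_label_hap1=lab,
                ab_label_hap2=other,
                depth=30,
                allele_depths=(15, 15),
                genotype_quality=99,
            )
        )
    return HaplotypeBlock(
        parent_id=parent_id,
        chrom=chrom,
        block_id=block_id,
        sites=sites,
        source=source,
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Reference error-free simulation (shared across tests for speed)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_analysis(clean_dataset):
    return analyze_dataset(clean_dataset)
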