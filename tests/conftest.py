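import pandas as pd
import pytest

from chimeraems.config import SimulationConfig
from chimeraems.provenance import SampleSheet, build_locus_matrix, partition
from chimeraems.simdata import (
    emit_sample_calls,
    generate_genome,
    plant_causal_genes,
    sample_layout,
    simulate_two_round_mutagenesis,
)
from chimeraems.twohit import assign_snps_to_genes, candidate_genes


def run_simulation(config: SimulationConfig) -> dict:
    """Full simulate -> partition -> candidates chain, all objects kept."""
    genome = generate_genome(config)
    truth = plant_causal_genes(
        config, genome, simulate_two_round_mutagenesis(config, genome)
    )
    calls, masks = emit_sample_calls(truth, config, genome)
    sheet = SampleSheet.from_layout(sample_layout(config))
    matrix = build_locus_matrix(calls, masks, sheet)
    part = partition(matrix, sheet)
    assigned = assign_snps_to_genes(part.loci, genome.genes_frame(),
                                    set(genome.chrom_names))
    candidates = {
        line: candidate_genes(assigned, line) for line in sheet.lines
    }
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "calls": calls,
        "masks": masks,
        "sheet": sheet,
        "matrix": matrix,
        "partition": part,
        "assigned": assigned,
        "candidates": candidates,
    }


@pytest.fixture(scope="session")
def recovery_conditions() -> SimulationConfig:
    """Zero-noise recovery design: 1 Mb, two lines, ~200 background +
    100 first-round + 100 second-round mutations per line, no green
    leak, three planted causal genes."""
    return SimulationConfig(green_leak_fraction=0.0, seed=1)


@pytest.fixture(scope="session")
def recovery_run(recovery_conditions) -> dict:
    return run_simulation(recovery_conditions)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        genome_length=50_000,
        n_genes=5,
        gene_length=500,
        background_snv_rate=1e-4,
        ems1_count=20,
        ems2_count=20,
        green_leak_fraction=0.0,
        n_causal_genes=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def four_sample_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample": ["GY1Y", "GY1G", "GY2Y", "GY2G"],
                "line": ["GY1", "GY1", "GY2", "GY2"],
                "sector": ["yellow", "green", "yellow", "green"],
            }
        )
    )
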