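import numpy as np
import pandas as pd
import pytest

from slamscreen.sgrna import SgRNALibrary
from slamscreen import simulate as sim


@pytest.fixture(scope="session")
def tiny_library() -> SgRNALibrary:
    """Hand-built whitelist: two targets x two guides plus two NTCs."""
    rows = [
        ("geneA_sg1", "ACGTACGTACGTACGTACGT", "geneA", False),
        ("geneA_sg2", "TTTTCCCCGGGGAAAATTTT", "geneA", False),
        ("geneB_sg1", "GGGGGGGGGGCCCCCCCCCC", "geneB", False),
        ("geneB_sg2", "ATATATATATATATATATAT", "geneB", False),
        ("NTC_sg1", "CCCCCAAAAACCCCCAAAAA", "NTC", True),
        ("NTC_sg2", "GTGTGTGTGTGTGTGTGTGT", "NTC", True),
    ]
    return SgRNALibrary(
        pd.DataFrame(
            rows, columns=["sgrna_id", "protospacer", "target_gene", "is_ntc"]
        )
    )


@pytest.fixture(scope="session")
def small_screen():
    """Count-level synthetic screen shared across tests (deterministic)."""
    genome = sim.build_genome(40, n_mito_genes=4, seed=11)
    nuclear = [g.gene_id for g in genome.genes if not g.is_mito]
    library = sim.make_library(nuclear[:2], sgrnas_per_gene=2, n_ntc=3, seed=11)
    truth = sim.make_truth(genome, library, n_cells=600, seed=11)
    counts = sim.simulate_counts(truth)
    return genome, library, truth, counts


@pytest.fixture(scope="session")
def read_level_screen(tmp_path_factory):
    """Small read-level simulation: SAM + per-read truth labels."""
    outdir = tmp_path_factory.mktemp("readsim")
    genome = sim.build_genome(25, n_mito_genes=2, seed=7)
    nuclear = [g.gene_id for g in genome.genes if not g.is_mito]
    library = sim.make_library(nuclear[:1], sgrnas_per_gene=1, n_ntc=2, seed=7)
    truth = sim.make_truth(
        genome, library, n_cells=60, seed=7,
        p_conversion=0.05, p_error=0.001, n_snps=30,
    )
    counts = sim.simulate_counts(truth)
    sam = outdir / "reads.sam"
    truth_reads = sim.simulate_reads(truth, counts, genome, sam)
    return genome, library, truth, counts, sam, truth_reads
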