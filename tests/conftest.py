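import numpy as np
import pandas as pd
import pytest

from isobench import (
    Annotation,
    SimConfig,
    TranscriptModel,
    build_reference_index,
    simulate,
)


@pytest.fixture(scope="session")
def tiny_annotation():
    """Three genes, seven transcripts, hand-built.

    GA (+): two multi-isoform transcripts sharing junctions plus a
    truncated isoform; GB (-): two isoforms; GC (+): one mono-exon gene.
    """
    return Annotation(
        [
            # GA: 4 exons, chain J1 J2 J3
            TranscriptModel(
                "GA.T1", "GA", "chr1", "+",
                ((1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700)),
            ),
            # GA: alternative acceptor on exon 3
            TranscriptModel(
                "GA.T2", "GA", "chr1", "+",
                ((1000, 1200), (1500, 1700), (2050, 2200), (2500, 2700)),
            ),
            # GA: 5'-truncated two-exon isoform (sub-chain of T1)
            TranscriptModel(
                "GA.T3", "GA", "chr1", "+", ((2000, 2200), (2500, 2700))
            ),
            # GB on minus strand: 3 exons
            TranscriptModel(
                "GB.T1", "GB", "chr1", "-",
                ((10000, 10300), (10800, 11000), (11400, 11600)),
            ),
            TranscriptModel(
                "GB.T2", "GB", "chr1", "-",
                ((10000, 10300), (10900, 11000), (11400, 11600)),
            ),
            # GC: mono-exon gene
            TranscriptModel("GC.T1", "GC", "chr1", "+", ((20000, 21000),)),
            # GD on chr2 to exercise chrom separation
            TranscriptModel(
                "GD.T1", "GD", "chr2", "+", ((5000, 5200), (5600, 5800))
            ),
        ]
    )


@pytest.fixture(scope="session")
def tiny_index(tiny_annotation):
    return build_reference_index(tiny_annotation)


@pytest.fixture(scope="session")
def sim_bundle():
    """A mid-sized seeded simulation with all planted categories."""
    cfg = SimConfig(
        seed=11,
        n_genes=25,
        isoforms_per_gene=3,
        p_truncate=0.2,
        p_exon_skip=0.2,
        p_site_shift=0.2,
        n_antisense=5,
        n_intergenic=5,
    )
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
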