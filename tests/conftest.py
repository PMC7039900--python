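import numpy as np
import pytest
from hypothesis import settings

from spliceprofile.gene_models import GeneModel
from spliceprofile.junction_io import JunctionRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_model(exon_lengths, intron_lengths, strand="+", chrom="chr1",
               gene="TEST", start=1000, excluded=frozenset()):
    """Build a GeneModel from exon/intron lengths laid out left to right."""
    assert len(intron_lengths) == len(exon_lengths) - 1
    pos = start
    intervals = []
    for i, el in enumerate(exon_lengths):
        intervals.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    if strand == "-":
        intervals = intervals[::-1]
    return GeneModel(
        gene_symbol=gene, chromosome=chrom, strand=strand,
        transcript_id=f"{gene}_tx", exons=tuple(intervals),
        excluded_exon_indices=frozenset(excluded),
    )


def junction(model_or_chrom, s, e, strand="undefined", reads=10):
    chrom = (
        model_or_chrom.chromosome
        if isinstance(model_or_chrom, GeneModel)
        else model_or_chrom
    )
    return JunctionRecord(chrom, s, e, strand, unique_reads=reads)


@pytest.fixture
def three_exon_model():
    # exons 100nt at 1000-1099, 2000-2099, 3000-3099
    return make_model([100, 100, 100], [900, 900], start=1000)


@pytest.fixture
def three_exon_model_minus():
    return make_model([100, 100, 100], [900, 900], start=1000, strand="-")


@pytest.fixture
def five_exon_model():
    return make_model([80, 120, 90, 60, 150], [500, 700, 400, 900], start=5000)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    from spliceprofile.synthetic_data import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        seed=11, n_genes=5, n_controls=40, n_patients=3,
        exon_count_range=(6, 14),
    )
    return simulate_cohort(cfg)
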