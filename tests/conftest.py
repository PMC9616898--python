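import pytest

from isoswitch import CohortConfig, PrimerPair, TranscriptModel, simulate_cohort
from isoswitch.quantify import isoform_fractions, tpm_normalize
from isoswitch.synthetic_data import effective_lengths

#: the isoform-discriminating primer pair used throughout the amplicon tests
FWD = "CCTCAGCAACAACCCCTCTA"
REV = "CCTGCTCTTCAATAACATCC"


@pytest.fixture
def primers() -> PrimerPair:
    return PrimerPair(forward=FWD, reverse=REV)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    cfg = CohortConfig(n_samples=18, n_switch_genes=10, n_null_genes=90, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_fractions(small_cohort):
    counts, models, junctions, samples, truth = small_cohort
    tpm = tpm_normalize(counts, effective_lengths(models))
    return tpm, isoform_fractions(tpm), truth


def make_transcript(exons, strand="+", gene="G", tid="T", chrom="chr1"):
    return TranscriptModel(gene, tid, chrom, strand, tuple(exons))
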