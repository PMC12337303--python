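import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from prernaseq.align import LocusIndex
from prernaseq.simulate import (
    SimConfig,
    default_species,
    make_locus,
    simulate_reads,
    size_select,
)


@pytest.fixture(scope="session")
def locus():
    """Default fixture locus: 100 nt flank + 157-nt mature 5.8S + 500 nt."""
    return make_locus(1)


@pytest.fixture(scope="session")
def species(locus):
    """Five-species pre-5.8S mix after smeared 160-400-nt gel selection."""
    return size_select(default_species(), (160, 400), "smeared")


@pytest.fixture(scope="session")
def locus_index(locus):
    return LocusIndex(locus.seq)


@pytest.fixture(scope="session")
def clean_sim(locus, species):
    """2000 error-free reads from the fixture, with ground truth."""
    cfg = SimConfig(n_reads=2000, error_rate=0.0, seed=5)
    return simulate_reads(locus, species, cfg)


@pytest.fixture(scope="session")
def sw_oracle():
    """Independent full Smith-Waterman oracle (Biopython, C implementation)
    on the package's scoring scheme: a length-k gap costs 3 + k."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


@pytest.fixture(scope="session")
def nw_oracle():
    """Independent global-alignment oracle with linear gap penalty -2."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner
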