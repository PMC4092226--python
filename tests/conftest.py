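import pytest

from ovamir.annotate import ReferenceSet, annotate_tags
from ovamir.preprocess import PreprocessConfig, preprocess_reads
from ovamir.simlib import SimConfig, simulate_dataset

#: a desk-scale library shared by many tests (session-cached; ~seconds)
SMALL_SIM = SimConfig(read_total=20_000, n_known=8, n_novel=4, n_pirna_loci=10,
                      genome_length=10_000, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def small_tags(small_dataset):
    tags, report = preprocess_reads(small_dataset.reads, PreprocessConfig(),
                                    small_dataset.contaminants)
    return tags, report


@pytest.fixture(scope="session")
def small_annotation(small_dataset, small_tags):
    tags, _ = small_tags
    refset = ReferenceSet.from_planted(small_dataset.genome,
                                       small_dataset.planted)
    return annotate_tags(tags, refset)
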