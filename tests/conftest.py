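import random

import pysam
import pytest

from bamql import fixtures as fx


@pytest.fixture(scope="session")
def small_bam(tmp_path_factory):
    """An 800-read indexed synthetic BAM with its truth table."""
    path = tmp_path_factory.mktemp("bam") / "small.bam"
    truth = fx.generate_bam(fx.SyntheticSpec(n_reads=800, seed=11), str(path))
    return str(path), truth


@pytest.fixture(scope="session")
def small_records(small_bam):
    path, _ = small_bam
    with pysam.AlignmentFile(path) as af:
        return list(af.fetch(until_eof=True))


@pytest.fixture()
def rng():
    return random.Random(1234)


@pytest.fixture(scope="session")
def header_names():
    return [n for n, _ in fx.DEFAULT_CONTIGS]
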