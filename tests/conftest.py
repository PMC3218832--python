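import numpy as np
import pytest

from emsaseq.motif_models import BindingModel, build_model
from emsaseq.sequencing_io import OligoDesign
from emsaseq.synthetic_data import (
    DEFAULT_DESIGN,
    make_control_pool,
    write_fastq,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return OligoDesign(
        degenerate_length=10, flank5="ACGT", flank3="TGCA", max_flank_mismatch=0
    )


@pytest.fixture
def toy_model():
    """Small width-3 model with distinct per-column preferences."""
    freqs = np.array(
        [
            [0.70, 0.10, 0.10, 0.10],
            [0.05, 0.60, 0.25, 0.10],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    return BindingModel(freqs, source="reference_pwm")


@pytest.fixture
def pool_fastq(tmp_path, rng):
    """A 500-read FASTQ written by the generator, with its true regions."""
    reads = make_control_pool(500, DEFAULT_DESIGN, rng=rng)
    regions = [
        r[len(DEFAULT_DESIGN.flank5) : len(DEFAULT_DESIGN.flank5) + 20] for r in reads
    ]
    path = tmp_path / "pool.fastq"
    write_fastq(path, reads)
    return path, reads, regions


def random_kmers(rng, n, k):
    bases = np.array(list("ACGT"))
    return ["".join(row) for row in bases[rng.integers(0, 4, size=(n, k))]]
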