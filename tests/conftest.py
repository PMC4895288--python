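import numpy as np
import pytest

from medoidshift.cli import toy_seg_text, two_blob_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160111)


@pytest.fixture
def blobs():
    """Two tight, well-separated blobs of 20 points each in 3-d."""
    return two_blob_matrix()


@pytest.fixture
def toy_seg(tmp_path):
    """The packaged 4-sample / 2-chromosome SEG fixture, on disk."""
    path = tmp_path / "toy.seg"
    path.write_text(toy_seg_text())
    return path
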