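import numpy as np
import pytest

from timsdda.chemistry import Peptide
from timsdda.core_model import TimsFrame
from timsdda.search import Psm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_frame(rng, n_peaks=1000, n_scans=50, frame_id=1, rt=10.0):
    """Random frame with a consistent linear scan <-> mobility mapping."""
    scan = rng.integers(0, n_scans, size=n_peaks)
    return TimsFrame(
        frame_id=frame_id,
        retention_time=rt,
        scan=scan,
        inv_ion_mobility=1.5 - 0.01 * scan,
        mz=rng.uniform(100.0, 1700.0, size=n_peaks),
        intensity=rng.integers(1, 1000, size=n_peaks).astype(float),
    )


@pytest.fixture
def frame(rng):
    return random_frame(rng)


def make_psm(
    spectrum_id="s1",
    sequence="PEPTIDEK",
    score=10.0,
    is_decoy=False,
    charge=2,
    **kwargs,
):
    """Minimal PSM for FDR / rescoring tests."""
    return Psm(
        spectrum_id=spectrum_id,
        peptide=Peptide(sequence, is_decoy=is_decoy),
        charge=charge,
        hyperscore=score,
        **kwargs,
    )
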