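import numpy as np
import pytest

from btpcorr.geometry import StructureFrame, TorsionSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(angles, index=1, kind="psi", residue=1):
    return TorsionSeries(index=index, residue_number=residue, kind=kind,
                         angles=np.asarray(angles, dtype=float))


@pytest.fixture
def tripeptide_frame():
    """Hand-placed backbone of a 3-residue chain (extended-ish, arbitrary)."""
    coords = {
        (1, "N"): np.array([0.0, 0.0, 0.0]),
        (1, "CA"): np.array([1.45, 0.0, 0.0]),
        (1, "C"): np.array([2.0, 1.4, 0.0]),
        (2, "N"): np.array([3.3, 1.5, 0.3]),
        (2, "CA"): np.array([4.1, 2.7, 0.4]),
        (2, "C"): np.array([5.5, 2.4, 1.0]),
        (3, "N"): np.array([6.4, 3.4, 1.1]),
        (3, "CA"): np.array([7.8, 3.2, 1.6]),
        (3, "C"): np.array([8.5, 4.5, 2.0]),
    }
    return StructureFrame(residue_numbers=(1, 2, 3), coords=coords)
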