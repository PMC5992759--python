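import numpy as np
import pytest

from alphamicro import cells, tracks


@pytest.fixture(scope="session")
def small_field():
    """Collimated synthetic field: 1200 tracks on 100 x 100 um^2."""
    fld = tracks.generate_collimated_field(1200, 10000.0, seed=101)
    tracks.total_dose(fld)
    return fld


@pytest.fixture(scope="session")
def flat_cell():
    """Flattened adherent-cell geometry: ellipsoidal nucleus of ~739 um^3
    (semi-axes 7 x 7 x 3.6 um) in a 2-um cytoplasm margin."""
    return cells.generate_synthetic_cell((7.0, 7.0, 3.6), 2.0, seed=7)


@pytest.fixture(scope="session")
def nucleus_slab():
    """A pure-nucleus slab, 10 z-voxels of 430 nm: tau3 of a vertical ray
    is exactly 4.3 um."""
    labels = np.zeros((10, 200, 200), dtype=np.uint8)
    labels[:, :, :] = 201
    return cells.LabelVolume(labels, (96.0, 96.0, 430.0))
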