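import numpy as np
import pytest

from ilstab import SampleMeta


@pytest.fixture
def meta():
    return SampleMeta(sample_id="toy", protein_conc=0.4, path_length=0.1,
                      mean_residue_weight=110.0)


@pytest.fixture
def toy_grid():
    """3 temperatures x 4 wavelengths toy ellipticity grid."""
    temperatures = np.array([25.0, 35.0, 45.0])
    wavelengths = np.array([210.0, 218.0, 226.0, 234.0])
    values = np.arange(12, dtype=float).reshape(3, 4) - 6.0
    return temperatures, wavelengths, values
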