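import numpy as np
import pytest

from adcrepro.dwi_data import DWISeries, ROIMask
from adcrepro.synthetic_data import (
    CasePreset,
    PhantomSpec,
    StudySpec,
    default_centre_specs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230710)


@pytest.fixture
def unit_phantom_spec():
    """Isotropic 1 mm grid, lesion r=8 and core r=3 voxels (== mm)."""
    return PhantomSpec(
        shape=(24, 24, 24),
        spacing=(1.0, 1.0, 1.0),
        r_lesion_mm=8.0,
        r_core_mm=3.0,
        b_values=(0.0, 30.0, 80.0, 150.0, 500.0),
    )


@pytest.fixture
def tiny_study_spec():
    """A scaled-down study (2 cases, 3 centres, small grid) for fast
    end-to-end runs; conditions and layout match the full design."""
    cases = (
        CasePreset("alpha", 8.0, 3.0, 1.1e-3, (0.0, 30.0, 80.0, 150.0, 500.0), 1.0),
        CasePreset(
            "beta", 9.0, 0.0, 0.9e-3, (30.0, 80.0, 150.0, 300.0, 500.0), 1.2,
            roi_types=("GTV", "CTV"),
        ),
    )
    base = PhantomSpec(shape=(28, 28, 12), spacing=(2.0, 2.0, 4.0), noise_sigma=2.0)
    return StudySpec(
        cases=cases, centres=default_centre_specs()[:3], base_phantom=base, seed=7
    )


def homogeneous_series(
    adc=1.0e-3, s0=100.0, b_values=(0.0, 30.0, 80.0, 150.0, 500.0), shape=(6, 6, 4)
):
    b = np.asarray(b_values, dtype=float)
    sig = s0 * np.exp(-b * adc)
    signal = np.broadcast_to(sig, shape + (b.size,)).copy()
    return DWISeries(signal=signal, b_values=b, spacing=(2.0, 2.0, 4.0))


def box_mask(shape, lo, hi, roi_type="GTV", centre="c1", spacing=(1.0, 1.0, 1.0)):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return ROIMask(mask=m, roi_type=roi_type, centre_id=centre, spacing=spacing)
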