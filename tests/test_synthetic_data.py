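import numpy as np
import pandas as pd
import pytest

from adcrepro.adc_fitting import FitOptions, fit_voxel_map
from adcrepro.contour_metrics import dice_coefficient
from adcrepro.dwi_data import load_dwi_series, select_b_subset
from adcrepro.synthetic_data import (
    PhantomSpec,
    PhantomTissue,
    add_rician_noise,
    build_phantom,
    default_study_spec,
    expected_delineation_count,
    ivim_signal,
    perturb_delineation,
    simulate_study,
)
from conftest import box_mask
from dataclasses import replace


def test_ivim_signal_closed_form():
    mono = PhantomTissue(s0=100.0, d=1.0e-3, f=0.0)
    b = np.array([0.0, 200.0, 500.0])
    np.testing.assert_allclose(ivim_signal(b, mono), 100.0 * np.exp(-b * 1e-3))
    perf = PhantomTissue(s0=100.0, d=1.0e-3, f=0.1, d_star=50e-3)
    assert ivim_signal(0.0, perf) == pytest.approx(100.0)
    expected = 100.0 * (0.1 * np.exp(-25.0) + 0.9 * np.exp(-0.5))
    assert ivim_signal(500.0, perf) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        ivim_signal(-1.0, perf)


def test_tissue_invariants():
    with pytest.raises(ValueError):
        PhantomTissue(s0=100.0, d=1.0e-3, f=1.0)
    with pytest.raises(ValueError):
        PhantomTissue(s0=100.0, d=2.0e-3, f=0.1, d_star=1.0e-3)  # d_star <= d
    with pytest.raises(ValueError):
        PhantomTissue(s0=0.0, d=1.0e-3)


def test_phantom_mask_sizes_match_enumeration(unit_phantom_spec):
    _, gtv, vtv = build_phantom(unit_phantom_spec)
    # independent brute-force count of integer lattice points in the spheres
    c = (np.array(unit_phantom_spec.shape) - 1) / 2.0
    n_lesion = n_core = 0
    for x in range(unit_phantom_spec.shape[0]):
        for y in range(unit_phantom_spec.shape[1]):
            for z in range(unit_phantom_spec.shape[2]):
                r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
                n_lesion += r2 <= 8.0**2
                n_core += r2 <= 3.0**2
    assert gtv.n_voxels == n_lesion
    assert vtv.n_voxels == n_lesion - n_core
    # VTV = GTV minus the core, exactly, hence a subset
    assert not (vtv.mask & ~gtv.mask).any()


def test_zero_core_makes_vtv_equal_gtv(unit_phantom_spec):
    spec = replace(unit_phantom_spec, r_core_mm=0.0)
    _, gtv, vtv = build_phantom(spec)
    np.testing.assert_array_equal(gtv.mask, vtv.mask)


def test_lesion_must_fit_grid(unit_phantom_spec):
    with pytest.raises(ValueError, match="grid"):
        build_phantom(replace(unit_phantom_spec, r_lesion_mm=100.0, r_core_mm=3.0))


def test_noiseless_perfusion_free_phantom_recovers_d(unit_phantom_spec):
    spec = replace(
        unit_phantom_spec,
        viable=PhantomTissue(s0=100.0, d=1.1e-3, f=0.0),
        necrotic=PhantomTissue(s0=130.0, d=2.5e-3, f=0.0),
    )
    series, gtv, vtv = build_phantom(spec)
    amap = fit_voxel_map(select_b_subset(series, 150.0), vtv, FitOptions("lls"))
    assert amap.n_excluded == 0
    np.testing.assert_allclose(amap.retained_values(), 1.1e-3, rtol=1e-10)


def test_rician_noise_moments(rng):
    from adcrepro.dwi_data import DWISeries

    # sigma=0 is the identity
    base = DWISeries(np.full((4, 4, 2, 2), 30.0), [0.0, 500.0], (1, 1, 1))
    assert add_rician_noise(base, 0.0, 1) is base

    n = 100_000
    zeros = DWISeries(np.zeros((n, 1, 1, 1)), [0.0], (1, 1, 1))
    noisy = add_rician_noise(zeros, 1.0, seed=11)
    # Rayleigh mean sigma*sqrt(pi/2)
    assert noisy.signal.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    bright = DWISeries(np.full((n, 1, 1, 1), 50.0), [0.0], (1, 1, 1))
    noisy = add_rician_noise(bright, 1.0, seed=12)
    assert noisy.signal.mean() == pytest.approx(np.sqrt(50.0**2 + 1.0), rel=1e-3)
    with pytest.raises(ValueError):
        add_rician_noise(bright, -1.0)


def test_perturbation_identity_and_determinism():
    mask = box_mask((20, 20, 10), (5, 5, 3), (12, 12, 7), spacing=(1.0, 1.0, 1.0))
    same = perturb_delineation(mask, 0.0, 0, seed=5)
    assert dice_coefficient(mask, same) == 1.0
    a = perturb_delineation(mask, 2.0, 1, seed=42)
    b = perturb_delineation(mask, 2.0, 1, seed=42)
    c = perturb_delineation(mask, 2.0, 1, seed=43)
    np.testing.assert_array_equal(a.mask, b.mask)
    assert not np.array_equal(a.mask, c.mask)
    with pytest.raises(ValueError, match="empty"):
        perturb_delineation(box_mask((4, 4, 4), (0, 0, 0), (0, 0, 0)), 1.0, 1, 1)


def test_pure_translation_dice_closed_form(rng):
    # a slab translated by k voxels along x: overlap (L-k), dice = (L-k)/L
    L, k = 10, 3
    slab = box_mask((30, 8, 8), (5, 0, 0), (5 + L, 8, 8), spacing=(1.0, 1.0, 1.0))
    shifted = box_mask((30, 8, 8), (5 + k, 0, 0), (5 + L + k, 8, 8))
    assert dice_coefficient(slab, shifted) == pytest.approx((L - k) / L)


def test_erosion_retry_never_returns_empty():
    tiny = box_mask((12, 12, 6), (5, 5, 2), (7, 7, 4), spacing=(1.0, 1.0, 1.0))
    for seed in range(12):
        out = perturb_delineation(tiny, 0.0, 4, seed=seed)
        assert not out.is_empty


def test_increasing_shift_monotonically_decreases_dice():
    mask = box_mask((24, 24, 12), (6, 6, 3), (16, 16, 9), spacing=(2.0, 2.0, 4.0))
    mean_dice = []
    for sigma in (0.5, 2.5, 6.0):
        dices = []
        for seed in range(8):
            p = perturb_delineation(mask, sigma, 0, seed=seed)
            dices.append(dice_coefficient(mask, p))
        mean_dice.append(np.mean(dices))
    assert mean_dice[0] > mean_dice[1] > mean_dice[2]


def test_default_study_bookkeeping():
    spec = default_study_spec()
    assert len(spec.centres) == 9
    assert sum(len(c.roi_types) for c in spec.cases) == 8
    assert expected_delineation_count(spec) == 72
    # nine distinct local methods
    own = {(c.own_condition, c.own_fit_options) for c in spec.centres}
    assert len(own) == 9


def test_simulate_study_layout_and_determinism(tmp_path, tiny_study_spec):
    out1 = simulate_study(tiny_study_spec, tmp_path / "s1")
    out2 = simulate_study(tiny_study_spec, tmp_path / "s2")
    manifest = pd.read_csv(out1 / "manifest.csv")
    assert len(manifest) == expected_delineation_count(tiny_study_spec) == 4 * 3
    # byte-identical manifest, voxel-identical volumes for the same seed
    assert (out1 / "manifest.csv").read_bytes() == (out2 / "manifest.csv").read_bytes()
    for case in ("alpha", "beta"):
        a = load_dwi_series(out1 / f"case_{case}" / "dwi_test.nii.gz",
                            out1 / f"case_{case}" / "dwi.bval")
        b = load_dwi_series(out2 / f"case_{case}" / "dwi_test.nii.gz",
                            out2 / f"case_{case}" / "dwi.bval")
        np.testing.assert_array_equal(a.signal, b.signal)
    # test and retest differ only by noise realisation (not identical)
    t = load_dwi_series(out1 / "case_alpha" / "dwi_test.nii.gz",
                        out1 / "case_alpha" / "dwi.bval")
    r = load_dwi_series(out1 / "case_alpha" / "dwi_retest.nii.gz",
                        out1 / "case_alpha" / "dwi.bval")
    assert not np.array_equal(t.signal, r.signal)
    assert (out1 / "study.yaml").exists()
    assert (out1 / "case_beta" / "truth" / "ctv.nii.gz").exists()
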