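"""ePIE updates, runs, position estimation/refinement, redundancy."""

import numpy as np
import pytest

from ptychospa.core import ObjectWave
from ptychospa.epie import (
    EpieConfig,
    align_global_phase,
    complex_correlation,
    data_redundancy,
    epie_run,
    epie_update,
    estimate_positions_xcorr,
)
from ptychospa.forward4d import simulate_dataset, simulate_pattern
from ptychospa.probe_scan import make_probe, scan_grid


@pytest.fixture(scope="module")
def small_instance():
    """Seeded (object window, probe, consistent pattern) triple."""
    probe = make_probe(300.0, 1.5, 1300.0, 64, 0.5)
    rng = np.random.default_rng(7)
    window = np.exp(1j * rng.normal(0, 0.5, (64, 64))) * (1 - 0.05 * rng.random((64, 64)))
    pattern = np.abs(np.fft.fft2(probe.values * window, norm="ortho")) ** 2
    return window, probe.values, pattern


class TestUpdate:
    def test_consistent_triple_is_fixed_point(self, small_instance):
        window, probe, pattern = small_instance
        new_w, new_p, err = epie_update(window, probe, pattern, 1.0, 1.0)
        assert err <= 1e-20
        assert np.abs(new_w - window).max() <= 1e-10
        assert np.abs(new_p - probe).max() <= 1e-10

    def test_zero_betas_are_identity(self, small_instance):
        window, probe, pattern = small_instance
        wrong = np.ones_like(window)
        new_w, new_p, _ = epie_update(wrong, probe, pattern, 0.0, 0.0)
        assert np.array_equal(new_w, wrong)
        assert np.array_equal(new_p, probe)

    def test_update_reduces_fourier_error(self, small_instance):
        window, probe, pattern = small_instance
        rng = np.random.default_rng(1)
        perturbed = window * np.exp(1j * rng.normal(0, 0.2, window.shape))
        _, _, err0 = epie_update(perturbed, probe, pattern, 0.0, 0.0)
        stepped, _, _ = epie_update(perturbed, probe, pattern, 0.5, 0.0)
        _, _, err1 = epie_update(stepped, probe, pattern, 0.0, 0.0)
        assert err1 < err0

    def test_all_zero_probe_rejected(self, small_instance):
        window, _, pattern = small_instance
        with pytest.raises(ZeroDivisionError):
            epie_update(window, np.zeros_like(window), pattern, 1.0, 1.0)


class TestRun:
    def test_vacuum_reconstructs_flat_phase(self, imaging_setup):
        obj, probe, scan = imaging_setup
        vacuum = ObjectWave(np.ones_like(obj.values), obj.pixel_size)
        data = simulate_dataset(vacuum, probe, scan, 0.0)
        res = epie_run(data, probe, EpieConfig(n_iter=15, seed=2), initial_positions=data.positions)
        mask = res.scanned_mask(0.3)
        assert np.sqrt(np.mean(res.object.phase[mask] ** 2)) <= 1e-3

    def test_error_trace_nonincreasing_after_burn_in(self, noiseless_dataset, imaging_setup):
        _, probe, _ = imaging_setup
        res = epie_run(noiseless_dataset, probe, EpieConfig(n_iter=30, seed=1),
                       initial_positions=noiseless_dataset.positions)
        trace = res.error_trace[5:]
        assert np.all(np.diff(trace) <= 0.01 * trace[:-1])

    def test_wrong_initial_defocus_recovered_by_probe_update(self, noiseless_dataset, imaging_setup):
        _, probe, _ = imaging_setup
        good = epie_run(noiseless_dataset, probe, EpieConfig(n_iter=40, seed=1),
                        initial_positions=noiseless_dataset.positions)
        wrong = make_probe(probe.kv, probe.csa_mrad, probe.defocus * 1.2, probe.n, probe.pixel_size)
        res = epie_run(noiseless_dataset, wrong, EpieConfig(n_iter=40, seed=1),
                       initial_positions=noiseless_dataset.positions)
        assert res.error_trace[-1] <= 2.0 * good.error_trace[-1]

    def test_global_phase_gauge_alignment(self):
        rng = np.random.default_rng(0)
        ref = np.exp(1j * rng.normal(0, 0.3, (32, 32)))
        rotated = ref * np.exp(1j * 1.1)
        assert complex_correlation(rotated, ref) == pytest.approx(1.0)
        aligned = align_global_phase(rotated, ref)
        assert np.abs(aligned - ref).max() <= 1e-12


class TestPositionEstimation:
    def test_on_grid_positions_recovered(self, shadow_dataset, shadow_setup):
        *_, step = shadow_setup
        est = estimate_positions_xcorr(shadow_dataset)
        resid = est - shadow_dataset.positions
        rms = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert rms <= 0.25 * step

    def test_pairwise_estimates_are_translation_invariant(self, shadow_dataset):
        import copy

        shifted = copy.deepcopy(shadow_dataset)
        # translating both the data positions and nominal grid in the
        # bookkeeping leaves pairwise shifts untouched; the centroid anchor
        # moves the integrated solution rigidly
        shifted.nominal_positions = shifted.nominal_positions + 5.0
        est0 = estimate_positions_xcorr(shadow_dataset)
        est1 = estimate_positions_xcorr(shifted)
        assert np.allclose(est1 - est0, 5.0, atol=1e-6)

    def test_jitter_residual_beats_injected_jitter(self, shadow_setup):
        obj, probe, _, step = shadow_setup
        scan = scan_grid(15 * step, step, 0.2 * step, seed=7)
        offset = 384 * 0.8 / 2 - 15 * step / 2
        scan.positions += offset
        scan.nominal += offset
        data = simulate_dataset(obj, probe, scan, 0.0)
        est = estimate_positions_xcorr(data)
        jitter = np.sqrt(np.mean(np.sum((data.positions - data.nominal_positions) ** 2, axis=1)))
        resid = np.sqrt(np.mean(np.sum((est - data.positions) ** 2, axis=1)))
        assert resid < jitter

    def test_featureless_data_fall_back_to_nominal(self, shadow_setup):
        obj, probe, scan, _ = shadow_setup
        vacuum = ObjectWave(np.ones_like(obj.values), obj.pixel_size)
        data = simulate_dataset(vacuum, probe, scan, 0.0)
        with pytest.warns(UserWarning, match="nominal"):
            est = estimate_positions_xcorr(data)
        assert np.allclose(est, data.nominal_positions)


class TestPositionRefinement:
    def test_zero_error_corrections_stay_small(self, shadow_dataset, shadow_setup):
        _, probe, _, _ = shadow_setup
        cfg = EpieConfig(n_iter=12, seed=1, position_refine=True)
        res = epie_run(shadow_dataset, probe, cfg, initial_positions=shadow_dataset.positions)
        drift = np.linalg.norm(res.refined_positions - shadow_dataset.positions, axis=1)
        assert np.mean(drift) < 0.05 * shadow_dataset.pixel_size

    def test_corrections_respect_cap(self, shadow_dataset, shadow_setup):
        _, probe, _, _ = shadow_setup
        cap = 0.2
        cfg = EpieConfig(n_iter=7, seed=1, position_refine=True,
                         position_refine_start=5, position_cap_px=cap)
        rng = np.random.default_rng(5)
        init = shadow_dataset.positions + rng.normal(0, 2.0, shadow_dataset.positions.shape)
        res = epie_run(shadow_dataset, probe, cfg, initial_positions=init)
        moved = np.abs(res.refined_positions - init) / shadow_dataset.pixel_size
        n_refine_iters = 3  # iterations 5..7
        assert np.all(moved <= cap * n_refine_iters + 1e-9)


class TestRedundancy:
    def test_hand_computed_toy_ratio(self, noiseless_dataset):
        # 3 patterns of 64 x 64 on a 100 x 100 object with a 64 x 64 probe
        import copy

        toy = copy.deepcopy(noiseless_dataset)
        toy.intensities = toy.intensities[:3]
        toy.positions = toy.positions[:3]
        toy.nominal_positions = toy.nominal_positions[:3]
        measured = 3 * 64 * 64
        unknowns = 2 * 100 * 100 + 2 * 64 * 64
        assert data_redundancy(toy, 100 * 100) == pytest.approx(measured / unknowns)

    def test_doubling_patterns_doubles_ratio(self, noiseless_dataset):
        import copy

        half = copy.deepcopy(noiseless_dataset)
        half.intensities = half.intensities[:128]
        half.positions = half.positions[:128]
        half.nominal_positions = half.nominal_positions[:128]
        assert data_redundancy(noiseless_dataset, 5000) == pytest.approx(
            2 * data_redundancy(half, 5000)
        )

    def test_known_probe_convention(self, noiseless_dataset):
        import copy

        toy = copy.deepcopy(noiseless_dataset)
        toy.intensities = toy.intensities[:1]
        toy.positions = toy.positions[:1]
        toy.nominal_positions = toy.nominal_positions[:1]
        # one pattern, detector grid equal to object grid, known probe
        assert data_redundancy(toy, 64 * 64, probe_pixels=0) == pytest.approx(0.5)
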