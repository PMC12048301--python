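"""Generator physics: calibration, lesion field, simulation, acquisition,
pseudo-ECG."""

import numpy as np
import pytest

from vftrig.core import OpticalMovie
from vftrig.events import detect_beats
from vftrig.synthetic import (
    AcquisitionModel,
    EctopicSpec,
    IonicParams,
    LesionSpec,
    PacingProtocol,
    PreparationConfig,
    TissueGrid,
    build_lesion_field,
    compute_pseudo_ecg,
    generate_episode_set,
    render_fluorescence,
    scaling_for_apd,
    simulate,
    single_cell_apd80,
)

IDEAL_RAMP_SLOPE = 89.0 / 5.6   # |delta APD| / border width, ms/mm


# ---------------------------------------------------------------------------
# Single-cell calibration
# ---------------------------------------------------------------------------


def test_calibration_round_trip():
    """Inverting the calibration curve reproduces the target APD within 3 ms
    for shortenings spanning -120 to -20 ms."""
    ionic = IonicParams()
    base = single_cell_apd80(ionic, 1.0)
    for d_apd in np.linspace(-120.0, -20.0, 10):
        s = float(scaling_for_apd(base + d_apd, ionic))
        realized = single_cell_apd80(ionic, s)
        assert abs(realized - (base + d_apd)) <= 3.0


def test_scaling_rejects_out_of_range():
    with pytest.raises(ValueError, match="calibration range"):
        scaling_for_apd(10.0, IonicParams())


# ---------------------------------------------------------------------------
# Lesion field
# ---------------------------------------------------------------------------


def test_lesion_field_identity_case():
    grid = TissueGrid(n_rows=64, n_cols=64)
    lesion = LesionSpec(
        radius_mm=3.9, border_width_mm=2.0, delta_apd_ms=0.0,
        bg_gradient_ms_per_mm=0.0,
    )
    lf = build_lesion_field(grid, lesion, baseline_apd_ms=270.0)
    np.testing.assert_allclose(lf.s_field, 1.0)
    np.testing.assert_allclose(lf.target_apd_map_ms, 270.0)


def test_lesion_field_ideal_ramp_slope():
    """The analytic target map's maximal border slope is |dAPD| / w_b."""
    grid = TissueGrid()
    lf = build_lesion_field(grid, LesionSpec(bg_gradient_ms_per_mm=0.0))
    gy, gx = np.gradient(lf.target_apd_map_ms, grid.dx_mm)
    slope = np.hypot(gy, gx).max()
    assert slope == pytest.approx(IDEAL_RAMP_SLOPE, rel=0.05)


def test_lesion_must_fit_in_grid():
    grid = TissueGrid(n_rows=48, n_cols=48)
    with pytest.raises(ValueError, match="fit"):
        build_lesion_field(grid, LesionSpec(radius_mm=9.0, border_width_mm=5.6))


# ---------------------------------------------------------------------------
# Tissue simulation
# ---------------------------------------------------------------------------


def test_equilibrium_without_stimulation():
    grid = TissueGrid(n_rows=32, n_cols=32)
    res = simulate(
        grid, IonicParams(), PacingProtocol(mode="none", n_beats=0),
        duration_ms=300.0, seed=0,
    )
    assert np.abs(res.voltage.frames).max() < 1e-9


def test_planar_wave_isochrones_monotone(paced_sim48):
    """A single paced beat produces activation times increasing with
    distance from the stimulus site."""
    grid, res = paced_sim48
    at = res.truth.true_at_ms[0]
    assert np.isfinite(at).all()
    rows, cols = np.indices(at.shape)
    dist = np.hypot(rows - 24, cols - 4) * grid.dx_mm
    order = np.argsort(dist.ravel())
    binned = at.ravel()[order].reshape(-1, 48).mean(axis=1)
    assert (np.diff(binned) > -0.5).all()
    r = np.corrcoef(dist.ravel(), at.ravel())[0, 1]
    assert r > 0.97


def test_unstable_timestep_rejected():
    grid = TissueGrid(n_rows=32, n_cols=32, diffusion_mm2_ms=0.3)
    with pytest.raises(ValueError, match="stability"):
        simulate(
            grid, IonicParams(), PacingProtocol(n_beats=1),
            duration_ms=100.0, dt_ms=0.2,
        )


def test_refractory_stimulus_fails_capture():
    """An ectopic delivered well before local repolarization cannot capture."""
    grid = TissueGrid(n_rows=48, n_cols=48)
    ect = EctopicSpec(
        site_px=(24, 24), stim_time_ms=520.0 + 150.0,  # ~150 ms after last beat
        max_refractory_retries=0,
    )
    res = simulate(
        grid, IonicParams(), PacingProtocol(n_beats=2, site_px=(24, 4)),
        ectopic=ect, duration_ms=1400.0, seed=0,
    )
    assert res.truth.capture_failure
    assert res.truth.trigger_stim_ms is None


def test_timestep_convergence():
    """Halving dt changes per-pixel activation times by < 0.5 ms."""
    grid = TissueGrid(n_rows=48, n_cols=48)
    ats = []
    for dt in (0.05, 0.025):
        res = simulate(
            grid, IonicParams(), PacingProtocol(n_beats=3, cycle_length_ms=400.0),
            duration_ms=1600.0, seed=0, dt_ms=dt,
        )
        ats.append(res.truth.true_at_ms[-1])
    assert np.nanmax(np.abs(ats[0] - ats[1])) < 0.5


def test_seed_determinism(tmp_path):
    cfg = PreparationConfig(
        grid=TissueGrid(n_rows=48, n_cols=48),
        lesion=LesionSpec(radius_mm=2.9, border_width_mm=2.4),
        pacing=PacingProtocol(n_beats=2, site_px=(24, 4)),
        ectopic=EctopicSpec(coupling_sd_ms=30.0),
        duration_ms=1800.0,
    )
    m1 = generate_episode_set(cfg, 1, seed=11, out_dir=tmp_path / "a")
    m2 = generate_episode_set(cfg, 1, seed=11, out_dir=tmp_path / "b")
    h1 = list(m1["preparations"][0]["files"].values())
    h2 = list(m2["preparations"][0]["files"].values())
    assert h1 == h2  # byte-identical artifacts under the same seed


# ---------------------------------------------------------------------------
# Fluorescence acquisition
# ---------------------------------------------------------------------------


def test_render_identity_without_degradation(sim96, clean_movie):
    v = sim96.voltage.frames
    lo, hi = v[:1000].min(), v[:1000].max()
    expect = (v - lo) / (hi - lo)
    np.testing.assert_allclose(clean_movie.frames, expect, atol=1e-5)


def test_rundown_halves_amplitude():
    t = np.arange(61000)[:, None, None] / 1000.0  # 61 s at 1 kHz
    frames = (np.sin(2 * np.pi * t) > 0).astype(np.float32) * np.ones((1, 4, 4))
    movie = OpticalMovie(frames=frames, dx_mm=1.0, frame_interval_ms=1.0)
    acq = AcquisitionModel(blur_sigma_px=0.0, noise_sd=0.0, rundown_per_min=0.5,
                           dead_pixel_fraction=0.0)
    out = render_fluorescence(movie, acq, seed=0)
    early = out.frames[:2000].max()
    late = out.frames[59500:60500].max()
    assert late == pytest.approx(0.5 * early, rel=0.02)


def test_noise_level_recovered(sim96):
    """Diastolic noise on rendered traces matches the configured sd within 20%."""
    acq = AcquisitionModel(blur_sigma_px=0.0, noise_sd=0.05,
                           rundown_per_min=0.0, dead_pixel_fraction=0.0)
    out = render_fluorescence(sim96.voltage, acq, seed=3)
    # diastole before the first beat
    seg = out.frames[:15]
    est = np.median(np.std(seg, axis=0))
    assert est == pytest.approx(0.05, rel=0.2)


# ---------------------------------------------------------------------------
# Pseudo-ECG forward model
# ---------------------------------------------------------------------------


def test_pseudo_ecg_zero_for_uniform_voltage():
    grid = TissueGrid(n_rows=32, n_cols=32)
    frames = np.ones((50, 32, 32), np.float32) * 0.7
    ecg = compute_pseudo_ecg(frames, grid)
    np.testing.assert_allclose(ecg.amplitude, 0.0, atol=1e-12)


def test_pseudo_ecg_polarity_reverses_with_mirrored_electrode(paced_sim48):
    """While a planar wavefront crosses mid-tissue, electrodes mirrored
    across the front see opposite polarities (the front is a dipole sheet:
    positive ahead, negative behind)."""
    grid, res = paced_sim48
    h, w = grid.extent_mm
    e1 = compute_pseudo_ecg(res.voltage.frames, grid, electrode_mm=(h / 2, w * 0.25, 15.0))
    e2 = compute_pseudo_ecg(res.voltage.frames, grid, electrode_mm=(h / 2, w * 0.75, 15.0))
    t_mid = int(round(res.truth.true_at_ms[0][24, 24]))   # front under the midline
    a1, a2 = e1.amplitude[t_mid], e2.amplitude[t_mid]
    assert abs(a1) > 0 and abs(a2) > 0
    assert np.sign(a1) == -np.sign(a2)


def test_pseudo_ecg_electrode_on_pixel_rejected():
    grid = TissueGrid(n_rows=32, n_cols=32)
    frames = np.zeros((10, 32, 32), np.float32)
    with pytest.raises(ValueError, match="electrode"):
        compute_pseudo_ecg(frames, grid, electrode_mm=(5.0, 5.0, 0.0))


def test_paced_rhythm_qrs_spacing():
    """Detected QRS deflections of a paced rhythm are spaced one cycle apart."""
    grid = TissueGrid(n_rows=64, n_cols=64)
    res = simulate(
        grid, IonicParams(), PacingProtocol(n_beats=5, site_px=(32, 4)),
        duration_ms=2800.0, seed=0,
    )
    beats = detect_beats(res.ecg)
    assert len(beats) == 5
    iv = np.diff([b.onset_ms for b in beats])
    # the first beat rises from full rest and has a slightly different
    # complex morphology; steady-state cycles are spaced to within a sample
    np.testing.assert_allclose(iv[1:], 500.0, atol=1.0)
    np.testing.assert_allclose(iv[0], 500.0, atol=2.5)
    assert all(b.kind == "paced" for b in beats)


def test_coupling_recovery_on_adjusted_episode(sim96):
    """The event stage recovers the commanded 350-ms coupling within 2 ms
    on the generator-adjusted noiseless episode."""
    from vftrig.events import classify_pvc

    beats = classify_pvc(detect_beats(sim96.ecg))
    pvcs = [b for b in beats if b.kind == "pvc" and b.coupling_ms is not None]
    assert len(pvcs) >= 1   # the trigger; a reentrant echo may follow
    assert abs(pvcs[0].coupling_ms - 350.0) <= 2.0
    assert abs(sim96.truth.coupling_realized_ms - pvcs[0].coupling_ms) <= 1e-6
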