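"""Phase mapping, singularity detection/tracking, trigger localization."""

import numpy as np
import pytest

from vftrig.core import OpticalMovie
from vftrig.maps import BeatWindow
from vftrig.phase import (
    PhaseMovie,
    classify_first_cycles,
    compute_phase,
    detect_singularities,
    localize_trigger,
    track_singularities,
)


def spiral_phase(n=48, charge=1, center=None):
    center = center or ((n - 1) / 2.0, (n - 1) / 2.0)
    rows, cols = np.indices((n, n))
    return np.angle(
        np.exp(1j * charge * np.arctan2(cols - center[1], rows - center[0]))
    )


def brute_force_windings(phase):
    """Independent per-plaquette loop-integral winding numbers."""
    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    nr, nc = phase.shape
    out = np.zeros((nr - 1, nc - 1), int)
    for i in range(nr - 1):
        for j in range(nc - 1):
            s = (
                wrap(phase[i + 1, j] - phase[i, j])
                + wrap(phase[i + 1, j + 1] - phase[i + 1, j])
                + wrap(phase[i, j + 1] - phase[i + 1, j + 1])
                + wrap(phase[i, j] - phase[i, j + 1])
            )
            out[i, j] = int(round(s / (2 * np.pi)))
    return out


# ---------------------------------------------------------------------------
# Phase computation
# ---------------------------------------------------------------------------


def test_sinusoid_phase_advances_linearly():
    f = 4.0  # Hz
    t = np.arange(0.0, 2000.0)  # ms
    x = np.cos(2 * np.pi * f * t / 1000.0)
    frames = np.tile(x[:, None, None], (1, 4, 4)).astype(np.float32)
    movie = OpticalMovie(frames=frames, dx_mm=1.0, frame_interval_ms=1.0)
    pm = compute_phase(movie)
    ph = np.unwrap(pm.phase[200:-200, 2, 2].astype(float))
    slope = np.polyfit(t[200:-200], ph, 1)[0]  # rad/ms
    assert slope == pytest.approx(2 * np.pi * f / 1000.0, rel=0.02)


def test_phase_antisymmetry_under_negation():
    t = np.arange(0.0, 1500.0)
    x = np.cos(2 * np.pi * 3.0 * t / 1000.0) + 0.2 * np.cos(2 * np.pi * 6.0 * t / 1000.0)
    frames = np.tile(x[:, None, None], (1, 3, 3)).astype(np.float32)
    m1 = OpticalMovie(frames=frames, dx_mm=1.0, frame_interval_ms=1.0)
    m2 = OpticalMovie(frames=-frames, dx_mm=1.0, frame_interval_ms=1.0)
    p1 = compute_phase(m1).phase[300:-300, 1, 1].astype(float)
    p2 = compute_phase(m2).phase[300:-300, 1, 1].astype(float)
    d = np.angle(np.exp(1j * (p2 - p1 - np.pi)))
    assert np.abs(d).max() < 1e-5


def test_window_too_short_rejected():
    frames = np.zeros((50, 4, 4), np.float32)
    movie = OpticalMovie(frames=frames, dx_mm=1.0, frame_interval_ms=1.0)
    with pytest.raises(ValueError, match="window"):
        compute_phase(movie, window_ms=(0.0, 40.0))


def test_phase_times_activation_consistently(sim96, clean_movie):
    """The instantaneous phase at the moment of activation is the same
    (narrowly dispersed) iso-phase at every pixel: crossing that iso-phase
    dates activation to within 5 ms of the map-stage AT."""
    from vftrig.maps import build_maps

    t0, t1 = sim96.truth.beat_windows_ms[1]
    at = build_maps(clean_movie, [BeatWindow(index=1, start_ms=t0, end_ms=t1)])[1]["AT"]
    pm = compute_phase(clean_movie, window_ms=(t0 - 200.0, t1 + 300.0), detrend_ms=500.0)
    rng = np.random.default_rng(0)
    pixels = [
        (r, c) for r, c in rng.integers(10, 86, size=(80, 2)) if at.valid[r, c]
    ]
    assert len(pixels) > 40
    phase_at_at = np.array(
        [pm.phase[pm.frame_index(at.values[r, c]), r, c] for r, c in pixels]
    )
    ref = float(np.median(phase_at_at))
    errs = []
    for (r, c), ph0 in zip(pixels, phase_at_at):
        k = pm.frame_index(at.values[r, c])
        seg = pm.phase[max(0, k - 15): k + 16, r, c].astype(float)
        below = seg < ref
        cross = np.nonzero(below[:-1] & ~below[1:] & (np.diff(seg) < np.pi))[0]
        if len(cross):
            t_axis = pm.t0_ms + (max(0, k - 15) + cross) * pm.frame_interval_ms
            errs.append(np.min(np.abs(t_axis - at.values[r, c])))
    assert len(errs) > 0.9 * len(pixels)
    errs = np.array(errs)
    assert (errs <= 5.0).mean() >= 0.9


# ---------------------------------------------------------------------------
# Singularities
# ---------------------------------------------------------------------------


def test_spiral_has_single_positive_singularity():
    ph = spiral_phase(charge=1)
    sings = detect_singularities(ph)
    assert len(sings) == 1
    s = sings[0]
    assert s.charge == 1
    assert np.hypot(s.position_px[0] - 23.5, s.position_px[1] - 23.5) <= 1.0


def test_mirrored_spiral_has_negative_charge():
    sings = detect_singularities(spiral_phase(charge=-1))
    assert len(sings) == 1 and sings[0].charge == -1


def test_planar_wave_has_no_singularity():
    rows = np.indices((40, 40))[0].astype(float)
    ph = np.angle(np.exp(1j * rows * 0.5))
    assert detect_singularities(ph) == []


def test_winding_matches_brute_force_on_random_fields():
    """Vectorized detector equals the loop-integral oracle, and total charge
    equals the boundary winding (topological identity)."""
    rng = np.random.default_rng(7)
    from scipy.ndimage import gaussian_filter

    for trial in range(40):
        z = gaussian_filter(rng.normal(size=(24, 24)), 2.0) + 1j * gaussian_filter(
            rng.normal(size=(24, 24)), 2.0
        )
        ph = np.angle(z)
        oracle = brute_force_windings(ph)
        sings = detect_singularities(ph)
        got = np.zeros_like(oracle)
        for s in sings:
            got[int(s.position_px[0] - 0.5), int(s.position_px[1] - 0.5)] = s.charge
        np.testing.assert_array_equal(got, oracle)
        # total charge equals the winding along the outer boundary
        def wrap(a):
            return (a + np.pi) % (2 * np.pi) - np.pi

        b = np.concatenate(
            [ph[0, :-1], ph[:-1, -1], ph[-1, ::-1][:-1], ph[::-1, 0][:-1]]
        )[::-1]
        boundary_winding = int(round(np.sum(wrap(np.diff(np.append(b, b[0])))) / (2 * np.pi)))
        assert int(oracle.sum()) == boundary_winding


def test_tracking_links_drifting_singularity():
    frames = []
    for k in range(20):
        frames.append(detect_singularities(spiral_phase(center=(20.0 + 0.8 * k, 24.0)), frame=k))
    tracks = track_singularities(frames, gate_px=3.0)
    assert len(tracks) == 1
    assert tracks[0].lifetime_frames == 20


# ---------------------------------------------------------------------------
# Trigger localization
# ---------------------------------------------------------------------------


def test_trigger_origin_within_two_pixels(sim96, clean_movie):
    truth = sim96.truth
    t0, t1 = truth.beat_windows_ms[-1]
    w = BeatWindow(index=9, start_ms=t0, end_ms=t1, label="ectopic")
    origin = localize_trigger(clean_movie, w)
    err = np.hypot(
        origin.site_px[0] - truth.trigger_site_px[0],
        origin.site_px[1] - truth.trigger_site_px[1],
    )
    assert err <= 2.0


def test_paced_beat_origin_at_pacing_site(paced_sim48):
    grid, res = paced_sim48
    t0, t1 = res.truth.beat_windows_ms[0]
    movie = res.voltage
    origin = localize_trigger(movie, BeatWindow(index=0, start_ms=t0, end_ms=t1))
    err = np.hypot(origin.site_px[0] - 24, origin.site_px[1] - 4)
    assert err <= 3.0


# ---------------------------------------------------------------------------
# First-cycle classification on constructed activity
# ---------------------------------------------------------------------------


def _constant_valid(n):
    return np.ones((n, n), bool)


def test_focal_source_is_breakthrough():
    """Expanding target waves carry no singularity: every cycle is focal."""
    n, n_t, cl = 40, 600, 150.0
    rows, cols = np.indices((n, n))
    r = np.hypot(rows - 20, cols - 20)
    t = np.arange(n_t)[:, None, None]
    ph = np.angle(np.exp(1j * (2 * np.pi * (t / cl) - 0.4 * r[None])))
    pm = PhaseMovie(phase=ph.astype(np.float32), valid=_constant_valid(n),
                    frame_interval_ms=1.0)
    per_frame = [detect_singularities(pm, f) for f in range(n_t)]
    tracks = track_singularities(per_frame)
    bounds = list(np.arange(0.0, 601.0, cl))
    labels = classify_first_cycles(pm, tracks, (20, 20), bounds, n_cycles=4)
    assert labels == ["breakthrough"] * 4


def test_anchored_spiral_is_rotor():
    n, n_t, cl = 40, 600, 150.0
    rows, cols = np.indices((n, n))
    theta = np.arctan2(cols - 20, rows - 20)
    r = np.hypot(rows - 20, cols - 20)
    t = np.arange(n_t)[:, None, None]
    ph = np.angle(np.exp(1j * (theta[None] - 0.35 * r[None] + 2 * np.pi * t / cl)))
    pm = PhaseMovie(phase=ph.astype(np.float32), valid=_constant_valid(n),
                    frame_interval_ms=1.0)
    per_frame = [detect_singularities(pm, f) for f in range(n_t)]
    tracks = track_singularities(per_frame)
    bounds = list(np.arange(0.0, 601.0, cl))
    labels = classify_first_cycles(pm, tracks, (20, 20), bounds, n_cycles=4)
    assert labels == ["rotor"] * 4


def test_truncated_sequence_warns():
    pm = PhaseMovie(phase=np.zeros((10, 8, 8), np.float32),
                    valid=_constant_valid(8), frame_interval_ms=1.0)
    with pytest.warns(UserWarning, match="truncated"):
        labels = classify_first_cycles(pm, [], (4, 4), [0.0, 5.0], n_cycles=5)
    assert len(labels) == 1
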