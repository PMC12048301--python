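"""Phase mapping, phase-singularity detection, and VF-onset analysis.

Instantaneous phase comes from the analytic signal (Hilbert transform) of
the mean-subtracted conditioned trace.  Phase singularities are found as
2x2 plaquettes whose wrapped phase winding is +-2*pi; they are linked into
tracks by nearest-neighbor association.  The trigger beat's tissue origin
is the centroid of the earliest-activated percentile of its activation
map, and each early VF cycle is classed as a focal breakthrough or a rotor
depending on whether a singularity track persists for a full rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .core import OpticalMovie, ScalarMap
from .maps import BeatWindow, MapParams, build_maps


@dataclass
class PhaseMovie:
    phase: np.ndarray               # (time, rows, cols), wrapped to (-pi, pi]
    valid: np.ndarray               # (rows, cols)
    frame_interval_ms: float
    t0_ms: float = 0.0
    dx_mm: float = 1.0

    def frame_index(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0_ms) / self.frame_interval_ms))


@dataclass
class Singularity:
    position_px: tuple              # subpixel (row, col)
    frame: int
    charge: int                     # +1 | -1
    track_id: int | None = None


@dataclass
class SingularityTrack:
    track_id: int
    charge: int
    frames: list = field(default_factory=list)
    positions: list = field(default_factory=list)

    @property
    def lifetime_frames(self) -> int:
        return self.frames[-1] - self.frames[0] + 1


@dataclass
class TriggerOrigin:
    site_px: tuple
    time_ms: float
    at_map: ScalarMap


@dataclass
class TriggerReport:
    episode_id: str
    origin_site_px: tuple
    origin_time_ms: float
    distance_to_border_mm: float
    border_zone: bool
    apd_gradient_ms_mm: float
    rt_gradient_ms_mm: float
    pattern_sequence: list

    def to_dict(self) -> dict:
        return {
            "episode_id": self.episode_id,
            "origin_site_px": list(map(float, self.origin_site_px)),
            "origin_time_ms": float(self.origin_time_ms),
            "distance_to_border_mm": float(self.distance_to_border_mm),
            "border_zone": bool(self.border_zone),
            "apd_gradient_ms_mm": float(self.apd_gradient_ms_mm),
            "rt_gradient_ms_mm": float(self.rt_gradient_ms_mm),
            "pattern_sequence": list(self.pattern_sequence),
        }


# ---------------------------------------------------------------------------
# Phase computation
# ---------------------------------------------------------------------------


def compute_phase(
    movie: OpticalMovie,
    window_ms: tuple | None = None,
    valid: np.ndarray | None = None,
    detrend_ms: float = 400.0,
    min_window_ms: float = 300.0,
    smooth_sigma_px: float = 1.0,
) -> PhaseMovie:
    """Instantaneous phase of every pixel over the analysis window.

    The trace is high-passed by subtracting a moving mean (``detrend_ms``,
    roughly one cycle of the activity of interest) before the Hilbert
    transform, so phase progresses through a full cycle per activation.
    The analytic signal is spatially smoothed (``smooth_sigma_px``) before
    taking the angle; without it, acquisition noise seeds large numbers of
    spurious short-lived singularity pairs.
    """
    t = movie.times_ms
    if window_ms is None:
        i0, i1 = 0, movie.n_frames
    else:
        i0 = max(0, movie.frame_index(window_ms[0]))
        i1 = min(movie.n_frames, movie.frame_index(window_ms[1]))
    if (i1 - i0) * movie.frame_interval_ms < min_window_ms:
        raise ValueError(
            f"analysis window shorter than {min_window_ms} ms; "
            "need >= 2 cycles of activity"
        )
    x = movie.frames[i0:i1].astype(np.float64)
    k = max(2, int(round(detrend_ms / movie.frame_interval_ms)))
    x = x - uniform_filter1d(x, k, axis=0, mode="nearest")
    analytic = hilbert(x, axis=0)
    if smooth_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        analytic = (
            gaussian_filter(analytic.real, (0, smooth_sigma_px, smooth_sigma_px))
            + 1j * gaussian_filter(analytic.imag, (0, smooth_sigma_px, smooth_sigma_px))
        )
    ph = np.angle(analytic).astype(np.float32)
    if valid is None:
        valid = np.ones(movie.shape, bool)
    ph[:, ~valid] = np.nan
    return PhaseMovie(
        phase=ph, valid=valid.copy(),
        frame_interval_ms=movie.frame_interval_ms,
        t0_ms=movie.t0_ms + i0 * movie.frame_interval_ms,
        dx_mm=movie.dx_mm,
    )


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * a))


# ---------------------------------------------------------------------------
# Singularity detection and tracking
# ---------------------------------------------------------------------------


def detect_singularities(
    phase: PhaseMovie | np.ndarray, frame: int = 0, valid: np.ndarray | None = None
) -> list[Singularity]:
    """Phase singularities in one frame by the plaquette winding number.

    For every 2x2 plaquette of valid pixels the wrapped phase differences
    are summed counterclockwise; a total of +-2*pi marks a singularity of
    that topological charge at the plaquette center.  Nearby opposite
    charges are both retained (figure-of-8 patterns).
    """
    if isinstance(phase, PhaseMovie):
        ph = phase.phase[frame]
        valid = phase.valid if valid is None else valid
    else:
        ph = np.asarray(phase)
        if valid is None:
            valid = np.isfinite(ph)
    p00 = ph[:-1, :-1]
    p01 = ph[:-1, 1:]
    p11 = ph[1:, 1:]
    p10 = ph[1:, :-1]
    # counterclockwise loop in (row, col) with row increasing downward:
    # (0,0) -> (1,0) -> (1,1) -> (0,1) -> (0,0)
    w = (
        _wrap(p10 - p00)
        + _wrap(p11 - p10)
        + _wrap(p01 - p11)
        + _wrap(p00 - p01)
    )
    ok = (
        valid[:-1, :-1] & valid[:-1, 1:] & valid[1:, 1:] & valid[1:, :-1]
        & np.isfinite(w)
    )
    winding = np.zeros_like(w)
    winding[ok] = np.round(w[ok] / (2 * np.pi))
    out = []
    for r, c in zip(*np.nonzero(np.abs(winding) == 1)):
        out.append(
            Singularity(
                position_px=(r + 0.5, c + 0.5),
                frame=frame,
                charge=int(winding[r, c]),
            )
        )
    return out


def track_singularities(
    per_frame: list[list[Singularity]], gate_px: float = 3.0
) -> list[SingularityTrack]:
    """Link per-frame singularities into tracks by nearest-neighbor
    association (same charge, displacement <= ``gate_px`` per frame)."""
    tracks: list[SingularityTrack] = []
    open_tracks: list[SingularityTrack] = []
    next_id = 0
    for frame_idx, sings in enumerate(per_frame):
        unmatched = list(sings)
        still_open = []
        for tr in open_tracks:
            if frame_idx - tr.frames[-1] > 1:
                tracks.append(tr)
                continue
            best, best_d = None, gate_px
            for s in unmatched:
                if s.charge != tr.charge:
                    continue
                d = np.hypot(
                    s.position_px[0] - tr.positions[-1][0],
                    s.position_px[1] - tr.positions[-1][1],
                )
                if d <= best_d:
                    best, best_d = s, d
            if best is not None:
                unmatched.remove(best)
                best.track_id = tr.track_id
                tr.frames.append(frame_idx)
                tr.positions.append(best.position_px)
                still_open.append(tr)
            else:
                tracks.append(tr)
        for s in unmatched:
            tr = SingularityTrack(
                track_id=next_id, charge=s.charge,
                frames=[frame_idx], positions=[s.position_px],
            )
            s.track_id = next_id
            next_id += 1
            still_open.append(tr)
        open_tracks = still_open
    tracks.extend(open_tracks)
    return sorted(tracks, key=lambda t: t.frames[0])


# ---------------------------------------------------------------------------
# Trigger localization
# ---------------------------------------------------------------------------


def localize_trigger(
    movie: OpticalMovie,
    trigger_window: BeatWindow,
    params: MapParams | None = None,
    percentile: float = 1.0,
    conditioned: np.ndarray | None = None,
) -> TriggerOrigin:
    """Tissue origin of the trigger beat.

    The per-pixel activation map of the trigger beat is computed and the
    origin is the centroid of the earliest-activated ``percentile`` of
    valid pixels; the origin time is the minimum activation time.
    """
    maps = build_maps(movie, [trigger_window], params, conditioned=conditioned)
    at = maps[trigger_window.index]["AT"]
    vals = at.values[at.valid]
    if not len(vals):
        raise ValueError("origin not mappable: trigger beat has no valid pixels")
    cut = np.percentile(vals, percentile)
    early = at.valid & (at.values <= cut)
    rr, cc = np.nonzero(early)
    site = (float(rr.mean()), float(cc.mean()))
    return TriggerOrigin(site_px=site, time_ms=float(np.nanmin(vals)), at_map=at)


# ---------------------------------------------------------------------------
# Early-cycle classification
# ---------------------------------------------------------------------------


def classify_first_cycles(
    phase: PhaseMovie,
    tracks: list[SingularityTrack],
    origin_px: tuple,
    cycle_bounds_ms: list,
    n_cycles: int = 5,
    rotor_radius_px: float = 10.0,
) -> list[str]:
    """Label each of the first post-trigger cycles "rotor" or "breakthrough".

    A cycle is a rotor when some singularity track overlapping it persists
    for at least one full rotation (one cycle length); otherwise the new
    activation is a focal breakthrough.  With fewer than ``n_cycles``
    available the sequence is truncated with a warning.
    """
    if len(cycle_bounds_ms) - 1 < n_cycles:
        warnings.warn(
            f"only {len(cycle_bounds_ms) - 1} cycles available; "
            f"sequence truncated"
        )
    labels = []
    for k in range(min(n_cycles, len(cycle_bounds_ms) - 1)):
        t0, t1 = cycle_bounds_ms[k], cycle_bounds_ms[k + 1]
        f0, f1 = phase.frame_index(t0), phase.frame_index(t1)
        cyc_frames = max(1, f1 - f0)
        rotor = False
        for tr in tracks:
            overlap = min(tr.frames[-1], f1) - max(tr.frames[0], f0)
            if overlap > 0 and tr.lifetime_frames >= cyc_frames:
                rotor = True
                break
        labels.append("rotor" if rotor else "breakthrough")
    return labels


def cycle_bounds_from_activity(
    movie: OpticalMovie,
    origin_px: tuple,
    start_ms: float,
    max_cycles: int = 6,
    min_cycle_ms: float = 80.0,
) -> list:
    """Successive activation times at the origin pixel after ``start_ms``,
    used as cycle boundaries for early-VF classification."""
    r, c = int(round(origin_px[0])), int(round(origin_px[1]))
    tr = movie.frames[:, r, c].astype(float)
    t = movie.times_ms
    i0 = max(0, movie.frame_index(start_ms))
    x = tr - uniform_filter1d(tr, 300, mode="nearest")
    d = np.gradient(x)
    bounds = []
    i = i0
    lockout = int(min_cycle_ms / movie.frame_interval_ms)
    thr = 0.25 * d[i0:].max() if len(d[i0:]) else 0
    while len(bounds) < max_cycles + 1 and i < len(t) - 2:
        if d[i] >= thr and (not bounds or i - movie.frame_index(bounds[-1]) >= lockout):
            bounds.append(float(t[i]))
            i += lockout
        else:
            i += 1
    return bounds
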