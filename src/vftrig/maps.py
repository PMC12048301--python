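"""Optical-signal conditioning and AT / APD80 / RT map extraction.

Per-pixel fluorescence traces are conditioned (baseline-drift removal,
polarity correction, per-beat amplitude normalization), activation times are
taken at the maximum upstroke derivative (a 50%-amplitude crossing is
available as an alternative), APD80 is the interval from activation to the
fall to 20% of the beat amplitude above diastolic baseline, and RT = AT +
APD80 pixel-wise.  Pixels failing the signal-to-noise gate or lacking a
measurable upstroke/recovery are masked — the analogue of the "noisy"
pixels excluded from experimental APD maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import savgol_filter

from .core import OpticalMovie, ScalarMap


@dataclass(frozen=True)
class BeatWindow:
    """Half-open analysis window [start, end) for one beat."""

    index: int
    start_ms: float
    end_ms: float
    label: str = "paced"        # "paced" | "intrinsic" | "ectopic"

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("beat window must have positive length")


def windows_from_beats(beats, movie: OpticalMovie, margin_ms: float = 30.0):
    """Non-overlapping beat windows from detected ECG beat onsets."""
    out = []
    onsets = [b.onset_ms for b in beats]
    for k, b in enumerate(beats):
        start = max(movie.t0_ms, b.onset_ms - margin_ms)
        end = onsets[k + 1] - 10.0 if k + 1 < len(onsets) else movie.times_ms[-1]
        label = "ectopic" if b.kind == "pvc" else b.kind
        if end > start + 50.0:
            out.append(BeatWindow(index=k, start_ms=start, end_ms=end, label=label))
    return out


@dataclass(frozen=True)
class MapParams:
    """Tunables for conditioning and map extraction."""

    baseline_window_ms: float = 700.0     # sliding-minimum window for drift removal
    baseline_smooth_ms: float = 80.0
    sg_window_ms: float = 7.0             # Savitzky-Golay length; 0 disables
    sg_order: int = 3
    snr_min: float = 5.0                  # beat amplitude / diastolic noise sd
    amp_min_frac: float = 0.25            # of the median beat amplitude; rejects
                                          # noise-only (dead) pixels, whose SNR
                                          # alone sits near the gate by construction
    at_method: str = "max_derivative"     # or "upstroke_50"
    apd_level: float = 0.8
    pre_upstroke_ms: float = 40.0         # baseline segment before the upstroke
    peak_search_ms: float = 150.0
    repol_lookahead_ms: float = 420.0     # repolarization may outlast the window
    max_apd_ms: float = 420.0             # guards against re-excited pixels
    min_amplitude: float = 1e-3


# ---------------------------------------------------------------------------
# Trace conditioning
# ---------------------------------------------------------------------------


def condition_trace(
    trace: np.ndarray,
    frame_interval_ms: float,
    params: MapParams | None = None,
) -> tuple[np.ndarray, bool]:
    """Remove baseline drift, fix polarity, smooth; returns (trace, usable).

    An all-constant trace is flagged unusable rather than raising.
    """
    params = params or MapParams()
    x = np.asarray(trace, dtype=float)
    if np.ptp(x) < params.min_amplitude:
        return np.zeros_like(x), False
    k = max(2, int(round(params.baseline_window_ms / frame_interval_ms)))
    baseline = minimum_filter1d(x, size=k, mode="nearest")
    baseline = uniform_filter1d(
        baseline, max(1, int(round(params.baseline_smooth_ms / frame_interval_ms))),
        mode="nearest",
    )
    y = x - baseline
    y = _fix_polarity(y, frame_interval_ms)
    y = _smooth(y, frame_interval_ms, params)
    return y, True


def _fix_polarity(y: np.ndarray, dt: float) -> np.ndarray:
    d = np.diff(y)
    if len(d) and np.abs(d.min()) > np.abs(d.max()):
        y = -(y - y.max())
    return y


def _smooth(y: np.ndarray, dt: float, params: MapParams) -> np.ndarray:
    if params.sg_window_ms <= 0:
        return y
    win = int(round(params.sg_window_ms / dt)) | 1   # odd
    if win <= params.sg_order + 1 or win >= len(y):
        return y
    return savgol_filter(y, win, params.sg_order)


# ---------------------------------------------------------------------------
# Per-trace measurements
# ---------------------------------------------------------------------------


def detect_activation(
    trace: np.ndarray,
    window: BeatWindow,
    frame_interval_ms: float,
    t0_ms: float = 0.0,
    params: MapParams | None = None,
) -> float | None:
    """Activation time within the window, or None when no upstroke is found.

    ``max_derivative``: time of the largest positive temporal derivative,
    refined by parabolic interpolation.  ``upstroke_50``: linear-interpolated
    crossing of 50% of the beat amplitude.
    """
    params = params or MapParams()
    i0 = max(0, int(round((window.start_ms - t0_ms) / frame_interval_ms)))
    i1 = min(len(trace), int(round((window.end_ms - t0_ms) / frame_interval_ms)))
    if i1 - i0 < 5:
        return None
    seg = np.asarray(trace[i0:i1], dtype=float)
    base = np.percentile(seg, 10)
    amp = seg.max() - base
    if amp < params.min_amplitude:
        return None
    if params.at_method == "upstroke_50":
        half = base + 0.5 * amp
        above = seg >= half
        j = int(np.argmax(above))
        if j == 0 or not above.any():
            return None
        f = (half - seg[j - 1]) / (seg[j] - seg[j - 1])
        return t0_ms + (i0 + j - 1 + f) * frame_interval_ms
    d = np.gradient(seg, frame_interval_ms)
    j = int(np.argmax(d))
    if d[j] <= 0 or j < 3:
        return None
    j_pre = max(j - max(1, int(round(8.0 / frame_interval_ms))), 0)
    if seg[j_pre] >= base + 0.4 * amp:
        return None   # already elevated: previous beat's plateau, not an upstroke
    off = 0.0
    if 0 < j < len(d) - 1:
        denom = d[j - 1] - 2 * d[j] + d[j + 1]
        if denom != 0:
            off = float(np.clip(0.5 * (d[j - 1] - d[j + 1]) / denom, -0.5, 0.5))
    return t0_ms + (i0 + j + off) * frame_interval_ms


def measure_apd(
    trace: np.ndarray,
    at_ms: float,
    frame_interval_ms: float,
    t0_ms: float = 0.0,
    level: float = 0.8,
    params: MapParams | None = None,
) -> float | None:
    """APD at the given repolarization level (0.8 -> APD80), or None.

    The AP peak is sought within ``peak_search_ms`` after activation; the
    measurement is the linear-interpolated crossing of
    ``baseline + (1 - level) * amplitude`` after the peak, minus AT.
    """
    params = params or MapParams()
    x = np.asarray(trace, dtype=float)
    i_at = int(round((at_ms - t0_ms) / frame_interval_ms))
    if not (0 <= i_at < len(x) - 3):
        return None
    i_pre0 = max(0, i_at - int(round(params.pre_upstroke_ms / frame_interval_ms)))
    base = float(np.median(x[i_pre0:i_at])) if i_at > i_pre0 else float(x[i_at])
    i_pk1 = min(len(x), i_at + int(round(params.peak_search_ms / frame_interval_ms)))
    seg_pk = x[i_at:i_pk1]
    if not len(seg_pk):
        return None
    i_peak = i_at + int(np.argmax(seg_pk))
    amp = x[i_peak] - base
    if amp < params.min_amplitude:
        return None
    thr = base + (1.0 - level) * amp
    i_end = min(len(x), i_at + int(round(params.max_apd_ms / frame_interval_ms)) + 2)
    after = x[i_peak:i_end]
    below = np.nonzero(after < thr)[0]
    if not len(below) or below[0] == 0:
        return None
    j = i_peak + below[0]
    f = (x[j - 1] - thr) / (x[j - 1] - x[j])
    t_cross = t0_ms + (j - 1 + f) * frame_interval_ms
    apd = t_cross - at_ms
    return float(apd) if 0 < apd <= params.max_apd_ms else None


# ---------------------------------------------------------------------------
# Whole-movie map extraction (vectorized path; same math as above)
# ---------------------------------------------------------------------------


def condition_movie(
    movie: OpticalMovie, params: MapParams | None = None
) -> np.ndarray:
    """Conditioned (drift-free, polarity-corrected, smoothed) frame stack."""
    params = params or MapParams()
    x = movie.frames.astype(np.float32)
    dt = movie.frame_interval_ms
    k = max(2, int(round(params.baseline_window_ms / dt)))
    baseline = minimum_filter1d(x, size=k, axis=0, mode="nearest")
    baseline = uniform_filter1d(
        baseline, max(1, int(round(params.baseline_smooth_ms / dt))),
        axis=0, mode="nearest",
    )
    y = x - baseline
    # movie-wide polarity decision from the mean trace
    m = y.mean(axis=(1, 2))
    d = np.diff(m)
    if len(d) and np.abs(d.min()) > np.abs(d.max()):
        y = -y
    if params.sg_window_ms > 0:
        win = int(round(params.sg_window_ms / dt)) | 1
        if win > params.sg_order + 1 and win < y.shape[0]:
            y = savgol_filter(y, win, params.sg_order, axis=0)
    return y


def build_maps(
    movie: OpticalMovie,
    windows: list[BeatWindow],
    params: MapParams | None = None,
    conditioned: np.ndarray | None = None,
) -> dict[int, dict[str, ScalarMap]]:
    """AT, APD80 and RT maps (with a shared validity mask) for each beat.

    The repolarization search may extend ``repol_lookahead_ms`` beyond the
    beat window (an early-coupled following beat truncates the measurement
    only at pixels it actually re-excites, which are masked).
    """
    params = params or MapParams()
    if not windows:
        raise ValueError("at least one beat window is required")
    y = conditioned if conditioned is not None else condition_movie(movie, params)
    dt = movie.frame_interval_ms
    t0 = movie.t0_ms
    n_t, nr, nc = y.shape
    out: dict[int, dict[str, ScalarMap]] = {}
    for w in windows:
        i0 = max(0, int(round((w.start_ms - t0) / dt)))
        i1 = min(n_t, int(round((w.end_ms - t0) / dt)))
        i2 = min(n_t, i1 + int(round(params.repol_lookahead_ms / dt)))
        if i1 - i0 < 5:
            raise ValueError(f"beat {w.index}: window too short")
        ext = np.asarray(y[i0:i2], dtype=np.float64)
        win = ext[: i1 - i0]
        at_idx, at_ms, amp, base, noise_sd = _activation_grid(win, dt, params)
        apd = _apd_grid(ext, at_idx, amp, base, dt, params)
        at_abs = t0 + i0 * dt + at_ms
        snr = np.where(noise_sd > 0, amp / noise_sd, np.inf)
        med_amp = np.nanmedian(np.where(amp > 0, amp, np.nan))
        valid = (
            np.isfinite(at_ms)
            & np.isfinite(apd)
            & (amp >= max(params.min_amplitude, params.amp_min_frac * med_amp))
            & (snr >= params.snr_min)
        )
        if not valid.any():
            raise ValueError(f"beat {w.index}: no valid pixels")
        rt = at_abs + apd
        mk = lambda v, kind: ScalarMap(
            values=np.where(valid, v, np.nan), valid=valid.copy(),
            kind=kind, dx_mm=movie.dx_mm, beat_index=w.index,
        )
        out[w.index] = {
            "AT": mk(at_abs, "AT"),
            "APD80": mk(apd, "APD80"),
            "RT": mk(rt, "RT"),
        }
    return out


def _activation_grid(win: np.ndarray, dt: float, params: MapParams):
    """Vectorized activation detection over a (time, rows, cols) window."""
    base = np.percentile(win, 10, axis=0)
    peak = win.max(axis=0)
    amp = peak - base
    if params.at_method == "upstroke_50":
        half = base + 0.5 * amp
        above = win >= half[None]
        j = above.argmax(axis=0)
        jm = np.clip(j, 1, None)
        v0 = np.take_along_axis(win, (jm - 1)[None], 0)[0]
        v1 = np.take_along_axis(win, jm[None], 0)[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.clip((half - v0) / (v1 - v0), 0.0, 1.0)
        at_ms = (jm - 1 + f) * dt
        ok = above.any(axis=0) & (j > 0)
        at_idx = jm
    else:
        d = np.gradient(win, dt, axis=0)
        j = d.argmax(axis=0)
        dpk = np.take_along_axis(d, j[None], 0)[0]
        jc = np.clip(j, 1, win.shape[0] - 2)
        dm = np.take_along_axis(d, (jc - 1)[None], 0)[0]
        dp = np.take_along_axis(d, (jc + 1)[None], 0)[0]
        denom = dm - 2 * np.take_along_axis(d, jc[None], 0)[0] + dp
        with np.errstate(invalid="ignore", divide="ignore"):
            off = np.clip(0.5 * (dm - dp) / denom, -0.5, 0.5)
        off[~np.isfinite(off)] = 0.0
        at_ms = (j + off) * dt
        ok = dpk > 0
        at_idx = j
    # a genuine upstroke rises out of diastole: reject window-edge maxima and
    # pixels whose trace is already elevated just before the "upstroke"
    # (e.g. the plateau tail of the previous beat poking into the window)
    pre_idx = np.maximum(at_idx - max(1, int(round(8.0 / dt))), 0)
    v_pre = np.take_along_axis(win, pre_idx[None], 0)[0]
    ok &= (at_idx >= 3) & (v_pre < base + 0.4 * amp)
    at_ms = np.where(ok, at_ms, np.nan)
    # diastolic noise: residual spread before the upstroke (never past it)
    t_axis = np.arange(win.shape[0])[:, None, None]
    pre_mask = t_axis < np.clip(at_idx - 3, 3, None)[None]
    pre = np.where(pre_mask, win, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        noise_sd = np.nanstd(np.diff(pre, axis=0), axis=0) / np.sqrt(2.0)
        base_pre = np.nanmedian(pre, axis=0)
    base = np.where(np.isfinite(base_pre), base_pre, base)
    amp = peak - base
    return at_idx, at_ms, amp, base, noise_sd


def _apd_grid(ext, at_idx, amp, base, dt, params: MapParams):
    """Vectorized APD at ``params.apd_level`` with re-excitation guard."""
    n_t = ext.shape[0]
    n_peak = int(round(params.peak_search_ms / dt))
    t_axis = np.arange(n_t)[:, None, None]
    in_peak = (t_axis >= at_idx[None]) & (t_axis <= (at_idx + n_peak)[None])
    pk = np.where(in_peak, ext, -np.inf).argmax(axis=0)
    thr = base + (1.0 - params.apd_level) * amp
    after = (t_axis > pk[None]) & (ext < thr[None])
    has = after.any(axis=0)
    j = after.argmax(axis=0)
    jm = np.clip(j, 1, None)
    w0 = np.take_along_axis(ext, (jm - 1)[None], 0)[0]
    w1 = np.take_along_axis(ext, jm[None], 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.clip((w0 - thr) / (w0 - w1), 0.0, 1.0)
    # AT at sub-sample precision is within half a frame of at_idx; the APD
    # reference below uses the integer activation index consistently
    apd = (jm - 1 + f - at_idx) * dt
    apd = np.where(has & (apd > 0) & (apd <= params.max_apd_ms), apd, np.nan)
    return apd
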