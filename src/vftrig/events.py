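"""Pseudo-ECG event analysis: beats, PVCs, T-wave overlap, VF episodes.

Beat onsets are defined as the time of the peak absolute slope of the
(lightly smoothed) ECG deflection — a scale- and offset-invariant
convention.  A premature ventricular complex (PVC) is a beat that matches
no pacing stimulus and arrives earlier than 90% of the prevailing cycle
length.  VF is operationalized at the ECG level as a run of at least
``min_cycles`` consecutive cycles shorter than 250 ms with cycle-length
coefficient of variation above 0.1; episodes lasting >= 8 s are sustained,
and an episode is spontaneous when the pacing rate at onset is <= 2 Hz and
no programmed extrastimulus fell within the preceding 2 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .core import EcgRecord

SUSTAINED_THRESHOLD_S = 8.0      # inclusive
RAPID_PACING_HZ = 2.0            # spontaneous requires rate <= 2 Hz


@dataclass
class BeatEvent:
    onset_ms: float
    kind: str = "intrinsic"            # "paced" | "intrinsic" | "pvc"
    coupling_ms: float | None = None   # PVC only
    r_on_t: bool | None = None         # PVC only
    t_end_ms: float | None = None      # estimated end of the preceding T wave


@dataclass
class VfEpisode:
    start_ms: float
    end_ms: float
    sustained: bool
    spontaneous: bool
    trigger: BeatEvent | None = None

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


@dataclass
class BeatDetectionParams:
    refractory_ms: float = 120.0
    smooth_ms: float = 8.0
    threshold_frac: float = 0.10        # of the typical strong-deflection height
    noise_mult: float = 6.0             # absolute guard: threshold >= mult * median
    pacing_match_ms: tuple = (-10.0, 140.0)  # (onset - stimulus) window for "paced"
    onset_gap_ms: float = 30.0          # sub-threshold gaps shorter than this stay
                                        # inside one complex
    onset_max_back_ms: float = 130.0    # onset never precedes the peak by more


def _slope_feature(
    amp: np.ndarray, dt: float, smooth_ms: float, baseline_ms: float = 80.0
) -> np.ndarray:
    """|d/dt| of the smoothed, high-passed trace.

    The moving-mean high-pass (``baseline_ms``) suppresses the slow T wave,
    which over a steep repolarization substrate can otherwise rival a weak
    ectopic QRS deflection.
    """
    k = max(1, int(round(smooth_ms / dt)))
    kb = max(k + 1, int(round(baseline_ms / dt)))
    hp = amp - uniform_filter1d(amp, kb)
    xs = uniform_filter1d(hp, k)
    feat = np.abs(np.gradient(xs, dt))
    return uniform_filter1d(feat, k)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample peak location via a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(off, -0.5, 0.5))


def _deflection_onset(feat: np.ndarray, i_peak: int, dt: float,
                      frac: float = 0.25, max_back_ms: float = 100.0) -> float:
    """Onset of a deflection: walk back from its slope-feature peak to the
    crossing of ``frac`` times the peak height (linearly interpolated).

    Approximates how a QRS onset is read off a trace; unlike the peak-slope
    time it does not drift with how long the wavefront takes to sweep the
    bulk of the tissue, which matters for slow ectopic beats arising in
    partially refractory tissue.  Requires a feature in which slower waves
    (T waves) are already suppressed.
    """
    level = frac * feat[i_peak]
    j_lo = max(0, i_peak - int(round(max_back_ms / dt)))
    j = i_peak
    while j > j_lo and feat[j - 1] >= level:
        j -= 1
    if j == 0 or feat[j - 1] >= level:
        return j * dt
    f = (feat[j] - level) / (feat[j] - feat[j - 1])
    return (j - f) * dt




def detect_beats(ecg: EcgRecord, params: BeatDetectionParams | None = None) -> list[BeatEvent]:
    """Locate QRS-like deflections; label those matching a pacing stimulus."""
    params = params or BeatDetectionParams()
    if ecg.duration_ms < 5000.0:
        warnings.warn("record shorter than 5 s; beat detection may be unreliable")
    amp = ecg.amplitude
    if np.ptp(amp) == 0:
        warnings.warn("flatline ECG: no beats detected")
        return []
    dt = ecg.sampling_interval_ms
    feat = _slope_feature(amp, dt, params.smooth_ms)
    # reference = median of the few tallest candidate deflections: robust to
    # a single very tall spike, to the QRS duty cycle, and to long quiet tails
    dist = max(1, int(round(params.refractory_ms / dt)))
    cands, _ = signal.find_peaks(feat, distance=dist)
    if not len(cands):
        return []
    ref = float(np.median(np.sort(feat[cands])[-5:]))
    thr = max(params.threshold_frac * ref, params.noise_mult * np.median(feat))
    idx = cands[feat[cands] >= thr]
    onsets = _complex_onsets(feat, idx, thr, dt, params)
    beats = []
    lo, hi = params.pacing_match_ms
    for i, onset in zip(idx, onsets):
        onset = float(ecg.time_ms[0] + onset)
        if beats and onset <= beats[-1].onset_ms + 10.0:
            # continuous fast activity: successive complexes share one
            # supra-threshold run; date later ones by their peaks
            onset = float(ecg.time_ms[i])
        rel = onset - ecg.pacing_times_ms
        paced = np.any((rel >= lo) & (rel <= hi)) if len(ecg.pacing_times_ms) else False
        beats.append(BeatEvent(onset_ms=onset, kind="paced" if paced else "intrinsic"))
    return beats


def _complex_onsets(
    feat: np.ndarray, idx: np.ndarray, thr: float, dt: float,
    params: BeatDetectionParams,
) -> list[float]:
    """Onset of each detected complex: the leading threshold crossing of the
    contiguous supra-threshold slope activity containing its peak.

    Sub-threshold gaps shorter than ``onset_gap_ms`` (e.g. between a focal
    source's first local deflection and the later bulk sweep) are bridged,
    so the onset dates the start of the whole complex regardless of which
    hump is taller.  During sustained fast activity the walk-back is capped
    at ``onset_max_back_ms`` before the peak.
    """
    from scipy.ndimage import binary_closing

    mask = feat >= thr
    gap = max(1, int(round(params.onset_gap_ms / dt)))
    mask = binary_closing(mask, structure=np.ones(gap, bool))
    onsets = []
    for i in idx:
        j = i
        j_lo = max(0, i - int(round(params.onset_max_back_ms / dt)))
        while j > j_lo and mask[j - 1]:
            j -= 1
        if j > 0 and feat[j] >= thr > feat[j - 1]:
            f = (feat[j] - thr) / (feat[j] - feat[j - 1])
            onsets.append((j - f) * dt)
        else:
            onsets.append(j * dt)
    return onsets


def qrs_onset_near(
    ecg: EcgRecord, approx_ms: float, halfwidth_ms: float = 60.0,
    params: BeatDetectionParams | None = None,
) -> float | None:
    """Refined onset of the single largest deflection near ``approx_ms``.

    Shares the slope-feature convention with :func:`detect_beats`; used by the
    generator to realize a commanded ECG coupling interval.
    """
    params = params or BeatDetectionParams()
    dt = ecg.sampling_interval_ms
    i0 = max(0, int((approx_ms - halfwidth_ms - ecg.time_ms[0]) / dt))
    i1 = min(len(ecg.time_ms), int((approx_ms + halfwidth_ms - ecg.time_ms[0]) / dt) + 1)
    if i1 - i0 < 5:
        return None
    feat = _slope_feature(ecg.amplitude, dt, params.smooth_ms)
    seg = feat[i0:i1]
    i = int(np.argmax(seg))
    if seg[i] <= 0:
        return None
    return float(ecg.time_ms[0] + _deflection_onset(feat, i0 + i, dt))


def classify_pvc(
    beats: list[BeatEvent],
    prematurity: float = 0.9,
    history: int = 5,
) -> list[BeatEvent]:
    """Label premature non-paced beats as PVCs and attach coupling intervals.

    The prevailing cycle length is the median of the last ``history``
    intervals between non-PVC beats.
    """
    if len(beats) < 3:
        return [replace(b) for b in beats]
    out: list[BeatEvent] = []
    base_onsets: list[float] = []
    for b in beats:
        b = replace(b)
        prev_onset = out[-1].onset_ms if out else None
        if b.kind != "paced" and prev_onset is not None and len(base_onsets) >= 2:
            intervals = np.diff(base_onsets[-(history + 1):])
            prevailing = float(np.median(intervals))
            interval = b.onset_ms - prev_onset
            if interval < prematurity * prevailing:
                b.kind = "pvc"
                b.coupling_ms = float(interval)
        if b.kind != "pvc":
            base_onsets.append(b.onset_ms)
        out.append(b)
    return out


@dataclass
class TWaveParams:
    blanking_ms: float = 100.0     # skip the QRS after onset
    search_ms: float = 500.0
    smooth_ms: float = 40.0
    min_amplitude_frac: float = 0.02   # of QRS peak-to-peak, else un-estimable


def _tangent_t_end(
    ecg: EcgRecord, onset_ms: float, stop_ms: float, params: TWaveParams
) -> tuple[float | None, str]:
    """T-wave end (absolute ms) after a beat onset by the tangent method,
    or None with a reason.  Requires the descending T limb to lie inside
    [onset + blanking, stop]."""
    dt = ecg.sampling_interval_ms
    t = ecg.time_ms
    start = onset_ms + params.blanking_ms
    stop = min(onset_ms + params.search_ms, stop_ms, t[-1])
    if stop - start < 80.0:
        return None, "repolarization segment too short"
    i0, i1 = int((start - t[0]) / dt), int((stop - t[0]) / dt)
    seg = uniform_filter1d(
        ecg.amplitude, max(1, int(round(params.smooth_ms / dt)))
    )[i0:i1]
    baseline = np.median(seg[-max(3, len(seg) // 8):])
    dev = seg - baseline
    qrs_i = int((onset_ms - t[0]) / dt)
    qrs_ptp = np.ptp(ecg.amplitude[max(0, qrs_i - 60): qrs_i + 120])
    ip = int(np.argmax(np.abs(dev)))
    if np.abs(dev[ip]) < params.min_amplitude_frac * qrs_ptp:
        return None, "T wave amplitude below noise"
    if ip >= len(seg) - max(3, int(30.0 / dt)):
        return None, "T peak truncated by the following complex"
    d = np.gradient(seg, dt)
    im = ip + int(np.argmax(np.abs(d[ip:])))
    slope = d[im]
    if slope == 0:
        return None, "flat post-peak limb"
    t_end = t[i0 + im] + (baseline - seg[im]) / slope
    return float(np.clip(t_end, start, onset_ms + params.search_ms)), ""


def twave_overlap(
    ecg: EcgRecord,
    pvc: BeatEvent,
    preceding: BeatEvent,
    params: TWaveParams | None = None,
    prior: BeatEvent | None = None,
) -> tuple[bool | None, float | None, str]:
    """R-on-T flag for a PVC by the tangent method on the preceding T wave.

    When the PVC itself obscures the preceding beat's T wave, the T-end
    offset is taken as a template from ``prior`` (an earlier beat of the
    prevailing rhythm), mirroring how an on-T coupling is read in practice.
    Returns ``(flag, t_end_ms, reason)``; ``flag`` is None when no estimate
    is possible.
    """
    params = params or TWaveParams()
    t_end, reason = _tangent_t_end(
        ecg, preceding.onset_ms, pvc.onset_ms - 40.0, params
    )
    if t_end is None and prior is not None:
        t_end_prior, reason2 = _tangent_t_end(
            ecg, prior.onset_ms, preceding.onset_ms - 40.0, params
        )
        if t_end_prior is not None:
            t_end = preceding.onset_ms + (t_end_prior - prior.onset_ms)
            reason = ""
        else:
            reason = f"{reason}; template beat: {reason2}"
    if t_end is None:
        return None, None, reason
    return bool(pvc.onset_ms <= t_end), t_end, ""


@dataclass
class VfDetectionParams:
    cycle_max_ms: float = 250.0
    cv_min: float = 0.1
    min_cycles: int = 4
    sustained_s: float = SUSTAINED_THRESHOLD_S
    rapid_hz: float = RAPID_PACING_HZ
    extrastim_lockout_ms: float = 2000.0


def _pacing_rate_at(ecg: EcgRecord, t_ms: float, lookback_ms: float = 5000.0) -> float:
    p = ecg.pacing_times_ms
    recent = p[(p >= t_ms - lookback_ms) & (p <= t_ms)]
    if len(recent) < 2:
        return 0.0
    return 1000.0 / float(np.median(np.diff(recent)))


def detect_vf(
    ecg: EcgRecord,
    beats: list[BeatEvent],
    params: VfDetectionParams | None = None,
) -> list[VfEpisode]:
    """Find VF episodes and classify them as sustained and/or spontaneous."""
    params = params or VfDetectionParams()
    if ecg.duration_ms < 10000.0:
        warnings.warn("record shorter than 10 s; VF detection window limited")
    onsets = np.array([b.onset_ms for b in beats])
    episodes: list[VfEpisode] = []
    if len(onsets) < params.min_cycles + 1:
        return episodes
    iv = np.diff(onsets)
    fast = iv < params.cycle_max_ms
    i = 0
    n = len(iv)
    while i <= n - params.min_cycles:
        win = iv[i: i + params.min_cycles]
        if np.all(fast[i: i + params.min_cycles]) and (
            np.std(win) / np.mean(win) > params.cv_min
        ):
            # extend the run to the first slow cycle or record end
            j = i + params.min_cycles
            while j < n and fast[j]:
                j += 1
            start = onsets[i]
            end = onsets[j] if j < n else float(ecg.time_ms[-1])
            duration_s = (end - start) / 1000.0
            rate = _pacing_rate_at(ecg, start)
            ex = ecg.extra_stim_times_ms
            recent_extra = np.any(
                (ex >= start - params.extrastim_lockout_ms) & (ex <= start)
            ) if len(ex) else False
            spontaneous = (rate <= params.rapid_hz + 1e-9) and not recent_extra
            trigger = None
            for b in beats:
                if b.kind == "pvc" and b.onset_ms <= start + 1.0:
                    trigger = b
            episodes.append(
                VfEpisode(
                    start_ms=float(start),
                    end_ms=float(end),
                    sustained=duration_s >= params.sustained_s,
                    spontaneous=spontaneous,
                    trigger=trigger,
                )
            )
            i = j + 1
        else:
            i += 1
    return episodes


def episode_summary(per_prep: dict) -> pd.DataFrame:
    """Per-preparation tally of spontaneous VF and PVC coupling statistics.

    Parameters
    ----------
    per_prep
        Mapping ``prep_id -> (beats, episodes)``.
    """
    rows = []
    for prep_id, (beats, episodes) in per_prep.items():
        spont = [e for e in episodes if e.spontaneous]
        sustained = [e for e in spont if e.sustained]
        pvcs = [b for b in beats if b.kind == "pvc"]
        trig_ids = {id(e.trigger) for e in episodes if e.trigger is not None}
        trig_cpl = [e.trigger.coupling_ms for e in episodes
                    if e.trigger is not None and e.trigger.coupling_ms is not None]
        non_trig_cpl = [b.coupling_ms for b in pvcs
                        if id(b) not in trig_ids and b.coupling_ms is not None]
        r_on_t = [b.r_on_t for b in pvcs if b.r_on_t is not None]
        rows.append(
            {
                "prep": prep_id,
                "n_spontaneous_vf": len(spont),
                "n_sustained": len(sustained),
                "n_nonsustained": len(spont) - len(sustained),
                "n_pvc": len(pvcs),
                "trigger_coupling_mean_ms": float(np.mean(trig_cpl)) if trig_cpl else np.nan,
                "nontrigger_coupling_mean_ms": float(np.mean(non_trig_cpl)) if non_trig_cpl else np.nan,
                "r_on_t_fraction": float(np.mean(r_on_t)) if r_on_t else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        total = {
            "prep": "ALL",
            "n_spontaneous_vf": int(df["n_spontaneous_vf"].sum()),
            "n_sustained": int(df["n_sustained"].sum()),
            "n_nonsustained": int(df["n_nonsustained"].sum()),
            "n_pvc": int(df["n_pvc"].sum()),
            "trigger_coupling_mean_ms": float(np.nanmean(df["trigger_coupling_mean_ms"]))
            if df["trigger_coupling_mean_ms"].notna().any() else np.nan,
            "nontrigger_coupling_mean_ms": float(np.nanmean(df["nontrigger_coupling_mean_ms"]))
            if df["nontrigger_coupling_mean_ms"].notna().any() else np.nan,
            "r_on_t_fraction": float(np.nanmean(df["r_on_t_fraction"]))
            if df["r_on_t_fraction"].notna().any() else np.nan,
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df
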