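"""Pseudo-ECG event analysis: beats, PVCs, T-wave overlap, VF episodes."""

import numpy as np
import pytest

from vftrig.core import EcgRecord
from vftrig.events import (
    BeatEvent,
    classify_pvc,
    detect_beats,
    detect_vf,
    episode_summary,
    twave_overlap,
)

from conftest import make_synthetic_ecg


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------


def test_detects_paced_train():
    # the complex onset (leading edge) precedes the Gaussian QRS center by
    # roughly half its footprint; stimuli sit just before the onsets
    times = 500.0 + 500.0 * np.arange(20)
    ecg = make_synthetic_ecg(times, duration_ms=11500.0, pacing_times_ms=times - 60)
    beats = detect_beats(ecg)
    assert len(beats) == 20
    iv = np.diff([b.onset_ms for b in beats])
    np.testing.assert_allclose(iv, 500.0, atol=2.0)
    assert all(b.kind == "paced" for b in beats)


def test_flat_record_is_empty():
    ecg = EcgRecord(time_ms=np.arange(0, 12000.0), amplitude=np.zeros(12000))
    with pytest.warns(UserWarning, match="flatline"):
        assert detect_beats(ecg) == []


def test_scale_and_offset_invariance():
    times = 500.0 + 500.0 * np.arange(10)
    e1 = make_synthetic_ecg(times)
    e2 = EcgRecord(time_ms=e1.time_ms, amplitude=10.0 * e1.amplitude + 3.0)
    t1 = [b.onset_ms for b in detect_beats(e1)]
    t2 = [b.onset_ms for b in detect_beats(e2)]
    np.testing.assert_allclose(t1, t2, atol=1e-9)


# ---------------------------------------------------------------------------
# PVC classification
# ---------------------------------------------------------------------------


def test_regular_rhythm_has_no_pvc():
    times = 500.0 + 500.0 * np.arange(15)
    beats = classify_pvc(detect_beats(make_synthetic_ecg(times)))
    assert all(b.kind != "pvc" for b in beats)


def test_premature_beat_coupling_recovered():
    base = 500.0 + 500.0 * np.arange(8)
    pvc_t = base[-1] + 297.0
    times = np.append(base, pvc_t)
    ecg = make_synthetic_ecg(times, pacing_times_ms=base - 60)
    beats = classify_pvc(detect_beats(ecg))
    pvcs = [b for b in beats if b.kind == "pvc"]
    assert len(pvcs) == 1
    assert pvcs[0].coupling_ms == pytest.approx(297.0, abs=5.0)


def test_short_history_defaults_gracefully():
    assert classify_pvc([BeatEvent(onset_ms=100.0)]) == [BeatEvent(onset_ms=100.0)]


# ---------------------------------------------------------------------------
# T-wave overlap (tangent method)
# ---------------------------------------------------------------------------


def _overlap_case(coupling):
    base = 600.0 + 600.0 * np.arange(6)
    times = np.append(base, base[-1] + coupling)
    ecg = make_synthetic_ecg(times, t_amp=0.3, t_delay_ms=280.0, t_width_ms=70.0)
    beats = classify_pvc(detect_beats(ecg))
    pvc = [b for b in beats if b.kind == "pvc"][0]
    k = beats.index(pvc)
    return twave_overlap(ecg, pvc, beats[k - 1], prior=beats[k - 2])


def test_short_coupling_is_r_on_t():
    flag, t_end, _ = _overlap_case(250.0)
    assert flag is True
    assert t_end is not None


def test_long_coupling_is_off_t():
    flag, t_end, _ = _overlap_case(500.0)
    assert flag is False


def test_absent_t_wave_flag_none():
    base = 600.0 + 600.0 * np.arange(6)
    times = np.append(base, base[-1] + 300.0)
    ecg = make_synthetic_ecg(times, t_amp=0.0)
    beats = classify_pvc(detect_beats(ecg))
    pvc = [b for b in beats if b.kind == "pvc"][0]
    k = beats.index(pvc)
    flag, _, reason = twave_overlap(ecg, pvc, beats[k - 1], prior=beats[k - 2])
    assert flag is None and reason


# ---------------------------------------------------------------------------
# VF episodes: duration and spontaneity boundaries
# ---------------------------------------------------------------------------


def _vf_beats_and_ecg(duration_s, pacing_cycle_ms=None, extra_stim=()):
    """Constructed beat list: organized rhythm, then irregular fast activity
    whose last fast deflection falls exactly ``duration_s`` after the first."""
    onsets = list(500.0 + 500.0 * np.arange(6))
    start = onsets[-1] + 320.0
    rng = np.random.default_rng(1)
    t, fast = start, []
    while t < start + duration_s * 1000.0 - 1.0:
        fast.append(t)
        t += 180.0 + rng.uniform(-45.0, 45.0)
    fast.append(start + duration_s * 1000.0)
    onsets += fast + [fast[-1] + 600.0]
    beats = [BeatEvent(onset_ms=o) for o in onsets]
    beats[6].kind = "pvc"
    beats[6].coupling_ms = 320.0
    t_axis = np.arange(0.0, onsets[-1] + 2000.0)
    pacing = (
        np.arange(500.0, 3200.0, pacing_cycle_ms) if pacing_cycle_ms else ()
    )
    ecg = EcgRecord(
        time_ms=t_axis, amplitude=np.sin(t_axis / 100.0),
        pacing_times_ms=pacing, extra_stim_times_ms=extra_stim,
    )
    return beats, ecg


@pytest.mark.parametrize(
    "duration_s,expect_sustained", [(8.0, True), (7.999, False)]
)
def test_sustained_threshold_inclusive_at_8s(duration_s, expect_sustained):
    beats, ecg = _vf_beats_and_ecg(duration_s)
    eps = detect_vf(ecg, beats)
    assert len(eps) == 1
    assert eps[0].duration_s == pytest.approx(duration_s, abs=1e-9)
    assert eps[0].sustained == expect_sustained
    assert eps[0].trigger is beats[6]


@pytest.mark.parametrize(
    "cycle_ms,expect_spont", [(500.0, True), (497.5, False)]
)
def test_spontaneous_requires_pacing_at_most_2hz(cycle_ms, expect_spont):
    """Exactly 2 Hz pacing still counts as spontaneous; faster does not."""
    beats, ecg = _vf_beats_and_ecg(9.0, pacing_cycle_ms=cycle_ms)
    eps = detect_vf(ecg, beats)
    assert len(eps) == 1
    assert eps[0].spontaneous == expect_spont


def test_extrastimulus_blocks_spontaneity():
    beats, ecg = _vf_beats_and_ecg(9.0, extra_stim=(3250.0,))
    eps = detect_vf(ecg, beats)
    assert len(eps) == 1
    assert not eps[0].spontaneous


def test_no_vf_in_regular_rhythm():
    times = 500.0 + 500.0 * np.arange(25)
    ecg = make_synthetic_ecg(times, duration_ms=13500.0)
    assert detect_vf(ecg, detect_beats(ecg)) == []


# ---------------------------------------------------------------------------
# Episode summary
# ---------------------------------------------------------------------------


def test_summary_counts_match_brute_force():
    from vftrig.events import VfEpisode

    per_prep = {}
    rng = np.random.default_rng(3)
    total = 0
    for p in range(4):
        n = int(rng.integers(0, 5))
        total += n
        eps = [
            VfEpisode(start_ms=1000.0 * k, end_ms=1000.0 * k + 9000.0,
                      sustained=True, spontaneous=True)
            for k in range(n)
        ]
        per_prep[f"p{p}"] = ([], eps)
    df = episode_summary(per_prep)
    assert int(df[df["prep"] == "ALL"]["n_spontaneous_vf"].iloc[0]) == total
    per_rows = df[df["prep"] != "ALL"]
    assert per_rows["n_spontaneous_vf"].sum() == total


def test_summary_empty_study():
    df = episode_summary({"p0": ([], [])})
    assert int(df["n_spontaneous_vf"].sum()) == 0
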