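"""Shared fixtures: one mid-size synthetic preparation (simulated once per
session) plus cheap constructed signals."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from vftrig.synthetic import (
    AcquisitionModel,
    EctopicSpec,
    IonicParams,
    LesionSpec,
    PacingProtocol,
    TissueGrid,
    compute_pseudo_ecg,
    render_fluorescence,
    simulate,
)


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def grid96() -> TissueGrid:
    return TissueGrid(n_rows=96, n_cols=96)


@pytest.fixture(scope="session")
def lesion96() -> LesionSpec:
    # 7.5% of a 37.4 x 37.4 mm sheet
    return LesionSpec(radius_mm=5.78, border_width_mm=5.6)


@pytest.fixture(scope="session")
def sim96(grid96, lesion96):
    """One lesioned preparation: 3 paced beats then a border ectopic."""
    return simulate(
        grid96,
        IonicParams(),
        PacingProtocol(n_beats=3),
        EctopicSpec(coupling_mean_ms=350.0, coupling_sd_ms=0.0),
        lesion=lesion96,
        seed=5,
        post_trigger_ms=450.0,
    )


@pytest.fixture(scope="session")
def clean_movie(sim96):
    """Noiseless, blur-free rendering: min-max-normalized voltage."""
    acq = AcquisitionModel(
        blur_sigma_px=0.0, noise_sd=0.0, rundown_per_min=0.0, dead_pixel_fraction=0.0
    )
    return render_fluorescence(sim96.voltage, acq, seed=0)


@pytest.fixture(scope="session")
def paced_sim48():
    """Homogeneous 48x48 sheet, one paced beat, no lesion."""
    grid = TissueGrid(n_rows=48, n_cols=48)
    return grid, simulate(
        grid, IonicParams(),
        PacingProtocol(n_beats=1, site_px=(24, 4)),
        ectopic=None, duration_ms=600.0, seed=0,
    )


def make_synthetic_ecg(
    beat_times_ms,
    duration_ms=12000.0,
    dt_ms=1.0,
    qrs_amp=1.0,
    qrs_width_ms=25.0,
    t_amp=0.25,
    t_delay_ms=280.0,
    t_width_ms=60.0,
    pacing_times_ms=(),
    extra_stim_times_ms=(),
    noise_sd=0.0,
    seed=0,
):
    """Constructed ECG: Gaussian QRS complexes with optional T waves."""
    from vftrig.core import EcgRecord

    t = np.arange(0.0, duration_ms, dt_ms)
    x = np.zeros_like(t)
    for bt in beat_times_ms:
        x += qrs_amp * np.exp(-0.5 * ((t - bt) / (qrs_width_ms / 2.355)) ** 2)
        if t_amp:
            x += t_amp * np.exp(
                -0.5 * ((t - bt - t_delay_ms) / (t_width_ms / 2.355)) ** 2
            )
    if noise_sd:
        x += np.random.default_rng(seed).normal(0, noise_sd, x.shape)
    return EcgRecord(
        time_ms=t, amplitude=x,
        pacing_times_ms=np.asarray(pacing_times_ms, dtype=float),
        extra_stim_times_ms=np.asarray(extra_stim_times_ms, dtype=float),
    )


@pytest.fixture
def synth_ecg():
    return make_synthetic_ecg
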