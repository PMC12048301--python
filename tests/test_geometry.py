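"""Gradient estimation, border delineation and distance measurements."""

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff

from vftrig.core import ScalarMap
from vftrig.geometry import (
    BORDER_ZONE_MM,
    delineate_border,
    distance_to_border,
    is_border_zone,
    local_gradient,
    measure_trigger_site,
    sample_nontrigger_sites,
)
from vftrig.maps import BeatWindow, build_maps

DX = 0.39


def ramp_map(slope_ms_mm, angle_deg, n=64):
    rows, cols = np.indices((n, n))
    theta = np.radians(angle_deg)
    proj = (rows * np.cos(theta) + cols * np.sin(theta)) * DX
    return ScalarMap(values=200.0 + slope_ms_mm * proj,
                     valid=np.ones((n, n), bool), kind="APD80", dx_mm=DX)


@pytest.mark.parametrize("angle", [0, 30, 45, 60, 90])
def test_gradient_exact_on_linear_ramp(angle):
    """Relative error below 1% on linear ramps of any orientation."""
    g = local_gradient(ramp_map(10.0, angle))
    vals = g.values[g.valid]
    assert len(vals)
    np.testing.assert_allclose(vals, 10.0, rtol=0.01)


def test_gradient_zero_on_constant_map():
    g = local_gradient(ramp_map(0.0, 0))
    assert np.abs(g.values[g.valid]).max() < 1e-9


def test_gradient_rejects_fully_masked():
    m = ramp_map(10.0, 0)
    m.valid[:] = False
    with pytest.raises(ValueError):
        local_gradient(m)


def test_gradient_repairs_isolated_but_masks_clustered_invalid():
    m = ramp_map(10.0, 0)
    m.valid[12, 12] = False          # isolated dead pixel: repaired
    m.valid[28:33, 28:33] = False    # clustered dropout: stays masked
    g = local_gradient(m)
    assert g.valid[12, 12]
    assert g.values[12, 12] == pytest.approx(10.0, rel=0.01)
    assert not g.valid[30, 30]
    assert not g.valid[33, 33]       # stencil margin around the cluster


# ---------------------------------------------------------------------------
# Border delineation
# ---------------------------------------------------------------------------


def test_uniform_map_has_no_lesion():
    with pytest.raises(ValueError, match="bimodal|manual"):
        delineate_border(ramp_map(0.0, 0))


def test_manual_threshold_on_step_map():
    n = 64
    vals = np.where(np.indices((n, n))[1] < 20, 180.0, 270.0)
    smap = ScalarMap(values=vals, valid=np.ones((n, n), bool), kind="APD80", dx_mm=DX)
    geom = delineate_border(smap, manual_threshold_ms=225.0)
    # contour lies at the step (between columns 19 and 20)
    cols = geom.contour_px[:, 1]
    step_cols = cols[(geom.contour_px[:, 0] > 2) & (geom.contour_px[:, 0] < n - 3)]
    assert np.all(np.abs(step_cols - 19.5) <= 0.6)


def test_recovered_contour_close_to_truth(sim96, clean_movie, lesion96):
    """Hausdorff distance between the delineated contour and the true border
    circle is at most half the transition width plus one pixel."""
    t0, t1 = sim96.truth.beat_windows_ms[1]
    maps = build_maps(clean_movie, [BeatWindow(index=1, start_ms=t0, end_ms=t1)])[1]
    geom = delineate_border(maps["APD80"])
    truth = sim96.truth.lesion_contour_px
    d1 = directed_hausdorff(geom.contour_px, truth)[0]
    d2 = directed_hausdorff(truth, geom.contour_px)[0]
    limit_px = (lesion96.border_width_mm / 2.0) / DX + 1.0
    assert max(d1, d2) <= limit_px


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@pytest.fixture()
def circle_geom():
    n = 96
    rows, cols = np.indices((n, n))
    r = np.hypot(rows - 48, cols - 48) * DX
    vals = np.where(r < 8.0, 180.0, 270.0)
    smap = ScalarMap(values=vals, valid=np.ones((n, n), bool), kind="APD80", dx_mm=DX)
    return delineate_border(smap, manual_threshold_ms=225.0)


def test_distance_brute_force_oracle(circle_geom):
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 95, size=(100, 2))
    for p in pts:
        d = distance_to_border(p, circle_geom)
        brute = np.min(np.hypot(*(circle_geom.contour_px - p).T)) * DX
        assert d == pytest.approx(brute, abs=DX / 2)


def test_border_zone_is_inclusive(circle_geom):
    on = circle_geom.contour_px[10]
    assert distance_to_border(on, circle_geom) == pytest.approx(0.0, abs=1e-9)
    assert is_border_zone(on, circle_geom)
    # a site exactly 3.5 mm outward along a radius is still border zone
    u = (on - np.array([48.0, 48.0]))
    u = u / np.linalg.norm(u)
    site_in = on + u * (BORDER_ZONE_MM / DX)
    site_out = on + u * ((BORDER_ZONE_MM + 0.45) / DX)
    assert is_border_zone(site_in, circle_geom)
    assert not is_border_zone(site_out, circle_geom)


# ---------------------------------------------------------------------------
# Site measurements
# ---------------------------------------------------------------------------


def test_nontrigger_sampling_deterministic(circle_geom):
    grad = local_gradient(ramp_map(1.5, 0, n=96))
    a = sample_nontrigger_sites(circle_geom, grad, grad, n=3, seed=42)
    b = sample_nontrigger_sites(circle_geom, grad, grad, n=3, seed=42)
    assert [s.site_px for s in a] == [s.site_px for s in b]
    assert all(s.role == "nontrigger" for s in a)
    for s in a:
        assert s.apd_gradient_ms_mm == pytest.approx(1.5, rel=0.05)


def test_nontrigger_clearance_too_large(circle_geom):
    grad = local_gradient(ramp_map(1.5, 0, n=96))
    with pytest.raises(ValueError, match="clearance"):
        sample_nontrigger_sites(circle_geom, grad, grad, n=3, seed=0,
                                clearance_mm=100.0)


def test_masked_trigger_site_raises(circle_geom):
    grad = local_gradient(ramp_map(1.5, 0, n=96))
    grad.valid[:] = False
    with pytest.raises(ValueError, match="masked"):
        measure_trigger_site((48, 48), circle_geom, grad, grad)
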