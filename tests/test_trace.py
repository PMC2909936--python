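import numpy as np
import pytest

from synaptrace.render import FieldSpec, Polyline, rasterize, simulate_field
from synaptrace.trace import (
    SQRT2,
    TraceConfig,
    dataframe_to_objects,
    measure_contour,
    objects_to_dataframe,
    segment,
    trace_image,
)


def _field(polylines, size_px=128, noise=0.0, seed=0):
    spec = FieldSpec(size_px=size_px, noise_sd_nm=max(noise, 1e-12))
    img = rasterize(polylines, spec)
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    return img, spec


def _centered_rod(spec, length_nm, angle_deg=0.0):
    c = spec.extent_nm / 2
    d = np.deg2rad(angle_deg)
    v = np.array([np.cos(d), np.sin(d)]) * length_nm / 2
    pts = np.array([[c, c] - v, [c, c] + v])
    return Polyline(pts, np.array([0.0, length_nm / 0.332]))


# --------------------------------------------------------- measure_contour

def test_measure_contour_orthogonal():
    path = [(0, i) for i in range(42)]   # 41 steps of 2 nm
    assert measure_contour(path, 2.0) == pytest.approx(82.0)


def test_measure_contour_diagonal():
    path = [(i, i) for i in range(11)]   # 10 diagonal steps
    assert measure_contour(path, 2.0) == pytest.approx(10 * SQRT2 * 2.0)


def test_measure_contour_rejects_disconnected():
    with pytest.raises(ValueError):
        measure_contour([(0, 0), (0, 3)], 2.0)


def test_measure_contour_short_paths():
    assert measure_contour([], 2.0) == 0.0
    assert measure_contour([(5, 5)], 2.0) == 0.0


# ----------------------------------------------------------------- segment

def test_segment_rejects_nan():
    img = np.zeros((16, 16))
    img[3, 3] = np.nan
    with pytest.raises(ValueError):
        segment(img)


def test_segment_constant_image_empty():
    assert not segment(np.zeros((32, 32))).any()


def test_segment_absolute_threshold():
    img = np.zeros((32, 32))
    img[10:12, 4:28] = 1.0
    mask = segment(img, TraceConfig(threshold_nm=0.5))
    assert mask.sum() == 2 * 24


# ------------------------------------------------------------- trace_image

def test_pure_noise_yields_no_objects():
    rng = np.random.default_rng(0)
    img = rng.normal(0.0, 0.05, (128, 128))
    objects, _, _ = trace_image(img, 2.0)
    assert objects == []


def test_straight_rod_traced_linear():
    spec = FieldSpec(size_px=128)
    rod = _centered_rod(spec, 83.0, angle_deg=20.0)
    img, _ = _field([rod], size_px=128)
    objects, _, _ = trace_image(img, spec.pixel_size_nm)
    assert len(objects) == 1
    o = objects[0]
    assert o.object_type == "linear"
    assert o.n_endpoints == 2 and o.n_junctions == 0
    # endpoint extension fills the rounded ridge caps, adding up to about
    # half the PSF width per end, so a perfectly straight rod reads high
    assert o.contour_nm == pytest.approx(83.0, rel=0.08)
    assert o.contour_nm >= 83.0 * 0.97


def test_sixty_degree_cross_traced_as_x():
    spec = FieldSpec(size_px=128)
    a = _centered_rod(spec, 90.0, angle_deg=0.0)
    b = _centered_rod(spec, 90.0, angle_deg=60.0)
    img, _ = _field([a, b], size_px=128)
    objects, _, _ = trace_image(img, spec.pixel_size_nm)
    assert len(objects) == 1
    o = objects[0]
    assert o.object_type == "crossed_X"
    assert o.n_junctions == 1 and o.n_endpoints == 4
    assert len(o.arms) == 4
    c = spec.extent_nm / 2
    assert o.junction_xy_nm == pytest.approx((c, c), abs=3.0)
    for length_nm, _path in o.arms:
        assert length_nm == pytest.approx(45.0, rel=0.12)


def test_y_junction_traced_as_y():
    spec = FieldSpec(size_px=128)
    c = spec.extent_nm / 2
    arms = []
    for ang in (90.0, 210.0, 330.0):
        d = np.deg2rad(ang)
        pts = np.array([[c, c], [c + 50 * np.cos(d), c + 50 * np.sin(d)]])
        arms.append(Polyline(pts, np.array([0.0, 50 / 0.332])))
    img, _ = _field(arms, size_px=128)
    objects, _, _ = trace_image(img, spec.pixel_size_nm)
    assert len(objects) == 1
    assert objects[0].object_type == "branched_Y"
    assert objects[0].n_endpoints == 3


def test_border_touch_flagged():
    spec = FieldSpec(size_px=96)
    pts = np.array([[0.0, 40.0], [90.0, 40.0]])
    img, _ = _field([Polyline(pts, np.array([0.0, 100.0]))], size_px=96)
    objects, _, _ = trace_image(img, spec.pixel_size_nm)
    assert objects and objects[0].touches_border


def test_noise_free_field_recovery(frag250):
    """Every generated molecule is found; linear contours within 5%."""
    spec = FieldSpec(size_px=384, noise_sd_nm=1e-9)
    img, truths, _ = simulate_field(spec, frag250,
                                    rng=np.random.default_rng(20))
    objects, _, _ = trace_image(img.data, spec.pixel_size_nm)
    n_traced = sum(1 if o.object_type == "linear" else 2 for o in objects)
    assert n_traced == len(truths)
    from synaptrace.wlc import Morphology
    n_free_truth = sum(t.morphology is Morphology.FREE for t in truths)
    linear = [o for o in objects if o.object_type == "linear"]
    assert len(linear) == n_free_truth
    mean = np.mean([o.contour_nm for o in linear])
    assert abs(mean - frag250.L_tot_nm) / frag250.L_tot_nm < 0.05
    for o in linear:   # per-molecule: straight outliers read a few nm high
        assert abs(o.contour_nm - frag250.L_tot_nm) / frag250.L_tot_nm < 0.10


def test_objects_dataframe_round_trip():
    spec = FieldSpec(size_px=128)
    a = _centered_rod(spec, 90.0, angle_deg=0.0)
    b = _centered_rod(spec, 90.0, angle_deg=60.0)
    img, _ = _field([a, b], size_px=128)
    objects, _, _ = trace_image(img, spec.pixel_size_nm)
    df = objects_to_dataframe(objects, field_id=3,
                              pixel_size_nm=spec.pixel_size_nm)
    assert set(df["field"]) == {3}
    back = dataframe_to_objects(df)
    assert len(back) == len(objects)
    o0, b0 = objects[0], back[0]
    assert b0.object_type == o0.object_type
    assert b0.contour_nm == pytest.approx(o0.contour_nm, abs=0.01)
    assert b0.junction_xy_nm == pytest.approx(o0.junction_xy_nm, abs=0.01)
    assert len(b0.armset.arms) == len(o0.arms)


def test_empty_objects_dataframe():
    df = objects_to_dataframe([], field_id=0)
    assert len(df) == 0
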