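import numpy as np
import pytest

from synaptrace.render import FieldSpec, Polyline, rasterize
from synaptrace.synapse import (
    Arm,
    ArmSet,
    ClassifyConfig,
    arm_profile,
    classify_crossed_object,
    orientation_call,
    pair_arms,
    population_stats,
)
from synaptrace.trace import TracedObject, trace_image

D_SE = 21.912
L_INT = 83.0 - D_SE   # 61.088


def _unit(deg):
    r = np.deg2rad(deg)
    return np.array([np.cos(r), np.sin(r)])


def _armset(spec):
    """ArmSet from (length, angle_deg) pairs."""
    return ArmSet([Arm(l, _unit(a)) for l, a in spec])


# --------------------------------------------------------------- pair_arms

def test_pair_arms_pairs_opposite_tangents():
    arms = _armset([(D_SE, 0), (D_SE, 90), (L_INT, 180), (L_INT, 270)])
    assignment = pair_arms(arms)
    assert sorted(map(sorted, assignment)) == [[0, 2], [1, 3]]


def test_pair_arms_rejects_kink():
    # all four arms on one side: no anti-aligned pairing exists
    arms = _armset([(20, 0), (20, 25), (20, 50), (20, 75)])
    assert pair_arms(arms) is None


def test_pair_arms_needs_four():
    with pytest.raises(ValueError):
        pair_arms(_armset([(20, 0), (20, 120), (20, 240)]))


def test_pair_arms_tie_breaks_by_length():
    # a perfect '+' is direction-degenerate only between 90-degree pairs,
    # straight-through pairing still wins; lengths break any residual tie
    arms = _armset([(D_SE, 0), (L_INT, 90), (L_INT, 180), (D_SE, 270)])
    assignment = pair_arms(arms)
    assert sorted(map(sorted, assignment)) == [[0, 2], [1, 3]]


# --------------------------------------------------------- orientation_call

def _four_arm(short2_deg, frag):
    """pX/Ap geometry: molecule 1 short along 0 deg, molecule 2 short at
    short2_deg; long arms opposite their shorts."""
    arms = _armset([
        (D_SE, 0), (L_INT, 180),
        (D_SE, short2_deg), (L_INT, short2_deg + 180),
    ])
    return orientation_call(arms, pair_arms(arms), frag)


def test_orientation_px(frag250):
    call = _four_arm(60, frag250)
    assert call.call == "pX"
    assert call.L_se_nm == pytest.approx(D_SE)
    assert sorted(call.molecule_arms_nm) == [(D_SE, L_INT)] * 2


def test_orientation_ap(frag250):
    call = _four_arm(240, frag250)
    assert call.call == "Ap"
    assert call.L_se_nm == pytest.approx(D_SE)


def test_orientation_incompatible_lengths(frag250):
    # four equal ~L_tot/2 arms: an accidental mid-molecule overlap
    arms = _armset([(41.5, 0), (41.5, 90), (41.5, 180), (41.5, 270)])
    call = orientation_call(arms, pair_arms(arms), frag250)
    assert call.call == "unclassified"
    assert call.L_se_nm is None


def test_orientation_unpaired_is_unclassified(frag250):
    arms = _armset([(D_SE, 0), (L_INT, 180), (D_SE, 60), (L_INT, 240)])
    assert orientation_call(arms, None, frag250).call == "unclassified"


def test_orientation_py(frag250):
    arms = _armset([(D_SE, 150), (D_SE + 3, 210), (L_INT + 5, 0)])
    call = orientation_call(arms, None, frag250)
    assert call.call == "pY"
    assert call.L_se_nm == pytest.approx(D_SE)


def test_orientation_three_arm_incompatible(frag250):
    # mid-length arms match neither the external nor the internal distance
    arms = _armset([(40, 0), (45, 120), (50, 240)])
    assert orientation_call(arms, None, frag250).call == "unclassified"


def test_orientation_three_arm_absorbed_ap(frag250):
    # short + internal + over-long doubled branch -> Ap, no L_se estimate
    arms = _armset([(D_SE, 0), (L_INT, 120), (L_INT + 14, 240)])
    call = orientation_call(arms, None, frag250)
    assert call.call == "Ap"
    assert call.L_se_nm is None


def test_orientation_three_arm_absorbed_px(frag250):
    # merged-shorts stub + two internal-length arms -> pX, no L_se estimate
    arms = _armset([(D_SE + 4, 0), (L_INT, 120), (L_INT + 2, 240)])
    call = orientation_call(arms, None, frag250)
    assert call.call == "pX"
    assert call.L_se_nm is None


# ------------------------------------------------------------- arm_profile

def _cross_objects(angle_deg=60.0, arm_short=D_SE, arm_long=L_INT):
    spec = FieldSpec(size_px=160)
    c = spec.extent_nm / 2
    pls = []
    for base in (0.0, angle_deg):
        d = _unit(base)
        pts = np.array([[c, c] - arm_long * d, [c, c] + arm_short * d])
        pls.append(Polyline(pts, np.array([0.0, 250.0])))
    img = rasterize(pls, spec)
    objects, _, _ = trace_image(img, spec.pixel_size_nm)
    return objects, spec


def test_arm_profile_lengths_and_tangents():
    objects, spec = _cross_objects()
    assert len(objects) == 1 and objects[0].object_type == "crossed_X"
    arms = arm_profile(objects[0], spec.pixel_size_nm)
    lengths = sorted(a.length_nm for a in arms.arms)
    # short arms carry the junction-gap correction plus end-cap extension,
    # a few nm of positive bias on a ~22 nm arm
    assert lengths[0] == pytest.approx(D_SE, abs=4.0)
    assert lengths[1] == pytest.approx(D_SE, abs=4.0)
    assert lengths[2] == pytest.approx(L_INT, abs=5.0)
    assert lengths[3] == pytest.approx(L_INT, abs=5.0)
    # each measured tangent lies near one of the four true directions
    truths = [_unit(a) for a in (0, 60, 180, 240)]
    for a in arms.arms:
        assert max(float(a.tangent @ t) for t in truths) > 0.95


def test_arm_profile_rejects_linear():
    o = TracedObject(0, "linear", 83.0, 2, 0, False)
    with pytest.raises(ValueError):
        arm_profile(o, 2.0)


def test_classify_crossed_object_end_to_end(frag250):
    objects, spec = _cross_objects()
    call = classify_crossed_object(objects[0], spec.pixel_size_nm, frag250)
    # shorts at 0 and 60 degrees leave on the same side -> parallel X
    assert call.call == "pX"
    assert call.L_se_nm == pytest.approx(D_SE, abs=3.0)


def test_classify_crossed_object_linear_passthrough(frag250):
    o = TracedObject(0, "linear", 83.0, 2, 0, False)
    assert classify_crossed_object(o, 2.0, frag250).call == "unclassified"


# -------------------------------------------------------- population_stats

def _linear(i, contour=83.0, border=False):
    return TracedObject(i, "linear", contour, 2, 0, border)


def test_population_stats_all_linear(frag250):
    report, calls = population_stats([_linear(0), _linear(1, 84.0)], 2.0,
                                     frag250)
    assert report.n_molecules == 2
    assert report.crossed_fraction == 0.0
    assert report.contour_mean_nm == pytest.approx(83.5)
    assert calls == []


def test_population_stats_requires_objects(frag250):
    with pytest.raises(ValueError):
        population_stats([], 2.0, frag250)


def test_population_stats_counts_crossed(frag250):
    objects, spec = _cross_objects()
    report, calls = population_stats([_linear(1)] + objects,
                                     spec.pixel_size_nm, frag250)
    assert report.n_molecules == 3
    assert report.n_crossed_objects == 1
    assert report.crossed_fraction == pytest.approx(2 / 3)
    assert report.counts["pX"] == 1
    assert "pX" in report.summary_table()


def test_population_stats_excludes_border(frag250):
    report, _ = population_stats([_linear(0), _linear(1, 120.0, border=True)],
                                 2.0, frag250)
    assert report.n_molecules == 1
    assert report.contour_mean_nm == pytest.approx(83.0)
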