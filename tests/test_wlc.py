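import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synaptrace.wlc import (
    CLAMP_SPAN_BP,
    GroundTruthRecord,
    MIN_CLEARANCE_NM,
    Morphology,
    Polyline,
    _self_clear,
    assemble_incidental,
    assemble_synapse,
    sample_chain,
    sample_chain_sa,
)


# ---------------------------------------------------------------- Polyline

def test_polyline_validation():
    with pytest.raises(ValueError):
        Polyline(np.zeros((3, 3)), np.zeros(3))
    with pytest.raises(ValueError):
        Polyline(np.zeros((3, 2)), np.zeros(2))


def test_polyline_contour_and_reverse():
    pl = Polyline(np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 10.0]]),
                  np.array([0.0, 5.0, 11.0]))
    assert pl.contour_nm == pytest.approx(11.0)
    rev = pl.reversed()
    assert rev.contour_nm == pytest.approx(11.0)
    assert rev.bp_at_point[0] == 11.0 and rev.bp_at_point[-1] == 0.0


@given(st.floats(-np.pi, np.pi), st.floats(-50, 50), st.floats(-50, 50))
def test_polyline_transform_preserves_contour(rot, tx, ty):
    pl = Polyline(np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 7.0]]),
                  np.array([0.0, 10.0, 17.0]))
    moved = pl.transformed(rot, np.array([tx, ty]))
    assert moved.contour_nm == pytest.approx(pl.contour_nm, rel=1e-9)


def test_index_at_bp(frag250):
    pl = sample_chain(frag250, rng=0)
    i = pl.index_at_bp(frag250.crossing_bp)
    assert pl.bp_at_point[i] == pytest.approx(frag250.crossing_bp, abs=1.0)


# ------------------------------------------------------------- sample_chain

def test_sample_chain_contour_exact(frag250):
    pl = sample_chain(frag250, rng=1)
    assert pl.contour_nm == pytest.approx(frag250.L_tot_nm, rel=1e-9)
    assert pl.bp_at_point[-1] == frag250.L_tot_bp


def test_sample_chain_odd_step_contour_exact(frag250):
    # 250 bp with a 7 bp step leaves a 5 bp remainder segment
    pl = sample_chain(frag250, step_bp=7, rng=2)
    assert pl.contour_nm == pytest.approx(frag250.L_tot_nm, rel=1e-9)


def test_sample_chain_stiff_limit_is_straight(frag250):
    pl = sample_chain(frag250, persistence_nm=1e12, rng=3, theta0=0.0)
    end = np.hypot(*pl.points[-1])
    assert end == pytest.approx(frag250.L_tot_nm, rel=1e-6)


def test_sample_chain_rigid_interval(frag250):
    pl = sample_chain(frag250, rng=4, theta0=0.0,
                      rigid_bp=(0, frag250.L_tot_bp))
    # fully rigid chain is a straight rod
    assert np.hypot(*pl.points[-1]) == pytest.approx(frag250.L_tot_nm, rel=1e-9)


def test_sample_chain_rejects_bad_params(frag250):
    with pytest.raises(ValueError):
        sample_chain(frag250, persistence_nm=0.0)
    with pytest.raises(ValueError):
        sample_chain(frag250, step_bp=0)


def test_sample_chain_deterministic(frag250):
    a = sample_chain(frag250, rng=np.random.default_rng(11))
    b = sample_chain(frag250, rng=np.random.default_rng(11))
    assert np.array_equal(a.points, b.points)


@settings(max_examples=10)
@given(st.integers(0, 10_000))
def test_sample_chain_finite(frag250, seed):
    pl = sample_chain(frag250, rng=seed)
    assert np.all(np.isfinite(pl.points))


def test_tangent_correlation_matches_2d_wlc(frag250):
    """Ensemble oracle: in-plane tangent correlation decays as exp(-s/2P)."""
    P = 50.0
    n_chains = 800
    rng = np.random.default_rng(12345)
    cos_acc = None
    for _ in range(n_chains):
        pl = sample_chain(frag250, persistence_nm=P, rng=rng, theta0=0.0)
        d = np.diff(pl.points, axis=0)
        theta = np.arctan2(d[:, 1], d[:, 0])
        c = np.cos(theta - theta[0])
        cos_acc = c if cos_acc is None else cos_acc + c
    mean_cos = cos_acc / n_chains
    rise = frag250.constants.rise_nm_per_bp
    s = np.arange(len(mean_cos)) * 2 * rise   # step_bp = 2
    expected = np.exp(-s / (2 * P))
    # compare at several separations; MC error ~ 1/sqrt(800) ~ 0.035
    for k in (10, 30, 60, 100, 124):
        assert mean_cos[k] == pytest.approx(expected[k], abs=0.06)


# -------------------------------------------------------------- self-clear

def test_self_clear_straight_rod():
    pts = np.column_stack([np.linspace(0, 80, 41), np.zeros(41)])
    assert _self_clear(Polyline(pts, np.arange(41, dtype=float)))


def test_self_clear_rejects_hairpin():
    # two long antiparallel strands 4 nm apart
    x = np.linspace(0, 40, 21)
    pts = np.vstack([np.column_stack([x, np.zeros(21)]),
                     np.column_stack([x[::-1], np.full(21, 4.0)])])
    assert not _self_clear(Polyline(pts, np.arange(42, dtype=float)))


def test_sample_chain_sa_is_self_clear(frag250):
    for seed in range(5):
        pl = sample_chain_sa(frag250, rng=seed)
        assert _self_clear(pl)


# -------------------------------------------------------- assemble_synapse

def _junction_tangent(truth: GroundTruthRecord, fragment) -> np.ndarray:
    """Unit tangent at the crossing toward the short (external) arm."""
    pl = truth.polyline
    i = pl.index_at_bp(truth.crossing_bp)
    j = i + 1 if fragment.closest_end == "external" else i - 1
    v = pl.points[j] - pl.points[i]
    return v / np.hypot(*v)


def test_assemble_rejects_non_synapse(frag250):
    with pytest.raises(ValueError):
        assemble_synapse(frag250, frag250, Morphology.FREE, rng=0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_px_geometry(frag250, seed):
    p1, p2, truths = assemble_synapse(frag250, frag250, Morphology.PX, rng=seed)
    for pl, t in zip((p1, p2), truths):
        assert pl.contour_nm == pytest.approx(frag250.L_tot_nm, rel=1e-9)
        assert t.true_L_se_nm == pytest.approx(21.912)
        i = pl.index_at_bp(frag250.crossing_bp)
        # both chains pass through the origin at the crossing coordinate
        assert np.hypot(*pl.points[i]) < 1e-9
        # external arm contour from the crossing to the nearest end
        ext = Polyline(pl.points[i:], pl.bp_at_point[i:])
        assert ext.contour_nm == pytest.approx(21.912, rel=1e-9)
        internal = Polyline(pl.points[:i + 1], pl.bp_at_point[:i + 1])
        assert internal.contour_nm == pytest.approx(61.088, rel=1e-9)
    # parallel: short-arm tangents on the same side
    t1 = _junction_tangent(truths[0], frag250)
    t2 = _junction_tangent(truths[1], frag250)
    assert float(t1 @ t2) > 0.0
    assert 40.0 <= truths[0].crossing_angle_deg <= 90.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ap_geometry(frag250, seed):
    _, _, truths = assemble_synapse(frag250, frag250, Morphology.AP, rng=seed)
    t1 = _junction_tangent(truths[0], frag250)
    t2 = _junction_tangent(truths[1], frag250)
    # antiparallel: short arm of molecule 2 leaves on the opposite side
    assert float(t1 @ t2) < 0.0


def test_py_shares_internal_branch(frag250):
    p1, p2, truths = assemble_synapse(frag250, frag250, Morphology.PY, rng=7)
    assert p1.contour_nm == pytest.approx(frag250.L_tot_nm, rel=1e-3)
    assert p2.contour_nm == pytest.approx(frag250.L_tot_nm, rel=1e-3)
    # the internal arms run together (sub-resolution lateral offset), the
    # external ends separate
    i1 = p1.index_at_bp(frag250.crossing_bp)
    i2 = p2.index_at_bp(frag250.crossing_bp)
    internal1 = p1.points[:i1 + 1]
    internal2 = p2.points[:i2 + 1]
    n = min(len(internal1), len(internal2))
    d = np.hypot(*(internal1[-n:] - internal2[-n:]).T)
    assert d.max() < 1.0
    ext_sep = np.hypot(*(p1.points[-1] - p2.points[-1]))
    assert ext_sep > MIN_CLEARANCE_NM


def test_synapse_truth_records(frag250):
    _, _, truths = assemble_synapse(frag250, frag250, Morphology.PX, rng=9)
    assert [t.molecule_id for t in truths] == [0, 1]
    assert [t.partner_id for t in truths] == [1, 0]
    assert all(t.morphology is Morphology.PX for t in truths)
    assert all(t.crossing_bp == frag250.crossing_bp for t in truths)


def test_ground_truth_json_round_trip(frag250):
    _, _, truths = assemble_synapse(frag250, frag250, Morphology.AP, rng=5)
    back = GroundTruthRecord.from_json(truths[0].to_json())
    assert back.molecule_id == truths[0].molecule_id
    assert back.morphology is Morphology.AP
    assert back.true_L_se_nm == truths[0].true_L_se_nm
    assert back.crossing_angle_deg == truths[0].crossing_angle_deg
    np.testing.assert_allclose(back.polyline.points,
                               truths[0].polyline.points, atol=1e-4)
    np.testing.assert_array_equal(back.polyline.bp_at_point,
                                  truths[0].polyline.bp_at_point)


def test_incidental_crossing_location(frag250):
    for seed in range(4):
        p1, p2, truths = assemble_incidental(frag250, frag250, rng=seed)
        assert all(t.morphology is Morphology.INCIDENTAL for t in truths)
        for t in truths:
            # crossing point is binding-site independent, away from the ends
            frac = t.crossing_bp / frag250.L_tot_bp
            assert 0.1 < frac < 0.9
            assert t.true_L_se_nm is None
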