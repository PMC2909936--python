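"""2D worm-like-chain simulation of deposited DNA and synapse assembly.

Molecules deposited on polylysine-mica and imaged in air are modelled as
discrete 2D worm-like chains equilibrated in the plane: successive tangent
angles receive independent zero-mean Gaussian increments with variance
ds/P, where P is the persistence length (default 50 nm, the consensus
value for B-DNA).  This is the 2D equilibrium statistics of a chain with
bending stiffness P*kT, whose in-plane tangent correlation decays as
exp(-s/2P).

Deposited chains are quasi-self-avoiding (two duplexes cannot occupy the
same surface site), so sampled conformations whose distant segments pass
closer than a clearance distance are rejected and redrawn; in a synapse the
protein dimer grips both duplexes around the crossing point, which is
modelled as a short rigid (straight) region of each chain centred on the
binding-site coordinate.

The three synapse morphologies observed for an asymmetric substrate are:

* ``pX`` (parallel X): the chains cross, the two short (external-side) arms
  leave the junction on the same side;
* ``Ap`` (antiparallel): a cross with one molecule's orientation reversed,
  so short pairs with long across the junction;
* ``pY`` (parallel Y): the internal arms are co-aligned into a single shared
  branch, only the two short external arms separate (3 visible branches).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from synaptrace.fragments import Fragment


class Morphology(str, Enum):
    FREE = "free"
    PX = "pX"
    PY = "pY"
    AP = "Ap"
    INCIDENTAL = "incidental"


SYNAPSE_MORPHOLOGIES = (Morphology.PX, Morphology.PY, Morphology.AP)

DEFAULT_PERSISTENCE_NM = 50.0
DEFAULT_STEP_BP = 2

#: rigid protein-clamped span around the synapse crossing point (bp): one
#: binding-site footprint's worth of DNA on each side of the crossing is
#: gripped straight by the nucleoprotein core
CLAMP_SPAN_BP = 44

#: minimum surface clearance between distant chain segments (nm): two
#: ridges whose binary masks merge under the tip PSF (roughly 2*sigma *
#: sqrt(2*ln(2/threshold)) ~ 10 nm) are unresolvable, so the generator
#: models the resolvable-conformation population
MIN_CLEARANCE_NM = 10.0
_MIN_ARC_NM = 15.0      # segments closer along the chain may approach freely
#: near a prescribed crossing the full clearance is geometrically
#: impossible; the requirement tapers to the separation a straight crossing
#: at the steepest allowed angle (40 deg) would give, 2*sin(20 deg)*r,
#: with a 10% tolerance
_TAPER_PER_NM = 0.615
_MAX_DRAWS = 40


@dataclass
class Polyline:
    """Ordered 2D point chain with a per-vertex bp coordinate.

    points : (n, 2) float array, nm, (x, y)
    bp_at_point : (n,) float array, monotone non-decreasing, 0 at the
        internal 5' end of the source fragment.
    """

    points: np.ndarray
    bp_at_point: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.bp_at_point = np.asarray(self.bp_at_point, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.points) != len(self.bp_at_point):
            raise ValueError("points and bp_at_point length mismatch")

    @property
    def contour_nm(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def index_at_bp(self, bp: float) -> int:
        return int(np.argmin(np.abs(self.bp_at_point - bp)))

    def transformed(self, rotation_rad: float, translation: np.ndarray) -> "Polyline":
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        R = np.array([[c, -s], [s, c]])
        return Polyline(self.points @ R.T + np.asarray(translation, float),
                        self.bp_at_point.copy())

    def reversed(self) -> "Polyline":
        return Polyline(self.points[::-1].copy(), self.bp_at_point[::-1].copy())


@dataclass
class GroundTruthRecord:
    """Per-molecule truth needed for recovery tests."""

    molecule_id: int
    polyline: Polyline
    morphology: Morphology
    partner_id: int | None = None
    crossing_bp: float | None = None
    true_L_se_nm: float | None = None
    crossing_angle_deg: float | None = None

    def to_json(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "morphology": self.morphology.value,
            "partner_id": self.partner_id,
            "crossing_bp": self.crossing_bp,
            "true_L_se_nm": self.true_L_se_nm,
            "crossing_angle_deg": self.crossing_angle_deg,
            "contour_nm": self.polyline.contour_nm,
            "points_nm": np.round(self.polyline.points, 4).tolist(),
            "bp_at_point": self.polyline.bp_at_point.tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruthRecord":
        return cls(
            molecule_id=d["molecule_id"],
            polyline=Polyline(np.array(d["points_nm"]), np.array(d["bp_at_point"])),
            morphology=Morphology(d["morphology"]),
            partner_id=d["partner_id"],
            crossing_bp=d["crossing_bp"],
            true_L_se_nm=d["true_L_se_nm"],
            crossing_angle_deg=d.get("crossing_angle_deg"),
        )


def _segment_lengths_bp(total_bp: int, step_bp: int) -> np.ndarray:
    n_full, rem = divmod(total_bp, step_bp)
    segs = np.full(n_full, step_bp, dtype=float)
    if rem:
        segs = np.append(segs, float(rem))
    return segs


def sample_chain(
    fragment: Fragment,
    persistence_nm: float = DEFAULT_PERSISTENCE_NM,
    step_bp: int = DEFAULT_STEP_BP,
    rng: np.random.Generator | int | None = None,
    theta0: float | None = None,
    rigid_bp: tuple[float, float] | None = None,
) -> Polyline:
    """Sample one deposited molecule as a discrete 2D worm-like chain.

    Per-step angular increments are N(0, ds/P) — the 2D equilibrium
    statistics for persistence length P, giving an in-plane tangent
    correlation <t(0).t(s)> = exp(-s/2P).  The total contour equals the
    fragment's L_tot_nm exactly by construction (a short last step absorbs
    the bp remainder).  ``rigid_bp`` straightens the chain over a bp
    interval (a protein-clamped region).
    """
    if persistence_nm <= 0:
        raise ValueError("persistence length must be positive")
    if step_bp < 1:
        raise ValueError("step_bp must be >= 1")
    rng = np.random.default_rng(rng)
    rise = fragment.constants.rise_nm_per_bp
    segs_bp = _segment_lengths_bp(fragment.L_tot_bp, step_bp)
    segs_nm = segs_bp * rise
    if theta0 is None:
        theta0 = rng.uniform(0, 2 * np.pi)
    dtheta = rng.normal(0.0, np.sqrt(segs_nm[1:] / persistence_nm))
    if rigid_bp is not None:
        bp_mid = np.cumsum(segs_bp)[:-1]   # bp coordinate of each hinge
        lo, hi = rigid_bp
        dtheta[(bp_mid >= lo) & (bp_mid <= hi)] = 0.0
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = segs_nm[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    bp = np.concatenate([[0.0], np.cumsum(segs_bp)])
    return Polyline(points, bp)


def _self_clear(pl: Polyline, min_clear_nm: float = MIN_CLEARANCE_NM,
                min_arc_nm: float = _MIN_ARC_NM) -> bool:
    """True if no two chain points far apart along the contour come closer
    than the clearance distance (2D excluded volume)."""
    p = pl.points
    d = np.hypot(*np.diff(p, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(d)])
    dx = p[:, None, :] - p[None, :, :]
    dist = np.hypot(dx[..., 0], dx[..., 1])
    arc = np.abs(s[:, None] - s[None, :])
    bad = (arc > min_arc_nm) & (dist < min_clear_nm)
    return not bad.any()


def _pair_margin(a: Polyline, b: Polyline,
                 min_clear_nm: float = MIN_CLEARANCE_NM,
                 junction_xy: np.ndarray | None = None) -> float:
    """Worst-case clearance margin between two chains (negative = too close).

    The required separation is ``min_clear_nm``, tapered near a prescribed
    crossing point to the separation a straight 40-degree crossing would
    give at that radius, since less than that is geometrically impossible.
    """
    pa, pb = a.points, b.points
    dx = pa[:, None, :] - pb[None, :, :]
    dist = np.hypot(dx[..., 0], dx[..., 1])
    floor = np.full_like(dist, min_clear_nm)
    if junction_xy is not None:
        ra = np.hypot(*(pa - junction_xy).T)
        rb = np.hypot(*(pb - junction_xy).T)
        r = np.minimum(ra[:, None], rb[None, :])
        floor = np.minimum(floor, _TAPER_PER_NM * r)
    return float((dist - floor).min())


def _pair_clear(a: Polyline, b: Polyline,
                min_clear_nm: float = MIN_CLEARANCE_NM,
                junction_xy: np.ndarray | None = None) -> bool:
    """True if the two chains keep clearance everywhere except near a
    prescribed crossing point."""
    return _pair_margin(a, b, min_clear_nm, junction_xy) >= 0.0


def sample_chain_sa(
    fragment: Fragment,
    persistence_nm: float = DEFAULT_PERSISTENCE_NM,
    step_bp: int = DEFAULT_STEP_BP,
    rng: np.random.Generator | int | None = None,
    max_tries: int = _MAX_DRAWS,
    rigid_bp: tuple[float, float] | None = None,
) -> Polyline:
    """Self-avoiding chain: redraw until distant segments keep clearance.

    Falls back to the last draw if no clear conformation appears within
    ``max_tries`` (vanishingly rare at the default stiffness)."""
    rng = np.random.default_rng(rng)
    pl = None
    for _ in range(max_tries):
        pl = sample_chain(fragment, persistence_nm, step_bp, rng,
                          rigid_bp=rigid_bp)
        if _self_clear(pl):
            return pl
    return pl


def _orient_through(chain: Polyline, bp: float, direction_rad: float,
                    toward: str) -> Polyline:
    """Rigidly move a chain so the vertex at ``bp`` sits at the origin and
    the local tangent toward the chosen end ('head' = increasing bp,
    'tail' = decreasing) points along ``direction_rad``."""
    i = chain.index_at_bp(bp)
    if toward == "head":
        j = min(i + 1, len(chain.points) - 1)
        d = chain.points[j] - chain.points[i]
    else:
        j = max(i - 1, 0)
        d = chain.points[j] - chain.points[i]
    cur = np.arctan2(d[1], d[0])
    rot = direction_rad - cur
    moved = Polyline(chain.points - chain.points[i], chain.bp_at_point)
    return moved.transformed(rot, np.zeros(2))


def _clamp_interval(fragment: Fragment, span_bp: float = CLAMP_SPAN_BP):
    c = fragment.crossing_bp
    return (c - span_bp / 2, c + span_bp / 2)


def assemble_synapse(
    f1: Fragment,
    f2: Fragment,
    morphology: Morphology,
    rng: np.random.Generator | int | None = None,
    persistence_nm: float = DEFAULT_PERSISTENCE_NM,
    step_bp: int = DEFAULT_STEP_BP,
    crossing_angle_deg: tuple[float, float] = (40.0, 90.0),
) -> tuple[Polyline, Polyline, list[GroundTruthRecord]]:
    """Build a synapsed pair of molecules joined at their binding sites.

    Both chains pass through the origin at their crossing bp coordinate,
    held straight over the protein-clamped span.  The short (external) arm
    of molecule 1 leaves along +x; for pX the short arm of molecule 2
    leaves at the crossing angle (same side), for Ap it leaves opposite
    (short pairs with long).  For pY the internal arms share a single path
    so only three branches are visible.  Conformations whose arms collide
    away from the junction are redrawn (excluded volume).
    """
    if morphology not in SYNAPSE_MORPHOLOGIES:
        raise ValueError(f"not a synapse morphology: {morphology}")
    rng = np.random.default_rng(rng)
    alpha = np.deg2rad(rng.uniform(*crossing_angle_deg))

    def _truths(p1: Polyline, p2: Polyline) -> list[GroundTruthRecord]:
        return [
            GroundTruthRecord(0, p1, morphology, partner_id=1,
                              crossing_bp=float(f1.crossing_bp),
                              true_L_se_nm=f1.d_closest_end_nm,
                              crossing_angle_deg=float(np.rad2deg(alpha))),
            GroundTruthRecord(1, p2, morphology, partner_id=0,
                              crossing_bp=float(f2.crossing_bp),
                              true_L_se_nm=f2.d_closest_end_nm,
                              crossing_angle_deg=float(np.rad2deg(alpha))),
        ]

    # direction of the short (closest-end) arm leaving the junction
    short1 = "head" if f1.closest_end == "external" else "tail"
    short2 = "head" if f2.closest_end == "external" else "tail"
    origin = np.zeros(2)

    if morphology in (Morphology.PX, Morphology.AP):
        ang2 = alpha if morphology is Morphology.PX else alpha + np.pi
        # joint rejection sampling: redraw both chains so one awkward
        # conformation of molecule 1 cannot force a colliding pair; keep the
        # best-clearance pair as a fallback
        best = (-np.inf, None, None)
        found = None
        for _ in range(_MAX_DRAWS):
            c1 = sample_chain(f1, persistence_nm, step_bp, rng,
                              rigid_bp=_clamp_interval(f1))
            q1 = _orient_through(c1, f1.crossing_bp, 0.0, toward=short1)
            if not _self_clear(q1):
                continue
            for _ in range(8):
                c2 = sample_chain(f2, persistence_nm, step_bp, rng,
                                  rigid_bp=_clamp_interval(f2))
                q2 = _orient_through(c2, f2.crossing_bp, ang2, toward=short2)
                if not _self_clear(q2):
                    continue
                margin = _pair_margin(q1, q2, junction_xy=origin)
                if margin > best[0]:
                    best = (margin, q1, q2)
                if margin >= 0.0:
                    found = (q1, q2)
                    break
            if found:
                break
        p1, p2 = found if found else best[1:]
        return p1, p2, _truths(p1, p2)

    # pY: shared internal branch + two separate external arms
    rise = f1.constants.rise_nm_per_bp
    beta1 = np.deg2rad(rng.uniform(25.0, 55.0))
    beta2 = np.deg2rad(rng.uniform(25.0, 55.0))

    def _arm(total_bp: float, direction: float,
             rigid_nm: float = CLAMP_SPAN_BP / 2 * 0.332) -> tuple:
        segs_bp = _segment_lengths_bp(int(round(total_bp)), step_bp)
        segs_nm = segs_bp * rise
        dtheta = rng.normal(0.0, np.sqrt(segs_nm[1:] / persistence_nm))
        hinge_s = np.cumsum(segs_nm)[:-1]
        dtheta[hinge_s <= rigid_nm] = 0.0   # clamped near the junction
        theta = direction + np.concatenate([[0.0], np.cumsum(dtheta)])
        steps = segs_nm[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        return pts, np.concatenate([[0.0], np.cumsum(segs_bp)])

    internal_bp1 = (f1.crossing_bp if f1.closest_end == "external"
                    else f1.L_tot_bp - f1.crossing_bp)

    def _molecule(ext_pts, ext_bp, shared_pts, shared_bp, fragment,
                  lateral) -> Polyline:
        # walk internal end -> junction -> external end; shared branch gets a
        # sub-resolution lateral offset so the chains are distinct objects
        # but render as one branch
        offset = np.array([0.0, lateral])
        internal = (shared_pts[::-1] + offset)[:-1]
        bp_internal = (shared_bp[::-1])[:-1]  # bp distance from junction
        pts = np.vstack([internal, [0.0, 0.0], ext_pts[1:]])
        if fragment.closest_end == "external":
            bp = np.concatenate([
                internal_bp1 - bp_internal,
                [internal_bp1],
                internal_bp1 + ext_bp[1:],
            ])
        else:   # internal end carries the high bp coordinates
            bp = np.concatenate([
                fragment.L_tot_bp - (internal_bp1 - bp_internal),
                [fragment.L_tot_bp - internal_bp1],
                fragment.L_tot_bp - internal_bp1 - ext_bp[1:],
            ])
        return Polyline(pts, bp)

    p1 = p2 = None
    for _ in range(_MAX_DRAWS):
        shared_pts, shared_bp = _arm(internal_bp1, 0.0)
        ext1 = _arm(f1.L_tot_bp - internal_bp1, np.pi - beta1)
        ext2 = _arm(f2.L_tot_bp - internal_bp1, np.pi + beta2)
        q1 = _molecule(*ext1, shared_pts, shared_bp, f1, lateral=+0.15)
        q2 = _molecule(*ext2, shared_pts, shared_bp, f2, lateral=-0.15)
        shared_pl = Polyline(shared_pts, shared_bp)
        e1 = Polyline(ext1[0], ext1[1])
        e2 = Polyline(ext2[0], ext2[1])
        if not (_self_clear(q1) and _self_clear(q2)):
            continue
        if not _pair_clear(e1, e2, junction_xy=origin):
            continue
        if not (_pair_clear(e1, shared_pl, junction_xy=origin)
                and _pair_clear(e2, shared_pl, junction_xy=origin)):
            continue
        p1, p2 = q1, q2
        break
    if p1 is None:
        p1, p2 = q1, q2
    return p1, p2, _truths(p1, p2)


def assemble_incidental(
    f1: Fragment,
    f2: Fragment,
    rng: np.random.Generator | int | None = None,
    persistence_nm: float = DEFAULT_PERSISTENCE_NM,
    step_bp: int = DEFAULT_STEP_BP,
    crossing_angle_deg: tuple[float, float] = (40.0, 140.0),
) -> tuple[Polyline, Polyline, list[GroundTruthRecord]]:
    """Two molecules crossing at random, binding-site-independent points —
    the background of accidental overlaps seen without protein."""
    rng = np.random.default_rng(rng)
    alpha = rng.uniform(*np.deg2rad(crossing_angle_deg))
    bp1 = rng.uniform(0.15, 0.85) * f1.L_tot_bp
    bp2 = rng.uniform(0.15, 0.85) * f2.L_tot_bp
    origin = np.zeros(2)
    p1 = p2 = None
    for _ in range(_MAX_DRAWS):
        c1 = sample_chain(f1, persistence_nm, step_bp, rng)
        q1 = _orient_through(c1, bp1, 0.0, toward="head")
        if _self_clear(q1):
            p1 = q1
            break
    for _ in range(_MAX_DRAWS):
        c2 = sample_chain(f2, persistence_nm, step_bp, rng)
        q2 = _orient_through(c2, bp2, alpha, toward="head")
        if not _self_clear(q2):
            continue
        if p1 is not None and not _pair_clear(p1, q2, junction_xy=origin):
            continue
        p2 = q2
        break
    if p1 is None:
        p1 = q1
    if p2 is None:
        p2 = q2
    truths = [
        GroundTruthRecord(0, p1, Morphology.INCIDENTAL, partner_id=1,
                          crossing_bp=float(p1.bp_at_point[p1.index_at_bp(bp1)]),
                          crossing_angle_deg=float(np.rad2deg(alpha))),
        GroundTruthRecord(1, p2, Morphology.INCIDENTAL, partner_id=0,
                          crossing_bp=float(p2.bp_at_point[p2.index_at_bp(bp2)]),
                          crossing_angle_deg=float(np.rad2deg(alpha))),
    ]
    return p1, p2, truths
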