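"""AFM-style field rendering: placement, rasterization, tip blur, noise.

A field is a square height image (nm units) containing a mixture of free
molecules, transposase-mediated synapses and incidental crossings.  Chains
are rasterized as thin ridges, convolved with a Gaussian point-spread
function standing in for tip broadening, normalised so an isolated straight
ridge peaks at ``height_amplitude``, and overlaid with i.i.d. Gaussian
pixel noise.  Ground truth (every polyline, its morphology, partner and
crossing coordinate) is serialised alongside each image.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter, binary_dilation

from synaptrace import __version__
from synaptrace.fragments import Fragment, fragment_r250
from synaptrace.wlc import (
    GroundTruthRecord,
    MIN_CLEARANCE_NM,
    Morphology,
    Polyline,
    SYNAPSE_MORPHOLOGIES,
    assemble_incidental,
    assemble_synapse,
    sample_chain_sa,
)

#: morphology mix emulating the protein-added condition: 24% of molecules in
#: synapses, split across pX/pY/Ap as observed (38:26:14 of 78 crossed).
PROTEIN_PROPORTIONS = {
    Morphology.FREE: 0.76,
    Morphology.PX: 0.24 * 38 / 78,
    Morphology.PY: 0.24 * 26 / 78,
    Morphology.AP: 0.24 * 14 / 78,
    Morphology.INCIDENTAL: 0.0,
}

#: protein-free condition: only the ~6% background of accidental overlaps.
NO_PROTEIN_PROPORTIONS = {
    Morphology.FREE: 0.94,
    Morphology.PX: 0.0,
    Morphology.PY: 0.0,
    Morphology.AP: 0.0,
    Morphology.INCIDENTAL: 0.06,
}


@dataclass
class FieldSpec:
    """Scan and mixture parameters for one synthetic field."""

    size_px: int = 512
    pixel_size_nm: float = 2.0
    tip_sigma_nm: float = 3.0
    height_amplitude_nm: float = 1.0
    noise_sd_nm: float = 0.05          # 0.05 x height_amplitude
    density_per_um2: float = 25.0
    proportions: dict = field(default_factory=lambda: dict(PROTEIN_PROPORTIONS))
    persistence_nm: float = 50.0
    step_bp: int = 2
    margin_px: int = 12
    max_place_retries: int = 60

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be positive")
        self.proportions = {Morphology(k): float(v)
                            for k, v in self.proportions.items()}
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"morphology proportions sum to {total}, not 1")

    @property
    def extent_nm(self) -> float:
        return self.size_px * self.pixel_size_nm

    @property
    def area_um2(self) -> float:
        return (self.extent_nm / 1000.0) ** 2

    def to_json(self) -> dict:
        d = asdict(self)
        d["proportions"] = {k.value: v for k, v in self.proportions.items()}
        return d


@dataclass
class HeightImage:
    data: np.ndarray          # (size, size) float32, nm
    pixel_size_nm: float

    def save(self, path) -> None:
        tifffile.imwrite(str(path), self.data.astype(np.float32),
                         metadata={"pixel_size_nm": self.pixel_size_nm})

    @classmethod
    def load(cls, path) -> "HeightImage":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray().astype(np.float32)
            meta = tf.shaped_metadata or [{}]
            px = float(meta[0].get("pixel_size_nm", 1.0))
        return cls(data=data, pixel_size_nm=px)


def _splat(points_nm: np.ndarray, canvas: np.ndarray, pixel_size: float,
           sub_nm: float = 0.5) -> None:
    """Accumulate arc-length mass of a polyline onto the pixel grid
    (bilinear), so ridge response after blurring is rotation-invariant."""
    pts = points_nm / pixel_size
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    samples = []
    weights = []
    for p0, d, L in zip(pts[:-1], seg, seglen):
        if L == 0:
            continue
        n = max(1, int(np.ceil(L * pixel_size / sub_nm)))
        t = (np.arange(n) + 0.5) / n
        samples.append(p0 + t[:, None] * d)
        weights.append(np.full(n, L * pixel_size / n))
    if not samples:
        return
    s = np.vstack(samples)
    w = np.concatenate(weights)
    x, y = s[:, 0], s[:, 1]
    i0 = np.floor(x).astype(int)
    j0 = np.floor(y).astype(int)
    fx, fy = x - i0, y - j0
    H, W = canvas.shape
    for di, dj, wt in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                       (0, 1, (1 - fx) * fy, ), (1, 1, fx * fy)):
        ii, jj = i0 + di, j0 + dj
        ok = (ii >= 0) & (ii < W) & (jj >= 0) & (jj < H)
        np.add.at(canvas, (jj[ok], ii[ok]), (w * wt)[ok])


def _ridge_norm(spec: FieldSpec) -> float:
    """Peak blurred response of an isolated long straight ridge rendered with
    the same splatting, used to scale ridges to height_amplitude."""
    n = 64
    canvas = np.zeros((n, n))
    y = n / 2 * spec.pixel_size_nm
    pts = np.array([[0.0, y], [n * spec.pixel_size_nm, y]])
    _splat(pts, canvas, spec.pixel_size_nm)
    blurred = gaussian_filter(canvas, spec.tip_sigma_nm / spec.pixel_size_nm)
    return float(blurred[:, n // 2].max())


def rasterize(polylines: list[Polyline], spec: FieldSpec) -> np.ndarray:
    """Noise-free height image of the given (field-coordinate) polylines."""
    canvas = np.zeros((spec.size_px, spec.size_px))
    for pl in polylines:
        _splat(pl.points, canvas, spec.pixel_size_nm)
    blurred = gaussian_filter(canvas, spec.tip_sigma_nm / spec.pixel_size_nm)
    norm = _ridge_norm(spec)
    return blurred * (spec.height_amplitude_nm / norm)


def render_field(
    molecules: list[GroundTruthRecord],
    spec: FieldSpec,
    rng: np.random.Generator | int | None = None,
) -> HeightImage:
    """Render placed molecules into a noisy height image."""
    rng = np.random.default_rng(rng)
    img = rasterize([m.polyline for m in molecules], spec)
    img = img + rng.normal(0.0, spec.noise_sd_nm, img.shape)
    img = img.astype(np.float32)
    if not np.all(np.isfinite(img)):
        raise FloatingPointError("rendered image contains non-finite pixels")
    return HeightImage(img, spec.pixel_size_nm)


class PlacementError(RuntimeError):
    """Raised when the requested density cannot be placed without overlap."""


def _object_pixels(polylines: list[Polyline], spec: FieldSpec) -> np.ndarray | None:
    """Integer pixel set covered by an object, or None if out of bounds."""
    pts = np.vstack([pl.points for pl in polylines]) / spec.pixel_size_nm
    lo, hi = spec.margin_px, spec.size_px - spec.margin_px
    if pts.min() < lo or pts.max() >= hi:
        return None
    px = set()
    for pl in polylines:
        p = pl.points / spec.pixel_size_nm
        seg = np.diff(p, axis=0)
        L = np.hypot(seg[:, 0], seg[:, 1])
        for p0, d, l in zip(p[:-1], seg, L):
            n = max(1, int(np.ceil(l * 2)))
            t = np.arange(n + 1) / n
            for q in p0 + t[:, None] * d:
                px.add((int(round(q[1])), int(round(q[0]))))
    return np.array(sorted(px))


def _place_objects(
    objects: list[tuple[list[Polyline], list[GroundTruthRecord]]],
    spec: FieldSpec,
    rng: np.random.Generator,
) -> tuple[list[GroundTruthRecord], int]:
    """Drop objects at random pose, rejecting collisions with previously
    placed material (prescribed within-object crossings excepted)."""
    occupancy = np.zeros((spec.size_px, spec.size_px), dtype=bool)
    placed: list[GroundTruthRecord] = []
    n_failed = 0
    next_id = 0
    # keep placed objects at least the resolvability clearance apart so
    # separate molecules never render as one merged object
    gap_px = int(np.ceil(MIN_CLEARANCE_NM / spec.pixel_size_nm))
    struct = np.ones((2 * gap_px + 1, 2 * gap_px + 1), dtype=bool)
    for polylines, truths in objects:
        ok = False
        for _ in range(spec.max_place_retries):
            phi = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(spec.margin_px * spec.pixel_size_nm,
                                spec.extent_nm - spec.margin_px * spec.pixel_size_nm,
                                size=2)
            moved = [pl.transformed(phi, shift) for pl in polylines]
            pix = _object_pixels(moved, spec)
            if pix is None:
                continue
            if occupancy[pix[:, 0], pix[:, 1]].any():
                continue
            stamp = np.zeros_like(occupancy)
            stamp[pix[:, 0], pix[:, 1]] = True
            occupancy |= binary_dilation(stamp, structure=struct)
            id_map = {}
            for t, pl in zip(truths, moved):
                gid = next_id
                next_id += 1
                id_map[t.molecule_id] = gid
            for t, pl in zip(truths, moved):
                placed.append(GroundTruthRecord(
                    molecule_id=id_map[t.molecule_id],
                    polyline=pl,
                    morphology=t.morphology,
                    partner_id=None if t.partner_id is None else id_map[t.partner_id],
                    crossing_bp=t.crossing_bp,
                    true_L_se_nm=t.true_L_se_nm,
                    crossing_angle_deg=t.crossing_angle_deg,
                ))
            ok = True
            break
        if not ok:
            n_failed += 1
    return placed, n_failed


def plan_and_place(
    spec: FieldSpec,
    fragment: Fragment | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[GroundTruthRecord], int]:
    """Draw a Poisson molecule count, assign morphologies from the mixture,
    assemble objects and place them in the field."""
    rng = np.random.default_rng(rng)
    fragment = fragment or fragment_r250()
    n = rng.poisson(spec.density_per_um2 * spec.area_um2)
    morphs = list(spec.proportions.keys())
    probs = np.array([spec.proportions[m] for m in morphs])
    assignment = rng.choice(len(morphs), size=n, p=probs)
    counts = {m: int(np.sum(assignment == i)) for i, m in enumerate(morphs)}
    objects: list[tuple[list[Polyline], list[GroundTruthRecord]]] = []
    n_free = counts.get(Morphology.FREE, 0)
    # odd per-class counts are rounded to a whole number of pairs with a
    # fair coin so the expected molecule count per class is preserved
    # (always demoting leftovers would bias the crossed fraction low)
    for m in SYNAPSE_MORPHOLOGIES:
        c = counts.get(m, 0)
        for _ in range((c + int(rng.integers(0, 2))) // 2):
            p1, p2, truths = assemble_synapse(
                fragment, fragment, m, rng,
                persistence_nm=spec.persistence_nm, step_bp=spec.step_bp)
            objects.append(([p1, p2], truths))
    c = counts.get(Morphology.INCIDENTAL, 0)
    for _ in range((c + int(rng.integers(0, 2))) // 2):
        p1, p2, truths = assemble_incidental(
            fragment, fragment, rng,
            persistence_nm=spec.persistence_nm, step_bp=spec.step_bp)
        objects.append(([p1, p2], truths))
    for _ in range(n_free):
        pl = sample_chain_sa(fragment, spec.persistence_nm, spec.step_bp, rng)
        objects.append(([pl], [GroundTruthRecord(0, pl, Morphology.FREE)]))
    order = rng.permutation(len(objects))
    objects = [objects[i] for i in order]
    return _place_objects(objects, spec, rng)


def simulate_field(
    spec: FieldSpec,
    fragment: Fragment | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[HeightImage, list[GroundTruthRecord], int]:
    rng = np.random.default_rng(rng)
    truths, n_failed = plan_and_place(spec, fragment, rng)
    img = render_field(truths, spec, rng)
    return img, truths, n_failed


def truth_to_json(truths: list[GroundTruthRecord]) -> str:
    return json.dumps([t.to_json() for t in truths], sort_keys=True)


def truth_from_json(text: str) -> list[GroundTruthRecord]:
    return [GroundTruthRecord.from_json(d) for d in json.loads(text)]


def config_hash(obj: dict) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def generate_dataset(
    n_fields: int,
    spec: FieldSpec,
    seed: int,
    out_dir,
    fragment: Fragment | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a reproducible dataset: per-field TIFF + truth JSON + manifest.

    The master seed spawns one child seed per field (recorded in the
    manifest) so fields are independent yet reproducible.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_fields)
    field_meta = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        img, truths, n_failed = simulate_field(spec, fragment, rng)
        tif = out / f"field_{k:03d}.tif"
        img.save(tif)
        (out / f"field_{k:03d}_truth.json").write_text(truth_to_json(truths))
        field_meta.append({
            "field": k,
            "tiff": tif.name,
            "truth": f"field_{k:03d}_truth.json",
            "seed_entropy": int(seed),
            "spawn_key": list(child.spawn_key),
            "n_molecules": len(truths),
            "n_placement_failures": n_failed,
        })
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "n_fields": n_fields,
        "field_spec": spec.to_json(),
        "config_hash": config_hash(spec.to_json()),
        "fields": field_meta,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
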