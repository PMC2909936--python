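"""Reusable end-to-end recovery experiments at the study's conditions.

These drive the full generator -> render -> trace -> classify chain and
compare the recovered quantities with the generator's ground truth.  They
are what the validation suite and the reproduction script both run; sizes
are arguments so callers can scale them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from synaptrace.fragments import Fragment, fragment_r250
from synaptrace.render import (
    FieldSpec,
    NO_PROTEIN_PROPORTIONS,
    PROTEIN_PROPORTIONS,
    render_field,
    simulate_field,
)
from synaptrace.synapse import ClassifyConfig, classify_crossed_object, population_stats
from synaptrace.trace import TraceConfig, trace_image
from synaptrace.wlc import Morphology, Polyline, assemble_synapse


def _center_in_canvas(polylines: list[Polyline], extent_nm: float,
                      rng: np.random.Generator, margin_nm: float = 20.0):
    """Random rotation, then translate the bounding-box centre to the canvas
    centre; returns None if the object does not fit."""
    phi = rng.uniform(0, 2 * np.pi)
    rot = [pl.transformed(phi, np.zeros(2)) for pl in polylines]
    pts = np.vstack([p.points for p in rot])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if np.any(hi - lo > extent_nm - 2 * margin_nm):
        return None
    shift = extent_nm / 2 - (lo + hi) / 2
    return [p.transformed(0.0, shift) for p in rot]


@dataclass
class SynapseRecoveryResult:
    n_per_class: int
    recall: dict                   # morphology -> fraction called correctly
    calls: dict                    # morphology -> {call: count}
    L_se_values: dict              # morphology -> list of measured L_se
    true_L_se_nm: float

    @property
    def mean_L_se_nm(self) -> float:
        vals = [v for vs in self.L_se_values.values() for v in vs]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def false_Ap_rate_parallel(self) -> float:
        """Ap calls among objects generated as pX or pY."""
        n = sum(sum(self.calls[m].values()) for m in ("pX", "pY"))
        bad = sum(self.calls[m].get("Ap", 0) for m in ("pX", "pY"))
        return bad / n if n else 0.0


def synapse_recovery(
    n_per_class: int = 70,
    seed: int = 0,
    noise_sd_nm: float | None = None,
    persistence_nm: float = 50.0,
    fragment: Fragment | None = None,
    canvas_px: int = 128,
    trace_config: TraceConfig | None = None,
    classify_config: ClassifyConfig | None = None,
) -> SynapseRecoveryResult:
    """Render n synapses per morphology one-per-image, trace and call them.

    ``noise_sd_nm=None`` uses the generator default; pass 0 for noise-free
    rendering.  ``persistence_nm`` very large gives exact (straight-armed)
    geometry.
    """
    fragment = fragment or fragment_r250()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    spec = FieldSpec(size_px=canvas_px, proportions=PROTEIN_PROPORTIONS,
                     persistence_nm=persistence_nm)
    if noise_sd_nm is not None:
        spec.noise_sd_nm = noise_sd_nm
    tcfg = trace_config or TraceConfig()
    ccfg = classify_config or ClassifyConfig()
    recall = {}
    calls = {}
    lse = {}
    for morph in (Morphology.PX, Morphology.PY, Morphology.AP):
        tally = {"pX": 0, "pY": 0, "Ap": 0, "unclassified": 0, "untraced": 0}
        values = []
        for _ in range(n_per_class):
            placed = None
            while placed is None:
                p1, p2, truths = assemble_synapse(
                    fragment, fragment, morph, rng,
                    persistence_nm=persistence_nm, step_bp=spec.step_bp)
                placed = _center_in_canvas([p1, p2], spec.extent_nm, rng)
            for t, pl in zip(truths, placed):
                t.polyline = pl
            img = render_field(truths, spec, rng)
            objects, sg, _ = trace_image(img.data, spec.pixel_size_nm, tcfg)
            crossed = [o for o in objects if o.object_type != "linear"]
            if not crossed:
                tally["untraced"] += 1
                continue
            obj = max(crossed, key=lambda o: o.contour_nm)
            call = classify_crossed_object(obj, spec.pixel_size_nm, fragment, ccfg)
            tally[call.call] += 1
            if call.call == morph.value and call.L_se_nm is not None:
                values.append(call.L_se_nm)
        recall[morph.value] = tally[morph.value] / n_per_class
        calls[morph.value] = tally
        lse[morph.value] = values
    return SynapseRecoveryResult(
        n_per_class=n_per_class, recall=recall, calls=calls,
        L_se_values=lse, true_L_se_nm=fragment.d_closest_end_nm)


@dataclass
class ContourRecoveryResult:
    n_molecules: int
    true_mean_nm: float
    measured_mean_nm: float
    measured_sd_nm: float | None
    rel_error: float


def contour_recovery(
    n_fields: int = 3,
    seed: int = 0,
    noise_sd_nm: float | None = 0.0,
    size_px: int = 384,
    trace_config: TraceConfig | None = None,
) -> ContourRecoveryResult:
    """Trace fields of free molecules and compare measured contour lengths
    with the exact ground-truth contour (83 nm for the 250 bp substrate)."""
    fragment = fragment_r250()
    spec = FieldSpec(size_px=size_px,
                     proportions={Morphology.FREE: 1.0, Morphology.PX: 0.0,
                                  Morphology.PY: 0.0, Morphology.AP: 0.0,
                                  Morphology.INCIDENTAL: 0.0})
    if noise_sd_nm is not None:
        spec.noise_sd_nm = noise_sd_nm
    tcfg = trace_config or TraceConfig()
    measured = []
    for k in range(n_fields):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3, k]))
        img, truths, _ = simulate_field(spec, fragment, rng)
        objects, _, _ = trace_image(img.data, spec.pixel_size_nm, tcfg)
        measured.extend(o.contour_nm for o in objects
                        if o.object_type == "linear" and not o.touches_border)
    measured = np.array(measured)
    true_mean = fragment.L_tot_nm
    return ContourRecoveryResult(
        n_molecules=len(measured),
        true_mean_nm=true_mean,
        measured_mean_nm=float(measured.mean()),
        measured_sd_nm=float(measured.std(ddof=1)) if len(measured) > 1 else None,
        rel_error=float(measured.mean() / true_mean - 1.0),
    )


@dataclass
class CrossedFractionResult:
    condition: str
    replicates: list              # per replicate: estimate, ci, truth fraction
    coverage: float               # fraction of replicates whose CI covers p
    mean_estimate: float
    generator_fraction: float


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054):
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    den = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / den
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / den
    return (max(0.0, centre - half), min(1.0, centre + half))


def crossed_fraction_replicates(
    n_replicates: int = 12,
    fields_per_replicate: int = 2,
    seed: int = 0,
    condition: str = "protein",
    size_px: int = 384,
    trace_config: TraceConfig | None = None,
) -> CrossedFractionResult:
    """Estimate the crossed-molecule fraction per seeded replicate and check
    95% Wilson CI coverage of the generator's mixture fraction."""
    props = PROTEIN_PROPORTIONS if condition == "protein" else NO_PROTEIN_PROPORTIONS
    p_gen = 1.0 - props[Morphology.FREE]
    spec = FieldSpec(size_px=size_px, proportions=props)
    tcfg = trace_config or TraceConfig()
    fragment = fragment_r250()
    reps = []
    covered = 0
    for r in range(n_replicates):
        n_lin = n_crossed_obj = 0
        for k in range(fields_per_replicate):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 4, r, k]))
            img, truths, _ = simulate_field(spec, fragment, rng)
            objects, _, _ = trace_image(img.data, spec.pixel_size_nm, tcfg)
            objects = [o for o in objects if not o.touches_border]
            n_lin += sum(o.object_type == "linear" for o in objects)
            n_crossed_obj += sum(o.object_type != "linear" for o in objects)
        n_mol = n_lin + 2 * n_crossed_obj
        est = 2 * n_crossed_obj / n_mol if n_mol else 0.0
        # molecules arrive in pairs, so the independent sampling unit is the
        # placed object; Wilson CI on the object fraction q, mapped to the
        # molecule fraction p = 2q/(1+q) (monotone, so endpoints transform)
        n_obj = n_lin + n_crossed_obj
        q_lo, q_hi = _wilson_ci(n_crossed_obj, n_obj)
        ci = (2 * q_lo / (1 + q_lo), 2 * q_hi / (1 + q_hi))
        hit = ci[0] <= p_gen <= ci[1]
        covered += hit
        reps.append({"estimate": est, "ci": ci, "n_molecules": n_mol,
                     "covered": bool(hit)})
    return CrossedFractionResult(
        condition=condition,
        replicates=reps,
        coverage=covered / n_replicates,
        mean_estimate=float(np.mean([r["estimate"] for r in reps])),
        generator_fraction=p_gen,
    )


def dimer_selection_rate(
    n_replicates: int = 100,
    seed: int = 0,
    noise_frac: float = 0.02,
    candidates=(1, 2, 3, 4),
) -> dict:
    """How often the band-ladder ranking picks n=2 on gels synthesised from
    the dimer model at the given migration noise."""
    from synaptrace.emsa import enumerate_complexes, infer_stoichiometry, synthesize_gel

    masses = [c.total_mass_kda for c in enumerate_complexes(2)]
    wins = 0
    r2s = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 5, r]))
        mig = synthesize_gel(masses, noise_frac=noise_frac, rng=rng)
        res = infer_stoichiometry(mig, candidates=candidates)
        if res["winner_n"] == 2:
            wins += 1
        top = next(d for d in res["ranking"] if d["n"] == 2)
        if top["r_squared"] is not None:
            r2s.append(top["r_squared"])
    return {"selection_rate": wins / n_replicates,
            "mean_r_squared": float(np.mean(r2s)) if r2s else None,
            "n_replicates": n_replicates,
            "noise_frac": noise_frac}
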