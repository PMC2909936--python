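"""Oligomeric-state inference from tagged/untagged EMSA band patterns.

The subunit-counting trick: mixing an untagged protein (16.4 kDa) with a
TrxA-tagged derivative (33.9 kDa) before adding DNA lets subunits exchange
freely, so an n-mer binding one DNA produces n+1 bands of distinct mass
(k tagged subunits, k = 0..n).  A dimer therefore gives exactly three
bands — the single intermediate band observed — and the bands' migrations
are linear in log10(theoretical mass), which is checked by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
from scipy import stats

DA_PER_BP = 660.0   # average mass of one dsDNA base pair


@dataclass(frozen=True)
class ProteinSpecies:
    name: str
    mass_kda: float

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError("mass must be positive")


#: the untagged DNA-binding transposase derivative and its TrxA fusion
ORFAB149 = ProteinSpecies("OrfAB[1-149]", 16.4)
TRXA_ORFAB149 = ProteinSpecies("TrxA-OrfAB[1-149]", 33.9)


@dataclass(frozen=True)
class ComplexModel:
    """A protein-DNA complex composition with its theoretical mass."""

    n_subunits: int
    n_tagged: int
    species: tuple[ProteinSpecies, ProteinSpecies]
    dna_bp: int
    dna_copies: int
    total_mass_kda: float

    @property
    def label(self) -> str:
        u, t = self.species
        n_un = self.n_subunits - self.n_tagged
        parts = []
        if n_un:
            parts.append(f"{n_un}x{u.name}")
        if self.n_tagged:
            parts.append(f"{self.n_tagged}x{t.name}")
        parts.append(f"{self.dna_copies}x{self.dna_bp}bp")
        return " + ".join(parts)

    def to_json(self) -> dict:
        return {"n_subunits": self.n_subunits, "n_tagged": self.n_tagged,
                "dna_bp": self.dna_bp, "dna_copies": self.dna_copies,
                "total_mass_kda": self.total_mass_kda, "label": self.label}


@dataclass
class GelObservation:
    label: str
    migration_mm: float
    assigned: ComplexModel | None = None

    def __post_init__(self) -> None:
        if self.migration_mm < 0:
            raise ValueError("migration must be non-negative")


def dna_mass(bp: int, da_per_bp: float = DA_PER_BP) -> float:
    """Mass (kDa) of a blunt dsDNA of ``bp`` base pairs."""
    if bp < 0:
        raise ValueError("bp must be non-negative")
    return bp * da_per_bp / 1000.0


def enumerate_complexes(
    n: int,
    species: tuple[ProteinSpecies, ProteinSpecies] = (ORFAB149, TRXA_ORFAB149),
    dna_bp: int = 36,
    dna_copies: int = 1,
    da_per_bp: float = DA_PER_BP,
) -> list[ComplexModel]:
    """All distinguishable compositions of an n-mer on DNA (k tagged,
    k = 0..n), sorted by ascending mass; coincident masses deduplicated."""
    if n < 1:
        raise ValueError("n must be >= 1")
    untagged, tagged = species
    out = []
    seen_masses = []
    for k in range(n + 1):
        mass = ((n - k) * untagged.mass_kda + k * tagged.mass_kda
                + dna_copies * dna_mass(dna_bp, da_per_bp))
        if any(abs(mass - m) < 1e-9 for m in seen_masses):
            import warnings

            warnings.warn("identical species masses: compositions coincide",
                          stacklevel=2)
            continue
        seen_masses.append(mass)
        out.append(ComplexModel(n, k, (untagged, tagged), dna_bp, dna_copies,
                                round(mass, 6)))
    return sorted(out, key=lambda c: c.total_mass_kda)


def dimer_pool(f_tagged: float) -> tuple[float, float, float]:
    """Binomial dimer proportions (untagged2, mixed, tagged2) under free
    subunit exchange at tagged fraction f."""
    if not 0.0 <= f_tagged <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    f = f_tagged
    return ((1 - f) ** 2, 2 * f * (1 - f), f ** 2)


def fit_log_linear(observations: list[GelObservation]) -> dict:
    """Least-squares fit of migration (mm) against log10(assigned mass).

    Returns slope (mm per log10 kDa), intercept, r_squared, n and an
    ``underdetermined`` flag for 2-point fits.
    """
    obs = [o for o in observations if o.assigned is not None]
    masses = [o.assigned.total_mass_kda for o in obs]
    if len(set(np.round(masses, 9))) < 2:
        raise ValueError("need >= 2 observations with distinct assigned masses")
    x = np.log10(masses)
    y = np.array([o.migration_mm for o in obs])
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "n": len(obs),
        "underdetermined": len(obs) == 2,
    }


def _best_assignment_r2(masses: np.ndarray, migrations: np.ndarray) -> tuple[float, list]:
    """Best order-preserving assignment of model masses to observed bands.

    Bands sorted by decreasing migration (fast to slow) pair with masses in
    increasing order; when counts differ the better-fitting subset of the
    larger side is chosen.  Returns (r2, pairs) with pairs as
    (mass, migration).
    """
    masses = np.sort(masses)
    order = np.argsort(-migrations)
    mig = migrations[order]
    nm, nb = len(masses), len(mig)
    k = min(nm, nb)
    if k < 2:
        return -np.inf, []
    best = (-np.inf, [])
    big_is_mass = nm >= nb
    big = masses if big_is_mass else mig
    small = mig if big_is_mass else masses
    for idx in combinations(range(len(big)), k):
        m = big[list(idx)] if big_is_mass else small
        g = small if big_is_mass else big[list(idx)]
        x, y = np.log10(m), g
        if np.ptp(x) == 0:
            continue
        r = stats.linregress(x, y)
        r2 = float(r.rvalue ** 2)
        if r2 > best[0]:
            best = (r2, list(zip(m, g)))
    return best


def infer_stoichiometry(
    migrations: list[float],
    candidates: list[int] = (1, 2, 3, 4),
    species: tuple[ProteinSpecies, ProteinSpecies] = (ORFAB149, TRXA_ORFAB149),
    dna_bp: int = 36,
    dna_copies: int = 1,
) -> dict:
    """Rank candidate oligomer sizes against an observed band ladder.

    Each candidate n predicts n+1 distinct masses; candidates are ranked by
    band-count match first, then by r^2 of the best order-preserving
    mass-to-band assignment.  Migration must decrease with mass (slope < 0)
    for a fit to count as consistent.
    """
    mig = np.asarray(migrations, dtype=float)
    if len(mig) < 2:
        raise ValueError("need at least 2 bands")
    ranking = []
    for n in candidates:
        models = enumerate_complexes(n, species, dna_bp, dna_copies)
        masses = np.array([m.total_mass_kda for m in models])
        count_match = len(models) == len(mig)
        r2, pairs = _best_assignment_r2(masses, mig)
        ranking.append({
            "n": n,
            "n_bands_predicted": len(models),
            "count_match": bool(count_match),
            "r_squared": r2 if np.isfinite(r2) else None,
            "assignment": [[float(a), float(b)] for a, b in pairs],
        })
    ranking.sort(key=lambda d: (d["count_match"],
                                -np.inf if d["r_squared"] is None else d["r_squared"]),
                 reverse=True)
    return {
        "winner_n": ranking[0]["n"] if ranking else None,
        "any_count_match": any(d["count_match"] for d in ranking),
        "ranking": ranking,
    }


def synthesize_gel(
    masses,
    slope: float = -60.0,
    intercept: float = 150.0,
    noise_frac: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> list[float]:
    """Synthetic band migrations mu = intercept + slope*log10(M), with
    multiplicative Gaussian migration noise (default 1%)."""
    rng = np.random.default_rng(rng)
    mu = intercept + slope * np.log10(np.asarray(masses, dtype=float))
    mu = mu * (1.0 + rng.normal(0.0, noise_frac, size=mu.shape))
    return [float(m) for m in mu]


def read_band_table(path):
    """Band table CSV (label, migration_mm) -> GelObservation list."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"label", "migration_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    return [GelObservation(str(r.label), float(r.migration_mm))
            for r in df.itertuples()]
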