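"""Sequence handling and bp/nm geometry for IRR-carrying DNA fragments.

The EMSA and AFM substrates are linear fragments built as
``5'-[internal flank]-[36 bp IRR]-[external flank]-3'``; the transposase
footprint (~22 bp of the 20-25 bp protected region) sits asymmetrically
inside the IRR, which is what makes the relative orientation of two paired
fragments readable from arm lengths in an image.

Coordinates are 0-based, half-open, with position 0 at the 5' end of the
internal flank.  Lengths convert to nm with a helical rise of 0.332 nm/bp,
the value consistent with the fragment sizes as reported (250 bp = 83 nm,
66 bp = 22 nm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Right inverted repeat of IS911, top strand (IRRa) and bottom strand (IRRb).
IRRA_SEQ = "TGAAGTGGTCAACAAAAACTGGCCACCGAGTTAGAG"
IRRB_SEQ = "CTCTAACTCGGTGGCCAGTTTTTGTTGACCACTTCA"


class SequenceError(ValueError):
    """Raised for malformed DNA sequences."""


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in "ACGT":
            raise SequenceError(f"non-ACGT character {c!r} at position {i}")
    return seq


@dataclass(frozen=True)
class IRSequence:
    """A named inverted-repeat sequence, 5'->3'."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _check_dna(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


IRRA = IRSequence("IRRa", IRRA_SEQ)
IRRB = IRSequence("IRRb", IRRB_SEQ)


@dataclass(frozen=True)
class GeometryConstants:
    """Physical constants for bp <-> nm conversion and binding-site extent.

    rise_nm_per_bp : helical rise of B-DNA as deposited; 0.332 nm/bp
        reproduces the printed fragment sizes exactly.
    footprint_span_bp : span of the protected transposase binding site
        (middle of the reported 20-25 bp range).
    binding_site_offset_bp : distance from the external tip of the IR to the
        external edge of the footprint.  16 bp places the footprint edge
        66 bp from the external end of a fragment with a 50 bp external
        flank, matching the measured binding-site position.
    """

    rise_nm_per_bp: float = 0.332
    footprint_span_bp: int = 22
    binding_site_offset_bp: int = 16

    def __post_init__(self) -> None:
        if self.rise_nm_per_bp <= 0:
            raise ValueError("rise must be positive")


DEFAULT_CONSTANTS = GeometryConstants()


@dataclass(frozen=True)
class FragmentSpec:
    """Composition of a linear fragment: internal flank | IR | external flank."""

    internal_flank_bp: int
    ir: IRSequence
    external_flank_bp: int

    def __post_init__(self) -> None:
        if self.internal_flank_bp < 0 or self.external_flank_bp < 0:
            raise ValueError("flank lengths must be non-negative")

    @property
    def total_bp(self) -> int:
        return self.internal_flank_bp + len(self.ir) + self.external_flank_bp


@dataclass(frozen=True)
class Fragment:
    """An annotated linear DNA fragment.

    binding_interval_bp is the half-open footprint interval along the
    fragment; d_closest_end_bp is the distance from the footprint to the
    nearer fragment end (66 bp for the 250 bp AFM substrate).
    """

    seq: str
    spec: FragmentSpec
    constants: GeometryConstants
    binding_interval_bp: tuple[int, int]

    @property
    def L_tot_bp(self) -> int:
        return len(self.seq)

    @property
    def L_tot_nm(self) -> float:
        return bp_to_nm(self.L_tot_bp, self.constants)

    @property
    def d_closest_end_bp(self) -> int:
        lo, hi = self.binding_interval_bp
        return min(lo, self.L_tot_bp - hi)

    @property
    def d_closest_end_nm(self) -> float:
        return bp_to_nm(self.d_closest_end_bp, self.constants)

    @property
    def closest_end(self) -> str:
        """Which fragment end ('internal' at bp 0 or 'external') is nearer
        to the binding site.  Ties resolve to 'external'."""
        lo, hi = self.binding_interval_bp
        return "internal" if lo < self.L_tot_bp - hi else "external"

    @property
    def crossing_bp(self) -> int:
        """bp coordinate where a synapse pairs this fragment: the footprint
        edge facing the closest end."""
        lo, hi = self.binding_interval_bp
        return lo if self.closest_end == "internal" else hi

    @property
    def centred(self) -> bool:
        """True when the binding site is no nearer to one end than L_tot/2
        (an orientation-uninformative substrate)."""
        return self.d_closest_end_bp >= self.L_tot_bp / 2 - max(
            0, self.binding_interval_bp[1] - self.binding_interval_bp[0]
        )

    def report(self) -> dict:
        return {
            "L_tot_bp": self.L_tot_bp,
            "L_tot_nm": self.L_tot_nm,
            "binding_interval_bp": list(self.binding_interval_bp),
            "d_closest_end_bp": self.d_closest_end_bp,
            "d_closest_end_nm": self.d_closest_end_nm,
            "closest_end": self.closest_end,
            "crossing_bp": self.crossing_bp,
            "internal_flank_bp": self.spec.internal_flank_bp,
            "external_flank_bp": self.spec.external_flank_bp,
            "ir_name": self.spec.ir.name,
        }

    def report_json(self) -> str:
        return json.dumps(self.report(), indent=2)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string (an involution)."""
    return _check_dna(seq).translate(_COMPLEMENT)[::-1]


def hybridize(a: IRSequence, b: IRSequence) -> dict:
    """Check whether two oligos anneal into a perfect duplex.

    Returns {'length_bp', 'perfect', 'mismatches'} where mismatches lists
    positions (along ``a``) at which ``b`` fails to base-pair.  A length
    mismatch is reported as imperfect with ``mismatches=None``.
    """
    if not a.seq or not b.seq:
        raise SequenceError("empty sequence cannot hybridize")
    if len(a) != len(b):
        return {"length_bp": None, "perfect": False, "mismatches": None,
                "detail": f"length mismatch {len(a)} vs {len(b)}"}
    expected = reverse_complement(a.seq)
    mismatches = [i for i, (x, y) in enumerate(zip(expected, b.seq)) if x != y]
    return {
        "length_bp": len(a) if not mismatches else None,
        "perfect": not mismatches,
        "mismatches": mismatches,
    }


def bp_to_nm(n: float, constants: GeometryConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a bp count to contour nm (linear, exact; round only to print)."""
    if n < 0:
        raise ValueError("bp count must be non-negative")
    return n * constants.rise_nm_per_bp


def _flank_fill(n: int, seed: int) -> str:
    """Deterministic pseudo-random flank sequence (the fragments' flanking
    plasmid sequence is irrelevant to the geometry; only length matters)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def build_fragment(
    spec: FragmentSpec,
    constants: GeometryConstants = DEFAULT_CONSTANTS,
) -> Fragment:
    """Assemble an annotated fragment from its composition.

    The footprint interval is placed inside the IR such that its external
    edge lies ``binding_site_offset_bp`` inward from the external IR tip and
    spans ``footprint_span_bp`` toward the internal side (it may protrude
    into the internal flank for short IRs, as protection footprints do).
    """
    i, e = spec.internal_flank_bp, spec.external_flank_bp
    seq = _flank_fill(i, seed=20100616) + spec.ir.seq + _flank_fill(e, seed=16)
    ir_end = i + len(spec.ir)  # external tip of the IR
    hi = ir_end - constants.binding_site_offset_bp
    lo = max(0, hi - constants.footprint_span_bp)
    if hi <= 0:
        raise ValueError("binding-site offset places footprint outside fragment")
    return Fragment(seq=seq, spec=spec, constants=constants,
                    binding_interval_bp=(lo, hi))


def fragment_r100(constants: GeometryConstants = DEFAULT_CONSTANTS) -> Fragment:
    """The 100 bp EMSA substrate: 14 bp internal | IRR | 50 bp external."""
    return build_fragment(FragmentSpec(14, IRRA, 50), constants)


def fragment_r250(constants: GeometryConstants = DEFAULT_CONSTANTS) -> Fragment:
    """The 250 bp AFM substrate: 164 bp internal | IRR | 50 bp external.

    Its binding site lies 66 bp (22 nm) from the external end, the asymmetry
    that makes synapse orientation readable."""
    return build_fragment(FragmentSpec(164, IRRA, 50), constants)


def read_fasta(path) -> list[IRSequence]:
    """Read sequences from a FASTA file into IRSequence records."""
    from Bio import SeqIO

    return [IRSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[IRSequence], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord

    _write([SeqRecord(Seq(r.seq), id=r.name, description="") for r in records],
           str(path), "fasta")
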