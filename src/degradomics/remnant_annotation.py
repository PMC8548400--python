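"""Ubiquitin C-terminal remnants and branched (isopeptide) peptide evidence.

When a proteasome proteolyzes a ubiquitin conjugate around the isopeptide
bond, a short C-terminal stub of ubiquitin (…LRLRGG) can remain linked to
the substrate lysine, yielding a branched peptide: a backbone peptide from
the substrate plus a GG / RGG / LRGG remnant hanging off a lysine side
chain.  This module enumerates remnants, computes their added monoisotopic
masses (for configuring search-engine variable modifications), validates
branched peptides reported upstream against a substrate's declared anchor
lysines, and classifies peptides that straddle fusion-construct junctions
(chimeric peptides, evidence that an entire tagged ubiquitin chain was
proteolyzed).

Remnants are stored canonically N-to-C ("RGG"); the outward, lysine-first
notation ("GGR") common in figures is accepted on input and converted by
reversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_io import PeptideObservation, Segment, SubstrateRecord, ValidationError
from .peptide_mapping import map_peptide

#: Monoisotopic residue masses, Da (versioned fixture; Unimod/expasy values).
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


@dataclass(frozen=True)
class RemnantSpec:
    """A ubiquitin C-terminal remnant.

    ``sequence`` runs N-to-C (e.g. "RGG"); ``paper_notation`` is the
    outward, lysine-first rendering (e.g. "GGR").  ``mono_mass`` is the
    added mass on the branch lysine (sum of residue masses, no extra
    water — the isopeptide bond condenses one water exactly as a backbone
    bond does).
    """

    sequence: str
    mono_mass: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def paper_notation(self) -> str:
        return self.sequence[::-1]


@dataclass(frozen=True)
class BranchedPeptideAnnotation:
    base_peptide: str
    branch_position: int
    remnant: str
    substrate_id: str
    anchor_residue: Optional[int]
    valid: bool
    reason: str


def remnant_mass(sequence: str) -> float:
    """Added monoisotopic mass (Da) of a remnant on a lysine side chain."""
    try:
        return sum(MONOISOTOPIC_RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r} in remnant") from None


def enumerate_remnants(
    ubiquitin: SubstrateRecord, min_len: int = 2, max_len: int = 4
) -> list[RemnantSpec]:
    """One remnant per length: the ubiquitin C-terminal suffix of that length.

    The default 2..4 range covers the detected GG, RGG and LRGG variants.
    """
    n = len(ubiquitin)
    if not (1 <= min_len <= max_len <= n):
        raise ValidationError(f"remnant length bounds ({min_len}, {max_len}) invalid")
    out = []
    for length in range(min_len, max_len + 1):
        seq = ubiquitin.sequence[n - length:]
        out.append(RemnantSpec(sequence=seq, mono_mass=remnant_mass(seq)))
    return out


def canonicalize_remnant(remnant: str, ubiquitin: SubstrateRecord) -> Optional[str]:
    """Return the N-to-C form of ``remnant`` if it is a ubiquitin C-suffix.

    Accepts either orientation ("RGG" or the outward "GGR"); returns None
    when neither reading is a ubiquitin C-terminal suffix.
    """
    remnant = remnant.upper()
    for candidate in (remnant, remnant[::-1]):
        if candidate and ubiquitin.sequence.endswith(candidate):
            return candidate
    return None


def annotate_branched_peptide(
    observation: PeptideObservation,
    substrate: SubstrateRecord,
    ubiquitin: SubstrateRecord,
) -> BranchedPeptideAnnotation:
    """Validate and localize a reported branched peptide.

    Valid iff (i) the remnant is a ubiquitin C-terminal suffix, (ii) the
    base peptide maps uniquely onto the substrate, and (iii) the branch
    lysine lands on a declared anchor lysine.  Invalid annotations carry a
    machine-readable reason.  Identification itself (spectral search with
    variable lysine modifications) is upstream of this module.
    """
    if observation.branch is None:
        raise ValidationError("observation carries no branch record")
    pos, remnant_in = observation.branch
    base = observation.sequence

    def fail(reason: str, anchor: Optional[int] = None) -> BranchedPeptideAnnotation:
        return BranchedPeptideAnnotation(
            base_peptide=base, branch_position=pos, remnant=remnant_in,
            substrate_id=substrate.id, anchor_residue=anchor,
            valid=False, reason=reason,
        )

    canonical = canonicalize_remnant(remnant_in, ubiquitin)
    if canonical is None:
        return fail("not-a-ubiquitin-suffix")
    hits = map_peptide(base, substrate)
    if not hits:
        return fail("unmapped")
    if len(hits) > 1:
        return fail("ambiguous-mapping")
    start, _ = hits[0]
    anchor = start + pos - 1
    if anchor not in substrate.anchor_lysines:
        return fail("not-an-anchor-lysine", anchor)
    return BranchedPeptideAnnotation(
        base_peptide=base, branch_position=pos, remnant=canonical,
        substrate_id=substrate.id, anchor_residue=anchor,
        valid=True, reason="ok",
    )


def classify_junction(
    peptide_interval: tuple[int, int], construct: list[Segment]
) -> tuple[str, list[str]]:
    """Classify a mapped interval against a fusion construct's segments.

    Returns ``("within_segment", [name])`` when the interval overlaps a
    single segment, ``("chimeric", names)`` when it spans two or more
    (junction-spanning evidence), and ``("unannotated", [])`` when it
    overlaps none.
    """
    start, end = peptide_interval
    if start > end:
        raise ValidationError(f"invalid interval ({start}, {end})")
    overlapped = [s.name for s in construct if start <= s.end and end >= s.start]
    if not overlapped:
        return "unannotated", []
    if len(overlapped) == 1:
        return "within_segment", overlapped
    return "chimeric", overlapped


def variable_modification_lines(
    ubiquitin: SubstrateRecord, min_len: int = 2, max_len: int = 4
) -> list[str]:
    """Search-engine variable-modification list: remnant masses on K."""
    return [
        f"{spec.mono_mass:.5f} K  # {spec.sequence} (outward {spec.paper_notation})"
        for spec in enumerate_remnants(ubiquitin, min_len, max_len)
    ]
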