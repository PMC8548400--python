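"""Mapping non-tryptic peptides onto substrate sequences.

A degradation product carries no enzyme-specificity constraint, so each
peptide is located by exact substring search over the substrate.  An
internal peptide spanning residues ``start..end`` is evidence for two
cleavage events: one at the bond ``start - 1`` (absent when the peptide
begins at the substrate N-terminus) and one at the bond ``end`` (absent at
the C-terminus).  Peptides matching at several positions are flagged
ambiguous and, by default, excluded from site-count integration to avoid
double counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core_io import PeptideTable, SubstrateRecord, ValidationError, logger

_IL_TABLE = str.maketrans("IL", "JJ")  # collapse isoleucine/leucine


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide located on a substrate (1-based inclusive coordinates)."""

    sequence: str
    substrate_id: str
    start: int
    end: int
    ambiguous: bool
    n_term_site: Optional[int]
    c_term_site: Optional[int]


def map_peptide(
    sequence: str, substrate: SubstrateRecord, il_equivalence: bool = False
) -> list[tuple[int, int]]:
    """All occurrences of ``sequence`` in the substrate, sorted by start.

    Overlapping occurrences are all reported.  With ``il_equivalence`` the
    isobaric residues I and L are treated as identical, as a search engine
    cannot distinguish them by fragment mass.  An empty list is a valid
    no-match result, not an error.
    """
    if not sequence:
        raise ValidationError("peptide sequence must be non-empty")
    hay, needle = substrate.sequence, sequence.upper()
    if il_equivalence:
        hay, needle = hay.translate(_IL_TABLE), needle.translate(_IL_TABLE)
    hits = []
    pos = hay.find(needle)
    while pos != -1:
        hits.append((pos + 1, pos + len(needle)))
        pos = hay.find(needle, pos + 1)
    return hits


def derive_sites(
    start: int, end: int, substrate_length: int
) -> tuple[Optional[int], Optional[int]]:
    """Cleavage sites bounding a product at ``start..end``.

    Returns ``(n_term_site, c_term_site)`` where a terminus-touching end has
    no internal cleavage site (``None``).
    """
    if not (1 <= start <= end <= substrate_length):
        raise ValidationError(
            f"coordinates ({start}, {end}) outside 1..{substrate_length}"
        )
    n_site = start - 1 if start > 1 else None
    c_site = end if end < substrate_length else None
    return n_site, c_site


def map_table(
    table: PeptideTable,
    substrate: SubstrateRecord,
    il_equivalence: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map every observation of ``table`` onto ``substrate``.

    Returns ``(mapped, unmapped)``.  ``mapped`` has one row per observation
    and occurrence with columns
    ``sample_id, condition, replicate, sequence, psm_count, branch_pos,
    branch_remnant, substrate_id, start, end, ambiguous, n_term_site,
    c_term_site``.  Observations with no occurrence are routed to the
    ``unmapped`` table (same columns as the input), not treated as errors.
    """
    mapped_rows, unmapped_idx = [], []
    n = len(substrate)
    cache: dict[str, list[tuple[int, int]]] = {}
    for idx, row in table.frame.iterrows():
        seq = row["sequence"]
        if seq not in cache:
            cache[seq] = map_peptide(seq, substrate, il_equivalence)
        hits = cache[seq]
        if not hits:
            unmapped_idx.append(idx)
            continue
        ambiguous = len(hits) > 1
        for start, end in hits:
            n_site, c_site = derive_sites(start, end, n)
            mapped_rows.append(
                {
                    **row.to_dict(),
                    "substrate_id": substrate.id,
                    "start": start,
                    "end": end,
                    "ambiguous": ambiguous,
                    "n_term_site": n_site,
                    "c_term_site": c_site,
                }
            )
    mapped = pd.DataFrame(
        mapped_rows,
        columns=list(table.frame.columns)
        + ["substrate_id", "start", "end", "ambiguous", "n_term_site", "c_term_site"],
    )
    unmapped = table.frame.loc[unmapped_idx].reset_index(drop=True)
    if len(unmapped):
        logger.info(
            "%d observation(s) did not map to %s", len(unmapped), substrate.id
        )
    n_amb = mapped.loc[mapped["ambiguous"], "sequence"].nunique() if len(mapped) else 0
    if n_amb:
        logger.info("%d peptide sequence(s) map ambiguously on %s", n_amb, substrate.id)
    return mapped, unmapped


def filter_replicates(
    table: PeptideTable, min_replicates: int = 2
) -> PeptideTable:
    """Replicate-presence filter, applied per condition.

    A peptide sequence is retained within a condition iff it was observed
    (PSM count >= 1) in at least ``min_replicates`` distinct replicates of
    that condition; retained observations keep their original counts.  With
    ``min_replicates=1`` every observed peptide passes (the in-vivo variant
    of the filter).
    """
    frame = table.frame
    if frame.empty:
        return PeptideTable(frame.copy(), provenance=table.provenance)
    n_reps = frame.groupby("condition")["replicate"].nunique()
    if min_replicates > int(n_reps.max()):
        raise ValidationError(
            f"min_replicates={min_replicates} exceeds the {int(n_reps.max())} "
            "replicate(s) present"
        )
    observed = frame[frame["psm_count"] >= 1]
    support = observed.groupby(["condition", "sequence"])["replicate"].nunique()
    keep_keys = set(support[support >= min_replicates].index)
    mask = [
        (cond, seq) in keep_keys
        for cond, seq in zip(frame["condition"], frame["sequence"])
    ]
    kept = frame[mask].reset_index(drop=True)
    logger.info(
        "replicate filter (>=%d): kept %d of %d observations",
        min_replicates,
        len(kept),
        len(frame),
    )
    return PeptideTable(kept, provenance=table.provenance)
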