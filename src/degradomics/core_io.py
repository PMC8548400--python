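"""Domain types and file I/O for degradation-product peptidomics.

The package analyses non-tryptic peptide products released when a proteasome
(the 20S core particle alone, or the 26S holoenzyme) digests a substrate.
Everything downstream operates on three kinds of input:

* substrate sequences (FASTA), optionally annotated with fusion-construct
  segments and "anchor" lysines expected to carry ubiquitin-remnant branches;
* identified-peptide tables (TSV) with sample / condition / replicate /
  peptide / PSM-count columns, where a PSM (peptide-spectrum match) count is
  the per-peptide "MS/MS count" reported by the upstream search engine;
* per-residue intrinsic-disorder score tracks (TSV, IUPRED-style, values in
  [0, 1]).

Residue coordinates are 1-based inclusive throughout the package.  Cleavage
site ``j`` denotes the peptide bond between residues ``j`` and ``j + 1``, so
residue ``j`` occupies the P1 position of that bond.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("degradomics")

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

PEPTIDE_COLUMNS = [
    "sample_id",
    "condition",
    "replicate",
    "sequence",
    "psm_count",
    "branch_pos",
    "branch_remnant",
]


class FormatError(ValueError):
    """Malformed input file (bad alphabet, missing column, ...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """A named stretch of a fusion construct (1-based, inclusive)."""

    name: str
    start: int
    end: int


@dataclass
class SubstrateRecord:
    """A substrate amino-acid sequence with optional construct annotations.

    Parameters
    ----------
    id : str
        Record identifier.
    sequence : str
        Upper-case amino-acid sequence over the 20 canonical letters.
    segments : list of Segment
        Non-overlapping, sorted annotations of fusion-construct parts
        (epitope tags, ubiquitin units, the substrate region itself).
    anchor_lysines : list of int
        Residue indices expected to carry isopeptide-linked ubiquitin
        remnants; each must point at a lysine.
    """

    id: str
    sequence: str
    segments: list[Segment] = field(default_factory=list)
    anchor_lysines: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("substrate sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(CANONICAL_AA)
        if bad:
            raise FormatError(
                f"non-canonical residue(s) {sorted(bad)} in substrate {self.id!r}"
            )
        n = len(self.sequence)
        prev_end = 0
        for seg in self.segments:
            if not (1 <= seg.start <= seg.end <= n):
                raise ValidationError(f"segment {seg} outside 1..{n}")
            if seg.start <= prev_end:
                raise ValidationError("segments must be sorted and non-overlapping")
            prev_end = seg.end
        for k in self.anchor_lysines:
            if not (1 <= k <= n) or self.sequence[k - 1] != "K":
                raise ValidationError(
                    f"anchor residue {k} of {self.id!r} is not a lysine"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, i: int) -> str:
        """Residue at 1-based index ``i``."""
        return self.sequence[i - 1]


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide in one sample, with its PSM (MS/MS) count."""

    sample_id: str
    condition: str
    replicate: int
    sequence: str
    psm_count: int
    branch: Optional[tuple[int, str]] = None  # (1-based position in peptide, remnant N->C)

    def __post_init__(self) -> None:
        if self.psm_count < 0:
            raise ValidationError("psm_count must be non-negative")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")
        if self.branch is not None:
            pos, _ = self.branch
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "K":
                raise ValidationError(
                    f"branch position {pos} of {self.sequence} is not a lysine"
                )


@dataclass
class PeptideTable:
    """A deduplicated table of peptide observations.

    Internally a :class:`pandas.DataFrame` with columns
    ``sample_id, condition, replicate, sequence, psm_count, branch_pos,
    branch_remnant``; rows unique per ``(sample_id, sequence, branch)``
    with duplicate PSM counts summed (PSMs are additive evidence).
    """

    frame: pd.DataFrame
    provenance: str = "in-memory"

    def __post_init__(self) -> None:
        missing = [c for c in PEPTIDE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"peptide table missing columns {missing}")
        self.frame = dedupe_frame(self.frame[PEPTIDE_COLUMNS])

    @classmethod
    def from_observations(
        cls, observations: Iterable[PeptideObservation], provenance: str = "in-memory"
    ) -> "PeptideTable":
        rows = []
        for o in observations:
            pos, rem = (o.branch if o.branch is not None else (np.nan, None))
            rows.append(
                (o.sample_id, o.condition, o.replicate, o.sequence, o.psm_count, pos, rem)
            )
        frame = pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)
        return cls(frame, provenance=provenance)

    @property
    def observations(self) -> list[PeptideObservation]:
        out = []
        for row in self.frame.itertuples(index=False):
            branch = None
            if pd.notna(row.branch_pos):
                branch = (int(row.branch_pos), str(row.branch_remnant))
            out.append(
                PeptideObservation(
                    sample_id=row.sample_id,
                    condition=row.condition,
                    replicate=int(row.replicate),
                    sequence=row.sequence,
                    psm_count=int(row.psm_count),
                    branch=branch,
                )
            )
        return out

    def total_psms(self) -> pd.Series:
        """Per-sample PSM totals."""
        return self.frame.groupby("sample_id")["psm_count"].sum()

    def __len__(self) -> int:
        return len(self.frame)


def dedupe_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Sum PSM counts over duplicate ``(sample, sequence, branch)`` keys."""
    if frame.empty:
        return frame.reset_index(drop=True)
    bad = frame["psm_count"] < 0
    if bad.any():
        raise ValidationError("negative psm_count in peptide table")
    keys = ["sample_id", "condition", "replicate", "sequence", "branch_pos", "branch_remnant"]
    before = len(frame)
    out = (
        frame.groupby(keys, dropna=False, as_index=False, sort=False)["psm_count"]
        .sum()[PEPTIDE_COLUMNS]
        .reset_index(drop=True)
    )
    if len(out) != before:
        logger.info("dedup: %d rows merged into %d", before, len(out))
    return out


@dataclass
class DisorderTrack:
    """Per-residue intrinsic-disorder scores for one protein (values in [0,1])."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValidationError(f"empty disorder track for {self.protein_id!r}")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValidationError(f"disorder scores outside [0,1] for {self.protein_id!r}")


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis.

    Defaults follow the study design: peptides must appear in 2 of 3
    replicates; zero integrated counts are replaced by the pseudo-value 0.1
    in the preference ratio; a two-fold ratio flags a site preference;
    samples with < 50 total PSMs are dropped from the occupancy matrix; the
    sample ordination uses the top 100 peptides; and the MS search strategy
    does not reliably identify products shorter than ~7 residues.
    """

    min_replicates: int = 2
    pseudo_value: float = 0.1
    fold_threshold: float = 2.0
    min_sample_psms: int = 50
    top_n_peptides: int = 100
    il_equivalence: bool = False
    preference_normalization: str = "raw"  # {"raw", "cpm"}
    detection_floor: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_replicates",
            "pseudo_value",
            "fold_threshold",
            "min_sample_psms",
            "top_n_peptides",
            "detection_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.preference_normalization not in ("raw", "cpm"):
            raise ValidationError("preference_normalization must be 'raw' or 'cpm'")

    def as_header_items(self) -> list[tuple[str, object]]:
        return [(f.name, getattr(self, f.name)) for f in dataclasses.fields(self)]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def load_substrate(
    path: str | Path,
    name: Optional[str] = None,
    segments: Optional[Sequence[tuple[str, int, int]]] = None,
    anchor_lysines: Optional[Sequence[int]] = None,
) -> SubstrateRecord:
    """Read a substrate from FASTA.

    ``name`` selects a record from a multi-record file; a single-record file
    needs no selection.  Lower-case input is upcased; any character outside
    the 20 canonical letters raises :class:`FormatError`.
    """
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if name is None:
        if len(records) > 1:
            raise ValidationError(
                f"{path} holds {len(records)} records; pass name= to select one"
            )
        name, seq = next(iter(records.items()))
    else:
        try:
            seq = records[name]
        except KeyError:
            raise ValidationError(f"record {name!r} not found in {path}") from None
    return SubstrateRecord(
        id=name,
        sequence=seq,
        segments=[Segment(*s) for s in (segments or [])],
        anchor_lysines=list(anchor_lysines or []),
    )


def load_peptides(path: str | Path, dialect: str = "generic") -> PeptideTable:
    """Read an identified-peptide TSV.

    ``dialect="generic"`` expects columns ``sample_id, condition, replicate,
    peptide, psm_count`` (optional ``branch_pos, branch_remnant``).
    ``dialect="maxquant"`` accepts a MaxQuant ``peptides.txt`` layout:
    per-experiment ``MS/MS Count <experiment>`` columns are melted into long
    form; otherwise a single ``MS/MS Count`` column (with an optional
    ``Experiment`` column) is used.  Rows with zero counts are dropped;
    duplicate keys are summed.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if dialect == "generic":
        frame = _ingest_generic(raw, path)
    elif dialect == "maxquant":
        frame = _ingest_maxquant(raw, path)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    if frame.empty:
        logger.warning("no peptide observations in %s", path)
    table = PeptideTable(frame, provenance=f"{path} ({dialect})")
    logger.info("loaded %d observations from %s", len(table), path)
    return table


def _ingest_generic(raw: pd.DataFrame, path) -> pd.DataFrame:
    required = ["sample_id", "condition", "replicate", "peptide", "psm_count"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    frame = pd.DataFrame(
        {
            "sample_id": raw["sample_id"],
            "condition": raw["condition"],
            "replicate": pd.to_numeric(raw["replicate"]).astype(int),
            "sequence": raw["peptide"].str.upper(),
            "psm_count": pd.to_numeric(raw["psm_count"]).astype(int),
            "branch_pos": pd.to_numeric(raw["branch_pos"], errors="coerce")
            if "branch_pos" in raw.columns
            else np.nan,
            "branch_remnant": raw.get("branch_remnant", None),
        }
    )
    return frame


def _ingest_maxquant(raw: pd.DataFrame, path) -> pd.DataFrame:
    seq_col = "Sequence"
    if seq_col not in raw.columns:
        raise FormatError(f"{path}: MaxQuant dialect requires a 'Sequence' column")
    per_exp = [c for c in raw.columns if c.lower().startswith("ms/ms count ")]
    rows = []
    if per_exp:
        for col in per_exp:
            exp = col[len("MS/MS Count "):].strip()
            counts = pd.to_numeric(raw[col], errors="coerce").fillna(0).astype(int)
            for seq, n in zip(raw[seq_col], counts):
                if n > 0:
                    rows.append((exp, exp, 1, seq.upper(), n, np.nan, None))
    else:
        count_col = next(
            (c for c in raw.columns if c.lower() == "ms/ms count"), None
        )
        if count_col is None:
            raise FormatError(f"{path}: no 'MS/MS Count' column in MaxQuant table")
        exps = raw["Experiment"] if "Experiment" in raw.columns else "sample"
        counts = pd.to_numeric(raw[count_col], errors="coerce").fillna(0).astype(int)
        for seq, n, exp in zip(raw[seq_col], counts, np.broadcast_to(exps, len(raw))):
            if n > 0:
                rows.append((str(exp), str(exp), 1, seq.upper(), n, np.nan, None))
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def load_disorder_tracks(path: str | Path) -> dict[str, DisorderTrack]:
    """Read per-residue disorder scores (TSV: protein_id, residue_index, score)."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    required = ["protein_id", "residue_index", "score"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    tracks = {}
    for pid, grp in raw.groupby("protein_id", sort=False):
        grp = grp.sort_values("residue_index")
        idx = grp["residue_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValidationError(f"{path}: residue indices of {pid!r} not contiguous from 1")
        tracks[str(pid)] = DisorderTrack(str(pid), grp["score"].to_numpy(float))
    return tracks


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def write_table(
    result: pd.DataFrame,
    path: str | Path,
    config: Optional[AnalysisConfig] = None,
    extra_header: Optional[dict] = None,
) -> None:
    """Write a tabular result as TSV with a '#'-prefixed config header.

    Floats are serialized at six significant digits, NA values as ``"NA"``;
    column order is preserved so the matching reader round-trips values.
    """
    path = Path(path)
    lines = []
    if config is not None:
        for key, value in config.as_header_items():
            lines.append(f"# {key} = {value}")
    for key, value in (extra_header or {}).items():
        lines.append(f"# {key} = {value}")
    body = result.to_csv(sep="\t", index=False, float_format="%.6g", na_rep="NA")
    try:
        path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("degradomics").joinpath("data", name)))


def cyclin_b1_nt() -> SubstrateRecord:
    """The 88-residue disordered N-terminal region of human cyclin B1.

    Synthetic transcription of the construct sequence: it carries the
    APC/C destruction-box degron (R42..N50) and 15 lysines, of which K64 is
    the declared isopeptide anchor used for chemical ubiquitination.
    """
    return load_substrate(
        _fixture_path("cyclin_b1_nt.fasta"),
        segments=[("degron", 42, 50)],
        anchor_lysines=[64],
    )


def cyclin_b1_nt_k64() -> SubstrateRecord:
    """The K64-only Cyclin B1-NT variant (all Lys->Arg except K64).

    Synthetic transcription of the chemically synthesized substrate used in
    the in-vitro digestions, where K64 is the single ubiquitination site.
    """
    return load_substrate(
        _fixture_path("cyclin_b1_nt_k64.fasta"),
        segments=[("degron", 42, 50)],
        anchor_lysines=[64],
    )


def ubiquitin() -> SubstrateRecord:
    """Human ubiquitin (76 aa); its C-terminus ...LRLRGG sources the remnants."""
    return load_substrate(_fixture_path("ubiquitin.fasta"))
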