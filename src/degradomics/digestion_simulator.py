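"""Synthetic two-condition, replicated, non-tryptic digestion tables.

The generator emulates the statistical structure of the study design — two
enzyme conditions digesting the same substrate in triplicate, with
site-specific cleavage preferences, a bounded product-length window, a
detection floor below which products are censored (the MS search strategy
cannot reliably identify peptides shorter than ~7 residues), PSM-count
sampling, and optional branched peptides at anchor lysines.  It makes no
claim to model enzyme kinetics: each detected product is drawn by two
independent boundary picks (N-terminal cut and C-terminal cut, weighted by
per-site weights, with the substrate termini as additional boundaries),
rejected until the product length falls inside the window.  Ground truth
(per-site log2 weight ratios, length windows, branch rate) is returned for
recovery tests.

Replicate r of a model with seed s uses seed s + r, so replicates are
reproducible independently of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import PeptideTable, SubstrateRecord, ValidationError, PEPTIDE_COLUMNS
from .peptide_mapping import map_peptide

DEFAULT_REMNANT_DISTRIBUTION = {"GG": 0.5, "RGG": 0.3, "LRGG": 0.2}


@dataclass
class DigestionModel:
    """Parameters of one enzyme condition's digestion.

    ``site_weights[j-1]`` is the relative propensity to cut bond ``j``
    (1..L-1); ``terminus_weight`` is the propensity of a product boundary
    to coincide with a substrate terminus (default: mean positive site
    weight).  ``depth`` is the number of detected product events per
    replicate.  ``branch_prob`` is the probability that a product covering
    an anchor lysine carries a ubiquitin remnant, drawn from
    ``remnant_distribution``.
    """

    substrate_id: str
    site_weights: np.ndarray
    length_min: int = 7
    length_max: int = 35
    detection_floor: int = 7
    depth: int = 50_000
    n_replicates: int = 3
    branch_prob: float = 0.0
    remnant_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_REMNANT_DISTRIBUTION)
    )
    terminus_weight: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.site_weights = np.asarray(self.site_weights, dtype=float)
        if np.any(self.site_weights < 0) or not np.any(self.site_weights > 0):
            raise ValidationError("site_weights must be >= 0 with at least one positive")
        if not (1 <= self.length_min <= self.length_max):
            raise ValidationError("need 1 <= length_min <= length_max")
        if self.depth < 0 or self.n_replicates < 1:
            raise ValidationError("depth must be >= 0 and n_replicates >= 1")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValidationError("branch_prob must be a probability")
        p = sum(self.remnant_distribution.values())
        if self.remnant_distribution and abs(p - 1.0) > 1e-9:
            raise ValidationError("remnant_distribution must sum to 1")
        if self.terminus_weight is None:
            self.terminus_weight = float(
                self.site_weights[self.site_weights > 0].mean()
            )


@dataclass
class GroundTruth:
    """What the simulator knows that the analysis must recover."""

    site_log2_ratio: pd.Series  # per-site log2(weight_a / weight_b)
    length_window_a: tuple[int, int]
    length_window_b: tuple[int, int]
    branch_prob_a: float
    branch_prob_b: float


def _boundary_weights(model: DigestionModel, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    # left boundary 0..L-1 (0 = N-terminus); right boundary 1..L (L = C-terminus)
    left = np.concatenate([[model.terminus_weight], model.site_weights])
    right = np.concatenate([model.site_weights, [model.terminus_weight]])
    return left, right


def _feasible(model: DigestionModel, length: int) -> bool:
    left, right = _boundary_weights(model, length - 1)
    pos_left = np.flatnonzero(left > 0)
    pos_right = set(np.flatnonzero(right > 0) + 1)
    for l in pos_left:
        for r in range(l + model.length_min, min(l + model.length_max, length) + 1):
            if r in pos_right:
                return True
    return False


def simulate_digest(
    model: DigestionModel, substrate: SubstrateRecord, replicate: int
) -> tuple[pd.DataFrame, int]:
    """One replicate's detected products, aggregated into PSM counts.

    Returns ``(frame, censored)`` where ``frame`` has the peptide-table
    columns plus ``start`` and ``end`` coordinates, and ``censored`` counts
    events whose product fell below the detection floor (observed +
    censored events = depth).
    """
    length = len(substrate)
    if len(model.site_weights) != length - 1:
        raise ValidationError(
            f"site_weights length {len(model.site_weights)} != {length - 1}"
        )
    cols = PEPTIDE_COLUMNS + ["start", "end"]
    if model.depth == 0:
        return pd.DataFrame(columns=cols), 0
    if not _feasible(model, length):
        raise ValidationError("no feasible product under the length constraints")
    rng = np.random.default_rng(model.seed + replicate)
    left_w, right_w = _boundary_weights(model, length - 1)
    left_p = left_w / left_w.sum()
    right_p = right_w / right_w.sum()
    lefts = np.empty(model.depth, dtype=np.int64)
    rights = np.empty(model.depth, dtype=np.int64)
    got = 0
    while got < model.depth:
        batch = max(4 * (model.depth - got), 1024)
        l = rng.choice(length, size=batch, p=left_p)           # cut index 0..L-1
        r = rng.choice(length, size=batch, p=right_p) + 1      # cut index 1..L
        size = r - l
        ok = (size >= model.length_min) & (size <= model.length_max)
        take = min(int(ok.sum()), model.depth - got)
        lefts[got:got + take] = l[ok][:take]
        rights[got:got + take] = r[ok][:take]
        got += take
    sizes = rights - lefts
    observed = sizes >= model.detection_floor
    censored = int((~observed).sum())
    pairs, counts = np.unique(
        np.stack([lefts[observed], rights[observed]], axis=1), axis=0,
        return_counts=True,
    )
    sample_id = f"{model.substrate_id}_rep{replicate}"
    rows = []
    for (l, r), c in zip(pairs, counts):
        rows.append(
            {
                "sample_id": sample_id,
                "condition": model.substrate_id,
                "replicate": replicate,
                "sequence": substrate.sequence[l:r],
                "psm_count": int(c),
                "branch_pos": np.nan,
                "branch_remnant": None,
                "start": int(l) + 1,
                "end": int(r),
            }
        )
    return pd.DataFrame(rows, columns=cols), censored


def simulate_condition(
    model: DigestionModel, substrate: SubstrateRecord, condition: str
) -> pd.DataFrame:
    """All replicates of one condition (sample ids ``<condition>_rep<r>``)."""
    frames = []
    for rep in range(1, model.n_replicates + 1):
        frame, _ = simulate_digest(model, substrate, rep)
        frame = frame.assign(
            condition=condition, sample_id=f"{condition}_rep{rep}"
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_two_condition(
    model_a: DigestionModel,
    model_b: DigestionModel,
    substrate: SubstrateRecord,
    condition_a: str = "20S",
    condition_b: str = "26S",
) -> tuple[PeptideTable, GroundTruth]:
    """Replicated two-condition digest plus its ground truth.

    The true per-site preference is ``log2(weight_a / weight_b)`` (infinite
    where only one enzyme uses a site), defined for sites positive in at
    least one model.
    """
    if model_a.substrate_id != model_b.substrate_id:
        raise ValidationError("the two models must share a substrate")
    frame = pd.concat(
        [
            simulate_condition(model_a, substrate, condition_a),
            simulate_condition(model_b, substrate, condition_b),
        ],
        ignore_index=True,
    )
    wa, wb = model_a.site_weights, model_b.site_weights
    defined = (wa > 0) | (wb > 0)
    with np.errstate(divide="ignore"):
        ratio = np.log2(wa) - np.log2(wb)
    truth = GroundTruth(
        site_log2_ratio=pd.Series(
            ratio[defined], index=np.flatnonzero(defined) + 1, name="log2_ratio"
        ),
        length_window_a=(model_a.length_min, model_a.length_max),
        length_window_b=(model_b.length_min, model_b.length_max),
        branch_prob_a=model_a.branch_prob,
        branch_prob_b=model_b.branch_prob,
    )
    table = PeptideTable(frame[PEPTIDE_COLUMNS], provenance="simulated")
    return table, truth


def inject_branches(
    table: PeptideTable,
    model: DigestionModel,
    substrate: SubstrateRecord,
    seed_offset: int = 7919,
) -> PeptideTable:
    """Add isopeptide branches to products covering an anchor lysine.

    Each PSM of an anchor-covering, uniquely mapping peptide independently
    becomes branched with probability ``branch_prob``; remnants are drawn
    from ``remnant_distribution`` and counts split accordingly.
    """
    if not substrate.anchor_lysines:
        raise ValidationError("substrate declares no anchor lysine")
    if model.branch_prob == 0 or table.frame.empty:
        return table
    rng = np.random.default_rng(model.seed + seed_offset)
    remnants = sorted(model.remnant_distribution)
    probs = np.array([model.remnant_distribution[r] for r in remnants])
    anchors = set(substrate.anchor_lysines)
    rows = []
    for row in table.frame.itertuples(index=False):
        row = row._asdict()
        hits = map_peptide(row["sequence"], substrate)
        anchor_hit = None
        if len(hits) == 1:
            start, end = hits[0]
            covered = anchors.intersection(range(start, end + 1))
            if covered:
                anchor_hit = (start, min(covered))
        if anchor_hit is None:
            rows.append(row)
            continue
        start, anchor = anchor_hit
        n = int(row["psm_count"])
        n_branched = rng.binomial(n, model.branch_prob)
        if n > n_branched:
            rows.append({**row, "psm_count": n - n_branched})
        if n_branched > 0:
            split = rng.multinomial(n_branched, probs)
            for remnant, c in zip(remnants, split):
                if c > 0:
                    rows.append(
                        {
                            **row,
                            "psm_count": int(c),
                            "branch_pos": anchor - start + 1,
                            "branch_remnant": remnant,
                        }
                    )
    return PeptideTable(
        pd.DataFrame(rows, columns=PEPTIDE_COLUMNS), provenance=table.provenance
    )


def log_uniform_weights(
    n_sites: int, rng: np.random.Generator, low: float = 0.125, high: float = 8.0
) -> np.ndarray:
    """Per-site weights log-uniform on [low, high] (ratio range for recovery tests)."""
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n_sites))
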