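"""Cleavage-site (P1) usage, enzyme preference, occupancy matrix, diversity.

The central statistic compares how often two proteasome species (for
instance the stand-alone 20S core particle versus the 26S holoenzyme) cut
each peptide bond of a substrate.  For every P1 position the PSM counts of
all peptide products bounded by that bond are integrated; the relative
preference of enzyme A over enzyme B at a site is then

    log2( (count_A or pseudo) / (count_B or pseudo) )

with zero counts replaced by a small pseudo-value (0.1 by default), and a
two-fold ratio in either direction flagging a site preference.  Sites used
by neither enzyme yield NA rather than a fabricated "no preference".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy

from .core_io import PeptideTable, ValidationError, logger

# ---------------------------------------------------------------------------
# Site-count integration
# ---------------------------------------------------------------------------


@dataclass
class SiteUsageTable:
    """Integrated PSM counts per cleavage site for one condition.

    ``counts`` is indexed by site ``j`` (P1 = residue ``j``); rows with zero
    total are omitted from storage but treated as 0 downstream.
    """

    substrate_id: str
    condition: str
    counts: pd.Series

    def count_at(self, site: int) -> float:
        return float(self.counts.get(site, 0.0))


def integrate_site_counts(
    mapped: pd.DataFrame,
    condition: str,
    *,
    ambiguous: str = "exclude",
    credit: str = "both",
) -> SiteUsageTable:
    """Integrate mapped-peptide PSM counts into per-site usage.

    Every unambiguous internal peptide contributes its PSM count to *both*
    bounding cleavage sites (each internal product is evidence of two
    cleavage events); terminus-touching products contribute to their single
    internal bound.  ``credit="nterm"`` restricts the credit to the
    N-terminal bound for sensitivity analysis.  Ambiguously mapping
    peptides are excluded by default; ``ambiguous="fractional"`` instead
    credits each of the k occurrences with 1/k of the count.
    """
    if ambiguous not in ("exclude", "fractional"):
        raise ValidationError(f"unknown ambiguous mode {ambiguous!r}")
    if credit not in ("both", "nterm"):
        raise ValidationError(f"unknown credit mode {credit!r}")
    sub = mapped[mapped["condition"] == condition]
    substrates = sub["substrate_id"].unique()
    if len(substrates) > 1:
        raise ValidationError(f"mixed substrates in one integration: {substrates}")
    substrate_id = substrates[0] if len(substrates) else "<none>"
    totals: dict[int, float] = {}
    if len(sub):
        if ambiguous == "exclude":
            sub = sub[~sub["ambiguous"]]
            weights = sub["psm_count"].astype(float)
        else:
            k = sub.groupby(["sample_id", "sequence"])["start"].transform("count")
            weights = sub["psm_count"].astype(float) / k
        for (n_site, c_site), w in zip(
            zip(sub["n_term_site"], sub["c_term_site"]), weights
        ):
            if pd.notna(n_site):
                totals[int(n_site)] = totals.get(int(n_site), 0.0) + w
            if credit == "both" and pd.notna(c_site):
                totals[int(c_site)] = totals.get(int(c_site), 0.0) + w
    counts = pd.Series(totals, dtype=float).sort_index()
    counts = counts[counts > 0]
    return SiteUsageTable(substrate_id, condition, counts)


# ---------------------------------------------------------------------------
# Preference statistic
# ---------------------------------------------------------------------------


def compute_preference(
    usage_a: SiteUsageTable,
    usage_b: SiteUsageTable,
    pseudo_value: float = 0.1,
    fold_threshold: float = 2.0,
    substrate_length: Optional[int] = None,
    normalize_cpm: bool = False,
) -> pd.DataFrame:
    """Per-site log2 relative cleavage preference of condition A over B.

    Returns a frame with columns ``site, value_a, value_b, log2_ratio,
    call`` where ``call`` is ``prefer_a`` when the ratio exceeds the fold
    threshold, ``prefer_b`` when it falls below its inverse, ``none`` in
    between, and ``na`` (with ``log2_ratio`` NA) at sites unobserved in
    both conditions.  Antisymmetric under swapping the two conditions.

    With ``normalize_cpm`` the integrated counts are first scaled to
    counts-per-million of each condition's total integrated count; note
    that this changes the meaning of the pseudo-value, which is applied on
    the normalized scale.
    """
    if pseudo_value <= 0:
        raise ValidationError("pseudo_value must be positive")
    if usage_a.substrate_id != usage_b.substrate_id:
        raise ValidationError(
            f"substrate mismatch: {usage_a.substrate_id!r} vs {usage_b.substrate_id!r}"
        )
    a, b = usage_a.counts.astype(float), usage_b.counts.astype(float)
    if normalize_cpm:
        a = a * 1e6 / a.sum() if a.sum() > 0 else a
        b = b * 1e6 / b.sum() if b.sum() > 0 else b
    if substrate_length is not None:
        sites = list(range(1, substrate_length))
    else:
        sites = sorted(set(a.index) | set(b.index))
    thr = np.log2(fold_threshold)
    rows = []
    for site in sites:
        va, vb = float(a.get(site, 0.0)), float(b.get(site, 0.0))
        if va == 0 and vb == 0:
            rows.append((site, va, vb, np.nan, "na"))
            continue
        ratio = np.log2((va or pseudo_value) / (vb or pseudo_value))
        call = "prefer_a" if ratio > thr else "prefer_b" if ratio < -thr else "none"
        rows.append((site, va or pseudo_value, vb or pseudo_value, ratio, call))
    return pd.DataFrame(
        rows, columns=["site", "value_a", "value_b", "log2_ratio", "call"]
    )


# ---------------------------------------------------------------------------
# Sample-by-peptide occupancy matrix
# ---------------------------------------------------------------------------


@dataclass
class HeatmapMatrix:
    """Filtered, normalized sample x peptide occupancy matrix.

    ``values`` holds, per (sample, peptide), the counts-per-million
    rescaled to each peptide's maximum (so every retained column has max
    exactly 1); ``cpm`` keeps the unrescaled CPM; ``peptide_maxima`` the
    per-peptide maximum CPM (the side bar-plot values).  Columns are
    ordered by the peptide's N-terminal residue on the substrate, then
    length, then lexicographically.
    """

    values: pd.DataFrame
    cpm: pd.DataFrame
    peptide_maxima: pd.Series
    filters_applied: dict = field(default_factory=dict)


def rescale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide every column by its maximum (idempotent)."""
    maxima = matrix.max(axis=0)
    return matrix.div(maxima.where(maxima > 0, 1.0), axis=1)


def build_heatmap(
    table: PeptideTable,
    mapped: pd.DataFrame,
    min_sample_psms: int = 50,
) -> HeatmapMatrix:
    """Build the normalized occupancy matrix over mapped peptides.

    Samples whose raw mapped-PSM total is below ``min_sample_psms`` are
    discarded, along with peptides observed in a single sample only.  The
    remaining counts are converted to counts-per-million of each sample's
    mapped total and rescaled to the per-peptide maximum.
    """
    if mapped.empty:
        raise ValidationError("no mapped peptides to build a heatmap from")
    starts = mapped.groupby("sequence")["start"].min()
    order = pd.DataFrame({"start": starts, "length": starts.index.str.len()})
    # tie-break: start position, then peptide length, then lexicographic
    order = order.sort_index(kind="stable").sort_values(
        ["start", "length"], kind="stable"
    )
    peptide_order = list(order.index)
    frame = table.frame[table.frame["sequence"].isin(peptide_order)]
    matrix = (
        frame.pivot_table(
            index="sample_id", columns="sequence", values="psm_count",
            aggfunc="sum", fill_value=0,
        )
        .reindex(columns=[p for p in peptide_order if p in set(frame["sequence"])])
        .astype(float)
    )
    n_samples0, n_peptides0 = matrix.shape
    sample_totals = matrix.sum(axis=1)
    matrix = matrix.loc[sample_totals >= min_sample_psms]
    if matrix.empty:
        raise ValidationError(
            f"all samples fall below {min_sample_psms} PSMs; nothing to plot"
        )
    sample_totals = sample_totals.loc[matrix.index]
    multi = (matrix > 0).sum(axis=0) >= 2
    matrix = matrix.loc[:, multi]
    if matrix.shape[1] == 0:
        raise ValidationError("no peptide observed in more than one sample")
    cpm = matrix.mul(1e6 / sample_totals, axis=0)
    maxima = cpm.max(axis=0)
    values = rescale_columns(cpm)
    filters = {
        "min_sample_psms": min_sample_psms,
        "samples_dropped": n_samples0 - matrix.shape[0],
        "peptides_dropped": n_peptides0 - matrix.shape[1],
    }
    logger.info("heatmap filters: %s", filters)
    return HeatmapMatrix(values=values, cpm=cpm, peptide_maxima=maxima,
                         filters_applied=filters)


# ---------------------------------------------------------------------------
# Sample ordination and clustering
# ---------------------------------------------------------------------------


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    # Torgerson scaling: double-center the squared distances and take the
    # leading eigenpairs; negative eigenvalues (non-Euclidean noise) clip to 0.
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:n_components]
    coords = v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
    for k in range(coords.shape[1]):  # sign convention: first sample >= 0
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def mds_ward_cluster(
    matrix: HeatmapMatrix, top_n: int = 100
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical MDS of samples and Ward clustering in MDS space.

    Distances are Euclidean over ``log2(CPM + 1)`` of the ``top_n``
    peptides ranked by their per-peptide maximum CPM (clamped to the number
    available).  Returns the 2-D coordinates per sample and the scipy Ward
    linkage matrix computed on the MDS-space distances.  Deterministic up
    to reflection; the sign convention fixes the first sample's coordinates
    to be non-negative.
    """
    cpm = matrix.cpm
    if cpm.shape[0] < 2:
        raise ValidationError("need at least two retained samples for MDS")
    top = matrix.peptide_maxima.sort_values(ascending=False, kind="stable")
    keep = list(top.index[: min(top_n, len(top))])
    x = np.log2(cpm[keep].to_numpy(float) + 1.0)
    d = squareform(pdist(x, metric="euclidean"))
    coords = classical_mds(d, n_components=2)
    z = linkage(pdist(coords), method="ward")
    frame = pd.DataFrame(coords, index=cpm.index, columns=["mds1", "mds2"])
    return frame, z


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(z):
        i, j = int(i), int(j)
        li = h - heights[i]
        lj = h - heights[j]
        nodes[n + k] = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# Product diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    condition: str
    richness: int
    shannon_entropy: float  # bits


def diversity(table: PeptideTable, condition: str) -> DiversitySummary:
    """Richness and Shannon entropy of a condition's product repertoire.

    Richness counts distinct peptide species (sequence plus any branch);
    entropy is taken over the PSM-count proportions across species, in
    bits, so ``0 <= entropy <= log2(richness)``.
    """
    sub = table.frame[table.frame["condition"] == condition]
    if sub.empty:
        return DiversitySummary(condition, 0, 0.0)
    counts = sub.groupby(
        ["sequence", "branch_pos", "branch_remnant"], dropna=False
    )["psm_count"].sum()
    counts = counts[counts > 0]
    h = float(entropy(counts.to_numpy(float), base=2)) if len(counts) else 0.0
    return DiversitySummary(condition, int(len(counts)), h)
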