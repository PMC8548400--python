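"""Positional amino-acid composition around used cleavage sites.

Protease nomenclature labels the residues flanking a scissile bond
P4-P3-P2-P1 | P1'-P2'-P3'-P4', with P1 immediately N-terminal to the cut.
For a cleavage site ``j`` the window therefore covers substrate residues
``j-3 .. j+4``; positions that fall off either terminus are marked absent
and excluded from that position's denominator.  Windows are weighted by
the site's integrated PSM count so that the composition reflects usage.

Information content follows the Schneider-Stephens sequence-logo
convention: ``IC(pos) = log2(20) - H(pos)`` with ``H`` the Shannon entropy
of the position's residue frequencies, and per-letter heights
``frequency x IC``.  No small-sample correction is applied by default.
The differential comparison between two enzymes reports signed frequency
differences plus a per-position chi-square test on the weighted counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core_io import CANONICAL_AA, SubstrateRecord, ValidationError
from .cleavage_analysis import SiteUsageTable

N_AA = len(CANONICAL_AA)


def position_labels(span: int) -> list[str]:
    """P<span>..P1, P1'..P<span>' labels, N- to C-terminal."""
    return [f"P{i}" for i in range(span, 0, -1)] + [
        f"P{i}'" for i in range(1, span + 1)
    ]


@dataclass
class PositionalFrequencyMatrix:
    """Weighted residue frequencies per window position.

    ``frequencies``: (position x amino acid) frame, rows summing to 1 over
    the residues observed at that position; ``effective_weight``: total
    count weight contributing to each position (edge windows contribute to
    fewer positions).
    """

    frequencies: pd.DataFrame
    effective_weight: pd.Series


@dataclass
class LogoMatrix:
    heights: pd.DataFrame          # (position x amino acid) bit heights
    information_content: pd.Series  # per-position IC, bits


def extract_windows(
    usage: SiteUsageTable, substrate: SubstrateRecord, span: int = 4
) -> list[tuple[list, float]]:
    """Weighted P<span>..P<span>' windows around each used site.

    Each entry is ``(residues, weight)`` where ``residues`` lists one
    letter per position or ``None`` where the window runs off a terminus.
    """
    n = len(substrate)
    windows = []
    for site, weight in usage.counts.items():
        site = int(site)
        if not (1 <= site <= n - 1):
            raise ValidationError(f"site {site} invalid for substrate of length {n}")
        residues = []
        for offset in range(-span + 1, span + 1):  # P-span..P1 then P1'..P-span'
            idx = site + offset
            residues.append(substrate.residue(idx) if 1 <= idx <= n else None)
        windows.append((residues, float(weight)))
    return windows


def frequency_matrix(
    windows: list[tuple[list, float]], span: int = 4
) -> PositionalFrequencyMatrix:
    """Weighted positional residue frequencies from a window list."""
    if not windows:
        raise ValidationError("no windows to build a frequency matrix from")
    labels = position_labels(span)
    counts = pd.DataFrame(0.0, index=labels, columns=list(CANONICAL_AA))
    for residues, weight in windows:
        if len(residues) != len(labels):
            raise ValidationError("window span does not match matrix span")
        for label, aa in zip(labels, residues):
            if aa is not None:
                counts.loc[label, aa] += weight
    weights = counts.sum(axis=1)
    freqs = counts.div(weights.where(weights > 0, 1.0), axis=0)
    return PositionalFrequencyMatrix(frequencies=freqs, effective_weight=weights)


def information_content(freqs: PositionalFrequencyMatrix) -> LogoMatrix:
    """Schneider-Stephens logo: IC(pos) = log2(20) - H(pos), heights = f*IC."""
    f = freqs.frequencies.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    h = -plogp.sum(axis=1)
    ic = np.where(freqs.effective_weight.to_numpy() > 0, np.log2(N_AA) - h, 0.0)
    heights = freqs.frequencies.mul(ic, axis=0)
    return LogoMatrix(
        heights=heights,
        information_content=pd.Series(ic, index=freqs.frequencies.index),
    )


def differential_logo(
    freqs_a: PositionalFrequencyMatrix, freqs_b: PositionalFrequencyMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Signed composition difference and per-position chi-square p-values.

    The difference is ``f_a - f_b`` per (position, residue).  For each
    position a chi-square test of homogeneity compares the two weighted
    count vectors, pooling residue categories whose total expected count is
    below 1; positions with no counts on either side, or a single pooled
    category, give p = 1.
    """
    if not freqs_a.frequencies.index.equals(freqs_b.frequencies.index):
        raise ValidationError("frequency matrices do not share positions")
    diff = freqs_a.frequencies - freqs_b.frequencies
    counts_a = freqs_a.frequencies.mul(freqs_a.effective_weight, axis=0)
    counts_b = freqs_b.frequencies.mul(freqs_b.effective_weight, axis=0)
    pvals = {}
    for pos in diff.index:
        pvals[pos] = _chisq_homogeneity(
            counts_a.loc[pos].to_numpy(float), counts_b.loc[pos].to_numpy(float)
        )
    return diff, pd.Series(pvals, name="p_value")


def flag_positions(
    pvals: pd.Series, alpha: float = 0.01, method: str = "bonferroni"
) -> pd.Series:
    """Decision rule for calling positions differentially composed.

    Scanning all window positions is a multiple-comparison problem, so the
    flagging rule controls the family-wise error (Bonferroni over the
    positions tested, the convention of differential-logo tooling);
    ``method="none"`` compares raw p-values against ``alpha`` directly.
    Returns a boolean Series (True = flagged).
    """
    if method == "bonferroni":
        return pvals < alpha / len(pvals)
    if method == "none":
        return pvals < alpha
    raise ValidationError(f"unknown correction method {method!r}")


def _chisq_homogeneity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        return 1.0
    if np.allclose(a / na, b / nb):
        return 1.0  # identical compositions carry no signal
    total = a + b
    n = na + nb
    # pool categories whose expected count (either row) would fall below 1
    expected_min = np.minimum(na, nb) * total / n
    keep = (total > 0) & (expected_min >= 1.0)
    pooled = ~keep & (total > 0)
    rows_a = list(a[keep]) + ([a[pooled].sum()] if pooled.any() else [])
    rows_b = list(b[keep]) + ([b[pooled].sum()] if pooled.any() else [])
    a2, b2 = np.asarray(rows_a, float), np.asarray(rows_b, float)
    k = len(a2)
    if k < 2:
        return 1.0
    exp_a = na * (a2 + b2) / n
    exp_b = nb * (a2 + b2) / n
    stat = np.sum((a2 - exp_a) ** 2 / exp_a) + np.sum((b2 - exp_b) ** 2 / exp_b)
    return float(chi2.sf(stat, df=k - 1))
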