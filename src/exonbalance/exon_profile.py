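"""Anchor-normalized exon-level TPM profiles and within-gene coverage transitions.

TPM here is within-gene: the denominator is the sum of length-normalized read
rates over the gene's own exons, so each sample's exon TPMs sum to 1e6. Any
transcriptome-wide constant cancels in the anchor normalization and in the
downstream exon-ratio index, which keeps the profile analysis self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, ValidationError
from .simulate import DEFAULT_EXON_IDS, DEFAULT_EXON_LENGTHS


@dataclass
class ExonModel:
    """Ordered exon ids and lengths for one gene (default: a 16-exon model,
    ids 2-17, matching a gene whose translated exons start at exon 2)."""

    gene_id: str = "CIZ1"
    exon_ids: Sequence[int] = DEFAULT_EXON_IDS
    exon_lengths: Sequence[int] = DEFAULT_EXON_LENGTHS

    def __post_init__(self) -> None:
        ids = list(self.exon_ids)
        if sorted(ids) != ids or len(set(ids)) != len(ids):
            raise ValidationError("exon ids must be strictly increasing")
        if len(ids) != len(self.exon_lengths):
            raise ValidationError("exon_ids and exon_lengths lengths differ")
        if any(l <= 0 for l in self.exon_lengths):
            raise ValidationError("exon lengths must be > 0")

    @property
    def feature_ids(self) -> list[str]:
        return [f"exon_{e}" for e in self.exon_ids]

    def lengths(self) -> pd.Series:
        return pd.Series(list(self.exon_lengths), index=self.feature_ids, dtype=float)


def compute_exon_tpm(counts: CountTable, model: ExonModel) -> pd.DataFrame:
    """Per-sample within-gene TPM: rate(e) = count(e)/len(e), scaled to 1e6.

    Returns an exons x samples DataFrame. An all-zero sample yields all-zero
    TPM with a warning rather than an error.
    """
    expected = model.feature_ids
    if list(counts.feature_ids) != expected:
        if set(counts.feature_ids) != set(expected):
            raise ValidationError(
                "count-table features do not match the exon model "
                f"(expected {expected[:3]}..., got {counts.feature_ids[:3]}...)"
            )
        mat = counts.counts.loc[expected]
    else:
        mat = counts.counts
    rates = mat.div(model.lengths(), axis=0).astype(float)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have zero counts across all exons",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = rates.div(totals.where(~zero, np.nan), axis=1) * 1e6
    return tpm.fillna(0.0)


def normalize_to_anchor(
    tpm: pd.DataFrame, anchor_exon: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Divide each sample's profile by its anchor-exon TPM.

    Samples with zero anchor TPM are not an error: they are dropped from the
    returned frame and reported in the exclusion map with a reason code.
    """
    anchor_row = f"exon_{anchor_exon}"
    if anchor_row not in tpm.index:
        raise ValidationError(f"anchor exon {anchor_exon} not in profile")
    anchor = tpm.loc[anchor_row]
    excluded = {s: "zero anchor-exon signal" for s in tpm.columns[anchor == 0]}
    kept = tpm.loc[:, anchor > 0]
    normalized = kept.div(anchor[anchor > 0], axis=1)
    return normalized, excluded


def compare_exon_levels(
    profiles: pd.DataFrame, exon_a: int, exon_b: int
) -> dict[str, float]:
    """Two-sided Mann-Whitney U comparing two exons' per-sample values.

    Unpaired by convention even though both exons come from the same samples.
    Exact p when both n <= 8 with no ties, normal approximation with tie and
    continuity correction otherwise.
    """
    row_a, row_b = f"exon_{exon_a}", f"exon_{exon_b}"
    for row in (row_a, row_b):
        if row not in profiles.index:
            raise ValidationError(f"{row} not in profiles")
    x = profiles.loc[row_a].to_numpy(dtype=float)
    y = profiles.loc[row_b].to_numpy(dtype=float)
    if x.size < 2:
        raise ValidationError("need >= 2 samples")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        warnings.warn("all values identical; no separation", stacklevel=2)
        return {"U": x.size * y.size / 2.0, "p": 1.0, "n": float(x.size)}
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {"U": float(res.statistic), "p": float(res.pvalue), "n": float(x.size)}


def detect_internal_tss(
    coverage: Sequence[float],
    min_segment: int = 3,
    ratio_threshold: float = 1.5,
) -> dict:
    """Single-changepoint binary segmentation on an ordered coverage vector.

    The breakpoint b (number of bins in the upstream segment) maximizes the
    size-weighted between-segment squared mean difference
    n1*n2/n * (mean1 - mean2)^2. Returns the breakpoint, the
    downstream/upstream mean ratio, and a transition flag: transitions with a
    ratio inside [1/ratio_threshold, ratio_threshold] are called "none".
    """
    x = np.asarray(coverage, dtype=float)
    n = x.size
    if n < 2 * min_segment:
        raise ValidationError(
            f"coverage vector needs >= {2 * min_segment} bins, got {n}"
        )
    csum = np.cumsum(x)
    total = csum[-1]
    bs = np.arange(min_segment, n - min_segment + 1)
    m1 = csum[bs - 1] / bs
    m2 = (total - csum[bs - 1]) / (n - bs)
    score = bs * (n - bs) / n * (m1 - m2) ** 2
    i = int(np.argmax(score))
    b = int(bs[i])
    up, down = float(m1[i]), float(m2[i])
    ratio = np.inf if up == 0 else down / up
    has_transition = not (1.0 / ratio_threshold <= ratio <= ratio_threshold)
    return {
        "breakpoint": b,
        "upstream_mean": up,
        "downstream_mean": down,
        "ratio": float(ratio),
        "transition": bool(has_transition),
    }
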