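"""Comparative-Ct (2^-ddCt) relative quantification and amplicon agreement.

Ct tables are long form: sample_id, amplicon, ct, reference_ct. Replicate
wells for the same sample/amplicon are averaged before dCt. dCt = ct -
reference_ct; ddCt subtracts the calibrator group's mean dCt per amplicon;
RQ = 2^-ddCt, so the calibrator group's geometric-mean RQ is 1.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata, ValidationError

CT_SOFT_RANGE = (10.0, 40.0)

SIGNIFICANCE_BANDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_band(p: float) -> str:
    for cut, band in SIGNIFICANCE_BANDS:
        if p < cut:
            return band
    return "ns"


def _validate_ct(records: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "amplicon", "ct", "reference_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    rec = records.copy()
    for col in ("ct", "reference_ct"):
        rec[col] = pd.to_numeric(rec[col])
        if not np.isfinite(rec[col]).all():
            raise ValidationError(f"non-finite {col} values")
    outside = (rec["ct"] < CT_SOFT_RANGE[0]) | (rec["ct"] > CT_SOFT_RANGE[1])
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} Ct value(s) outside the typical "
            f"{CT_SOFT_RANGE[0]:.0f}-{CT_SOFT_RANGE[1]:.0f} cycle range",
            stacklevel=3,
        )
    # replicate wells averaged per sample x amplicon before dCt
    return rec.groupby(["sample_id", "amplicon"], as_index=False).agg(
        ct=("ct", "mean"), reference_ct=("reference_ct", "mean")
    )


def compute_rq(
    records: pd.DataFrame, calibrator: Sequence[str]
) -> pd.DataFrame:
    """Relative quantity per sample and amplicon via 2^-ddCt.

    ``calibrator`` names the samples whose mean dCt (per amplicon) is the
    reference; every amplicon must have at least one calibrator record.
    Returns sample_id, amplicon, dct, ddct, rq.
    """
    rec = _validate_ct(records)
    calib = set(calibrator)
    if not calib:
        raise ValidationError("empty calibrator set")
    rec["dct"] = rec["ct"] - rec["reference_ct"]
    out = []
    for amp, sub in rec.groupby("amplicon", sort=True):
        cal = sub[sub["sample_id"].isin(calib)]
        if cal.empty:
            raise ValidationError(f"amplicon {amp!r} has no calibrator record")
        ref_dct = cal["dct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - ref_dct
        sub["rq"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return (
        pd.concat(out)
        .sort_values(["sample_id", "amplicon"])
        .reset_index(drop=True)[["sample_id", "amplicon", "dct", "ddct", "rq"]]
    )


def aggregate_by_stage(
    rq: pd.DataFrame,
    metadata: SampleMetadata,
    amplicon_pair: tuple[str, str],
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage RQ summaries plus a between-amplicon t test per stage.

    The test is an unpaired two-sample t test on RQ values of the two
    amplicons within a stage — Welch by default, pooled-variance when
    ``pooled``. Stages where either amplicon has fewer than two samples get a
    summary only (test skipped and flagged).
    """
    stage = metadata.stage_of()
    missing = set(rq["sample_id"]) - set(stage.index)
    if missing:
        raise ValidationError(f"samples missing from metadata: {sorted(missing)[:5]}")
    df = rq.copy()
    df["stage"] = df["sample_id"].map(stage)

    summaries = (
        df.groupby(["stage", "amplicon"])["rq"]
        .agg(
            n="count",
            mean="mean",
            median="median",
            q1=lambda v: v.quantile(0.25),
            q3=lambda v: v.quantile(0.75),
        )
        .reset_index()
    )

    a, b = amplicon_pair
    tests = []
    for st, sub in df.groupby("stage", sort=True):
        x = sub.loc[sub["amplicon"] == a, "rq"].to_numpy()
        y = sub.loc[sub["amplicon"] == b, "rq"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            tests.append(
                {"stage": st, "amplicon_a": a, "amplicon_b": b, "n_a": len(x),
                 "n_b": len(y), "t": np.nan, "p": np.nan, "band": "skipped"}
            )
            continue
        res = stats.ttest_ind(x, y, equal_var=pooled)
        p = float(res.pvalue)
        if np.isnan(p):  # zero variance in both identical vectors
            p = 1.0
        tests.append(
            {"stage": st, "amplicon_a": a, "amplicon_b": b, "n_a": len(x),
             "n_b": len(y), "t": float(res.statistic), "p": p,
             "band": significance_band(p)}
        )
    return summaries, pd.DataFrame(tests)


def amplicon_correlation(
    rq: pd.DataFrame, pair: tuple[str, str], scale: str = "log2"
) -> dict[str, float]:
    """Pearson correlation between two amplicons' per-sample RQ values.

    Default scale is log2(rq) since RQ is multiplicative; linear available.
    Returns r, n, two-sided p (t reference). Zero variance in either vector
    gives r = NaN with a flag.
    """
    if scale not in ("linear", "log2"):
        raise ValidationError(f"unknown scale {scale!r}")
    a, b = pair
    wide = rq.pivot_table(index="sample_id", columns="amplicon", values="rq")
    for amp in pair:
        if amp not in wide.columns:
            raise ValidationError(f"amplicon {amp!r} not in RQ table")
    paired = wide[[a, b]].dropna()
    if len(paired) < 3:
        raise ValidationError("need >= 3 paired samples")
    x = paired[a].to_numpy(dtype=float)
    y = paired[b].to_numpy(dtype=float)
    if scale == "log2":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValidationError("non-positive RQ cannot be log-scaled")
        x, y = np.log2(x), np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return {"r": np.nan, "n": float(len(paired)), "p": np.nan}
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "n": float(len(paired)), "p": float(res.pvalue)}
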