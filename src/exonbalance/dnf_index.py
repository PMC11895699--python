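"""The AD:RD domain-imbalance index and cohort segmentation into groups A-D.

The index for a sample is the ratio of its 3' anchor-domain exon TPM
(exon 14) to its 5' replication-domain exon TPM (exon 5). Samples partition
into four groups:

    A: ratio > 2            (anchor domain more than twofold elevated)
    B: 1.1 < ratio <= 2     (intermediate elevation)
    C: 0.9 <= ratio <= 1.1  (balanced, within 10%)
    D: ratio < 0.9          (anchor domain depleted)

Boundary ties at 0.9 and 1.1 fall to C (the conservative "balanced" call) and
a ratio of exactly 2 falls to B, honoring the strict "exceeds 2" rule for A.
The ratio is computed on raw within-gene TPM; any anchor normalization cancels.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata, ValidationError

GROUPS = ("A", "B", "C", "D")

AD_EXON = 14
RD_EXON = 5


def classify_group(ratio: float) -> str:
    """Map a positive finite AD:RD ratio to exactly one of A/B/C/D."""
    if not math.isfinite(ratio) or ratio <= 0:
        raise ValidationError(f"ratio must be positive finite, got {ratio}")
    if ratio > 2.0:
        return "A"
    if ratio > 1.1:
        return "B"
    if ratio >= 0.9:
        return "C"
    return "D"


def compute_dnf_index(
    tpm: pd.DataFrame, ad_exon: int = AD_EXON, rd_exon: int = RD_EXON
) -> pd.DataFrame:
    """Per-sample AD:RD TPM ratio plus group label.

    Returns a DataFrame with columns sample_id, ratio, group, excluded,
    reason. Samples whose RD exon TPM is zero are excluded with a reason,
    never classified.
    """
    ad_row, rd_row = f"exon_{ad_exon}", f"exon_{rd_exon}"
    for row in (ad_row, rd_row):
        if row not in tpm.index:
            raise ValidationError(f"{row} missing from TPM profile")
    ad = tpm.loc[ad_row]
    rd = tpm.loc[rd_row]
    rows = []
    for sid in tpm.columns:
        if rd[sid] == 0:
            rows.append((sid, np.nan, "", True, "zero RD signal"))
        else:
            ratio = float(ad[sid] / rd[sid])
            if ratio == 0:
                rows.append((sid, ratio, "", True, "zero AD signal"))
            else:
                rows.append((sid, ratio, classify_group(ratio), False, ""))
    return pd.DataFrame(
        rows, columns=["sample_id", "ratio", "group", "excluded", "reason"]
    )


def cohort_profile(
    records: pd.DataFrame,
    metadata: SampleMetadata | None = None,
    stratify_by: str = "none",
) -> pd.DataFrame:
    """A-D counts and proportions per stratum (stage/subtype/receptor_status).

    Excluded samples are reported in the n_excluded column and never counted
    in the group proportions. With stratify_by="none" a single "cohort" row is
    returned.
    """
    if stratify_by not in ("none", "stage", "subtype", "receptor_status"):
        raise ValidationError(f"unknown stratifier {stratify_by!r}")
    rec = records.copy()
    if stratify_by == "none":
        rec["stratum"] = "cohort"
    else:
        if metadata is None:
            raise ValidationError("metadata required for stratification")
        lookup = metadata.samples.set_index("sample_id")[stratify_by]
        missing = set(rec["sample_id"]) - set(lookup.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)[:5]}")
        rec["stratum"] = rec["sample_id"].map(lookup)
    out = []
    for stratum, sub in rec.groupby("stratum", sort=True):
        kept = sub[~sub["excluded"]]
        n = len(kept)
        counts = {g: int((kept["group"] == g).sum()) for g in GROUPS}
        props = {g: (counts[g] / n if n else np.nan) for g in GROUPS}
        out.append(
            {
                "stratum": stratum,
                "n": n,
                "n_excluded": int(sub["excluded"].sum()),
                **{f"n_{g}": counts[g] for g in GROUPS},
                **{f"prop_{g}": props[g] for g in GROUPS},
            }
        )
    return pd.DataFrame(out)


def profile_chi_squared(subset: pd.Series, cohort: pd.Series) -> dict[str, float]:
    """Goodness-of-fit of a stratum's A-D counts against cohort proportions.

    ``subset`` holds observed counts per group, ``cohort`` the reference
    proportions. Groups with zero expected count and zero observed are
    dropped from the statistic; zero expected with nonzero observed makes the
    test degenerate (p = 0). df = (groups with expected > 0) - 1.
    """
    obs = np.asarray([subset.get(g, 0) for g in GROUPS], dtype=float)
    prop = np.asarray([cohort.get(g, 0.0) for g in GROUPS], dtype=float)
    n = obs.sum()
    if n < 1:
        raise ValidationError("subset must contain at least one sample")
    if not np.isclose(prop.sum(), 1.0, atol=1e-9):
        raise ValidationError("cohort proportions must sum to 1")
    exp = prop * n
    degenerate = (exp == 0) & (obs > 0)
    if degenerate.any():
        return {"chi2": np.inf, "df": float(int((exp > 0).sum()) - 1), "p": 0.0}
    keep = exp > 0
    chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    df = int(keep.sum()) - 1
    if n < 5 * keep.sum():
        warnings.warn("small stratum: chi-squared approximation is coarse", stacklevel=2)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": chi2, "df": float(df), "p": p}
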