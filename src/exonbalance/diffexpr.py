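"""Two-group negative-binomial differential analysis for count matrices.

The model is the standard RNA-seq one: counts k_ij ~ NB with mean s_j * mu_gi
and variance mu + phi*mu^2, where s_j is a per-sample size factor
(median-of-ratios), mu_gi the group mean of feature i, and phi_i a per-feature
dispersion estimated by the method of moments with optional shrinkage toward a
mean-dispersion trend phi(mu) = a/mu + b. Significance is a Wald test on
log2(mu_2/mu_1) with a delta-method standard error and a normal reference,
followed by Benjamini-Hochberg FDR. The same machinery serves gene counts and
ATAC consensus-peak counts; features are just ids.

This is a deliberately transparent re-implementation of the usual
shrinkage-heavy packages: estimates are moment-based and documented, and
accuracy is validated against planted truth and analytic oracles rather than
against any particular package's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, ValidationError

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Normalization


def estimate_size_factors(counts: CountTable) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor(s) = median over features (nonzero in every sample) of
    count(f, s) / geometric-mean_f. When no feature is nonzero in all samples
    the total-count ratio is used instead, with a warning.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        ref = mat[all_nonzero]
        log_geo = np.log(ref).mean(axis=1)
        factors = np.median(np.exp(np.log(ref) - log_geo[:, None]), axis=0)
    else:
        warnings.warn(
            "no feature nonzero in all samples; falling back to total-count ratio",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if np.any(totals == 0):
            raise ValidationError("sample with zero total counts")
        factors = totals
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion


@dataclass
class DispersionEstimates:
    phi: pd.Series  # per-feature dispersion >= 0 (NaN for untestable features)
    method: str  # "moments" or "trend-shrunk"


def _group_masks(groups: pd.Series, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray, list]:
    g = groups.reindex(sample_ids)
    if g.isna().any():
        raise ValidationError("group labels missing for some samples")
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly two group levels required, got {levels}")
    m1 = (g == levels[0]).to_numpy()
    m2 = (g == levels[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    return m1, m2, levels


def estimate_dispersions(
    counts: CountTable,
    size_factors: pd.Series,
    groups: pd.Series,
    shrink_weight: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments dispersion on normalized counts, pooled within groups.

    phi_hat = max(0, (s2 - mu) / mu^2) with s2 the within-group pooled variance
    and mu the grand mean of normalized counts. With shrink_weight w > 0 the
    estimate is blended with a fitted mean-dispersion trend a/mu + b:
    phi = (1-w)*phi_hat + w*phi_trend(mu).
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValidationError("shrink_weight must lie in [0, 1]")
    m1, m2, _ = _group_masks(groups, counts.sample_ids)
    sf = size_factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    norm = counts.counts.to_numpy(dtype=float) / sf[None, :]

    mu = norm.mean(axis=1)
    n1, n2 = int(m1.sum()), int(m2.sum())
    var1 = norm[:, m1].var(axis=1, ddof=1)
    var2 = norm[:, m2].var(axis=1, ddof=1)
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.maximum(0.0, (s2 - mu) / mu**2)
    phi[mu == 0] = np.nan

    method = "moments"
    if shrink_weight > 0:
        ok = np.isfinite(phi) & (mu > 0)
        # least squares for phi = a/mu + b over moment estimates
        if ok.sum() >= 10:
            x = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
            coef, *_ = np.linalg.lstsq(x, phi[ok], rcond=None)
            a, b = coef
            trend = np.maximum(0.0, a / np.where(mu > 0, mu, np.nan) + b)
            phi = np.where(ok, (1 - shrink_weight) * phi + shrink_weight * trend, phi)
            method = "trend-shrunk"
    return DispersionEstimates(
        phi=pd.Series(phi, index=counts.feature_ids, name="dispersion"), method=method
    )


# ---------------------------------------------------------------------------
# Wald test


def nb_wald_test(
    counts: CountTable,
    size_factors: pd.Series,
    dispersions: DispersionEstimates,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-feature Wald test of log2(mu_2 / mu_1) under the NB model.

    Group means are computed on size-factor-normalized counts; when a group
    mean is zero, half the smallest nonzero normalized count of that feature
    is added to both group means to keep the ratio finite. The standard error
    comes from the delta method on Var(k_ij) = s_j*mu + phi*(s_j*mu)^2.
    Features with zero counts in both groups are reported untested (NaN).
    """
    m1, m2, levels = _group_masks(groups, counts.sample_ids)
    sf = size_factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    raw = counts.counts.to_numpy(dtype=float)
    norm = raw / sf[None, :]
    phi = dispersions.phi.reindex(counts.feature_ids).to_numpy(dtype=float)

    n1, n2 = int(m1.sum()), int(m2.sum())
    mu1 = norm[:, m1].mean(axis=1)
    mu2 = norm[:, m2].mean(axis=1)
    base_mean = norm.mean(axis=1)

    testable = (mu1 > 0) | (mu2 > 0)
    mn = np.min(np.where(norm > 0, norm, np.inf), axis=1)
    min_nonzero = np.where(np.isfinite(mn), mn, np.nan)
    pseudo = np.where((mu1 == 0) | (mu2 == 0), 0.5 * min_nonzero, 0.0)
    a1 = mu1 + pseudo
    a2 = mu2 + pseudo

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(a2 / a1)
        phi_eff = np.where(np.isfinite(phi), phi, 0.0)
        # Var(mean of normalized counts) per group; y_ij = k_ij / s_j has
        # variance mu/s_j + phi*mu^2 under the NB model.
        v1 = (a1[:, None] / sf[m1][None, :] + phi_eff[:, None] * a1[:, None] ** 2).sum(axis=1) / n1**2
        v2 = (a2[:, None] / sf[m2][None, :] + phi_eff[:, None] * a2[:, None] ** 2).sum(axis=1) / n2**2
        se = np.sqrt(v1 / (a1**2) + v2 / (a2**2)) / LOG2
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    log2fc[~testable] = np.nan
    se[~testable] = np.nan
    p[~testable] = np.nan

    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "group1": levels[0],
            "group2": levels[1],
        }
    )


# ---------------------------------------------------------------------------
# Multiple testing, direction calls and pi ranking


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1.

    NaN entries (untested features) propagate as NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        out = np.empty(m)
        out[order] = qv
        q[ok] = out
    return q


def call_degs(
    results: pd.DataFrame, lfc_min: float = 1.0, q_max: float = 0.05
) -> pd.Series:
    """UP iff log2FC >= lfc_min and q < q_max; DN iff log2FC <= -lfc_min and
    q < q_max; otherwise NS (untested features are NS)."""
    lfc = results["log2fc"]
    q = results["q"]
    sig = q.notna() & (q < q_max)
    direction = np.where(
        sig & (lfc >= lfc_min), "UP", np.where(sig & (lfc <= -lfc_min), "DN", "NS")
    )
    return pd.Series(direction, index=results.index, name="direction")


def pi_values(results: pd.DataFrame, q_floor: float = 1e-300) -> pd.Series:
    """pi = log2FC * -log10(q); q = 0 is clamped to ``q_floor`` with a warning."""
    q = results["q"].to_numpy(dtype=float)
    if np.any(q == 0):
        warnings.warn("q = 0 clamped before -log10", stacklevel=2)
        q = np.maximum(q, q_floor)
    pi = results["log2fc"].to_numpy(dtype=float) * -np.log10(q)
    return pd.Series(pi, index=results.index, name="pi")


def pi_rank(results: pd.DataFrame) -> pd.DataFrame:
    """Attach pi values and sort descending (ties broken by feature id)."""
    out = results.copy()
    out["pi"] = pi_values(results)
    return out.sort_values(
        ["pi", "feature_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# One-call pipeline


def run_de(
    counts: CountTable,
    groups: pd.Series,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Size factors -> dispersions -> Wald test -> BH -> direction calls -> pi."""
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf, groups, shrink_weight=shrink_weight)
    res = nb_wald_test(counts, sf, disp, groups)
    res["q"] = adjust_bh(res["p"].to_numpy())
    res["direction"] = call_degs(res, lfc_min=lfc_min, q_max=q_max)
    res["pi"] = pi_values(res)
    return res
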