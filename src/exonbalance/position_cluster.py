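"""Positional analysis of direction-labelled genes.

Genes are treated as points at their start coordinate (strand is ignored).
Sliding 10-Mb windows (1-Mb step) are scored per category — all genes,
coding/lncRNA, and UP/DN split by biotype — as fold enrichment of window
density over chromosome-wide density. Windows whose UP-coding enrichment
clears both the chromosomal and the local-gene-density thresholds, with
enough UP genes, are merged into cluster calls. Gene-set overlap enrichment
uses the hypergeometric upper tail with BH correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .io import GeneAnnotationTable, ValidationError

CATEGORIES = (
    "all",
    "coding",
    "lncRNA",
    "up_coding",
    "up_lncRNA",
    "dn_coding",
    "dn_lncRNA",
)


def _gene_frame(
    annotation: GeneAnnotationTable, directions: pd.Series
) -> pd.DataFrame:
    df = annotation.genes[["gene_id", "chrom", "start", "biotype"]].copy()
    missing = set(directions.index) - set(df["gene_id"])
    if missing:
        raise ValidationError(
            f"directed genes missing from annotation: {sorted(missing)[:5]}"
        )
    df["direction"] = df["gene_id"].map(directions).fillna("NS")
    return df


def _category_flags(df: pd.DataFrame) -> pd.DataFrame:
    coding = df["biotype"] == "protein_coding"
    lnc = df["biotype"] == "lncRNA"
    up = df["direction"] == "UP"
    dn = df["direction"] == "DN"
    return pd.DataFrame(
        {
            "all": np.ones(len(df), dtype=bool),
            "coding": coding,
            "lncRNA": lnc,
            "up_coding": up & coding,
            "up_lncRNA": up & lnc,
            "dn_coding": dn & coding,
            "dn_lncRNA": dn & lnc,
        },
        index=df.index,
    )


def chromosome_summary(
    annotation: GeneAnnotationTable,
    directions: pd.Series,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-chromosome counts and densities (genes per Mb) by category,
    plus a genome-wide "total" row."""
    df = _gene_frame(annotation, directions)
    unknown = set(df["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValidationError(f"genes on unknown chromosome(s): {sorted(unknown)}")
    flags = _category_flags(df)
    rows = []
    for chrom, length in chrom_lengths.items():
        sel = df["chrom"] == chrom
        row = {"chrom": chrom, "length_bp": length}
        for cat in CATEGORIES:
            n = int(flags.loc[sel, cat].sum())
            row[f"n_{cat}"] = n
            row[f"density_{cat}"] = n / (length / 1e6)
        rows.append(row)
    total_len = sum(chrom_lengths.values())
    total = {"chrom": "total", "length_bp": total_len}
    for cat in CATEGORIES:
        n = int(flags[cat].sum())
        total[f"n_{cat}"] = n
        total[f"density_{cat}"] = n / (total_len / 1e6)
    rows.append(total)
    return pd.DataFrame(rows)


def scan_windows(
    annotation: GeneAnnotationTable,
    directions: pd.Series,
    chrom_lengths: dict[str, int],
    window_bp: int = 10_000_000,
    step_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Sliding-window category counts and fold enrichments per chromosome.

    The final partial window is kept and its density uses the actual span.
    fe_vs_chrom = window density / chromosome density per category (NaN when
    the chromosome has no genes of that category). fe_vs_local (UP-coding
    only) = the window's UP-coding share of genes divided by the chromosome's
    UP-coding share (NaN for windows with no genes).
    """
    if not (window_bp >= step_bp > 0):
        raise ValidationError("require window >= step > 0")
    df = _gene_frame(annotation, directions)
    unknown = set(df["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValidationError(f"genes on unknown chromosome(s): {sorted(unknown)}")
    flags = _category_flags(df)
    out = []
    for chrom, length in chrom_lengths.items():
        sel = (df["chrom"] == chrom).to_numpy()
        starts = df.loc[sel, "start"].to_numpy()
        cflags = {c: flags.loc[sel, c].to_numpy() for c in CATEGORIES}
        chrom_n = {c: int(cflags[c].sum()) for c in CATEGORIES}
        chrom_dens = {c: chrom_n[c] / length for c in CATEGORIES}
        chrom_up_share = (
            chrom_n["up_coding"] / chrom_n["all"] if chrom_n["all"] else np.nan
        )
        if window_bp >= length:
            win_starts = [0]
        else:
            win_starts = list(range(0, length - window_bp + step_bp, step_bp))
            if win_starts[-1] + window_bp < length:
                win_starts.append(win_starts[-1] + step_bp)
        for ws in win_starts:
            we = min(ws + window_bp, length)
            span = we - ws
            inside = (starts >= ws) & (starts < we)
            row = {"chrom": chrom, "start": ws, "end": we, "span_bp": span}
            for cat in CATEGORIES:
                n = int(cflags[cat][inside].sum())
                row[f"n_{cat}"] = n
                dens = n / span
                row[f"fe_{cat}"] = (
                    dens / chrom_dens[cat] if chrom_dens[cat] > 0 else np.nan
                )
            n_all = row["n_all"]
            if n_all > 0 and chrom_up_share and chrom_up_share > 0:
                row["fe_local_up_coding"] = (
                    row["n_up_coding"] / n_all
                ) / chrom_up_share
            else:
                row["fe_local_up_coding"] = np.nan
            out.append(row)
    return pd.DataFrame(out)


@dataclass
class ClusterCall:
    chrom: str
    start: int
    end: int
    peak_start: int
    peak_end: int
    fe_vs_chrom: float
    fe_vs_local: float
    n_up: int


def call_clusters(
    windows: pd.DataFrame,
    fe_chrom_min: float = 2.0,
    fe_local_min: float = 2.0,
    min_up: int = 5,
) -> pd.DataFrame:
    """Merge qualified windows into cluster calls.

    A window qualifies when its UP-coding fold enrichment over the chromosome
    average and over local gene density both reach the thresholds and it holds
    at least ``min_up`` UP coding genes. Overlapping or bookended qualified
    windows on the same chromosome merge; the peak is the window with maximal
    fe_vs_chrom.
    """
    qual = windows[
        (windows["fe_up_coding"] >= fe_chrom_min)
        & (windows["fe_local_up_coding"] >= fe_local_min)
        & (windows["n_up_coding"] >= min_up)
    ].sort_values(["chrom", "start"])
    calls = []
    for chrom, sub in qual.groupby("chrom", sort=True):
        current: list[pd.Series] = []
        for _, w in sub.iterrows():
            if current and w["start"] <= current[-1]["end"]:
                current.append(w)
            else:
                if current:
                    calls.append(_merge_cluster(chrom, current))
                current = [w]
        if current:
            calls.append(_merge_cluster(chrom, current))
    cols = [
        "chrom", "start", "end", "peak_start", "peak_end",
        "fe_vs_chrom", "fe_vs_local", "n_up",
    ]
    return pd.DataFrame([c.__dict__ for c in calls], columns=cols)


def _merge_cluster(chrom: str, members: list[pd.Series]) -> ClusterCall:
    peak = max(members, key=lambda w: w["fe_up_coding"])
    return ClusterCall(
        chrom=chrom,
        start=int(min(w["start"] for w in members)),
        end=int(max(w["end"] for w in members)),
        peak_start=int(peak["start"]),
        peak_end=int(peak["end"]),
        fe_vs_chrom=float(peak["fe_up_coding"]),
        fe_vs_local=float(peak["fe_local_up_coding"]),
        n_up=int(max(w["n_up_coding"] for w in members)),
    )


def biotype_fractions(
    directions: pd.Series, annotation: GeneAnnotationTable, conf: float = 0.95
) -> pd.DataFrame:
    """lncRNA fraction among UP and among DN genes with Clopper-Pearson CI."""
    df = _gene_frame(annotation, directions)
    rows = []
    for direction in ("UP", "DN"):
        sub = df[df["direction"] == direction]
        n = len(sub)
        if n == 0:
            rows.append(
                {"direction": direction, "n": 0, "n_lncRNA": 0,
                 "fraction": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        k = int((sub["biotype"] == "lncRNA").sum())
        alpha = 1.0 - conf
        low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        rows.append(
            {"direction": direction, "n": n, "n_lncRNA": k,
             "fraction": k / n, "ci_low": low, "ci_high": high}
        )
    return pd.DataFrame(rows)


def overlap_enrichment(
    query: set[str], collection: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric upper-tail overlap of a query gene list with named sets.

    Sets are intersected with the universe before testing; p = P(X >= k) with
    population N = |universe|, K = |set|, draws n = |query|. BH across the
    collection; sorted by p then set name.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    if not set(query) <= set(universe):
        raise ValidationError("query must be a subset of the universe")
    n = len(query)
    big_n = len(universe)
    rows = []
    for name, members in collection.items():
        in_universe = set(members) & set(universe)
        k_cap = len(in_universe)
        k = len(in_universe & set(query))
        p = float(stats.hypergeom.sf(k - 1, big_n, k_cap, n)) if k_cap else 1.0
        rows.append(
            {
                "set": name,
                "set_size": k_cap,
                "query_size": n,
                "universe_size": big_n,
                "overlap": k,
                "percent_overlap": 100.0 * k / k_cap if k_cap else np.nan,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out.sort_values(["p", "set"]).reset_index(drop=True)
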