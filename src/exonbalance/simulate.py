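"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its spec (including the seed): identical
specs give bit-identical outputs. Planted truth is always returned alongside
the data so downstream recovery can be scored without external files.

Count noise is negative binomial parameterized by mean mu and dispersion phi
with variance mu + phi*mu^2; phi = 0 degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountTable, GeneAnnotationTable, SampleMetadata

# Representative per-exon lengths (bp) for a 16-exon gene model, exon ids 2-17.
DEFAULT_EXON_LENGTHS: tuple[int, ...] = (
    132, 92, 121, 185, 76, 154, 103, 88, 187, 142, 164, 95, 178, 118, 109, 640,
)
DEFAULT_EXON_IDS: tuple[int, ...] = tuple(range(2, 18))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion) -> np.ndarray:
    """NB draw with variance mu + phi*mu^2; phi = 0 is special-cased to Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if np.any(phi < 0):
        raise ValueError("dispersion must be >= 0")
    if np.all(phi == 0):
        return rng.poisson(mean)
    phi = np.broadcast_to(phi, mean.shape).copy()
    out = np.empty(mean.shape, dtype=np.int64)
    zero = phi == 0
    if zero.any():
        out[zero] = rng.poisson(mean[zero])
    nz = ~zero
    r = 1.0 / phi[nz]
    p = r / (r + mean[nz])
    out[nz] = rng.negative_binomial(r, p)
    return out


def _library_scales(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal per-sample depth factors with mean 1 and the given CV."""
    if cv < 0:
        raise ValueError("library_size_cv must be >= 0")
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# Exon-level counts (within-gene coverage profile)


@dataclass
class ExonSimSpec:
    """Exon-level NB counts with an optional 3'-shifted regime.

    Expected count for exon e in sample s is

        scale_s * exon_length(e) * (base_abundance + alpha * [e >= internal_tss_exon])

    so ``alpha`` > 0 emulates a second transcript starting inside the gene
    (elevated 3' coverage) and ``alpha`` < 0 a 3'-depleted profile; the
    downstream/upstream length-normalized ratio is 1 + alpha/base_abundance.
    """

    exon_ids: Sequence[int] = DEFAULT_EXON_IDS
    exon_lengths: Sequence[int] = DEFAULT_EXON_LENGTHS
    base_abundance: float = 5.0
    internal_tss_exon: int = 10
    alpha: float = 0.0
    dispersion: float = 0.05
    library_size_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.exon_ids) != len(self.exon_lengths):
            raise ValueError("exon_ids and exon_lengths lengths differ")
        if len(self.exon_ids) < 2:
            raise ValueError("need at least two exons")
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be > 0")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be > 0")
        if self.base_abundance + self.alpha <= 0:
            raise ValueError("base_abundance + alpha must stay > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.internal_tss_exon not in self.exon_ids:
            raise ValueError("internal_tss_exon not in exon_ids")

    def expected_rates(self) -> np.ndarray:
        """Per-exon per-bp expected coverage (before library scaling)."""
        ids = np.asarray(self.exon_ids)
        return self.base_abundance + self.alpha * (ids >= self.internal_tss_exon)


def simulate_exon_counts(
    spec: ExonSimSpec, n_samples: int, sample_ids: Sequence[str] | None = None
) -> CountTable:
    """Draw an exons x samples NB count table under the two-transcript model.

    Overdispersion acts at the gene level: each sample draws one Gamma
    abundance factor (mean 1, CV^2 = dispersion) shared by every exon, and
    exon counts are Poisson around scale * factor * length * rate. Marginally
    each exon count is NB with variance mu + dispersion*mu^2, while the
    within-sample exon ratio carries only Poisson read noise — the structure
    real exon-level coverage of a single gene has.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lengths = np.asarray(spec.exon_lengths, dtype=float)
    rates = spec.expected_rates()
    scales = _library_scales(rng, n_samples, spec.library_size_cv)
    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        gene_factor = rng.gamma(shape, scale=spec.dispersion, size=n_samples)
    else:
        gene_factor = np.ones(n_samples)
    mean = lengths[:, None] * rates[:, None] * (scales * gene_factor)[None, :]
    counts = rng.poisson(mean)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    df = pd.DataFrame(
        counts, index=[f"exon_{e}" for e in spec.exon_ids], columns=list(sample_ids)
    )
    df.index.name = "feature_id"
    return CountTable(df)


# ---------------------------------------------------------------------------
# Cohorts with planted imbalance-regime structure


@dataclass
class CohortSimSpec:
    """A cohort assembled from planted exon-imbalance regimes.

    ``regime_alpha`` values are chosen relative to the exon spec's base
    abundance so the expected downstream:upstream ratio of regime k is
    1 + alpha_k / base_abundance.
    """

    group_sizes: Sequence[int]
    regime_alpha: Sequence[float]
    stage_assignment: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) == 0:
            raise ValueError("at least one regime is required")
        if len(self.group_sizes) != len(self.regime_alpha):
            raise ValueError("group_sizes and regime_alpha lengths differ")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("every regime needs >= 1 sample")
        n = sum(self.group_sizes)
        if self.stage_assignment is not None and len(self.stage_assignment) != n:
            raise ValueError("stage_assignment length must equal total samples")


def regime_alpha_for_ratio(ratio: float, base_abundance: float) -> float:
    """Alpha giving an expected downstream:upstream ratio of ``ratio``."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return (ratio - 1.0) * base_abundance


def simulate_cohort(
    spec: CohortSimSpec, exon_spec: ExonSimSpec
) -> tuple[CountTable, SampleMetadata, pd.DataFrame]:
    """Concatenate per-regime exon tables; return counts, metadata and truth."""
    from .dnf_index import classify_group

    seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.group_sizes))
    tables, truth_rows = [], []
    offset = 0
    for k, (n_k, alpha_k) in enumerate(zip(spec.group_sizes, spec.regime_alpha)):
        regime_spec = ExonSimSpec(
            exon_ids=exon_spec.exon_ids,
            exon_lengths=exon_spec.exon_lengths,
            base_abundance=exon_spec.base_abundance,
            internal_tss_exon=exon_spec.internal_tss_exon,
            alpha=alpha_k,
            dispersion=exon_spec.dispersion,
            library_size_cv=exon_spec.library_size_cv,
            seed=int(seeds[k].generate_state(1)[0] % (2**31)),
        )
        ids = [f"S{offset + i + 1:04d}" for i in range(n_k)]
        tables.append(simulate_exon_counts(regime_spec, n_k, sample_ids=ids).counts)
        ratio = 1.0 + alpha_k / exon_spec.base_abundance
        for sid in ids:
            truth_rows.append((sid, k, alpha_k, ratio, classify_group(ratio)))
        offset += n_k
    counts = pd.concat(tables, axis=1)
    counts.index.name = "feature_id"
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "regime", "alpha", "expected_ratio", "expected_group"],
    )
    if spec.stage_assignment is not None:
        stages = list(spec.stage_assignment)
    else:
        cycle = ("I", "II", "III", "IV")
        stages = [cycle[i % 4] for i in range(offset)]
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": truth["sample_id"],
                "stage": stages,
                "subtype": "NA",
                "receptor_status": "NA",
            }
        )
    )
    return CountTable(counts), meta, truth


# ---------------------------------------------------------------------------
# Genomes with planted UP-gene clusters


@dataclass
class GenomeSimSpec:
    """A point-gene genome with direction labels and planted UP clusters.

    Background genes are placed uniformly per chromosome proportional to
    length; each is UP with probability deg_fraction*up_fraction and DN with
    probability deg_fraction*(1-up_fraction). Inside every planted cluster
    interval, additional UP genes are added so the local UP density reaches
    ``cluster_density_fold`` times the background UP density. Biotype defaults
    mirror the observed lncRNA shares among UP (38%) and DN (4%) genes.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000_000, "chr2": 200_000_000, "chr3": 200_000_000}
    )
    n_genes: int = 3900  # ~6.5 genes/Mb on the default 600-Mb genome, the human-genome rate
    deg_fraction: float = 0.08
    up_fraction: float = 0.15
    lncRNA_fraction: float = 0.30
    up_lncRNA_fraction: float = 0.38
    dn_lncRNA_fraction: float = 0.04
    cluster_intervals: Sequence[tuple[str, int, int]] = ()
    cluster_density_fold: float = 5.0
    cluster_lncRNA_fraction: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            self.deg_fraction,
            self.up_fraction,
            self.lncRNA_fraction,
            self.up_lncRNA_fraction,
            self.dn_lncRNA_fraction,
            self.cluster_lncRNA_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.cluster_density_fold < 1.0:
            raise ValueError("cluster_density_fold must be >= 1")
        for chrom, start, end in self.cluster_intervals:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"cluster on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"cluster {chrom}:{start}-{end} outside chromosome")


def simulate_genome(spec: GenomeSimSpec) -> tuple[GeneAnnotationTable, pd.Series, pd.DataFrame]:
    """Return (annotation, per-gene UP/DN/NS labels, planted-cluster truth)."""
    rng = np.random.default_rng(spec.seed)
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    genome_len = lengths.sum()
    per_chrom = rng.multinomial(spec.n_genes, lengths / genome_len)

    rows: list[tuple] = []
    directions: list[str] = []

    def add_gene(chrom: str, start: int, direction: str, is_lnc: bool) -> None:
        gid = f"g{len(rows) + 1:06d}"
        glen = int(rng.integers(1_000, 100_000))
        end = min(start + glen, spec.chrom_lengths[chrom])
        if end <= start:
            start = max(0, end - 1_000)
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((gid, chrom, start, end, strand, "lncRNA" if is_lnc else "protein_coding"))
        directions.append(direction)

    p_up = spec.deg_fraction * spec.up_fraction
    p_dn = spec.deg_fraction * (1.0 - spec.up_fraction)
    for chrom, n_c in zip(chroms, per_chrom):
        starts = np.sort(rng.integers(0, spec.chrom_lengths[chrom] - 1, size=n_c))
        u = rng.random(n_c)
        for s, ui in zip(starts, u):
            if ui < p_up:
                direction, p_lnc = "UP", spec.up_lncRNA_fraction
            elif ui < p_up + p_dn:
                direction, p_lnc = "DN", spec.dn_lncRNA_fraction
            else:
                direction, p_lnc = "NS", spec.lncRNA_fraction
            add_gene(chrom, int(s), direction, bool(rng.random() < p_lnc))

    bg_up_density = spec.n_genes * p_up / genome_len  # genes per bp
    truth_rows = []
    for chrom, start, end in spec.cluster_intervals:
        extra_mean = (spec.cluster_density_fold - 1.0) * bg_up_density * (end - start)
        n_extra = int(rng.poisson(extra_mean))
        for s in np.sort(rng.integers(start, end - 1, size=n_extra)):
            add_gene(chrom, int(s), "UP", bool(rng.random() < spec.cluster_lncRNA_fraction))
        truth_rows.append((chrom, start, end, n_extra))
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "n_planted_up"])

    ann = GeneAnnotationTable(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])
    )
    dirs = pd.Series(directions, index=ann.genes["gene_id"].to_numpy(), name="direction")
    return ann, dirs, truth


# ---------------------------------------------------------------------------
# Two-group count matrices with planted log2 fold changes


@dataclass
class DegSimSpec:
    """Two-condition NB count matrix with planted log2 fold changes.

    Baseline means are log-uniform over ``mean_range``; planted features get a
    group-2 mean of baseline * 2**log2fc. ``n_per_group`` is an int or a
    (n1, n2) pair.
    """

    n_features: int = 2000
    n_per_group: int | tuple[int, int] = 20
    mean_range: tuple[float, float] = (5.0, 500.0)
    dispersion: float = 0.1
    n_up: int = 0
    n_dn: int = 0
    lfc_up: float = 2.0
    lfc_dn: float = -2.0
    library_size_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_up + self.n_dn > self.n_features:
            raise ValueError("more planted features than features")
        if self.n_up and self.lfc_up == 0 or self.n_dn and self.lfc_dn == 0:
            raise ValueError("planted log2FC must be nonzero")
        if self.mean_range[0] <= 0 or self.mean_range[1] < self.mean_range[0]:
            raise ValueError("invalid mean_range")

    @property
    def group_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_group, int):
            return (self.n_per_group, self.n_per_group)
        return tuple(self.n_per_group)  # type: ignore[return-value]


def simulate_deg_counts(spec: DegSimSpec) -> tuple[CountTable, pd.Series, pd.DataFrame]:
    """Return (counts, condition labels g1/g2, planted-truth table)."""
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.group_sizes
    m = spec.n_features
    lo, hi = spec.mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))

    lfc = np.zeros(m)
    planted = rng.choice(m, size=spec.n_up + spec.n_dn, replace=False)
    lfc[planted[: spec.n_up]] = spec.lfc_up
    lfc[planted[spec.n_up :]] = spec.lfc_dn

    scales = _library_scales(rng, n1 + n2, spec.library_size_cv)
    mean = base[:, None] * scales[None, :]
    mean[:, n1:] *= (2.0**lfc)[:, None]
    counts = _nb_sample(rng, mean, spec.dispersion)

    fids = [f"f{i + 1:05d}" for i in range(m)]
    sids = [f"S{j + 1:04d}" for j in range(n1 + n2)]
    table = CountTable(pd.DataFrame(counts, index=fids, columns=sids))
    groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=sids, name="condition")
    truth = pd.DataFrame(
        {"feature_id": fids, "baseline_mean": base, "true_log2fc": lfc}
    )
    truth["planted"] = np.where(lfc > 0, "UP", np.where(lfc < 0, "DN", "NS"))
    return table, groups, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables with coupled/uncoupled amplicons


def coupling_matrix(
    amplicons: Sequence[str] = ("ex5", "ex7", "ex14", "ex16"),
    within_rd: float = 0.95,
    within_ad: float = 0.95,
    between: float = 0.0,
) -> pd.DataFrame:
    """Block correlation: 5'-domain pair coupled, 3'-domain pair coupled,
    cross-domain coupling set by ``between``."""
    half = len(amplicons) // 2
    r = np.full((len(amplicons), len(amplicons)), between, dtype=float)
    r[:half, :half] = within_rd
    r[half:, half:] = within_ad
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=list(amplicons), columns=list(amplicons))


@dataclass
class QpcrSimSpec:
    """Per-sample latent log2 amplicon abundances with a coupling structure.

    Ct = reference_ct + target_ct_offset - log2 abundance + N(0, ct_noise_sd).
    """

    n_samples: int = 60
    amplicons: Sequence[str] = ("ex5", "ex7", "ex14", "ex16")
    coupling: pd.DataFrame | None = None
    abundance_log2_sd: float = 1.0
    ct_noise_sd: float = 0.25
    reference_ct: float = 15.0
    target_ct_offset: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.coupling is None:
            self.coupling = coupling_matrix(self.amplicons)
        r = self.coupling.loc[list(self.amplicons), list(self.amplicons)].to_numpy()
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(r, r.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ValueError("coupling matrix must be positive semi-definite")


def simulate_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Return a long-form Ct table: sample_id, amplicon, ct, reference_ct."""
    rng = np.random.default_rng(spec.seed)
    amps = list(spec.amplicons)
    r = spec.coupling.loc[amps, amps].to_numpy()
    cov = spec.abundance_log2_sd**2 * r
    latent = rng.multivariate_normal(np.zeros(len(amps)), cov, size=spec.n_samples,
                                     method="eigh")
    noise = (
        rng.normal(0.0, spec.ct_noise_sd, size=latent.shape)
        if spec.ct_noise_sd > 0
        else np.zeros_like(latent)
    )
    ct = spec.reference_ct + spec.target_ct_offset - latent + noise
    rows = []
    for i in range(spec.n_samples):
        sid = f"S{i + 1:04d}"
        for j, amp in enumerate(amps):
            rows.append((sid, amp, float(ct[i, j]), spec.reference_ct))
    return pd.DataFrame(rows, columns=["sample_id", "amplicon", "ct", "reference_ct"])
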