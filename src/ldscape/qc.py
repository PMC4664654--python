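"""Within-population SNP and sample quality control.

Filters mirror standard SNP-chip practice for breed-level panels: drop
non-autosomal markers, then samples with excess missingness, then one member
of each closely related pair (PI_HAT), then SNPs failing call rate, minor
allele frequency, and an exact Hardy-Weinberg test.  The fixed order matters
(sample removal changes SNP statistics) and is documented here rather than
made configurable, so reports are reproducible.

All filters are applied within each population independently using
within-population allele frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for :func:`apply_qc`.

    Defaults: SNPs need a call rate >= 0.95 and MAF >= 0.05 and exact-HWE
    p >= 0.001; samples may miss at most 10% of genotypes; of any sample pair
    with PI_HAT > 0.25 one member is dropped.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    max_sample_missing: float = 0.10
    max_ibd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha", "max_sample_missing", "max_ibd"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------

def snp_call_rate(g: GenotypeMatrix, snp_index: int) -> float:
    """Fraction of samples with a non-missing genotype at one SNP."""
    col = g.genotypes[:, snp_index]
    return float((col != MISSING).sum() / col.size)


def call_rates(g: GenotypeMatrix) -> np.ndarray:
    """Vector of per-SNP call rates."""
    return (g.genotypes != MISSING).mean(axis=0)


def sample_missing_rates(g: GenotypeMatrix) -> np.ndarray:
    return (g.genotypes == MISSING).mean(axis=1)


def allele2_freqs(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of allele2; NaN where all genotypes are missing."""
    geno = g.genotypes
    ok = geno != MISSING
    n = ok.sum(axis=0)
    total = np.where(ok, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, total / (2.0 * n), np.nan)


def minor_allele_freq(g: GenotypeMatrix, snp_index: int) -> float:
    """min(p, 1-p) for allele2 frequency p; NaN if the SNP is all-missing."""
    p = allele2_freqs(g.subset(snps=[snp_index]))[0]
    return float(min(p, 1.0 - p)) if np.isfinite(p) else float("nan")


def minor_allele_freqs(g: GenotypeMatrix) -> np.ndarray:
    p = allele2_freqs(g)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def _het_probabilities(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Returns (support, probabilities) for the number of heterozygotes among
    ``n`` diploids carrying ``n_a`` copies of the rarer allele, under random
    union of gametes (Levene's distribution).  Computed by the stable ratio
    recurrence from the modal class.
    """
    n_b = 2 * n - n_a
    if n_a > n_b:  # ensure n_a is the rarer allele count
        n_a, n_b = n_b, n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    probs = np.empty(hets.size, dtype=float)
    mid = hets.size // 2
    probs[mid] = 1.0
    # P(h+2)/P(h) = 4*n_aa*n_bb/((h+2)(h+1)) with n_aa=(n_a-h)/2, n_bb=(n_b-h)/2
    for k in range(mid, hets.size - 1):
        h = hets[k]
        probs[k + 1] = probs[k] * ((n_a - h) / 2.0) * ((n_b - h) / 2.0) * 4.0 / ((h + 2) * (h + 1))
    for k in range(mid, 0, -1):
        h = hets[k]
        probs[k - 1] = probs[k] * (h * (h - 1)) / (4.0 * ((n_a - h) / 2.0 + 1) * ((n_b - h) / 2.0 + 1))
    probs /= probs.sum()
    return hets, probs


def hwe_exact_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (plain, not mid-p).

    The p-value sums the probabilities of all heterozygote counts (given the
    observed allele counts and sample size) whose conditional probability does
    not exceed that of the observed count.  Monomorphic input returns 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_hom1 + n_het
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hets, probs = _het_probabilities(n, min(n_a, 2 * n - n_a))
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value for every SNP (vector convenience)."""
    geno = g.genotypes
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = geno[:, j]
        col = col[col != MISSING]
        out[j] = hwe_exact_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


# ---------------------------------------------------------------------------
# relatedness (PI_HAT, method of moments)
# ---------------------------------------------------------------------------

def ibd_pihat(
    g: GenotypeMatrix,
    sample_i: int,
    sample_j: int,
    freqs: np.ndarray | None = None,
    min_snps: int = 50,
) -> float:
    """Method-of-moments PI_HAT = P(IBD=2) + P(IBD=1)/2 for one sample pair.

    Observed identity-by-state counts over pairwise-complete polymorphic SNPs
    are equated with their expectations under IBD states 0/1/2 and solved
    sequentially; the state probabilities are truncated to [0, 1] and
    renormalised.  The expectations draw alleles *without replacement* from
    the observed allele pool (falling-factorial products instead of powers of
    the plug-in frequency), the small-sample correction that keeps PI_HAT
    unbiased near 0 when frequencies come from the same modest panel.
    Passing external reference ``freqs`` instead treats them as an
    effectively infinite allele pool.  Returns NaN when fewer than
    ``min_snps`` SNPs overlap.
    """
    geno = g.genotypes
    a = geno[sample_i]
    b = geno[sample_j]
    typed = geno != MISSING
    if freqs is not None:
        big = 1e9  # external frequencies: finite-pool corrections vanish
        finite = np.isfinite(freqs)
        n_alleles = np.where(finite, big, 0.0)
        na = np.where(finite, np.nan_to_num(freqs) * big, 0.0)
    else:
        n_alleles = 2 * typed.sum(axis=0)
        na = np.where(typed, geno, 0).sum(axis=0)  # copies of allele2 in the panel
    ok = (
        (a != MISSING) & (b != MISSING) & (na > 0) & (na < n_alleles) & (n_alleles >= 4)
    )
    if ok.sum() < min_snps:
        return float("nan")
    a, b = a[ok].astype(int), b[ok].astype(int)
    x = n_alleles[ok].astype(float)
    nA = na[ok].astype(float)
    nB = x - nA
    ibs = 2 - np.abs(a - b)
    n_ibs = np.array([(ibs == 0).sum(), (ibs == 1).sum(), (ibs == 2).sum()], dtype=float)

    d4 = x * (x - 1) * (x - 2) * (x - 3)
    d3 = x * (x - 1) * (x - 2)
    e0_ibs0 = float((2 * nA * (nA - 1) * nB * (nB - 1) / d4).sum())
    e0_ibs1 = float(
        (4 * nA * (nA - 1) * (nA - 2) * nB / d4 + 4 * nB * (nB - 1) * (nB - 2) * nA / d4).sum()
    )
    e0_ibs2 = float(ok.sum()) - e0_ibs0 - e0_ibs1
    e1_ibs1 = float((2 * nA * (nA - 1) * nB / d3 + 2 * nB * (nB - 1) * nA / d3).sum())
    e1_ibs2 = float(ok.sum()) - e1_ibs1
    n_tot = float(ok.sum())

    p0 = n_ibs[0] / e0_ibs0 if e0_ibs0 > 0 else 0.0
    p1 = (n_ibs[1] - p0 * e0_ibs1) / e1_ibs1 if e1_ibs1 > 0 else 0.0
    p2 = (n_ibs[2] - p0 * e0_ibs2 - p1 * e1_ibs2) / n_tot
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    s = probs.sum()
    if s > 0:
        probs = probs / s
    return float(probs[2] + probs[1] / 2.0)


def pihat_matrix(g: GenotypeMatrix, min_snps: int = 50) -> np.ndarray:
    """Symmetric PI_HAT matrix over all sample pairs (NaN diagonal)."""
    n = g.n_samples
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = ibd_pihat(g, i, j, min_snps=min_snps)
    return out


# ---------------------------------------------------------------------------
# staged QC
# ---------------------------------------------------------------------------

@dataclass
class PopulationQc:
    """QC outcome for one population."""

    population: str
    retained: GenotypeMatrix
    samples_removed_missing: list[str] = field(default_factory=list)
    samples_removed_ibd: list[str] = field(default_factory=list)
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0

    @property
    def n_samples_removed(self) -> int:
        return len(self.samples_removed_missing) + len(self.samples_removed_ibd)

    @property
    def n_snps_removed(self) -> int:
        return self.snps_removed_call_rate + self.snps_removed_maf + self.snps_removed_hwe


@dataclass
class QcReport:
    """Per-population QC outcomes plus the shared input dimensions."""

    per_population: dict[str, PopulationQc]
    n_input_samples: int
    n_input_snps: int

    def population(self, name: str) -> PopulationQc:
        return self.per_population[name]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for pop, r in self.per_population.items():
            rows.append(
                {
                    "population": pop,
                    "samples_in": r.retained.n_samples + r.n_samples_removed,
                    "samples_removed_missing": len(r.samples_removed_missing),
                    "samples_removed_ibd": len(r.samples_removed_ibd),
                    "samples_retained": r.retained.n_samples,
                    "snps_in": self.n_input_snps,
                    "snps_removed_call_rate": r.snps_removed_call_rate,
                    "snps_removed_maf": r.snps_removed_maf,
                    "snps_removed_hwe": r.snps_removed_hwe,
                    "snps_retained": r.retained.n_snps,
                }
            )
        return pd.DataFrame(rows)


def _qc_one_population(pop: str, g: GenotypeMatrix, cfg: QcConfig) -> PopulationQc:
    # (2) samples with excess missingness
    miss = sample_missing_rates(g)
    keep_samples = miss <= cfg.max_sample_missing
    removed_missing = [g.sample_ids[i] for i in np.flatnonzero(~keep_samples)]
    g = g.subset(samples=np.flatnonzero(keep_samples))

    # (3) relatedness pruning: drop the lower-call-rate member of each pair
    # with PI_HAT above the bound; tie broken by dropping the later sample id.
    removed_ibd: list[str] = []
    if g.n_samples >= 2:
        pihat = pihat_matrix(g)
        sample_cr = 1.0 - sample_missing_rates(g)
        active = np.ones(g.n_samples, dtype=bool)
        with np.errstate(invalid="ignore"):
            flagged = np.argwhere(np.triu(pihat > cfg.max_ibd, k=1))
        # deterministic processing order: by (i, j)
        for i, j in flagged:
            if not (active[i] and active[j]):
                continue
            if sample_cr[i] < sample_cr[j]:
                drop = i
            elif sample_cr[j] < sample_cr[i]:
                drop = j
            else:
                drop = i if g.sample_ids[i] > g.sample_ids[j] else j
            active[drop] = False
            removed_ibd.append(g.sample_ids[drop])
        g = g.subset(samples=np.flatnonzero(active))

    if g.n_samples == 0:
        raise ValueError(
            f"population {pop!r}: all samples removed by QC; relax max_sample_missing/max_ibd"
        )

    # (4) call rate
    cr = call_rates(g)
    keep = cr >= cfg.min_call_rate
    n_call = int((~keep).sum())
    g = g.subset(snps=np.flatnonzero(keep))

    # (5) MAF
    maf = minor_allele_freqs(g)
    keep = maf >= cfg.min_maf
    n_maf = int((~keep).sum())
    g = g.subset(snps=np.flatnonzero(keep))

    # (6) HWE exact test
    pvals = hwe_pvalues(g)
    keep = pvals >= cfg.hwe_alpha
    n_hwe = int((~keep).sum())
    g = g.subset(snps=np.flatnonzero(keep))

    if g.n_snps == 0:
        raise ValueError(f"population {pop!r}: all SNPs removed by QC; relax thresholds")

    return PopulationQc(
        population=pop,
        retained=g,
        samples_removed_missing=removed_missing,
        samples_removed_ibd=removed_ibd,
        snps_removed_call_rate=n_call,
        snps_removed_maf=n_maf,
        snps_removed_hwe=n_hwe,
    )


def apply_qc(g: GenotypeMatrix, cfg: QcConfig = QcConfig()) -> QcReport:
    """Run the staged QC within each population independently.

    Stage order: samples by missingness, samples by relatedness, then SNPs by
    call rate, MAF, and HWE.  Non-autosomal markers are assumed already
    dropped at load time (the reader enforces this).
    """
    if g.population is None:
        raise ValueError("population labels must be attached before QC")
    per_pop = {
        pop: _qc_one_population(pop, sub, cfg)
        for pop, sub in g.split_by_population().items()
    }
    return QcReport(per_population=per_pop, n_input_samples=g.n_samples, n_input_snps=g.n_snps)


# ---------------------------------------------------------------------------
# marker summaries
# ---------------------------------------------------------------------------

def maf_spectrum(g: GenotypeMatrix, bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Proportion of SNPs per MAF bin (half-open bins; last bin closed).

    Returns a DataFrame with columns bin_lower, bin_upper, proportion, plus
    the per-matrix mean and sd of MAF in ``.attrs``.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 0.55, 0.05)
    maf = minor_allele_freqs(g)
    maf = maf[np.isfinite(maf)]
    counts, edges = np.histogram(maf, bins=bin_edges)
    out = pd.DataFrame(
        {
            "bin_lower": edges[:-1],
            "bin_upper": edges[1:],
            "proportion": counts / counts.sum() if counts.sum() else np.nan,
        }
    )
    out.attrs["maf_mean"] = float(maf.mean()) if maf.size else float("nan")
    out.attrs["maf_sd"] = float(maf.std(ddof=1)) if maf.size > 1 else float("nan")
    return out


def chromosome_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-chromosome marker coverage: count, span, and mean inter-SNP gap.

    span = max(pos) - min(pos); mean gap = span / (count - 1).  A chromosome
    with fewer than two SNPs gets NaN span/gap.
    """
    rows = []
    for chrom, sub in g.markers.groupby("chrom", sort=True):
        pos = sub["pos_bp"].to_numpy()
        n = len(pos)
        span = float(pos.max() - pos.min()) if n >= 2 else float("nan")
        rows.append(
            {
                "chrom": chrom,
                "n_snps": n,
                "span_bp": span,
                "mean_gap_bp": span / (n - 1) if n >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
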