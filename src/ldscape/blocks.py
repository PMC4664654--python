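"""Haplotype-block detection by the Gabriel confidence-interval method.

A pair of SNPs is classified from the confidence interval of |D'|, obtained
by profiling the two-locus multinomial likelihood over D' in [0, 1] with
allele frequencies held at their sample estimates:

* STRONG_LD      — CI lower bound >= 0.70 and upper bound >= 0.98;
* RECOMB         — CI upper bound < 0.90 (strong evidence of historical
                   recombination);
* UNINFORMATIVE  — anything else.

A block is a run of markers whose outermost pair is STRONG_LD and in which at
least 95% of informative pairs (STRONG_LD or RECOMB) are STRONG_LD.  The
constants are the Haploview defaults and are all exposed in
:class:`BlockParams`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .ldcore import EmSettings, _em_batch, _pair_count_tables, _two_locus_genotype_probs
from .qc import minor_allele_freqs


class PairClass(enum.Enum):
    STRONG_LD = "STRONG_LD"
    RECOMB = "RECOMB"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class DprimeCI:
    lower: float
    upper: float
    classification: PairClass

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper <= 1):
            raise ValueError("require 0 <= lower <= upper <= 1")


@dataclass(frozen=True)
class BlockParams:
    """Gabriel-scan constants (Haploview-default values)."""

    confidence: float = 0.90
    strong_lower: float = 0.70
    strong_upper: float = 0.98
    recomb_upper: float = 0.90
    informative_frac: float = 0.95
    min_maf: float = 0.05
    max_span_kb: float = 500.0
    grid_points: int = 101


@dataclass(frozen=True)
class HaploBlock:
    chrom: int
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...]

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# D' confidence intervals by likelihood profiling
# ---------------------------------------------------------------------------

def _profile_loglik(counts: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Log-likelihood of each table over a grid of |D'| values.

    ``counts``: (P, 3, 3) tables; returns (P, len(grid)).  The sign of D is
    taken from the EM solution of each table; |D'| scales the corresponding
    signed Dmax.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(1, 2))
    pA = (counts.sum(axis=2) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    pB = (counts.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    pAB_em, _, _ = _em_batch(counts, 1e-10, 2000)
    D_em = pAB_em - pA * pB
    dmax = np.where(
        D_em >= 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    sign = np.where(D_em >= 0, 1.0, -1.0)
    D = sign[:, None] * dmax[:, None] * grid[None, :]  # (P, G)
    pAB = pA[:, None] + 0 * D
    pAB = pA[:, None] * pB[:, None] + D
    pAb = pA[:, None] - pAB
    paB = pB[:, None] - pAB
    pab = 1 - pA[:, None] - pB[:, None] + pAB
    eps = 1e-12
    probs = _two_locus_genotype_probs(
        np.clip(pAB, eps, 1), np.clip(pAb, eps, 1), np.clip(paB, eps, 1), np.clip(pab, eps, 1)
    )
    return (counts[:, None, :, :] * np.log(probs)).sum(axis=(2, 3))


def _ci_batch(counts: np.ndarray, params: BlockParams) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) |D'| CI bounds for a stack of 3x3 tables."""
    grid = np.linspace(0.0, 1.0, params.grid_points)
    ll = _profile_loglik(counts, grid)
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    w /= w.sum(axis=1, keepdims=True)
    alpha_half = (1.0 - params.confidence) / 2.0
    cum_lo = np.cumsum(w, axis=1)
    cum_hi = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    lower_idx = np.argmax(cum_lo >= alpha_half, axis=1)
    upper_idx = grid.size - 1 - np.argmax(cum_hi[:, ::-1] >= alpha_half, axis=1)
    return grid[lower_idx], grid[upper_idx]


def _classify(lower: np.ndarray, upper: np.ndarray, params: BlockParams) -> np.ndarray:
    out = np.full(lower.shape, PairClass.UNINFORMATIVE, dtype=object)
    out[(lower >= params.strong_lower) & (upper >= params.strong_upper)] = PairClass.STRONG_LD
    out[upper < params.recomb_upper] = PairClass.RECOMB
    return out


def dprime_ci(
    counts: np.ndarray, confidence: float = 0.90, params: BlockParams | None = None
) -> DprimeCI:
    """|D'| confidence interval and Gabriel classification for one pair.

    Degenerate tables (either locus monomorphic, or no samples) are
    UNINFORMATIVE with the vacuous interval [0, 1].
    """
    if params is None:
        params = BlockParams(confidence=confidence)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("counts must be a 3x3 table")
    n = counts.sum()
    if n < 1:
        return DprimeCI(0.0, 1.0, PairClass.UNINFORMATIVE)
    pA = (counts.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    pB = (counts.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    if not (0 < pA < 1 and 0 < pB < 1):
        return DprimeCI(0.0, 1.0, PairClass.UNINFORMATIVE)
    lower, upper = _ci_batch(counts[None], params)
    cls = _classify(lower, upper, params)[0]
    return DprimeCI(float(lower[0]), float(upper[0]), cls)


# ---------------------------------------------------------------------------
# Gabriel block scan
# ---------------------------------------------------------------------------

@dataclass
class BlockSummary:
    """Panel-level block structure summary (Table-1-style columns)."""

    n_blocks: int
    total_length_bp: int
    mean_length_bp: float
    snps_in_blocks: int
    mean_snps_per_block: float
    max_snps_per_block: int

    def to_frame(self, population: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "population": population,
                    "n_blocks": self.n_blocks,
                    "total_length_bp": self.total_length_bp,
                    "mean_length_bp": self.mean_length_bp,
                    "snps_in_blocks": self.snps_in_blocks,
                    "mean_snps_per_block": self.mean_snps_per_block,
                    "max_snps_per_block": self.max_snps_per_block,
                }
            ]
        )


def summarize_blocks(blocks: list[HaploBlock]) -> BlockSummary:
    if not blocks:
        return BlockSummary(0, 0, float("nan"), 0, float("nan"), 0)
    lengths = [b.length_bp for b in blocks]
    counts = [b.n_snps for b in blocks]
    return BlockSummary(
        n_blocks=len(blocks),
        total_length_bp=int(sum(lengths)),
        mean_length_bp=float(np.mean(lengths)),
        snps_in_blocks=int(sum(counts)),
        mean_snps_per_block=float(np.mean(counts)),
        max_snps_per_block=int(max(counts)),
    )


def find_blocks(
    g: GenotypeMatrix,
    params: BlockParams = BlockParams(),
    em_settings: EmSettings = EmSettings(),
) -> tuple[list[HaploBlock], BlockSummary]:
    """Gabriel confidence-interval block scan on a single-population matrix.

    Candidate spans have a STRONG_LD outermost pair, physical span at most
    ``max_span_kb``, and members with MAF >= ``min_maf``; a candidate is
    accepted when >= ``informative_frac`` of its informative internal pairs
    are STRONG_LD.  Acceptance is greedy from the longest span downward
    (ties: leftmost start), skipping overlaps.  Blocks never span chromosome
    boundaries.
    """
    maf = minor_allele_freqs(g)
    eligible = np.flatnonzero(maf >= params.min_maf)
    chrom_arr = g.markers["chrom"].to_numpy()
    pos_arr = g.markers["pos_bp"].to_numpy()
    blocks: list[HaploBlock] = []

    for c in np.unique(chrom_arr):
        idx = eligible[chrom_arr[eligible] == c]
        m = idx.size
        if m < 2:
            continue
        pos = pos_arr[idx]
        # classify all eligible pairs within the span bound
        pair_list = []
        hi = np.searchsorted(pos, pos + params.max_span_kb * 1000.0, side="right")
        for a in range(m):
            for b in range(a + 1, hi[a]):
                pair_list.append((a, b))
        if not pair_list:
            continue
        pairs = np.array(pair_list)
        tables = _pair_count_tables(g.genotypes, np.column_stack([idx[pairs[:, 0]], idx[pairs[:, 1]]]))
        lower, upper = _ci_batch(tables, params)
        # degenerate tables -> uninformative
        n_t = tables.sum(axis=(1, 2)).astype(float)
        pA = (tables.sum(axis=2) @ np.array([0.0, 1.0, 2.0])) / (2 * n_t)
        pB = (tables.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n_t)
        cls = _classify(lower, upper, params)
        degenerate = ~((pA > 0) & (pA < 1) & (pB > 0) & (pB < 1))
        cls[degenerate] = PairClass.UNINFORMATIVE
        cls_mat = np.full((m, m), PairClass.UNINFORMATIVE, dtype=object)
        cls_mat[pairs[:, 0], pairs[:, 1]] = cls

        # candidate spans: outermost pair strong, >= 2 markers
        candidates = []
        for a, b in pairs[cls == PairClass.STRONG_LD]:
            candidates.append((pos[b] - pos[a], a, b))
        candidates.sort(key=lambda t: (-t[0], pos[t[1]]))

        used = np.zeros(m, dtype=bool)
        for span, a, b in candidates:
            if used[a : b + 1].any():
                continue
            members = np.arange(a, b + 1)
            sub = cls_mat[np.ix_(members, members)]
            iu = np.triu_indices(members.size, k=1)
            labels = sub[iu]
            n_strong = int((labels == PairClass.STRONG_LD).sum())
            n_recomb = int((labels == PairClass.RECOMB).sum())
            n_inform = n_strong + n_recomb
            if n_inform == 0 or n_strong / n_inform < params.informative_frac:
                continue
            used[a : b + 1] = True
            blocks.append(
                HaploBlock(
                    chrom=int(c),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    snp_indices=tuple(int(i) for i in idx[a : b + 1]),
                )
            )

    blocks.sort(key=lambda b: (b.chrom, b.start_bp))
    return blocks, summarize_blocks(blocks)


def blocks_to_frame(blocks: list[HaploBlock], g: GenotypeMatrix) -> pd.DataFrame:
    """BED-like table (1-based inclusive) with comma-joined member SNP ids."""
    ids = g.markers["id"].to_numpy()
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "n_snps": b.n_snps,
                "snp_ids": ",".join(ids[list(b.snp_indices)]),
            }
            for b in blocks
        ],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "snp_ids"],
    )
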