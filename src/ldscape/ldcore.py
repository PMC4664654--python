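"""Two-locus LD from unphased genotypes via EM haplotype-frequency estimation.

For a pair of biallelic SNPs the 3x3 genotype table determines all haplotype
counts except for double heterozygotes, which mix the coupling (AB/ab) and
repulsion (Ab/aB) phases.  The EM iteration splits the double-het class by the
current phase probabilities (E-step) and recounts haplotypes (M-step),
maximising the two-locus multinomial likelihood.  From the converged pAB we
derive D = pAB - pA*pB, D' = |D|/Dmax, the signed correlation r, and r^2.

"A" and "B" denote allele2 at each locus (the genotype-code convention of
:mod:`ldscape.io`), so the sign of r refers to the allele2/allele2 haplotype.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .qc import minor_allele_freqs

PAIR_COLUMNS = [
    "chrom", "snp_i", "snp_j", "id_i", "id_j", "distance_bp",
    "pA", "pB", "pAB", "D", "Dprime", "r", "r2", "n_eff",
    "maf_i", "maf_j", "converged",
]


@dataclass(frozen=True)
class EmSettings:
    """EM convergence control: stop when |delta pAB| < tol or at max_iter."""

    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class EmResult:
    pAB: float
    converged: bool
    n_iter: int

    def __float__(self) -> float:
        return self.pAB


@dataclass(frozen=True)
class PairLD:
    """LD statistics for one syntenic SNP pair."""

    snp_i: int
    snp_j: int
    distance_bp: int
    pA: float
    pB: float
    pAB: float
    D: float
    Dprime: float
    r: float
    r2: float
    n_eff: int
    converged: bool = True
    defined: bool = True


# ---------------------------------------------------------------------------
# EM on 3x3 genotype count tables
# ---------------------------------------------------------------------------

def counts_from_genotypes(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts over pairwise-complete samples.

    Rows index the code at the first locus, columns the second.
    """
    ok = (gi != MISSING) & (gj != MISSING)
    idx = gi[ok].astype(np.int64) * 3 + gj[ok].astype(np.int64)
    return np.bincount(idx, minlength=9).reshape(3, 3)


def _two_locus_genotype_probs(pAB, pAb, paB, pab):
    """3x3 genotype-class probabilities from haplotype frequencies.

    Inputs broadcast; output has shape (..., 3, 3).  Diploids are random
    unions of two gametes; the double-het class pools both phases.
    """
    h = np.stack([pab, paB, pAb, pAB], axis=-1)  # haplotype k: A-bit = k>>1, B-bit = k&1
    out = np.zeros(np.asarray(h).shape[:-1] + (3, 3))
    for k1 in range(4):
        for k2 in range(4):
            out[..., (k1 >> 1) + (k2 >> 1), (k1 & 1) + (k2 & 1)] += h[..., k1] * h[..., k2]
    return out


def _table_loglik(t: np.ndarray, pAB: np.ndarray, pA: np.ndarray, pB: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of each 3x3 table at given pAB (vectorised)."""
    probs = _two_locus_genotype_probs(pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(np.maximum(probs, 1e-300))
    return (t * lp).sum(axis=(-2, -1))


def _em_single_start(t, n, pA, pB, known_AB, n_dh, init, tol, max_iter):
    """One EM run from the given per-table initial pAB."""
    pAB = init.copy()
    converged = np.zeros(len(t), dtype=bool)
    n_iter = np.zeros(len(t), dtype=int)
    mono = (pA <= 0) | (pA >= 1) | (pB <= 0) | (pB >= 1)
    converged[mono] = True
    pAB[mono] = (pA * pB)[mono]
    active = ~converged
    for _ in range(max_iter):
        if not active.any():
            break
        pab = 1 - pA - pB + pAB
        pAb = pA - pAB
        paB = pB - pAB
        num = pAB * pab
        den = num + pAb * paB
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(den > 0, num / den, 0.5)
        new = (known_AB + n_dh * f) / (2 * n)
        done = np.abs(new - pAB) < tol
        pAB = np.where(active, new, pAB)
        n_iter[active] += 1
        converged |= active & done
        active &= ~done
    return pAB, converged, n_iter


def _em_batch(
    tables: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over a stack of 3x3 tables.

    Three deterministic starts are run — linkage equilibrium pA*pB plus one
    near each boundary of the admissible interval
    [max(0, pA+pB-1), min(pA, pB)] — and the converged solution with the
    highest likelihood is kept (ties: smallest pAB).  The extra starts cost
    little and protect against the saddle at pA*pB that equilibrium-only EM
    cannot leave (e.g. a table of pure double heterozygotes, whose likelihood
    peaks at both D' = +/-1), and against local maxima of the two-locus
    likelihood.  Returns (pAB, converged, n_iter).  Tables where either locus
    is monomorphic yield pAB = pA*pB (D = 0) and are marked converged.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    n = t.sum(axis=(1, 2))
    g1 = t.sum(axis=2)  # counts by first-locus genotype
    g2 = t.sum(axis=1)
    pA = (g1[:, 1] + 2 * g1[:, 2]) / (2 * n)
    pB = (g2[:, 1] + 2 * g2[:, 2]) / (2 * n)
    known_AB = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    n_dh = t[:, 1, 1]

    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    width = hi - lo
    starts = [pA * pB, lo + 1e-3 * width, hi - 1e-3 * width]

    best = None
    for init in starts:
        pAB, conv, n_iter = _em_single_start(t, n, pA, pB, known_AB, n_dh, init, tol, max_iter)
        ll = _table_loglik(t, pAB, pA, pB)
        if best is None:
            best = [pAB, conv, n_iter, ll]
        else:
            better = (ll > best[3] + 1e-10) | (
                (np.abs(ll - best[3]) <= 1e-10) & (pAB < best[0] - 1e-12)
            )
            for k, new in enumerate((pAB, conv, n_iter, ll)):
                best[k] = np.where(better, new, best[k])
    return best[0], best[1].astype(bool), best[2].astype(int)


def em_haplotype_freq(counts: np.ndarray, settings: EmSettings = EmSettings()) -> EmResult:
    """EM estimate of the AB (allele2/allele2) haplotype frequency.

    ``counts`` is the 3x3 joint genotype count table.  A non-converged run
    returns the last iterate with ``converged=False``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("counts must be a 3x3 table")
    if counts.sum() < 1:
        raise ValueError("empty count table")
    pAB, conv, n_iter = _em_batch(counts[None], settings.tol, settings.max_iter)
    return EmResult(float(pAB[0]), bool(conv[0]), int(n_iter[0]))


def _ld_stats(
    pAB: np.ndarray, pA: np.ndarray, pB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(D, Dprime, r, r2) from haplotype and allele frequencies (vectorised)."""
    D = pAB - pA * pB
    with np.errstate(invalid="ignore", divide="ignore"):
        dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
        dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
        dmax = np.where(D >= 0, dmax_pos, dmax_neg)
        dprime = np.where(dmax > 0, np.abs(D) / dmax, np.nan)
        denom = np.sqrt(pA * (1 - pA) * pB * (1 - pB))
        r = np.where(denom > 0, D / denom, np.nan)
    return D, dprime, r, r * r


def ld_from_pair(
    g: GenotypeMatrix, snp_i: int, snp_j: int, settings: EmSettings = EmSettings()
) -> PairLD:
    """Full LD statistics for one same-chromosome SNP pair.

    Samples missing at either locus are excluded pairwise; allele frequencies
    are taken from the pairwise-complete subset for internal consistency.
    A locus monomorphic after missingness yields ``defined=False`` with NaN
    statistics.
    """
    mi, mj = g.markers.iloc[snp_i], g.markers.iloc[snp_j]
    if mi["chrom"] != mj["chrom"]:
        raise ValueError("ld_from_pair requires syntenic SNPs")
    counts = counts_from_genotypes(g.genotypes[:, snp_i], g.genotypes[:, snp_j])
    n_eff = int(counts.sum())
    distance = int(abs(int(mj["pos_bp"]) - int(mi["pos_bp"])))
    pAB_a, conv, _ = _em_batch(counts[None], settings.tol, settings.max_iter)
    n = counts.sum()
    pA = (counts.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    pB = (counts.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    defined = bool(0 < pA < 1 and 0 < pB < 1)
    if not defined:
        nan = float("nan")
        return PairLD(snp_i, snp_j, distance, float(pA), float(pB), nan, nan, nan,
                      nan, nan, n_eff, bool(conv[0]), False)
    D, dprime, r, r2 = _ld_stats(pAB_a, np.array([pA]), np.array([pB]))
    return PairLD(
        snp_i, snp_j, distance, float(pA), float(pB), float(pAB_a[0]),
        float(D[0]), float(dprime[0]), float(r[0]), float(r2[0]),
        n_eff, bool(conv[0]), True,
    )


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------

def syntenic_pairs(g: GenotypeMatrix, max_dist_bp: int) -> np.ndarray:
    """All (i, j), i<j, same chromosome, |pos_j - pos_i| <= max_dist_bp.

    Deterministic order: by (chrom, i, j).  Returns an (n_pairs, 2) int array.
    """
    chrom = g.markers["chrom"].to_numpy()
    pos = g.markers["pos_bp"].to_numpy()
    out = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        hi = np.searchsorted(p, p + max_dist_bp, side="right")
        for k, i in enumerate(idx):
            js = idx[k + 1 : hi[k]]
            if js.size:
                out.append(np.column_stack([np.full(js.size, i), js]))
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(out, axis=0)


def _pair_count_tables(geno: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Stack of 3x3 joint genotype count tables for the given pairs."""
    gi = geno[:, pairs[:, 0]]
    gj = geno[:, pairs[:, 1]]
    ok = (gi != MISSING) & (gj != MISSING)
    joint = (gi.astype(np.int64) * 3 + gj.astype(np.int64))
    n_pairs = pairs.shape[0]
    pair_idx = np.broadcast_to(np.arange(n_pairs), gi.shape)
    flat = pair_idx[ok] * 9 + joint[ok]
    return np.bincount(flat, minlength=n_pairs * 9).reshape(n_pairs, 3, 3)


def windowed_ld_scan(
    g: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    settings: EmSettings = EmSettings(),
    chunk_size: int = 20_000,
) -> pd.DataFrame:
    """EM-based LD for every syntenic pair within ``max_dist_bp``.

    Returns one row per pair (columns :data:`PAIR_COLUMNS`) in deterministic
    (chrom, i, j) order.  Pairs monomorphic among pairwise-complete samples
    get NaN statistics.  ``maf_i``/``maf_j`` are whole-matrix per-SNP MAFs so
    that consumers can filter by marker MAF thresholds without rescanning.
    """
    pairs = syntenic_pairs(g, max_dist_bp)
    maf = minor_allele_freqs(g)
    chrom = g.markers["chrom"].to_numpy()
    pos = g.markers["pos_bp"].to_numpy()
    ids = g.markers["id"].to_numpy()
    frames = []
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start : start + chunk_size]
        tables = _pair_count_tables(g.genotypes, chunk)
        n = tables.sum(axis=(1, 2)).astype(float)
        pA = (tables.sum(axis=2) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
        pB = (tables.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
        pAB, conv, _ = _em_batch(tables, settings.tol, settings.max_iter)
        D, dprime, r, r2 = _ld_stats(pAB, pA, pB)
        poly = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
        for arr in (D, dprime, r, r2):
            arr[~poly] = np.nan
        i, j = chunk[:, 0], chunk[:, 1]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom[i],
                    "snp_i": i,
                    "snp_j": j,
                    "id_i": ids[i],
                    "id_j": ids[j],
                    "distance_bp": np.abs(pos[j] - pos[i]).astype(np.int64),
                    "pA": pA,
                    "pB": pB,
                    "pAB": pAB,
                    "D": D,
                    "Dprime": dprime,
                    "r": r,
                    "r2": r2,
                    "n_eff": n.astype(int),
                    "maf_i": maf[i],
                    "maf_j": maf[j],
                    "converged": conv,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)[PAIR_COLUMNS]


def adjust_r2(r2, n, beta: int = 1):
    """Sample-size-adjusted LD: r2 - 1/(beta*n).

    beta=1 for unphased genotypes, beta=2 when gametic phase is known.  The
    result may be negative; flooring is left to consumers that require
    positivity.
    """
    if beta not in (1, 2):
        raise ValueError("beta must be 1 (unphased) or 2 (phased)")
    return np.asarray(r2, dtype=float) - 1.0 / (beta * np.asarray(n, dtype=float))
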