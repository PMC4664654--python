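"""Effective-population-size trajectories from binned, adjusted r^2.

At drift-recombination equilibrium the expected r^2 between loci at
recombination distance c in a population of effective size N is approximately
1/(alpha + 4Nc) (Sved's relation; alpha corrects for mutation).  Inverting it
per distance bin gives the effective size

    N_T = (4 f(c_t))^-1 * (E[r^2_adj | c_t]^-1 - alpha)

referring to T = 1/(2 f(c_t)) generations ago, where c_t is the bin's
representative recombination distance and r^2_adj = r^2 - 1/(beta n) removes
the finite-sample contribution (beta = 1 for unphased genotypes, 2 for known
gametic phase).  Physical distance maps to Morgans with a genome-wide
constant (default 1 cM/Mb); a Haldane transform is available for sensitivity
analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldcore import adjust_r2


def _default_c_bins() -> np.ndarray:
    # log-spaced recombination-distance bins; T = 1/(2c) covers ~10-1000
    # generations ago for distances of 50 kb - 5 Mb at 1 cM/Mb
    return np.geomspace(5e-4, 5e-2, 17)


@dataclass(frozen=True)
class NeSettings:
    """Parameters of the LD-to-Ne inversion.

    alpha: mutation correction (1 ignores mutation; 2 or 2.2 are common
    corrections).  beta: sample-size adjustment mode (1 unphased, 2 phased).
    map_function: LINEAR treats f(c)=c under the 1 cM/Mb convention; HALDANE
    applies f(c) = (1 - exp(-2m))/2 to the map distance m in Morgans.
    """

    alpha: float = 1.0
    beta: int = 1
    morgans_per_bp: float = 1e-8
    map_function: str = "LINEAR"
    bin_edges_c: np.ndarray = field(default_factory=_default_c_bins)
    exclude_nonpositive_pairs: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.beta not in (1, 2):
            raise ValueError("beta must be 1 or 2")
        if self.map_function not in ("LINEAR", "HALDANE"):
            raise ValueError("map_function must be LINEAR or HALDANE")

    def f(self, c):
        """Effective recombination rate for map distance c (Morgans)."""
        c = np.asarray(c, dtype=float)
        if self.map_function == "LINEAR":
            return np.minimum(c, 0.5)
        return 0.5 * (1.0 - np.exp(-2.0 * c))


@dataclass(frozen=True)
class NeBin:
    """One point of the Ne trajectory."""

    c_t: float
    T_gen: float
    mean_adj_r2: float
    Ne: float
    n_pairs: int
    floored: bool = False


NE_COLUMNS = ["T_gen", "Ne", "c_t", "mean_adj_r2", "n_pairs"]


def ne_from_bin(mean_adj_r2: float, c_t: float, settings: NeSettings = NeSettings()) -> NeBin:
    """Invert Sved's relation for one bin.

    Ne = (4 f(c_t))^-1 (1/mean_adj_r2 - alpha); a negative result (adjusted
    r^2 above 1/alpha) is floored at 0 with a flag; non-positive mean_adj_r2
    yields NaN (the bin is undefined).
    """
    if c_t <= 0:
        raise ValueError("c_t must be positive")
    f = float(settings.f(c_t))
    T = 1.0 / (2.0 * f)
    if not np.isfinite(mean_adj_r2) or mean_adj_r2 <= 0:
        return NeBin(c_t, T, float(mean_adj_r2), float("nan"), 0)
    ne = (1.0 / (4.0 * f)) * (1.0 / mean_adj_r2 - settings.alpha)
    floored = ne < 0
    return NeBin(c_t, T, float(mean_adj_r2), max(ne, 0.0), 0, floored)


def ne_trajectory(pairs: pd.DataFrame, settings: NeSettings = NeSettings()) -> pd.DataFrame:
    """Bin a pair table by recombination distance and invert each bin.

    ``pairs`` is a windowed-scan table (needs distance_bp, r2, n_eff).  Each
    pair's r^2 is adjusted with its own n_eff; negative adjusted values are
    kept in the bin average by default (truncating them inflates the mean and
    biases Ne downward), with ``exclude_nonpositive_pairs=True`` available as
    a sensitivity switch.  Returns one row per populated bin
    with columns :data:`NE_COLUMNS`, sorted by T_gen ascending (recent
    first).  The representative c_t is the mean pair c within the bin.
    """
    if pairs.empty:
        return pd.DataFrame(columns=NE_COLUMNS)
    ok = np.isfinite(pairs["r2"].to_numpy())
    c = pairs["distance_bp"].to_numpy(dtype=float) * settings.morgans_per_bp
    c = np.minimum(c, 0.5)
    adj = adjust_r2(pairs["r2"].to_numpy(), pairs["n_eff"].to_numpy(), settings.beta)
    if settings.exclude_nonpositive_pairs:
        ok &= adj > 0
    c, adj = c[ok], adj[ok]

    edges = np.asarray(settings.bin_edges_c, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (c >= lo) & (c < hi)
        if not in_bin.any():
            continue
        c_t = float(c[in_bin].mean())
        mean_adj = float(adj[in_bin].mean())
        nb = ne_from_bin(mean_adj, c_t, settings)
        rows.append(
            {
                "T_gen": nb.T_gen,
                "Ne": nb.Ne,
                "c_t": c_t,
                "mean_adj_r2": mean_adj,
                "n_pairs": int(in_bin.sum()),
            }
        )
    out = pd.DataFrame(rows, columns=NE_COLUMNS)
    return out.sort_values("T_gen", ascending=True, ignore_index=True)
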