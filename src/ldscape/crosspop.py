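"""Cross-population phase persistence, divergence time, and NJ trees.

When two populations descend from a common ancestor, the correlation (across
shared marker pairs) of their signed two-locus r statistics decays with the
recombination distance c between the markers approximately as exp(-2cT),
where T is the number of generations since the split.  Regressing
ln(correlation) on c therefore estimates T as -slope/2, and the correlation
in the shortest-distance bin approximates the LD of the common ancestral
population.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix
from .ldcore import EmSettings, windowed_ld_scan

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _orientation(a1: str, a2: str, b1: str, b2: str) -> float:
    """+1 if (b1,b2) matches (a1,a2) (directly or by strand flip), -1 if
    swapped, NaN if irreconcilable or strand-ambiguous (A/T, C/G)."""
    if {a1, a2} == {_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)}:
        return float("nan")  # ambiguous: complement equals the same allele set
    if (b1, b2) == (a1, a2):
        return 1.0
    if (b1, b2) == (a2, a1):
        return -1.0
    c1, c2 = _COMPLEMENT.get(b1), _COMPLEMENT.get(b2)
    if (c1, c2) == (a1, a2):
        return 1.0
    if (c1, c2) == (a2, a1):
        return -1.0
    return float("nan")


def shared_pair_phase(
    g_pop1: GenotypeMatrix,
    g_pop2: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    settings: EmSettings = EmSettings(),
) -> pd.DataFrame:
    """Signed r in both populations for every shared syntenic SNP pair.

    Markers are matched by id and allele-harmonised: a swapped allele1/allele2
    orientation negates that marker's contribution to r in population 2;
    strand-ambiguous (A/T, C/G) or irreconcilable markers are dropped with a
    logged count.  Returns columns id_i, id_j, distance_bp, r_pop1, r_pop2,
    maf-columns per population.
    """
    m1 = g_pop1.markers.set_index("id")
    m2 = g_pop2.markers.set_index("id")
    common = m1.index.intersection(m2.index)
    orient = {}
    n_dropped = 0
    for mid in common:
        o = _orientation(
            str(m1.at[mid, "allele1"]), str(m1.at[mid, "allele2"]),
            str(m2.at[mid, "allele1"]), str(m2.at[mid, "allele2"]),
        )
        if np.isnan(o):
            n_dropped += 1
        else:
            orient[mid] = o
    if n_dropped:
        logger.warning("dropped %d shared markers with ambiguous/irreconcilable alleles", n_dropped)

    keep1 = np.flatnonzero(g_pop1.markers["id"].isin(orient.keys()))
    keep2 = np.flatnonzero(g_pop2.markers["id"].isin(orient.keys()))
    s1 = g_pop1.subset(snps=keep1)
    s2 = g_pop2.subset(snps=keep2)

    scan1 = windowed_ld_scan(s1, max_dist_bp, settings)
    scan2 = windowed_ld_scan(s2, max_dist_bp, settings)
    scan1 = scan1.set_index(["id_i", "id_j"])
    scan2 = scan2.set_index(["id_i", "id_j"])
    joined = scan1.join(scan2, how="inner", lsuffix="_pop1", rsuffix="_pop2").reset_index()

    o = np.array([orient[i] for i in joined["id_i"]]) * np.array(
        [orient[j] for j in joined["id_j"]]
    )
    out = pd.DataFrame(
        {
            "id_i": joined["id_i"],
            "id_j": joined["id_j"],
            "chrom": joined["chrom_pop1"],
            "distance_bp": joined["distance_bp_pop1"],
            "r_pop1": joined["r_pop1"],
            "r_pop2": joined["r_pop2"] * o,
            "maf_i_pop1": joined["maf_i_pop1"],
            "maf_j_pop1": joined["maf_j_pop1"],
            "maf_i_pop2": joined["maf_i_pop2"],
            "maf_j_pop2": joined["maf_j_pop2"],
        }
    )
    ok = np.isfinite(out["r_pop1"]) & np.isfinite(out["r_pop2"])
    return out.loc[ok].reset_index(drop=True)


PHASE_COLUMNS = [
    "bin_lower_kb", "bin_upper_kb", "correlation", "n_pairs", "mean_dist_bp", "mean_c",
]


def phase_correlation(
    stream: pd.DataFrame,
    bin_width_kb: float = 10.0,
    max_kb: float = 1000.0,
    morgans_per_bp: float = 1e-8,
) -> pd.DataFrame:
    """Pearson correlation of (r_pop1, r_pop2) within half-open distance bins.

    Bins cover (0, max_kb] in ``bin_width_kb`` steps.  Bins with fewer than
    two pairs or zero variance get a NaN correlation.
    """
    edges = np.arange(0.0, max_kb + bin_width_kb, bin_width_kb)
    dist_kb = stream["distance_bp"].to_numpy() / 1000.0
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (dist_kb >= lo) & (dist_kb < hi)
        r1 = stream["r_pop1"].to_numpy()[in_bin]
        r2 = stream["r_pop2"].to_numpy()[in_bin]
        d = stream["distance_bp"].to_numpy()[in_bin]
        if r1.size >= 2 and np.std(r1) > 0 and np.std(r2) > 0:
            corr = float(np.corrcoef(r1, r2)[0, 1])
        else:
            corr = float("nan")
        rows.append(
            {
                "bin_lower_kb": lo,
                "bin_upper_kb": hi,
                "correlation": corr,
                "n_pairs": int(in_bin.sum()),
                "mean_dist_bp": float(d.mean()) if d.size else float("nan"),
                "mean_c": float(d.mean()) * morgans_per_bp if d.size else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=PHASE_COLUMNS)


@dataclass(frozen=True)
class DivergenceEstimate:
    """OLS fit of ln(phase correlation) on recombination distance c."""

    T: float
    slope: float
    intercept: float
    r0_sq_proxy: float
    n_bins_used: int
    floored: bool = False


def estimate_divergence_time(
    table: pd.DataFrame,
    fit_range_kb: tuple[float, float] = (0.0, 500.0),
    morgans_per_bp: float = 1e-8,
    include_first_bin: bool = True,
) -> DivergenceEstimate:
    """T (generations since divergence) from a phase-correlation table.

    Ordinary least squares of ln(correlation) on the mean recombination
    distance c of each bin, over bins inside ``fit_range_kb`` with a defined
    positive correlation; T = -slope/2.  A positive slope floors T at 0 with
    a flag.  The first-bin correlation is reported as the ancestral-LD proxy.
    """
    t = table.copy()
    in_range = (t["bin_lower_kb"] >= fit_range_kb[0]) & (t["bin_upper_kb"] <= fit_range_kb[1])
    t = t.loc[in_range]
    r0 = float(t["correlation"].iloc[0]) if len(t) else float("nan")
    usable = np.isfinite(t["correlation"]) & (t["correlation"] > 0) & np.isfinite(t["mean_c"])
    n_excluded = int((~usable & np.isfinite(t["correlation"])).sum())
    if n_excluded:
        logger.warning("excluded %d bins with non-positive correlation from log-regression", n_excluded)
    t = t.loc[usable]
    if not include_first_bin and len(t):
        t = t.iloc[1:]
    if len(t) < 3:
        raise ValueError(f"need >= 3 usable bins for the regression, have {len(t)}")
    c = t["mean_c"].to_numpy()
    y = np.log(t["correlation"].to_numpy())
    fit = stats.linregress(c, y)
    T = -fit.slope / 2.0
    floored = T < 0
    return DivergenceEstimate(
        T=max(T, 0.0),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r0_sq_proxy=r0,
        n_bins_used=len(t),
        floored=floored,
    )


# ---------------------------------------------------------------------------
# neighbor-joining trees
# ---------------------------------------------------------------------------

def check_distance_matrix(labels: list[str], d: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.abs(d - d.T).max() > tol:
        raise ValueError("distance matrix is asymmetric beyond tolerance")
    if np.abs(np.diag(d)).max() > tol:
        raise ValueError("distance matrix diagonal must be zero")
    return (d + d.T) / 2.0


def nj_tree(labels: list[str], d: np.ndarray) -> str:
    """Canonical Saitou-Nei neighbor-joining; returns a Newick string.

    Deterministic: the Q-matrix minimum is taken at the first (row-major)
    minimizing pair, so ties break by label order.  Two taxa yield a single
    edge of total length d split evenly.
    """
    d = check_distance_matrix(labels, d)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [f"{lab}" for lab in labels]
    if n == 2:
        half = d[0, 1] / 2.0
        return f"({nodes[0]}:{half:.10g},{nodes[1]}:{half:.10g});"

    active = list(range(n))
    dist = d.copy()
    newick = {i: nodes[i] for i in range(n)}
    next_id = n
    dist_full = {(i, j): dist[i, j] for i in range(n) for j in range(n)}

    def getd(i, j):
        return 0.0 if i == j else dist_full[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(getd(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * getd(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = getd(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (getd(i, k) + getd(j, k) - dij)
            dist_full[(min(u, k), max(u, k))] = duk
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [u]

    # resolve the final three nodes with the closed form
    i, j, k = active
    dij, dik, djk = getd(i, j), getd(i, k), getd(j, k)
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    return f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"


def divergence_matrix(
    estimates: dict[tuple[str, str], DivergenceEstimate], labels: list[str]
) -> tuple[list[str], np.ndarray]:
    """Assemble a symmetric pairwise-T matrix from divergence estimates."""
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), est in estimates.items():
        ia, ib = labels.index(a), labels.index(b)
        d[ia, ib] = d[ib, ia] = est.T
    return labels, d


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a labeled square TSV distance matrix (e.g. an external F_ST table)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError("distance matrix rows and columns must carry the same labels")
    return labels, df.to_numpy(dtype=float)
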