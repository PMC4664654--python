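"""EM haplotype frequencies vs a grid-search likelihood oracle; pair scans."""
import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ldscape.io import MISSING
from ldscape.ldcore import (
    EmSettings,
    _table_loglik,
    adjust_r2,
    counts_from_genotypes,
    em_haplotype_freq,
    ld_from_pair,
    syntenic_pairs,
    windowed_ld_scan,
)

from conftest import make_matrix


def grid_search_pAB(table: np.ndarray) -> float:
    """Independent maximizer of the explicit two-locus likelihood.

    Dense grid over the admissible pAB interval followed by a bounded
    scalar refinement inside the best bracket.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    pA = (t.sum(1) @ [0, 1, 2]) / (2 * n)
    pB = (t.sum(0) @ [0, 1, 2]) / (2 * n)
    lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
    if hi - lo < 1e-12:
        return lo
    grid = np.linspace(lo, hi, 4001)
    lls = _table_loglik(t, grid, np.full_like(grid, pA), np.full_like(grid, pB))
    k = int(np.argmax(lls))
    a, b = grid[max(0, k - 1)], grid[min(grid.size - 1, k + 1)]

    def neg(x):
        return -float(_table_loglik(t, np.asarray(x), np.asarray(pA), np.asarray(pB)))

    res = minimize_scalar(neg, bounds=(a, b), method="bounded", options={"xatol": 1e-12})
    return float(res.x) if neg(res.x) <= -lls[k] else float(grid[k])


def random_polymorphic_tables(n_tables: int, max_total: int, seed: int):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_tables:
        n = int(rng.integers(2, max_total + 1))
        t = rng.multinomial(n, rng.dirichlet(np.ones(9))).reshape(3, 3).astype(float)
        nA = t.sum(1) @ [0, 1, 2]
        nB = t.sum(0) @ [0, 1, 2]
        if nA in (0, 2 * n) or nB in (0, 2 * n):
            continue
        out.append(t)
    return out


def test_em_matches_grid_oracle_on_random_tables():
    """EM equals the likelihood maximizer to 1e-6 on 200 random tables."""
    settings = EmSettings(tol=1e-12, max_iter=10_000)
    worst = 0.0
    for t in random_polymorphic_tables(200, 30, seed=12345):
        em = em_haplotype_freq(t, settings).pAB
        assert abs(em - grid_search_pAB(t)) < 1e-6
        worst = max(worst, abs(em - grid_search_pAB(t)))
    assert worst < 1e-6


def test_em_unambiguous_phases_counting_estimate():
    """With no double heterozygotes EM converges to the direct gamete count."""
    t = np.zeros((3, 3))
    t[0, 0] = 2
    t[2, 2] = 2
    res = em_haplotype_freq(t)
    assert res.pAB == pytest.approx(0.5, abs=1e-12)
    assert res.n_iter <= 2
    g = make_matrix([[0, 0], [0, 0], [2, 2], [2, 2]])
    p = ld_from_pair(g, 0, 1)
    assert (p.pAB, p.D, p.r, p.r2) == pytest.approx((0.5, 0.25, 1.0, 1.0))


def test_em_independence_gives_zero_D():
    # planted product table: counts proportional to HWE independence
    t = np.outer([1, 2, 1], [1, 2, 1]) * 4.0
    res = em_haplotype_freq(t)
    assert res.pAB == pytest.approx(0.25, abs=1e-8)


def test_perfect_repulsion():
    g = make_matrix([[0, 2], [0, 2], [2, 0], [2, 0]])
    p = ld_from_pair(g, 0, 1)
    assert p.r == pytest.approx(-1.0)
    assert p.r2 == pytest.approx(1.0)
    assert p.Dprime == pytest.approx(1.0)


def test_allele_flip_symmetry():
    """Swapping allele1/allele2 at one locus flips r's sign, not r^2."""
    rng = np.random.default_rng(77)
    tight = EmSettings(tol=1e-13, max_iter=10_000)
    geno = rng.integers(0, 3, size=(40, 2)).astype(np.int8)
    g = make_matrix(geno)
    p = ld_from_pair(g, 0, 1, tight)
    flipped = geno.copy()
    flipped[:, 1] = 2 - flipped[:, 1]
    g2 = make_matrix(flipped)
    p2 = ld_from_pair(g2, 0, 1, tight)
    assert p2.r == pytest.approx(-p.r, abs=1e-7)
    assert p2.r2 == pytest.approx(p.r2, abs=1e-7)


def test_pair_symmetry_and_missing_handling():
    rng = np.random.default_rng(78)
    geno = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = MISSING
    g = make_matrix(geno)
    a = ld_from_pair(g, 0, 1)
    b = ld_from_pair(g, 1, 0)
    assert a.r2 == pytest.approx(b.r2, abs=1e-12)
    assert abs(a.r) == pytest.approx(abs(b.r), abs=1e-12)
    ok = (geno[:, 0] != MISSING) & (geno[:, 1] != MISSING)
    assert a.n_eff == int(ok.sum())
    assert counts_from_genotypes(geno[:, 0], geno[:, 1]).sum() == a.n_eff


def test_windowed_scan_pair_enumeration():
    g = make_matrix([[0, 1, 2]], positions=[1, 500_001, 1_200_001])
    pairs = syntenic_pairs(g, 1_000_000)
    assert pairs.tolist() == [[0, 1], [1, 2]]


def test_colocated_pair_count():
    n = 6
    g = make_matrix(np.zeros((2, n), dtype=np.int8), positions=[100] * n)
    assert len(syntenic_pairs(g, 1000)) == n * (n - 1) // 2


def test_scan_matches_brute_force(const_n_sim):
    g, _ = const_n_sim
    sub = g.subset(snps=np.arange(120))
    pairs = syntenic_pairs(sub, 1_000_000)
    chrom = sub.markers["chrom"].to_numpy()
    pos = sub.markers["pos_bp"].to_numpy()
    brute = [
        (i, j)
        for i in range(sub.n_snps)
        for j in range(i + 1, sub.n_snps)
        if chrom[i] == chrom[j] and abs(int(pos[j]) - int(pos[i])) <= 1_000_000
    ]
    assert pairs.tolist() == [list(p) for p in brute]
    # scan statistics agree with the single-pair path
    scan = windowed_ld_scan(sub, 1_000_000)
    for k in (0, len(scan) // 2, len(scan) - 1):
        row = scan.iloc[k]
        p = ld_from_pair(sub, int(row.snp_i), int(row.snp_j))
        assert row.r2 == pytest.approx(p.r2, abs=1e-9)
        assert row.n_eff == p.n_eff


def test_adjust_r2_formula():
    assert adjust_r2(0.30, 50, beta=1) == pytest.approx(0.28)
    assert adjust_r2(0.30, 50, beta=2) == pytest.approx(0.29)
    assert adjust_r2(1 / 100, 50, beta=2) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        adjust_r2(0.3, 50, beta=3)


def test_r2_decays_with_distance(const_n_sim):
    """Mean r^2 decreases over increasing distance classes at equilibrium."""
    from scipy.stats import spearmanr

    g, _ = const_n_sim
    scan = windowed_ld_scan(g, 2_000_000)
    dist = scan["distance_bp"].to_numpy()
    edges = np.linspace(0, 2_000_000, 9)
    means = [
        scan["r2"].to_numpy()[(dist >= a) & (dist < b)].mean()
        for a, b in zip(edges[:-1], edges[1:])
    ]
    rho, _ = spearmanr(np.arange(len(means)), means)
    assert rho == -1.0  # strictly decreasing class means
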