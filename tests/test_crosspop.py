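"""Phase persistence, divergence-time regression, neighbor-joining."""
import numpy as np
import pandas as pd
import pytest

from ldscape.crosspop import (
    estimate_divergence_time,
    nj_tree,
    phase_correlation,
    shared_pair_phase,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# phase streams and correlations
# ---------------------------------------------------------------------------

def two_random_pops(seed, n=60, m=40):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.2, 0.8, m)
    draw = lambda: (
        (rng.random((n, m)) < freqs).astype(np.int8)
        + (rng.random((n, m)) < freqs).astype(np.int8)
    )
    return make_matrix(draw(), positions=(np.arange(m) * 5000 + 1).tolist()), make_matrix(
        draw(), positions=(np.arange(m) * 5000 + 1).tolist()
    )


def test_self_comparison_r_equal(split_sim):
    g, _ = split_sim
    pop = g.split_by_population()["P1"].subset(snps=np.arange(100))
    stream = shared_pair_phase(pop, pop, 500_000)
    assert len(stream) > 0
    assert np.allclose(stream.r_pop1, stream.r_pop2, atol=1e-12)
    table = phase_correlation(stream)
    populated = table.dropna(subset=["correlation"])
    assert (populated.correlation > 0.999999).all()


def test_allele_swap_harmonization():
    """Swapping allele1/allele2 at one SNP in one population changes nothing
    after harmonization."""
    from ldscape.ldcore import EmSettings

    tight = EmSettings(tol=1e-13, max_iter=10_000)
    g1, g2 = two_random_pops(41)
    base = shared_pair_phase(g1, g2, 500_000, settings=tight)
    m = g2.markers.copy()
    m.loc[3, ["allele1", "allele2"]] = ["G", "A"]
    geno = g2.genotypes.copy()
    geno[:, 3] = 2 - geno[:, 3]
    g2s = make_matrix(geno, positions=m["pos_bp"].tolist(), alleles=("A", "G"))
    g2s.markers.loc[3, ["allele1", "allele2"]] = ["G", "A"]
    swapped = shared_pair_phase(g1, g2s, 500_000, settings=tight)
    merged = base.merge(swapped, on=["id_i", "id_j"], suffixes=("", "_sw"))
    assert np.allclose(merged.r_pop2, merged.r_pop2_sw, atol=1e-7)


def test_ambiguous_alleles_dropped():
    g1, g2 = two_random_pops(42)
    g1.markers.loc[0, ["allele1", "allele2"]] = ["A", "T"]  # strand-ambiguous
    g2.markers.loc[0, ["allele1", "allele2"]] = ["A", "T"]
    stream = shared_pair_phase(g1, g2, 500_000)
    assert "snp1" not in set(stream.id_i) | set(stream.id_j)


def test_independent_populations_near_zero_correlation():
    g1, g2 = two_random_pops(43, n=80, m=60)
    stream = shared_pair_phase(g1, g2, 500_000)
    table = phase_correlation(stream, bin_width_kb=1000.0)
    corr = table.dropna(subset=["correlation"]).correlation
    assert len(corr) >= 1
    assert np.abs(corr).max() < 0.25  # null correlation at ~1700 pairs


def test_constant_r_bin_flagged():
    stream = pd.DataFrame(
        {"distance_bp": [5000, 6000], "r_pop1": [0.5, 0.5], "r_pop2": [0.1, 0.2]}
    )
    table = phase_correlation(stream)
    assert np.isnan(table.loc[0, "correlation"])


# ---------------------------------------------------------------------------
# divergence-time regression
# ---------------------------------------------------------------------------

def exponential_table(T, bins_kb=np.arange(5, 500, 10)):
    c = bins_kb * 1000 * 1e-8
    return pd.DataFrame(
        {
            "bin_lower_kb": bins_kb - 5,
            "bin_upper_kb": bins_kb + 5,
            "correlation": np.exp(-2 * c * T),
            "n_pairs": 100,
            "mean_dist_bp": bins_kb * 1000.0,
            "mean_c": c,
        }
    )


@pytest.mark.parametrize("T", [0.0, 25.0, 150.0, 600.0])
def test_noiseless_exponential_recovered_exactly(T):
    est = estimate_divergence_time(exponential_table(T))
    assert est.T == pytest.approx(T, abs=1e-6)
    if T == 150.0:
        assert est.slope == pytest.approx(-300.0, rel=1e-9)


def test_positive_slope_floors_at_zero():
    table = exponential_table(50.0)
    table["correlation"] = table["correlation"].iloc[::-1].to_numpy()  # rising
    est = estimate_divergence_time(table)
    assert est.T == 0.0 and est.floored


def test_nonpositive_bins_excluded():
    table = exponential_table(100.0)
    table.loc[3, "correlation"] = -0.05
    est = estimate_divergence_time(table)
    assert est.n_bins_used == len(table) - 1
    assert est.T == pytest.approx(100.0, rel=0.05)


def test_split_time_recovered_from_simulation(split_sim):
    """Two populations split 100 generations ago: T̂ within +/-35%."""
    g, truth = split_sim
    pops = g.split_by_population()
    stream = shared_pair_phase(pops["P1"], pops["P2"], 1_000_000)
    table = phase_correlation(stream, 10.0)
    est = estimate_divergence_time(table, (0.0, 500.0))
    T_true = truth.split_generations_ago("P1", "P2")
    assert T_true == 100
    assert 65 <= est.T <= 135
    # correlations decrease with distance (short vs long range)
    short = table.correlation[:10].mean()
    long = table.correlation[40:50].mean()
    assert short > long


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    nwk = nj_tree(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    import dendropy

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_nj_two_taxa_edge():
    nwk = nj_tree(["A", "B"], np.array([[0.0, 4.2], [4.2, 0.0]]))
    import dendropy

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(4.2)


def random_additive_matrix(rng, n_taxa=6):
    """Distances induced by a random binary tree with random edge lengths."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = rng.uniform(0.1, 2.0)
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
    return labels, d


def test_nj_reproduces_additive_matrices_exactly():
    """On additive matrices the NJ tree metric equals the input to 1e-9."""
    import random

    import dendropy

    for seed in range(5):
        rng = random.Random(seed)
        labels, d = random_additive_matrix(rng)
        nwk = nj_tree(labels, d)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {t.label: t for t in tree.taxon_namespace}
        pdm = tree.phylogenetic_distance_matrix()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j], abs=1e-9)


def test_nj_matches_scikit_bio():
    """Independent cross-check against scikit-bio's NJ on a random matrix."""
    import random

    import dendropy
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    labels, d = random_additive_matrix(random.Random(99))
    ours = dendropy.Tree.get(data=nj_tree(labels, d), schema="newick",
                             taxon_namespace=dendropy.TaxonNamespace(labels))
    theirs = dendropy.Tree.get(
        data=str(skbio_nj(DistanceMatrix(d, labels))),
        schema="newick", taxon_namespace=ours.taxon_namespace,
    )
    rf = dendropy.calculate.treecompare.symmetric_difference(ours, theirs)
    assert rf == 0


def test_asymmetric_matrix_rejected():
    with pytest.raises(ValueError, match="asymmetric"):
        nj_tree(["A", "B", "C"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float))
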