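"""QC statistics against enumeration oracles and planted-defect fixtures."""
import numpy as np
import pytest
from scipy.special import gammaln

from ldscape.io import MISSING
from ldscape.qc import (
    QcConfig,
    apply_qc,
    call_rates,
    chromosome_summary,
    hwe_exact_pvalue,
    ibd_pihat,
    maf_spectrum,
    minor_allele_freq,
    minor_allele_freqs,
    snp_call_rate,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Direct enumeration of Levene's conditional distribution."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    if na == 0 or na == 2 * n:
        return 1.0
    na = min(na, 2 * n - na)
    hets = np.arange(na % 2, na + 1, 2)
    aa = (na - hets) // 2
    bb = n - aa - hets
    lp = (
        gammaln(n + 1) - gammaln(aa + 1) - gammaln(hets + 1) - gammaln(bb + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    # the het count is invariant under allele relabeling, so it indexes the
    # rarer-allele support directly
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def test_call_rate_and_maf_basic():
    g = make_matrix([[0], [0], [1]])
    assert snp_call_rate(g, 0) == 1.0
    assert minor_allele_freq(g, 0) == pytest.approx(1 / 6)
    g2 = make_matrix([[2], [2]])
    assert minor_allele_freq(g2, 0) == 0.0
    g3 = make_matrix([[MISSING]] + [[0]] * 9)
    assert snp_call_rate(g3, 0) == pytest.approx(0.9)


def test_planted_missingness_rate(const_n_sim):
    g, _ = const_n_sim
    # this run has no missingness; plant 4% and recompute
    rng = np.random.default_rng(0)
    geno = g.genotypes.copy()
    mask = rng.random(geno.shape) < 0.04
    geno[mask] = MISSING
    g2 = make_matrix(geno[:, :200])
    assert call_rates(g2).mean() == pytest.approx(1 - mask[:, :200].mean(), abs=1e-12)


def test_hwe_exact_small_cases():
    # 2 diploids, both het: allele counts 2/2; P(het=2)=2/3, P(het=0)=1/3
    assert hwe_exact_pvalue(0, 2, 0) == pytest.approx(1.0)
    assert hwe_exact_pvalue(1, 0, 1) == pytest.approx(1 / 3)
    assert hwe_exact_pvalue(7, 0, 0) == 1.0  # monomorphic


def test_hwe_matches_enumeration_oracle():
    rng = np.random.default_rng(202)
    for _ in range(400):
        n = int(rng.integers(1, 51))
        h1 = int(rng.integers(0, n + 1))
        het = int(rng.integers(0, n - h1 + 1))
        h2 = n - h1 - het
        assert hwe_exact_pvalue(h1, het, h2) == pytest.approx(
            hwe_enumeration_oracle(h1, het, h2), abs=1e-12
        )


def test_pihat_self_and_unrelated(const_n_sim):
    g, _ = const_n_sim
    # duplicate of itself -> IBS2 everywhere -> PI_HAT 1
    geno = np.vstack([g.genotypes[:5], g.genotypes[0:1]])
    gd = make_matrix(geno)
    assert ibd_pihat(gd, 0, 5) == pytest.approx(1.0, abs=1e-6)
    # independent draws from the same population -> ~0
    vals = [abs(ibd_pihat(g, i, j)) for i, j in [(0, 1), (2, 3), (4, 5)]]
    assert max(vals) < 0.15


def test_pihat_full_sibs():
    """Gametes drawn from two shared parents give PI_HAT near 0.5."""
    rng = np.random.default_rng(5)
    n_snps = 5000
    freqs = rng.uniform(0.2, 0.8, n_snps)
    parents = (rng.random((4, n_snps)) < freqs).astype(np.int8)  # 2 parents x 2 haps

    def child():
        a = parents[rng.integers(0, 2, n_snps), np.arange(n_snps)]
        b = parents[2 + rng.integers(0, 2, n_snps), np.arange(n_snps)]
        return a + b

    sibs = np.vstack([child(), child()])
    # background unrelated samples so allele freqs are estimable
    bg = (rng.random((30, n_snps)) < freqs).astype(np.int8) + (
        rng.random((30, n_snps)) < freqs
    ).astype(np.int8)
    g = make_matrix(np.vstack([sibs, bg]), positions=(np.arange(n_snps) + 1).tolist())
    assert ibd_pihat(g, 0, 1) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------------------
# staged QC
# ---------------------------------------------------------------------------

def _clean_panel(rng, n=60, m=400):
    freqs = rng.uniform(0.2, 0.5, m)
    geno = (rng.random((n, m)) < freqs).astype(np.int8) + (rng.random((n, m)) < freqs).astype(
        np.int8
    )
    return geno


def test_apply_qc_clean_fixture_removes_nothing():
    rng = np.random.default_rng(8)
    g = make_matrix(_clean_panel(rng))
    rep = apply_qc(g).population("POP1")
    assert rep.n_samples_removed == 0
    assert rep.n_snps_removed == 0


def test_apply_qc_planted_defects_counted_per_stage():
    """Each planted defect is removed at exactly its stage."""
    rng = np.random.default_rng(10)
    geno = _clean_panel(rng, n=60, m=800)
    # plant 10 low-MAF SNPs (columns 0..9): a single carrier heterozygote
    geno[:, :10] = 0
    geno[0, :10] = 1
    # plant 5 call-rate failures (columns 10..14): 20% missing
    geno[:12, 10:15] = MISSING
    # plant 3 HWE failures (columns 15..17): all heterozygous
    geno[:, 15:18] = 1
    # plant one duplicate sample (relatedness) and one high-missingness sample
    geno[1] = geno[0]
    geno[2, 80:] = MISSING  # 80% missing
    g = make_matrix(geno)
    rep = apply_qc(g).population("POP1")
    assert rep.samples_removed_missing == ["s3"]
    assert len(rep.samples_removed_ibd) == 1 and rep.samples_removed_ibd[0] in ("s1", "s2")
    assert rep.snps_removed_call_rate == 5
    assert rep.snps_removed_maf == 10
    assert rep.snps_removed_hwe == 3
    assert rep.retained.n_snps == 800 - 18
    assert rep.retained.n_samples == 58


def test_apply_qc_idempotent():
    rng = np.random.default_rng(10)
    g = make_matrix(_clean_panel(rng))
    once = apply_qc(g).population("POP1").retained
    twice = apply_qc(once).population("POP1")
    assert twice.n_samples_removed == 0 and twice.n_snps_removed == 0
    assert np.array_equal(once.genotypes, twice.retained.genotypes)


def test_hwe_rejection_rate_nominal():
    """Under random-mating sampling the exact test rejects ~alpha of SNPs.

    20,000 SNPs x 500 diploids drawn at HWE with MAF ~ U(0.05, 0.5); the
    rejection rate at alpha=0.001 must sit in the binomial 95% band around
    0.001 (the discrete test is slightly conservative, which the band allows
    at this sample size).
    """
    rng = np.random.default_rng(0)
    n, m = 500, 20_000
    p = rng.uniform(0.05, 0.5, m)
    geno = (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p).astype(np.int8)
    n_het = (geno == 1).sum(axis=0)
    n_hom2 = (geno == 2).sum(axis=0)
    n_hom1 = n - n_het - n_hom2
    pvals = np.array(
        [hwe_exact_pvalue(int(a), int(h), int(b)) for a, h, b in zip(n_hom1, n_het, n_hom2)]
    )
    rate = (pvals < 0.001).mean()
    half = 1.96 * np.sqrt(0.001 * 0.999 / m)
    assert 0.001 - half <= rate <= 0.001 + half


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_maf_spectrum_single_bin_and_format():
    g = make_matrix([[1, 1], [0, 0], [1, 1], [0, 0]])  # MAF 0.25 at both SNPs
    spectrum = maf_spectrum(g, np.arange(0, 0.55, 0.05))
    assert spectrum.loc[(spectrum.bin_lower == 0.25), "proportion"].iloc[0] == 1.0
    assert spectrum["proportion"].sum() == pytest.approx(1.0)
    assert spectrum.attrs["maf_mean"] == pytest.approx(0.25)


def test_chromosome_summary_span_and_gap():
    import pandas as pd

    from ldscape.io import GenotypeMatrix

    markers = pd.DataFrame(
        {
            "chrom": [1, 1, 1, 2],
            "id": ["a", "b", "c", "d"],
            "pos_bp": [1000, 11000, 21000, 5000],
            "allele1": "A",
            "allele2": "G",
        }
    )
    g = GenotypeMatrix(
        genotypes=np.array([[0, 1, 2, 1]], dtype=np.int8),
        markers=markers,
        sample_ids=["s1"],
    )
    summ = chromosome_summary(g).set_index("chrom")
    assert summ.loc[1, "span_bp"] == 20000
    assert summ.loc[1, "mean_gap_bp"] == 10000
    assert np.isnan(summ.loc[2, "mean_gap_bp"])


def test_simulated_maf_matches_truth(const_n_sim):
    """Sample MAF tracks the simulator's whole-population frequency."""
    g, truth = const_n_sim
    pop_maf = np.minimum(truth.allele_freqs["P"], 1 - truth.allele_freqs["P"])
    sample_maf = minor_allele_freqs(g)
    # binomial sampling error at 2n=100 draws: sd <= 0.05; check in bulk
    assert np.median(np.abs(sample_maf - pop_maf)) < 0.04
    assert np.corrcoef(sample_maf, pop_maf)[0, 1] > 0.95
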