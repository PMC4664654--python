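"""Shared fixtures: small hand panels and session-scoped simulations.

The heavier Wright-Fisher runs are session-scoped so module tests and the
acceptance tests share one realisation each.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ldscape.io import GenotypeMatrix
from ldscape.simdata import Epoch, SimConfig, Split, simulate


def make_matrix(geno, positions=None, chrom=1, pops=None, alleles=("A", "G")):
    """Small GenotypeMatrix from a nested list of codes (samples x SNPs)."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_snps = geno.shape
    if positions is None:
        positions = (np.arange(n_snps) * 10_000 + 1).tolist()
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"snp{j + 1}" for j in range(n_snps)],
            "pos_bp": positions,
            "allele1": alleles[0],
            "allele2": alleles[1],
        }
    )
    return GenotypeMatrix(
        genotypes=geno,
        markers=markers,
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        population=np.array(pops if pops is not None else ["POP1"] * n_samples, dtype=object),
    )


@pytest.fixture(scope="session")
def const_n_sim():
    """Constant N=100 WF run: 50 samples, >=2000 ascertained SNPs.

    Used for Sved-consistency and Ne-recovery checks: 15 chromosomes of 5 Mb,
    1000 loci each started near frequency 0.5, 400 generations (4N) of
    burn-in, chip-like MAF >= 0.05 ascertainment on the sample.
    """
    cfg = SimConfig(
        seed=7,
        n_chrom=15,
        chrom_length_bp=5_000_000,
        n_snps_per_chrom=1000,
        populations={"P": (Epoch(100, 400),)},
        sample_sizes={"P": 50},
        ascertainment_maf=0.05,
        init_beta=(50, 50),
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def split_sim():
    """Two populations split 100 generations ago from an ancestor of N=200.

    60 chromosomes of 1 Mb x 160 loci give dense shared pairs for the
    phase-correlation regression; 50 diploids sampled per side.  The long
    mutation-drift burn-in (1500 generations with symmetric mutation 1e-4)
    equilibrates ancestral LD across the whole fitted distance range, which
    the exp(-2cT) regression assumes.
    """
    cfg = SimConfig(
        seed=11,
        n_chrom=60,
        chrom_length_bp=1_000_000,
        n_snps_per_chrom=160,
        mutation_rate=1e-4,
        populations={
            "ANC": (Epoch(200, 1500),),
            "P1": (Epoch(200, 100),),
            "P2": (Epoch(200, 100),),
        },
        splits=(Split(1500, "ANC", ("P1", "P2")),),
        sample_sizes={"P1": 50, "P2": 50},
        ascertainment_maf=0.05,
        init_beta=(50, 50),
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def sved_check():
    """Two-locus equilibrium validation at N=100, c=0.01 (shared, ~25 s)."""
    from ldscape.simdata import equilibrium_r2_check

    return equilibrium_r2_check(seed=1)


@pytest.fixture(scope="session")
def six_breed_panel():
    """Six-population chip-like panel with a bottlenecked population."""
    from ldscape.simdata import make_six_breed_fixture

    return make_six_breed_fixture(seed=23)
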