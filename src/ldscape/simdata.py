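"""Forward-in-time diploid Wright-Fisher simulation with recombination.

The simulator provides ground truth for the whole analysis chain: discrete
generations, random mating (each gamete draws a uniform parent), crossovers
independent across marker intervals with probability distance x
``morgans_per_bp`` (capped at 0.5; chromosome boundaries recombine freely),
optional symmetric mutation, population splits that found child populations
from the parent's current gamete pool, chip-like MAF ascertainment in a
reference sample, and uniform missing-genotype noise.  Everything is
reproducible from a single integer seed.

Desk-scale sizes (N <= a few hundred, a few thousand markers) are the design
point: they make LD-based parameter recovery a clean oracle while keeping
runs to seconds.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, write_genotype_table, write_plink
from .ldcore import _em_batch, _pair_count_tables


@dataclass(frozen=True)
class Epoch:
    """Constant-size episode of a population's schedule."""

    size: int
    duration: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("population size must be >= 2")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class Split:
    """At forward time ``time`` the parent's pool founds the child populations."""

    time: int
    parent: str
    children: tuple[str, ...]


@dataclass
class SimConfig:
    """Demography, marker map, and sampling scheme of one simulation."""

    seed: int
    n_chrom: int = 1
    chrom_length_bp: int = 1_000_000
    n_snps_per_chrom: int = 100
    morgans_per_bp: float = 1e-8
    mutation_rate: float = 0.0
    populations: dict[str, tuple[Epoch, ...]] = field(default_factory=dict)
    splits: tuple[Split, ...] = ()
    sample_sizes: dict[str, int] = field(default_factory=dict)
    ascertainment_maf: float = 0.0
    ascertainment_pop: str | None = None  # None -> pooled over all samples
    missing_rate: float = 0.0
    init_beta: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        for r in (self.mutation_rate, self.missing_rate, self.ascertainment_maf):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if not self.populations:
            raise ValueError("at least one population schedule required")

    @property
    def root(self) -> str:
        children = {c for s in self.splits for c in s.children}
        roots = [p for p in self.populations if p not in children]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root population, found {roots}")
        return roots[0]

    def start_time(self, pop: str) -> int:
        if pop == self.root:
            return 0
        for s in self.splits:
            if pop in s.children:
                return s.time
        raise ValueError(f"population {pop!r} has no origin")

    def end_time(self) -> int:
        return max(
            self.start_time(p) + sum(e.duration for e in sched)
            for p, sched in self.populations.items()
        )

    def size_at(self, pop: str, t: int) -> int:
        """Population size during generation step t -> t+1."""
        rel = t - self.start_time(pop)
        for e in self.populations[pop]:
            if rel < e.duration:
                return e.size
            rel -= e.duration
        return self.populations[pop][-1].size


@dataclass
class SimTruth:
    """Ground truth retained alongside the sampled genotypes."""

    config: SimConfig
    split_times: dict[str, int]            # child population -> forward split time
    end_time: int
    haplotypes: dict[str, np.ndarray]      # pop -> (2*n_samples, n_kept_snps) of sampled gametes
    allele_freqs: dict[str, np.ndarray]    # pop -> whole-population allele2 freq at sampling
    kept_snps: np.ndarray                  # indices into the pre-ascertainment map
    positions: pd.DataFrame                # kept marker map (chrom, id, pos_bp)

    def split_generations_ago(self, pop_a: str, pop_b: str) -> int:
        """Generations before sampling at which the lineages of two terminal
        populations last shared a pool (walk the split tree upward)."""
        cfg = self.config

        def lineage(p: str) -> list[tuple[str, int]]:
            out = [(p, cfg.start_time(p))]
            while p != cfg.root:
                for s in cfg.splits:
                    if p in s.children:
                        p = s.parent
                        out.append((p, cfg.start_time(p)))
                        break
            return out

        la = dict(lineage(pop_a))
        for anc, _ in lineage(pop_b):
            if anc in la:
                # divergence happens when that shared ancestor split
                for s in cfg.splits:
                    if s.parent == anc:
                        return self.end_time - s.time
        raise ValueError("populations do not share an ancestor")

    def to_json_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "end_time": self.end_time,
            "split_times": self.split_times,
            "populations": {
                p: [[e.size, e.duration] for e in sched]
                for p, sched in self.config.populations.items()
            },
            "sample_sizes": self.config.sample_sizes,
            "n_kept_snps": int(self.kept_snps.size),
        }


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Evenly spaced marker map and per-interval recombination probabilities."""
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        pos = np.linspace(1, cfg.chrom_length_bp, cfg.n_snps_per_chrom).round().astype(np.int64)
        pos = np.maximum.accumulate(pos)  # guard against rounding collisions
        for k, p in enumerate(pos):
            rows.append((c, f"snp{c}_{k + 1}", int(p), "A", "G"))
    markers = pd.DataFrame(rows, columns=["chrom", "id", "pos_bp", "allele1", "allele2"])
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    rec = np.minimum(np.diff(pos) * cfg.morgans_per_bp, 0.5)
    rec[np.diff(chrom) != 0] = 0.5
    return markers, rec


def _next_generation(
    haps: np.ndarray, n_off: int, rec: np.ndarray, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """One Wright-Fisher generation: (2N, L) gametes -> (2*n_off, L)."""
    n_parents = haps.shape[0] // 2
    L = haps.shape[1]
    col = np.arange(L)[None, :]
    gametes = []
    for _ in range(2):
        par = rng.integers(0, n_parents, n_off)
        start = rng.integers(0, 2, n_off).astype(np.int8)
        if L > 1:
            switch = (rng.random((n_off, L - 1)) < rec).astype(np.int8)
            choice = np.concatenate([start[:, None], switch], axis=1)
            np.cumsum(choice, axis=1, out=choice)
            choice &= 1
        else:
            choice = start[:, None]
        gametes.append(haps[2 * par[:, None] + choice, col])
    out = np.empty((2 * n_off, L), dtype=np.uint8)
    out[0::2] = gametes[0]
    out[1::2] = gametes[1]
    if mu > 0:
        out ^= (rng.random(out.shape) < mu).astype(np.uint8)
    return out


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run the configured demography and return sampled genotypes plus truth."""
    rng = np.random.default_rng(cfg.seed)
    markers, rec = _marker_map(cfg)
    L = len(markers)
    root = cfg.root
    end = cfg.end_time()
    splits_by_time: dict[int, list[Split]] = {}
    for s in cfg.splits:
        splits_by_time.setdefault(s.time, []).append(s)

    a, b = cfg.init_beta
    freqs0 = rng.beta(a, b, L)
    n0 = cfg.size_at(root, 0)
    pools: dict[str, np.ndarray] = {
        root: (rng.random((2 * n0, L)) < freqs0).astype(np.uint8)
    }

    for t in range(end):
        stepped: set[str] = set()
        for s in sorted(splits_by_time.get(t, []), key=lambda s: s.parent):
            parent = pools.pop(s.parent)
            for child in s.children:
                pools[child] = _next_generation(
                    parent, cfg.size_at(child, t), rec, cfg.mutation_rate, rng
                )
                stepped.add(child)
        for pop in sorted(pools):
            if pop in stepped:
                continue
            pools[pop] = _next_generation(
                pools[pop], cfg.size_at(pop, t), rec, cfg.mutation_rate, rng
            )

    # sampling
    sample_sizes = cfg.sample_sizes or {p: min(25, pools[p].shape[0] // 2) for p in pools}
    geno_parts, hap_truth, freq_truth, sample_ids, pop_labels = [], {}, {}, [], []
    for pop in sorted(sample_sizes):
        if pop not in pools:
            raise ValueError(f"cannot sample {pop!r}: not alive at the end of the schedule")
        n_pop = pools[pop].shape[0] // 2
        n_s = sample_sizes[pop]
        if n_s > n_pop:
            raise ValueError(f"sample size {n_s} exceeds population size {n_pop} for {pop!r}")
        chosen = np.sort(rng.choice(n_pop, n_s, replace=False))
        rows = np.column_stack([2 * chosen, 2 * chosen + 1]).ravel()
        haps = pools[pop][rows]
        hap_truth[pop] = haps
        freq_truth[pop] = pools[pop].mean(axis=0)
        geno_parts.append((haps[0::2].astype(np.int8) + haps[1::2]).astype(np.int8))
        sample_ids.extend(f"{pop}_{k + 1}" for k in range(n_s))
        pop_labels.extend([pop] * n_s)
    genotypes = np.concatenate(geno_parts, axis=0)

    # chip-like ascertainment on a reference sample
    if cfg.ascertainment_maf > 0:
        if cfg.ascertainment_pop is not None:
            mask = np.array([p == cfg.ascertainment_pop for p in pop_labels])
            ref = genotypes[mask]
        else:
            ref = genotypes
        p_ref = ref.mean(axis=0) / 2.0
        maf = np.minimum(p_ref, 1 - p_ref)
        kept = np.flatnonzero(maf >= cfg.ascertainment_maf)
    else:
        kept = np.arange(L)
    genotypes = genotypes[:, kept]
    markers_kept = markers.iloc[kept].reset_index(drop=True)
    hap_truth = {p: h[:, kept] for p, h in hap_truth.items()}
    freq_truth = {p: f[kept] for p, f in freq_truth.items()}

    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes = np.where(miss, np.int8(MISSING), genotypes).astype(np.int8)

    g = GenotypeMatrix(
        genotypes=genotypes,
        markers=markers_kept,
        sample_ids=sample_ids,
        population=np.array(pop_labels, dtype=object),
    )
    truth = SimTruth(
        config=cfg,
        split_times={c: s.time for s in cfg.splits for c in s.children},
        end_time=end,
        haplotypes=hap_truth,
        allele_freqs=freq_truth,
        kept_snps=kept,
        positions=markers_kept[["chrom", "id", "pos_bp"]].copy(),
    )
    return g, truth


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def wf_replicate_frequencies(
    n: int, n_reps: int, n_gens: int, p0: float, seed: int
) -> np.ndarray:
    """Final allele frequencies of independent single-locus WF replicates.

    Used to validate the drift engine: without mutation the frequency is a
    martingale, so the replicate mean stays near p0.
    """
    rng = np.random.default_rng(seed)
    counts = rng.binomial(2 * n, p0, n_reps)
    for _ in range(n_gens):
        counts = rng.binomial(2 * n, counts / (2.0 * n))
    return counts / (2.0 * n)


def equilibrium_r2_check(
    n_pop: int = 100,
    c: float = 0.01,
    n_generations: int | None = None,
    n_reps: int = 12000,
    sample_size: int = 50,
    maf_min: float = 0.05,
    min_pairs: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Mean sample-size-adjusted r^2 across replicate two-locus WF runs.

    Each replicate is an independent constant-size diploid population with
    two loci at recombination distance ``c``, started at linkage equilibrium
    (frequency 0.5) and run for ``n_generations`` (default 4N).  At the end,
    ``sample_size`` diploids are drawn, r^2 is estimated by EM from the
    unphased genotypes, and 1/n is subtracted (unphased adjustment).  Pairs
    with either locus below ``maf_min`` in the sample are excluded, mimicking
    chip ascertainment.  Returns the mean adjusted r^2, the pair count, and
    Sved's closed-form expectation 1/(1 + 4Nc) for reference.
    """
    if n_generations is None:
        n_generations = 4 * n_pop
    rng = np.random.default_rng(seed)
    two_n = 2 * n_pop
    haps = (rng.random((n_reps, two_n, 2)) < 0.5).astype(np.uint8)
    rep = np.arange(n_reps)[:, None]
    for _ in range(n_generations):
        par = rng.integers(0, n_pop, (n_reps, two_n))
        start = rng.integers(0, 2, (n_reps, two_n), dtype=np.int64)
        switch = rng.random((n_reps, two_n)) < c
        second = start ^ switch
        a0 = haps[rep, 2 * par + start, 0]
        a1 = haps[rep, 2 * par + second, 1]
        haps = np.stack([a0, a1], axis=-1)

    # sample unphased genotypes
    g = (haps[:, 0 : 2 * sample_size : 2, :] + haps[:, 1 : 2 * sample_size : 2, :]).astype(int)
    p_hat = g.mean(axis=1) / 2.0  # (R, 2)
    maf = np.minimum(p_hat, 1 - p_hat)
    keep = (maf >= maf_min).all(axis=1)

    joint = g[keep, :, 0] * 3 + g[keep, :, 1]
    n_kept = int(keep.sum())
    tables = np.zeros((n_kept, 9))
    for v in range(9):
        tables[:, v] = (joint == v).sum(axis=1)
    tables = tables.reshape(n_kept, 3, 3)
    pAB, _, _ = _em_batch(tables, 1e-10, 5000)
    pA = p_hat[keep, 0]
    pB = p_hat[keep, 1]
    D = pAB - pA * pB
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    adj = r2 - 1.0 / sample_size
    if n_kept < min_pairs:
        raise RuntimeError(f"only {n_kept} polymorphic replicate pairs (< {min_pairs})")
    return {
        "mean_adj_r2": float(adj.mean()),
        "n_pairs": n_kept,
        "sved_expectation": 1.0 / (1.0 + 4.0 * n_pop * c),
    }


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

def six_breed_config(seed: int, small: bool = True) -> SimConfig:
    """Six populations from a common ancestor with staggered splits.

    The demography emulates a chip study of related breeds: two deep lineages
    (a 'reference' pair and a local group), one strongly bottlenecked local
    population, ~uniform marker spacing, chip-like MAF ascertainment and 2%
    missingness.  Each terminal population ends with a brief census expansion
    (large herd, small historical effective size), so that a 30-animal sample
    is not dominated by full and half sibs.  The small variant (default)
    keeps runtimes to seconds.
    """
    n_chrom, n_per = (10, 300) if small else (29, 450)
    grow = Epoch(600, 8)  # terminal census expansion
    return SimConfig(
        seed=seed,
        n_chrom=n_chrom,
        chrom_length_bp=20_000_000,
        n_snps_per_chrom=n_per,
        morgans_per_bp=1e-8,
        mutation_rate=2e-5,
        populations={
            "ANC": (Epoch(200, 200),),
            "REF_ANC": (Epoch(180, 80),),
            "LOC_ANC": (Epoch(200, 100),),
            "ref_a": (Epoch(120, 112), grow),
            "ref_b": (Epoch(120, 112), grow),
            "bottleneck": (Epoch(50, 92), grow),
            "LOC_B": (Epoch(200, 40),),
            "local_a": (Epoch(200, 52), grow),
            "LOC_C": (Epoch(200, 20),),
            "local_b": (Epoch(180, 32), grow),
            "local_c": (Epoch(160, 32), grow),
        },
        splits=(
            Split(200, "ANC", ("REF_ANC", "LOC_ANC")),
            Split(280, "REF_ANC", ("ref_a", "ref_b")),
            Split(300, "LOC_ANC", ("bottleneck", "LOC_B")),
            Split(340, "LOC_B", ("local_a", "LOC_C")),
            Split(360, "LOC_C", ("local_b", "local_c")),
        ),
        sample_sizes={
            "bottleneck": 30,
            "local_a": 30,
            "local_b": 30,
            "local_c": 30,
            "ref_a": 30,
            "ref_b": 30,
        },
        ascertainment_maf=0.05,
        missing_rate=0.02,
    )


def make_six_breed_fixture(seed: int, out_dir: str | Path | None = None):
    """Simulate the six-population panel; optionally write PLINK + truth JSON.

    Writes ``panel.bed/.bim/.fam``, ``panel.pops.tsv`` and ``truth.json`` when
    ``out_dir`` is given.  Returns (GenotypeMatrix, SimTruth).
    """
    g, truth = simulate(six_breed_config(seed))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_plink(g, out_dir / "panel")
        pd.DataFrame({"sample_id": g.sample_ids, "population": g.population}).to_csv(
            out_dir / "panel.pops.tsv", sep="\t", index=False
        )
        (out_dir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
    return g, truth


def make_block_fixture(
    seed: int,
    n_samples: int = 100,
    n_flank: int = 4,
    n_block: int = 5,
) -> tuple[GenotypeMatrix, tuple[int, int]]:
    """Synthetic planted-block panel (direct haplotype draws, not WF).

    One chromosome: ``n_flank`` freely recombining SNPs, then ``n_block``
    SNPs carried on two founder haplotypes only (a zero-recombination
    segment, |D'| = 1 between all members), then ``n_flank`` more free SNPs.
    Returns the matrix and the (start, end) marker indices of the planted
    segment.
    """
    rng = np.random.default_rng(seed)
    n_snps = 2 * n_flank + n_block
    two_n = 2 * n_samples
    haps = np.empty((two_n, n_snps), dtype=np.uint8)
    for j in list(range(n_flank)) + list(range(n_flank + n_block, n_snps)):
        haps[:, j] = rng.random(two_n) < rng.uniform(0.2, 0.8)
    f1 = rng.integers(0, 2, n_block, dtype=np.uint8)
    founders = np.stack([f1, 1 - f1])  # complementary, so every member SNP is polymorphic
    which = (rng.random(two_n) < 0.6).astype(int)
    haps[:, n_flank : n_flank + n_block] = founders[which]
    geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    markers = pd.DataFrame(
        {
            "chrom": 1,
            "id": [f"snp{j + 1}" for j in range(n_snps)],
            "pos_bp": (np.arange(n_snps) * 10_000 + 1).astype(np.int64),
            "allele1": "A",
            "allele2": "G",
        }
    )
    g = GenotypeMatrix(
        genotypes=geno,
        markers=markers,
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        population=np.array(["POP1"] * n_samples, dtype=object),
    )
    return g, (n_flank, n_flank + n_block - 1)
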