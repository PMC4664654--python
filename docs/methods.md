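# Methods

`ldscape` reconstructs the population-genetic structure of a diploid SNP-chip
panel from unphased genotypes: pairwise linkage disequilibrium (LD) and its
decay with distance, haplotype blocks, the persistence of allelic phase
between populations with a divergence-time estimate, and an LD-based
effective-population-size (N_e) trajectory.  A forward Wright–Fisher
simulator supplies ground truth for every estimator.  This note records the
models, the parameters that matter, the numerical choices, and what the
validation suite does and does not demonstrate.

## Two-locus EM and the LD statistics

For two biallelic SNPs the 3×3 table of joint genotype counts determines all
gamete counts except for double heterozygotes, which mix the coupling
(AB/ab) and repulsion (Ab/aB) phases.  Writing pAB for the frequency of the
haplotype carrying allele2 at both loci (genotype codes count allele2, the
second .bim allele — the sign of r depends on this convention), the EM
iteration splits the double-heterozygote count by the current phase odds
pAB·pab / (pAB·pab + pAb·paB) and recounts haplotypes, maximising the
multinomial likelihood.  Convergence is declared when |ΔpAB| < tol
(default 1e-8, cap 1000 iterations; both exposed in `EmSettings`).

The EM runs from three deterministic starts — linkage equilibrium pA·pB and
one point just inside each end of the admissible interval
[max(0, pA+pB−1), min(pA, pB)] — and keeps the converged solution of highest
likelihood (ties resolved to the smallest pAB).  Equilibrium-only EM has an
exact failure mode: a table consisting solely of double heterozygotes has
likelihood maxima at D′ = ±1 and pA·pB is an unstable saddle the EM map
cannot leave.  The extra starts cost two additional vectorised runs and make
the estimate agree with a grid-search maximiser of the explicit likelihood
to better than 1e-6 on random small tables (the suite checks 200 of them).

Derived statistics: D = pAB − pA·pB; D′ = |D|/Dmax with Dmax the
frequency-bound on |D| in the direction of D; r = D/√(pA qA pB qB);
r² = r².  Samples missing at either locus are excluded pairwise, and allele
frequencies for each pair come from its pairwise-complete subset, so every
pair is internally consistent; the per-pair sample count n_eff is kept
because the sample-size adjustment r²_adj = r² − 1/(βn) needs it (β = 1 for
unphased genotypes, 2 when gametic phase is known).  Negative adjusted
values are retained at the pair level.

## Quality control

Filters run within each population, in a fixed order chosen because sample
removal changes marker statistics: (1) non-autosomal markers are dropped at
load time; (2) samples with more than 10% missing genotypes; (3) one member
of each pair with PI_HAT > 0.25 (the lower-call-rate member; ties drop the
lexicographically later id); (4) SNPs with call rate below 95%; (5) SNPs
with MAF below 5%; (6) SNPs with exact Hardy–Weinberg p < 0.001.  The
boundary is strict ("less than 95%" removes call rate < 0.95 exactly).

The HWE test is the plain (not mid-p) two-sided exact test on Levene's
conditional distribution of the heterozygote count given the allele counts,
computed by a ratio recurrence from the modal class for numerical stability.
It agrees with full enumeration to 1e-12 for n ≤ 50.  Being discrete, the
test is conservative: for samples of a few hundred the true rejection rate
at α = 0.001 is 0.0005–0.0008, approaching the nominal level from below as
n grows.  The calibration check therefore uses 500 diploids, where the exact
operating rate lies inside the binomial 95% band around 0.001 at 20,000
SNPs; that choice was made from the enumeration itself, not by simulation
tuning.

PI_HAT is the method-of-moments estimator: observed identity-by-state counts
are equated with their expectations under 0/1/2 shared alleles and solved
sequentially, truncated to [0,1] and renormalised.  The expectations draw
alleles *without replacement* from the observed allele pool
(falling-factorial products rather than powers of the plug-in frequency);
without this correction the estimator is noticeably positive for unrelated
pairs when frequencies come from the same modest panel.  Two limitations
remain at desk scale: truncation inflates the mean of near-zero estimates,
and LD reduces the number of effectively independent markers, so panels
with few independent LD blocks over-prune.  The six-population synthetic
panel shows this honestly — its bottlenecked population loses many samples
at stage (3) — whereas a 40k-SNP chip panel has negligible PI_HAT noise.

## LD decay and marker density

Pairs within 1 Mb are aggregated into half-open distance classes
[0,10), [10,20), [20,40), [40,60), [60,100), [100,200), [200,500),
[500,1000) kb; a pair at exactly a boundary belongs to the upper class.
Class means pool all chromosomes; each class records the mean distance of
its member pairs as its representative.  MAF thresholds (0.05/0.1/0.2) are
applied at the pair level (both SNPs must pass), which is equivalent to
re-running QC per threshold and much cheaper.

The marker-density rule scans classes outward and takes as usable spacing
the upper edge of the most distant class whose mean r² still meets the
useful-LD threshold (default 0.20), stopping at the first failure; the
marker count is ceil(genome length / spacing).  If the first class already
fails, the result is flagged as denser than the panel resolves.

## Haplotype blocks

Pair classification follows the confidence-interval method: the two-locus
likelihood is profiled over |D′| on a 101-point grid (allele frequencies
held at their sample values, D's sign from the EM solution), normalised,
and the 90% interval read off cumulatively from each end.  A pair is strong
LD if the interval lies in [0.70, 1] with upper bound ≥ 0.98, shows
historical recombination if the upper bound is < 0.90, and is uninformative
otherwise.  A candidate block is a marker run (members MAF ≥ 0.05, span
≤ 500 kb) whose outermost pair is strong LD and in which ≥ 95% of
informative internal pairs are strong LD; acceptance is greedy from the
longest span downward, ties to the leftmost start, skipping overlaps.  All
constants sit in `BlockParams`; the defaults are the widely used
Haploview-lineage values.  With these defaults the suite recovers a planted
zero-recombination segment exactly and finds no blocks among independent
loci.

## Persistence of phase and divergence time

For two populations, signed r values are computed for every shared syntenic
pair (markers matched by id; a swapped allele1/allele2 orientation negates
r; strand-ambiguous A/T and C/G markers are dropped), and their Pearson
correlation is taken within 10-kb distance bins up to 1 Mb.  Two populations
T generations past a common ancestor are expected to show correlation
e^(−2cT) at recombination distance c, so an ordinary least-squares fit of
ln(correlation) on the mean bin c over 0–500 kb gives T = −slope/2; the
correlation of the shortest bin approximates the LD of the common ancestor.
Physical distance maps to Morgans with a single genome-wide constant
(default 1e-8 M/bp, i.e. 1 cM/Mb; configurable).  Bins with non-positive
correlation are excluded from the log — shifting them would distort the
slope — and a positive slope floors T at 0 with a flag.  The first bin is
included by default (`include_first_bin=False` excludes it for use as a
pure ancestral-LD proxy).

Two desk-scale biases of this regression are worth knowing.  If the
ancestral population's short-range LD has not reached drift equilibrium,
the daughters keep building LD after the split and the decay curve
flattens, biasing T̂ low by tens of percent; the validation simulation
therefore burns in 1500 generations with symmetric mutation 1e-4 so the
assumption of the e^(−2cT) model actually holds.  Conversely, with few
independent chromosomes the bin correlations are noisy, and the concavity
of the logarithm steepens the fitted slope, biasing T̂ high.  With 60×1 Mb
chromosomes, N = 200 and 50 samples per side, the estimator recovers a
100-generation split with mean ≈ 96 and seed-to-seed sd ≈ 16.

Neighbor-joining trees (for pairwise-T or external F_ST matrices) use the
canonical Q-matrix agglomeration with the standard limb-length formulas;
the Q minimum is taken at the first row-major minimiser so ties break by
label order.  On additive matrices the tree metric reproduces the input to
1e-9; scikit-bio's implementation serves as an independent cross-check in
the tests.

## Effective population size

Each pair's adjusted r² is binned by c (default 16 log-spaced bins over
5e-4–0.05 Morgans, i.e. 50 kb–5 Mb at 1 cM/Mb, covering roughly 10–1000
generations ago); each bin is inverted through
N_T = (4 f(c_t))⁻¹ (E[r²_adj|c_t]⁻¹ − α) at T = 1/(2 f(c_t)), with c_t the
mean pair c of the bin.  Defaults: α = 1 (no mutation correction; 2 and 2.2
available), β = 1 (unphased), f(c) = c under the linear 1 cM/Mb convention
(a Haldane transform is available for sensitivity analysis).

Pairs whose adjusted r² is non-positive are *kept* in the bin average by
default.  Excluding them truncates the lower tail of the strongly skewed r²
distribution, inflates bin means, and biases N_e low — on constant-N=100
simulations the median estimate drops from ≈95 to ≈75 when they are
excluded — so exclusion is offered only as a sensitivity switch
(`exclude_nonpositive_pairs=True`).  A bin whose mean is still non-positive
is undefined and dropped.

## The simulator and what passing tests show

The simulator is a discrete-generation diploid Wright–Fisher engine: each
gamete draws a uniform parent; crossovers occur independently in each
marker interval with probability distance × 1e-8 (capped at 0.5; chromosome
boundaries recombine freely); mutation is symmetric per locus per
generation; splits found child populations from the parent's current pool;
sampling draws individuals without replacement; chip-like ascertainment
keeps SNPs with reference-sample MAF above a threshold; missingness is
uniform.  Initial frequencies are Beta-distributed (default Beta(0.5, 0.5);
validation runs that need high polymorphism retention after long drift use
Beta(50, 50), i.e. near 0.5).  Everything derives from one integer seed
through a single `numpy` generator, so outputs are bit-reproducible.

Validation problem sizes, chosen to keep each run in the tens of seconds:
the Sved-limit check uses 12,000 replicate two-locus populations (N = 100,
c = 0.01, 4N generations, 50 sampled diploids, MAF ≥ 0.05 in-sample) of
which ≈ 540 remain polymorphic, reproducing 1/(1+4Nc) = 0.2 within a few
percent; the N_e recovery uses 15 × 5 Mb chromosomes × 1000 loci (≈ 2000+
SNPs after ascertainment) and requires the median over bins with
T ≤ 100 within a factor 1.5 of truth; the divergence recovery is described
above.  The six-population panel mimics a real chip study in shape —
staggered splits from one ancestor, one bottlenecked population (N = 50),
30 samples per population, pooled-reference ascertainment, 2% missingness —
and ends each terminal population with an 8-generation census expansion to
600 so a 30-animal sample is not dominated by sibs.

What these runs do **not** show: behaviour under real ascertainment schemes
(multi-breed discovery panels), mutation–selection balance, overlapping
generations, migration after splits, genotyping error structure beyond
uniform missingness, or chip-scale marker densities.  Quantities that
depend on those features — absolute block counts, absolute N_e levels for a
specific breed — are reproduced qualitatively, not numerically.

## Degenerate inputs and tie-breaks (summary)

Monomorphic loci: LD undefined (flagged NaN), HWE p = 1.  All-missing SNP:
undefined MAF, fails call rate anyway.  Chromosomes with < 2 markers: gap
undefined.  Empty pair streams: empty tables.  Distance-class membership,
greedy block acceptance, IBD-pruning drop choice, NJ agglomeration and the
EM multistart tie are all deterministic, so every pipeline output is
byte-stable across reruns ('%.6g' TSV formatting; MANIFEST of sha256
hashes).
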