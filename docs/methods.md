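# Methods

## Model overview

`syngs` is a fully stochastic forward-in-time simulator of recurrent
genomic selection (GS) in synthetic populations. A *synthetic* is built
from Np fully homozygous parent lines; its genetic properties are driven
by three information sources that genomic prediction can exploit:
pedigree relationships, cosegregation (sample LD created by drawing few
parental gametes, transmitted through linkage), and ancestral LD carried
over from the source population. The simulator makes these separable by
construction (scenarios `Re-LDA-SNP`, `Re-LEA-SNP`, `Re-LDA-Ped`,
`Un-LDA-SNP`).

## Genome and meiosis

The genome is a genetic map of 10 chromosomes totalling 1913 cM
(maize-like). Real marker positions are not reproduced; loci are placed
uniformly at random, which preserves density but not fine map structure.
Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson(length/100) with uniform breakpoints, no interference, no
obligate chiasma, no sex differences. Positions are cM; intervals are
half-open `[start, end)` and a locus exactly on a breakpoint belongs to
the right-hand segment. Every haplotype tracks *origin segments* —
which founder line contributed each stretch — as exact partitions of
each chromosome, with same-founder neighbours merged on creation, so
segment statistics need no post-processing.

## Ancestral populations

Two source populations with contrasting LD come from one staged
simulation (defaults in parentheses):

1. i.i.d. Bernoulli(0.5) alleles in a population of N (1500) diploids;
2. random mating for t (3000) generations at mutation rate μ (2.5e-5 per
   locus per gamete per generation; recurrent 0↔1 flips, no new sites);
3. bottleneck to N_b (30) individuals, t_b (15) further generations —
   this phase generates extensive long-range LD (`LR`);
4. expansion to N_e (10,000) with 3 rounds of random mating → `LR`;
5. 100 more generations at N_e break the long-range associations → `SR`.

Mating is standard Wright–Fisher: each offspring draws two parents
uniformly with replacement (selfing possible), one gamete each. The
final `LR` frequencies fix the *minor-allele* designation (ties at 0.5
toward allele 1) and the reference frequencies used for all centering
downstream, for `SR`-derived material too (the 100 extra generations at
large size leave frequencies nearly unchanged). The ancestral
individuals are the pedigree reference base: treated as unrelated and
non-inbred although they share simulated ancestry.

**Scaling.** A `scale_factor` s multiplies population sizes and
multiplies the long phase durations (equilibrium and `SR`) by the same
factor, preserving the t/N ratios that govern drift and LD build-up; the
bottleneck is clamped at ≥10 individuals and its short duration is kept.
The desk profile (s = 0.1) therefore runs N 150 → bottleneck 10 →
expansion 1000 in ~10 s. Consequences to keep in mind: drift-scale
quantities are faithful, but the bottleneck of 10 (not 30) produces
somewhat stronger ancestral LD, and a shortened `SR` phase leaves more
mid-range LD than the full-scale run would.

**Desk locus numbers.** The desk profile keeps the full 1913 cM map with
26,000 loci and a QTL pool of 4200 (the full-scale study uses 37,286 and
5000). These numbers are set by feasibility preconditions: after
fixation losses in the scaled ancestral stage (~30% of loci stay
polymorphic), the default marker density of 2.5 SNPs/cM still requires
4783 polymorphic non-QTL loci and the trait still requires 1000
polymorphic QTL-pool loci.

## Trait and calibration

The trait is purely additive over n_qtl (1000) QTL sampled per replicate
from the polymorphic QTL pool. Absolute effects are gamma with scale 0.4
and shape 1.66 — parameters implemented literally as stated for this
genetic model, giving E|a| = 0.664; the parameterization is exposed
because the literature also uses the swapped convention. Signs are ±1
with probability ½. TBVs are g = (W − 2p)a with W minor-allele counts
and p the ancestral `LR` frequencies.

The error variance σ²_e is calibrated once per experiment: over ≥50
independent QTL samplings, the variance of TBVs across all `LR`
individuals is recorded and σ²_e is set to its mean, making ancestral
heritability average 0.5 (slightly below, by Jensen's inequality, since
h² = v/(v+σ²_e) is concave in v). σ²_e is then held fixed for every
replicate and cycle. Heritability inside a synthetic is lower, because a
finite parent sample captures only part of the ancestral variance.

## Prediction model

GBLUP: y_i = μ + g_i + ε_i on the training set (TS), with
(g) ~ MVN(0, σ²_a K) over TS ∪ candidates and (ε) ~ MVN(0, σ²_ε I).
The kernel is either

* the VanRaden genomic relationship matrix over the SNP panel (QTL
  excluded; the panel is a uniform random sample of polymorphic non-QTL
  loci at the requested density), centered and scaled with *ancestral*
  frequencies — k_ij = Σ_k (x_ik−2p_k)(x_jk−2p_k) / Σ_k 2p_k(1−p_k); or
* the pedigree numerator relationship matrix by the tabular method over
  all recorded ancestors. Doubled haploids are recorded with a DH flag:
  their off-diagonals follow the tabular rule through the gamete-source
  individual and the diagonal is set to 2 (F = 1), which the plain
  recursion cannot represent.

REML uses the spectral decomposition of the TS block: profiling σ²_a and
μ (GLS) out of the restricted likelihood leaves a 1-D criterion in
δ = σ²_ε/σ²_a, minimized by bounded scalar search on log δ ∈ [−9, 9]·ln10
with tolerance 1e-10 (tests verify agreement with a direct two-parameter
optimizer to 1e-6 in δ). Eigenvalues are clipped at zero; a kernel whose
smallest eigenvalue is below −1e-8·tr(K)/n receives one diagonal jitter
of 1e-8·tr(K)/n before the fit fails.

Candidates never contribute phenotypes; their breeding values are the
covariance projection ĝ = K[cand, TS] (K_TT + δI)⁻¹ (y − μ̂). Because
(α, μ̂, δ) are frozen at training, candidates of any later cycle are
scored by computing only their kernel rows against the fixed TS
(genomic: from genotypes with the fixed ancestral p; pedigree: by
extending the tabular recursion) — the only construction consistent with
selection *without retraining*.

## Recurrent selection scheme

Per replicate: sample Np parents (2Np disjoint ones for the unrelated
scenario) → optionally reshuffle parental QTL/SNP blocks per chromosome
(`Re-LEA-SNP`) → build SynNR → draw TS (250) and 100 initial candidates
disjointly → phenotype the TS and fit the model once → 30 cycles of:
score candidates, record metrics *before* selection, select the top 10
(ties broken at random; all-equal scores degrade to random selection),
random-mate them (uniform pairs with replacement, selfing allowed, as in
synthetic construction) into 100 new candidates.

Undefined accuracies (constant TBV or EBV vectors) are reported as
missing, never as zero, and excluded from cycle means with their count
reported. EBV vectors that are constant in exact arithmetic — e.g.
pedigree BLUP in an F2 family, where every candidate relates identically
to every TS member — still carry float-level noise after the matrix
algebra; a spread below 1e-8·max(1, σ_a) is therefore treated as
constant rather than correlated against.

Each generation of a synthetic has max(NTS + 100 + 50, 400) individuals
(one individual per Syn0 single cross): the smallest design that always
allows disjoint TS/candidate sampling. How many progeny per cross the
original design used is not stated anywhere; one per cross is the
default and configurable.

## Metrics

* accuracy: Pearson r between candidate TBVs and EBVs;
* cumulative gain: (mean TBV − cycle-0 mean)/σ_A(anc);
* additive variance: sample (n−1) variance of TBVs / σ²_A(anc) (at
  n = 100 candidates the n vs n−1 choice moves the value by 1%);
* mean length of origin segments (same-founder neighbours merged);
* optional pedigree statistics: mean inbreeding F = a_ii − 1 of the
  candidates and the variance of TS–candidate relationships, a proxy for
  the erosion of pedigree information across cycles.

## Seeding and reproducibility

Every replicate takes one root seed; per-stage generators (trait,
markers, parents, synthetic, sampling, phenotype, cycles) are split from
it via `SeedSequence.spawn`, so replicates are bitwise reproducible and
stages statistically independent. Grid runs derive replicate seeds
deterministically from (root seed, cell index, replicate index), all
below 2³¹; outputs are byte-identical across reruns and execution
orders.

## Problem sizes of the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: scale
factor 0.1, full map, 26,000 loci, 20–30 replicates per condition
(pooled over three independent ancestral simulations in the acceptance
script, so that ancestral-stage Monte-Carlo variance is averaged over
rather than conditioned on). The full-scale study (500 replicates,
N = 10,000, 37,286 loci) is cluster work via the same `ExperimentGrid`
API with `scale_factor=1`.

## Known limitations

* No crossover interference, gene conversion, sex-specific maps or
  structural variation; mutation cannot create new sites.
* Uniform random locus placement instead of a real map; results that
  depend on fine map structure (e.g. local marker clustering) may
  differ.
* Purely additive trait: no dominance, epistasis or QTL×environment
  interaction.
* At desk scale, between-run variance of accuracy summaries is dominated
  by the ancestral stage; replicate means conditioned on a single
  ancestral population can shift by ±0.1.
* The synthetic-data layer emulates neutral evolution only; real source
  germplasm has undergone directional selection (Bulmer-type negative
  LD), so recombination could release variance in ways this simulator
  will not show.
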