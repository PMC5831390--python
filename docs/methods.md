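# Methods

## Model and assumptions

All scores are plug-in Shannon estimates on a table of within-accession
allele frequencies `p_ij` (allele *i*, accession *j*), in bits, with the
standard convention 0·log 0 = 0 implemented by masking zero terms — never by
pseudo-counts, which would shift every reported value. The prior over
accessions is fixed at 1/N (every accession equally likely to be drawn);
all downstream identities assume it, and no weighted-prior option is
offered. Reproduction is assumed diploid-like when frequencies are derived
from genotype calls; loci are treated as independent throughout.

Specificity of allele *i* is `S_i = Σ_j p_ij/(N p̄_i) · log2(p_ij/p̄_i)` with
`p̄_i` the mean frequency across accessions; rarity of accession *j* is
`R_j = Σ_i p_ij S_i` per locus; divergence is the Kullback–Leibler
divergence `D_j = Σ_i p_ij log2(p_ij/p̄_i)` per locus. Multi-locus scores
are the **unweighted mean over loci** — loci are not weighted by allele
count — applied identically to rarity and divergence so that the three-way
identity `I(X;M) = Σ_i p̄_i S_i = mean_j R_j = mean_j D_j` (exact per locus)
survives aggregation on complete data.

## Missing data

Missingness is modelled per accession-locus block: within an accession a
locus is observed (frequencies sum to 1) or missing as a unit, matching how
genotyping failures present; a partially missing locus is invalid input.
For each allele, `p̄_i` and the effective N use only the accessions where
its locus was observed, so the specificity ceiling drops to
`log2(n_available)` — missing data inherently penalize an allele's absolute
score, and the relative specificity `S_i / log2(n_available)` removes that
penalty when wanted. Each accession's rarity/divergence averages only its
observed loci, unweighted by how many loci those are (the alternative —
weighting accessions by loci scored — is defensible but not taken; the
choice matters only for collections with very uneven missingness). With
missing data the three mutual-information routes are no longer identical,
so the API reports all three rather than pretending to one number. Alleles
never observed among the available accessions (`p̄_i = 0`) are flagged
undefined rather than scored 0, and are excluded from locus sums.

## Validation and numerics

Frequencies are double precision; per-locus sum-to-one is enforced at 1e-9.
Strict mode (default) rejects violating loci naming the offender; lenient
mode renormalizes the block, which is deliberately not the default because
silent renormalization hides upstream errors. Tiny negative specificities
from round-off on monomorphic rows (|S| < 1e-15) are clamped to exactly 0.
Row and column order are preserved everywhere; all outputs are order-stable.

## Core selection

The greedy core starts from the accession with maximum full-collection
rarity, then repeatedly adds the candidate maximizing the mean divergence of
the grown subset, the reference frequencies being the means *within that
subset*. Ties break by input column order (first wins) — the determinism
matters more than which tied candidate is taken. The objective trace records
the subset's mean divergence after every addition (a singleton subset has
divergence 0 by definition).

Exact mode recomputes the candidate-inclusive reference for every candidate,
using incrementally maintained column sums (O(A) per candidate) — a
brute-force from-scratch oracle in the test suite guards this optimization.
Fast mode freezes the reference `p̂_i` at the running mean of the committed
core, updating it only when an accession is committed, never per candidate;
this is what makes each step a single pass at collection scale. Auto mode
(default) scores exactly until the core holds 30 accessions, then switches
to the running mean. One wrinkle the fast approximation creates: a candidate
can carry an allele absent from the core (`p̂_i = 0`), where the KL term
diverges. Those rows fall back to the candidate-inclusive mean, keeping the
objective finite while preserving the strong preference for novel alleles.

Biallelic tables can be stored compactly as one row per locus with the
complementary frequency implied; since the complement is determined, scoring
the compact view with the complement expanded is algebraically identical to
scoring the full table, so selection always runs on the full row set and
compaction is purely a storage form.

## Evaluation criteria

Modified Rogers distance uses `sqrt(Σ(p_ia − p_ib)² / (2L))` over the L
pairwise-complete loci, with the shared-locus count surfaced since pairwise
deletion changes the effective marker set per pair. Shannon diversity is the
entropy (natural log, nats) of the *globally pooled* normalized mean allele
frequencies across all alleles of all loci — a convention-sensitive
quantity: a per-locus-averaged entropy is equally defensible and gives
different numbers, so comparisons must use a single convention. Allele
richness counts an allele as present on strictly positive mean frequency;
no minimum-frequency cutoff is applied, because lost-allele accounting is an
absence criterion.

## Synthetic collections

The generator emulates the structure that matters for these scores: per-locus
multiallelic base profiles drawn from a symmetric Dirichlet (concentration
1.0 by default — flat over the simplex), accession-level drift produced by
resampling each accession's profile from a Dirichlet centred on the base
with spread set by `accession_divergence_scale` (default 0.3, a moderately
structured panel; 0 collapses all accessions onto the base profile),
planted rare accessions owning private alleles (extra allele rows with
frequency 0.5 in the owner, or 1 in inbred mode), an inbred mode fixing each
accession at one allele per locus (frequencies in {0,1}, as for largely
homozygous landrace lines), and per accession-locus block masking at a
configurable rate. Defaults describe a desk-scale panel of 100 accessions at
50 biallelic loci. Every draw flows from one seeded generator, so the
ground-truth manifest is replayable. Planted blocks are never masked, so the
planted signal stays observable at any missing rate.

What the generator does *not* emulate: linkage between loci, pedigree or
coalescent ancestry, genotyping error, and structured (non-random)
missingness. Passing tests therefore demonstrate correctness of the
estimators and the selection algorithm under independent loci and clean
frequencies — not robustness to LD or systematic missing-data patterns in
real marker data.

## Problem sizes and test design

The test and acceptance workloads use desk-scale collections chosen to
exercise every code path while keeping the full suite fast: the four-
accession toy table for exact printed values, 100+ random tables (2–20
accessions, mixed allele counts) for the mutual-information identity at
1e-9, a 7,986-column single-locus table for the missing-data specificity
ceiling, 20-accession × 10-locus tables (20 seeds) for brute-force
equivalence of the greedy, and 200-accession collections with 3 planted
private-allele accessions (20 seeds) for recovery by a size-20 core.
Statistical ordering (greedy beats random subsets on mean divergence) is
checked over 50 seeds at 60 accessions × 30 loci.

## Known limitations

Plug-in entropies are biased at small within-accession sample sizes; no
bias-corrected estimator is provided. The greedy selection is a heuristic
with no optimality guarantee beyond each step's argmax, and offers no
backtracking or exchange moves. Polyploid dosage beyond diploid-like
segregation, imputation and phasing are out of scope.
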