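# Methods

This note records the models, conventions and numerical choices behind
`endofilter`, and what the synthetic test bed does and does not establish.

## The artifact model

Endonuclease-based fragmentation cuts preferentially at hairpin-forming
(palindromic) genomic sites; during end repair the polymerase fill-in step
can mis-incorporate a base at the hairpin center. Because the cut sites are
sequence-determined, the same wrong base appears at the same coordinate in
many independent molecules and many independent libraries, so the artifact
survives consensus-based variant calling and recurs across a cohort. The
filter exploits three consequences: a palindromic reference context centered
on the call, concentration of the variant base 10–15 bases from a read edge
(the fill-in happens near the cut), and frequent soft clipping of the
supporting reads (multiple mis-incorporations at the fragment end that the
aligner clips away).

## Coordinates and data model

Variant positions are 1-based on input/output (VCF/TSV convention); all
internal read arithmetic is 0-based half-open (BAM convention), converted
exactly once at the I/O boundary. The variant identity key used for
recurrence counting and whitelist matching is the 4-tuple
(chrom, pos, ref, alt). Read-level filters applied when collecting evidence
(mapped, primary, non-duplicate, MAPQ ≥ 0) are defaults, overridable in the
API and CLI; base qualities and overlapping-mate deduplication are
deliberately not modeled.

## In-read offset and allele assignment

The offset of a variant on a read is found by walking the CIGAR left to
right with a (query, reference) cursor pair: M/=/X advance both, I/S advance
the query, D/N advance the reference, H neither. A position falling inside a
deletion has no offset and the read supports neither allele. For indels the
anchor base's offset is used, and a read supports the alternate allele iff
an I/D op of exactly the inserted/deleted length immediately follows the
anchor; a read with an adjacent indel of a different length supports neither
allele. Correctness is defined against a per-base expansion oracle
(fuzz-tested on 10,000 random CIGARs).

## Positional bias (two-sample KS test)

Alt-supporting and wildtype-supporting offsets are compared with a
two-sample two-sided Kolmogorov–Smirnov test. Offsets are first folded to
the distance from the nearest read end, `min(o, L−1−o)`, because the
artifact concentrates near *either* edge symmetrically; the raw-offset
transform is available as an option. When n_alt·n_ref ≤ 10,000 the p-value
is computed exactly under the label-permutation null, conditional on the
pooled offsets: an integer dynamic program over tie groups counts the
relabelings whose statistic reaches the observed one, which equals full
enumeration of all C(n₁+n₂, n₁) assignments and remains exact under the
heavy ties integer offsets produce. Larger samples use the asymptotic
two-sided distribution. Variants with fewer than 3 reads in either class are
scored "not evaluable" with p = 1 — a deliberately conservative convention
(no evidence of bias) that lets the soft-clip feature decide.

## SNV-centered palindromes

The SCP arm is the largest k ≤ 20 (window flank 20, covering every length
the artifact produces in practice) such that base center−i is complementary
to base center+i for all i ≤ k; the center base is free (the variant sits in
the hairpin loop), so reported lengths 2k+1 are odd. A mirror
(literal-reversal) mode exists for comparison but the reverse-complement
hairpin is the default, since hairpin structure is what the enzyme
recognizes. Arms are exact matches — no mismatch or bulge tolerance — and
any N stops extension. Contexts with k < 2 are reported as length 0
(shorter matches are ubiquitous by chance: a random context has k ≥ 1 with
probability 1/4). Indels are length 0 by contract. The implementation is
checked against an exhaustive try-every-k oracle, and is invariant under
reverse-complementing the window.

## Stage 1: cohort recurrence

A call is removed when it recurs in ≥ 2 distinct cohort samples; within a
sample duplicate listings count once. The threshold of 2 distinct samples is
the package default (a configurable flag) — artifacts in practice recur far
more often, so the result is insensitive to the exact value. Counting is
leave-one-out by default so a private variant can never be removed by its
own presence in the pool; an include-self mode reproduces pooled
bookkeeping. Whitelisted calls are never removed at this stage regardless of
recurrence, but they are rescued *into* stage 2, not auto-accepted —
recurrent genuine drivers are exactly the calls one most wants the
classifier to look at.

## Stage 2: logistic noise model

Features are x₁ = −log₁₀(p_KS + ε) with ε = 1e-300 (guards p = 0; a raw
p-value compresses all artifact signal near zero) and x₂ = soft-clip ratio
of alt reads (any S op of length ≥ 1 by default). Non-evaluable KS simply
yields x₁ = 0 with no special-casing. The model is a maximum-likelihood
logistic regression (Newton, tolerance 1e-8) of P(artifact | x₁, x₂); under
perfect separation, where the MLE diverges, the fit falls back to an
L2-penalized solution (penalty 1e-6) with a warning. The decision threshold
t on predicted probability maximizes sensitivity + specificity over all
distinct predicted probabilities, ties broken toward the larger t (fewer
removals); `p ≥ t` classifies as noise, so boundary points are removed. A
cut on probability is equivalent to a straight threshold line in feature
space, exposed via `decision_line()`. The threshold sweep is verified
against an exhaustive cut-point oracle, and coefficient estimates against a
known generative model (recovery within 3 standard errors at n = 5,000).

## Signature refitting

SNVs are strand-normalized into the 96 classes X[R>A]Y with pyrimidine
reference R; contexts containing N are excluded and counted. Exposures
solve min ‖f − Pw‖² over the simplex {w ≥ 0, Σw = 1} — squared Euclidean
distance on frequencies is the standard refitting convention, and makes the
problem a convex QP whose solution is scale-invariant in the input counts.
The solver is SLSQP followed by an exact active-set polish (the
equality-constrained least-squares KKT system on the working support), so
noise-free mixtures are recovered to 1e-6 and the returned point satisfies
the KKT conditions to the same tolerance; correctness is defined by KKT
residuals and a dense grid-search oracle on the simplex, not by solver
identity. No de-novo signature extraction (NMF) is attempted. The bundled
synthetic matrix has three full-rank profiles — "noise" mass on C>A/T>G
classes, "genuine" mass on C>T, and a flat background — so mixture recovery
is identifiable without any external download.

## The simulator

The simulator emulates the study conditions the filter targets. Defaults:
3 samples; a pool of 200 artifact sites placed at hairpin centers (odd SCP
lengths 5–21) that each sample carries with probability 0.9 (so most sites
recur, but a fraction stay private and must be caught by the classifier);
50 private genuine SNVs per sample; 100-base single-end reads at depth 50,
VAF 0.5, per-base error 0.001. Artifact alt reads place the variant
uniformly 10–15 bases from a randomly chosen read edge and are soft-clipped
at that edge with probability 0.5; genuine alt reads are uniform in-read
with clip probability 0.05 — these magnitudes mirror the observed feature
distributions of enzymatic versus sonicated libraries. Alternate alleles
are drawn from a signature mixture conditioned on the local trinucleotide
(artifacts from the noise profile, genuine calls from the genuine profile),
so filtering visibly shifts the refitted exposures. All randomness flows
from one integer seed through numpy Generators; output (FASTA, BAM, tables)
is byte-identical across runs.

What the simulator does *not* model: paired-end reads and overlapping
mates, realistic base-quality profiles, alignment (reads are emitted
pre-aligned with constructed CIGARs), indel artifacts, germline
contamination, and copy-number-driven VAF variation. Passing end-to-end
tests therefore demonstrates that the algorithm recovers implanted signal
under its own generative assumptions — near-perfect separation on simulated
data is expected, and real libraries with noisier features will sit closer
to the decision boundary.

## Problem sizes and determinism

The test suite exercises the pipeline end to end at the default simulation
scale (about 690 calls over three 35,000-read BAMs), which completes in
seconds; oracle-equivalence suites use 10,000 fuzzed CIGARs, 1,000 random
41-mers, and exhaustive permutation enumeration for pooled sample sizes up
to 10. The acceptance script reruns both the full-scale bookkeeping
reconstruction (14,715 calls against a two-sample recurrence pool) and the
default simulation. Every stochastic component is seeded; property-based
tests run derandomized.

## Known limitations

* The two training features are assumed sufficient; SCP length is reported
  but deliberately not a model input (it is strongly collinear with the
  positional features on artifact calls, and keeping it out leaves it as an
  independent diagnostic).
* Recurrence counting requires a cohort of libraries prepared with the same
  fragmentation chemistry; with a small or heterogeneous pool, stage 1
  loses power and the classifier carries the load.
* The exact-KS dynamic program is quadratic in sample counts and is capped
  at n_alt·n_ref = 10,000; beyond that the asymptotic p-value is used,
  which is slightly conservative at moderate depth.
* Whitelist matching is exact-key only; no left-alignment/normalization of
  indel representations is performed, so callers should normalize calls
  upstream.
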