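# Methods

This note documents the models, algorithms and design choices behind
`straincomp`, in the order data flows through the two tracks.

## Coordinates and interval algebra

All in-memory coordinates are 0-based half-open; GFF3 and human-facing
reports use 1-based inclusive.  Region sets are kept as sorted,
disjoint, maximally merged interval lists per replicon; union,
complement, intersection and Jaccard are sorted-sweep implementations.
Because these operations carry the whole uniqueness analysis, they are
verified in the test suite against an independent per-base boolean
array oracle on replicons up to 100 kb, including the conservation
identity (covered + complement = replicon length).

## Alignment handling

External aligner output is accepted as MAF (UCSC `a`/`s` dialect, the
`s` source field read as `<genome>.<replicon>`) or as a 9/10-column
TSV.  Minus-strand MAF coordinates, counted from the sequence end, are
converted to forward-strand half-open intervals on input.  Downstream
coverage is strand-agnostic: similarity counts bases shared regardless
of orientation.

The built-in anchor aligner exists so synthetic genomes need no
external tool.  It finds exact k-mer matches (default k = 15, both
strands, `N` never matches), groups them by (target replicon, strand,
diagonal), and chains consecutive anchors within a gap bound (default
100 bp); chains spanning at least the minimum segment length become
segments.  Chaining is greedy and ties break by leftmost query start,
so output is deterministic.  With i.i.d. uniform random background the
expected number of chance 15-mer collisions between two 10-kb
sequences is 2·(10⁴)²/4¹⁵ ≪ 1, so planted verbatim blocks are
recovered cleanly with at most k−1 bp of slack at each edge.  The
aligner makes no claim of parity with production aligners (no gaps, no
substitution scoring); when real assemblies are analysed, segments
should come from a real aligner via the readers.

## Similarity, uniqueness and the two 300-bp thresholds

Segments are filtered to keep query spans **≥ 300 bp**; unique regions
keep complement intervals **strictly > 300 bp**.  The two thresholds
are deliberately different operators (≥ vs >) because they arise from
two different filtering rules in the workflow this package
re-implements; both are configurable.  A base aligned by several
segments counts once (union semantics), so repeats cannot inflate
similarity above 100%.  Genome totals pool all replicons (chromosome
plus plasmids).  Whether a published similarity score counted
alignment columns or reference-base coverage is generally ambiguous;
this package implements reference-base coverage.

The uniqueness report counts a CDS as "in" a unique region when at
least 50% of its length overlaps the unique set — the membership rule
is a package choice (no standard definition exists) and is a
parameter.  Hypothetical proteins are recognised by case-insensitive
substring match on "hypothetical protein".

## Order conservation

Matched segments are ranked along each genome by (declared replicon
order, start).  The default `strict_rank` criterion counts segments
whose rank is identical in both genomes; it is deliberately strict and
yields very small conserved fractions for heavily rearranged genomes
(published six-strain comparisons of this kind report 0.3–5%).  The
`lis` mode (longest increasing subsequence of the rank permutation) is
the common relaxation and is provided because the "same order"
criterion behind published counts is rarely operationalized; the
strict mode is the default and the choice is recorded in every output.
Both modes are validated against exhaustive brute force over
permutations up to n = 6 and sampled permutations at n = 8.

## Pan-genome clustering

Protein products are clustered by single-linkage over pairwise global
alignment (match +1, mismatch −1, gap open −2, extend −0.5), with
identity = identical columns / aligned columns and coverage = aligned
columns / shorter length; the default thresholds (50% / 50%) follow
common pan-genome practice and are configurable.  A shared-5-mer
prefilter skips hopeless pairs.  Cluster ids are the lexicographically
smallest member, making clustering invariant to input order.  Core
counts from real studies depend strongly on the (usually unstated)
clustering method and thresholds, so no exact published core size is
claimed — the partition property (cells sum to the cluster count) and
recovery of constructed homolog families are what the tests enforce.

## Pathway completeness

A pathway definition is a non-empty set of required EC codes.
`fraction_complete` is the share of pathways entirely contained in the
genome's annotated EC set; `fraction_all_but_one` allows one missing
enzyme and includes complete pathways, so it is never smaller.  EC
matching is exact string match (wildcard dashes are preserved as
written in definitions and annotations).

## Kinetic curve summary (the nine parameters)

Each well's curve is summarised by: baseline y₀ (mean of the first 3
points), raw minimum, raw maximum, span, average height, lag λ,
maximum slope μ, plateau (mean of the last 8 points) and AUC.  μ is
the largest first difference of a 5-point centered moving average
divided by the time step; λ is the intercept of the tangent at the
maximum-slope point with the baseline, clamped to the observed time
range (a flat curve has μ = 0 and λ = the last time point).  AUC is
the trapezoidal integral of the baseline-subtracted signal clamped
below at zero, making activity invariant (to ≈1e−6 relative) under
constant signal offsets.

These nine summaries are this package's declared set; other phenomics
suites use similar but not identical parameter lists.

## Sigmoid models and fitting

The three models share the interpretable parameterisation (A, μ, λ,
y₀; Richards adds the shape ν).  At ν = 1 the Richards curve is
algebraically identical to the logistic — which is why model selection
treats near-equal residuals as ties and prefers fewer parameters
(order: logistic, gompertz, richards).  Fits use bounded trust-region
least squares seeded from the curve-parameter summary; non-convergence
is reported as `converged = False` with an infinite-RSS sentinel, never
an exception.  Fitted parameters are diagnostic only: activity always
uses the direct AUC, because truncated or irregular curves make
model-estimated activities unreliable.

## Activity, categorization, ΔA

Activity = mean replicate AUC.  Replicates are flagged inconsistent
when (max − min)/mean > 0.25 — the tolerance is a package choice.
Per-plate categorization uses fraction-of-maximum cutpoints (0.25,
0.50, 0.75 of the plate maximum → low / lower-middle / upper-middle /
high); published four-level figures of this kind never print their
thresholds, so the cutpoints are explicit parameters and categorical
outputs should be treated as interpretation-dependent.  Heat-map
values are per-plate min-max normalized; a constant plate maps to 0.

ΔA = A(strain2) − A(strain1) per substrate; σ_A uses the n−1
denominator.  The default call rule is zero-centered (ΔA < −σ_A /
ΔA > +σ_A), matching the literal published rule; a mean-centered mode
(μ_A ± σ_A) is provided because scatter plots of such analyses draw
the band lines at the mean, and the two readings genuinely disagree
when μ_A ≠ 0.  With σ_A = 0 everything is shared.  Note σ_A is
computed over *all* substrates, so large planted (or real) effects
widen the band themselves; recovery guarantees in the tests are stated
against the noise-induced σ measured on effect-free substrates.

## Synthetic data: what it emulates and what it does not

*Genomes.*  Random i.i.d. uniform DNA background with planted verbatim
shared blocks (optionally shuffled/inverted per genome) and planted
unique blocks, packed first-fit across declared replicons; truth
records exact coordinates.  Uniform background is sufficient to make
15-mer anchors specific; it does not emulate GC skew, repeats, or
mutation between "orthologous" blocks — shared blocks are exact
copies, so alignment sensitivity to divergence is *not* exercised.
For unique-recovery benchmarks the block plans tile each replicon
exactly (shared + unique blocks, no background), so the planted unique
truth is precisely the complement of the shared blocks; the measured
Jaccard ≥ 0.95 then reflects only aligner edge effects.

*Annotations.*  CDSs are laid left-to-right with multinomially
distributed intergenic gaps (default 0.8 CDS/kb, mean 900 bp, which is
bacteria-like), products hypothetical with a stated fraction (default
0.35, in the range reported for environmental actinobacteria), one
category per CDS from a weight table.  No operons, no overlapping
genes, no pseudogenes.

*PM plates.*  Curves are one of the three sigmoid models plus additive
Gaussian noise clipped at zero (default σ = 5 OmniLog units against
amplitudes of 100–250, i.e. a few percent) on the 0–72 h, 15-min grid
(289 points); duplicates per strain by default.  Real OmniLog noise is
not characterised publicly; Gaussian additive noise is an assumption.
The plate truth labels a substrate strain-specific when the noiseless
AUC differs by more than 50% (relative to the larger), a margin chosen
to sit far clear of the noise band so recovery tests are unambiguous.
Richards test curves use ν = 2, since at the default ν = 1 the
"generating model" is not identifiable from a logistic.

## Problem sizes

The bundled benchmarks use six 28-kb genomes for recovery runs, 10–20
kb pairs for aligner unit tests, 200 simulated curves for AUC accuracy
and 24-substrate plates for ΔA recovery — sizes at which every
interval operation can be cross-checked against a per-base oracle and
the whole suite stays interactive.  All stages are linear or
n log n in the data size except the all-vs-all protein clustering,
which is quadratic in the number of CDSs before the k-mer prefilter.

## Known limitations

* The anchor aligner requires exact matches; divergent homology needs
  an external aligner.
* Exact reproduction of published similarity/uniqueness tables for
  real assemblies depends on the original aligner's (unstated)
  parameters and is out of scope; the published numbers are used as
  arithmetic inputs, not as alignment targets.
* EC wildcard semantics are string-literal; no EC hierarchy expansion.
* The Venn display convention caps at 6 genomes (cell counts are
  computed for any N).
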