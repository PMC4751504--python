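# Methods notes

This note records the modelling choices behind ap2kit: what each stage
assumes, which knobs matter, what the synthetic-data generator does and
does not emulate, and where the design was genuinely open.

## Domain model

The family-defining domains (AP2, ~60 residues; B3) are modelled as gapless
position-specific scoring matrices rather than profile HMMs. The downstream
questions — does a protein carry the domain, how many copies, where — need
presence, count and position, not alignment detail; a gapless PSSM answers
them with an order of magnitude less machinery and is exactly testable.
Consequences to keep in mind: domains with internal indels relative to the
seed score lower than an HMM would score them, and bit scores are not
comparable to HMMER's.

* Match columns: < 50 % gaps in the seed (`gap_threshold`). Columns failing
  this are dropped entirely.
* Pseudocount 0.1 added per residue over a 21-letter alphabet (20 amino
  acids + X); X scores 0 in every column so unknown residues are neutral.
* Background frequencies come from the seed itself, with the same
  pseudocounting. A seed therefore defines both signal and null — adequate
  for domain discovery, not for remote-homology search.
* The consensus is the per-column count argmax (ties alphabetical); it is
  used both for planting synthetic domains and as the anchor reference for
  the phylogeny alignment.

### Significance

E-values come from a Gumbel null fitted by the method of moments to the
maximum full-window scores of `n_shuffles` (default 1000, minimum 200)
i.i.d. background sequences of the mean proteome length. The method of
moments was chosen over maximum likelihood because it is closed-form,
deterministic and accurate enough in the far tail for a gate as permissive
as E < 1. The E-value of a score *s* in a database of D proteins is
D·(1 − exp(−exp(−(s − μ)/β))), with D = the number of scanned proteins.
Windows shorter than the profile hanging off either sequence end are
scored on the corresponding profile columns and flagged `truncated`; they
participate in candidate collection but never count as complete domains.

Window acceptance is greedy best-score-first among windows with positive
score, discarding windows overlapping an accepted hit by more than L/2.
With a ~60-column profile the null mean of a full window is deeply negative
(≈ −130 bits), so "positive score" is already a stringent filter for
complete domains; short truncated windows reach positive scores
occasionally, which is why the short-domain exclusion exists downstream.

## Family identification

* Candidates: profile route (any hit at E < `evalue_max`, default 1.0) or
  similarity route (local alignment to a known family query at ≥ 40 %
  identity over ≥ 60 % coverage). Both routes are recorded; similarity-only
  candidates without a scannable domain are later excluded as `no_domain`.
* Splice variants: the annotation maps proteins to genes; the longest
  isoform per gene is kept (ties: lexicographically smallest protein id).
  The underlying assumption — that the longest isoform carries the complete
  domain complement — is also how the synthetic generator builds isoforms.
* Exclusions are explicit and ordered: `short_domain` when the best
  family-domain hit covers less than `short_fraction` (default 0.5) of the
  profile; `divergent_domain` when it misses the E gate; `no_domain` when
  there is no hit at all. Every discarded candidate appears exactly once in
  the exclusions table for manual review; there is no silent filtering.
* Architectures: two non-truncated AP2 hits ⇒ AP2; one AP2 plus a B3 hit ⇒
  RAV; a single AP2 ⇒ DREB/ERF (resolved by the phylogeny); ≥ 3 AP2 hits ⇒
  AP2 with a warning flag. Names are assigned per subfamily in chromosomal
  order, with chromosomes ordered naturally on their trailing integer and
  ties broken by gene start, end, then gene id — fully deterministic and
  independent of input file order.

## Phylogeny

Clustal-style progressive alignment is replaced by profile anchoring: each
domain subsequence is globally aligned (BLOSUM62, gap open 10, extend 0.5)
to the profile consensus and its residues are projected onto the L
consensus columns; insertions relative to the consensus are discarded.
Column homology is therefore inherited from the profile, and the "MSA" is
deterministic, order-independent and dependency-free. The price is that
alignment information inside insertions is ignored — acceptable because
the tree is built on the conserved domain only, as is standard for this
family. Rows occupying < 30 % of columns are dropped with a warning.

* Distances: p-distance with pairwise deletion by default; a Poisson
  correction (−ln(1 − p)) is available as a config option. Pairs sharing no
  columns are an error, except inside bootstrap replicates where the pair
  is assigned the maximum observed distance (resampling can empty a sparse
  pair; aborting a replicate would bias supports).
* Neighbor joining is the canonical Saitou–Nei algorithm. Exact Q ties are
  broken on the smallest leaf labels under the candidate pair, and row sums
  r_i are accumulated in sorted order; together these make the tree
  bit-identical under any permutation of the input rows, which blind index
  tie-breaking cannot guarantee. Negative branch lengths are clamped to
  zero with the raw value retained on the node.
* Bootstrap: column resampling with replacement (B = 1000 by default);
  supports are integer counts of replicates containing the same leaf
  bipartition, displayed against the recorded B.
* Group labels: a query leaf takes the label of the smallest
  edge-bipartition side containing it and at least one anchor, provided all
  anchors on that side agree; otherwise `unclassified`. Members the anchors
  cannot place are reported but never forced into a group, and the pipeline
  leaves them unnamed rather than guessing.

## Duplication and synteny

Pairwise alignment is delegated to Biopython's `PairwiseAligner` (affine
gaps; a gap of length k costs open + (k−1)·extend, with the EMBOSS-like
defaults 10/0.5 and BLOSUM62). The first optimal alignment is always taken,
which is deterministic; the optimal score is unique regardless. Metrics:
identity = identical aligned pairs / aligned pairs; similarity = aligned
pairs with positive substitution score / aligned pairs; coverage = aligned
pairs / length of the longer sequence (the conservative reading of
"matching length"). Thresholds apply to similarity by default; a config
switch (`metric`) applies them to identity instead, since the published
criterion is ambiguous between the two.

Tandem clusters are connected components over family members joined when
on one chromosome, separated by at most `max_intervening` (default 1)
genes in the full annotation order, and passing the thresholds. Two
threshold modes are first-class: `relaxed` (similarity ≥ 0.40, coverage
≥ 0.60 — the published relaxed criteria) and `stringent` (0.70/0.80, this
package's stand-in for the stricter unpublished criteria; both are
reported side by side by the CLI). Segmental pairs must additionally be
anchored in (or fall inside) one intra-species synteny block and are
suppressed when the pair already shares a tandem cluster. Synteny blocks
are inputs, not inferred.

## Stress differential expression

The SAM recipe: d = (x̄_stress − x̄_control)/(s + s₀) with s the two-sample
pooled standard error and s₀ a variance-stabilizing fudge factor. s₀
defaults to "auto" = the median pooled SE across genes for the contrast —
a simplification of SAM's quantile tuning that keeps the statistic
deterministic; the knob is exposed. Significance: group labels are permuted
(all distinct splits enumerated exactly whenever there are at most
`n_permutations` of them, which covers every replicated design up to 4v4;
a warning is emitted below 20 distinct splits); for threshold t,
FDR(t) = median over permutations of #{|d*| ≥ t} / #{|d| ≥ t}, and
q(gene) is the minimum FDR over thresholds at or below |d| of that gene,
capped at 1. Calls gate jointly on |log2FC| > 1 (after a pseudocount of 1)
and q ≤ 0.05 by default; whether the published analysis gated jointly or
on fold change alone is ambiguous, so a `fc_only` switch exists.
Unreplicated contrasts cannot be permuted: the pipeline falls back to
fold-change-only calls with q reported as NA and a loud warning.

The 4-stress × {1, 2, 5, 10, 24} h grid is the generator's default design;
the pipeline itself accepts any condition/timepoint metadata.

## Duplicate-pair divergence

Pairs are compared on log2 fold-change vectors over the concatenated
stress × timepoint grid (20 points by default), using pairwise-complete
Pearson correlation. PCC ≥ 0.5 ⇒ subfunctionalization (the published
cutoff); PCC ≤ 0.1 ⇒ neofunctionalization. No numeric
neofunctionalization cutoff has been published — 0.1 is this package's
choice of a "near zero or negative" boundary, it reproduces the reference
pairs at −0.491 and 0.002 while leaving a 0.361 pair unclassified rather
than forcing it, and it is configurable. Pairs with fewer than
`min_points` (default 10) complete points, or with a constant vector, are
unclassified with a stated reason.

## Synthetic data: what it emulates, and what it does not

The generator plants every feature the pipeline claims to detect: member
proteins with domains sampled near the seed consensus (substitution rate
0.05) in i.i.d. background flanks, across the three architectures; two
single-domain sequence variants ("DREB-like"/"ERF-like", 12 fixed
substitutions each on disjoint positions) that also define the labeled
anchors; decoys of pure background; truncated secondary isoforms for 20 %
of member genes; tandem clusters of sizes 6+2+2+2 and two segmental pairs
whose copies are tuned by rejection to a target global-alignment identity
± 0.03 (i.i.d. substitutions, no indels inside domains); a GFF3 with
subfamily-appropriate exon counts; synteny blocks supporting the segmental
pairs and cross-species ortholog anchors; and expression with
Normal(5, 1) baselines, per-condition latent profiles (sd 1.5), planted
log2 effects (default ±2) and pair correlations induced by latent mixing.

The mixing weight solves the attenuation equation: with latent variance
σ_l² and fold-change noise variance σ_e² = noise_sd²(1/n_s + 1/n_c), the
observed PCC of the mixed pair is ρ̃·σ_l²/(σ_l² + σ_e²), so
ρ̃ = ρ_target(σ_l² + σ_e²)/σ_l², with an error if |ρ̃| > 1.

Deliberately not emulated: nucleotide sequence and codon structure, indel
evolution inside domains, expression count overdispersion (counts are
round(2^x) of Gaussian log-abundances), probe-level summarization, and any
correlation between chromosomal position and expression. Passing the
suite therefore demonstrates algorithmic correctness under the stated
generative model — exact recovery of planted structure, calibrated error
rates — not performance on real proteomes, where domain divergence,
fragmented gene models and heavy-tailed counts will lower sensitivity.
Two practical reflections of this appear in the defaults: identity-tuned
duplicate copies mutate their domain along with the rest of the protein,
so tandem copies sit farther from their subfamily variant than scattered
members and occasionally take the sister group's label in the anchored
tree; and DE calibration runs use latent_sd = 0 so that planted effects
are the only true signal against which false positives are counted.

## Problem sizes and determinism

The default simulated survey is 5 chromosomes, 60 members (12 AP2, 8 RAV,
40 single-domain including 12 tandem-cluster genes and 4 segmental genes),
200 decoys, 3 replicates per condition — large enough that every detector
is exercised, small enough that the full pipeline runs in well under a
minute. Error-rate measurements use 50 null datasets of 150 genes
(4 replicates), 10 effect-planted datasets, 100 additive matrices of 8–16
leaves, 200 brute-force NJ comparisons, 100 alignment-enumeration pairs
and 1000 divergence trials. All randomness flows through named integer
seeds (numpy `default_rng`); identical seeds give bit-identical artifacts,
including trees (see the NJ tie-breaking above) and permutation q-values
(exact enumeration where feasible).

## Known limitations

* The PSSM scan cannot model domain indels; a strongly gapped real domain
  may be found only as a truncated/short hit and excluded (the exclusion
  list makes this auditable).
* Seed-derived backgrounds make E-values seed-relative; comparing E-values
  across profiles built from different seeds is not meaningful.
* The bootstrap resamples columns of the anchored domain alignment only;
  support values say nothing about regions outside the domain.
* Segmental detection trusts the input synteny blocks; no de novo
  collinearity search is attempted.
* The SAM s₀ "auto" rule is a median, not SAM's full quantile optimization;
  with very few genes the statistic is correspondingly cruder.
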