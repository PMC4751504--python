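# ap2kit

Genome-wide characterization of the AP2/EREBP superfamily of plant
transcription factors: the toolkit takes a proteome (FASTA), its annotation
(GFF3), domain seed alignments, expression tables and synteny blocks, and
produces the complete family survey a molecular-evolution study needs —
which proteins belong to the family, how their domain architectures split
them into the AP2, RAV, DREB and ERF subfamilies, how they are related
phylogenetically, which of them arose by tandem or segmental duplication,
how they respond to abiotic stress, and whether duplicated copies have
diverged in expression.

It is written for researchers studying gene-family expansion in plant
genomes (the motivating system is the grass *Brachypodium distachyon* and
its DREB/ERF stress regulators), but every stage is generic: any domain
seed alignment and any annotated proteome will do.

## What it computes

**Domain discovery.** A position-specific scoring matrix is built from a
seed alignment: match columns are the alignment columns with < 50 % gaps,
and each column scores residue *a* as

    S_j(a) = log2( (c_ja + 0.1) / (n_j + 2.1) / q_a )

with add-0.1 pseudocounts and background frequencies *q* estimated from the
seed. Proteins are scanned with a gapless sliding window; significance
comes from a Gumbel null fitted (method of moments) to maximum window
scores of background-shuffled sequences, so each hit gets an E-value
E(s) = D·(1 − exp(−exp(−(s−μ)/β))) for a database of D proteins. Candidates
are retained at E < 1.0, or through local-alignment similarity to known
family queries (≥ 40 % identity over ≥ 60 % coverage).

**Family assembly.** Splice variants collapse to the longest isoform per
gene; candidates whose best domain hit is too short (< L/2), insignificant,
or absent are excluded with an auditable reason. Two complete AP2 domains ⇒
AP2 subfamily; AP2 + B3 ⇒ RAV; a single AP2 domain ⇒ DREB/ERF, resolved by
phylogeny. Members are named `<prefix><SUBFAMILY>-<k>` in chromosomal
order (`Bd1 < Bd2 < Bd10`).

**Phylogeny.** Domain regions are aligned to the profile consensus
(insertions projected out), giving a deterministic alignment over the L
profile columns. Distances are p-distances with pairwise deletion
(Poisson correction optional); trees are canonical Saitou–Nei
neighbor joining, Q(i,j) = (n−2)d(i,j) − r_i − r_j, with bootstrap supports
from column resampling (default B = 1000). Subfamily/subgroup labels
propagate from labeled anchor sequences: each query leaf takes the label of
the smallest edge-bipartition side containing it and at least one anchor,
if those anchors agree — otherwise it stays unclassified.

**Duplication.** Tandem clusters are connected components of family members
on one chromosome separated by at most one intervening gene (counted on the
full annotation) that pass similarity/coverage thresholds on global protein
alignments (stringent 70 %/80 %; relaxed 40 %/60 %). Segmental pairs must be
anchored in one intra-species synteny block. Cross-species blocks map
members to orthologs with per-species counts.

**Stress expression.** RPKM normalization, Affymetrix-style probe filtering
(perfect, unique, exonic alignments only), and SAM differential-expression
calling: d = (x̄_s − x̄_c)/(s + s₀) with a permutation FDR, genes called
up/down at |log2FC| > 1 and q ≤ 0.05.

**Duplicate divergence.** Each duplicated pair is correlated (Pearson)
over its log2 fold-change vectors across the 4-stress × 5-timepoint grid;
PCC ≥ 0.5 ⇒ subfunctionalization, PCC ≤ 0.1 ⇒ neofunctionalization.

A synthetic-data generator (`ap2kit.synthetic_data`) emulates all inputs
with planted ground truth — members, architectures, isoforms,
identity-tuned tandem/segmental duplicates, fold-change effects and
pair correlations — so the full pipeline is exercisable and testable
without downloading any genome.

## Worked example

```python
from collections import Counter
from ap2kit import synthetic_data as sd
from ap2kit.family_identify import identify_family, assign_names, members_table
from ap2kit.phylogeny import anchor_msa, bootstrap_support, label_groups

params = sd.SimParams(rng_seed=42)          # 5 chromosomes, 60 members, 200 decoys
profiles = sd.default_profiles()            # calibrated AP2 + B3 PSSMs
records, models, truth = sd.gen_proteome_gff(params, profiles)
anchors, queries = sd.gen_reference_sets(params, profiles)

members, excluded = identify_family(records, models, list(profiles.values()), queries)
print(f"retained {len(members)} family members, excluded {len(excluded)} candidates")
print("exclusion reasons:", dict(Counter(e.reason for e in excluded)))

items = [(m.gene_id, m.sequence[h.start:h.end])
         for m in members if m.subfamily == "DREB_ERF_unresolved"
         for h in [max((x for x in m.hits if x.domain_name == "AP2"),
                       key=lambda x: x.score)]]
items += [(a.sequence.id, a.sequence.residues) for a in anchors]
tree = bootstrap_support(anchor_msa(profiles["AP2"], items), B=1000, rng_seed=425)
labels = label_groups(tree, anchors)
for m in members:
    if m.subfamily == "DREB_ERF_unresolved" and labels.get(m.gene_id) in ("DREB", "ERF"):
        m.subfamily = labels[m.gene_id]
assign_names(members, "Bd")
print("subfamily sizes:", dict(Counter(m.subfamily for m in members)))
```

prints

```
retained 60 family members, excluded 18 candidates
exclusion reasons: {'splice_variant': 12, 'short_domain': 5, 'no_domain': 1}
subfamily sizes: {'AP2': 12, 'RAV': 8, 'DREB': 21, 'ERF': 19}
```

All 60 planted members are recovered with no false positives (the 18
exclusions are the planted splice isoforms plus decoys that briefly
entered through truncated or similarity-only matches), and the subfamily
split matches the planted architectures, with the single-domain members
divided between DREB and ERF by the anchored phylogeny.

The same workflow is available as a command-line pipeline with resumable
per-stage TSV/Newick artifacts:

```sh
ap2kit all --outdir out --seed 42          # simulate → identify → … → diverge
ap2kit phylo --config my_run.yaml          # re-run one stage
```

## Layout

| module | contents |
| --- | --- |
| `ap2kit.io_formats` | FASTA / GFF3 / Newick / TSV readers and writers (0-based half-open internally) |
| `ap2kit.domain_profile` | PSSM construction, scanning, Gumbel E-value calibration |
| `ap2kit.family_identify` | candidate collection, isoform collapse, exclusions, architectures, naming |
| `ap2kit.phylogeny` | profile-anchored MSA, p-distances, NJ, bootstrap, anchor labeling |
| `ap2kit.duplication_synteny` | global/local alignment metrics, tandem/segmental detection, ortholog mapping |
| `ap2kit.expression_stress` | RPKM, tissue profiles, probe filter, SAM permutation DE |
| `ap2kit.divergence` | duplicate-pair PCC classification |
| `ap2kit.synthetic_data` | planted-truth genome/expression generator |
| `ap2kit.cli` | the `ap2kit` stage runner |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
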