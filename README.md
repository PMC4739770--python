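# fragvocab

Detection of sub-domain-sized peptide fragments whose sequence **and**
structure similarity is shared across globally different protein folds.

Protein domains classified into different folds are usually assumed to be
unrelated: their overall structures cannot be superposed, and fold-level
similarity alone can arise by convergence.  Local similarities are another
matter.  A fragment of 10–40 residues that recurs in several folds with
*both* significant profile-level sequence similarity and a superposable
backbone is best explained by common descent — a remnant of an ancient
peptide that predates the folds it now inhabits.  This package implements
the comparative pipeline for finding such fragments in a classified domain
library, and the statistical analysis that separates homology from
structural convergence.  It is written for structural bioinformaticians
who want to run, test, or extend this kind of survey at desk scale.

## What it computes

**Detection pipeline** (`fragvocab.pipeline`):

1. *Profile search.*  Each domain's MSA becomes a position-specific profile
   (Henikoff weights, background-mixture pseudocounts).  All domain pairs
   are compared in both directions by Smith–Waterman over the log-odds
   column score `s(p,q) = log2 Σ_a p_a q_a / f_a`; only reciprocal matches
   are kept, with the two probabilities averaged.  Significance is
   calibrated empirically: local scores of shuffled-column profile pairs
   are fitted with a Gumbel extreme-value law (location corrected for
   `ln(m·n)` search-space size), and p-values map onto a 0–100 probability
   scale anchored so that p = 5×10⁻⁵ ⇔ probability 70.
2. *Structural verification.*  The aligned segments are superposed by a
   TM-align-style iterative aligner (Kabsch superposition, proximity-matrix
   dynamic programming, distance-cutoff refinement).  The TM-score
   `TM = (1/L) Σ 1/(1+(dᵢ/d₀)²)`, `d₀ = 1.24·(L−15)^⅓ − 1.8`, is
   normalized by the shorter segment.
3. *Filtering.*  Matches survive with probability ≥ 70, TM ≥ 0.5, both
   segments spanning ≥ 2 secondary-structure elements (Cα-geometry
   assignment), only between domains of different folds; single
   connections between well-populated superfamilies are pruned.
4. *Clustering and census.*  Fragment instances pool by single-linkage
   when their intervals mutually overlap ≥ 80%; clusters covering most of
   their member domains are flagged as global fold similarity; survivors
   are trimmed to majority-occupancy consensus boundaries and counted per
   fold and superfamily.
5. *Annotation.*  A cluster is annotated with a ligand category
   (nucleic acid, metal, iron–sulfur cluster, nucleotide/cofactor) when
   any instance makes ≥ 3 atomic contacts within 3 Å of such an entity.

**Correlation analysis** (`fragvocab.correlation`): each fragment is
scanned against the library structurally (query-length-normalized TM ≥
0.5); every structural hit is then scored in sequence space over the
*fixed* structural alignment.  Homologous hits (superfamilies where the
fragment occurs) should show sequence score rising with TM; analogous hits
(other folds) should not.  The contrast is tested by OLS regression with a
slope t-test at α = 10⁻¹⁰.

**Synthetic fold generator** (`fragvocab.synthetic`): idealized
helix/strand scaffolds grouped into folds, with fragments planted across
folds at controlled sequence identity and coordinate noise, analog decoys
(same backbone, unrelated sequence), per-domain MSAs under a
BLOSUM62-conditional substitution model with per-site rate heterogeneity,
and pseudo-ligands placed at controlled contact distances — all with a
ground-truth manifest, so every pipeline stage is testable without any
external database.

## Worked example

```sh
fragvocab simulate --out lib --seed 1
fragvocab run --library lib --out clusters.tsv
fragvocab annotate --library lib --clusters clusters.tsv --out annotated.tsv
fragvocab census --clusters annotated.tsv
```

The `run` step prints the stage audit:

```json
{
 "n_clusters": 3,
 "n_clusters_unflagged": 3,
 "n_domains": 20,
 "n_pruned": 8,
 "n_searched": 190,
 "n_verified": 8
}
```

190 domain pair comparisons collapse to 8 verified inter-fold matches,
which pool into 3 clusters — one per fragment planted by the simulation,
none relying on global fold similarity.  The census then reads:

```
c001	3	3	-	nucleic_acid
c002	3	3	-	iron_sulfur
c003	3	3	-	metal
```

Each cluster spans 3 folds and 3 superfamilies, shows no within-domain
repetition, and carries the ligand category of the pseudo-ligand the
generator placed on one of its instances.  The same workflow is available
as a library call (`fragvocab.pipeline.run_detection`).

## Layout

| module | contents |
| --- | --- |
| `fragvocab.data` | domain records, classification labels, intervals |
| `fragvocab.profiles` | profiles, column scores, local DP, Gumbel null |
| `fragvocab.structure` | Kabsch, TM-score, structural aligner, SSE assignment |
| `fragvocab.pipeline` | search → verify → prune → cluster → census |
| `fragvocab.ligands` | contact rule and category annotation |
| `fragvocab.correlation` | structural scan, partitioning, regression |
| `fragvocab.motifs` | reference supersecondary-motif selection |
| `fragvocab.synthetic` | fold/fragment/MSA/ligand generator with ground truth |
| `fragvocab.io` | FASTA/A3M, PDB (gemmi), TSV, JSON readers/writers |
| `fragvocab.cli` | `fragvocab` subcommands over the library |

Methodological details and the design decisions behind the defaults are in
[docs/methods.md](docs/methods.md).
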