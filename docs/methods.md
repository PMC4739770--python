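# Methods

This note records the models, parameter choices, and numerical conventions
behind `fragvocab`, and what the synthetic benchmark does and does not
establish about behaviour on real structure libraries.

## Problem setting

Input is a library of classified domains: per-domain sequence, multiple
sequence alignment, Cα coordinates (optionally with additional atoms and
bound-ligand records), and a family/superfamily/fold/class label.  The
hierarchy carries the survey's logic: family and superfamily membership
imply accepted homology, whereas a shared fold alone may reflect
convergence.  The pipeline therefore searches for *inter-fold* pairs whose
local sequence similarity is individually significant and whose aligned
segments also superpose — the combination that is hard to explain without
common descent — and aggregates them into fragment clusters.

## Sequence profiles and significance

**Profile construction.**  MSAs are reduced to match columns (A3M
convention: lowercase and `.` are insertions relative to row 1).  Sequences
get Henikoff position-based weights; column probabilities mix the weighted
observed frequencies `g` with Robinson–Robinson background frequencies
`f`: `p = (1−τ) g + τ f` with `τ = w · a/(a + n_eff − 1)`, `a = 1`,
default pseudocount weight `w = 0.5`, and `n_eff` the column's effective
sequence count (inverse participation ratio of the normalized weights).
A single-sequence column thus receives exactly `w` of background mass, and
pseudocount influence decays as alignments deepen.

**Column score and alignment.**  Two columns score
`s(p,q) = log2 Σ_a p_a q_a / f_a` bits — the symmetric co-emission
log-odds.  Domains are compared full-length (never as fragments) by
Smith–Waterman with affine gaps, default open 4.5 bits and extend 0.75
bits.  These defaults were tuned on the generator's planted-fragment
recovery benchmark: weaker penalties let random positive tails extend
alignments far beyond the shared fragment, inflating both the null
location and the segment boundaries used later for interval clustering.

**Empirical null.**  Because the score depends on profile composition and
gap settings, significance is calibrated in-repo rather than taken from
theory: scores of shuffled-column profile pairs (composition preserved,
position destroyed) are fitted by maximum likelihood with a Gumbel law for
maxima, after regressing out the Karlin–Altschul-style `ln(m·n)` length
trend in the location.  At least 500 samples are required; 2000 are used
for the reported calibration.  On 5000 fresh shuffled pairs the fraction
with p < 0.01 matches 0.01 within binomial error (the acceptance script
recomputes this).

**Probability scale.**  P-values map to a 0–100 "probability" through a
logistic in −log10 p with unit slope per decade, anchored by construction
so that p = 5×10⁻⁵ ⇔ 70.  The 70/0.5 working point (probability ≥ 70,
TM ≥ 0.5) is the match-acceptance criterion throughout.  The scale is a
rank-preserving analogue of the posterior-style probabilities of
profile-HMM search tools; numerical agreement with any external tool is
not a goal.

**Reciprocity.**  A pair is retained only if both directions report a
local alignment and the two segments mutually cover ≥ 50% of each other;
the pair carries the average of the two probabilities.  With a symmetric
column score the two directions rarely disagree, but the check guards the
contract when scoring is extended.

## Structure comparison

**Superposition and TM-score.**  Kabsch least-squares superposition (SVD,
reflection excluded, collinear inputs rejected).  The TM-score of a fixed
residue pairing is maximized over superpositions by the standard iterative
scheme — superpose on a seed subset, reselect pairs inside a distance
cutoff, iterate — with seeds from contiguous runs of the pairing (full,
half, quarter length) and a cutoff schedule descending 8 → 0.5 Å so that
tightly fitting subsets can dominate when `d₀` is small.  `d₀` is clamped
at 0.5 Å for normalization lengths ≤ 21, where the cube-root formula turns
non-positive.  On small cases the implementation agrees exactly with an
exhaustive subset-enumeration oracle (tested to 10⁻⁶).

**Structural aligner.**  The pairing itself is found heuristically: seeds
from gapless 8-residue window superpositions (top 8 by a TM-like diagonal
score) plus a secondary-structure-string alignment and the identity
diagonal; each seed is refined by iterating superposition (on pairs within
the 8 → 4.5 → 3.5 Å cutoff schedule) → proximity matrix
`S_ij = 1/(1+d²_ij/d₀²)` → semiglobal DP with gap penalty 0.6 (no extend),
until the pair set repeats or 30 rounds.  Converged candidates are ranked
by a single-superposition proxy score and the best by full TM-score
maximization is returned, with TM reported under both length
normalizations.  Two normalization conventions are used downstream:
match verification normalizes by the *shorter* aligned segment
(conservative for unequal segments; configurable), fragment scans by the
*query* length.

**Secondary structure.**  Assignment uses Cα geometry only: a window
start is helical when d(i,i+3) ∈ [4.6, 6.4] Å and the Cα pseudo-torsion
∈ [−70°, −30°] (the generator's helical screw sense), strand when
d(i,i+2) ∈ [6.1, 7.4] Å, d(i,i+3) ∈ [8.8, 11.4] Å and |torsion| ≥ 130°.
A run of ≥ 3 consecutive valid starts (single gaps closed) paints the
residues its windows cover.  The torsion and d(i,i+3) conditions exist
because tight turns mimic helix/strand distances and would otherwise merge
flanking elements — which matters directly for the single-element filter:
a match whose aligned segment spans only one secondary-structure element
is discarded, since single helices or strands superpose trivially.  The
windows are calibrated to the generator's ideal geometry plus 0.5 Å
noise; real structures with distorted SSEs would need re-calibration
against a DSSP-style reference.

## Detection pipeline

Stage order: all-vs-all search → reciprocal filtering → structural
verification → thresholding (probability ≥ 70, TM ≥ 0.5, ≥ 2 SSEs per
segment, inter-fold only) → sparse-connection pruning → interval
clustering → global-similarity triage → optional curation → consensus
trimming → census.  Stage counts are reported for audit and are
monotonically non-increasing along the filter chain.

Decisions worth recording:

* **Segment-core trimming.**  After verification, match segments are
  trimmed to the residues whose structural alignment places them within
  5 Å (kept when ≥ 8 such pairs exist).  Local sequence alignments
  over-extend into the flanking scaffolds by chance; since the scaffolds
  belong to different folds they do not superpose, and shedding them makes
  the interval-overlap clustering see the fragment itself rather than the
  alignment's tails.
* **"Larger" superfamilies** for pruning are those with ≥ 2 member
  domains in the library (configurable): a singleton superfamily never has
  the opportunity to make a second connection, so its single links are not
  penalized.
* **Overlap rule.**  Instances pool when intervals mutually overlap
  ≥ 80% of *each* interval's length — the conservative reading that
  prevents a short interval from absorbing a long one.  Same-domain
  instances connected by this rule are merged to their union interval, so
  the repetition flag in the census means two genuine copies, not two
  reports of one occurrence.
* **Global-similarity triage** is automated: a cluster is flagged when the
  median fraction of member-domain length covered by its instances is
  ≥ 0.8.  Homologous fold change (circular permutation, hairpin swaps)
  produces such whole-domain clusters; in manual surveys they are removed
  by inspection, here by this proxy plus the curation config
  (`{"merge": [[...]], "drop": [...]}`), which records provenance for
  every action.
* **Consensus trimming** aligns every instance structurally to the
  longest instance of its cluster and keeps reference columns occupied by
  ≥ 50% of instances; each instance is trimmed to its residues inside the
  consensus span.  Structure, not sequence, is used as the within-cluster
  aligner because instances may be near or below the sequence twilight
  zone while remaining superposable.

## Ligand contacts

A fragment instance interacts with a bound entity when ≥ 3 atom pairs lie
within 3 Å.  All atoms of the instance's residues are used; when only Cα
coordinates exist the cutoff widens to 5 Å with a logged warning, since
the 3 Å rule presumes side chains.  Nucleic-acid polymers are recognized
by residue codes (A, C, G, U, DA, DC, DG, DT) rather than HET codes.  A
cluster receives a category when *any* instance passes the test; the
manual-include mechanism adds categories known from evidence outside the
coordinate files (e.g. complexes solved only by NMR), flagged "curated".

## Correlation analysis

Fragments are scanned against the library with windows of 1.2× the query
length sliding at L/4 steps, the best window per domain kept at
query-normalized TM ≥ 0.5.  The window capacity (single size, 120% of the
query) spans the ±20% length variation expected of diverged fragment
copies at a fraction of the cost of a size sweep.  Sequence similarity of
each hit is the mean profile column score over the *fixed* structural
alignment — no sequence-driven realignment — so the two similarity axes
are measured independently.  Hits partition into homolog (target
superfamily in the fragment's occurrence map, excluding the query's own),
analog (target fold entirely outside the map), or excluded (the query's
own superfamily, or an unlisted superfamily of a listed fold — the bucket
that makes the partition exhaustive without forcing an unsafe call).
Per partition, sequence score is regressed on TM by OLS with a two-sided
slope t-test (n−2 df) at α = 10⁻¹⁰, and Gaussian fits summarize the score
distributions above TM 0.5.  No probability floor is applied to scan
hits.

## Reference motifs

The baseline for the correlation contrast is a set of frequent
supersecondary motifs (two secondary structures joined by a loop) drawn
from any motif library in the documented JSON schema; the generator emits
one.  Selection: scan clusters by descending frequency, pick one
seeded-random representative per cluster among members with exactly the
target length (24 residues — the typical consensus-fragment length), ≥ 6
residues per element and loop ≤ 6; eliminate non-compact representatives;
keep the most frequent survivors.  Compactness has no agreed criterion, so
a stand-in rule is used and flagged in output metadata: ≥ 3 inter-element
Cα pairs within 8 Å.

## Synthetic data model

The generator emulates a classification-database survey at desk scale.
Defaults are the benchmark study conditions: 5 folds × 4 domains, 3
planted fragments at 40% sequence identity and 0.5 Å coordinate noise,
3 analog decoys, MSAs of depth 20 at mutation rate 0.3, ligand placements
at 2.9 Å with exactly 3 contact atoms, seed 1.

* **Geometry.**  Ideal helices (1.5 Å rise, 100°/residue, 2.3 Å radius)
  and strands (3.4 Å axial zigzag) joined by clash-avoiding random coil;
  fragment templates are explicit antiparallel hairpins with tight
  circular-arc turns (2.8 Å/residue loop step) so turn geometry does not
  read as strand.  Planted lengths (24, 28, 26) are subdomain-sized,
  around the typical consensus length, with the β-hairpin long enough that
  its `d₀` tolerates the benchmark noise (the generator's calibration
  property: every planted instance recovers its template at TM ≥ 0.7
  under the default conditions).
* **Divergence model.**  Each fragment draws a fixed *mutable complement*
  (60% of positions at 40% identity); every instance substitutes exactly
  those positions via BLOSUM62-conditional draws.  Instance→template
  identity equals the configured fraction, and instance↔instance identity
  is approximately the same — the conserved-core behaviour of real
  homologous motifs.  Fully independent per-instance mutation would push
  pairwise identity to ~16% over ~25 columns, which no sequence method
  could detect and which would make the stated benchmark incoherent.
* **Rate heterogeneity.**  MSA rows mutate per position: 0.05 at the
  fragment's conserved core, 0.5 at its mutable sites, 0.3 elsewhere —
  constrained sites evolve slowly, unconstrained ones fast.  This is what
  gives profile columns their position-specific information; with a
  uniform rate, planted pairs score near the null.
* **Decoys** reuse a template backbone (0.3 Å jitter) with a
  background-resampled sequence: structurally convincing, sequence-blank.
* **Determinism.**  One root seed; per-domain streams derive by stable
  hashing of the domain id, so any subset regenerates identically, and
  `emit_dataset` output is byte-identical across runs.

**What the benchmark shows — and does not.**  Passing tests establish that
the pipeline discriminates planted homology from structural analogy under
idealized geometry, star-topology MSAs, and cleanly separated folds.  Real
libraries have distorted secondary structure, phylogenetically correlated
MSAs, domain-boundary artifacts, and a continuum of fold similarity; the
absolute thresholds (70/0.5) are taken from practice on real data and the
synthetic results do not re-validate them there.  Scaling behaviour beyond
tens of domains (the all-vs-all stage is quadratic) is likewise untested.

## Numerical conventions and edge cases

* Intervals are 1-based and closed; all interval arithmetic uses this
  convention exclusively.
* PDB I/O: first model, altloc A or blank, coordinates at PDB precision
  (3 decimals); non-amino-acid residues become ligand records.
* Kabsch requires ≥ 3 non-collinear pairs; TM-score requires non-empty
  pairs; the aligner requires ≥ 5 residues; degenerate inputs raise
  `ValueError` rather than returning sentinel scores.
* DP tracebacks recompute cell recurrences with exact float comparisons
  and a fixed tie order (diagonal > vertical > horizontal), making
  alignments deterministic.
* The Gumbel fit refuses score sets with near-zero variance, and the null
  model refuses fewer than 500 samples.
* Cluster ids are assigned after sorting components by their first
  instance, so shuffling the input domain order changes nothing but the
  labels.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the 20-domain benchmark
(~190 pair comparisons), a 2000-sample calibration evaluated on 5000
fresh null pairs, correlation sets of 500 hits per partition, and
oracle checks on ≤ 10-residue cases where exhaustive subset enumeration
is feasible.  These sizes exercise every code path while keeping the
whole analysis reproducible in minutes on one CPU.
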