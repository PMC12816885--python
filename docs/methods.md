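# Methods

This note documents the models and procedures implemented in
`gendemarc`, the parameters that matter, the numerical conventions, and
what the synthetic benchmark does and does not demonstrate.

## Pairwise proteome metrics

### Alignment engine

All protein comparisons use Smith–Waterman local alignment under
BLOSUM62 with affine gaps (open 11, extend 1, scored on the first and
subsequent gap positions respectively), executed through Biopython's C
`PairwiseAligner`. When several alignments are co-optimal the aligner's
first traceback is used; identity is `100 · identities / columns` with
internal gap columns in the denominator, and query coverage is the
fraction of the query spanned by the local alignment.

Significance uses the Karlin–Altschul form `E = K·m·n·exp(−λS)` with
the ungapped constants λ = 0.3176, K = 0.134 applied to the gapped raw
score *S* as an approximation (`m`, `n` the full sequence lengths); the
bit score is `(λS − ln K)/ln 2`. These constants are a documented
convention: the absolute E-values are approximate, but the ≤ 10⁻⁵
ceilings used by the AAI/POCP filters are far from the decision
boundary for any biologically meaningful hit at desk scale.

### Search strategy

The all-vs-all search is quadratic in proteome size. Two screens keep
desk-scale runs fast without changing results materially:

* a k-mer prefilter (default: candidate pairs must share ≥ 1 exact
  4-mer). For homologs at ≥ 60 % identity over ~100 aa the expected
  number of shared 4-mers is > 10, so the probability of discarding a
  true hit is negligible; unrelated pairs are mostly skipped. Setting
  `min_shared_kmers=0` disables the prefilter entirely (the exhaustive
  mode used by the oracle tests).
* a raw-score screen derived from the E-value ceiling: alignments whose
  optimal score cannot reach `E ≤ max(ceilings)` are dropped before
  traceback. This screen is exact with respect to the hit filters.

Because the optimal local alignment between two sequences does not
depend on direction, each unordered pair is searched once and both
directional best-hit maps are derived from the same hit table; AAI and
POCP are therefore symmetric by construction, and best-hit ties are
broken toward the lexicographically smallest subject id.

### Filters

AAI averages reciprocal best hits with identity ≥ 40 %, query coverage
≥ 50 % and E ≤ 10⁻⁵ in both directions (EzAAI-style defaults). POCP
counts proteins with any hit at E < 10⁻⁵, identity > 40 % and an
alignable region > 50 % of the query, per the POCP definition; note the
deliberate strict-vs-non-strict differences between the two
conventions. A pair with no qualifying reciprocal best hit has an
*undefined* AAI — an explicit flag, never a silent NaN — and contributes
no edge to the criterion graph.

## Boundary detection

The pooled unique-pair AAI values are density-estimated with a Gaussian
kernel, bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)` (the classical
rule of thumb; sample sd, ddof = 1), evaluated on a 512-point grid
spanning the data range extended by 3 bandwidths.

**Valley definition.** A reported boundary is an interior grid point
whose density is ≤ both neighbours and which separates two *significant
modes* — strict local maxima reaching at least 10 % of the curve's peak
density. The significance requirement exists because a raw
lowest-local-minimum rule latches onto near-zero wiggles beside
isolated points in sparse tails at small bandwidths; requiring flanking
modes restores the intended notion of "the valley of a bimodal
distribution". The flanking modes may lie outside the 60–80 % search
window (the within-genus mode typically does); only the valley itself
must lie inside it. Among candidate valleys the lowest density wins,
with ties broken toward the lower abscissa.

**Sensitivity sweep.** The bandwidth multiplier `adjust` is swept over
0.5–2.0 in steps of 0.1 (16 evaluations — fine enough to bound the
interval). Whether a boundary exists at all is decided on the
`adjust = 1` curve, which also supplies the headline threshold; the
sweep interval `[min, max]` of valley positions quantifies robustness.
If the default-bandwidth curve shows no valley the estimate carries a
no-boundary flag (the behaviour expected of, e.g., POCP distributions
that lack a clear bimodal pattern), since valleys appearing only at
other bandwidths are smoothing artefacts.

## Genus delineation

Pairs with AAI ≥ threshold *and* POCP ≥ threshold (both inclusive;
POCP default 50 %) form the edges of a criterion graph. Connected
components are the candidate genera — the simplest faithful reading of
"grouping the pairs that meet both criteria"; a clique-based rule would
be stricter and is noted as an alternative. Each component is tested
for monophyly on the rooted input tree (singletons are monophyletic by
definition). A non-monophyletic component is resolved greedily: at each
step the member whose removal leaves the fewest intruders is removed
(ties broken toward the lexicographically last id, so the rule is
deterministic), until the remainder is monophyletic or a singleton.
Removed genomes are reported as exclusions with a reason code rather
than silently dropped — the analogue of excluding rogue MAGs by
inspection, made auditable. Unrooted trees are not supported.

## Relative evolutionary divergence

For a node with parent RED *p*, branch *d* to its parent and mean
branch-length distance *u* from the parent to all leaves descending
through the node, `RED = p + (1 − p)·d/u`, with RED 0 at the root and
exactly 1 at every leaf. Multifurcations are handled natively (the mean
runs over all descendant leaves). Zero-length branches inherit the
parent's RED; an internal node whose entire subtree has zero length has
no defined RED and raises. RED is invariant under global rescaling of
branch lengths.

A taxon's RED is the RED of its members' MRCA. Singleton taxa have no
circumscribing internal node; the leaf's parent's RED is returned with
an explicit `singleton` flag rather than interpolating along the
pendant edge — conservative and visible to the caller. "Core clade"
RED is the same statistic evaluated on a named subset (e.g. validly
published species only). Rank summaries use the median (mean of the
central pair for even counts).

## Marker–phenotype concordance

The validated clade of a gene tree is the MRCA of the experimentally
validated reference sequences — the minimal defensible formalisation of
a clade drawn around references in a figure. A single reference falls
back to its parent node; a reference set spanning the whole tree
returns the root with a warning, since such a clade carries no signal.
A genome is a member when at least one of its genes lies in the clade;
genomes with no gene in the tree are *absent* (distinct from
non-member) and are tallied in separate absent/positive and
absent/negative side channels. Agreement is `(n11 + n00) / total` over
genomes with both calls. Phenotypes are three-valued
(positive/negative/variable); "variable" records are excluded from the
counts by default, reflecting strains whose literature status is
inconsistent.

A neighbour-joining helper (scikit-bio `nj` over 100 − global identity,
midpoint-rooted) is provided for building gene trees in synthetic
tests; real analyses should supply a maximum-likelihood gene tree.

## Synthetic data generator

The generator emulates the statistical structure the pipeline exploits,
with closed-form truth:

* **Tree.** A balanced backbone of `n_genera` clades. Genus subtrees
  are ultrametric with height `intra_depth/2` on stems of length
  `(inter_depth − intra_depth)/2`, so between-genus leaf distance is
  exactly `inter_depth`. Within a genus, coalescences are drawn from
  the deepest fifth of the clade, keeping every within-genus pairwise
  distance close to `intra_depth`; this concentrates the planted
  within-genus identity at the configured value instead of letting it
  spread far above it.
* **Proteomes.** `n_families` (default 150) families of length 100 aa
  evolve along the tree under a 20-state Jukes–Cantor model (Poisson
  substitution events, uniform replacement over the 19 other residues),
  giving the closed-form expected identity
  `floor + (100 − floor)·exp(−d·20/19)` for path distance *d*, with
  `floor = 5 %` the random-alignment baseline. Families are lost
  irreversibly per branch with probability 0.03, producing POCP < 100
  with an analysable expectation. Default depths plant within-genus
  identity ≈ 85 % and between-genus ≈ 70 %, so the pooled AAI
  distribution is bimodal with its valley inside the 60–80 % window.
* **Marker.** The marker gene is carried only by the genomes of
  `marker_genera`; its tree is the induced carrier subtree with
  reference genes grafted across the children of the carrier clade's
  root (so the validated clade spans exactly the carriers), and the
  phenotype equals carrier status.

All outputs are byte-deterministic given the config seed (independent
numpy generator streams for tree, proteomes and marker).

**What the synthetic benchmark does not show.** Sequences evolve
without indels (equal lengths per family), under a uniform substitution
model rather than an empirical matrix, with no rate heterogeneity, no
paralogy, no contamination or annotation error, and phenotype noise
only if planted. Passing the recovery tests demonstrates that the
statistics and decision rules behave as designed under their own model
assumptions — not that real proteomes will produce equally clean
bimodality or perfectly monophyletic criterion groups.

## Numerical and interface conventions

* Nucleotide global identity (16S-style comparisons): Needleman–Wunsch
  with match +1, mismatch −1, gap −2 (linear), terminal gaps penalised;
  identity over all alignment columns including gaps. Identity
  conventions differ across aligners, so values published from other
  tools (Clustal Omega, blastn) are expected to deviate by a fraction
  of a percentage point. The pair is canonically ordered before
  alignment, making the result exactly symmetric. The commonly accepted
  genus-level 16S similarity band (92–95 %) is used for flagging.
* G+C content is pooled over records, excludes ambiguity codes from
  numerator and denominator, and is reported to 0.1 precision.
* FASTA records are validated against the declared alphabet (X/N
  ambiguity allowed, gaps rejected); duplicate ids and illegal
  characters raise errors naming the record and position. Newick trees
  round-trip with branch lengths to 1e-9 and internal labels verbatim.
* The pipeline report is deterministic for identical inputs and
  configuration: no timestamps, sorted keys, digests of inputs in a
  provenance block. A stage failure aborts with the stage name; partial
  outputs are retained.

## Problem sizes

The default validation conditions are 2 genera × 5 genomes with 150
families of 100 aa (45 genome pairs per run); boundary-recovery
statistics use 500-value samples over 100 seeds, and end-to-end
recovery uses 20 independently seeded runs. These sizes give stable
Monte-Carlo estimates for every statistic the tests assert while
keeping a full validation run on a single CPU in the minutes range.

## Known limitations

* The Karlin–Altschul constants are ungapped approximations applied to
  gapped scores; E-values are conventional, not calibrated.
* The greedy intruder-removal rule is an explicit stand-in for a
  human decision ("which rogue genomes to exclude") that published
  analyses typically make by inspection; it is deterministic and
  auditable but not guaranteed minimal in the number of removals.
* The exact membership of curated single-copy marker sets is not
  hard-coded; marker-subset AAI takes any marker map as input.
* Headline values from published genus revisions (specific boundary
  percentages, RED values against a reference taxonomy) depend on the
  underlying genome sets and reference trees; this package reproduces
  the procedures and validates them on synthetic data with known truth.
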