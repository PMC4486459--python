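# Methods

This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic studies do and do not establish.

## Distances

Distances are pairwise divergences under the Tamura–Nei (TN93) model with a
composite-likelihood twist: base frequencies are the pooled empirical
nucleotide frequencies over all sequences, and the two
transition/transversion rate ratios (κ₁ for purines, κ₂ for pyrimidines)
are estimated once by maximising the likelihood of the pooled pairwise
mismatch-count matrix, profiling out a common divergence. With the rates
fixed, each pair's divergence is the maximum-likelihood branch length for
its own 4×4 mismatch counts (safeguarded Newton iteration on the
log-likelihood derivative, transition probabilities from the
eigendecomposition of the reversible generator). On a two-sequence input
the pooled counts are the pair's counts, so the estimate coincides with the
per-pair TN93 ML distance — which is how the estimator is validated against
the closed-form TN93 formula.

Choices:

* **Gap handling** is pairwise deletion. Same-family full-length cDNAs have
  very uneven gap content only at their ends; complete deletion would
  discard those columns for every pair. Exposed as the encoding step, not a
  flag, because nothing downstream depends on the alternative.
* **Saturation** (likelihood still increasing at 15 substitutions/site) is
  flagged per pair (`d = NaN`, `saturated` mask) rather than capped; the
  tree builder then refuses the matrix naming the offending pair.
* **Standard errors** come from resampling alignment columns (default
  1,000 replicates), re-estimating the shared rates per replicate. Group
  means (within/between cluster) recompute the same cell set in every
  replicate matrix, so their SEs inherit the full estimator variability.

## Trees

Saitou–Nei neighbor joining with the lowest-index pair winning ties in the
Q criterion (determinism), negative branch lengths clamped to zero and
flagged (the convention of standard distance-matrix software). Bootstrap
supports are percentages of replicate NJ trees containing each bipartition;
supports are stored per *bipartition*, not per node, because rerooting
invalidates node-attached annotations. An alignment whose distances are all
zero yields an arbitrary topology; it is flagged degenerate and all
supports are set to zero.

Anchored clade extraction works on splits of the unrooted tree: a cluster
is the smallest split side that contains all of the cluster's anchor
sequences and has support at least `min_support` (default 70%). Working
with splits avoids any dependence on midpoint-rooting tie-breaks. The 70%
default maps the study's Bayesian-posterior clade thresholds onto bootstrap
support only heuristically; it is a parameter, not a claim.

Cluster cutting (used to delimit the deep G-Id/G-Ii and B-clade groups)
removes the k−1 longest internal edges; with clusters separated by long
stems this recovers exactly the planted groups in simulation.

## Locus calling

The biological constraint: a diploid individual can carry at most
`max_alleles = 2` alleles of one locus. The caller starts from the whole
(midpoint-rooted, polytomy-resolved) allele tree as a single candidate
locus and recursively splits every clade in which some individual exceeds
the constraint into its child clades. This yields the coarsest
tree-consistent partition compatible with diploidy: groups are only ever
split when violated, so merging two sibling groups produced by a split
reinstates a violation. A violating single leaf (more than two copies of
one unique sequence in an individual) cannot be split and marks the
partition invalid. Identical sequences shared by individuals occupy one
column (unique cDNAs), matching how cloned cDNA sets are reported.

Gene-content (CNV) inference is then read off the counts: a locus group
shows haplotypic variation when some individual carries no allele of it
while another does. With presence probability 0.7 per haplotype, the
default synthetic cohort plants such deletions in essentially every run,
and the caller recovers them exactly whenever the partition is exact.

## Codon site models

GY94 codon process over the 61 sense codons: single-nucleotide exchanges
with rate π_j · κ^[transition] · ω^[nonsynonymous], codon frequencies from
the F3X4 parameterisation estimated on the data (positional nucleotide
frequencies, stop codons excluded, floored at 1e-8 so every sense codon
stays reachable in short alignments). The mixture of ω classes is scaled
jointly so one unit of branch length is one expected substitution per codon
averaged over classes — the simulator uses the same convention, which is
what makes parameter-recovery round trips meaningful.

Models: M0 (single ω), M1a (ω₀ ≤ 1 plus ω = 1), M2a (M1a plus ω₂ ≥ 1),
M3 (three free classes), M8 (beta-distributed ω discretised into 10
equal-probability categories — category means computed analytically from
incomplete beta functions — plus a selection class ω_s ≥ 1).

Numerics:

* Felsenstein pruning on compressed site patterns with per-node rescaling
  (max-normalisation with accumulated logs), vectorised over patterns;
  transition matrices from the symmetrised eigendecomposition of the
  reversible generator. The engine is validated to 1e-8 against explicit
  summation over all ancestral codon states (an independent expm-based
  oracle) on small instances.
* Optimisation: L-BFGS-B on unconstrained transforms (log for κ/ω/scale,
  logistic for proportions and bounded ω, stick-breaking for multi-class
  proportions), two fixed deterministic starts per model, numerical
  gradients with step 1e-6.
* Branch lengths: the input (NJ) tree topology is kept; a single global
  length scale is estimated under M0 and fixed for the richer models. All
  models therefore share one branch-length set, which preserves the nesting
  inequalities exactly and keeps fits fast.
* A terminal stop codon column is dropped for all sequences; internal stops
  are an error naming sequence and codon. All-identical alignments are
  flagged degenerate: ω is unidentifiable and lnL is the multinomial
  constant Σ log π.

LRTs clamp 2ΔL at zero. Degrees of freedom are 2 for M1a/M2a and M1a/M8
and 4 for M0/M3 — the parameter-count difference — rather than a uniform 2;
for the two selection tests (the ones that gate site calling) this is the
same convention the study applied. Under M1a-simulated data the M1a/M2a
test is conservative (boundary mixture), which the type-I simulations
reproduce.

Site identification is **naive empirical Bayes**: posterior class
memberships at the MLEs, P(ω > 1) summed over selection classes. Full
Bayes-empirical-Bayes integration over parameter uncertainty is not
implemented; the consensus rule (P > 0.9 in at least two of M2a/M3/M8)
absorbs much of the difference, and the site-recovery simulations quantify
the operating characteristics this package actually has: at 12 taxa and
500 codons with 10% of sites at ω = 4, sensitivity is moderate (above
one-half) and the false-positive rate stays below the 0.9-posterior
nominal level. NEB posteriors are known to be overconfident on small trees;
calls on fewer than ~6 sequences should not be trusted.

## PBR tables

Translation maps codon i of the alignment to mature position i − offset;
the leader offset defaults to 24 residues (the canonical class I leader).
The shipped peptide-contact map (35 α1/α2 positions with their 1–9 peptide
contacts) and KIR D1/D2 contact set (14 positions; critical subset 80, 83,
142, 146, 149) are data files, versioned with the package and editable;
rows are marked by provenance, with positions not recoverable from the
study text completed from the canonical class I groove-contact assignments.
Variability is tabulated per lineage as residue sets (gaps and ambiguous
codons excluded); positions outside the alignment are listed as uncovered,
never silently dropped.

## MHC:KIR scoring

Hydrogen bonds: donor and acceptor heavy atoms on opposite chain roles,
distance ≤ 3.5 Å; if explicit hydrogens are present the D–H…A angle must
reach 120°, otherwise an antecedent–donor–acceptor proxy angle ≥ 90° is
required (an isolated donor with no bonded neighbour passes on distance
alone). Donor/acceptor roles follow the standard residue chemistry, with an
element-based fallback for nonstandard residues.

Desolvation: cross-interface heavy-atom pairs within 6 Å scored by a
symmetric 18-class atomic contact table. The shipped table is constructed
from per-class transfer energies (e_ij = (g_i + g_j)/2; apolar
carbon/sulfur favourable, charged nitrogen/oxygen costly) and is labelled
synthetic in its header: it follows the structure of published
atomic-contact-energy potentials without reproducing any particular one.
Both the typing rules and the energies are TSV inputs and can be swapped.

The index I = k·h / ln|dG| is evaluated on the magnitude of dG;
|dG| ≤ 1 + 1e-6 makes the logarithm non-positive and the score
indeterminate (never an infinity). k — "the average energy of an H-bond" —
has no principled single value; the default 5 kcal/mol is a mid-range
literature figure, and since k rescales I linearly it cannot change any
calibrated classification. Threshold calibration minimises total
misclassification over midpoints of the observed scores, resolving ties to
the midpoint of the class means; on overlapping equal-variance Gaussian
score distributions the achieved error matches the closed-form Bayes error
to within sampling noise.

The published cross-species validation of the index (mean I of 5,250 for 45
interacting vs 1,376 for 71 non-interacting pairs, 15% combined error, and
the worked-example values 26,615 and 2,975) depends on 116 externally built
homology models and experimental interaction labels; those inputs are out
of this package's scope (homology modelling is an input boundary), so the
index is validated here by its synthetic contracts instead: exact
planted-bond recovery, desolvation additivity, rigid-motion invariance, and
calibration behaviour.

## Synthetic generators: what they do and do not emulate

* The codon simulator draws sites i.i.d. from the configured ω mixture and
  evolves them by exact transition probabilities on the given tree. No
  recombination, no indels, no rate variation beyond the ω classes — so
  recovery results certify the inference machinery, not robustness to
  misspecification.
* The population simulator plants loci on a star topology (one founder per
  locus from a common ancestor, alleles radiating from each founder) with
  hard separation between divergence scales (default 10% between loci, 2%
  within). Real loci can exchange sequence (gene conversion) and violate
  this separability; the caller's perfect recovery rate is an upper bound
  tied to these conditions. Defaults mirror the study design: 12
  individuals, four loci, 1,041-nt coding sequences, presence probability
  0.7 per haplotype.
* Toy complexes plant idealised near-linear 2.9 Å bonds among carbon decoys
  and far-field polar atoms; they exercise the detector's geometry exactly
  but say nothing about hydrogen placement or side-chain flexibility in
  real structures.

## Problem sizes

The shipped studies use 500-codon alignments on 6-taxon trees (20 seeds)
for parameter recovery and LRT operating characteristics, one 12-taxon
scan for site recovery, 50 simulated populations for the locus caller, and
200-atom toy complexes — sizes at which each quantity is stable to the
reported precision while the whole suite stays interactive on one core.

## Known limitations

* NEB (not BEB) site posteriors; see above.
* The composite-likelihood distance shares rates through the pooled counts
  rather than a full joint maximisation over all pairs; the two differ
  negligibly at the divergences involved here (validated against the
  closed-form TN93 on single pairs).
* Bootstrap supports are a heuristic stand-in for the Bayesian posteriors
  used in the study's original trees; cluster delimitation is robust to
  this for deep, long-stemmed splits only.
* The contact-energy table is a constructed surrogate with the documented
  structure; absolute dG values are not comparable to published FastContact
  outputs, and hence neither are absolute I values — classification after
  calibration is the supported use.
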