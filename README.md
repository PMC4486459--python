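# divkit

Analysis toolkit for the diversification of multigene MHC class I families
in New World monkeys (Platyrrhini), built around the 12-individual capuchin
monkey (*Cebus albifrons*) study design: cloned full-length class I cDNAs
from a small population, with the goals of (i) quantifying sequence
diversity, (ii) deciding how many transcribed loci the cDNAs represent and
whether haplotypes vary in gene content, (iii) detecting positive selection
at the peptide-binding region (PBR), and (iv) ranking candidate MHC:KIR
receptor pairings from structural models.

## What it computes

**Distances.** Pairwise distances under a Tamura–Nei composite-likelihood
scheme: the transition/transversion rate ratios (purine κ₁, pyrimidine κ₂)
and base frequencies are shared across all pairs — estimated once from the
pooled pairwise mismatch counts — and a per-pair divergence *d* is then
profiled by maximum likelihood. Standard errors come from a site-resampling
bootstrap (default 1,000 replicates). Gaps are handled by pairwise deletion.

**Trees and clusters.** Saitou–Nei neighbor joining with a deterministic
tie rule, bipartition supports from bootstrap replicates, anchored clade
extraction (smallest well-supported split containing a set of reference
sequences), and cluster cutting at the deepest splits.

**Locus calling.** A diploid individual carries at most two alleles of one
locus, so any clade in which an individual has three or more sequences
cannot be a single locus. The caller finds the coarsest tree-consistent
partition satisfying the constraint by top-down clade splitting, and flags
haplotype gene-content variation (an individual with zero alleles of a
locus group others carry).

**Selection.** Codon site models over a GY94 process with F3X4 frequencies:
M0 (one ω), M1a (nearly neutral), M2a (+ selection class), M3 (discrete,
3 classes), and M8 (beta + selection class, 10 equal-probability beta
categories), fitted by maximum likelihood with Felsenstein pruning.
Likelihood-ratio tests compare 2ΔL against χ² (df = 2 for M1a/M2a and
M1a/M8, df = 4 for M0/M3). A codon is called positively selected when its
empirical-Bayes posterior P(ω > 1) exceeds 0.9 in at least two of the three
selection-capable models.

**PBR variability.** Translation into mature class I numbering (default
24-residue leader offset) and per-position amino-acid tabulation over a
shipped 35-position peptide-contact map and 14-position KIR D1/D2 contact
set (critical positions 80, 83, 142, 146, 149).

**MHC:KIR interaction index.** For a two-chain complex: interface hydrogen
bonds *h* (donor–acceptor heavy atoms ≤ 3.5 Å across the interface, with a
D–H…A angle ≥ 120° when hydrogens are present), a desolvation energy *dG*
summed from an 18-class atomic contact potential over cross-interface heavy
atoms within 6 Å, and the index

    I = k·h / ln|dG|

with *k* the average energy of one hydrogen bond (default 5 kcal/mol).
A threshold calibrated on labelled pairs converts *I* into
interacting/non-interacting calls with false-positive and false-negative
rates.

Every stage has a synthetic generator with known ground truth (codon
alignments under planted ω classes, diploid populations with planted locus
structure and deletions, toy complexes with planted hydrogen bonds), so the
whole chain is testable without any downloads.

## Worked example

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_distances_tree_loci.py
```

prints (seed 1):

```
cohort: 22 unique alleles over 12 individuals, 4 loci; 7 individual x locus deletions planted
mean pairwise distance 21.3% (mean bootstrap SE 1.58%)
locus caller: 4 groups (true: 4), valid=True, pure=True, haplotypic_variation=True
  within-G1: 3.8% +- 0.33%
  ...
  G1 vs G2: 26.9% +- 1.68%
```

— the caller recovers the four planted loci exactly (`pure=True`: every
recovered group contains alleles of a single true locus), each group obeys
the ≤ 2 alleles/individual constraint (`valid`), the planted gene-content
variation is flagged, and within-group diversity (~4%) sits far below
between-group divergence (~25%), the separation the partition rests on.
`analysis/03_selection_scan.py` then fits the site models on a 12-taxon
alignment with ~10% of codons planted at ω = 4:

```
LRT M1a vs M2a: 2dL=176.96 df=2 p=3.74e-39
consensus calls: 37 sites; sensitivity 69% (34/49 planted), false-positive rate 0.7%
```

and `analysis/04_kir_interface.py` scores the toy complex — detecting
exactly the 12 planted interface H-bonds — and calibrates the index
threshold on synthetic labelled pairs (0% error on separated classes).

The same steps run from the command line: `divkit simulate|distance|tree|
clades|loci|selection|kir-score|kir-calibrate|run` (see `divkit --help`),
and `divkit run --config pipeline.yaml` executes the full chain with
config-hash caching.

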