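#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Simulates (i) a 12-individual diploid cohort transcribing four polymorphic
MHC-like loci whose haplotypes vary in gene content, (ii) a codon alignment
evolved under a mixture of omega classes with a planted positive-selection
class, and (iii) a toy two-chain complex with planted interface hydrogen
bonds. Writes everything under results/synthetic/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from divkit import (
    CodonSimConfig,
    PopulationSimConfig,
    ToyComplexConfig,
    generate_toy_complex,
    simulate_codon_alignment,
    simulate_population_alleles,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
TWELVE_TAXON = (
    "(((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1):0.1,((e:0.2,f:0.2):0.1,"
    "(g:0.2,h:0.2):0.1):0.1,((i:0.2,j:0.2):0.1,(k:0.2,l:0.2):0.1):0.1);"
)


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    pop = simulate_population_alleles(PopulationSimConfig(seed=SEED))
    pop.alleles.to_fasta(OUT / "cohort_alleles.fasta")
    pop.genotype.astype(int).to_csv(OUT / "cohort_genotypes.tsv", sep="\t")
    pd.Series(pop.locus_of).to_csv(OUT / "cohort_true_loci.tsv", sep="\t", header=["locus"])
    pop.copy_number.to_csv(OUT / "cohort_true_copy_number.tsv", sep="\t")
    print(
        f"cohort: {len(pop.alleles)} unique alleles over "
        f"{pop.genotype.shape[0]} individuals, {pop.copy_number.shape[1]} loci; "
        f"{int((pop.copy_number == 0).sum().sum())} individual x locus deletions planted"
    )

    cfg = CodonSimConfig(
        tree_newick=TWELVE_TAXON, kappa=2.0,
        site_classes=[(0.5, 0.2), (0.4, 1.0), (0.1, 4.0)], n_codons=500, seed=SEED,
    )
    aln, labels = simulate_codon_alignment(cfg)
    aln.to_fasta(OUT / "selection_alignment.fasta")
    np.savetxt(OUT / "selection_true_classes.tsv", labels, fmt="%d")
    (OUT / "selection_tree.nwk").write_text(TWELVE_TAXON + "\n")
    print(
        f"selection alignment: {len(aln)} taxa x {cfg.n_codons} codons, "
        f"{int((labels == 2).sum())} sites planted under omega=4"
    )

    s, manifest = generate_toy_complex(ToyComplexConfig(n_planted_hbonds=12, n_decoy_atoms=200, seed=SEED))
    s.to_pdb(OUT / "toy_complex.pdb")
    pd.DataFrame(manifest, columns=["donor_atom", "acceptor_atom"]).to_csv(
        OUT / "toy_planted_bonds.tsv", sep="\t", index=False
    )
    print(f"toy complex: {len(s.atoms)} atoms, {len(manifest)} planted interface H-bonds")


if __name__ == "__main__":
    main()
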