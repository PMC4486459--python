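import dendropy
import numpy as np
import pytest

from divkit import (
    AlignedSequenceSet,
    CodonSimConfig,
    PopulationSimConfig,
    SequenceRecord,
    ToyComplexConfig,
    generate_toy_complex,
    simulate_codon_alignment,
    simulate_population_alleles,
)

SIX_TAXON_TREE = "((a:0.3,b:0.3):0.15,(c:0.3,d:0.3):0.15,(e:0.3,f:0.3):0.15);"


@pytest.fixture(scope="session")
def six_taxon_tree() -> str:
    return SIX_TAXON_TREE


@pytest.fixture(scope="session")
def neutral_alignment():
    """Long neutral simulation on the six-taxon tree."""
    cfg = CodonSimConfig(
        tree_newick=SIX_TAXON_TREE, kappa=2.0, site_classes=[(1.0, 1.0)], n_codons=2000, seed=42
    )
    return simulate_codon_alignment(cfg)


@pytest.fixture(scope="session")
def population_sample():
    return simulate_population_alleles(PopulationSimConfig(seed=11))


@pytest.fixture(scope="session")
def toy_complex():
    return generate_toy_complex(ToyComplexConfig(n_planted_hbonds=12, n_decoy_atoms=200, seed=4))


@pytest.fixture
def tiny_alignment():
    """Three diverged 12-nt sequences (hand-written, gap-free)."""
    return AlignedSequenceSet(
        [
            SequenceRecord("s1", "ATGAAACCCGGG"),
            SequenceRecord("s2", "ATGAAGCCCGGG"),
            SequenceRecord("s3", "ATGAAACCTGGA"),
        ]
    )


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def brute_force_mixture_loglik(aln, tree, kappa, site_classes, scale, pi):
    """Independent likelihood oracle: explicit summation over all ancestral
    codon-state assignments, with transition matrices from scipy expm."""
    from scipy.linalg import expm

    from divkit.codon import CODON_INDEX, N_CODONS, CodonProcess, gy94_rate_matrix

    proc = CodonProcess(kappa, pi, site_classes)  # only for the rate scale
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = tree.leaf_nodes()
    n_codons = aln.length // 3
    codes = {
        r.name: [CODON_INDEX[r.sequence[3 * i : 3 * i + 3]] for i in range(n_codons)]
        for r in aln.records
    }
    total = 0.0
    for site in range(n_codons):
        site_like = 0.0
        for prop, omega in site_classes:
            Q, _ = gy94_rate_matrix(kappa, omega, pi)
            Q = Q / proc.scale
            P = {
                id(n): expm(Q * ((n.edge.length or 0.0) * scale))
                for n in tree.preorder_node_iter()
                if n.parent_node is not None
            }
            class_like = 0.0
            for assignment in np.ndindex(*([N_CODONS] * len(internals))):
                states = {id(n): s for n, s in zip(internals, assignment)}
                term = pi[states[id(tree.seed_node)]]
                for n in tree.preorder_node_iter():
                    if n.parent_node is None:
                        continue
                    s = codes[n.taxon.label][site] if n.is_leaf() else states[id(n)]
                    term *= P[id(n)][states[id(n.parent_node)], s]
                    if term == 0.0:
                        break
                class_like += term
            site_like += prop * class_like
        total += np.log(site_like)
    return total
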