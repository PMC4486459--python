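"""Synthetic-data generators with known ground truth.

Three generators feed the pipeline's three input classes:

* codon alignments evolved under a GY94 mixture of omega site classes on a
  given tree (oracle for the site-model fitter);
* diploid populations transcribing several polymorphic loci whose haplotypes
  vary in gene content (oracle for the locus caller and CNV detector);
* toy two-chain atomic structures with planted hydrogen bonds among decoy
  atoms (oracle for the interface scorer).

All three are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import AlignedSequenceSet, SequenceRecord
from .codon import N_CODONS, NUCS, SENSE_CODONS, STOP_CODONS, CodonProcess
from .structure import Atom, ComplexStructure

# ---------------------------------------------------------------- codon sim


@dataclass
class CodonSimConfig:
    tree_newick: str
    kappa: float = 2.0
    site_classes: list[tuple[float, float]] = field(default_factory=lambda: [(1.0, 1.0)])
    codon_freqs: np.ndarray | None = None  # 61-vector; uniform if None
    n_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not self.site_classes:
            raise ValueError("site_classes must be non-empty")
        props = np.array([p for p, _ in self.site_classes], dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("site-class proportions must sum to 1")
        if any(w < 0 for _, w in self.site_classes):
            raise ValueError("omega values must be >= 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.codon_freqs is None:
            self.codon_freqs = np.full(N_CODONS, 1.0 / N_CODONS)
        else:
            self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
            if self.codon_freqs.shape != (N_CODONS,):
                raise ValueError(f"codon_freqs must have length {N_CODONS}")
            if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
                raise ValueError("codon_freqs must sum to 1")


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree


def _sample_rows(P: np.ndarray, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical draw per row of P[states]."""
    cum = np.cumsum(P[states], axis=1)
    u = rng.random((len(states), 1)) * cum[:, -1:]
    return (cum < u).sum(axis=1)


def simulate_codon_alignment(config: CodonSimConfig):
    """Evolve a codon alignment down ``config.tree_newick``.

    Returns ``(alignment, site_class_labels)`` where labels give the true
    omega-class index of each codon column.
    """
    tree = _parse_tree(config.tree_newick)
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 taxa")
    total = sum(e.length or 0.0 for e in tree.edges())
    if total <= 0:
        raise ValueError("tree has zero total branch length")

    rng = np.random.default_rng(config.seed)
    process = CodonProcess(config.kappa, config.codon_freqs, config.site_classes)
    labels = rng.choice(process.n_classes, size=config.n_codons, p=process.proportions)

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(N_CODONS, size=config.n_codons, p=process.pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = states[id(node.parent_node)]
        child = np.empty(config.n_codons, dtype=np.intp)
        for k in range(process.n_classes):
            mask = labels == k
            if not mask.any():
                continue
            P = process.transition_matrix(t, k)
            child[mask] = _sample_rows(P, parent_states[mask], rng)
        states[id(node)] = child

    records = []
    for leaf in sorted(leaves, key=lambda n: n.taxon.label):
        seq = "".join(SENSE_CODONS[s] for s in states[id(leaf)])
        records.append(SequenceRecord(leaf.taxon.label, seq))
    return AlignedSequenceSet(records), labels


# ----------------------------------------------------------- population sim


@dataclass
class LocusSpec:
    name: str
    allele_pool_size: int
    presence_probability: float = 1.0

    def __post_init__(self):
        if self.allele_pool_size < 1:
            raise ValueError("allele_pool_size must be >= 1")
        if not 0.0 <= self.presence_probability <= 1.0:
            raise ValueError("presence_probability must be in [0,1]")


@dataclass
class PopulationSimConfig:
    """A diploid population transcribing several MHC-like loci.

    Defaults mirror a 12-individual cohort with four separable loci whose
    haplotypes may lack a locus (gene-content variation), full-length
    1,041-nt coding sequences, loci ~10% diverged and alleles ~2% apart
    within a locus.
    """

    n_individuals: int = 12
    loci: list[LocusSpec] = field(
        default_factory=lambda: [LocusSpec(f"L{i + 1}", 6, 0.7) for i in range(4)]
    )
    divergence_between_loci: float = 0.10
    polymorphism_within_locus: float = 0.02
    seq_length: int = 1041
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not self.loci:
            raise ValueError("need at least one locus")
        if self.divergence_between_loci <= self.polymorphism_within_locus:
            raise ValueError("loci must be more diverged than alleles within a locus")
        if self.seq_length % 3:
            raise ValueError("seq_length must be a multiple of 3")


@dataclass
class PopulationSample:
    alleles: AlignedSequenceSet  # unique allele sequences actually observed
    genotype: "pandas.DataFrame"  # individuals x alleles, bool presence
    locus_of: dict[str, str]  # allele name -> true locus
    copy_number: "pandas.DataFrame"  # individuals x loci, gene copies (0/1/2)


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.choice(N_CODONS, size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def _mutate_coding(codons: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Substitute nucleotides at an expected per-site ``rate``, never creating
    an in-frame stop codon."""
    out = list(codons)
    L = 3 * len(out)
    n_sub = rng.binomial(L, min(rate, 1.0))
    positions = rng.choice(L, size=n_sub, replace=False) if n_sub else []
    for pos in positions:
        ci, p = divmod(int(pos), 3)
        codon = out[ci]
        choices = [n for n in NUCS if n != codon[p]]
        rng.shuffle(choices)
        for n in choices:
            cand = codon[:p] + n + codon[p + 1 :]
            if cand not in STOP_CODONS:
                out[ci] = cand
                break
    return out


def simulate_population_alleles(config: PopulationSimConfig) -> PopulationSample:
    """Star-tree population: one ancestral coding sequence, one founder per
    locus at ``divergence_between_loci``, alleles radiating from each founder
    at ``polymorphism_within_locus``. Each diploid individual draws, per
    locus, up to two allele copies (each haplotype carries the locus with its
    ``presence_probability``)."""
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    n_codons = config.seq_length // 3
    ancestor = _random_coding_sequence(n_codons, rng)

    pools: dict[str, list[str]] = {}
    locus_of: dict[str, str] = {}
    for locus in config.loci:
        founder = _mutate_coding(ancestor, config.divergence_between_loci, rng)
        names = []
        for a in range(locus.allele_pool_size):
            allele = _mutate_coding(founder, config.polymorphism_within_locus, rng)
            name = f"{locus.name}*{a + 1:02d}"
            pools.setdefault(locus.name, []).append("".join(allele))
            locus_of[name] = locus.name
            names.append(name)

    individuals = [f"Ind{i + 1:02d}" for i in range(config.n_individuals)]
    locus_names = [l.name for l in config.loci]
    copy_number = pd.DataFrame(0, index=individuals, columns=locus_names, dtype=int)
    carried: dict[str, set[str]] = {ind: set() for ind in individuals}
    for ind in individuals:
        while True:
            carried[ind].clear()
            for locus in config.loci:
                copies = int(rng.random() < locus.presence_probability) + int(
                    rng.random() < locus.presence_probability
                )
                copy_number.loc[ind, locus.name] = copies
                for _ in range(copies):
                    a = int(rng.integers(locus.allele_pool_size))
                    carried[ind].add(f"{locus.name}*{a + 1:02d}")
            if carried[ind]:
                break  # an individual with no MHC sequence at all is unobservable

    observed = sorted({a for s in carried.values() for a in s})
    genotype = pd.DataFrame(
        [[a in carried[ind] for a in observed] for ind in individuals],
        index=individuals,
        columns=observed,
    )
    records = [
        SequenceRecord(name, pools[locus_of[name]][int(name.split("*")[1]) - 1]) for name in observed
    ]
    return PopulationSample(
        alleles=AlignedSequenceSet(records),
        genotype=genotype,
        locus_of={a: locus_of[a] for a in observed},
        copy_number=copy_number,
    )


# ------------------------------------------------------------- toy complex


@dataclass
class ToyComplexConfig:
    n_planted_hbonds: int = 12
    n_decoy_atoms: int = 200
    chain_separation: float = 8.0  # Angstrom between decoy slabs and the interface
    jitter: float = 0.05  # Angstrom of uniform positional noise
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_hbonds < 0:
            raise ValueError("n_planted_hbonds must be >= 0")
        if self.n_decoy_atoms < 0:
            raise ValueError("n_decoy_atoms must be >= 0")
        # planted donor-acceptor distance is 2.9 A; both endpoints may move by
        # sqrt(3)*jitter, and the detector cuts at 3.5 A — keep a margin
        if 2.9 + 2 * np.sqrt(3.0) * self.jitter > 3.4:
            raise ValueError("jitter too large to guarantee planted bonds survive")


def generate_toy_complex(config: ToyComplexConfig) -> tuple[ComplexStructure, list[tuple[int, int]]]:
    """Two-chain toy structure: chain A ("MHC") holds backbone-amide donors,
    chain B ("KIR") the matching carbonyl acceptors 2.9 A away; decoy carbons
    (plus far-field N/O) pad both chains. Returns the structure and the
    manifest of (donor_atom_index, acceptor_atom_index) planted pairs."""
    rng = np.random.default_rng(config.seed)
    jit = lambda: rng.uniform(-config.jitter, config.jitter, size=3)

    atoms: list[Atom] = []
    manifest: list[tuple[int, int]] = []
    for i in range(config.n_planted_hbonds):
        x = 6.0 * i
        ca = np.array([x, -1.5, 0.0]) + jit()
        n = np.array([x, 0.0, 0.0]) + jit()
        h = n + np.array([0.0, 1.0, 0.0])
        o = np.array([x, 2.9, 0.0]) + jit()
        c = np.array([x, 3.9, 1.1]) + jit()
        atoms.append(Atom("A", "GLY", i + 1, "CA", "C", tuple(ca)))
        donor_idx = len(atoms)
        atoms.append(Atom("A", "GLY", i + 1, "N", "N", tuple(n)))
        atoms.append(Atom("A", "GLY", i + 1, "H", "H", tuple(h)))
        acceptor_idx = len(atoms)
        atoms.append(Atom("B", "GLY", i + 1, "O", "O", tuple(o)))
        atoms.append(Atom("B", "GLY", i + 1, "C", "C", tuple(c)))
        manifest.append((donor_idx, acceptor_idx))

    width = max(6.0 * config.n_planted_hbonds, 30.0)
    for j in range(config.n_decoy_atoms):
        chain = "A" if j % 2 == 0 else "B"
        y = rng.uniform(-4.0 - config.chain_separation, -4.0) if chain == "A" else rng.uniform(
            6.9, 6.9 + config.chain_separation
        )
        pos = (rng.uniform(-5.0, width), y, rng.uniform(-10.0, 10.0))
        if j % 7 == 3:  # sprinkle polar atoms well away from the interface
            elem, name = ("O", "OD1") if j % 2 else ("N", "NZ")
            resname = "ASP" if elem == "O" else "LYS"
        else:
            elem, name, resname = "C", "CB", "ALA"
        atoms.append(Atom(chain, resname, 1000 + j, name, elem, pos))

    return ComplexStructure(atoms, {"A": "MHC", "B": "KIR"}), manifest
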