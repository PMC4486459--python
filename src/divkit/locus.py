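"""Allele-to-locus assignment and haplotype gene-content (CNV) inference.

A diploid individual can carry at most two alleles of one locus, so any
clade of the allele tree in which some individual has three or more
sequences cannot be a single locus. The caller finds the coarsest
tree-consistent partition satisfying the constraint by top-down splitting:
start with the whole tree as one candidate locus and split every violating
clade into its child clades until all groups are compatible with diploidy.
Gene-content variation across haplotypes is then read off the per-individual
counts: a locus some individuals lack entirely while others carry it.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd


def validate_genotype_matrix(gm: pd.DataFrame) -> None:
    if gm.shape[0] == 0 or gm.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    if not gm.any(axis=0).all():
        missing = list(gm.columns[~gm.any(axis=0)])
        raise ValueError(f"sequences present in no individual: {missing}")
    if not gm.any(axis=1).all():
        missing = list(gm.index[~gm.any(axis=1)])
        raise ValueError(f"individuals with no sequence: {missing}")


@dataclass
class LocusPartition:
    groups: dict[str, set[str]]  # group label -> sequence names
    per_individual_counts: pd.DataFrame  # individuals x groups
    valid: bool
    multiple_optima: bool = False


@dataclass
class CnvReport:
    carries_locus: pd.DataFrame  # individuals x groups, bool
    haplotypic_variation: bool


def _rooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    work = tree.clone(depth=1)
    if not work.is_rooted:
        work.is_rooted = True
        work.reroot_at_midpoint(update_bipartitions=False)
    # a multifurcation (e.g. the suppressed root of an unrooted tree) would
    # force an all-children split; zero-length resolution keeps splits binary
    work.resolve_polytomies()
    return work


def assign_loci(tree: dendropy.Tree, gm: pd.DataFrame, max_alleles: int = 2) -> LocusPartition:
    """Coarsest clade partition of the genotype columns in which no
    individual exceeds ``max_alleles`` sequences per group.

    The tree may contain extra leaves (references/anchors); they are ignored.
    ``valid`` is False when even single-sequence granularity violates the
    constraint, which can only happen through duplicate columns collapsed
    upstream. A clade tie (several equally coarse valid refinements) cannot
    arise in this top-down scheme, but a violating multifurcation deeper than
    binary is split into all children at once and flags ``multiple_optima``.
    """
    validate_genotype_matrix(gm)
    cols = set(gm.columns)
    work = _rooted_copy(tree)
    leaf_labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    missing = cols - leaf_labels
    if missing:
        raise ValueError(f"genotype columns absent from tree: {sorted(missing)}")

    def clade_cols(node):
        return [lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in cols]

    groups: list[list[str]] = []
    valid = True
    multiple_optima = False
    stack = [work.seed_node]
    while stack:
        node = stack.pop()
        members = clade_cols(node)
        if not members:
            continue
        counts = gm[members].sum(axis=1)
        if counts.max() <= max_alleles:
            groups.append(members)
            continue
        if node.is_leaf():
            # a single unique sequence cannot be split further
            groups.append(members)
            valid = False
            continue
        children = node.child_nodes()
        if len(children) > 2:
            multiple_optima = True
        stack.extend(reversed(children))

    # stable order: by first appearance in the tree's leaf order
    order = [lf.taxon.label for lf in work.leaf_node_iter() if lf.taxon.label in cols]
    groups.sort(key=lambda g: min(order.index(m) for m in g))
    named = {f"G{i + 1}": set(g) for i, g in enumerate(groups)}
    counts = pd.DataFrame(
        {label: gm[sorted(members)].sum(axis=1) for label, members in named.items()},
        index=gm.index,
    )
    return LocusPartition(named, counts, valid, multiple_optima)


def detect_cnv(part: LocusPartition, gm: pd.DataFrame) -> CnvReport:
    """Gene-content variation: a group is variable in copy number when some
    individual carries no allele of it while another carries at least one."""
    if not part.valid:
        raise ValueError("cannot interpret an invalid partition as loci")
    carries = part.per_individual_counts > 0
    variation = bool(((~carries).any(axis=0) & carries.any(axis=0)).any())
    return CnvReport(carries_locus=carries, haplotypic_variation=variation)
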