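"""Translation to mature MHC class I numbering and peptide-binding-region
variability tables.

Full-length class I cDNAs encode a leader peptide before the mature chain;
"position 62" in the structural literature is position 62 of the mature
protein, so translated alignments are renumbered with a configurable leader
offset (default 24 residues, the canonical class I leader length). The
variability tabulator then asks, for each groove position of the shipped
contact map: which amino acids does each lineage carry there, is the
position variable, is it under positive selection, and which residues are
shared between lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio.Seq import Seq

DEFAULT_LEADER_OFFSET = 24


@dataclass
class ProteinAlignment:
    """Aligned amino-acid sequences with a mature-numbering offset:
    mature position m sits at codon column m + offset (1-based)."""

    sequences: dict[str, str]
    offset: int = DEFAULT_LEADER_OFFSET

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def residues_at(self, mature_pos: int) -> dict[str, str]:
        col = mature_pos + self.offset - 1
        if col < 0 or col >= self.length:
            raise IndexError(f"mature position {mature_pos} outside alignment")
        return {name: seq[col] for name, seq in self.sequences.items()}

    def covers(self, mature_pos: int) -> bool:
        col = mature_pos + self.offset - 1
        return 0 <= col < self.length


def translate_and_number(aln, numbering_offset: int = DEFAULT_LEADER_OFFSET) -> ProteinAlignment:
    """Translate a codon-aligned nucleotide set; stops may only be terminal.

    Gap codons ('---') become '-'; codons containing N or a partial gap
    become 'X'. Internal stops raise with the offending sequence/position
    (the frame-sanity check that catches reverse-complemented input).
    """
    if aln.length % 3:
        raise ValueError(f"alignment length {aln.length} is not divisible by 3")
    n_codons = aln.length // 3
    out = {}
    for rec in aln.records:
        aas = []
        for c in range(n_codons):
            codon = rec.sequence[3 * c : 3 * c + 3]
            if codon == "---":
                aas.append("-")
            elif set(codon) <= set("ACGT"):
                aa = str(Seq(codon).translate())
                if aa == "*":
                    if c < n_codons - 1:
                        raise ValueError(f"internal stop codon in {rec.name} at codon {c + 1}")
                    continue  # terminal stop: end of precursor
                aas.append(aa)
            else:
                aas.append("X")
        out[rec.name] = "".join(aas)
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:  # only a terminal-stop column may shorten a row
        target = min(lengths)
        out = {k: v[:target] for k, v in out.items()}
    return ProteinAlignment(out, offset=numbering_offset)


@dataclass
class ContactMap:
    peptide_contacts: dict[int, frozenset[int]]  # MHC pos -> peptide positions (1-9)
    source: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for pos, peps in self.peptide_contacts.items():
            if not 1 <= pos <= 182:
                raise ValueError(f"MHC position {pos} outside the alpha1/alpha2 range")
            if not peps <= frozenset(range(1, 10)):
                raise ValueError(f"peptide positions for {pos} outside 1..9")

    @property
    def positions(self) -> list[int]:
        return sorted(self.peptide_contacts)

    @classmethod
    def load(cls, path=None) -> "ContactMap":
        df = _read_data_tsv(path, "peptide_contacts.tsv")
        contacts = {
            int(r.mhc_pos): frozenset(int(p) for p in str(r.peptide_positions).split(","))
            for r in df.itertuples()
        }
        return cls(contacts, {int(r.mhc_pos): r.source for r in df.itertuples()})


@dataclass
class KirContactSet:
    positions: frozenset[int]
    critical: frozenset[int]

    def __post_init__(self):
        if not self.critical <= self.positions:
            raise ValueError("critical positions must be a subset of the contact set")

    @classmethod
    def load(cls, path=None) -> "KirContactSet":
        df = _read_data_tsv(path, "kir_contacts.tsv")
        return cls(
            frozenset(int(r.mhc_pos) for r in df.itertuples()),
            frozenset(int(r.mhc_pos) for r in df.itertuples() if int(r.critical) == 1),
        )


def _read_data_tsv(path, default_name):
    if path is None:
        path = resources.files("divkit.data") / default_name
    return pd.read_csv(path, sep="\t", comment="#")


def tabulate_variability(
    proteins: ProteinAlignment,
    lineages: dict[str, str],
    cmap: ContactMap,
    selected=None,
    kir: KirContactSet | None = None,
) -> pd.DataFrame:
    """Per-position variability table over the contact-map positions.

    One row per MHC position with: residue set per lineage (gaps/X excluded),
    overall ``variable`` flag (>= 2 distinct residues), ``selected`` flag from
    a consensus site set (codon positions mapped through the leader offset),
    KIR-contact flags, and ``covered`` False for positions outside the
    alignment (listed, never dropped).
    """
    missing = set(proteins.sequences) - set(lineages)
    if missing:
        raise ValueError(f"sequences without a lineage label: {sorted(missing)}")
    lineage_names = sorted(set(lineages.values()))
    selected_mature = set()
    if selected is not None:
        selected_mature = {p - proteins.offset for p in selected.positions}

    rows = []
    for pos in cmap.positions:
        row: dict = {
            "mhc_pos": pos,
            "peptide_positions": ",".join(map(str, sorted(cmap.peptide_contacts[pos]))),
            "covered": proteins.covers(pos),
            "kir_contact": kir is not None and pos in kir.positions,
            "kir_critical": kir is not None and pos in kir.critical,
            "selected": pos in selected_mature,
        }
        residues: dict[str, set[str]] = {l: set() for l in lineage_names}
        if row["covered"]:
            for name, aa in proteins.residues_at(pos).items():
                if aa not in ("-", "X"):
                    residues[lineages[name]].add(aa)
        all_res = set().union(*residues.values()) if residues else set()
        row["variable"] = len(all_res) >= 2
        row["n_residues"] = len(all_res)
        for l in lineage_names:
            row[f"residues_{l}"] = frozenset(residues[l])
        rows.append(row)
    return pd.DataFrame(rows).set_index("mhc_pos")


def shared_residue_counts(table: pd.DataFrame, pair: tuple[str, str]) -> int:
    """Number of variable contact positions at which the two lineages share
    at least one amino acid."""
    cols = [f"residues_{l}" for l in pair]
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"unknown lineage {c.removeprefix('residues_')!r}")
    count = 0
    for _, row in table.iterrows():
        if not row["variable"]:
            continue
        a, b = row[cols[0]], row[cols[1]]
        if pair[0] == pair[1]:
            if a:
                count += 1
        elif a & b:
            count += 1
    return count
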