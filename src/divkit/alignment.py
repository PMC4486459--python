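"""Aligned sequence sets with per-individual and per-lineage tags."""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGT-N")


@dataclass
class SequenceRecord:
    name: str
    sequence: str
    individual_id: str | None = None
    lineage: str | None = None


@dataclass
class AlignedSequenceSet:
    """A nucleotide alignment: equal-length sequences over {A,C,G,T,-,N},
    unique names, optional individual/lineage tags per record."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("sequence names must be unique")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        for r in self.records:
            bad = set(r.sequence.upper()) - ALPHABET
            if bad:
                raise ValueError(f"{r.name}: illegal characters {sorted(bad)}")
            r.sequence = r.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> SequenceRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def subset(self, names) -> "AlignedSequenceSet":
        wanted = set(names)
        return AlignedSequenceSet([r for r in self.records if r.name in wanted])

    def columns(self, indices) -> "AlignedSequenceSet":
        """A new alignment keeping the given column indices, in order
        (the site-resampling primitive behind every bootstrap here)."""
        return AlignedSequenceSet(
            [
                SequenceRecord(r.name, "".join(r.sequence[i] for i in indices), r.individual_id, r.lineage)
                for r in self.records
            ]
        )

    @classmethod
    def from_fasta(cls, path) -> "AlignedSequenceSet":
        """Read FASTA; a header of the form ``name|individual|lineage`` fills
        the optional tags (missing fields may be omitted)."""
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            records.append(
                SequenceRecord(
                    name=parts[0],
                    sequence=str(rec.seq),
                    individual_id=parts[1] if len(parts) > 1 and parts[1] else None,
                    lineage=parts[2] if len(parts) > 2 and parts[2] else None,
                )
            )
        return cls(records)

    def to_fasta(self, path) -> None:
        recs = []
        for r in self.records:
            rid = r.name
            if r.individual_id or r.lineage:
                rid = f"{r.name}|{r.individual_id or ''}"
                if r.lineage:
                    rid += f"|{r.lineage}"
            recs.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
        SeqIO.write(recs, str(path), "fasta")
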