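"""Atomic structures for interface scoring: a flat atom table with chain
roles (which chain is the MHC class I molecule and which the KIR receptor),
read from and written to PDB format."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser


@dataclass
class Atom:
    chain: str
    resname: str
    resseq: int
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class ComplexStructure:
    atoms: list[Atom]
    # chain id -> "MHC" | "KIR"; chains without a role are ignored by scoring
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates on atom {a.chain}/{a.resseq}/{a.name}")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def role_of(self, atom: Atom) -> str | None:
        return self.roles.get(atom.chain)

    def atoms_in_role(self, role: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if self.roles.get(a.chain) == role]

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> "ComplexStructure":
        """Rigid-body copy: optional 3x3 rotation applied first, then translation."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = []
        for a in self.atoms:
            p = R @ np.asarray(a.xyz) + t
            out.append(Atom(a.chain, a.resname, a.resseq, a.name, a.element, tuple(p)))
        return ComplexStructure(out, dict(self.roles))

    @classmethod
    def from_pdb(cls, path, mhc_chain: str, kir_chain: str) -> "ComplexStructure":
        parser = PDBParser(QUIET=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = parser.get_structure("complex", str(path))[0]
        atoms = []
        for chain in model:
            for res in chain:
                if res.id[0] != " ":  # skip waters / hetero groups
                    continue
                for at in res:
                    elem = (at.element or at.get_name()[0]).strip().upper()
                    atoms.append(
                        Atom(chain.id, res.get_resname(), res.id[1], at.get_name(), elem, tuple(map(float, at.coord)))
                    )
        roles = {mhc_chain: "MHC", kir_chain: "KIR"}
        present = {a.chain for a in atoms}
        for cid in (mhc_chain, kir_chain):
            if cid not in present:
                raise ValueError(f"chain {cid!r} not found in {path}")
        return cls(atoms, roles)

    def to_pdb(self, path) -> None:
        with open(path, "w") as fh:
            for i, a in enumerate(self.atoms, start=1):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name}{'':1s}{a.resname:>3s} {a.chain:1s}{a.resseq:4d}    "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
                )
            fh.write("END\n")
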