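"""Structure-based MHC:KIR interaction scoring.

Three ingredients feed the interaction index:

* ``h`` — interface hydrogen bonds, detected geometrically: donor/acceptor
  heavy atoms on opposite chain roles within 3.5 A, with a D-H...A angle of
  at least 120 degrees when hydrogens are present, else an
  antecedent-donor-acceptor proxy angle of at least 90 degrees;
* ``dG`` — a desolvation energy: the sum, over cross-interface heavy-atom
  pairs within a contact radius, of a tabulated 18-class atomic contact
  energy (kcal/mol);
* ``k`` — the average energy of one hydrogen bond (kcal/mol, configurable).

The index is I = k*h / ln|dG|; |dG| within 1 + 1e-6 of zero/one makes the
logarithm degenerate and the score indeterminate. A threshold calibrated on
labelled pairs turns index values into interacting/non-interacting calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Atom, ComplexStructure

HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 120.0
PROXY_ANGLE_CUTOFF = 90.0
CONTACT_RADIUS = 6.0
DEFAULT_K = 5.0  # kcal/mol per hydrogen bond
_LN_DOMAIN_EPS = 1e-6

# donor/acceptor heavy-atom roles by (residue, atom); backbone via wildcard
_DONORS = {
    ("*", "N"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


def _is_donor(a: Atom) -> bool:
    if a.resname == "PRO" and a.name == "N":
        return False
    if (a.resname, a.name) in _DONORS or ("*", a.name) in _DONORS:
        return True
    # fall back by element for non-standard residues
    return a.element == "N" and (a.resname, a.name) not in _ACCEPTORS


def _is_acceptor(a: Atom) -> bool:
    if (a.resname, a.name) in _ACCEPTORS or ("*", a.name) in _ACCEPTORS:
        return True
    return a.element == "O"


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 180.0
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class HBond:
    donor_index: int
    acceptor_index: int
    distance: float
    angle: float | None  # D-H...A if hydrogens present, else proxy angle


@dataclass
class HBondList:
    bonds: list[HBond]

    @property
    def h(self) -> int:
        return len(self.bonds)


def detect_interface_hbonds(
    s: ComplexStructure,
    d_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> HBondList:
    """All donor-acceptor pairs bridging the MHC/KIR interface that satisfy
    the geometric criteria. Symmetric in which chain holds the donor."""
    roles = {s.roles.get(a.chain) for a in s.atoms}
    if not {"MHC", "KIR"} <= roles:
        raise ValueError("structure must contain both an MHC-role and a KIR-role chain")

    coords = s.coords()
    heavy = [i for i, a in enumerate(s.atoms) if a.element != "H"]
    hydros = [i for i, a in enumerate(s.atoms) if a.element == "H"]

    # attach hydrogens and antecedent heavy atoms to potential donors
    attached_h: dict[int, list[int]] = {}
    antecedent: dict[int, int] = {}
    if heavy:
        if hydros:
            dist_h = cdist(coords[hydros], coords[heavy])
            for hi_pos, hi in enumerate(hydros):
                j = int(np.argmin(dist_h[hi_pos]))
                if dist_h[hi_pos, j] <= 1.3:
                    attached_h.setdefault(heavy[j], []).append(hi)
        dist_hh = cdist(coords[heavy], coords[heavy])
        np.fill_diagonal(dist_hh, np.inf)
        for ai_pos, ai in enumerate(heavy):
            order = np.argsort(dist_hh[ai_pos])
            for j in order:
                cand = heavy[j]
                if dist_hh[ai_pos, j] > 1.9:
                    break
                if s.atoms[cand].chain == s.atoms[ai].chain:
                    antecedent[ai] = cand
                    break

    donors = [i for i in heavy if s.roles.get(s.atoms[i].chain) and _is_donor(s.atoms[i])]
    acceptors = [i for i in heavy if s.roles.get(s.atoms[i].chain) and _is_acceptor(s.atoms[i])]
    bonds = []
    if donors and acceptors:
        dmat = cdist(coords[donors], coords[acceptors])
        for di_pos, di in enumerate(donors):
            for ai_pos, ai in enumerate(acceptors):
                if s.roles[s.atoms[di].chain] == s.roles[s.atoms[ai].chain]:
                    continue
                dist = dmat[di_pos, ai_pos]
                if dist > d_cutoff:
                    continue
                hs = attached_h.get(di, [])
                if hs:
                    ang = max(_angle(coords[di], coords[h], coords[ai]) for h in hs)
                    if ang < angle_cutoff:
                        continue
                elif di in antecedent:
                    ang = _angle(coords[antecedent[di]], coords[di], coords[ai])
                    if ang < PROXY_ANGLE_CUTOFF:
                        continue
                else:
                    ang = None
                bonds.append(HBond(di, ai, float(dist), ang))
    return HBondList(sorted(bonds, key=lambda b: (b.donor_index, b.acceptor_index)))


# ------------------------------------------------------------- desolvation


class ContactPotential:
    """18-class atomic contact potential: typing rules + symmetric energies."""

    def __init__(self, typing: pd.DataFrame, energies: pd.DataFrame):
        self.rules = {(r.residue, r.atom): r.type for r in typing.itertuples()}
        self.energy = energies
        if not np.allclose(energies.values, energies.values.T, atol=1e-9):
            raise ValueError("contact-energy table must be symmetric")
        self._fallback = {"C": "C_ALIPH", "N": "N_AMIDE_SC", "O": "O_HYDROXYL", "S": "S"}

    @classmethod
    def load(cls, typing_path=None, energies_path=None) -> "ContactPotential":
        data = resources.files("divkit.data")
        typing = pd.read_csv(typing_path or data / "atom_types.tsv", sep="\t", comment="#")
        energies = pd.read_csv(
            energies_path or data / "contact_energies.tsv", sep="\t", comment="#", index_col=0
        )
        return cls(typing, energies)

    def type_of(self, a: Atom) -> str | None:
        if a.element == "H":
            return None
        t = self.rules.get((a.resname, a.name)) or self.rules.get(("*", a.name))
        if t is None:
            t = self._fallback.get(a.element)
        return t

    def pair_energy(self, t1: str, t2: str) -> float:
        return float(self.energy.loc[t1, t2])


def desolvation_energy(
    s: ComplexStructure,
    contact_radius: float = CONTACT_RADIUS,
    potential: ContactPotential | None = None,
) -> float:
    """Sum of tabulated contact energies over cross-interface heavy-atom
    pairs within ``contact_radius`` (kcal/mol). Untypable heavy atoms are
    excluded with a warning listing them."""
    potential = potential or ContactPotential.load()
    mhc_idx = s.atoms_in_role("MHC")
    kir_idx = s.atoms_in_role("KIR")
    if not mhc_idx or not kir_idx:
        raise ValueError("structure must contain both an MHC-role and a KIR-role chain")

    untyped = []

    def typed(indices):
        out = []
        for i in indices:
            a = s.atoms[i]
            if a.element == "H":
                continue
            t = potential.type_of(a)
            if t is None:
                untyped.append(f"{a.chain}/{a.resname}{a.resseq}/{a.name}")
            else:
                out.append((i, t))
        return out

    mhc, kir = typed(mhc_idx), typed(kir_idx)
    if untyped:
        warnings.warn(f"excluded {len(untyped)} untypable atoms: {', '.join(untyped[:8])}")
    if not mhc or not kir:
        return 0.0
    coords = s.coords()
    dmat = cdist(coords[[i for i, _ in mhc]], coords[[i for i, _ in kir]])
    total = 0.0
    ii, jj = np.nonzero(dmat <= contact_radius)
    for a, b in zip(ii, jj):
        total += potential.pair_energy(mhc[a][1], kir[b][1])
    return float(total)


# ------------------------------------------------------------------- index


@dataclass
class InteractionScore:
    h: int
    dG: float
    k: float
    I: float
    call: str | None = None  # interacting | non-interacting | indeterminate
    pair_id: str | None = None


def interaction_index(h: int, dG: float, k: float = DEFAULT_K) -> InteractionScore:
    """I = k*h / ln|dG|, evaluated on the magnitude of the desolvation
    energy. |dG| <= 1 + 1e-6 puts the logarithm at or below zero, so the
    score is flagged indeterminate instead of producing an infinity."""
    if h < 0:
        raise ValueError("h must be >= 0")
    mag = abs(dG)
    if h == 0:
        return InteractionScore(h=0, dG=dG, k=k, I=0.0)
    if mag <= 1.0 + _LN_DOMAIN_EPS:
        return InteractionScore(h=h, dG=dG, k=k, I=float("nan"), call="indeterminate")
    return InteractionScore(h=h, dG=dG, k=k, I=float(k * h / np.log(mag)))


def score_complex(
    s: ComplexStructure,
    k: float = DEFAULT_K,
    d_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
    contact_radius: float = CONTACT_RADIUS,
    potential: ContactPotential | None = None,
) -> InteractionScore:
    """Full pipeline for one complex: h, dG, and the index."""
    hb = detect_interface_hbonds(s, d_cutoff, angle_cutoff)
    dG = desolvation_energy(s, contact_radius, potential)
    return interaction_index(hb.h, dG, k)


# -------------------------------------------------------------- calibration


@dataclass
class CalibrationResult:
    threshold: float
    fp_rate: float
    fn_rate: float
    calls: list[str]
    scores: list[float] = field(repr=False, default_factory=list)


def calibrate_and_classify(scores, labels) -> CalibrationResult:
    """Choose the index threshold minimising total misclassification on
    labelled pairs (score >= threshold => interacting); ties resolve to the
    midpoint between the class means."""
    values = [s.I if isinstance(s, InteractionScore) else float(s) for s in scores]
    labs = list(labels)
    if len(values) != len(labs):
        raise ValueError("scores and labels differ in length")
    if set(labs) - {"positive", "negative"}:
        raise ValueError("labels must be 'positive' or 'negative'")
    pos = np.array([v for v, l in zip(values, labs) if l == "positive"])
    neg = np.array([v for v, l in zip(values, labs) if l == "negative"])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one score in each class")
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise ValueError("indeterminate scores cannot be calibrated")

    vals = np.sort(np.unique(np.concatenate([pos, neg])))
    candidates = np.concatenate(
        [[vals[0] - 1.0], (vals[1:] + vals[:-1]) / 2.0, [vals[-1] + 1.0]]
    )
    errors = np.array([(pos < thr).sum() + (neg >= thr).sum() for thr in candidates])
    best = errors.min()
    optima = candidates[errors == best]
    if len(optima) == 1:
        threshold = float(optima[0])
    else:
        threshold = float((pos.mean() + neg.mean()) / 2.0)
    calls = ["interacting" if v >= threshold else "non-interacting" for v in values]
    fp = float((neg >= threshold).sum() / len(neg))
    fn = float((pos < threshold).sum() / len(pos))
    return CalibrationResult(threshold, fp, fn, calls, values)
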