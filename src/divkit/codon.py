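"""Codon-state machinery shared by the simulator and the site-model fitter.

The 61 sense codons of the standard genetic code form the state space of a
Goldman–Yang style substitution process: single-nucleotide exchanges only,
with a transition/transversion rate ratio ``kappa``, a nonsynonymous rate
multiplier ``omega`` (the dN/dS ratio), and target codon frequencies ``pi``.
Codon frequencies may be given directly or built from positional nucleotide
frequencies (the F3X4 parameterisation).
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_table.stop_codons))
SENSE_CODONS = tuple(sorted(c for c in _table.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
AMINO_ACIDS = tuple(_table.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the a<->b nucleotide exchange is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _pair_classification():
    """Classify every single-step codon pair.

    Returns index arrays (i, j) over codon pairs differing at exactly one
    nucleotide, plus boolean arrays ``transition`` and ``nonsynonymous``.
    """
    ii, jj, ts, ns = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[k], cj[k]))
            ns.append(AMINO_ACIDS[i] != AMINO_ACIDS[j])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


PAIR_I, PAIR_J, PAIR_TS, PAIR_NONSYN = _pair_classification()


def f3x4_frequencies(pos_nuc_freqs: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Codon frequencies from 3x4 positional nucleotide frequencies.

    ``pos_nuc_freqs[p, n]`` is the frequency of nucleotide ``NUCS[n]`` at codon
    position ``p``. Stop codons are excluded and the 61-vector renormalised.
    A small floor keeps every sense codon reachable even when a nucleotide is
    absent at some position in a short alignment.
    """
    pos = np.asarray(pos_nuc_freqs, dtype=float)
    if pos.shape != (3, 4):
        raise ValueError(f"expected a 3x4 frequency table, got shape {pos.shape}")
    if not np.allclose(pos.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each positional frequency row must sum to 1")
    pi = np.empty(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = pos[0, NUC_INDEX[codon[0]]] * pos[1, NUC_INDEX[codon[1]]] * pos[2, NUC_INDEX[codon[2]]]
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def positional_nuc_freqs(sequences) -> np.ndarray:
    """Observed nucleotide frequencies per codon position over an iterable of
    in-frame nucleotide strings (gaps/N ignored)."""
    counts = np.zeros((3, 4))
    for seq in sequences:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            for p in range(3):
                n = s[i + p]
                if n in NUC_INDEX:
                    counts[p, NUC_INDEX[n]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("no countable nucleotides at some codon position")
    return counts / totals


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Unscaled GY94 generator and its mean rate under ``pi``.

    Off-diagonal rate i->j is ``pi_j * kappa^[transition] * omega^[nonsyn]``
    for single-nucleotide changes and 0 otherwise. Returns ``(Q, mu)`` where
    ``mu = -sum_i pi_i Q_ii`` (expected substitutions per codon per unit time
    before any scaling).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    rates = pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_NONSYN, omega, 1.0)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = float(-(pi * np.diag(Q)).sum())
    return Q, mu


class CodonProcess:
    """A scaled mixture of GY94 processes sharing kappa and pi.

    Site classes are ``(proportion, omega)`` pairs; the common scaling makes
    one unit of branch length equal one expected substitution per codon,
    averaged over classes (the convention codon-model software uses, so
    simulated and fitted branch lengths live on the same scale).
    """

    def __init__(self, kappa: float, pi: np.ndarray, site_classes):
        props = np.array([p for p, _ in site_classes], dtype=float)
        omegas = np.array([w for _, w in site_classes], dtype=float)
        if len(props) == 0:
            raise ValueError("site_classes must be non-empty")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if np.any(omegas < 0):
            raise ValueError("omega values must be >= 0")
        self.kappa = float(kappa)
        self.pi = np.asarray(pi, dtype=float)
        self.proportions = props
        self.omegas = omegas

        qs, mus = [], []
        for w in omegas:
            Q, mu = gy94_rate_matrix(kappa, w, self.pi)
            qs.append(Q)
            mus.append(mu)
        scale = float(np.dot(props, mus))
        if scale <= 0:
            raise ValueError("degenerate process: zero mean substitution rate")
        self._eigs = []
        sqrt_pi = np.sqrt(self.pi)
        for Q in qs:
            Qs = Q / scale
            # reversible: symmetrise with pi^(1/2) and use a symmetric solver
            S = Qs * sqrt_pi[:, None] / sqrt_pi[None, :]
            lam, U = np.linalg.eigh((S + S.T) / 2.0)
            left = U.T * sqrt_pi[None, :]
            right = U / sqrt_pi[:, None]
            self._eigs.append((lam, right, left))
        self.scale = scale

    @property
    def n_classes(self) -> int:
        return len(self.proportions)

    def transition_matrix(self, t: float, class_index: int = 0) -> np.ndarray:
        """P(t) for one site class; rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        lam, right, left = self._eigs[class_index]
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P
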