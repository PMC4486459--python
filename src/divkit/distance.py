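"""Pairwise evolutionary distances under a Tamura–Nei composite-likelihood
scheme.

The estimator shares the two transition/transversion rate ratios (purine
kappa1, pyrimidine kappa2) and the base frequencies across all sequence
pairs — fitting them once on the pooled pairwise mismatch counts — and then
profiles a per-pair branch length by maximum likelihood with those rates
fixed. On a two-sequence alignment the pooled counts are the pair's counts,
so the estimate coincides with the per-pair TN93 maximum-likelihood
distance. Standard errors come from a site-resampling bootstrap of the full
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

NUC_ORDER = "TCAG"
_NUC_IDX = {n: i for i, n in enumerate(NUC_ORDER)}
# transition partners in NUC_ORDER indexing: T<->C (pyrimidine), A<->G (purine)
_PYR_TS = (0, 1)
_PUR_TS = (2, 3)

_T_MAX = 15.0  # substitutions/site beyond which a pair is called saturated


def _tn93_eig(k1: float, k2: float, pi: np.ndarray):
    """Eigendecomposition of the scaled TN93 generator.

    k1 multiplies the purine transition rate, k2 the pyrimidine one; the
    generator is scaled to one expected substitution per site per unit t.
    """
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            r = pi[j]
            if {i, j} == set(_PUR_TS):
                r *= k1
            elif {i, j} == set(_PYR_TS):
                r *= k2
            Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    Q /= mu
    sp = np.sqrt(pi)
    S = Q * sp[:, None] / sp[None, :]
    lam, U = np.linalg.eigh((S + S.T) / 2.0)
    right = U / sp[:, None]
    left = U.T * sp[None, :]
    return lam, right, left


def _p_matrices(t: np.ndarray, eig, order: int = 0) -> np.ndarray:
    """P(t) for a vector of branch lengths; order 1/2 give d/dt and d2/dt2."""
    lam, right, left = eig
    w = np.exp(np.outer(t, lam)) * lam[None, :] ** order
    return np.einsum("ab,mb,bc->mac", right, w, left)


def _pooled_loglik(params: np.ndarray, counts: np.ndarray, pi: np.ndarray) -> float:
    t, k1, k2 = np.exp(params)
    eig = _tn93_eig(k1, k2, pi)
    P = _p_matrices(np.array([t]), eig)[0]
    P = np.maximum(P, 1e-300)
    return float(-(counts * np.log(pi[:, None] * P)).sum())


def estimate_shared_rates(counts_pooled: np.ndarray, pi: np.ndarray) -> tuple[float, float]:
    """Composite-likelihood estimate of (kappa1, kappa2) from pooled 4x4
    mismatch counts, profiling out a common divergence."""
    off = counts_pooled.sum() - np.trace(counts_pooled)
    if off == 0:
        return 1.0, 1.0
    best = None
    for k0 in (1.0, 4.0):
        res = minimize(
            _pooled_loglik,
            x0=np.log([0.1, k0, k0]),
            args=(counts_pooled, pi),
            method="L-BFGS-B",
            bounds=[(-12, np.log(_T_MAX)), (-5, 7), (-5, 7)],
        )
        if best is None or res.fun < best.fun:
            best = res
    _, k1, k2 = np.exp(best.x)
    return float(k1), float(k2)


def _pair_distances(counts: np.ndarray, pi: np.ndarray, k1: float, k2: float):
    """ML branch length per pair given shared rates.

    counts: (m, 4, 4) mismatch matrices. Returns (d, saturated) arrays.
    A safeguarded Newton iteration on the per-pair log-likelihood; pairs whose
    likelihood keeps increasing at _T_MAX are flagged saturated (d = nan).
    """
    m = counts.shape[0]
    total = counts.sum(axis=(1, 2))
    diff = total - np.einsum("mii->m", counts)
    d = np.zeros(m)
    saturated = np.zeros(m, dtype=bool)
    active = (diff > 0) & (total > 0)
    if not active.any():
        return d, saturated

    eig = _tn93_eig(k1, k2, pi)
    p_raw = np.where(total > 0, diff / np.maximum(total, 1), 0.0)
    t = np.clip(-np.log(np.maximum(1.0 - p_raw * 4.0 / 3.0, 1e-3)) * 0.75, 1e-4, _T_MAX / 2)
    lo = np.full(m, 1e-9)
    hi = np.full(m, _T_MAX)
    for _ in range(60):
        P = np.maximum(_p_matrices(t, eig), 1e-300)
        P1 = _p_matrices(t, eig, order=1)
        P2 = _p_matrices(t, eig, order=2)
        g = np.einsum("mij,mij->m", counts, P1 / P)
        h = np.einsum("mij,mij->m", counts, P2 / P - (P1 / P) ** 2)
        lo = np.where(g > 0, np.maximum(lo, t), lo)
        hi = np.where(g < 0, np.minimum(hi, t), hi)
        step = np.where(h < 0, g / h, 0.0)
        t_new = t - step
        bad = (t_new <= lo) | (t_new >= hi) | (h >= 0)
        t_new = np.where(bad, (lo + hi) / 2.0, t_new)
        if np.max(np.abs(t_new - t) * active) < 1e-12:
            t = t_new
            break
        t = t_new
    saturated = active & (t > 0.98 * _T_MAX)
    d = np.where(active, t, 0.0)
    d[saturated] = np.nan
    return d, saturated


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    se: np.ndarray
    saturated: np.ndarray = None
    replicates: np.ndarray | None = field(default=None, repr=False)  # (reps, n, n)

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n) or self.se.shape != (n, n):
            raise ValueError("matrix shapes do not match labels")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


def _encode(aln) -> np.ndarray:
    """Sequences as int codes in NUC_ORDER; 4 marks gap/N (pairwise-deleted)."""
    arr = np.full((len(aln), aln.length), 4, dtype=np.int8)
    for i, rec in enumerate(aln.records):
        for j, ch in enumerate(rec.sequence):
            arr[i, j] = _NUC_IDX.get(ch, 4)
    return arr


def _joint_codes(arr: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-pair, per-column joint nucleotide code (0..15), 16 = not comparable."""
    n = arr.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    J = np.empty((len(pairs), arr.shape[1]), dtype=np.int8)
    for m, (i, j) in enumerate(pairs):
        a, b = arr[i], arr[j]
        code = a.astype(np.int16) * 4 + b
        code[(a == 4) | (b == 4)] = 16
        J[m] = code
    return J, pairs


def _counts_from_codes(J: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
    sub = J if cols is None else J[:, cols]
    m = sub.shape[0]
    flat = (np.arange(m)[:, None] * 17 + sub).ravel()
    c = np.bincount(flat, minlength=m * 17).reshape(m, 17)[:, :16].astype(float)
    # symmetrise: direction carries no information under reversibility
    c = c.reshape(m, 4, 4)
    return (c + c.transpose(0, 2, 1)) / 2.0


def _matrix_from_counts(counts, pi, n, pairs):
    pooled = counts.sum(axis=0)
    k1, k2 = estimate_shared_rates(pooled, pi)
    dvec, sat = _pair_distances(counts, pi, k1, k2)
    D = np.zeros((n, n))
    S = np.zeros((n, n), dtype=bool)
    for m, (i, j) in enumerate(pairs):
        D[i, j] = D[j, i] = dvec[m]
        S[i, j] = S[j, i] = sat[m]
    return D, S


def mcl_distances(aln, bootstrap_reps: int = 1000, seed: int = 0) -> DistanceMatrix:
    """Composite-likelihood TN93 distance matrix with bootstrap SEs.

    Gaps and N are handled by pairwise deletion. Saturated pairs (likelihood
    unbounded in the divergence) get ``d = nan`` and a ``saturated`` flag
    rather than a silently capped value.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    arr = _encode(aln)
    n = len(aln)
    pi_counts = np.bincount(arr[arr < 4].ravel(), minlength=4).astype(float)
    if pi_counts.sum() == 0:
        raise ValueError("alignment has no countable nucleotides")
    pi = np.maximum(pi_counts / pi_counts.sum(), 1e-6)
    pi /= pi.sum()

    J, pairs = _joint_codes(arr)
    counts = _counts_from_codes(J)
    D, S = _matrix_from_counts(counts, pi, n, pairs)

    se = np.zeros((n, n))
    reps = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        L = aln.length
        reps = np.empty((bootstrap_reps, n, n))
        for r in range(bootstrap_reps):
            cols = rng.integers(0, L, size=L)
            c = _counts_from_codes(J, cols)
            reps[r], _ = _matrix_from_counts(c, pi, n, pairs)
        se = np.nanstd(reps, axis=0, ddof=1)
    return DistanceMatrix(list(aln.names), D, se, S, replicates=reps)


def group_distance(dm: DistanceMatrix, groups: dict[str, str], mode: str, select=None):
    """Mean distance over a set of cells defined by a label->group map.

    mode="within": cells whose two endpoints share a group (optionally only
    the group named by ``select``); mode="between": cells whose endpoints lie
    in two different groups (optionally only the pair ``select=(g1, g2)``).
    Returns (mean, bootstrap SE) with the SE taken over the same cell set in
    each bootstrap replicate of the full matrix.
    """
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")
    members: dict[str, list[int]] = {}
    for label, g in groups.items():
        members.setdefault(g, []).append(dm.index_of(label))
    if mode == "within":
        wanted = [select] if select is not None else sorted(members)
        for g in wanted:
            if g not in members:
                raise ValueError(f"empty group {g!r}")
            if len(members[g]) < 2:
                raise ValueError(f"group {g!r} has a single member; no within-group distance")
        cells = [
            (i, j)
            for g in wanted
            for a, i in enumerate(members[g])
            for j in members[g][a + 1 :]
        ]
    else:
        if select is not None:
            g1, g2 = select
            if g1 not in members or g2 not in members:
                raise ValueError(f"unknown group in pair {select!r}")
            pairs_of_groups = [(g1, g2)]
        else:
            gs = sorted(members)
            pairs_of_groups = [(a, b) for ai, a in enumerate(gs) for b in gs[ai + 1 :]]
        cells = [(i, j) for g1, g2 in pairs_of_groups for i in members[g1] for j in members[g2]]
    if not cells:
        raise ValueError("no cells selected")
    ii = np.array([c[0] for c in cells])
    jj = np.array([c[1] for c in cells])
    mean = float(np.mean(dm.d[ii, jj]))
    if dm.replicates is not None:
        se = float(np.nanstd(dm.replicates[:, ii, jj].mean(axis=1), ddof=1))
    else:
        se = float("nan")
    return mean, se
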