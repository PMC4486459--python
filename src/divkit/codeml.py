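"""Maximum-likelihood codon site models and positive-selection site calls.

Implements the standard site-model family over GY94 codon processes with
F3X4 frequencies estimated from the data:

* M0  — one omega for all sites;
* M1a — nearly neutral: omega0 < 1 and omega1 = 1;
* M2a — M1a plus a selection class with omega2 >= 1;
* M3  — unconstrained discrete omega distribution (3 classes);
* M8  — beta-distributed omega on (0,1) (10 equal-probability categories)
        plus a selection class with omega_s >= 1.

Likelihoods use Felsenstein pruning with per-node rescaling on compressed
site patterns; branch lengths are the input-tree lengths times a scale
factor estimated under M0 and then held fixed for the richer models, so all
five fits share one branch-length set. Sites under positive selection are
identified empirical-Bayes style (posterior membership of omega>1 classes at
the MLEs) and a consensus rule across models turns posteriors into calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc, betaincinv
from scipy.stats import chi2

from .codon import (
    CODON_INDEX,
    N_CODONS,
    STOP_CODONS,
    CodonProcess,
    f3x4_frequencies,
    positional_nuc_freqs,
)

MODELS = ("M0", "M1a", "M2a", "M3", "M8")
SELECTION_MODELS = ("M2a", "M3", "M8")
_NESTED_DF = {("M1a", "M2a"): 2, ("M1a", "M8"): 2, ("M0", "M3"): 4}
M8_NCAT = 10


# ------------------------------------------------------------------ pruning


class CodonPruner:
    """Pruning-algorithm likelihood evaluator for one alignment + tree."""

    def __init__(self, aln, tree):
        if aln.length % 3:
            raise ValueError("alignment length must be divisible by 3")
        self.names = list(aln.names)
        leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if set(self.names) != leaf_labels:
            raise ValueError("tree leaves and sequence names differ")

        n_codons = aln.length // 3
        codes = np.full((len(self.names), n_codons), N_CODONS, dtype=np.int16)
        stops = []
        for i, rec in enumerate(aln.records):
            for c in range(n_codons):
                codon = rec.sequence[3 * c : 3 * c + 3]
                if codon in CODON_INDEX:
                    codes[i, c] = CODON_INDEX[codon]
                elif codon in STOP_CODONS:
                    stops.append((rec.name, c + 1, codon))
        internal = [s for s in stops if s[1] < n_codons]
        if internal:
            listing = ", ".join(f"{n}:codon {p} ({c})" for n, p, c in internal[:5])
            raise ValueError(f"internal stop codons: {listing}")
        if stops:  # terminal stop column: drop it for everyone
            codes = codes[:, :-1]
            n_codons -= 1
        self.n_codons = n_codons

        patterns, inverse = np.unique(codes, axis=1, return_inverse=True)
        self.pattern_index = inverse  # site -> pattern
        self.weights = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
        self.n_patterns = patterns.shape[1]
        self.leaf_codes = {self.names[i]: patterns[i] for i in range(len(self.names))}

        self.pi = f3x4_frequencies(
            positional_nuc_freqs(r.sequence for r in aln.records)
        )
        self.invariant = bool(
            all((patterns[0] == patterns[i]).all() for i in range(patterns.shape[0]))
            and (patterns[0] < N_CODONS).all()
        )

        # postorder traversal schedule
        self._postorder = []
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                self._root = node
            self._postorder.append(node)
        self.tree_length = sum(e.length or 0.0 for e in tree.edges() if e.head_node.parent_node)

    def class_site_loglikes(self, kappa: float, site_classes, scale: float) -> np.ndarray:
        """log L_k(pattern) for every site class; shape (n_classes, n_patterns)."""
        process = CodonProcess(kappa, self.pi, site_classes)
        out = np.empty((process.n_classes, self.n_patterns))
        for k in range(process.n_classes):
            out[k] = self._prune_one(process, k, scale)
        return out

    def _prune_one(self, process, class_index: int, scale: float) -> np.ndarray:
        partials: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in self._postorder:
            if node.is_leaf():
                codes = self.leaf_codes[node.taxon.label]
                part = np.zeros((N_CODONS, self.n_patterns))
                known = codes < N_CODONS
                part[codes[known], np.nonzero(known)[0]] = 1.0
                part[:, ~known] = 1.0
                partials[id(node)] = part
                logscale[id(node)] = np.zeros(self.n_patterns)
                continue
            part = np.ones((N_CODONS, self.n_patterns))
            ls = np.zeros(self.n_patterns)
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * scale
                P = process.transition_matrix(t, class_index)
                part *= P @ partials.pop(id(child))
                ls += logscale.pop(id(child))
            mx = part.max(axis=0)
            mx[mx == 0] = 1.0
            part /= mx
            partials[id(node)] = part
            logscale[id(node)] = ls + np.log(mx)
        root_part = partials[id(self._root)]
        return np.log(np.maximum(process.pi @ root_part, 1e-300)) + logscale[id(self._root)]

    def mixture_loglik(self, kappa, site_classes, scale):
        """Total lnL and the per-pattern, per-class joint log-likelihoods."""
        props = np.array([p for p, _ in site_classes])
        cls = self.class_site_loglikes(kappa, site_classes, scale)
        joint = np.log(np.maximum(props, 1e-300))[:, None] + cls
        m = joint.max(axis=0)
        site_log = m + np.log(np.exp(joint - m).sum(axis=0))
        return float(self.weights @ site_log), joint, site_log


# ------------------------------------------------------------------- models


@dataclass
class SiteModelFit:
    model_id: str
    lnL: float
    kappa: float
    branch_scale: float
    proportions: np.ndarray
    omegas: np.ndarray
    per_site_posterior: np.ndarray  # sites x classes
    pos_selection_posterior: np.ndarray  # sites, P(omega > 1)
    pi: np.ndarray = field(repr=False, default=None)
    beta_params: tuple[float, float] | None = None  # (p, q) for M8
    n_free_params: int = 0
    converged: bool = True
    degenerate: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.pos_selection_posterior)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _beta_category_means(p: float, q: float, k: int = M8_NCAT) -> np.ndarray:
    """Mean omega within each of k equal-probability bins of Beta(p, q)."""
    edges = betaincinv(p, q, np.linspace(0.0, 1.0, k + 1))
    upper = betainc(p + 1.0, q, edges)
    means = (upper[1:] - upper[:-1]) * (p / (p + q)) * k
    return np.clip(means, 1e-8, 1.0 - 1e-8)


def _model_classes(model_id: str, x: np.ndarray):
    """Decode an unconstrained parameter vector into (kappa, classes, extra)."""
    kappa = np.exp(x[0])
    if model_id == "M0":
        return kappa, [(1.0, np.exp(x[1]))], None
    if model_id == "M1a":
        p0 = _sigmoid(x[1])
        w0 = _sigmoid(x[2])
        return kappa, [(p0, w0), (1.0 - p0, 1.0)], None
    if model_id == "M2a":
        p0 = _sigmoid(x[1])
        p1 = (1.0 - p0) * _sigmoid(x[2])
        p2 = 1.0 - p0 - p1
        w0 = _sigmoid(x[3])
        w2 = 1.0 + np.exp(x[4])
        return kappa, [(p0, w0), (p1, 1.0), (p2, w2)], None
    if model_id == "M3":
        p0 = _sigmoid(x[1])
        p1 = (1.0 - p0) * _sigmoid(x[2])
        p2 = 1.0 - p0 - p1
        ws = np.exp(x[3:6])
        return kappa, list(zip((p0, p1, p2), ws)), None
    if model_id == "M8":
        p0 = _sigmoid(x[1])
        p, q = np.exp(x[2]), np.exp(x[3])
        ws = 1.0 + np.exp(x[4])
        means = _beta_category_means(p, q)
        classes = [(p0 / M8_NCAT, w) for w in means] + [(1.0 - p0, ws)]
        return kappa, classes, (p, q)
    raise ValueError(f"unknown model {model_id!r}")


_STARTS = {
    "M0": [np.log([2.0, 0.4]), np.log([1.5, 1.0])],
    "M1a": [np.array([np.log(2.0), 1.0, -1.5]), np.array([np.log(2.0), 2.0, -3.0])],
    "M2a": [
        np.array([np.log(2.0), 1.0, 1.0, -1.5, 0.0]),
        np.array([np.log(2.0), 2.0, 2.0, -3.0, 1.0]),
    ],
    "M3": [
        np.array([np.log(2.0), 0.5, 0.0, np.log(0.05), np.log(0.5), np.log(1.5)]),
        np.array([np.log(2.0), 1.0, 1.0, np.log(0.2), np.log(1.0), np.log(3.0)]),
    ],
    "M8": [
        np.array([np.log(2.0), 2.0, np.log(0.5), np.log(1.5), 0.0]),
        np.array([np.log(2.0), 3.0, np.log(1.0), np.log(4.0), 1.0]),
    ],
}
_BOUNDS = {
    "M0": [(-3, 4), (-9, 3)],
    "M1a": [(-3, 4), (-12, 12), (-12, 7)],
    "M2a": [(-3, 4), (-12, 12), (-12, 12), (-12, 7), (-7, 5)],
    "M3": [(-3, 4), (-12, 12), (-12, 12), (-9, 3), (-9, 3), (-9, 3)],
    "M8": [(-3, 4), (-12, 12), (np.log(0.005), np.log(99)), (np.log(0.005), np.log(99)), (-7, 5)],
}


def _degenerate_fit(pruner: CodonPruner, model_id: str) -> SiteModelFit:
    """All sequences identical: omega is unidentifiable; the likelihood is
    maximised at zero tree length, where lnL is the multinomial constant
    sum_sites log pi(codon)."""
    pi = pruner.pi
    lnL = float(
        sum(
            w * np.log(pi[pruner.leaf_codes[pruner.names[0]][p]])
            for p, w in enumerate(pruner.weights)
        )
    )
    kappa, classes, extra = _model_classes(model_id, _STARTS[model_id][0])
    props = np.array([p for p, _ in classes])
    post = np.tile(props, (pruner.n_codons, 1))
    psel = post[:, np.array([w for _, w in classes]) > 1.0].sum(axis=1)
    return SiteModelFit(
        model_id=model_id,
        lnL=lnL,
        kappa=1.0,
        branch_scale=0.0,
        proportions=props,
        omegas=np.array([w for _, w in classes]),
        per_site_posterior=post,
        pos_selection_posterior=psel,
        pi=pi,
        beta_params=extra,
        n_free_params=0,
        degenerate=True,
    )


def fit_site_model(
    aln,
    tree,
    model_id: str,
    branch_scale: float | None = None,
    n_starts: int = 2,
    pruner: CodonPruner | None = None,
) -> SiteModelFit:
    """Fit one site model by maximum likelihood.

    For M0 the global branch-length scale is a free parameter; for the other
    models it defaults to the M0 estimate (computed here if not supplied).
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; choose from {MODELS}")
    pruner = pruner or CodonPruner(aln, tree)
    if pruner.invariant:
        return _degenerate_fit(pruner, model_id)

    if model_id == "M0":
        scale_free = True
    else:
        scale_free = False
        if branch_scale is None:
            branch_scale = fit_site_model(aln, tree, "M0", pruner=pruner).branch_scale

    def objective(theta):
        if scale_free:
            s = np.exp(theta[0])
            x = theta[1:]
        else:
            s = branch_scale
            x = theta
        kappa, classes, _ = _model_classes(model_id, x)
        lnL, _, _ = pruner.mixture_loglik(kappa, classes, s)
        return -lnL

    starts = _STARTS[model_id][:n_starts]
    bounds = list(_BOUNDS[model_id])
    if scale_free:
        starts = [np.concatenate(([np.log(0.5)], s)) for s in starts]
        bounds = [(-8, 4)] + bounds

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "eps": 1e-6, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    if scale_free:
        scale = float(np.exp(theta[0]))
        x = theta[1:]
    else:
        scale = float(branch_scale)
        x = theta
    kappa, classes, extra = _model_classes(model_id, x)
    lnL, joint, site_log = pruner.mixture_loglik(kappa, classes, scale)

    post_pat = np.exp(joint - site_log[None, :]).T  # patterns x classes
    post = post_pat[pruner.pattern_index]
    omegas = np.array([w for _, w in classes])
    psel = post[:, omegas > 1.0].sum(axis=1)
    return SiteModelFit(
        model_id=model_id,
        lnL=lnL,
        kappa=float(kappa),
        branch_scale=scale,
        proportions=np.array([p for p, _ in classes]),
        omegas=omegas,
        per_site_posterior=post,
        pos_selection_posterior=psel,
        pi=pruner.pi,
        beta_params=extra,
        n_free_params=len(theta),
        converged=bool(best.success),
    )


def fit_models(aln, tree, models=MODELS, n_starts: int = 2) -> dict[str, SiteModelFit]:
    """Fit a set of site models sharing the M0 branch-length scale."""
    pruner = CodonPruner(aln, tree)
    fits: dict[str, SiteModelFit] = {}
    m0 = fit_site_model(aln, tree, "M0", pruner=pruner, n_starts=n_starts)
    scale = m0.branch_scale
    if "M0" in models:
        fits["M0"] = m0
    for mid in models:
        if mid == "M0":
            continue
        fits[mid] = fit_site_model(aln, tree, mid, branch_scale=scale, pruner=pruner, n_starts=n_starts)
    return fits


# --------------------------------------------------------------------- LRT


@dataclass
class LrtResult:
    stat: float
    df: int
    p_value: float


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LrtResult:
    """Likelihood-ratio test between a nested model pair.

    2*(lnL_alt - lnL_null) against chi-square; negative statistics (the
    boundary case) clamp to 0 with p = 1.
    """
    key = (null_fit.model_id, alt_fit.model_id)
    if key not in _NESTED_DF:
        raise ValueError(f"{key[0]} vs {key[1]} is not a supported nested pair")
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    df = _NESTED_DF[key]
    return LrtResult(stat=stat, df=df, p_value=float(chi2.sf(stat, df)) if stat > 0 else 1.0)


# ------------------------------------------------------------ site calling


@dataclass
class SelectedSite:
    position: int  # 1-based codon position in the alignment
    posteriors: dict[str, float]
    supporting_models: tuple[str, ...]


@dataclass
class SelectedSiteSet:
    sites: list[SelectedSite]
    threshold: float
    min_models: int

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


def selected_sites(
    fits: dict[str, SiteModelFit], threshold: float = 0.9, min_models: int = 2
) -> SelectedSiteSet:
    """Consensus positive-selection calls: a codon is reported when its
    posterior P(omega > 1) exceeds ``threshold`` in at least ``min_models``
    of the supplied selection-capable fits."""
    use = {m: f for m, f in fits.items() if m in SELECTION_MODELS}
    if not use:
        raise ValueError("need at least one of " + ", ".join(SELECTION_MODELS))
    lengths = {f.n_sites for f in use.values()}
    if len(lengths) != 1:
        raise ValueError(f"fits cover different alignment lengths: {sorted(lengths)}")
    n = lengths.pop()
    sites = []
    for s in range(n):
        probs = {m: float(f.pos_selection_posterior[s]) for m, f in use.items()}
        supporting = tuple(m for m, p in sorted(probs.items()) if p > threshold)
        if len(supporting) >= min_models:
            sites.append(SelectedSite(s + 1, probs, supporting))
    return SelectedSiteSet(sites, threshold, min_models)
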