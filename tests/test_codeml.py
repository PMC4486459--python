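"""Codon site models: oracle equivalence of the pruning likelihood, model
nesting, LRT arithmetic, and posterior behaviour."""

import numpy as np
import pytest

from divkit import (
    AlignedSequenceSet,
    CodonSimConfig,
    SequenceRecord,
    fit_models,
    fit_site_model,
    lrt,
    selected_sites,
    simulate_codon_alignment,
)
from divkit.codeml import CodonPruner, SiteModelFit, _beta_category_means

from conftest import brute_force_mixture_loglik, parse_tree


@pytest.mark.parametrize(
    "newick,n_codons,seed",
    [
        ("(a:0.2,b:0.3,c:0.25);", 5, 2),
        ("((a:0.2,b:0.3):0.1,c:0.25,d:0.15);", 8, 9),
        ("((a:0.4,b:0.1):0.2,c:0.3,d:0.2);", 10, 17),
    ],
)
def test_pruning_matches_brute_force(newick, n_codons, seed):
    """The pruned likelihood equals explicit summation over all ancestral
    codon states (independent expm-based oracle) to 1e-8."""
    cfg = CodonSimConfig(
        tree_newick=newick, kappa=2.0, site_classes=[(0.6, 0.3), (0.4, 2.0)], n_codons=n_codons, seed=seed
    )
    aln, _ = simulate_codon_alignment(cfg)
    tree = parse_tree(newick)
    pruner = CodonPruner(aln, tree)
    for kappa, scale in ((1.7, 0.9), (3.0, 0.4)):
        classes = [(0.6, 0.3), (0.4, 2.0)]
        lnL, _, _ = pruner.mixture_loglik(kappa, classes, scale)
        oracle = brute_force_mixture_loglik(aln, tree, kappa, classes, scale, pruner.pi)
        assert lnL == pytest.approx(oracle, abs=1e-8)


def test_invariant_alignment_degenerate():
    """All-identical sequences: omega unidentifiable, the fit is flagged and
    lnL equals the multinomial constant sum(log pi)."""
    seq = "ATGAAACCCGGGTTTCTG"
    aln = AlignedSequenceSet([SequenceRecord(n, seq) for n in "abc"])
    tree = parse_tree("(a:0.1,b:0.1,c:0.1);")
    fit = fit_site_model(aln, tree, "M0")
    assert fit.degenerate
    pruner = CodonPruner(aln, tree)
    expected = sum(np.log(pruner.pi[pruner.leaf_codes["a"][p]]) * w for p, w in enumerate(pruner.weights))
    assert fit.lnL == pytest.approx(expected, abs=1e-9)


def test_internal_stop_reported_with_position():
    aln = AlignedSequenceSet(
        [
            SequenceRecord("a", "ATGTAACCC"),  # TAA at codon 2 (internal)
            SequenceRecord("b", "ATGAAACCC"),
            SequenceRecord("c", "ATGAAGCCC"),
        ]
    )
    with pytest.raises(ValueError, match="a:codon 2"):
        CodonPruner(aln, parse_tree("(a:0.1,b:0.1,c:0.1);"))


def test_terminal_stop_column_dropped():
    aln = AlignedSequenceSet(
        [
            SequenceRecord("a", "ATGAAATAA"),
            SequenceRecord("b", "ATGAAGTAA"),
            SequenceRecord("c", "ATGAAATGA"),
        ]
    )
    pruner = CodonPruner(aln, parse_tree("(a:0.1,b:0.1,c:0.1);"))
    assert pruner.n_codons == 2


class TestModelFits:
    @pytest.fixture(scope="class")
    def m2a_data(self, six_taxon_tree):
        cfg = CodonSimConfig(
            tree_newick=six_taxon_tree,
            kappa=2.0,
            site_classes=[(0.6, 0.2), (0.3, 1.0), (0.1, 4.0)],
            n_codons=300,
            seed=5,
        )
        aln, labels = simulate_codon_alignment(cfg)
        fits = fit_models(aln, parse_tree(six_taxon_tree), models=("M0", "M1a", "M2a", "M3", "M8"))
        return aln, labels, fits

    def test_nesting_inequalities(self, m2a_data):
        _, _, fits = m2a_data
        assert fits["M2a"].lnL >= fits["M1a"].lnL - 1e-6
        assert fits["M3"].lnL >= fits["M0"].lnL - 1e-6
        assert fits["M8"].lnL >= fits["M1a"].lnL - 1.0  # not strictly nested in this parameterisation

    def test_posterior_rows_sum_to_one(self, m2a_data):
        _, _, fits = m2a_data
        for fit in fits.values():
            assert np.allclose(fit.per_site_posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_selection_class_detected(self, m2a_data):
        _, labels, fits = m2a_data
        assert fits["M2a"].omegas[-1] > 1.5
        r = lrt(fits["M1a"], fits["M2a"])
        assert r.p_value < 0.01

    def test_called_sites_are_enriched_in_planted(self, m2a_data):
        """Consensus calls hit the planted omega=4 class: moderate
        sensitivity, tight false-positive rate over neutral sites."""
        _, labels, fits = m2a_data
        sel = selected_sites(fits)
        planted = set(np.nonzero(labels == 2)[0] + 1)
        called = set(sel.positions)
        neutral = set(range(1, len(labels) + 1)) - planted
        assert len(called & planted) / len(planted) >= 0.4
        assert len(called & neutral) / len(neutral) <= 0.05


class TestLrt:
    def _fit(self, model_id, lnL):
        return SiteModelFit(
            model_id=model_id,
            lnL=lnL,
            kappa=2.0,
            branch_scale=1.0,
            proportions=np.array([1.0]),
            omegas=np.array([0.5]),
            per_site_posterior=np.ones((1, 1)),
            pos_selection_posterior=np.zeros(1),
        )

    def test_equal_likelihoods(self):
        r = lrt(self._fit("M1a", -100.0), self._fit("M2a", -100.0))
        assert r.stat == 0.0
        assert r.p_value == 1.0

    def test_chi2_quantile_identity(self):
        r = lrt(self._fit("M1a", -100.0), self._fit("M2a", -100.0 + 5.991 / 2))
        assert r.p_value == pytest.approx(0.05, abs=5e-4)
        assert r.df == 2

    def test_negative_stat_clamped(self):
        r = lrt(self._fit("M1a", -100.0), self._fit("M2a", -101.0))
        assert r.stat == 0.0 and r.p_value == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit("M2a", -10.0), self._fit("M3", -9.0))


class TestSelectedSites:
    def _fit(self, model_id, psel):
        psel = np.asarray(psel, dtype=float)
        return SiteModelFit(
            model_id=model_id,
            lnL=-1.0,
            kappa=2.0,
            branch_scale=1.0,
            proportions=np.array([1.0]),
            omegas=np.array([2.0]),
            per_site_posterior=np.ones((len(psel), 1)),
            pos_selection_posterior=psel,
        )

    def test_consensus_rule(self):
        fits = {
            "M2a": self._fit("M2a", [0.95, 0.95, 0.2]),
            "M3": self._fit("M3", [0.99, 0.5, 0.95]),
            "M8": self._fit("M8", [0.1, 0.82, 0.99]),
        }
        sel = selected_sites(fits, threshold=0.9, min_models=2)
        assert sel.positions == [1, 3]
        assert sel.sites[0].supporting_models == ("M2a", "M3")

    def test_empty_when_no_selection_class(self):
        fits = {m: self._fit(m, [0.0, 0.0]) for m in ("M2a", "M3", "M8")}
        assert selected_sites(fits).positions == []

    def test_length_mismatch_rejected(self):
        fits = {"M2a": self._fit("M2a", [0.95]), "M3": self._fit("M3", [0.95, 0.2])}
        with pytest.raises(ValueError):
            selected_sites(fits)


def test_beta_discretisation_means():
    """Equal-probability category means integrate back to the beta mean."""
    for p, q in ((0.5, 0.5), (2.0, 5.0), (0.2, 1.0)):
        means = _beta_category_means(p, q)
        assert means.shape == (10,)
        assert np.all(np.diff(means) > 0)
        assert means.mean() == pytest.approx(p / (p + q), rel=1e-3)
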