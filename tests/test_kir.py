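"""Interface H-bond detection, contact-energy desolvation, the interaction
index, and threshold calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from divkit import (
    ToyComplexConfig,
    calibrate_and_classify,
    desolvation_energy,
    detect_interface_hbonds,
    generate_toy_complex,
    interaction_index,
)
from divkit.kir import ContactPotential, HBOND_ANGLE_CUTOFF, HBOND_DISTANCE_CUTOFF, PROXY_ANGLE_CUTOFF, _is_acceptor, _is_donor
from divkit.structure import Atom, ComplexStructure


def brute_force_hbonds(s: ComplexStructure, d_cutoff=HBOND_DISTANCE_CUTOFF):
    """Independent oracle: plain double loop over all atom pairs with the
    same geometric rules."""
    bonds = set()
    atoms = s.atoms
    for i, d in enumerate(atoms):
        if d.element == "H" or not _is_donor(d) or s.roles.get(d.chain) is None:
            continue
        for j, a in enumerate(atoms):
            if a.element == "H" or not _is_acceptor(a) or s.roles.get(a.chain) is None:
                continue
            if s.roles[d.chain] == s.roles[a.chain]:
                continue
            pd, pa = np.array(d.xyz), np.array(a.xyz)
            if np.linalg.norm(pd - pa) > d_cutoff:
                continue
            hs = [
                k
                for k, h in enumerate(atoms)
                if h.element == "H" and np.linalg.norm(np.array(h.xyz) - pd) <= 1.3
            ]
            if hs:
                ok = False
                for k in hs:
                    ph = np.array(atoms[k].xyz)
                    v1, v2 = pd - ph, pa - ph
                    ang = np.degrees(
                        np.arccos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
                    )
                    if ang >= HBOND_ANGLE_CUTOFF:
                        ok = True
                if not ok:
                    continue
            else:
                ante = [
                    (np.linalg.norm(np.array(x.xyz) - pd), k)
                    for k, x in enumerate(atoms)
                    if k != i and x.element != "H" and x.chain == d.chain
                    and np.linalg.norm(np.array(x.xyz) - pd) <= 1.9
                ]
                if ante:
                    _, k = min(ante)
                    px = np.array(atoms[k].xyz)
                    v1, v2 = px - pd, pa - pd
                    ang = np.degrees(
                        np.arccos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
                    )
                    if ang < PROXY_ANGLE_CUTOFF:
                        continue
            bonds.add((i, j))
    return bonds


class TestHbondDetector:
    def test_planted_bonds_exactly_recovered(self, toy_complex):
        s, manifest = toy_complex
        hb = detect_interface_hbonds(s)
        assert hb.h == 12
        assert {(b.donor_index, b.acceptor_index) for b in hb.bonds} == set(manifest)

    def test_equals_brute_force_oracle(self, toy_complex):
        s, _ = toy_complex
        ours = {(b.donor_index, b.acceptor_index) for b in detect_interface_hbonds(s).bonds}
        assert ours == brute_force_hbonds(s)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_oracle_equivalence_random_structures(self, seed):
        s, _ = generate_toy_complex(
            ToyComplexConfig(n_planted_hbonds=seed * 3, n_decoy_atoms=150, jitter=0.08, seed=seed)
        )
        ours = {(b.donor_index, b.acceptor_index) for b in detect_interface_hbonds(s).bonds}
        assert ours == brute_force_hbonds(s)

    def test_role_swap_symmetry(self, toy_complex):
        s, _ = toy_complex
        swapped = ComplexStructure(list(s.atoms), {"A": "KIR", "B": "MHC"})
        assert detect_interface_hbonds(swapped).h == detect_interface_hbonds(s).h

    def test_single_role_rejected(self):
        s = ComplexStructure([Atom("A", "GLY", 1, "N", "N", (0, 0, 0))], {"A": "MHC"})
        with pytest.raises(ValueError):
            detect_interface_hbonds(s)


def _two_atom_complex(dist=4.0):
    return ComplexStructure(
        [
            Atom("A", "ALA", 1, "CB", "C", (0.0, 0.0, 0.0)),
            Atom("B", "LYS", 1, "NZ", "N", (dist, 0.0, 0.0)),
        ],
        {"A": "MHC", "B": "KIR"},
    )


class TestDesolvation:
    def test_two_atom_hand_sum(self):
        """One typed atom per chain at 4 A: dG equals the single table entry."""
        pot = ContactPotential.load()
        dG = desolvation_energy(_two_atom_complex(), potential=pot)
        assert dG == pytest.approx(pot.pair_energy("C_BETA", "N_LYS"))

    def test_no_contacts_zero(self):
        assert desolvation_energy(_two_atom_complex(dist=50.0)) == 0.0

    def test_duplication_additivity(self, toy_complex):
        s, _ = toy_complex
        dG = desolvation_energy(s)
        doubled = ComplexStructure(
            list(s.atoms)
            + [
                Atom("B", a.resname, a.resseq + 5000, a.name, a.element, a.xyz)
                for a in s.atoms
                if a.chain == "B"
            ],
            dict(s.roles),
        )
        assert desolvation_energy(doubled) == pytest.approx(2 * dG, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_complex):
        s, _ = toy_complex
        R = Rotation.from_euler("zyx", [0.4, -1.2, 2.2]).as_matrix()
        moved = s.transformed(R, (11.0, -3.0, 7.0))
        assert desolvation_energy(moved) == pytest.approx(desolvation_energy(s), abs=1e-9)
        assert detect_interface_hbonds(moved).h == detect_interface_hbonds(s).h


class TestInteractionIndex:
    def test_zero_bonds_zero_index(self):
        assert interaction_index(0, 123.0).I == 0.0

    def test_formula_arithmetic(self):
        assert interaction_index(10, np.e, k=5.0).I == pytest.approx(50.0)
        assert interaction_index(10, -np.e, k=5.0).I == pytest.approx(50.0)  # magnitude convention

    def test_degenerate_domain_indeterminate(self):
        score = interaction_index(4, 0.5)
        assert score.call == "indeterminate"
        assert not np.isinf(score.I)

    def test_monotone_in_h(self):
        scores = [interaction_index(h, 20.0, k=5.0).I for h in range(6)]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestCalibration:
    def test_perfect_separation_zero_error(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(5000, 100, 50)
        neg = rng.normal(1300, 100, 50)
        res = calibrate_and_classify(
            list(pos) + list(neg), ["positive"] * 50 + ["negative"] * 50
        )
        assert res.fp_rate == 0.0 and res.fn_rate == 0.0

    def test_two_scores_midpoint(self):
        res = calibrate_and_classify([10.0, 2.0], ["positive", "negative"])
        assert res.threshold == pytest.approx(6.0)

    def test_overlapping_gaussians_near_bayes_error(self):
        """Equal-variance Gaussians: empirical total error within 3 points of
        the closed-form Bayes error Phi(-delta / (2 sigma))."""
        rng = np.random.default_rng(1)
        mu_p, mu_n, sigma, n = 3000.0, 2000.0, 800.0, 10000
        pos = rng.normal(mu_p, sigma, n)
        neg = rng.normal(mu_n, sigma, n)
        res = calibrate_and_classify(
            list(pos) + list(neg), ["positive"] * n + ["negative"] * n
        )
        total_error = (res.fp_rate + res.fn_rate) / 2
        bayes = norm.cdf(-(mu_p - mu_n) / (2 * sigma))
        assert abs(total_error - bayes) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            calibrate_and_classify([1.0, 2.0], ["positive", "positive"])
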