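"""Boltzmann machinery, binding energies, decomposition, key residues."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyclinterface.ensemble_energetics import (
    GoContactScorer,
    ResidueContributionTable,
    ScoredMember,
    boltzmann_weights,
    ensemble_binding_energy,
    interface_binding_energy,
    minimize,
    per_residue_contributions,
    score_member,
    score_structure,
    select_key_residues,
)
from cyclinterface.structures_io import AtomRecord, ResidueKey, Structure

finite_energies = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=20
)


def _ca(serial, chain, seq, xyz):
    return AtomRecord(
        serial=serial, atom_name="CA", element="C", residue_name="GLY",
        chain_id=chain, residue_seq=seq, insertion_code="",
        coords=tuple(float(v) for v in xyz), vdw_radius=1.70,
    )


def _two_chain_single_contact():
    """One interchain contact between A:5 and B:7, nothing else in range."""
    atoms = [
        _ca(1, "A", 5, (0, 0, 0)),
        _ca(2, "A", 6, (100, 0, 0)),
        _ca(3, "B", 7, (5, 0, 0)),
        _ca(4, "B", 8, (200, 0, 0)),
    ]
    return Structure("single_contact", atoms)


class TestScoreStructure:
    def test_native_pose_energy_and_decomposition(self, toy_structure):
        scorer = GoContactScorer(toy_structure)
        total, per_res = score_structure(toy_structure, scorer)
        n_contacts = len(scorer.contact_r0)
        assert total == pytest.approx(-scorer.epsilon * n_contacts, abs=1e-9)
        assert sum(per_res.values()) == pytest.approx(total, abs=1e-9)

    def test_single_residue_no_interactions(self):
        s = Structure("lonely", [_ca(1, "A", 1, (0, 0, 0))])
        total, per_res = score_structure(s, GoContactScorer(s))
        assert total == 0.0
        assert per_res == {ResidueKey("A", 1): 0.0}

    def test_total_matches_naive_double_loop(self, toy_structure, rng):
        """Independent re-evaluation with an explicit pair loop."""
        scorer = GoContactScorer(toy_structure)
        perturbed = toy_structure.with_coords(
            toy_structure.coords() + rng.normal(0, 0.2, (len(toy_structure.atoms), 3))
        )
        total, _ = score_structure(perturbed, scorer)
        ca = {a.residue_key: np.array(a.coords) for a in perturbed.atoms
              if a.atom_name == "CA"}
        oracle = 0.0
        for (ki, kj), r0 in scorer.contact_r0.items():
            r = np.linalg.norm(ca[kj] - ca[ki])
            q = r0 / r
            oracle += scorer.epsilon * (5 * q**12 - 6 * q**10)
        for ki, kj in scorer.clash_pairs:
            r = np.linalg.norm(ca[kj] - ca[ki])
            if r < scorer.sigma_clash:
                oracle += scorer.eps_clash * ((scorer.sigma_clash / r) ** 12 - 1)
        assert total == pytest.approx(oracle, abs=1e-9)

    def test_gradient_matches_numerical(self, toy_structure, rng):
        scorer = GoContactScorer(toy_structure)
        from cyclinterface.pipeline import ca_trace

        ca = ca_trace(toy_structure)
        keys = [a.residue_key for a in ca.atoms]
        x = ca.coords() + rng.normal(0, 0.1, (len(keys), 3))
        _, grad = scorer.energy_and_grad(x, keys)
        h = 1e-6
        for i in (0, 10, 25):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                num = (
                    scorer.energy_and_grad(xp, keys)[0]
                    - scorer.energy_and_grad(xm, keys)[0]
                ) / (2 * h)
                assert grad[i, d] == pytest.approx(num, abs=1e-4)


class TestMinimize:
    class _Quadratic:
        """Separable test potential with minimum at (1, 2, 3) per atom."""

        center = np.array([1.0, 2.0, 3.0])

        def score(self, structure):
            raise NotImplementedError

        def energy_and_grad(self, coords, keys):
            d = coords - self.center
            return float((d * d).sum()), 2.0 * d

    def test_quadratic_converges_to_analytic_minimum(self):
        s = Structure("q", [_ca(1, "A", 1, (9.0, -4.0, 0.0))])
        results = minimize(s, self._Quadratic(), n_restarts=3, jitter_sigma=0.5, seed=0)
        for structure, energy in results:
            assert energy == pytest.approx(0.0, abs=1e-6)
            assert np.allclose(structure.coords()[0], [1, 2, 3], atol=1e-3)

    def test_native_start_zero_jitter_unchanged(self, toy_structure):
        from cyclinterface.pipeline import ca_trace

        ca = ca_trace(toy_structure)
        scorer = GoContactScorer(toy_structure)
        results = minimize(ca, scorer, n_restarts=1, jitter_sigma=0.0, seed=0)
        structure, energy = results[0]
        start_energy, _ = scorer.energy_and_grad(
            ca.coords(), [a.residue_key for a in ca.atoms]
        )
        assert energy <= start_energy + 1e-9
        assert np.abs(structure.coords() - ca.coords()).max() < 1e-6

    def test_restarts_reproducible_and_descending(self, toy_structure):
        from cyclinterface.pipeline import ca_trace

        ca = ca_trace(toy_structure)
        scorer = GoContactScorer(toy_structure)
        a = minimize(ca, scorer, n_restarts=10, seed=4)
        b = minimize(ca, scorer, n_restarts=10, seed=4)
        assert len(a) == 10
        for (sa, ea), (sb, eb) in zip(a, b):
            assert ea == eb
            assert np.array_equal(sa.coords(), sb.coords())


class TestBoltzmannWeights:
    def test_uniform_for_equal_energies(self):
        w, q = boltzmann_weights([0.0, 0.0, 0.0])
        assert np.allclose(w, [1 / 3] * 3, atol=1e-15)
        assert q == pytest.approx(3.0)

    def test_two_level_system(self):
        w, _ = boltzmann_weights([0.0, 1.0], kT=1.0)
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert w[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-12)

    def test_extreme_spread_no_overflow(self):
        w, _ = boltzmann_weights([0.0, 1e6], kT=1.0)
        assert w[0] == pytest.approx(1.0, abs=1e-12)
        assert w[1] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="kT"):
            boltzmann_weights([0.0], kT=0.0)
        with pytest.raises(ValueError, match="at least one"):
            boltzmann_weights([])
        with pytest.raises(ValueError, match="finite"):
            boltzmann_weights([np.inf])

    @given(energies=finite_energies, kt=st.floats(0.01, 100))
    def test_normalization(self, energies, kt):
        w, _ = boltzmann_weights(energies, kT=kt)
        assert abs(w.sum() - 1.0) < 1e-12
        assert ((w >= 0) & (w <= 1)).all()

    @given(energies=finite_energies, shift=st.floats(-1000, 1000))
    def test_shift_invariance(self, energies, shift):
        w1, _ = boltzmann_weights(energies)
        w2, _ = boltzmann_weights([e + shift for e in energies])
        assert np.abs(w1 - w2).max() < 1e-12

    def test_lowering_one_energy_raises_its_weight(self):
        base = [1.0, 2.0, 3.0]
        w1, _ = boltzmann_weights(base)
        lowered = [1.0, 0.5, 3.0]
        w2, _ = boltzmann_weights(lowered)
        assert w2[1] > w1[1]


class TestBindingEnergy:
    @pytest.mark.parametrize(
        "e_complex,e_a,e_b,expected",
        [(-10.0, -4.0, -6.0, 0.0), (-12.0, -4.0, -6.0, -2.0), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_defining_difference(self, e_complex, e_a, e_b, expected):
        assert interface_binding_energy(e_complex, e_a, e_b) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            interface_binding_energy(np.nan, 0.0, 0.0)

    def test_single_member_expectation(self):
        m = ScoredMember("m", e_complex=-10.0, e_chain_cyclin=-4.0,
                         e_chain_kinase=-2.8)
        ens = ensemble_binding_energy([m])
        assert ens.e_binding == pytest.approx(m.e_binding)
        assert ens.e_binding == pytest.approx(-3.2)

    def test_equal_complex_scores_give_plain_mean(self):
        members = [
            ScoredMember(f"m{i}", e_complex=-5.0, e_chain_cyclin=0.0,
                         e_chain_kinase=-5.0 - eb)
            for i, eb in enumerate([-1.0, -2.0, -3.0])
        ]
        assert [m.e_binding for m in members] == [-1.0, -2.0, -3.0]
        ens = ensemble_binding_energy(members)
        assert ens.e_binding == pytest.approx(-2.0, abs=1e-12)

    def test_two_member_direct_oracle(self):
        members = [
            ScoredMember("a", e_complex=0.0, e_chain_cyclin=0.0, e_chain_kinase=1.0),
            ScoredMember("b", e_complex=5.0, e_chain_cyclin=4.0, e_chain_kinase=5.0),
        ]
        # E_b members: -1 and -4; weights from complex scores [0, 5]
        p0 = 1 / (1 + np.exp(-5.0))
        expected = p0 * (-1.0) + (1 - p0) * (-4.0)
        ens = ensemble_binding_energy(members, kT=1.0)
        assert ens.e_binding == pytest.approx(expected, abs=1e-12)

    def test_expectation_bounded_by_member_range(self, rng):
        members = [
            ScoredMember(f"m{i}", *rng.normal(0, 3, size=3)) for i in range(25)
        ]
        ens = ensemble_binding_energy(members)
        ebs = [m.e_binding for m in members]
        assert min(ebs) - 1e-12 <= ens.e_binding <= max(ebs) + 1e-12

    def test_low_temperature_limit_selects_argmin(self, rng):
        members = [
            ScoredMember(f"m{i}", *rng.normal(0, 2, size=3)) for i in range(10)
        ]
        best = min(members, key=lambda m: m.e_complex)
        ens = ensemble_binding_energy(members, kT=1e-6)
        assert ens.e_binding == pytest.approx(best.e_binding, abs=1e-9)

    def test_high_temperature_limit_is_mean(self, rng):
        # unit-scale scores with a well-separated mean binding energy, so
        # the O(1/kT) correction sits far below the tolerance
        members = [
            ScoredMember(
                f"m{i}",
                rng.normal(0, 0.5),
                rng.normal(0, 0.5),
                5.0 + rng.normal(0, 0.5),
            )
            for i in range(10)
        ]
        mean_eb = np.mean([m.e_binding for m in members])
        ens = ensemble_binding_energy(members, kT=1e6)
        assert ens.e_binding == pytest.approx(mean_eb, rel=1e-6)


class TestPerResidueContributions:
    def test_single_contact_half_split(self):
        s = _two_chain_single_contact()
        scorer = GoContactScorer(s)
        member = score_member("m0", s, "A", "B", scorer)
        assert member.e_binding == pytest.approx(-1.0, abs=1e-9)
        table = per_residue_contributions([member], [1.0])
        assert table.contributions[ResidueKey("A", 5)] == pytest.approx(-0.5, abs=1e-9)
        assert table.contributions[ResidueKey("B", 7)] == pytest.approx(-0.5, abs=1e-9)
        assert table.contributions[ResidueKey("A", 6)] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ensemble_equals_single_member(self, toy_structure):
        scorer = GoContactScorer(toy_structure)
        m = score_member("m", toy_structure, "A", "B", scorer)
        single = per_residue_contributions([m], [1.0])
        triple = per_residue_contributions([m, m, m], [1 / 3] * 3)
        for key in single.contributions:
            assert triple.contributions[key] == pytest.approx(
                single.contributions[key], abs=1e-12
            )

    def test_contributions_sum_to_expectation(self, toy_structure, rng):
        scorer = GoContactScorer(toy_structure)
        members = []
        for i in range(10):
            perturbed = toy_structure.with_coords(
                toy_structure.coords()
                + rng.normal(0, 0.1, (len(toy_structure.atoms), 3))
            )
            members.append(score_member(f"m{i}", perturbed, "A", "B", scorer))
        ens = ensemble_binding_energy(members)
        table = per_residue_contributions(members, ens.weights)
        assert sum(table.contributions.values()) == pytest.approx(
            ens.e_binding, abs=1e-9
        )

    def test_residue_set_mismatch_rejected(self):
        s = _two_chain_single_contact()
        scorer = GoContactScorer(s)
        good = score_member("g", s, "A", "B", scorer)
        bad = score_member("b", s.select_chains(["A"]), "A", "A", scorer)
        with pytest.raises(ValueError, match="residue set"):
            per_residue_contributions([good, bad], [0.5, 0.5])


class TestSelectKeyResidues:
    @staticmethod
    def _table(contribs, e_b):
        return ResidueContributionTable(
            contributions={ResidueKey("A", i + 1): c for i, c in enumerate(contribs)},
            e_binding=e_b,
        )

    def test_half_percent_rule(self):
        table = self._table([-0.9, -0.099, -0.001], e_b=-1.0)
        keys = select_key_residues(table, min_fraction=0.005)
        assert keys == [ResidueKey("A", 1), ResidueKey("A", 2)]

    def test_all_below_threshold_empty(self):
        table = self._table([0.001, -0.002], e_b=-1.0)
        assert select_key_residues(table) == []

    def test_single_residue_carrying_everything(self):
        table = self._table([-2.0], e_b=-2.0)
        assert select_key_residues(table) == [ResidueKey("A", 1)]

    def test_zero_total_rejected(self):
        table = self._table([0.5, -0.5], e_b=0.0)
        with pytest.raises(ZeroDivisionError):
            select_key_residues(table)

    def test_sorted_by_contribution_magnitude(self):
        table = self._table([-0.2, -0.7, -0.1], e_b=-1.0)
        keys = select_key_residues(table)
        assert keys == [ResidueKey("A", 2), ResidueKey("A", 1), ResidueKey("A", 3)]
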