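"""Energy terms: closed forms, naive-double-loop oracle, invariances."""

import numpy as np
import pytest

from cyslock import confsearch, ligands, scoring
from cyslock.scoring import (
    COULOMB_CONSTANT,
    ScoringConfig,
    ScoringError,
    best_score,
    coulomb_energy_arrays,
    lj_energy_arrays,
    score_conformer,
    score_set,
)


def naive_coulomb(q1, x1, q2, x2, dielectric, cutoff):
    e = 0.0
    for i in range(len(q1)):
        for j in range(len(q2)):
            r = np.linalg.norm(x1[i] - x2[j])
            if r <= cutoff:
                e += COULOMB_CONSTANT * q1[i] * q2[j] / (dielectric * r)
    return e


def naive_lj(s1, e1, x1, s2, e2, x2, cutoff):
    e = 0.0
    for i in range(len(s1)):
        for j in range(len(s2)):
            r = np.linalg.norm(x1[i] - x2[j])
            if r <= cutoff:
                sig = 0.5 * (s1[i] + s2[j])
                eps = np.sqrt(e1[i] * e2[j])
                e += 4.0 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    return e


def pair(r):
    """One ligand atom at origin, one pocket atom at distance r on x."""
    return np.zeros((1, 3)), np.array([[r, 0.0, 0.0]])


class TestClosedForms:
    def test_unit_charges_at_one_angstrom(self):
        xl, xp = pair(1.0)
        e = coulomb_energy_arrays(
            np.array([1.0]), xl, np.array([-1.0]), xp,
            dielectric=1.0, cutoff=np.inf,
        )
        assert e == pytest.approx(-COULOMB_CONSTANT, abs=1e-9)

    def test_zero_charge_pocket(self):
        rng = np.random.default_rng(0)
        xl, xp = rng.normal(size=(4, 3)), rng.normal(size=(6, 3)) + 5
        e = coulomb_energy_arrays(
            rng.normal(size=4), xl, np.zeros(6), xp, dielectric=1.0
        )
        assert e == 0.0

    def test_pair_beyond_cutoff_contributes_nothing(self):
        xl, xp = pair(13.0)
        e = coulomb_energy_arrays(
            np.array([1.0]), xl, np.array([1.0]), xp,
            dielectric=1.0, cutoff=12.0,
        )
        assert e == 0.0

    def test_lj_zero_at_sigma(self):
        xl, xp = pair(3.4)
        e = lj_energy_arrays(
            np.array([3.4]), np.array([1.0]), xl,
            np.array([3.4]), np.array([1.0]), xp,
        )
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_lj_minimum_is_minus_epsilon(self):
        sig, eps = 3.4, 0.25
        xl, xp = pair(2 ** (1 / 6) * sig)
        e = lj_energy_arrays(
            np.array([sig]), np.array([eps]), xl,
            np.array([sig]), np.array([eps]), xp,
        )
        assert e == pytest.approx(-eps, abs=1e-9)

    def test_lj_at_two_sigma(self):
        xl, xp = pair(2.0 * 3.0)
        e = lj_energy_arrays(
            np.array([3.0]), np.array([1.0]), xl,
            np.array([3.0]), np.array([1.0]), xp,
        )
        assert e == pytest.approx(4.0 * (2.0**-12 - 2.0**-6), abs=1e-12)

    def test_coincident_atoms_singular(self):
        xl, xp = pair(0.0)
        with pytest.raises(ScoringError):
            lj_energy_arrays(
                np.array([3.0]), np.array([1.0]), xl,
                np.array([3.0]), np.array([1.0]), xp,
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_random_small_systems(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, m = rng.integers(1, 21, size=2)
        q1, q2 = rng.normal(size=n), rng.normal(size=m)
        s1, s2 = rng.uniform(2.5, 4.0, n), rng.uniform(2.5, 4.0, m)
        e1, e2 = rng.uniform(0.05, 0.3, n), rng.uniform(0.05, 0.3, m)
        x1 = rng.normal(size=(n, 3))
        x2 = rng.normal(size=(m, 3)) + np.array([6.0, 0, 0])
        cut = rng.uniform(5.0, 15.0)
        assert coulomb_energy_arrays(q1, x1, q2, x2, 4.0, cut) == pytest.approx(
            naive_coulomb(q1, x1, q2, x2, 4.0, cut), abs=1e-8
        )
        assert lj_energy_arrays(s1, e1, x1, s2, e2, x2, cut) == pytest.approx(
            naive_lj(s1, e1, x1, s2, e2, x2, cut), abs=1e-8
        )

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        q1, q2 = rng.normal(size=5), rng.normal(size=8)
        s1, s2 = rng.uniform(3, 4, 5), rng.uniform(3, 4, 8)
        e1, e2 = rng.uniform(0.1, 0.3, 5), rng.uniform(0.1, 0.3, 8)
        x1 = rng.normal(size=(5, 3))
        x2 = rng.normal(size=(8, 3)) + 5
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([10.0, -3.0, 2.0])
        before = (
            coulomb_energy_arrays(q1, x1, q2, x2, 4.0, 12.0),
            lj_energy_arrays(s1, e1, x1, s2, e2, x2, 12.0),
        )
        after = (
            coulomb_energy_arrays(q1, x1 @ R.T + t, q2, x2 @ R.T + t, 4.0, 12.0),
            lj_energy_arrays(s1, e1, x1 @ R.T + t, s2, e2, x2 @ R.T + t, 12.0),
        )
        assert after == pytest.approx(before, abs=1e-8)

    def test_charge_antisymmetry(self):
        rng = np.random.default_rng(11)
        q1, q2 = rng.normal(size=4), rng.normal(size=6)
        x1, x2 = rng.normal(size=(4, 3)), rng.normal(size=(6, 3)) + 4
        base = coulomb_energy_arrays(q1, x1, q2, x2, 2.0, np.inf)
        assert coulomb_energy_arrays(-q1, x1, -q2, x2, 2.0, np.inf) == (
            pytest.approx(base, abs=1e-12)
        )
        assert coulomb_energy_arrays(-q1, x1, q2, x2, 2.0, np.inf) == (
            pytest.approx(-base, abs=1e-12)
        )


@pytest.fixture(scope="module")
def docked(toy_pocket):
    lig = ligands.parse_ligand("C=CC(=O)NCC", "L1")
    anchored = ligands.apply_michael_addition(
        lig, ligands.detect_warheads(lig)[0]
    )
    start = confsearch.place_anchor(anchored, toy_pocket)
    return confsearch.enumerate_conformers(start, 60.0, cap=300)


class TestConformerScoring:
    def test_weight_identity(self, docked, toy_pocket):
        conf = docked.conformers[0]
        cfg = ScoringConfig(w_es=0.0, w_vdw=1.0)
        b = score_conformer(conf, toy_pocket, cfg)
        assert b.total == b.vdw
        cfg2 = ScoringConfig(w_es=2.0, w_vdw=0.5)
        b2 = score_conformer(conf, toy_pocket, cfg2)
        assert b2.total == pytest.approx(
            2.0 * b2.electrostatic + 0.5 * b2.vdw, abs=1e-9
        )

    def test_clash_scores_positive(self):
        # ligand atom buried 1.0 A into a pocket atom of sigma ~3.5
        xl, xp = pair(1.0)
        e = lj_energy_arrays(
            np.array([3.5]), np.array([0.1]), xl,
            np.array([3.5]), np.array([0.1]), xp,
        )
        assert e > 100.0  # r << sigma: strongly repulsive

    def test_score_set_matches_per_conformer(self, docked, toy_pocket):
        cfg = ScoringConfig()
        batch = score_set(docked, toy_pocket, cfg)
        for i in [0, len(batch) // 2, len(batch) - 1]:
            single = score_conformer(
                docked.conformers[i], toy_pocket, cfg, conformer_index=i
            )
            assert batch[i].total == pytest.approx(single.total, abs=1e-9)
            assert batch[i].electrostatic == pytest.approx(
                single.electrostatic, abs=1e-9
            )

    def test_best_score_is_argmin_with_tie_to_lowest_index(
        self, docked, toy_pocket
    ):
        cfg = ScoringConfig()
        batch = score_set(docked, toy_pocket, cfg)
        best = best_score(docked, toy_pocket, cfg)
        assert best.total == min(b.total for b in batch)
        first_min = min(
            (b for b in batch), key=lambda b: (b.total, b.conformer_index)
        )
        assert best.conformer_index == first_min.conformer_index

    def test_empty_set_rejected(self, docked, toy_pocket):
        empty = confsearch.ConformerSet(
            anchored=docked.anchored, conformers=[],
            increment_deg=60.0, cap=10,
        )
        with pytest.raises(ValueError):
            best_score(empty, toy_pocket)

    def test_unparameterized_pocket_rejected(self, docked):
        from cyslock import fixtures, structures

        s = structures.read_structure(fixtures.make_toy_pocket(2))
        raw = structures.extract_pocket(s, structures.find_anchor(s, "A", 107))
        with pytest.raises(ScoringError):
            score_conformer(docked.conformers[0], raw)
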