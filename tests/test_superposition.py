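"""Kabsch fitting, iterative centroid superposition, variance recovery."""

import numpy as np
import pytest

from mrprep import (CoreError, GeometryError, core_positions, kabsch,
                    make_target, pairwise_rmsd, superpose_to_centroid)
from mrprep.simulate import _random_rotation

from oracles import quaternion_rmsd


def _random_cloud(rng, n=10, scale=10.0):
    return rng.uniform(-scale, scale, size=(n, 3))


def _rigidly_move(rng, coords):
    rot = _random_rotation(rng)
    shift = rng.uniform(-15, 15, size=3)
    return coords @ rot.T + shift


class TestKabsch:
    def test_identical_sets(self):
        coords = _random_cloud(np.random.default_rng(0))
        tr, rmsd = kabsch(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-10)

    def test_recovers_known_motion(self):
        coords = _random_cloud(np.random.default_rng(1))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = coords @ rot90.T + np.array([5.0, 0.0, 0.0])
        tr, rmsd = kabsch(coords, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.apply(moved), coords, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        fixed = _random_cloud(rng)
        moving = fixed + rng.normal(0, 1.0, size=fixed.shape)
        moving = _rigidly_move(rng, moving)
        _, rmsd = kabsch(fixed, moving)
        assert rmsd == pytest.approx(quaternion_rmsd(fixed, moving), abs=1e-9)

    def test_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(3)
        a = _random_cloud(rng)
        b = a + rng.normal(0, 0.5, size=a.shape)
        _, r_ab = kabsch(a, b)
        _, r_ba = kabsch(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        _, r_moved = kabsch(a, _rigidly_move(rng, b))
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    def test_geometry_errors(self):
        rng = np.random.default_rng(4)
        good = _random_cloud(rng, 5)
        with pytest.raises(GeometryError):
            kabsch(good, good[:4])
        with pytest.raises(GeometryError):
            kabsch(good[:2], good[:2])
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(GeometryError):
            kabsch(line, line)


class TestCorePositions:
    def _member(self, numbers, seed=0):
        model, _ = make_target(max(numbers), seed)
        chain = model.single_chain
        chain.residues = [r for r in chain.residues if r.number in set(numbers)]
        return model

    def test_intersection_of_coverage(self):
        members = [self._member(range(1, 101)), self._member(range(5, 101)),
                   self._member(range(1, 96))]
        core = core_positions(members)
        assert core == tuple(range(5, 96))
        assert len(core) == 91

    def test_single_member(self):
        member = self._member(range(3, 40))
        assert core_positions([member]) == tuple(range(3, 40))

    def test_empty_intersection(self):
        with pytest.raises(CoreError):
            core_positions([self._member(range(1, 20)), self._member(range(30, 50))])

    def test_random_coverage_matches_brute_force(self):
        rng = np.random.default_rng(5)
        cover = [set(rng.choice(np.arange(1, 60), size=45, replace=False).tolist())
                 for _ in range(4)]
        members = [self._member(sorted(c)) for c in cover]
        assert set(core_positions(members)) == set.intersection(*cover)


class TestSuperposeToCentroid:
    def test_identical_copies_converge_to_zero(self):
        rng = np.random.default_rng(6)
        base, _ = make_target(50, 6)
        members = []
        for i in range(3):
            copy = base.copy()
            copy.id = f"c{i}"
            copy.transform(_random_rotation(rng), rng.uniform(-30, 30, 3))
            members.append(copy)
        ens = superpose_to_centroid(members)
        assert max(ens.member_rmsd) < 1e-6
        assert float(np.max(ens.variance)) < 1e-12

    def test_gaussian_noise_rmsd_matches_closed_form(self):
        """Mean member r.m.s.d. about a sample mean is sigma*sqrt(3)*sqrt(1-1/n)."""
        from mrprep import FamilySpec, make_family
        sigma, n_members = 0.3, 10
        target, _ = make_target(200, 21)
        models, _, _ = make_family(target, FamilySpec(
            n_residues=200, n_members=n_members, identity=1.0,
            core_sd=sigma, loop_sd=sigma, loop_fraction=0.0,
            rigid_motion=True, seed=21))
        ens = superpose_to_centroid(models)
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 1.0 / n_members)
        assert np.mean(ens.member_rmsd) == pytest.approx(expected, rel=0.10)

    def test_member_order_invariance(self, tiered_family):
        _t, models, _s, _sd = tiered_family
        forward = superpose_to_centroid(models)
        backward = superpose_to_centroid(models[::-1])
        by_id_f = dict(zip([m.id for m in forward.members], forward.member_rmsd))
        by_id_b = dict(zip([m.id for m in backward.members], backward.member_rmsd))
        for key in by_id_f:
            assert by_id_f[key] == pytest.approx(by_id_b[key], abs=1e-6)

    def test_variance_decomposition_conserved(self, tiered_superposed):
        ens = tiered_superposed
        n = len(ens.members)
        total_sq = sum(r ** 2 * len(ens.core_positions) for r in ens.member_rmsd)
        assert n * float(np.sum(ens.variance)) == pytest.approx(total_sq, rel=1e-9)

    def test_two_tier_noise_separation(self, tiered_family, tiered_superposed):
        """Positions ranked by estimated variance separate the injected tiers."""
        _t, _m, _s, sd_map = tiered_family
        ens = tiered_superposed
        core_idx = np.array(ens.core_positions) - 1
        truth_loop = sd_map[core_idx] > 1.0
        n_loop = int(truth_loop.sum())
        ranked = np.argsort(-ens.variance)  # most variable first
        top = np.zeros(len(core_idx), dtype=bool)
        top[ranked[:n_loop]] = True
        agreement = float((top == truth_loop).mean())
        assert agreement >= 0.95

    def test_too_few_members(self):
        model, _ = make_target(20, 0)
        with pytest.raises(ValueError):
            superpose_to_centroid([model])


class TestPairwiseRmsd:
    def test_self_and_rigid_copy(self):
        rng = np.random.default_rng(8)
        model, _ = make_target(40, 8)
        assert pairwise_rmsd(model, model) == pytest.approx(0.0, abs=1e-10)
        moved = model.copy()
        moved.transform(_random_rotation(rng), rng.uniform(-10, 10, 3))
        assert pairwise_rmsd(model, moved) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_copy_monte_carlo(self):
        """Per-residue noise of sd sigma gives r.m.s.d. near sigma*sqrt(3)."""
        sigma = 0.5
        model, _ = make_target(30, 9)
        rng = np.random.default_rng(9)
        values = []
        for _ in range(1000):
            noisy = model.copy()
            for res in noisy.single_chain.residues:
                disp = rng.normal(0, sigma, 3)
                for atom in res.atoms:
                    atom.position = atom.position + disp
            values.append(pairwise_rmsd(model, noisy))
        # the Kabsch fit absorbs 6 dof out of 3*30 coordinates
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / (3 * 30))
        assert np.mean(values) == pytest.approx(expected, rel=0.05)
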