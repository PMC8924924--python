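"""The GRAPHite network: radial basis, blocks, invariances, checkpointing."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poseranker.graphite import (BesselBasis, ConfigurationError, DomainError,
                                 GraphiteNet, bessel_basis_values,
                                 continuous_filter_conv, interaction_block,
                                 readout)
from poseranker.synthetic import _random_rotation, restricted_vocabulary
from .conftest import tiny_complex


class TestBesselBasis:
    def test_vanishes_exactly_at_cutoff(self):
        for n_basis in (1, 4, 16, 64):
            basis = BesselBasis(cutoff=5.0, n_basis=n_basis)
            assert np.all(basis.values(5.0) == 0.0)

    def test_zero_distance_limit(self):
        for n_basis in (1, 16, 64):
            basis = BesselBasis(cutoff=5.0, n_basis=n_basis)
            expected = np.sqrt(2.0 / 5.0)
            assert np.allclose(basis.values(0.0), expected, atol=1e-9)

    def test_closed_form_midpoint(self):
        # b_1(R_c/2) = sqrt(2/R_c) * sin(pi/2)/(pi/2) for R_c = 4
        basis = BesselBasis(cutoff=4.0, n_basis=1)
        expected = np.sqrt(2.0 / 4.0) * np.sin(np.pi / 2) / (np.pi / 2)
        assert basis.values(2.0)[0] == pytest.approx(expected, abs=1e-12)
        assert basis.values(2.0)[0] == pytest.approx(0.45016, abs=1e-5)

    def test_domain_errors(self):
        basis = BesselBasis(cutoff=4.0)
        with pytest.raises(DomainError):
            basis.values(-0.1)
        with pytest.raises(DomainError):
            basis.values(4.1)

    def test_continuity_near_cutoff(self):
        basis = BesselBasis(cutoff=4.0, n_basis=16)
        eps = 1e-7
        assert np.all(np.abs(basis.values(4.0 - eps)) < 1e-5)

    def test_functional_alias(self):
        basis = BesselBasis(cutoff=4.0, n_basis=3)
        d = np.array([0.5, 1.5])
        assert np.array_equal(bessel_basis_values(d, basis), basis.values(d))


def _block_params(rng, c=8, n_basis=4):
    return {"kernel": rng.normal(size=(n_basis, c)),
            "W1": rng.normal(size=(c, c)), "b1": rng.normal(size=c),
            "W2": rng.normal(size=(c, c)), "b2": rng.normal(size=c),
            "gamma": np.ones(c), "beta": np.zeros(c)}


class TestInteractionBlock:
    def test_zero_edges_gives_skip_only(self):
        rng = np.random.default_rng(0)
        params = _block_params(rng)
        basis = BesselBasis(cutoff=4.0, n_basis=4)
        h = rng.normal(size=(5, 8))
        skip = rng.normal(size=(3, 8))
        empty = (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
        out = interaction_block(h, skip, empty, basis, params)
        # same as zeroing the kernel with edges present
        edges = (np.array([0, 1]), np.array([0, 2]), np.array([1.0, 2.0]))
        params_zero = dict(params, kernel=np.zeros_like(params["kernel"]))
        out_zero = interaction_block(h, skip, edges, basis, params_zero)
        assert np.allclose(out, out_zero, atol=1e-12)

    def test_convolution_linearity_in_sources(self):
        rng = np.random.default_rng(1)
        basis = BesselBasis(cutoff=4.0, n_basis=4)
        kernel = rng.normal(size=(4, 8))
        h = rng.normal(size=(1, 8))
        h2 = np.vstack([h, h])  # two identical sources
        one = continuous_filter_conv(
            h, (np.array([0]), np.array([0]), np.array([2.0])), basis, kernel, 1)
        two = continuous_filter_conv(
            h2, (np.array([0, 1]), np.array([0, 0]), np.array([2.0, 2.0])),
            basis, kernel, 1)
        assert np.allclose(two, 2.0 * one, atol=1e-12)

    def test_width_mismatch_raises(self):
        rng = np.random.default_rng(2)
        params = _block_params(rng, c=8)
        basis = BesselBasis(cutoff=4.0, n_basis=4)
        skip = rng.normal(size=(3, 4))  # wrong width
        empty = (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
        with pytest.raises(ValueError):
            interaction_block(rng.normal(size=(5, 8)), skip, empty, basis, params)


class TestReadout:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        params = {"W1": rng.normal(size=(16, 8)), "b1": rng.normal(size=8),
                  "W2": rng.normal(size=(8, 1)), "b2": rng.normal(size=1)}
        lig = rng.normal(size=(6, 8))
        rec = rng.normal(size=(9, 8))
        base = readout([lig], [rec], params)
        shuffled = readout([lig[rng.permutation(6)]],
                           [rec[rng.permutation(9)]], params)
        assert shuffled == pytest.approx(base, abs=1e-10)

    def test_duplicating_atoms_doubles_pooled_features(self):
        rng = np.random.default_rng(4)
        lig = rng.normal(size=(5, 8))
        assert np.allclose(np.vstack([lig, lig]).sum(axis=0),
                           2 * lig.sum(axis=0))

    def test_empty_readout_is_configuration_error(self):
        params = {"W1": np.zeros((0, 8)), "b1": np.zeros(8),
                  "W2": np.zeros((8, 1)), "b2": np.zeros(1)}
        with pytest.raises(ConfigurationError):
            readout([], [], params)


@pytest.fixture(scope="module")
def small_net():
    return GraphiteNet("l->l->r->l", vocab=restricted_vocabulary(),
                       channels=16, hidden=32, n_basis=8, seed=0)


class TestForward:
    def test_rigid_motion_invariance(self, small_net):
        rng = np.random.default_rng(5)
        for trial in range(20):
            example = tiny_complex(rng)
            base = small_net.score(example)
            R = _random_rotation(rng)
            t = rng.normal(0, 8, 3)
            moved = replace(
                example,
                receptor=example.receptor.with_coords(
                    example.receptor.coords @ R.T + t),
                pose=replace(example.pose, coords=example.pose.coords @ R.T + t))
            assert small_net.score(moved) == pytest.approx(base, abs=1e-4)

    def test_atom_permutation_invariance(self, small_net):
        rng = np.random.default_rng(6)
        for trial in range(20):
            example = tiny_complex(rng)
            base = small_net.score(example)
            n_rec = len(example.receptor.atoms)
            perm = rng.permutation(n_rec)
            rec = example.receptor
            atoms = tuple(replace(rec.atoms[i], index=k)
                          for k, i in enumerate(perm))
            permuted_rec = replace(
                rec, atoms=atoms,
                chain_ids=tuple(rec.chain_ids[i] for i in perm),
                res_names=tuple(rec.res_names[i] for i in perm),
                res_seqs=tuple(rec.res_seqs[i] for i in perm),
                atom_names=tuple(rec.atom_names[i] for i in perm))
            permuted = replace(example, receptor=permuted_rec)
            assert small_net.score(permuted) == pytest.approx(base, abs=1e-5)

    def test_ligand_only_config_ignores_pose_placement(self):
        net = GraphiteNet("l->l->l", vocab=restricted_vocabulary(),
                          channels=16, hidden=32, seed=1)
        rng = np.random.default_rng(7)
        example = tiny_complex(rng)
        base = net.score(example)
        R = _random_rotation(rng)
        t = rng.normal(0, 6, 3)
        com = example.pose.coords.mean(axis=0)
        moved_pose = (example.pose.coords - com) @ R.T + com + t
        moved = replace(example, pose=replace(example.pose, coords=moved_pose))
        assert net.score(moved) == pytest.approx(base, abs=1e-6)

    def test_ligand_only_config_ignores_receptor(self):
        net = GraphiteNet("l->l", vocab=restricted_vocabulary(),
                          channels=16, hidden=32, seed=1)
        rng = np.random.default_rng(8)
        example = tiny_complex(rng)
        base = net.score(example)
        other = replace(example, receptor=tiny_complex(rng).receptor,
                        ligand=example.ligand, pose=example.pose)
        assert net.score(other) == pytest.approx(base, abs=1e-12)

    def test_bit_reproducible_across_instances(self):
        rng = np.random.default_rng(9)
        example = tiny_complex(rng)
        a = GraphiteNet("l->l->r", vocab=restricted_vocabulary(),
                        channels=16, hidden=32, seed=42).score(example)
        b = GraphiteNet("l->l->r", vocab=restricted_vocabulary(),
                        channels=16, hidden=32, seed=42).score(example)
        assert a == b

    def test_gradients_match_finite_differences(self, small_net):
        rng = np.random.default_rng(10)
        example = tiny_complex(rng)
        prepared = small_net.prepare(example)
        _, cache = small_net.forward(prepared, with_cache=True)
        grads = small_net.backward(cache, 1.0)
        eps = 1e-6
        for key in ["L0.kernel", "L1.src.ligand", "L2.tgt.ligand",
                    "L1.W2", "L2.gamma", "out.W1", "out.b2"]:
            arr = small_net.params[key]
            idx = tuple(int(rng.integers(s)) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            up = small_net.forward(prepared)
            arr[idx] = orig - eps
            down = small_net.forward(prepared)
            arr[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, abs=1e-5, rel=1e-4)


class TestRescoreAttempt:
    def test_single_pose(self, small_net, small_attempt):
        _, poses = small_attempt
        scored = small_net.rescore_attempt(poses[:1])
        assert len(scored) == 1 and scored[0].rank == 1

    def test_output_is_permutation(self, small_net, small_attempt):
        _, poses = small_attempt
        scored = small_net.rescore_attempt(poses)
        assert sorted(sp.docking_rank for sp in scored) == \
               sorted(ex.pose.rank for ex in poses)
        assert sorted(sp.rank for sp in scored) == list(range(1, len(poses) + 1))

    def test_ties_preserve_docking_order(self, small_attempt):
        _, poses = small_attempt
        net = GraphiteNet("l->l", vocab=restricted_vocabulary(),
                          channels=8, hidden=16, seed=0)
        # identical coordinates => exactly equal logits => stable tie-break
        template = poses[0]
        tied = [replace(template, pose=replace(template.pose, rank=r))
                for r in (4, 1, 3, 2)]
        scored = net.rescore_attempt(tied)
        assert [sp.logit for sp in scored] == [scored[0].logit] * 4
        assert [sp.docking_rank for sp in scored] == [1, 2, 3, 4]

    def test_empty_attempt_raises(self, small_net):
        with pytest.raises(ValueError):
            small_net.rescore_attempt([])


class TestCheckpoint:
    def test_roundtrip_bit_exact(self, tmp_path, small_attempt):
        _, poses = small_attempt
        net = GraphiteNet("l->l->r->l", vocab=restricted_vocabulary(),
                          channels=16, hidden=32, seed=3)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = GraphiteNet.load(path)
        for key in net.params.keys():
            assert np.array_equal(net.params[key], loaded.params[key])
        assert loaded.score(poses[0]) == net.score(poses[0])


@settings(derandomize=True, max_examples=100)
@given(st.floats(min_value=0.5, max_value=12.0, allow_nan=False),
       st.integers(min_value=1, max_value=64))
def test_bessel_basis_boundary_properties(cutoff, n_basis):
    """For any cutoff and basis count: exact zero at the cutoff and the
    analytic sqrt(2/R_c) limit at d=0."""
    basis = BesselBasis(cutoff=cutoff, n_basis=n_basis)
    assert np.all(basis.values(cutoff) == 0.0)
    assert np.allclose(basis.values(0.0), np.sqrt(2.0 / cutoff), atol=1e-9)
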