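"""Cross-docking curation: superposition, site clustering, capping, splits."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poseranker.crossdock import (BindingSiteCluster, GroupMember,
                                  Superposition, SuperpositionError,
                                  cap_representatives, cluster_binding_sites,
                                  kabsch, ligand_center_of_mass, make_split,
                                  max_boundary_identity, positive_pose_filter,
                                  sequence_identity, superpose_group)
from poseranker.io_model import PoseRecord
from poseranker.synthetic import SyntheticSpec, _random_rotation, gen_poses, gen_target


def _target(seed=0, index=0):
    return gen_target(SyntheticSpec(seed=seed), index)


class TestKabsch:
    def test_recovers_known_rigid_transform(self):
        rng = np.random.default_rng(0)
        points = rng.normal(0, 5, (30, 3))
        R = _random_rotation(rng)
        t = rng.normal(0, 10, 3)
        moved = points @ R.T + t
        transform, rmsd = kabsch(moved, points)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(transform.apply(moved), points, atol=1e-6)
        assert np.allclose(transform.rotation @ R, np.eye(3), atol=1e-6)

    def test_matches_scipy_oracle_on_noisy_point_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(0, 3, (25, 3))
            b = a @ _random_rotation(rng).T + rng.normal(0, 5, 3) \
                + rng.normal(0, 0.5, (25, 3))
            _, rmsd = kabsch(a, b)
            rot, ssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            oracle = np.sqrt(np.mean(np.sum(
                ((a - a.mean(0)) @ rot.as_matrix().T - (b - b.mean(0))) ** 2,
                axis=1)))
            assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_inverse_composition(self):
        rng = np.random.default_rng(2)
        T = Superposition(_random_rotation(rng), rng.normal(0, 5, 3))
        x = rng.normal(0, 3, (10, 3))
        assert np.allclose(T.inverse().apply(T.apply(x)), x, atol=1e-9)


class TestSuperposeGroup:
    def test_group_of_one_is_identity(self):
        target = _target()
        group = superpose_group([("s0", target.receptor)], "T0")
        assert len(group.members) == 1
        member = group.members[0]
        assert member.ca_rmsd == 0.0
        assert np.allclose(member.transform.rotation, np.eye(3))

    def test_rotated_copy_recovered(self):
        rng = np.random.default_rng(3)
        target = _target()
        R = _random_rotation(rng)
        t = rng.normal(0, 20, 3)
        moved = target.receptor.with_coords(target.receptor.coords @ R.T + t)
        group = superpose_group([("ref", target.receptor), ("rot", moved)], "T0")
        member = group.members[1]
        assert member.ca_rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(member.transform.apply(moved.coords),
                           target.receptor.coords, atol=1e-6)

    def test_member_beyond_cap_dropped(self):
        rng = np.random.default_rng(4)
        target = _target()
        coords = target.receptor.coords
        # random independent re-draw: optimal fit RMSD far above 5 A
        scrambled = target.receptor.with_coords(
            coords + rng.normal(0, 8, coords.shape))
        _, check = kabsch(scrambled.coords, coords)
        assert check > 5.0
        group = superpose_group([("ref", target.receptor),
                                 ("bad", scrambled)], "T0")
        assert group.dropped == ("bad",)
        assert len(group.members) == 1

    def test_no_shared_anchors_raises(self):
        a = _target(index=0).receptor
        b = _target(index=1).receptor
        from dataclasses import replace
        b = replace(b, chain_ids=("B",) * len(b.atoms))
        with pytest.raises(SuperpositionError):
            superpose_group([("a", a), ("b", b)], "T0")


def _member_at(com, sid="s"):
    pose = PoseRecord(coords=np.tile(np.asarray(com, dtype=float), (4, 1)),
                      score=0.0, rank=1)
    target = _target()
    return GroupMember(structure_id=sid, receptor=target.receptor,
                       ligand=target.ligand, native_pose=pose,
                       transform=Superposition.identity(), ca_rmsd=0.0)


class TestClusterBindingSites:
    def _group(self, coms):
        from poseranker.crossdock import TargetGroup
        members = tuple(_member_at(c, f"s{i}") for i, c in enumerate(coms))
        return TargetGroup(target_id="T0", members=members)

    def test_four_angstrom_coms_merge(self):
        clusters = cluster_binding_sites(self._group([(0, 0, 0), (4, 0, 0)]))
        assert len(clusters) == 1

    def test_six_angstrom_coms_separate(self):
        clusters = cluster_binding_sites(self._group([(0, 0, 0), (6, 0, 0)]))
        assert len(clusters) == 2

    def test_single_ligand_single_cluster(self):
        clusters = cluster_binding_sites(self._group([(1, 2, 3)]))
        assert len(clusters) == 1 and len(clusters[0].members) == 1

    def test_chaining_transitive_merge(self):
        # 0-4-8: consecutive pairs within eps merge transitively
        clusters = cluster_binding_sites(
            self._group([(0, 0, 0), (4, 0, 0), (8, 0, 0)]))
        assert len(clusters) == 1

    def test_input_order_invariance(self):
        coms = [(0, 0, 0), (4, 0, 0), (20, 0, 0), (26, 0, 0)]
        a = cluster_binding_sites(self._group(coms))
        b = cluster_binding_sites(self._group(coms[::-1]))
        def signature(clusters):
            return sorted(tuple(sorted(np.round(c.centers[:, 0]).astype(int)))
                          for c in clusters)
        assert signature(a) == signature(b)

    def test_com_is_unweighted_mean(self):
        member = _member_at((1.0, 2.0, 3.0))
        assert np.allclose(ligand_center_of_mass(member), [1.0, 2.0, 3.0])


class TestCapRepresentatives:
    def _cluster(self, n):
        members = tuple(_member_at((i, 0, 0), f"s{i}") for i in range(n))
        return BindingSiteCluster(cluster_id=0, members=members,
                                  centers=np.zeros((n, 3)))

    def test_small_cluster_untouched(self):
        capped = cap_representatives(self._cluster(3), seed=0)
        assert len(capped.members) == 3

    def test_deterministic_for_seed(self):
        cluster = self._cluster(100)
        a = cap_representatives(cluster, seed=9)
        b = cap_representatives(cluster, seed=9)
        assert [m.structure_id for m in a.members] == \
               [m.structure_id for m in b.members]
        assert len(a.members) == 5

    def test_selection_is_uniform_over_seeds(self):
        cluster = self._cluster(100)
        counts = np.zeros(100)
        n_seeds = 400
        for seed in range(n_seeds):
            capped = cap_representatives(cluster, seed=seed)
            for m in capped.members:
                counts[int(m.structure_id[1:])] += 1
        freqs = counts / n_seeds
        assert freqs.mean() == pytest.approx(0.05, abs=1e-9)
        assert np.all(np.abs(freqs - 0.05) < 0.04)


class TestPositivePoseFilter:
    def test_hand_counted_retention(self):
        spec = SyntheticSpec(seed=6, n_poses=12)
        target = gen_target(spec, 0)
        rng = np.random.default_rng(0)
        with_hit = gen_poses(target, spec, rng=rng, counts=(1, 1, 10))
        no_hit = gen_poses(target, spec, rng=rng, counts=(0, 2, 10))
        attempts = {"a1": with_hit, "a2": no_hit,
                    "a3": gen_poses(target, spec, rng=rng, counts=(2, 0, 10)),
                    "a4": gen_poses(target, spec, rng=rng, counts=(0, 0, 12))}
        kept = positive_pose_filter(attempts)
        assert set(kept) == {"a1", "a3"}

    def test_labels_untouched(self):
        spec = SyntheticSpec(seed=6, n_poses=8)
        target = gen_target(spec, 0)
        poses = gen_poses(target, spec, counts=(1, 1, 6))
        before = [ex.label for ex in poses]
        positive_pose_filter({"a": poses})
        assert [ex.label for ex in poses] == before


class TestMakeSplit:
    def test_shared_uniprot_colocated(self):
        targets = {f"T{i}": "" for i in range(8)}
        uniprot = {f"T{i}": f"U{i // 2}" for i in range(8)}
        split = make_split(targets, "uniprot", seed=0, uniprot_of=uniprot)
        for i in range(0, 8, 2):
            assert split.side(f"T{i}") == split.side(f"T{i+1}")

    def test_similar_sequences_colocated(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
        similar = base[:5] + "G" + base[6:]  # ~98% identical
        different = "GG" + base[::-1][:-2]
        targets = {"A": base, "B": similar, "C": different}
        split = make_split(targets, "seqsim70", seed=1)
        assert split.side("A") == split.side("B")

    def test_boundary_identity_below_threshold(self):
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        targets = {f"T{i}": "".join(rng.choice(aas, size=50)) for i in range(6)}
        split = make_split(targets, "seqsim70", seed=0)
        sides = set(split.assignment.values())
        if len(sides) == 2:
            assert max_boundary_identity(targets, split) < 0.70

    def test_identity_measure_basics(self):
        assert sequence_identity("AAAA", "AAAA") == 1.0
        assert sequence_identity("AAAA", "AATA") == 0.75

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_split({"A": ""}, "bogus")


class TestArtifactWriters:
    def test_groups_json_roundtrips(self, tmp_path):
        import json
        from poseranker.crossdock import write_groups_json
        target = _target()
        group = superpose_group([("s0", target.receptor)], "T0",
                                ligands=[(target.ligand, target.native_pose)])
        clusters = cluster_binding_sites(group)
        path = tmp_path / "groups.json"
        write_groups_json({"T0": (group, clusters)}, path)
        data = json.loads(path.read_text())
        assert data["T0"]["members"][0]["structure_id"] == "s0"
        assert np.allclose(data["T0"]["members"][0]["rotation"], np.eye(3))
        assert len(data["T0"]["clusters"]) == 1

    def test_split_csv(self, tmp_path):
        import pandas as pd
        from poseranker.crossdock import write_split_csv
        split = make_split({"A": "", "B": ""}, "uniprot", seed=3,
                           uniprot_of={"A": "U1", "B": "U1"})
        path = tmp_path / "split.csv"
        write_split_csv(split, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["target_id", "side", "kind", "seed"]
        assert set(df["side"]) <= {"train", "test"}
        assert (df["seed"] == 3).all()
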