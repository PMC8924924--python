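"""Symmetry-corrected RMSD and the hit/gap/miss labeling rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from poseranker.io_model import GAP, HIT, MISS
from poseranker.crossdock import Superposition
from poseranker.poselabel import (MatchingError, automorphisms, crossdock_rmsd,
                                  label_pose, label_record, symmetry_rmsd)
from poseranker.synthetic import _random_rotation
from .conftest import make_benzene, random_topology


def rdkit_automorphisms(topology):
    """Independent oracle: self-substructure matches of an RDKit molecule."""
    mol = Chem.RWMol()
    for atom in topology.atoms:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    order_map = {"1": Chem.BondType.SINGLE, "2": Chem.BondType.DOUBLE,
                 "3": Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}
    for i, j, order in topology.bonds:
        mol.AddBond(i, j, order_map[order])
    m = mol.GetMol()
    matches = m.GetSubstructMatches(m, uniquify=False, maxMatches=100000)
    return np.array(matches, dtype=np.int64)


def permutation_automorphisms(topology):
    """Second oracle for tiny molecules: filter all permutations."""
    n = len(topology.atoms)
    elements = [a.element for a in topology.atoms]
    bond_map = {}
    for i, j, order in topology.bonds:
        bond_map[frozenset((i, j))] = order
    perms = []
    for perm in itertools.permutations(range(n)):
        if any(elements[perm[i]] != elements[i] for i in range(n)):
            continue
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                a = bond_map.get(frozenset((i, j)))
                b = bond_map.get(frozenset((perm[i], perm[j])))
                if a != b:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            perms.append(perm)
    return np.array(perms, dtype=np.int64)


class TestLabelPose:
    @pytest.mark.parametrize("rmsd,expected", [
        (0.0, HIT), (2.5, HIT), (2.50001, GAP), (4.0, GAP), (4.1, MISS),
        (100.0, MISS)])
    def test_boundaries(self, rmsd, expected):
        assert label_pose(rmsd) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            label_pose(-0.1)

    def test_partition_has_no_holes(self):
        rng = np.random.default_rng(0)
        for rmsd in rng.uniform(0, 10, 200):
            assert label_pose(rmsd) in (HIT, GAP, MISS)


class TestSymmetryRmsd:
    def test_identical_coords(self, benzene):
        topo, coords = benzene
        rmsd, _ = symmetry_rmsd(coords, coords, topo)
        assert rmsd == 0.0

    def test_uniform_translation(self, benzene):
        topo, coords = benzene
        rmsd, _ = symmetry_rmsd(coords + np.array([3.0, 0, 0]), coords, topo)
        assert rmsd == pytest.approx(3.0, abs=1e-12)

    def test_benzene_ring_rotation_is_symmetric(self):
        topo, coords = make_benzene()
        _, rotated = make_benzene(rotate_deg=60.0)
        rmsd, _ = symmetry_rmsd(rotated, coords, topo)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        identity_rmsd = np.sqrt(np.mean(np.sum((rotated - coords) ** 2, axis=1)))
        assert identity_rmsd > 1.0

    def test_benzene_has_twelve_automorphisms(self, benzene):
        topo, _ = benzene
        assert len(automorphisms(topo)) == 12

    def test_atom_count_mismatch(self, benzene):
        topo, coords = benzene
        with pytest.raises(MatchingError):
            symmetry_rmsd(coords[:5], coords, topo)

    def test_never_exceeds_identity_mapping(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            topo = random_topology(rng, int(rng.integers(5, 12)))
            native = topo.coords
            pose = native + rng.normal(0, 2, native.shape)
            rmsd, _ = symmetry_rmsd(pose, native, topo)
            identity = np.sqrt(np.mean(np.sum((pose - native) ** 2, axis=1)))
            assert rmsd <= identity + 1e-12

    def test_invariant_under_automorphic_relabeling(self):
        rng = np.random.default_rng(2)
        topo, coords = make_benzene()
        perms = automorphisms(topo)
        pose = coords + rng.normal(0, 1.5, coords.shape)
        base, _ = symmetry_rmsd(pose, coords, topo)
        for perm in perms[:6]:
            relabeled, _ = symmetry_rmsd(pose[perm], coords, topo)
            assert relabeled == pytest.approx(base, abs=1e-9)

    def test_oracle_equivalence_on_random_molecules(self):
        """Matches exhaustive automorphism enumeration (two oracles) on 30
        random molecules of up to 12 heavy atoms."""
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            topo = random_topology(rng, n)
            native = topo.coords
            pose = native + rng.normal(0, 1.0, native.shape)
            rmsd, _ = symmetry_rmsd(pose, native, topo)
            oracle_perms = rdkit_automorphisms(topo)
            diffs = pose[None, :, :] - native[oracle_perms]
            oracle = np.min(np.sqrt(np.mean(np.sum(diffs ** 2, axis=2), axis=1)))
            assert rmsd == pytest.approx(oracle, abs=1e-12)
            if n <= 7:
                perms2 = permutation_automorphisms(topo)
                diffs2 = pose[None, :, :] - native[perms2]
                oracle2 = np.min(np.sqrt(np.mean(np.sum(diffs2 ** 2, axis=2),
                                                 axis=1)))
                assert rmsd == pytest.approx(oracle2, abs=1e-12)

    def test_label_record_consistency(self, benzene):
        topo, coords = benzene
        rec = label_record(coords + 3.0, coords, topo)
        assert rec.label == label_pose(rec.rmsd)


class TestCrossdockRmsd:
    def test_identity_transform_equals_symmetry_rmsd(self, benzene):
        topo, coords = benzene
        pose = coords + np.array([1.0, 0, 0])
        direct, _ = symmetry_rmsd(pose, coords, topo)
        crossed, _ = crossdock_rmsd(pose, coords, topo, Superposition.identity())
        assert crossed == pytest.approx(direct, abs=1e-12)

    def test_transformed_native_matches_transformed_pose(self, benzene):
        topo, coords = benzene
        rng = np.random.default_rng(4)
        R = _random_rotation(rng)
        t = rng.normal(0, 5, 3)
        T = Superposition(R, t)
        rmsd, _ = crossdock_rmsd(T.apply(coords), coords, topo, T)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_offset_recovered(self):
        rng = np.random.default_rng(5)
        topo = random_topology(rng, 9)
        coords = topo.coords
        R = _random_rotation(rng)
        t = rng.normal(0, 5, 3)
        T = Superposition(R, t)
        delta = np.array([0.0, 2.0, 0.0])
        pose = T.apply(coords) + delta
        rmsd, _ = crossdock_rmsd(pose, coords, topo, T)
        # the offset shifts every atom equally, so RMSD equals its length,
        # unless a nontrivial automorphism does even better
        assert rmsd <= 2.0 + 1e-9
        assert rmsd == pytest.approx(2.0, abs=1e-6)

    def test_missing_transform_errors(self, benzene):
        topo, coords = benzene
        with pytest.raises(MatchingError):
            crossdock_rmsd(coords, coords, topo, None)


def test_label_table_writer(tmp_path):
    import pandas as pd
    from poseranker.poselabel import write_label_table
    rows = [("T0:c0", "p000", 1.2, "hit"), ("T0:c0", "p001", 6.0, "miss")]
    path = tmp_path / "labels.csv"
    write_label_table(rows, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["attempt_id", "pose_id", "rmsd", "label"]
    assert len(df) == 2


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
def test_labels_partition_the_rmsd_axis(rmsd):
    """Every non-negative RMSD gets exactly one label, consistent with the
    2.5 / 4 Å thresholds."""
    label = label_pose(rmsd)
    if rmsd <= 2.5:
        assert label == HIT
    elif rmsd > 4.0:
        assert label == MISS
    else:
        assert label == GAP
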