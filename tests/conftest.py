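import numpy as np
import pytest

from poseranker.io_model import (AtomRecord, ComplexExample, LIGAND,
                                 LigandTopology, PoseRecord, RECEPTOR,
                                 ReceptorStructure)
from poseranker.synthetic import SyntheticSpec, gen_poses, gen_target


def make_benzene(rotate_deg: float = 0.0) -> tuple[LigandTopology, np.ndarray]:
    """Benzene ring (C.ar x6, aromatic bonds) in the xy plane."""
    angles = np.deg2rad(np.arange(6) * 60.0 + rotate_deg)
    coords = np.stack([1.396 * np.cos(angles), 1.396 * np.sin(angles),
                       np.zeros(6)], axis=1)
    atoms = tuple(AtomRecord(index=i, element="C", sybyl_type="C.ar",
                             coords=tuple(c), entity=LIGAND)
                  for i, c in enumerate(coords))
    bonds = tuple((i, (i + 1) % 6, "ar") for i in range(6))
    return LigandTopology(atoms=atoms, bonds=bonds), coords


@pytest.fixture
def benzene():
    return make_benzene()


def random_topology(rng: np.random.Generator, n_atoms: int) -> LigandTopology:
    """Random connected molecule (tree + occasional ring closure)."""
    elements = ["C", "C", "C", "N", "O"]
    coords = np.zeros((n_atoms, 3))
    bonds = []
    for i in range(1, n_atoms):
        parent = int(rng.integers(i))
        direction = rng.normal(size=3)
        coords[i] = coords[parent] + 1.5 * direction / np.linalg.norm(direction)
        bonds.append((parent, i, str(rng.choice(["1", "2"]))))
    if n_atoms >= 4 and rng.random() < 0.5:
        i, j = sorted(rng.choice(n_atoms, size=2, replace=False))
        if not any({a, b} == {i, j} for a, b, _ in bonds):
            bonds.append((int(i), int(j), "1"))
    atoms = tuple(AtomRecord(index=i, element=str(rng.choice(elements)),
                             sybyl_type="C.3", coords=tuple(coords[i]),
                             entity=LIGAND)
                  for i in range(n_atoms))
    return LigandTopology(atoms=atoms, bonds=tuple(bonds))


def tiny_complex(rng: np.random.Generator, n_lig: int = 8,
                 n_rec: int = 20) -> ComplexExample:
    """Small random complex for invariance checks."""
    topo = random_topology(rng, n_lig)
    pose = PoseRecord(coords=topo.coords + rng.normal(0, 0.1, (n_lig, 3)),
                      score=0.0, rank=1)
    rec_coords = rng.normal(0, 4.0, (n_rec, 3))
    rec_types = [str(rng.choice(["C.3", "C.ar", "N.am", "O.2", "O.3"]))
                 for _ in range(n_rec)]
    atoms = tuple(AtomRecord(index=i, element=t.split(".")[0], sybyl_type=t,
                             coords=tuple(c), entity=RECEPTOR)
                  for i, (t, c) in enumerate(zip(rec_types, rec_coords)))
    receptor = ReceptorStructure(
        atoms=atoms, chain_ids=("A",) * n_rec,
        res_names=("GC3",) * n_rec, res_seqs=tuple(range(1, n_rec + 1)),
        atom_names=tuple(t.split(".")[0] for t in rec_types))
    return ComplexExample(receptor=receptor, ligand=topo, pose=pose)


@pytest.fixture
def small_target():
    spec = SyntheticSpec(seed=5, n_poses=24)
    return gen_target(spec, 0), spec


@pytest.fixture
def small_attempt(small_target):
    target, spec = small_target
    rng = np.random.default_rng(17)
    return target, gen_poses(target, spec, rng=rng, counts=(4, 4, 16))
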