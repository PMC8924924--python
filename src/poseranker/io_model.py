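"""Domain types and structure IO for protein-ligand pose examples.

The atomic unit of training and evaluation is a :class:`ComplexExample`: one
receptor conformation, one ligand topology, one docked pose, and a hit/gap/
miss label plus provenance metadata.  Receptors travel as PDB (read with
gemmi), ligands and poses as Mol2 (SYBYL dialect) or SDF (read with RDKit).
Only heavy atoms are ever represented; hydrogens are dropped on ingestion.
Coordinates are Angstrom throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .sybyl import (PSEUDO_RESIDUES, SybylVocabulary, collapse_metal,
                    is_buffer, is_water, type_protein_atom)

RDLogger.DisableLog("rdApp.*")

LIGAND = "ligand"
RECEPTOR = "receptor"

#: Default margin (Å) added around the ligand bounding box when truncating the
#: receptor to a pocket for network input.
POCKET_MARGIN = 8.0


class FormatError(ValueError):
    """Input file could not be parsed in the expected format."""


class EmptyStructureError(ValueError):
    """A structure or selection contains no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with its SYBYL chemical-environment type."""

    index: int
    element: str
    sybyl_type: str
    coords: tuple[float, float, float]
    entity: str  # LIGAND or RECEPTOR
    is_metal: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.element in ("H", "D"):
            raise ValueError("hydrogens are not represented")


@dataclass(frozen=True)
class LigandTopology:
    """Ligand heavy atoms plus covalent bonds.

    Bonds are used only for symmetry-aware RMSD matching; the network itself
    never sees covalent structure.
    """

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, str], ...]  # (i, j, order); order "1","2","3","ar"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond references a missing atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g


@dataclass(frozen=True)
class ReceptorStructure:
    """Receptor heavy atoms with chain/residue annotations and retained metals."""

    atoms: tuple[AtomRecord, ...]
    chain_ids: tuple[str, ...]
    res_names: tuple[str, ...]
    res_seqs: tuple[int, ...]
    atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.atoms) == len(self.chain_ids) == len(self.res_names)
                == len(self.res_seqs) == len(self.atom_names)):
            raise ValueError("annotation arrays must parallel the atom list")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "ReceptorStructure":
        atoms = tuple(replace(a, coords=tuple(c)) for a, c in zip(self.atoms, coords))
        return replace(self, atoms=atoms)


@dataclass(frozen=True)
class PoseRecord:
    """One docked placement of a ligand: coordinates, score and rank."""

    coords: np.ndarray  # (n_atoms, 3)
    score: float
    rank: int
    receptor_conf_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("pose coordinates must be (n, 3)")
        if self.rank < 1:
            raise ValueError("docking rank starts at 1")


HIT, GAP, MISS, UNLABELED = "hit", "gap", "miss", "unlabeled"


@dataclass(frozen=True)
class ComplexExample:
    """Receptor conformation + ligand pose + label + provenance."""

    receptor: ReceptorStructure
    ligand: LigandTopology
    pose: PoseRecord
    label: str = UNLABELED
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pose.coords.shape[0] != len(self.ligand.atoms):
            raise ValueError("pose coordinate count must equal ligand atom count")
        if self.label not in (HIT, GAP, MISS, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")


# ---------------------------------------------------------------------------
# Receptor IO


def _best_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer of each alternate-location group."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return list(chosen.values())


def read_receptor(path: str | Path) -> ReceptorStructure:
    """Read a receptor PDB file.

    Waters and common crystallographic buffer molecules are dropped, hydrogens
    are dropped, whitelisted metal ions (Na, Fe, Mg, K, Mn, Zn, Ca) are
    retained, and every retained atom is assigned a SYBYL type from the
    residue-template table.
    """
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from None
    if len(structure) == 0:
        raise FormatError(f"no models in {path}")
    model = structure[0]

    atoms: list[AtomRecord] = []
    chain_ids: list[str] = []
    res_names: list[str] = []
    res_seqs: list[int] = []
    atom_names: list[str] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            if is_water(resname) or is_buffer(resname):
                continue
            info = gemmi.find_tabulated_residue(resname)
            is_polymer = ((info is not None and info.is_amino_acid())
                          or resname in PSEUDO_RESIDUES)
            for atom in _best_altloc(residue):
                element = atom.element.name
                if element in ("H", "D"):
                    continue
                metal = collapse_metal(element)
                if not is_polymer and metal is None:
                    # Hetero group: keep whitelisted metal ions only.
                    continue
                sybyl = type_protein_atom(resname, atom.name, element)
                atoms.append(AtomRecord(
                    index=len(atoms), element=element, sybyl_type=sybyl,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    entity=RECEPTOR, is_metal=metal is not None))
                chain_ids.append(chain.name)
                res_names.append(resname)
                res_seqs.append(residue.seqid.num)
                atom_names.append(atom.name)
    if not atoms:
        raise EmptyStructureError(f"no protein atoms in {path}")
    return ReceptorStructure(tuple(atoms), tuple(chain_ids), tuple(res_names),
                             tuple(res_seqs), tuple(atom_names))


def write_receptor(receptor: ReceptorStructure, path: str | Path) -> None:
    """Write a receptor to PDB via gemmi (inverse of :func:`read_receptor`)."""
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for atom, cid, rname, rseq, aname in zip(
            receptor.atoms, receptor.chain_ids, receptor.res_names,
            receptor.res_seqs, receptor.atom_names):
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        key = (cid, rseq, rname)
        if key not in residues:
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(rseq, " ")
            if atom.is_metal or rname not in ("ALA", "ARG", "ASN", "ASP", "CYS",
                                              "GLN", "GLU", "GLY", "HIS", "ILE",
                                              "LEU", "LYS", "MET", "PHE", "PRO",
                                              "SER", "THR", "TRP", "TYR", "VAL"):
                res.het_flag = "H"
            else:
                res.het_flag = "A"
            # add_residue copies; keep the returned reference for atom adds
            residues[key] = chains[cid].add_residue(res)
        g_atom = gemmi.Atom()
        g_atom.name = aname
        g_atom.element = gemmi.Element(atom.element)
        g_atom.pos = gemmi.Position(*atom.coords)
        g_atom.occ = 1.0
        residues[key].add_atom(g_atom)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Ligand IO

_BOND_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "ar",
}
_BOND_ORDER_TO_RDKIT = {v: k for k, v in _BOND_ORDER_FROM_RDKIT.items()}

SYBYL_PROP = "sybyl_types"  # SDF property carrying space-separated SYBYL types


def sybyl_type_from_rdkit_atom(atom: Chem.Atom) -> str:
    """Derive a SYBYL type from element, aromaticity and hybridization."""
    el = atom.GetSymbol()
    metal = collapse_metal(el)
    if metal is not None:
        return metal
    if el in ("F", "Cl", "Br", "I"):
        return el
    if atom.GetIsAromatic():
        if el in ("C", "N"):
            return f"{el}.ar"
    hyb = atom.GetHybridization()
    if el == "C":
        if hyb == Chem.HybridizationType.SP:
            return "C.1"
        if hyb == Chem.HybridizationType.SP2:
            # Guanidinium-like carbons get the cation type.
            if atom.GetFormalCharge() > 0:
                return "C.cat"
            return "C.2"
        return "C.3"
    if el == "N":
        if atom.GetFormalCharge() > 0 and hyb == Chem.HybridizationType.SP3:
            return "N.4"
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            if other.GetSymbol() == "C":
                for b2 in other.GetBonds():
                    if (b2.GetBondType() == Chem.BondType.DOUBLE
                            and b2.GetOtherAtom(other).GetSymbol() == "O"):
                        return "N.am"
        if hyb == Chem.HybridizationType.SP:
            return "N.1"
        if hyb == Chem.HybridizationType.SP2:
            return "N.2"
        return "N.3"
    if el == "O":
        if hyb == Chem.HybridizationType.SP2:
            return "O.2"
        if atom.GetFormalCharge() < 0:
            return "O.co2"
        return "O.3"
    if el == "S":
        n_o = sum(1 for b in atom.GetBonds()
                  if b.GetOtherAtom(atom).GetSymbol() == "O")
        if n_o >= 2:
            return "S.o2"
        if n_o == 1:
            return "S.o"
        if hyb == Chem.HybridizationType.SP2:
            return "S.2"
        return "S.3"
    if el == "P":
        return "P.3"
    return el


def _topology_from_rdkit(mol: Chem.Mol, sybyl_types: list[str]) -> LigandTopology:
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(AtomRecord(
            index=atom.GetIdx(), element=atom.GetSymbol(),
            sybyl_type=sybyl_types[atom.GetIdx()],
            coords=(pos.x, pos.y, pos.z), entity=LIGAND,
            is_metal=collapse_metal(atom.GetSymbol()) is not None))
    bonds = []
    for bond in mol.GetBonds():
        order = _BOND_ORDER_FROM_RDKIT.get(bond.GetBondType(), "1")
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return LigandTopology(tuple(atoms), tuple(bonds))


def _strip_hydrogens(mol: Chem.Mol) -> Chem.Mol:
    try:
        return Chem.RemoveHs(mol, sanitize=False)
    except Exception:
        return mol


def read_ligand(path: str | Path) -> tuple[LigandTopology, list[PoseRecord]]:
    """Read a ligand from Mol2 or SDF.

    Returns the (heavy-atom) topology and one :class:`PoseRecord` per
    conformer/record in the file.  SYBYL types come from the Mol2 atom block
    when available, from the ``sybyl_types`` SDF property if present, and are
    otherwise derived from the RDKit molecule.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise FormatError(f"cannot parse Mol2 file {path}")
        types_by_name = {}
        heavy = []
        for atom in mol.GetAtoms():
            if atom.GetSymbol() in ("H", "D"):
                continue
            heavy.append(atom.GetIdx())
            t = (atom.GetPropsAsDict().get("_TriposAtomType")
                 or sybyl_type_from_rdkit_atom(atom))
            types_by_name[atom.GetIdx()] = t
        mol_noh = _strip_hydrogens(mol)
        if mol_noh.GetNumAtoms() != len(heavy):
            raise FormatError(f"hydrogen stripping failed for {path}")
        sybyl = [types_by_name[idx] for idx in heavy]
        topo = _topology_from_rdkit(mol_noh, sybyl)
        pose = PoseRecord(coords=topo.coords, score=0.0, rank=1)
        return topo, [pose]
    if suffix in (".sdf", ".sd", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=False)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise FormatError(f"cannot parse SDF file {path}")
        first = mols[0]
        if first.HasProp(SYBYL_PROP):
            sybyl = first.GetProp(SYBYL_PROP).split()
            if len(sybyl) != first.GetNumAtoms():
                raise FormatError(f"bad {SYBYL_PROP} property in {path}")
        else:
            try:
                Chem.SanitizeMol(first)
            except Exception:
                pass
            sybyl = [sybyl_type_from_rdkit_atom(a) for a in first.GetAtoms()]
        topo = _topology_from_rdkit(first, sybyl)
        poses = []
        for k, m in enumerate(mols):
            if m.GetNumAtoms() != first.GetNumAtoms():
                raise FormatError(f"record {k} in {path} has a different atom count")
            conf = m.GetConformer()
            coords = np.array([[conf.GetAtomPosition(i).x,
                                conf.GetAtomPosition(i).y,
                                conf.GetAtomPosition(i).z]
                               for i in range(m.GetNumAtoms())])
            score = float(m.GetProp("docking_score")) if m.HasProp("docking_score") else 0.0
            rank = int(m.GetProp("docking_rank")) if m.HasProp("docking_rank") else k + 1
            conf_id = m.GetProp("receptor_conf_id") if m.HasProp("receptor_conf_id") else ""
            poses.append(PoseRecord(coords=coords, score=score, rank=rank,
                                    receptor_conf_id=conf_id))
        return topo, poses
    raise FormatError(f"unsupported ligand format: {path}")


def write_ligand(topology: LigandTopology, poses: list[PoseRecord],
                 path: str | Path) -> None:
    """Write a ligand and its poses as a multi-record SDF.

    SYBYL types, docking scores/ranks and receptor conformation ids are stored
    as SDF properties so that :func:`read_ligand` round-trips them.
    """
    mol = Chem.RWMol()
    for atom in topology.atoms:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    for i, j, order in topology.bonds:
        mol.AddBond(i, j, _BOND_ORDER_TO_RDKIT[order])
    base = mol.GetMol()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    sybyl = " ".join(a.sybyl_type for a in topology.atoms)
    for pose in poses:
        m = Chem.Mol(base)
        conf = Chem.Conformer(m.GetNumAtoms())
        for idx, xyz in enumerate(pose.coords):
            conf.SetAtomPosition(idx, [float(x) for x in xyz])
        m.AddConformer(conf)
        m.SetProp(SYBYL_PROP, sybyl)
        m.SetProp("docking_score", repr(float(pose.score)))
        m.SetProp("docking_rank", str(pose.rank))
        if pose.receptor_conf_id:
            m.SetProp("receptor_conf_id", pose.receptor_conf_id)
        writer.write(m)
    writer.close()


# ---------------------------------------------------------------------------
# Selection and featurization


class EmptySelectionError(ValueError):
    """A spatial selection matched no atoms."""


def select_pocket(receptor: ReceptorStructure,
                  box: tuple[np.ndarray, np.ndarray],
                  buffer: float = 0.0) -> ReceptorStructure:
    """Receptor atoms inside an axis-aligned box expanded by ``buffer`` Å.

    The boundary is closed: an atom exactly on the expanded face is included.
    """
    lo = np.asarray(box[0], dtype=float) - buffer
    hi = np.asarray(box[1], dtype=float) + buffer
    if np.any(hi < lo):
        raise ValueError("degenerate box")
    coords = receptor.coords
    mask = np.all((coords >= lo) & (coords <= hi), axis=1)
    if not mask.any():
        raise EmptySelectionError("no receptor atoms in the requested region")
    idx = np.flatnonzero(mask)
    atoms = tuple(replace(receptor.atoms[i], index=k) for k, i in enumerate(idx))
    return ReceptorStructure(
        atoms,
        tuple(receptor.chain_ids[i] for i in idx),
        tuple(receptor.res_names[i] for i in idx),
        tuple(receptor.res_seqs[i] for i in idx),
        tuple(receptor.atom_names[i] for i in idx))


def encode_onehot(atom: AtomRecord, vocab: SybylVocabulary) -> np.ndarray:
    """One-hot feature vector for an atom (disjoint ligand/receptor blocks)."""
    return vocab.encode(atom.sybyl_type, atom.entity)


def assemble_atoms(example: ComplexExample,
                   pocket_margin: float | None = POCKET_MARGIN,
                   ) -> tuple[np.ndarray, np.ndarray, list[AtomRecord]]:
    """Flatten a complex into network-input arrays.

    Receptor atoms are truncated by default to those within ``pocket_margin``
    Å of any ligand-pose atom (pass ``None`` to keep the full receptor); a
    distance criterion keeps the atom set — and hence the logit — invariant
    under rigid motion of the complex.  Returns ``(coords (A,3),
    is_ligand (A,) bool, atoms)`` with ligand atoms first in topology order,
    then receptor atoms.
    """
    pose_coords = example.pose.coords
    receptor = example.receptor
    if pocket_margin is not None and len(receptor.atoms):
        from scipy.spatial import cKDTree

        d_min, _ = cKDTree(pose_coords).query(receptor.coords, k=1)
        idx = np.flatnonzero(d_min <= pocket_margin)
        if len(idx) == 0:
            receptor = ReceptorStructure((), (), (), (), ())
        else:
            atoms = tuple(replace(receptor.atoms[i], index=k)
                          for k, i in enumerate(idx))
            receptor = ReceptorStructure(
                atoms,
                tuple(receptor.chain_ids[i] for i in idx),
                tuple(receptor.res_names[i] for i in idx),
                tuple(receptor.res_seqs[i] for i in idx),
                tuple(receptor.atom_names[i] for i in idx))
    lig_atoms = [replace(a, coords=tuple(c))
                 for a, c in zip(example.ligand.atoms, pose_coords)]
    rec_atoms = list(receptor.atoms)
    coords = np.vstack([pose_coords, receptor.coords]) if rec_atoms else pose_coords
    is_ligand = np.zeros(len(lig_atoms) + len(rec_atoms), dtype=bool)
    is_ligand[:len(lig_atoms)] = True
    return coords, is_ligand, lig_atoms + rec_atoms


def assemble_arrays(example: ComplexExample,
                    pocket_margin: float | None = POCKET_MARGIN,
                    ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Lightweight variant of :func:`assemble_atoms` for featurization.

    Returns ``(coords, is_ligand, sybyl_types, entities)`` without
    constructing per-atom records; same truncation rule.
    """
    pose_coords = example.pose.coords
    receptor = example.receptor
    rec_coords = receptor.coords if receptor.atoms else np.zeros((0, 3))
    if pocket_margin is not None and len(rec_coords):
        from scipy.spatial import cKDTree

        d_min, _ = cKDTree(pose_coords).query(rec_coords, k=1)
        idx = np.flatnonzero(d_min <= pocket_margin)
    else:
        idx = np.arange(len(rec_coords))
    n_lig = len(example.ligand.atoms)
    coords = np.vstack([pose_coords, rec_coords[idx]]) if len(idx) \
        else np.asarray(pose_coords)
    is_ligand = np.zeros(n_lig + len(idx), dtype=bool)
    is_ligand[:n_lig] = True
    types = [a.sybyl_type for a in example.ligand.atoms] + \
            [receptor.atoms[i].sybyl_type for i in idx]
    entities = [LIGAND] * n_lig + [RECEPTOR] * len(idx)
    return coords, is_ligand, types, entities


# ---------------------------------------------------------------------------
# Manifest (JSON-lines, one ComplexExample per line, coordinates by file ref)


def write_manifest(entries: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for entry in entries:
            fh.write(json.dumps(entry) + "\n")


def read_manifest(path: str | Path) -> list[dict]:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                entries.append(json.loads(line))
    return entries


def load_examples(manifest_path: str | Path) -> list[ComplexExample]:
    """Materialize :class:`ComplexExample` objects from a JSON-lines manifest.

    Each entry references a receptor PDB and a ligand SDF/Mol2 by path
    (relative to the manifest) plus a pose index within the ligand file.
    Receptor and ligand files are cached across entries.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    receptors: dict[str, ReceptorStructure] = {}
    ligands: dict[str, tuple[LigandTopology, list[PoseRecord]]] = {}
    examples = []
    for entry in read_manifest(manifest_path):
        rpath = str(root / entry["receptor_file"])
        lpath = str(root / entry["ligand_file"])
        if rpath not in receptors:
            receptors[rpath] = read_receptor(rpath)
        if lpath not in ligands:
            ligands[lpath] = read_ligand(lpath)
        topo, poses = ligands[lpath]
        pose = poses[entry.get("pose_index", 0)]
        meta = {k: v for k, v in entry.items()
                if k not in ("receptor_file", "ligand_file", "pose_index", "label")}
        examples.append(ComplexExample(
            receptor=receptors[rpath], ligand=topo, pose=pose,
            label=entry.get("label", UNLABELED), metadata=meta))
    return examples
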