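"""SYBYL atom typing tables and the one-hot vocabulary.

Receptor atoms read from PDB files are typed through a fixed residue-template
lookup (standard amino acids plus whitelisted metal ions), which keeps typing
deterministic and dependency-free.  Ligand atoms carry SYBYL types from Mol2
input or are derived from an RDKit molecule.  All metals collapse to a single
``Met`` type, and ligand/receptor types occupy disjoint one-hot blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Metal elements retained on receptor ingestion; everything else inorganic is dropped.
METAL_WHITELIST = frozenset({"Na", "Fe", "Mg", "K", "Mn", "Zn", "Ca"})

#: The single collapsed SYBYL type used for every retained metal.
METAL_TYPE = "Met"

#: Reserved fallback type for out-of-vocabulary atoms (opt-in).
OTHER_TYPE = "other"

# Backbone typing shared by all standard residues.  OXT covers the C-terminus.
_BACKBONE = {"N": "N.am", "CA": "C.3", "C": "C.2", "O": "O.2", "OXT": "O.co2"}

# Side-chain atom name -> SYBYL type, per standard residue.
_SIDECHAINS: dict[str, dict[str, str]] = {
    "ALA": {"CB": "C.3"},
    "ARG": {"CB": "C.3", "CG": "C.3", "CD": "C.3", "NE": "N.pl3",
            "CZ": "C.cat", "NH1": "N.pl3", "NH2": "N.pl3"},
    "ASN": {"CB": "C.3", "CG": "C.2", "OD1": "O.2", "ND2": "N.am"},
    "ASP": {"CB": "C.3", "CG": "C.2", "OD1": "O.co2", "OD2": "O.co2"},
    "CYS": {"CB": "C.3", "SG": "S.3"},
    "GLN": {"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.2", "NE2": "N.am"},
    "GLU": {"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.co2", "OE2": "O.co2"},
    "GLY": {},
    "HIS": {"CB": "C.3", "CG": "C.ar", "ND1": "N.ar", "CD2": "C.ar",
            "CE1": "C.ar", "NE2": "N.ar"},
    "ILE": {"CB": "C.3", "CG1": "C.3", "CG2": "C.3", "CD1": "C.3"},
    "LEU": {"CB": "C.3", "CG": "C.3", "CD1": "C.3", "CD2": "C.3"},
    "LYS": {"CB": "C.3", "CG": "C.3", "CD": "C.3", "CE": "C.3", "NZ": "N.4"},
    "MET": {"CB": "C.3", "CG": "C.3", "SD": "S.3", "CE": "C.3"},
    "PHE": {"CB": "C.3", "CG": "C.ar", "CD1": "C.ar", "CD2": "C.ar",
            "CE1": "C.ar", "CE2": "C.ar", "CZ": "C.ar"},
    "PRO": {"CB": "C.3", "CG": "C.3", "CD": "C.3"},
    "SER": {"CB": "C.3", "OG": "O.3"},
    "THR": {"CB": "C.3", "OG1": "O.3", "CG2": "C.3"},
    "TRP": {"CB": "C.3", "CG": "C.ar", "CD1": "C.ar", "CD2": "C.ar",
            "NE1": "N.ar", "CE2": "C.ar", "CE3": "C.ar", "CZ2": "C.ar",
            "CZ3": "C.ar", "CH2": "C.ar"},
    "TYR": {"CB": "C.3", "CG": "C.ar", "CD1": "C.ar", "CD2": "C.ar",
            "CE1": "C.ar", "CE2": "C.ar", "CZ": "C.ar", "OH": "O.3"},
    "VAL": {"CB": "C.3", "CG1": "C.3", "CG2": "C.3"},
}

# Pseudo-atom residues used by the synthetic generator: each three-letter code
# carries exactly one typed heavy atom, so synthetic receptors survive a PDB
# round trip with their SYBYL types intact.
PSEUDO_RESIDUES: dict[str, tuple[str, str]] = {
    "GC3": ("C", "C.3"),
    "GCR": ("C", "C.ar"),
    "GC2": ("C", "C.2"),
    "GNM": ("N", "N.am"),
    "GN4": ("N", "N.4"),
    "GN3": ("N", "N.3"),
    "GO2": ("O", "O.2"),
    "GO3": ("O", "O.3"),
}

_GENERIC_BY_ELEMENT = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3"}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
# Common crystallographic buffer/cryoprotectant molecules, removed on ingestion.
_BUFFER_NAMES = {"SO4", "PO4", "GOL", "EDO", "PEG", "ACT", "DMS", "MPD", "TRS",
                 "NO3", "FMT", "CIT", "BME", "IMD", "EPE", "MES"}


def is_water(resname: str) -> bool:
    return resname.strip().upper() in _WATER_NAMES


def is_buffer(resname: str) -> bool:
    return resname.strip().upper() in _BUFFER_NAMES


def collapse_metal(element: str) -> str | None:
    """Return the collapsed metal type if ``element`` is a whitelisted metal."""
    el = element.capitalize()
    return METAL_TYPE if el in METAL_WHITELIST else None


def type_protein_atom(resname: str, atom_name: str, element: str) -> str:
    """SYBYL type for a receptor atom via the residue-template table.

    Unknown residues or atom names fall back to a generic per-element type.
    """
    res = resname.strip().upper()
    name = atom_name.strip().upper()
    metal = collapse_metal(element)
    if metal is not None:
        return metal
    if res in PSEUDO_RESIDUES:
        return PSEUDO_RESIDUES[res][1]
    if res in _SIDECHAINS:
        if name in _BACKBONE:
            return _BACKBONE[name]
        if name in _SIDECHAINS[res]:
            return _SIDECHAINS[res][name]
    el = element.capitalize()
    return _GENERIC_BY_ELEMENT.get(el, el)


DEFAULT_RECEPTOR_TYPES: tuple[str, ...] = (
    "C.3", "C.2", "C.ar", "C.cat",
    "N.am", "N.ar", "N.pl3", "N.4", "N.3",
    "O.2", "O.3", "O.co2",
    "S.3", "P.3", METAL_TYPE,
)

DEFAULT_LIGAND_TYPES: tuple[str, ...] = (
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    "O.3", "O.2", "O.co2",
    "S.3", "S.2", "S.o", "S.o2",
    "P.3", "F", "Cl", "Br", "I", METAL_TYPE,
)


class VocabularyError(KeyError):
    """An atom type is not present in the vocabulary."""


@dataclass(frozen=True)
class SybylVocabulary:
    """Ordered SYBYL type vocabulary with disjoint ligand and receptor blocks.

    Ligand types occupy one-hot indices ``[0, n_ligand)`` and receptor types
    ``[n_ligand, size)``: the two entities are encoded separately even when
    they share a type string.  When ``allow_other`` is set, each block ends
    with a reserved ``other`` slot absorbing out-of-vocabulary types.
    """

    ligand_types: tuple[str, ...] = DEFAULT_LIGAND_TYPES
    receptor_types: tuple[str, ...] = DEFAULT_RECEPTOR_TYPES
    allow_other: bool = False
    _lig_index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)
    _rec_index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        lig = list(self.ligand_types)
        rec = list(self.receptor_types)
        if self.allow_other:
            lig.append(OTHER_TYPE)
            rec.append(OTHER_TYPE)
        if len(set(lig)) != len(lig) or len(set(rec)) != len(rec):
            raise ValueError("duplicate types within an entity block")
        object.__setattr__(self, "_lig_index", {t: i for i, t in enumerate(lig)})
        object.__setattr__(self, "_rec_index",
                           {t: i + len(lig) for i, t in enumerate(rec)})

    @property
    def size(self) -> int:
        return len(self._lig_index) + len(self._rec_index)

    def index(self, sybyl_type: str, entity: str) -> int:
        """One-hot index for a (type, entity) pair, after metal collapsing."""
        metal = collapse_metal(sybyl_type.split(".")[0])
        t = METAL_TYPE if metal is not None and "." not in sybyl_type else sybyl_type
        block = self._lig_index if entity == "ligand" else self._rec_index
        if t in block:
            return block[t]
        if self.allow_other:
            return block[OTHER_TYPE]
        raise VocabularyError(f"{entity} type {sybyl_type!r} not in vocabulary")

    def encode(self, sybyl_type: str, entity: str) -> np.ndarray:
        vec = np.zeros(self.size)
        vec[self.index(sybyl_type, entity)] = 1.0
        return vec
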