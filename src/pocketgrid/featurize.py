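"""Per-atom chemical featurization: the 18-channel voxel feature vector.

Each heavy atom is described by 18 channels:

==========  =================================================================
channel     meaning
==========  =================================================================
0-8         one-hot atom class over {B, C, N, O, P, S, Se, halogen, metal}
9           hybridization (1 = sp, 2 = sp2, 3 = sp3; 0 if unknown)
10          heavy-atom neighbour count
11          heteroatom (non C/H) neighbour count
12          Gasteiger partial charge (e)
13-17       binary SMARTS flags {hydrophobic, aromatic, acceptor, donor, ring}
==========  =================================================================

The paper's feature list ("hybridization, heavy atoms, heteroatoms,
hydrophobic, aromatic, partial charge, acceptor, donor, and ring") names nine
features; with the 9-class element one-hot this is the unique layout filling
the stated 18 channels.  The five SMARTS patterns are the ones published with
the featurizer the paper cites.  Channel order is frozen: saved tensors are a
bit-exact contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .structio import ProteinStructure

__all__ = [
    "N_CHANNELS",
    "CHANNEL_NAMES",
    "FeaturizedAtom",
    "FeaturizationError",
    "featurize_structure",
    "featurize_mol",
    "smarts_flags",
    "structure_to_mol",
]

N_CHANNELS = 18

CHANNEL_NAMES = (
    "B", "C", "N", "O", "P", "S", "Se", "halogen", "metal",
    "hybridization", "heavyvalence", "heterovalence", "partialcharge",
    "hydrophobic", "aromatic", "acceptor", "donor", "ring",
)

# Atom classes by atomic number.  Metals follow the fixed lookup of the cited
# featurizer: everything outside the named organics/halogens that is a metal.
_ATOM_CLASSES: list[tuple[frozenset[int], int]] = [
    (frozenset({5}), 0),            # B
    (frozenset({6}), 1),            # C
    (frozenset({7}), 2),            # N
    (frozenset({8}), 3),            # O
    (frozenset({15}), 4),           # P
    (frozenset({16}), 5),           # S
    (frozenset({34}), 6),           # Se
    (frozenset({9, 17, 35, 53}), 7),  # halogens
    (
        frozenset(
            [3, 4, 11, 12, 13]
            + list(range(19, 32))
            + list(range(37, 51))
            + list(range(55, 84))
            + list(range(87, 104))
        ),
        8,
    ),
]

# SMARTS definitions published with the cited featurizer.
_SMARTS_PATTERNS = (
    ("hydrophobic", "[#6+0!$(*~[#7,#8,F]),SH0+0v2,s+0,S^3,Cl+0,Br+0,I+0]"),
    ("aromatic", "[a]"),
    (
        "acceptor",
        "[!$([#1,#6,F,Cl,Br,I,o,s,nX3,#7v5,#15v5,#16v4,#16v6,*+1,*+2,*+3])]",
    ),
    ("donor", "[!$([#6,H0,-,-2,-3]),$([!H0;#7,#8,#9])]"),
    ("ring", "[r]"),
)
_COMPILED_SMARTS = tuple(
    (name, Chem.MolFromSmarts(s)) for name, s in _SMARTS_PATTERNS
)

_HYBRIDIZATION = {
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}


class FeaturizationError(RuntimeError):
    """Raised when a structure cannot be prepared for featurization."""


@dataclass(frozen=True)
class FeaturizedAtom:
    coords: np.ndarray
    features: np.ndarray  # length 18


def _atom_class(atomic_num: int) -> int | None:
    for members, idx in _ATOM_CLASSES:
        if atomic_num in members:
            return idx
    return None


def smarts_flags(mol: Chem.Mol, atom_index: int) -> dict[str, bool]:
    """Membership of one atom in the five SMARTS classes.

    The patterns are evaluated on the whole molecule, so e.g. a carbon only
    counts as hydrophobic if none of its neighbours is N/O/F.
    """
    if atom_index < 0 or atom_index >= mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    flags = {}
    for name, pattern in _COMPILED_SMARTS:
        matches = {i for (i,) in mol.GetSubstructMatches(pattern)}
        flags[name] = atom_index in matches
    return flags


def _match_sets(mol: Chem.Mol) -> list[set[int]]:
    return [
        {i for (i,) in mol.GetSubstructMatches(pattern)}
        for _, pattern in _COMPILED_SMARTS
    ]


def structure_to_mol(structure: ProteinStructure) -> Chem.Mol:
    """Build an RDKit molecule (with bonds) from a parsed structure.

    Connectivity is perceived through the PDB machinery: standard-residue
    template bonds by atom name plus proximity for inter-residue links.
    """
    lines = []
    serial = 0
    for atom in structure.atoms:
        serial += 1
        name = atom.name or atom.element
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {serial:>5} {name:<4.4}{atom.residue_name:>4.3} "
            f"{atom.chain_id[:1]}{atom.residue_index:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{atom.element.upper():>2}"
        )
    lines.append("END")
    mol = Chem.MolFromPDBBlock("\n".join(lines), sanitize=False, removeHs=False)
    if mol is None:
        raise FeaturizationError(
            f"structure {structure.id!r}: could not build a molecule"
        )
    _restore_bond_orders(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise FeaturizationError(
            f"structure {structure.id!r}: sanitization failed: {exc}"
        ) from exc
    return mol


# Kekule double-bond patterns per residue (PDB atom-name pairs).  The PDB
# reader assigns single bonds only; backbone carbonyls apply to every
# residue, side-chain patterns cover the aromatic/carbonyl residues the
# fixture templates and common structures use.
_SIDECHAIN_DOUBLE_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CG", "CD1"), ("CE1", "CZ"), ("CE2", "CD2")],
    "TYR": [("CG", "CD1"), ("CE1", "CZ"), ("CE2", "CD2")],
    "TRP": [("CG", "CD1"), ("CE2", "CD2"), ("CE3", "CZ3"), ("CZ2", "CH2")],
    "HIS": [("CG", "CD2"), ("CE1", "ND1")],
    "ASP": [("CG", "OD1")],
    "GLU": [("CD", "OE1")],
    "ASN": [("CG", "OD1")],
    "GLN": [("CD", "OE1")],
    "ARG": [("CZ", "NH1")],
}


def _restore_bond_orders(mol: Chem.Mol) -> None:
    """Promote template-known bonds to double before sanitization."""
    by_residue: dict[tuple, dict[str, int]] = {}
    for atom in mol.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is None:
            continue
        key = (info.GetChainId(), info.GetResidueNumber(), info.GetResidueName())
        by_residue.setdefault(key, {})[info.GetName().strip()] = atom.GetIdx()
    for (chain, resnum, resname), names in by_residue.items():
        pairs = [("C", "O")] + _SIDECHAIN_DOUBLE_BONDS.get(resname.strip(), [])
        for a_name, b_name in pairs:
            if a_name in names and b_name in names:
                bond = mol.GetBondBetweenAtoms(names[a_name], names[b_name])
                if bond is not None:
                    bond.SetBondType(Chem.BondType.DOUBLE)


def featurize_mol(mol: Chem.Mol) -> list[FeaturizedAtom]:
    """18-channel feature vectors for every heavy atom of an RDKit molecule."""
    if mol.GetNumConformers() == 0:
        raise FeaturizationError("molecule has no 3D coordinates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        AllChem.ComputeGasteigerCharges(mol, throwOnParamFailure=False)
    match_sets = _match_sets(mol)
    conf = mol.GetConformer()
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue  # heavy-atom representation: hydrogens never featurized
        idx = atom.GetIdx()
        vec = np.zeros(N_CHANNELS, dtype=np.float32)
        cls = _atom_class(atom.GetAtomicNum())
        if cls is not None:
            vec[cls] = 1.0
        vec[9] = _HYBRIDIZATION.get(atom.GetHybridization(), 0)
        neighbours = atom.GetNeighbors()
        vec[10] = sum(1 for n in neighbours if n.GetAtomicNum() > 1)
        vec[11] = sum(1 for n in neighbours if n.GetAtomicNum() not in (1, 6))
        charge = atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(charge):
            warnings.warn(
                f"non-finite Gasteiger charge on atom {idx}; clamped to 0",
                stacklevel=2,
            )
            charge = 0.0
        vec[12] = charge
        for k, members in enumerate(match_sets):
            vec[13 + k] = 1.0 if idx in members else 0.0
        pos = conf.GetAtomPosition(idx)
        out.append(
            FeaturizedAtom(
                coords=np.array([pos.x, pos.y, pos.z]), features=vec
            )
        )
    return out


def featurize_structure(structure: ProteinStructure) -> list[FeaturizedAtom]:
    """One :class:`FeaturizedAtom` per heavy atom of a parsed structure."""
    return featurize_mol(structure_to_mol(structure))
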