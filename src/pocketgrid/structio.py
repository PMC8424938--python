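"""Molecular structure I/O and the core structure model.

Reads protein structures from PDB (via biotite) and TRIPOS mol2 (via
MDAnalysis), exposes a light :class:`ProteinStructure` model with per-chain
sequences, and writes point clouds (predicted pocket centers, site points)
back out as mol2 files with one dummy ``Du`` atom per point.

All coordinates are Cartesian angstroms in the file's own frame; nothing is
re-oriented at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "ProteinStructure",
    "SiteCoords",
    "ParseError",
    "read_structure",
    "read_site",
    "structure_center",
    "write_points_mol2",
]

# 3-letter -> 1-letter amino-acid codes; anything else maps to "X".
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ParseError(ValueError):
    """A structure file could not be parsed.

    Carries the offending path and, where known, a human-readable location
    (line or record) so batch pipelines can report exactly what failed.
    """

    def __init__(self, path, message: str):
        self.path = str(path)
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, position (A), and residue bookkeeping."""

    element: str
    coords: np.ndarray
    chain_id: str
    residue_name: str
    residue_index: int
    name: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class ProteinStructure:
    """A parsed protein: ordered atoms partitioned into chains.

    ``sequence`` maps chain id to its one-letter amino-acid string (derived
    from residue names; non-standard residues become ``X``).  ``n_residues``
    is the total residue count over retained chains — the ``N`` used by the
    k-mer fingerprint machinery.
    """

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        for atom in self.atoms:
            if not np.all(np.isfinite(atom.coords)):
                raise ValueError(
                    f"structure {self.id!r}: non-finite coordinates on atom "
                    f"{atom.name!r}"
                )

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    @property
    def chains(self) -> dict[str, list[Atom]]:
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    @property
    def sequence(self) -> dict[str, str]:
        seqs: dict[str, str] = {}
        for cid, atoms in self.chains.items():
            letters = []
            last = None
            for a in atoms:
                key = (a.residue_index, a.residue_name)
                if key != last:
                    letters.append(THREE_TO_ONE.get(a.residue_name.upper(), "X"))
                    last = key
            seqs[cid] = "".join(letters)
        return seqs

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.sequence.values())

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def subset_chains(self, chain_ids) -> "ProteinStructure":
        keep = set(chain_ids)
        return ProteinStructure(
            id=self.id, atoms=[a for a in self.atoms if a.chain_id in keep]
        )


@dataclass(frozen=True)
class SiteCoords:
    """Binding-site or ligand atom positions (A)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("SiteCoords requires a non-empty (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("SiteCoords contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _element_from_mol2_type(sybyl_type: str) -> str:
    """``C.3`` -> ``C``, ``N.am`` -> ``N``, ``Du`` -> ``Du``."""
    return sybyl_type.split(".")[0].capitalize()


def _read_pdb(path: Path, structure_id: str) -> ProteinStructure:
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises several parse error types
        raise ParseError(path, f"PDB parse failure: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(path, "PDB file contains no atoms")
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).capitalize()
        atoms.append(
            Atom(
                element=element or "X",
                coords=np.array(arr.coord[i], dtype=float),
                chain_id=str(arr.chain_id[i]) or "A",
                residue_name=str(arr.res_name[i]),
                residue_index=int(arr.res_id[i]),
                name=str(arr.atom_name[i]),
            )
        )
    return ProteinStructure(id=structure_id, atoms=atoms)


def _read_mol2(path: Path, structure_id: str) -> ProteinStructure:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(path))
        except Exception as exc:
            raise ParseError(path, f"mol2 parse failure: {exc}") from exc
    if len(universe.atoms) == 0:
        raise ParseError(path, "mol2 file contains no atoms")
    atoms = []
    for a in universe.atoms:
        resname = str(a.resname)
        # TRIPOS subst_name is commonly "ALA12"; strip the trailing number.
        resbase = resname.rstrip("0123456789") or resname
        atoms.append(
            Atom(
                element=_element_from_mol2_type(str(a.type)),
                coords=np.array(a.position, dtype=float),
                chain_id="A",  # mol2 carries no chain ids
                residue_name=resbase,
                residue_index=int(a.resid),
                name=str(a.name),
            )
        )
    return ProteinStructure(id=structure_id, atoms=atoms)


def read_structure(path, fmt: str | None = None) -> ProteinStructure:
    """Read a protein structure from a PDB or TRIPOS mol2 file.

    Parameters
    ----------
    path:
        File to read.  The format is taken from ``fmt`` (``"pdb"`` or
        ``"mol2"``) or, when omitted, from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    structure_id = path.stem
    if fmt == "pdb":
        return _read_pdb(path, structure_id)
    if fmt == "mol2":
        return _read_mol2(path, structure_id)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def structure_center(structure: ProteinStructure) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates (A).

    The reference pipeline places its voxel box at "the center of the
    protein"; heavy atoms only, so a hydrogen-stripped and a protonated copy
    of the same model agree.
    """
    coords = structure.coords(heavy_only=True)
    if len(coords) == 0:
        raise ValueError(f"structure {structure.id!r} has no heavy atoms")
    return coords.mean(axis=0)


def read_site(path) -> SiteCoords:
    """Read binding-site / ligand atom positions from a mol2 file."""
    structure = _read_mol2(Path(path), Path(path).stem) if Path(path).exists() else None
    if structure is None:
        raise FileNotFoundError(path)
    return SiteCoords(points=structure.coords())


def write_points_mol2(points, path, mol_name: str = "pocket") -> None:
    """Write a point cloud as a TRIPOS mol2 with one ``Du`` atom per point.

    Coordinates are printed at 4 decimals, so a read/write round trip is
    exact to well under 0.001 A.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("write_points_mol2 requires a non-empty (n, 3) array")
    lines = [
        "@<TRIPOS>MOLECULE",
        mol_name,
        f"{len(pts)} 0 1",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, (x, y, z) in enumerate(pts, start=1):
        lines.append(
            f"{i:>4} Du{i:<4} {x:>10.4f} {y:>10.4f} {z:>10.4f} Du 1 PCK1 0.0000"
        )
    Path(path).write_text("\n".join(lines) + "\n")
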