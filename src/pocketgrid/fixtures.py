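"""Deterministic synthetic structures, sites and probability grids.

Everything downstream (featurization, voxelization, cleaning, training,
evaluation) is exercised on structures built here, so no external database
is needed.  Toy proteins are ideal alpha-helices assembled from a small
template library of real amino-acid geometries (G, A, S, C, F) — backbone
atoms on helical coordinates, side chains grown along idealized directions —
so the cheminformatics backend sees chemically sane molecules (template
bonds, aromatic PHE rings, plausible Gasteiger charges).

Every generator is a pure function of its seed/config and ships its own
ground truth (sequences, true center, per-chain site contact, expected
pocket memberships); tests never assert values that are not derivable from
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import Atom, ProteinStructure, SiteCoords, write_points_mol2
from .voxelize import GridSpec

__all__ = [
    "FixtureConfig",
    "ToyProtein",
    "make_toy_protein",
    "make_cleaning_batch",
    "make_probability_grid",
    "write_fixture_dir",
]

# ideal alpha-helix internal coordinates
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# residues the template library can grow beyond CB
_TEMPLATE_ALPHABET = "GASCF"
_ONE_TO_THREE = {"G": "GLY", "A": "ALA", "S": "SER", "C": "CYS", "F": "PHE"}


@dataclass(frozen=True)
class FixtureConfig:
    n_residues: int = 20
    n_chains: int = 1
    site_radius: float = 3.0
    n_site_points: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.n_residues, self.n_chains, self.n_site_points) < 1:
            raise ValueError("fixture sizes must be positive")
        if self.site_radius <= 0:
            raise ValueError("site_radius must be positive")
        if self.n_residues < 3:
            raise ValueError("need >= 3 residues for a meaningful chain")


@dataclass
class ToyProtein:
    """A generated structure with its construction-time ground truth."""

    structure: ProteinStructure
    site: SiteCoords
    ligand: SiteCoords
    sequences: dict[str, str]
    site_chain: str  # the chain the site was placed against
    site_center: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension placement: position d with |cd| = bond,
    angle(b, c, d) = angle and torsion(a, b, c, d) = torsion."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helix_backbone(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ideal alpha-helix N/CA/C/O coordinates built from internal
    coordinates (phi = -57, psi = -47, omega = 180)."""
    n_pos = np.zeros((n, 3))
    ca = np.zeros((n, 3))
    c_pos = np.zeros((n, 3))
    o_pos = np.zeros((n, 3))
    n_pos[0] = np.zeros(3)
    ca[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c_pos[0] = ca[0] + _B_CA_C * np.array(
        [np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0]
    )
    for i in range(n - 1):
        n_pos[i + 1] = _place(
            n_pos[i], ca[i], c_pos[i], _B_C_N, _A_CA_C_N, _PSI
        )
        ca[i + 1] = _place(
            ca[i], c_pos[i], n_pos[i + 1], _B_N_CA, _A_C_N_CA, _OMEGA
        )
        c_pos[i + 1] = _place(
            c_pos[i], n_pos[i + 1], ca[i + 1], _B_CA_C, _A_N_CA_C, _PHI
        )
    for i in range(n):
        # carbonyl O is anti-planar to the next amide N
        o_pos[i] = _place(
            n_pos[i], ca[i], c_pos[i], _B_C_O, _A_CA_C_O, _PSI + 180.0
        )
    return n_pos, ca, c_pos, o_pos


def _radial_direction(chain_atoms: list[Atom], point: np.ndarray) -> np.ndarray:
    """Unit vector from the chain's helix axis through ``point``."""
    cas = np.array([a.coords for a in chain_atoms if a.name == "CA"])
    axis_dir = _unit(cas[-1] - cas[0])
    rel = point - cas.mean(axis=0)
    radial = rel - rel.dot(axis_dir) * axis_dir
    norm = np.linalg.norm(radial)
    if norm < 1e-6:
        radial = np.cross(axis_dir, np.array([1.0, 0.0, 0.0]))
        norm = np.linalg.norm(radial)
    return radial / norm


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # idealized tetrahedral CB from the backbone frame
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


def _sidechain_atoms(letter, n, ca, c) -> list[tuple[str, str, np.ndarray]]:
    """(atom_name, element, coords) beyond the backbone for one residue."""
    if letter == "G":
        return []
    cb = _cb_position(n, ca, c)
    out = [("CB", "C", cb)]
    u = _unit(cb - ca)
    if letter == "S":
        out.append(("OG", "O", cb + 1.42 * u))
    elif letter == "C":
        out.append(("SG", "S", cb + 1.81 * u))
    elif letter == "F":
        cg = cb + 1.50 * u
        ring_center = cg + 1.39 * u
        v = _unit(np.cross(u, _unit(np.cross(u, ca - n))))
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        for k, name in enumerate(names):
            ang = np.deg2rad(60.0 * k)
            pos = ring_center + 1.39 * (-np.cos(ang) * u + np.sin(ang) * v)
            out.append((name, "C", pos))
    return out


def _build_chain(
    sequence: str, chain_id: str, offset: np.ndarray
) -> list[Atom]:
    n_pos, ca, c_pos, o_pos = _helix_backbone(len(sequence))
    atoms = []
    for i, letter in enumerate(sequence):
        res = _ONE_TO_THREE[letter]
        backbone = [
            ("N", "N", n_pos[i]),
            ("CA", "C", ca[i]),
            ("C", "C", c_pos[i]),
            ("O", "O", o_pos[i]),
        ]
        side = _sidechain_atoms(letter, n_pos[i], ca[i], c_pos[i])
        for name, element, pos in backbone + side:
            atoms.append(
                Atom(
                    element=element,
                    coords=np.asarray(pos, dtype=float) + offset,
                    chain_id=chain_id,
                    residue_name=res,
                    residue_index=i + 1,
                    name=name,
                )
            )
    return atoms


def make_toy_protein(config: FixtureConfig = FixtureConfig()) -> ToyProtein:
    """Generate a helix-like protein with a pocket point cloud on chain A.

    The site cloud is anchored ~3 A outside a mid-chain residue of the first
    chain, so chain A always has atoms within 4 A of the site while any
    second chain (offset 30 A away) never does.  The ligand is a tighter
    cloud inside the site.
    """
    rng = np.random.default_rng(config.seed)
    chain_ids = [chr(ord("A") + i) for i in range(config.n_chains)]
    sequences = {
        cid: "".join(rng.choice(list(_TEMPLATE_ALPHABET), config.n_residues))
        for cid in chain_ids
    }
    atoms: list[Atom] = []
    for i, cid in enumerate(chain_ids):
        offset = np.array([30.0 * i, 0.0, 0.0])
        atoms.extend(_build_chain(sequences[cid], cid, offset))
    structure = ProteinStructure(id=f"toy{config.seed}", atoms=atoms)

    # anchor the site on the middle residue of chain A, radially outward
    chain_a = [a for a in atoms if a.chain_id == chain_ids[0]]
    mid_res = config.n_residues // 2 + 1
    anchor = next(
        a for a in chain_a if a.residue_index == mid_res and a.name == "CA"
    )
    outward = _radial_direction(chain_a, anchor.coords)
    site_center = anchor.coords + 3.0 * outward
    offsets = rng.normal(size=(config.n_site_points - 1, 3))
    offsets *= (
        rng.uniform(0, config.site_radius, config.n_site_points - 1)[:, None]
        / np.linalg.norm(offsets, axis=1)[:, None]
    )
    site_points = np.vstack([site_center, site_center + offsets])
    lig_offsets = rng.normal(size=(9, 3))
    lig_offsets *= (
        rng.uniform(0, config.site_radius / 2, 9)[:, None]
        / np.linalg.norm(lig_offsets, axis=1)[:, None]
    )
    ligand_points = np.vstack([site_center, site_center + lig_offsets])
    return ToyProtein(
        structure=structure,
        site=SiteCoords(points=site_points),
        ligand=SiteCoords(points=ligand_points),
        sequences=sequences,
        site_chain=chain_ids[0],
        site_center=site_center,
    )


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write a minimal PDB file for a toy structure."""
    lines = []
    serial = 0
    for atom in structure.atoms:
        serial += 1
        name = atom.name or atom.element
        # standard short-name padding: 1-3 char names start in column 14
        name_field = f" {name:<3.3}" if len(name) < 4 else f"{name:<4.4}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {serial:>5} {name_field}{atom.residue_name:>4.3} "
            f"{atom.chain_id[:1]}{atom.residue_index:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{atom.element.upper():>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_cleaning_batch(
    outdir, seed: int = 0
) -> tuple[dict, dict, dict, dict[str, str]]:
    """A batch exercising every branch of the cleaning pipeline.

    Writes structure/site files under ``outdir`` and returns
    ``(structure_paths, site_paths, mapping, expected_dispositions)``:

    * ``dupA``/``dupB`` share a UniProt id; their sequences differ by one
      terminal residue, so their sliding Tanimoto is high and the longer
      (``dupB``) is kept while ``dupA`` is deduplicated,
    * ``broken`` is an unparseable file (dropped at parse time),
    * ``farsite`` has its site cloud placed 80 A from the protein center
      (dropped by the 70 A filter),
    * ``okA``/``okB`` are healthy singletons (kept).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure_paths: dict[str, Path] = {}
    site_paths: dict[str, Path] = {}

    def emit(name: str, toy: ToyProtein, site_points: np.ndarray | None = None):
        spath = outdir / f"{name}.pdb"
        toy.structure.id = name
        write_pdb(toy.structure, spath)
        sites = site_points if site_points is not None else toy.site.points
        site_path = outdir / f"{name}_site.mol2"
        write_points_mol2(sites, site_path, mol_name=f"{name}_site")
        structure_paths[name] = spath
        site_paths[name] = site_path

    base = make_toy_protein(FixtureConfig(n_residues=20, seed=seed))
    emit("dupA", base)

    longer = make_toy_protein(FixtureConfig(n_residues=21, seed=seed + 1))
    # same sequence as dupA plus one extra terminal residue
    seq = base.sequences["A"] + "A"
    longer.sequences = {"A": seq}
    longer.structure = ProteinStructure(
        id="dupB", atoms=_build_chain(seq, "A", np.zeros(3))
    )
    mid = next(
        a
        for a in longer.structure.atoms
        if a.residue_index == 11 and a.name == "CA"
    )
    outward = _radial_direction(longer.structure.atoms, mid.coords)
    pts = mid.coords + 3.0 * outward + np.zeros((4, 3))
    emit("dupB", longer, site_points=pts)

    emit("okA", make_toy_protein(FixtureConfig(n_residues=18, seed=seed + 2)))
    emit("okB", make_toy_protein(FixtureConfig(n_residues=24, seed=seed + 3)))

    far = make_toy_protein(FixtureConfig(n_residues=16, seed=seed + 4))
    center = far.structure.coords(heavy_only=True).mean(axis=0)
    far_pts = center + np.array([80.0, 0.0, 0.0]) + far.site.points - far.site.center
    emit("farsite", far, site_points=far_pts)

    broken_path = outdir / "broken.pdb"
    broken_path.write_text("ATOM this file is deliberately truncated gar")
    bsite = outdir / "broken_site.mol2"
    write_points_mol2(np.zeros((1, 3)), bsite, mol_name="broken_site")
    structure_paths["broken"] = broken_path
    site_paths["broken"] = bsite

    mapping = {
        "dupA": "U1", "dupB": "U1", "okA": "U2", "okB": "U3",
        "farsite": "U4", "broken": "U5",
    }
    expected = {
        "dupA": "deduplicated", "dupB": "kept", "okA": "kept", "okB": "kept",
        "farsite": "dropped_distance", "broken": "dropped_parse",
    }
    return structure_paths, site_paths, mapping, expected


def make_probability_grid(
    pocket_specs: list[tuple[tuple[int, int, int], float, float]],
    noise_level: float = 0.2,
    seed: int = 0,
    spec: GridSpec | None = None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, list[frozenset]]:
    """A probability grid of Gaussian blobs over sub-threshold noise.

    ``pocket_specs`` is a list of ``(center_ijk, sigma_voxels, amplitude)``.
    Expected component memberships are derived analytically from the
    construction: a blob of amplitude A covers the voxels within radius
    ``sigma * sqrt(2 ln(A / threshold))`` of its center; blobs whose
    super-threshold balls touch (26-connectivity) are merged in the
    expectation.  Noise is scaled strictly below the threshold so it can
    never create components on its own.
    """
    spec = spec or GridSpec()
    if not 0 <= noise_level < threshold:
        raise ValueError("noise_level must stay strictly below the threshold")
    s = spec.side
    rng = np.random.default_rng(seed)
    grid = rng.uniform(0.0, max(noise_level, 1e-9), size=(s, s, s))
    if noise_level == 0:
        grid[:] = 0.0
    ii = np.arange(s)
    zz, yy, xx = np.meshgrid(ii, ii, ii, indexing="ij")
    blob_voxels: list[set] = []
    for (ci, cj, ck), sigma, amp in pocket_specs:
        if not (0 <= ci < s and 0 <= cj < s and 0 <= ck < s):
            raise ValueError(f"blob center {(ci, cj, ck)} outside the grid")
        if amp <= threshold:
            raise ValueError("blob amplitude must exceed the threshold")
        d2 = (zz - ci) ** 2 + (yy - cj) ** 2 + (xx - ck) ** 2
        blob = amp * np.exp(-d2 / (2 * sigma**2))
        grid = np.maximum(grid, blob)
        r2 = 2 * sigma**2 * np.log(amp / threshold)
        blob_voxels.append(
            {tuple(v) for v in np.argwhere(d2 < r2 - 1e-12)}
        )
    grid = np.clip(grid, 0.0, 0.999999)

    # merge blobs whose super-threshold sets are 26-connected or overlap
    merged: list[set] = []
    for vox in blob_voxels:
        vox = set(vox)
        absorbed = True
        while absorbed:
            absorbed = False
            for other in merged:
                if _touching(vox, other):
                    vox |= other
                    merged.remove(other)
                    absorbed = True
                    break
        merged.append(vox)
    return grid, [frozenset(v) for v in merged]


def _touching(a: set, b: set) -> bool:
    for i, j, k in a:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if (i + di, j + dj, k + dk) in b:
                        return True
    return False


def write_fixture_dir(outdir, seed: int = 0, n_structures: int = 3) -> dict:
    """Write a complete toy dataset (PDB + mol2 + mapping TSV) to ``outdir``.

    Returns a manifest of what was written (also saved as manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "structures": []}
    mapping_lines = []
    for i in range(n_structures):
        toy = make_toy_protein(FixtureConfig(n_residues=20, seed=seed + i))
        name = f"toy{seed + i}"
        write_pdb(toy.structure, outdir / f"{name}.pdb")
        write_points_mol2(toy.site.points, outdir / f"{name}_site.mol2")
        write_points_mol2(toy.ligand.points, outdir / f"{name}_ligand.mol2")
        mapping_lines.append(f"{name}\tU{seed + i}")
        manifest["structures"].append(
            {
                "id": name,
                "sequence": toy.sequences,
                "site_center": [round(float(x), 4) for x in toy.site_center],
            }
        )
    (outdir / "mapping.tsv").write_text("\n".join(mapping_lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
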