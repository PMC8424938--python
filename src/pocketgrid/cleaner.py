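"""Structural-similarity data cleaning.

The training-set curation pipeline: group structures by UniProt accession,
fingerprint every sequence as a stack of tripeptide MACCS keys, measure
within-cluster similarity with a sliding-window Tanimoto index, keep one
representative per cluster (the longest sequence), retain only chains in
contact with the binding site, and drop entries whose site lies further than
``max_site_dist`` from the protein center (such sites cannot be represented
inside the voxel box).

A protein of N residues yields N-2 overlapping 3-mers (frame 3, stride 1);
each 3-mer is embodied as a neutral tripeptide molecule and fingerprinted
with the 167-bit MACCS dictionary, giving an (N-2) x 167 bit matrix.  Two
equal-length matrices are compared by pooling all bits into one vector and
taking |intersection| / |union| over on-bits; unequal lengths slide the
shorter matrix along the longer and keep the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import (
    ParseError,
    ProteinStructure,
    SiteCoords,
    read_site,
    read_structure,
    structure_center,
)

__all__ = [
    "FingerprintMatrix",
    "Cluster",
    "CleaningConfig",
    "CleaningReport",
    "kmers",
    "fingerprint_matrix",
    "tanimoto_equal",
    "sliding_tanimoto",
    "cluster_by_uniprot",
    "select_representative",
    "filter_distant_site",
    "retain_site_chains",
    "run_cleaning",
]

MACCS_BITS = 167


@dataclass(frozen=True)
class FingerprintMatrix:
    """(N-2) x 167 bit matrix; row r is the MACCS key of 3-mer r."""

    bits: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        b = np.asarray(self.bits, dtype=bool)
        if b.ndim != 2 or b.shape[1] != MACCS_BITS:
            raise ValueError(
                f"fingerprint matrix must have {MACCS_BITS} columns, "
                f"got shape {b.shape}"
            )
        object.__setattr__(self, "bits", b)

    def __len__(self) -> int:
        return self.bits.shape[0]


@dataclass
class Cluster:
    uniprot_id: str
    members: dict[str, str]  # structure id -> sequence

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.uniprot_id!r} is empty")


@dataclass(frozen=True)
class CleaningConfig:
    similarity_threshold: float = 0.8
    max_site_dist: float = 70.0
    contact_cutoff: float = 4.0
    k: int = 3


@dataclass
class CleaningReport:
    """Per-structure dispositions (a partition of the input) plus
    per-cluster mean pairwise similarity."""

    dispositions: dict[str, str] = field(default_factory=dict)
    cluster_similarity: dict[str, float] = field(default_factory=dict)
    flagged_for_review: set[str] = field(default_factory=set)
    errors: dict[str, str] = field(default_factory=dict)

    VALID = ("kept", "dropped_parse", "dropped_distance", "deduplicated")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "structure_id": sid,
                "disposition": disp,
                "needs_review": sid in self.flagged_for_review,
                "error": self.errors.get(sid, ""),
            }
            for sid, disp in sorted(self.dispositions.items())
        ]
        return pd.DataFrame(rows)


def kmers(sequence: str, k: int = 3) -> list[str]:
    """All consecutive substrings of length ``k`` (stride 1): N-k+1 of them."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@lru_cache(maxsize=20_000)
def _maccs_row(kmer: str) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSequence(kmer)
    if mol is None:
        raise ValueError(
            f"3-mer {kmer!r} could not be embodied as a tripeptide molecule"
        )
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(MACCS_BITS, dtype=bool)
    for bit in fp.GetOnBits():
        arr[bit] = True
    arr.setflags(write=False)
    return arr


def fingerprint_matrix(sequence: str, source_id: str = "") -> FingerprintMatrix:
    """Stack of tripeptide MACCS keys: shape (N-2, 167).

    Each 3-mer is built as a neutral (uncapped zwitterion-free) tripeptide;
    a residue that cannot be mapped to a molecule (e.g. ``X``) raises with
    the offending 3-mer named.
    """
    rows = [_maccs_row(km) for km in kmers(sequence, k=3)]
    return FingerprintMatrix(bits=np.array(rows), source_id=source_id)


def _pooled_tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        # two all-zero fingerprints are identical objects
        return 1.0
    return inter / union


def tanimoto_equal(a1: FingerprintMatrix, a2: FingerprintMatrix) -> float:
    """Tanimoto index of two equal-length fingerprint matrices.

    The matrices are pooled row-aligned into single bit vectors before the
    set computation.
    """
    if len(a1) != len(a2):
        raise ValueError(
            f"matrices have different lengths ({len(a1)} vs {len(a2)}); "
            "use sliding_tanimoto"
        )
    return _pooled_tanimoto(a1.bits.ravel(), a2.bits.ravel())


def sliding_tanimoto(a1: FingerprintMatrix, a2: FingerprintMatrix) -> float:
    """Maximum Tanimoto index over all alignments of the shorter matrix.

    Equal lengths reduce to :func:`tanimoto_equal`; otherwise a window of the
    shorter length slides along the longer matrix with stride 1 and the
    maximum windowed index is returned.
    """
    if len(a1) == 0 or len(a2) == 0:
        raise ValueError("fingerprint matrices must be non-empty")
    if len(a1) == len(a2):
        return tanimoto_equal(a1, a2)
    longer, shorter = (a1, a2) if len(a1) > len(a2) else (a2, a1)
    w = len(shorter)
    flat_short = shorter.bits.ravel()
    best = 0.0
    for start in range(len(longer) - w + 1):
        window = longer.bits[start : start + w].ravel()
        best = max(best, _pooled_tanimoto(window, flat_short))
    return best


def cluster_by_uniprot(
    mapping: dict[str, str] | str | Path,
    structures: dict[str, str],
) -> list[Cluster]:
    """Group structures (id -> sequence) by their UniProt accession.

    ``mapping`` is either a dict or a two-column TSV
    (``structure_id<TAB>uniprot_id``).  Every structure id must be mapped.
    """
    if not isinstance(mapping, dict):
        df = pd.read_csv(
            mapping, sep="\t", header=None, names=["structure_id", "uniprot_id"],
            dtype=str, comment="#",
        )
        mapping = dict(zip(df.structure_id, df.uniprot_id))
    clusters: dict[str, dict[str, str]] = {}
    for sid, seq in structures.items():
        if sid not in mapping:
            raise KeyError(f"structure id {sid!r} missing from UniProt mapping")
        clusters.setdefault(mapping[sid], {})[sid] = seq
    return [
        Cluster(uniprot_id=uid, members=members)
        for uid, members in sorted(clusters.items())
    ]


def mean_pairwise_similarity(cluster: Cluster) -> float:
    """Mean sliding Tanimoto over all member pairs (1.0 for singletons)."""
    ids = sorted(cluster.members)
    if len(ids) == 1:
        return 1.0
    fps = {sid: fingerprint_matrix(cluster.members[sid], sid) for sid in ids}
    sims = [
        sliding_tanimoto(fps[a], fps[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    ]
    return float(np.mean(sims))


def select_representative(
    cluster: Cluster, similarity_threshold: float = 0.8
) -> tuple[str, float, bool]:
    """Pick the longest-sequence member (ties: lexicographically smallest id).

    Returns ``(structure_id, mean_pairwise_similarity, below_threshold)``;
    the flag warns when the cluster's mean similarity falls below the
    threshold at which structures are regarded as redundant copies.
    """
    best = min(
        cluster.members, key=lambda sid: (-len(cluster.members[sid]), sid)
    )
    sim = mean_pairwise_similarity(cluster)
    return best, sim, sim < similarity_threshold


def filter_distant_site(
    structure: ProteinStructure,
    site: SiteCoords,
    max_site_dist: float = 70.0,
) -> str:
    """``"drop"`` iff any site point lies strictly beyond ``max_site_dist``
    from the protein center (such a site cannot live inside the voxel box);
    otherwise ``"keep"``."""
    center = structure_center(structure)
    dists = np.linalg.norm(site.points - center, axis=1)
    return "drop" if float(dists.max()) > max_site_dist else "keep"


def retain_site_chains(
    structure: ProteinStructure,
    site: SiteCoords,
    contact_cutoff: float = 4.0,
) -> ProteinStructure:
    """Keep exactly the chains with >= 1 heavy atom within ``contact_cutoff``
    of any site point; the chains without the binding site are removed to
    soften the extreme voxel class imbalance.

    Raises if no chain touches the site (the structure then needs manual
    review rather than silent dropping).
    """
    keep = []
    for cid, atoms in structure.chains.items():
        coords = np.array(
            [a.coords for a in atoms if a.is_heavy], dtype=float
        )
        if len(coords) == 0:
            continue
        d2 = (
            (coords[:, None, :] - site.points[None, :, :]) ** 2
        ).sum(axis=2)
        if np.sqrt(d2.min()) <= contact_cutoff:
            keep.append(cid)
    if not keep:
        raise ValueError(
            f"structure {structure.id!r}: no chain within "
            f"{contact_cutoff} A of the binding site; flagged for review"
        )
    return structure.subset_chains(keep)


def _structure_sequence(structure: ProteinStructure) -> str:
    return "".join(structure.sequence.values())


def run_cleaning(
    structure_paths: dict[str, str | Path],
    site_paths: dict[str, str | Path],
    mapping: dict[str, str] | str | Path,
    config: CleaningConfig = CleaningConfig(),
) -> tuple[CleaningReport, dict[str, ProteinStructure]]:
    """The full cleaning pipeline over a batch of structure/site files.

    Order: parse-failure removal, UniProt clustering, representative
    selection (cluster losers become ``deduplicated``), site-chain
    retention (failures are flagged, not dropped), then the site-distance
    filter.  Per-structure errors never abort the batch; the report's
    dispositions always partition the input ids.
    """
    report = CleaningReport()
    parsed: dict[str, ProteinStructure] = {}
    sites: dict[str, SiteCoords] = {}
    for sid, path in structure_paths.items():
        try:
            parsed[sid] = read_structure(path)
            sites[sid] = read_site(site_paths[sid])
        except (ParseError, FileNotFoundError, KeyError, ValueError) as exc:
            report.dispositions[sid] = "dropped_parse"
            report.errors[sid] = str(exc)

    clusters = cluster_by_uniprot(
        mapping, {sid: _structure_sequence(s) for sid, s in parsed.items()}
    )

    retained: dict[str, ProteinStructure] = {}
    for cluster in clusters:
        rep, sim, below = select_representative(
            cluster, config.similarity_threshold
        )
        report.cluster_similarity[cluster.uniprot_id] = sim
        for sid in cluster.members:
            if sid != rep:
                report.dispositions[sid] = "deduplicated"
        if below and len(cluster.members) > 1:
            report.flagged_for_review.add(rep)

        structure = parsed[rep]
        try:
            structure = retain_site_chains(
                structure, sites[rep], config.contact_cutoff
            )
        except ValueError as exc:
            report.flagged_for_review.add(rep)
            report.errors[rep] = str(exc)

        if (
            filter_distant_site(structure, sites[rep], config.max_site_dist)
            == "drop"
        ):
            report.dispositions[rep] = "dropped_distance"
            continue
        report.dispositions[rep] = "kept"
        retained[rep] = structure
    return report, retained
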