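"""Pocket-prediction evaluation: DCC, success rate, DVO, PLI and F1.

Per structure, the predicted pocket is compared with the annotated site by

* DCC — Euclidean distance between the predicted and actual site centers;
  a prediction with DCC <= 4 A counts as a correctly located site,
* DVO — Jaccard overlap between predicted and actual site voxel sets on the
  common 36^3 grid (computed for correctly located sites only),
* PLI — the fraction of ligand voxels lying inside the predicted site
  (again only when DCC <= 4 A).

Classification: DCC <= 4 A is a true positive, DCC > 4 A a false positive,
and no prediction at all a false negative; there are no true negatives since
every structure has a site.  F1 = 2TP / (2TP + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .structio import SiteCoords
from .voxelize import GridSpec, PocketPrediction, SiteMask, voxelize_site

__all__ = [
    "EvalRecord",
    "SummaryStats",
    "dcc",
    "success_rate",
    "dvo",
    "pli",
    "evaluate_structure",
    "summarize",
    "f1_score",
    "round_half_up",
]

NO_PREDICTION = float("inf")
DCC_THRESHOLD = 4.0


@dataclass(frozen=True)
class EvalRecord:
    """One structure's evaluation: its class and (for TPs) the overlaps."""

    structure_id: str
    dcc: float  # inf encodes "no prediction"
    klass: str  # TP | FP | FN
    dvo: float | None = None  # defined only for TP records
    pli: float | None = None

    def __post_init__(self):
        if self.klass not in ("TP", "FP", "FN"):
            raise ValueError(f"invalid class {self.klass!r}")
        if (self.klass == "FN") != np.isinf(self.dcc):
            raise ValueError("FN records must (only) carry dcc = no-prediction")
        if self.klass != "TP" and (self.dvo is not None or self.pli is not None):
            raise ValueError("dvo/pli are defined only for TP records")


@dataclass(frozen=True)
class SummaryStats:
    tp: int
    fp: int
    fn: int
    f1: float
    success_rate: float
    mean_dvo: float | None
    mean_pli: float | None


def dcc(pred_center, actual_center) -> float:
    """Distance center-center (A)."""
    a = np.asarray(pred_center, dtype=float)
    b = np.asarray(actual_center, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("centers must be finite")
    return float(np.linalg.norm(a - b))


def success_rate(records: list[EvalRecord], threshold: float = DCC_THRESHOLD) -> float:
    """Fraction of sites with DCC <= threshold; misses and non-predictions
    count in the denominator only."""
    if not records:
        raise ValueError("success_rate of an empty record set is undefined")
    hits = sum(1 for r in records if r.dcc <= threshold)
    return hits / len(records)


def _as_voxel_set(obj) -> set:
    if isinstance(obj, SiteMask):
        return obj.voxels
    if isinstance(obj, PocketPrediction):
        return set(obj.voxels)
    return set(obj)


def dvo(pred, actual) -> float:
    """Discretized volume overlap: |pred & actual| / |pred | actual|."""
    p, a = _as_voxel_set(pred), _as_voxel_set(actual)
    if not p and not a:
        raise ValueError("DVO of two empty voxel sets is undefined")
    return len(p & a) / len(p | a)


def pli(ligand, pred) -> float:
    """Proportion of the ligand inside the predicted site:
    |ligand & pred| / |ligand|."""
    lig, p = _as_voxel_set(ligand), _as_voxel_set(pred)
    if not lig:
        raise ValueError("PLI with an empty ligand voxel set is undefined")
    return len(lig & p) / len(lig)


def evaluate_structure(
    pockets: list[PocketPrediction],
    actual_site: SiteCoords,
    spec: GridSpec,
    ligand: SiteCoords | None = None,
    structure_id: str = "",
    policy: str = "min_dcc",
) -> EvalRecord:
    """Score one structure's predictions against its annotated site.

    ``policy`` selects which pocket is paired with the site: ``"min_dcc"``
    (the closest pocket) or ``"top_ranked"`` (the highest-mean-probability
    pocket, i.e. the first of the sorted prediction list).  No pockets at
    all yields an FN record.
    """
    if policy not in ("min_dcc", "top_ranked"):
        raise ValueError(f"unknown pairing policy {policy!r}")
    if not pockets:
        return EvalRecord(structure_id=structure_id, dcc=NO_PREDICTION, klass="FN")
    site_center = actual_site.center
    if policy == "top_ranked":
        chosen = pockets[0]
    else:
        chosen = min(pockets, key=lambda p: dcc(p.center, site_center))
    d = dcc(chosen.center, site_center)
    if d > DCC_THRESHOLD:
        return EvalRecord(structure_id=structure_id, dcc=d, klass="FP")
    site_mask = voxelize_site(actual_site, spec)
    record_dvo = dvo(chosen, site_mask)
    record_pli = None
    if ligand is not None:
        ligand_mask = voxelize_site(ligand, spec)
        record_pli = pli(ligand_mask, chosen)
    return EvalRecord(
        structure_id=structure_id, dcc=d, klass="TP",
        dvo=record_dvo, pli=record_pli,
    )


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN); zero when the denominator vanishes."""
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, the convention used for printed F1 tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(records: list[EvalRecord]) -> SummaryStats:
    """Aggregate per-structure records into TP/FP/FN counts, F1, success
    rate, and mean DVO/PLI over true positives."""
    if not records:
        raise ValueError("cannot summarize an empty record set")
    tp = sum(1 for r in records if r.klass == "TP")
    fp = sum(1 for r in records if r.klass == "FP")
    fn = sum(1 for r in records if r.klass == "FN")
    dvos = [r.dvo for r in records if r.klass == "TP" and r.dvo is not None]
    plis = [r.pli for r in records if r.klass == "TP" and r.pli is not None]
    return SummaryStats(
        tp=tp, fp=fp, fn=fn,
        f1=f1_score(tp, fp, fn),
        success_rate=success_rate(records),
        mean_dvo=float(np.mean(dvos)) if dvos else None,
        mean_pli=float(np.mean(plis)) if plis else None,
    )
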