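"""Score pocket predictions with DCC, DVO, PLI and the F1 protocol.

Constructs a small synthetic evaluation set — one perfect prediction, one
offset prediction, one miss and one structure without any prediction — and
summarizes the outcome the way the result tables do.
"""

import numpy as np

from pocketgrid.metrics import evaluate_structure, round_half_up, summarize
from pocketgrid.structio import SiteCoords
from pocketgrid.voxelize import GridSpec, PocketPrediction, voxelize_site

spec = GridSpec()
records = []
rng = np.random.default_rng(0)

for sid, offset, predict_anything in [
    ("perfect", 0.0, True),     # DCC 0  -> TP
    ("near", 3.0, True),        # DCC 3  -> TP (<= 4 A)
    ("off", 12.0, True),        # DCC 12 -> FP
    ("silent", 0.0, False),     # no prediction -> FN
]:
    site = SiteCoords(points=spec.center + rng.normal(0, 1.5, size=(12, 3)))
    pockets = []
    if predict_anything:
        mask = voxelize_site(site, spec)
        shifted = {(i + int(offset // 2), j, k) for i, j, k in mask.voxels}
        pockets = [PocketPrediction(
            voxels=shifted, center=site.center + [offset, 0, 0], mean_prob=0.9
        )]
    records.append(
        evaluate_structure(pockets, site, spec, ligand=site, structure_id=sid)
    )

for r in records:
    d = "no-prediction" if np.isinf(r.dcc) else f"{r.dcc:4.1f} A"
    extras = f" dvo={r.dvo:.2f} pli={r.pli:.2f}" if r.klass == "TP" else ""
    print(f"{r.structure_id:>8}: DCC {d:>14} -> {r.klass}{extras}")

stats = summarize(records)
print(f"\nTP={stats.tp} FP={stats.fp} FN={stats.fn} "
      f"F1={round_half_up(stats.f1, 2)} success_rate={stats.success_rate:.2f}")
# F1 counts a hit as DCC <= 4 A; a structure with no prediction at all is
# a false negative (every structure has a true site, so there are no TNs).
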