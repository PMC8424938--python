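"""Run the structural-similarity cleaning pipeline on a synthetic batch.

The batch contains an unparseable file, a near-duplicate pair sharing a
UniProt id, a structure whose site lies 80 A from its center, and two
healthy singletons — one per branch of the cleaning flow.
"""

import tempfile

from pocketgrid.cleaner import fingerprint_matrix, run_cleaning, sliding_tanimoto
from pocketgrid.fixtures import make_cleaning_batch
from pocketgrid.structio import read_structure

with tempfile.TemporaryDirectory() as tmp:
    structures, sites, mapping, expected = make_cleaning_batch(tmp, seed=0)
    report, retained = run_cleaning(structures, sites, mapping)

    seqs = {
        sid: "".join(read_structure(p).sequence.values())
        for sid, p in structures.items() if sid.startswith("dup")
    }

print("dispositions (kept / deduplicated / dropped_parse / dropped_distance):")
for sid, disp in sorted(report.dispositions.items()):
    print(f"  {sid:>8} -> {disp}")

sim = sliding_tanimoto(
    fingerprint_matrix(seqs["dupA"]), fingerprint_matrix(seqs["dupB"])
)
print(f"\nduplicate pair sliding Tanimoto: {sim:.3f} "
      "(>= 0.8 marks structures as redundant copies)")
print(f"retained for training: {sorted(retained)}")
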