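"""One-shot pipeline: synthetic apo/holo systems to a full report bundle.

Generates a loop-mobile ("apo") and loop-closed ("holo") system from one
seed, runs every analysis, and writes DF matrices, RMSD series, contact
and H-bond tables, crystal comparisons and a provenance record.
"""

import json
from pathlib import Path

from loopdyn import RunConfig, run

cfg = RunConfig(outdir="scratch/example_run", seed=7, n_frames=150,
                n_replicas=2)
summary = run(cfg)

print("artifacts:", sorted(p.name for p in Path(cfg.outdir).iterdir()))
print("\nmean RMSD (A):")
for key, value in summary["rmsd_mean"].items():
    print(f"  {key:10s} {value:7.3f}")
print("\nstable-contact comparison:", json.dumps(summary["contacts"]))
print("loop angle between the generated apo and holo structures: "
      f"{summary['crystal']['loop_angle']['angle']:.2f} deg")
# The apo loop RMSD dwarfs its core RMSD while the holo loop stays quiet,
# and excluding the loop collapses the apo whole-protein RMSD -- the
# two-state generator reproduces the bound-vs-free contrast by design.
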