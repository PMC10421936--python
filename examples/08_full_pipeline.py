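"""End-to-end pipeline run on a simulated cohort.

Writes a synthetic cohort to disk, runs every stage (quantify -> diffexpr ->
cluster -> eqtl -> citnet -> targets) through the orchestrator, and prints
the manifest's per-stage record counts.  The same run is available from the
shell as `mirtriad demo <outdir>`.
"""

import json
import tempfile
from pathlib import Path

from mirtriad import simulate_and_run

with tempfile.TemporaryDirectory() as tmp:
    run_dir = simulate_and_run(Path(tmp) / "demo", n_subjects=100,
                               n_triplets=12, seed=1)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    for stage, info in manifest["stages"].items():
        print(f"{stage}: {info}")
    print("\noutputs:", sorted(p.name for p in run_dir.glob("*.tsv")))
# The manifest records thresholds, seeds and row counts per stage; rerunning
# with the same configuration reproduces byte-identical outputs.
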