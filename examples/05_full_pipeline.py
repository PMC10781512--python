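"""One-config end-to-end run: simulate -> align -> call -> test -> targets.

Equivalent to `miredit run --config cfg.yaml`; every stage output lands in
the run directory together with a manifest of parameters and checksums.
"""

import json
import tempfile
from pathlib import Path

import miredit as m
from miredit.pipeline import PipelineConfig, run_pipeline

outdir = Path(tempfile.mkdtemp()) / "demo-run"
cfg = PipelineConfig(
    outdir=str(outdir),
    simulate=m.SimConfig(
        n_hairpins=6,
        coverage_mean=300,
        group_sizes=(4, 4),
        planted_sites=(m.PlantedSite("sim-mir-001-3p", 6, 0.85, 0.40),),
        rng_seed=3,
    ),
)
manifest = run_pipeline(cfg)
print(json.dumps(manifest["stages"], indent=2))
print(f"\noutputs in {outdir}:")
for p in sorted(outdir.glob("*.tsv")):
    print(f"  {p.name}")

# The manifest records per-stage record counts; rerunning with the same
# config reproduces identical table checksums.
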