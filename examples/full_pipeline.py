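"""Run the whole pipeline end to end and print its report.

One seeded call simulates trial-level data, reduces it to reactivity
cells, computes reliability, per-bin contrasts and the trajectory fit,
and writes every table plus a manifest to an output directory. Identical
config + seed reproduces the bundle byte for byte.
"""

import tempfile
from pathlib import Path

from emgreact.pipeline import RunConfig, run_pipeline

outdir = Path(tempfile.mkdtemp()) / "run"
config = RunConfig(output_dir=outdir, seed=1, n_participants=40,
                   n_trials_per_condition=10)
run_pipeline(config)

print("files written:")
for p in sorted(outdir.iterdir()):
    print(f"  {p.name}")
print()
print((outdir / "summary.txt").read_text())
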