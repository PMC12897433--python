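"""Run every stage end to end from a single configuration and list the
artifacts. Identical (config, seed) runs are byte-identical.

Run:  python examples/04_full_pipeline.py
Equivalent CLI:  shgquant run-all --outdir example_run --seed 0
"""

from pathlib import Path

from shgquant.config import PipelineConfig
from shgquant.pipeline import run_pipeline

config = PipelineConfig(
    outdir="example_run",
    seed=0,
    # shrink the default study for a quick demo
    n_animals=3,
    images_per_animal=6,
    window_stride=10,
    n_trees=50,
    k_folds=10,
)

outdir = run_pipeline(config)

print("\nartifacts:")
for path in sorted(Path(outdir).iterdir()):
    print(f"  {path.name}")
print("\nreport:")
print((Path(outdir) / "report.txt").read_text())
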