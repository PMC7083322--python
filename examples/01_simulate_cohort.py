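"""Simulate a small paired test–retest OCTA cohort and write it to disk.

Each eye gets two acquisitions of two retinal layers (superficial, deep)
sharing one ground-truth vessel tree but with independent speckle, plus a
FAZ polygon and the emulated manual rater's delineations.
"""

from pathlib import Path

from octarep import SimulationConfig, generate_cohort
from octarep.pipeline import run_simulate

config = SimulationConfig(image_size_px=256, n_healthy=3, n_pathology=3, seed=42)
cohort = generate_cohort(config)

for rec in cohort:
    print(
        f"{rec.eye_id}  group={rec.group:9s} age={rec.age:5.1f}  "
        f"true vessel fraction={rec.tree.true_vessel_fraction:.3f}  "
        f"images={len(rec.images)}"
    )
# true vessel fraction: ground-truth area coverage of the rendered vessels;
# pathology eyes are sparser because terminal capillaries were dropped.

outdir = Path("scratch/example_cohort")
manifest = run_simulate(config, outdir)
print(f"\nwrote cohort (PNG images + FAZ JSONs + manifest) to {manifest.parent}")
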