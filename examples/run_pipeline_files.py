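"""File-based end-to-end run: scan CSV in, gait parameters and manifest out.

Writes a simulated recording to disk in the plain-text scan dialect, then
runs the whole pipeline with the default configuration.  All intermediate
artifacts (sensor transforms, background mask, leg track, events,
parameters, run manifest) land in the output directory, so a run can be
audited or resumed stage by stage.
"""

import json
import tempfile
from pathlib import Path

import gaitlidar as gl
from gaitlidar.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    paths = gl.make_fixture("straight_walk", tmp, seed=5)
    print(f"scan file: {Path(paths['scans']).stat().st_size / 1e6:.1f} MB")

    out_dir = Path(tmp) / "out"
    result = run_pipeline(paths["scans"], out_dir=out_dir)

    print("artifacts written:")
    for path in sorted(out_dir.iterdir()):
        print(f"  {path.name}")
    print("\nrecovered parameters:")
    for key, value in result["parameters"].summary().items():
        print(f"  {key:<18}{value:10.3f}")
    manifest = json.loads((out_dir / "manifest.json").read_text())
    print(f"\nmanifest config hash: {manifest['config_hash']}")
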