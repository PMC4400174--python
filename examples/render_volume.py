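"""Build a label-encoded Cartesian volume from a segmented phantom and render it.

Each polar frame is denoised and remapped (wall in [0, 200]), the lumen
interior is cleared, features are stamped (guide-wire 210, apposed strut 230,
malapposed strut 255), frames are warped to Cartesian disks, lumen-centered,
and stacked; a maximum-value projection surfaces the most important voxel on
each ray (the encoding is ordered by clinical priority).
"""

import numpy as np

from ivoct import AcquisitionConfig, make_phantom_polar_pullback
from ivoct import pipeline
from ivoct.visualize import LABEL_APPOSED, LABEL_GUIDEWIRE, LABEL_MALAPPOSED
import tempfile
from pathlib import Path

cfg = AcquisitionConfig(n_frames=12, n_alines=256)
stack, truth = make_phantom_polar_pullback(
    cfg, rows=400, stent_frames=(2, 9), noise_sd=6.0, seed=4
)
out = Path(tempfile.mkdtemp(prefix="ivoct_render_"))
pcfg = pipeline.PipelineConfig(
    cartesian_size=256, volume_size=128, stent_length_mm=1.4, margin_frames=2,
    render_views=("axial", "cutaway-y"),
)
summary = pipeline.process_stack(stack, out, pcfg, cfg)

import tifffile
vol = tifffile.imread(out / "volume.tif")
print(f"volume: {vol.shape} voxels, encoding: wall 0-200, guide-wire {LABEL_GUIDEWIRE}, "
      f"apposed {LABEL_APPOSED}, malapposed {LABEL_MALAPPOSED}")
for name, label in [("guide-wire", LABEL_GUIDEWIRE), ("apposed", LABEL_APPOSED),
                    ("malapposed", LABEL_MALAPPOSED)]:
    print(f"  {name:11s} voxels: {(vol == label).sum()}")
print(f"summary: {summary['strut_count']} struts detected, "
      f"{summary['malapposed_count']} malapposed; artifacts in {out}")
print("In the cutaway render the wall is a red ramp, struts yellow, the wire gray,")
print("and malapposed struts blue - the colors are a pure lookup on the label values.")
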