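"""Render synthetic CLOD scans and compare ring artifacts across materials.

Builds one scan per compensating material (air vs optical grease), reads the
center ROI back, and prints the fringe visibility and the ROI coefficient of
variation. Lower visibility and lower CV mean a cleaner scan.
"""

import numpy as np

from clodscan import (
    GroundTruthResponse,
    LensGeometry,
    ROISpec,
    ScanConfig,
    default_material,
    extract_channel,
    fringe_visibility,
    render_scan,
    roi_stats,
    roi_window,
)

geometry = LensGeometry()
truth = GroundTruthResponse()
config = ScanConfig(mode="reflective", seed=1)

print("25 cGy footprint, reflective mode, 300 dpi, 3.5 mm ROI")
for name in ("air", "DS", "SC", "OG"):
    material = default_material(name, config.mode)
    image, manifest = render_scan([0.25], geometry, material, config, truth)
    red = extract_channel(image, "red")
    window = roi_window(
        ROISpec(tuple(manifest["footprints"][0]["center_mm"])),
        image.dpi,
        red.pixels.shape,
    )
    stats = roi_stats(red, window)
    vis = fringe_visibility(material)
    print(
        f"  {name:>3}: visibility {vis:.4f}  ROI mean {stats.mean:8.1f} counts"
        f"  SD {stats.sd:7.1f}  CV {stats.cv:.4f}"
    )
print(
    "\nAir shows strong Newton's rings (high visibility, high CV); optical\n"
    "grease nearly index-matches the glass and lens, so its scan is the\n"
    "most uniform."
)
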