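"""Generate a synthetic intertidal shore and plan a kite flight over it.

Builds a 40 x 24 m rocky-shore scene (heightfield, coverage classes, tidal
water line), plans a serpentine two-strip flight at 15 m, and renders one
colour frame.  Printed numbers: scene relief, water coverage, the camera
footprint, and the rendered image statistics.
"""

import numpy as np

from shoremapper.spectra import default_camera_responses
from shoremapper.synthetic import (
    extract_waterline,
    footprint_polygon,
    generate_scene,
    plan_flight,
    render_views,
)

scene = generate_scene(size_m=(40.0, 24.0), seed=1)
print(f"scene: {scene.size_m[0]:.0f} x {scene.size_m[1]:.0f} m, "
      f"grid {scene.heightfield.shape}, "
      f"elevation {scene.heightfield.min():.2f}..{scene.heightfield.max():.2f} m")
print(f"water datum {scene.water_datum} m; "
      f"{(scene.coverage == 7).mean():.0%} of cells are water")

waterline = extract_waterline(scene)
print(f"waterline: {len(waterline)} points at elevation "
      f"{waterline[:, 2].mean():.3f} +- {waterline[:, 2].std():.4f} m")

plan = plan_flight(scene, altitude_m=15.0, overlap=0.55, seed=2, n_images=8)
fp = footprint_polygon(plan.poses[0], plan.intrinsics,
                       float(np.median(scene.heightfield)))
xs, ys = fp.exterior.xy
print(f"flight: {len(plan)} poses, altitude {plan.altitude_range[0]:.1f}-"
      f"{plan.altitude_range[1]:.1f} m, footprint "
      f"{max(xs) - min(xs):.1f} x {max(ys) - min(ys):.1f} m")

images, truth = render_views(scene, plan, default_camera_responses(), seed=3)
img = images[0]
print(f"rendered {len(images)} colour frames; {img.pixels.shape[1]}x"
      f"{img.pixels.shape[0]} px, camera-linear values "
      f"{img.pixels.min():.4f}..{img.pixels.max():.4f}")
# the footprint is the ~22 x 15 m regime of a consumer camera at kite height;
# pixel values are reflectance x channel response x exposure
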