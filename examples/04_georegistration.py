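"""Triad-scale + Horn geo-registration: why local beats global accuracy.

A scale-less reconstruction is geo-referenced in two stages: absolute scale
from tape-measured 2 m GCP triangle edges, then a rigid Horn alignment to
the handheld-GPS coordinates.  Because the scale never touches the GPS,
metre-level GPS noise inflates only the *global* residual; the *local*
(edge-length) residual stays at numerical precision.
"""

import numpy as np

from shoremapper.geodesy import GeodeticOrigin
from shoremapper.geometry import random_rotation
from shoremapper.georef import GCPRecord, SimilarityTransform, georegister

origin = GeodeticOrigin(-35.0857, 150.6933, 0.0)
rng = np.random.default_rng(0)

# three equilateral 2 m triads; reconstruction frame = arbitrary similarity
true_enu = []
for t in range(3):
    c = np.array([rng.uniform(-20, 20), rng.uniform(-10, 10), rng.uniform(0, 2)])
    R = random_rotation(rng)
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(3):
        ang = phase + 2 * np.pi * k / 3
        true_enu.append(c + R @ (2.0 / np.sqrt(3) *
                                 np.array([np.cos(ang), np.sin(ang), 0.0])))
true_enu = np.asarray(true_enu)
recon = SimilarityTransform(1 / 5.7, random_rotation(rng), rng.normal(0, 3, 3))

for gps_sd in (0.0, 1.2):
    gcps = []
    for i, p in enumerate(true_enu):
        lat, lon, alt = origin.enu_to_geodetic(p + rng.normal(0, gps_sd, 3))
        gcps.append(GCPRecord(gcp_id=f"g{i}", triad_id=i // 3,
                              lat_deg=float(lat), lon_deg=float(lon),
                              alt_m=float(alt), edge_m=2.0,
                              recon_xyz=recon.apply(p)))
    tf, report = georegister(gcps, origin)
    print(f"GPS noise sd {gps_sd:.1f} m -> scale {tf.scale:.6f} "
          f"(true {5.7:.1f}); global residual {report.global_residual_m:.4f} m, "
          f"local residual {report.local_residual_m:.2e} m")
# the global residual tracks the GPS noise while the local residual stays
# tiny: the map is locally precise even with a metre-grade receiver
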