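"""Visibility-squared weighting of the differential phase sinogram.

Bone scatters x-rays at small angles and destroys fringe visibility, so
the phase of rays through bone is noise-dominated and backprojects into
streaks.  Weighting the phase sinogram with the squared relative
visibility down-weights exactly those rays.  The comparison below
reconstructs the same low-dose scan with and without the weighting.
"""

import numpy as np
import scipy.ndimage as ndi

from talbotct import AcquisitionConfig, acquire, build_phantom, fbp_phase, retrieve
from talbotct.phantom import Tissue

ph = build_phantom(256, pixel_size_um=30.0, scene="bone_streak", seed=5)
cfg = AcquisitionConfig(n_projections=301, n_steps=4, flux=1e3, seed=5)
sinos = retrieve(acquire(ph, cfg))
print(f"relative visibility through bone drops to {sinos.rel_visibility.min():.2f}")

plain = fbp_phase(sinos, output_size=ph.size)
weighted = fbp_phase(sinos, output_size=ph.size, weight_visibility=True)

# probe a soft-tissue region away from the bone disc
soft = ph.labels == int(Tissue.SOFT_TISSUE)
bx, by = ph.features["bone"]["center_px"]
Y, X = np.ogrid[: ph.size, : ph.size]
c = ph.size // 2
far = (X - c - bx) ** 2 + (Y - c - by) ** 2 > (0.12 * ph.size) ** 2
roi = ndi.binary_erosion(soft & far, iterations=3)

print(f"off-bone delta std, unweighted : {plain[roi].std():.3e}")
print(f"off-bone delta std, weighted   : {weighted[roi].std():.3e}")
print(
    "\nThe weighting reduces the streak noise radiating from the bone disc"
    "\nin this low-dose regime; it only reduces the magnitude of the"
    "\nstreaks and biases values near bone, so quantitative analyses use"
    "\nthe unweighted reconstruction."
)
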