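"""Solve Talbot and Talbot-Lau interferometer geometries from first principles.

Given grating periods, design energy, fractional Talbot order and the phase
shift of G1, the package returns the analyzer period p2, the inter-grating
distance d, the source-grating distance l and the cone magnification M.
"""

import math

from talbotct import talbot_distance, talbot_lau_geometry, wavelength

print("Photon wavelengths")
for e in (23.0, 35.0):
    print(f"  {e:4.0f} keV -> {wavelength(e):.5f} angstrom")

print("\nThree-grating tube design (23 keV, p0=10 um, p1=3.51 um, order 3, pi/2):")
tube = talbot_lau_geometry(10.0, 3.51, 23.0, 3, "pi_half")
print(f"  magnification M = {tube.magnification:.3f}")
print(f"  analyzer period p2 = {tube.p2_um:.3f} um")
print(f"  inter-grating distance d = {tube.d_mm:.1f} mm")
print(f"  source-to-G1 distance l = {tube.l_mm:.0f} mm")

print("\nPlane-wave synchrotron design (35 keV, p1=4.79 um, order 5, pi):")
sr = talbot_lau_geometry(math.inf, 4.79, 35.0, 5, "pi")
print(f"  self-image period p2 = {sr.p2_um:.2f} um")
print(f"  Talbot distance d = {sr.d_mm:.1f} mm")
print(f"  (same as talbot_distance: {talbot_distance(4.79, 35.0, 5, 'pi'):.1f} mm)")

print(
    "\nThe cone design magnifies the G1 self-image onto G2: p2 = M p1 for a"
    "\npi/2 grating, and d grows by the same factor over the plane-wave"
    "\nfractional Talbot distance."
)
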