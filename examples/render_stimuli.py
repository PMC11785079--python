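"""Render scaled gratings and inspect their local spatial-frequency fields.

Builds the 28-class NSD-style catalog, renders one annulus, and compares the
analytic local spatial frequency at a few eccentricities with the inverse-
eccentricity law the stimuli are designed around.
"""

import numpy as np

from sfmaps import local_stimulus, make_catalog, render_grating

catalog = make_catalog("nsd")
print(f"catalog: {len(catalog)} classes, "
      f"{sum(len(c.phases) for c in catalog)} (class, phase) stimuli")

annulus = next(c for c in catalog if c.shape == "annulus"
               and c.freq.omega_r == 6)
img = render_grating(annulus, phase=0.0, n_px=512, extent_deg=8.4)
print(f"rendered annulus (omega_r=6): {img.pixels.shape} px, "
      f"{img.ppd:.1f} px/deg, anti-aliasing mask radius "
      f"{img.mask_radius_deg:.3f} deg")

print("\neccentricity -> local spatial frequency (cycles/deg):")
for r in (0.5, 1.0, 2.0, 4.0):
    ls = local_stimulus(r, 0.0, annulus.freq)
    print(f"  r = {r:.1f} deg : {ls.sf_cpd:.3f} cpd "
          f"(period {ls.period_dpc:.3f} deg/cycle)")

# Each doubling of eccentricity halves the local frequency: a single scaled
# grating probes every retinotopic location near its own sensitive range.
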