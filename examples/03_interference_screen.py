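"""Interference screening against an unlabeled control.

A background ion overlapping an isotopologue m/z makes that channel
unusable. The screen finds such channels automatically: after
natural-abundance correction, an unlabeled control should have essentially
all signal at M0, so any residual fraction above threshold flags an
interference. Flagged channels are excluded (and the rest renormalized) in
the labeled-sample fits.
"""

import numpy as np

from sisaflux import screen_interferences, flux_image
from sisaflux.isotopes import na_correct_image
from sisaflux.msi_io import IonImageStack
from sisaflux.synthetic import (
    PhantomSpec,
    generate_phantom,
    palmitate_interference_contaminants,
)

spec = PhantomSpec(width=24, height=16, seed=7,
                   contaminants=palmitate_interference_contaminants(intensity=80))
phantom = generate_phantom(spec)

report = screen_interferences(phantom.unlabeled, tissue_mask=phantom.tissue_mask,
                              threshold=0.02)
print("flagged palmitate isotopologues:", report.flagged_indices("palmitate"))
print("flagged stearate isotopologues:", report.flagged_indices("stearate"))
print("-> exactly the M1/M4/M5 channels that received injected background ions.\n")

iso_mask = report.mask_for("palmitate")
stack = phantom.labeled
corrected = stack.tensor.copy()
sl = stack.channel_slice("palmitate")
corrected[sl] = na_correct_image(stack.tensor[sl], mask=iso_mask)
cstack = IonImageStack(targets=stack.targets, tensor=corrected, grid=stack.grid)
img = flux_image(cstack, "palmitate", tissue_mask=phantom.tissue_mask,
                 iso_mask=iso_mask)
print(f"masked fit, tumor   g = {np.nanmean(img.g[phantom.tumor_mask]):.3f} (true 0.55)")
print(f"masked fit, healthy g = {np.nanmean(img.g[phantom.healthy_mask]):.3f} (true 0.20)")
print("-> with 14 of 17 channels the system is still overdetermined;")
print("   excluding interferences costs almost no accuracy.")
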