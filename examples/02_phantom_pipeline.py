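"""Full imaging pipeline on a synthetic two-region brain phantom.

Generates a labeled phantom (tumor g = 0.55, healthy g = 0.20, 1% noise),
writes it as imzML, reads it back, extracts isotopologue images, segments
tissue, corrects natural abundance and fits the de novo lipogenesis model at
every pixel.
"""

import tempfile
from pathlib import Path

import numpy as np

from sisaflux import PhantomSpec, generate_phantom, flux_image, region_summary
from sisaflux.isotopes import na_correct_image
from sisaflux.msi_io import IonImageStack, extract_ion_images, read_imzml
from sisaflux.preprocess import segment_tissue
from sisaflux.synthetic import write_imzml

phantom = generate_phantom(PhantomSpec(width=24, height=16, seed=3))

with tempfile.TemporaryDirectory() as tmp:
    path = str(Path(tmp) / "labeled.imzML")
    write_imzml(phantom.labeled, path)
    spectra = read_imzml(path)
    stack = extract_ion_images(spectra, phantom.labeled.targets, tol_ppm=10)

mask = segment_tissue(stack, seed=0)
print(f"segmented {mask.n_tissue} tissue pixels "
      f"(ground truth {phantom.tissue_mask.sum()})")

corrected = stack.tensor.copy()
for t in stack.targets:
    sl = stack.channel_slice(t.name)
    corrected[sl] = na_correct_image(stack.tensor[sl])
cstack = IonImageStack(targets=stack.targets, tensor=corrected, grid=stack.grid)

img = flux_image(cstack, "palmitate", tissue_mask=mask.mask, t_hours=48.0)
cmp = region_summary(img, phantom.tumor_mask, phantom.healthy_mask)
print(f"tumor   g = {cmp.mean_a:.3f} +/- {cmp.sd_a:.3f}")
print(f"healthy g = {cmp.mean_b:.3f} +/- {cmp.sd_b:.3f}")
print(f"flux ratio = {cmp.ratio:.2f}  ({cmp.test}: t = {cmp.t_statistic:.1f})")
print("-> the tumor synthesizes its palmitate ~2.75x faster than healthy tissue;")
print("   pool-size matrix effects cancel because only isotopologue ratios enter.")
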