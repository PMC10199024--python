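# sisaflux

Quantitative flux imaging from stable-isotope-labeled mass spectrometry
imaging (MSI) data.

When an animal is fed a ¹³C tracer (e.g. U-¹³C glucose), every metabolite's
isotopologue pattern — the intensities a₀…aₙ at the monoisotopic m/z plus
k·1.0033548 Da — encodes how much of that metabolite was made from the tracer.
Pool-size MSI images are confounded by pixel-dependent matrix effects, but
isotopologue *ratios* are not: all isotopologues of a metabolite ionize with
the same efficiency. `sisaflux` turns imzML images of labeled tissue into
per-pixel maps of

- **fractional labeling**  f_x = a_x / Σⱼ aⱼ,
- **fractional carbon-atom labeling**  L = Σⱼ j·aⱼ / (n Σⱼ aⱼ), and
- **fractional biosynthesis flux** g(t) — the fraction of a fatty-acid pool
  newly synthesized during the labeling period — via per-pixel Spatial
  Isotopologue Spectral Analysis (SISA).

For a fatty acid built from n acetyl units with monomer labeling X =
(X₀, X₁, X₂), SISA models the isotopologue fractions as

    P = g · power(X, n) + (1 − g) · power(N, n)

jointly inferring X and g at every pixel (power = n-fold self-convolution;
N = pre-existing pool labeling). For palmitate (n = 8) the 17 isotopologue
equations overdetermine the 3 free parameters. Stearate adds an elongation
term e(t) for pre-existing palmitate extended by one labeled unit:

    P = g · power(X, 9) + e · conv(X, power(N, 8)) + (1 − g − e) · power(N, 9)

The package also provides classical ISA (known tracer labeling T and
dilution D) as a reference model, natural-abundance correction, interference
screening against unlabeled control tissue, tissue segmentation, mass
recalibration, an error-propagation analysis, and a synthetic phantom
generator so the entire pipeline is testable without any downloads.

## Worked example

Fit the de novo lipogenesis model to a single noiseless isotopologue pattern
and recover the generating parameters:

```python
import numpy as np
from sisaflux import sisa_forward, fit_sisa

X_true, g_true = (0.45, 0.15, 0.40), 0.55     # acetyl-CoA labeling, turnover
observed = sisa_forward(X_true, (1, 0, 0), g_true, n_subunits=8)
fit = fit_sisa(observed)
print(f"g = {fit.g:.4f}   X = {np.round(fit.X, 4)}   sse = {fit.sse:.2e}")
```

prints

```
g = 0.5500   X = [0.45 0.15 0.4 ]   sse = 2.96e-32
```

i.e. 55% of the palmitate pool was newly synthesized during labeling, from a
precursor pool in which 40% of acetyl units carry two heavy carbons.

End-to-end on a synthetic two-region brain phantom (tumor g = 0.55, healthy
g = 0.20, 1% intensity noise):

```python
import numpy as np
from sisaflux import PhantomSpec, generate_phantom, flux_image
from sisaflux.isotopes import na_correct_image
from sisaflux.msi_io import IonImageStack

phantom = generate_phantom(PhantomSpec(width=24, height=16, seed=3))
stack = phantom.labeled
corrected = stack.tensor.copy()
for t in stack.targets:
    sl = stack.channel_slice(t.name)
    corrected[sl] = na_correct_image(stack.tensor[sl])
cstack = IonImageStack(targets=stack.targets, tensor=corrected, grid=stack.grid)
img = flux_image(cstack, "palmitate", tissue_mask=phantom.tissue_mask)
print(f"tumor   g = {np.nanmean(img.g[phantom.tumor_mask]):.3f}")
print(f"healthy g = {np.nanmean(img.g[phantom.healthy_mask]):.3f}")
```

prints

```
tumor   g = 0.550
healthy g = 0.200
```

an ~2.75-fold higher lipogenic flux in the tumor region. The scripts in
`examples/` walk through each capability (forward models and fitting, the
imzML pipeline, interference screening, error propagation) with commentary.

## Command line

The same pipeline is scriptable from a shell:

```sh
sisaflux simulate --out phantom --seed 9 --with-interferences
sisaflux extract  --imzml phantom/labeled.imzML --targets phantom/targets.csv --out labeled
sisaflux extract  --imzml phantom/unlabeled.imzML --targets phantom/targets.csv --out unlabeled --unlabeled
sisaflux screen   --stack unlabeled/stack.npz --mask unlabeled/tissue_mask.csv --out screened
sisaflux flux     --stack labeled/stack.npz --mask labeled/tissue_mask.csv \
                  --target palmitate --screen-report screened/interference_report.csv --out flux
sisaflux errorprop --n-reps 100 --measured-error 0.003 --out ep
```

Every output directory carries a `provenance.json` (command, options, config
hash, software version).

## Layout

- `src/sisaflux/msi_io.py` — imzML I/O, m/z ladders, extraction, recalibration
- `src/sisaflux/preprocess.py` — segmentation, 3×3 Gaussian blur, TIC normalization
- `src/sisaflux/isotopes.py` — fractional labeling, NA correction, interference screen
- `src/sisaflux/sisa.py` — forward models, per-pixel fitting, flux images, ROI stats
- `src/sisaflux/errorprop.py` — measured error, noise-gradient simulation, projection
- `src/sisaflux/synthetic.py` — ground-truth phantom generator and imzML writer
- `src/sisaflux/cli.py` — the `sisaflux` command
- `docs/methods.md` — models, assumptions, parameter defaults, limitations
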