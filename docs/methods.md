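# Methods

## Problem and model

`sisaflux` quantifies *fractional biosynthesis fluxes* from mass spectrometry
imaging (MSI) of tissue from animals fed a stable-isotope tracer (typically
U-¹³C glucose). The observable at each pixel is the isotopologue pattern of a
target metabolite: intensities a₀…aₙ at the monoisotopic ion m/z plus
k·1.0033548 Da for k heavy carbons. Two derived per-pixel quantities are
matrix-effect free, because all isotopologues of a metabolite ionize with the
same efficiency:

- fractional labeling  f_x = a_x / Σⱼ aⱼ
- fractional carbon-atom labeling  L = Σⱼ j·aⱼ / (n · Σⱼ aⱼ)

Fatty acids are polymers of two-carbon (acetyl-CoA) units, so their labeling
pattern is a polynomial in the monomer labeling 3-vector (m₀, m₁, m₂) — the
probability of an acetyl unit carrying 0, 1 or 2 heavy carbons. Writing
`power(m, n)` for the n-fold self-convolution of that vector, the classical
isotopologue-spectral-analysis (ISA) model of a product with n subunits is

    P = g·power((1−D)·N + D·T, n) + (1−g)·power(N, n)

with T the tracer-derived monomer labeling, D the tracer dilution, N the
pre-existing pool labeling and g(t) the fraction of the pool newly
synthesized during the labeling period. On imaging platforms T and D cannot
be measured, so the spatial variant replaces the synthesis-pool labeling with
a free simplex vector X that is inferred jointly with g at every pixel:

    P = g·power(X, n) + (1−g)·power(N, n)

For palmitate (n = 8) this gives 17 isotopologue equations for 3 free
parameters (2 simplex d.o.f. + g): overdetermined, and algebraically
identical to the classical model when X = (1−D)N + DT. Stearate is made by
appending one unit to palmitate, so its model separates fully de novo
synthesis (g) from elongation of pre-existing chains (e):

    P = g·power(X, 9) + e·conv(X, power(N, 8)) + (1−g−e)·power(N, 9)

The biologically meaningful total for stearate is g + e, the fraction newly
made during labeling. Everything is fractional; no absolute fluxes
(moles/time) are produced, and the labeling duration t is carried as
metadata only — no rate-constant extrapolation.

## Pipeline

1. **Read imzML** (processed or continuous; continuous is expanded on read)
   with pyimzml. Coordinates are 0-based, x right / y down.
2. **Recalibration** (optional): per pixel, observed peaks within a search
   tolerance (default 20 ppm) of user-supplied reference m/z values are
   matched; a linear ppm-shift-vs-m/z model is fitted per pixel (≥3 matches),
   falling back to a constant offset (2 matches) or the grid-median model
   (<2). The published adaptive-pixel approach is cited without formulas, so
   this simple robust variant is the package's own choice. Intensities are
   never changed.
3. **Extraction**: per pixel and ladder m/z, peak intensities within
   ±tol_ppm (default 10 ppm, matched to a ~43k-FWHM instrument) are summed
   into the (channels × height × width) tensor. Overlapping windows between
   targets are logged, not merged — the interference screen is the
   authoritative exclusion mechanism.
4. **Segmentation**: pixels are projected onto the top principal components
   (default 5) of their channel vectors and split by 2-means; the cluster
   with higher mean total ion current is tissue. The tissue rule and
   component count are package choices (seeded, deterministic).
5. **Denoising** (optional): 3×3 Gaussian blur, sigma 1 px truncated to the
   3×3 support, reflect boundaries, kernel normalized to sum 1. Applied to
   raw intensity images before ratio formation; a config switch allows
   blurring fractional images instead.
6. **Normalization** (optional, `tic`): per-pixel division by total ion
   current, rescaled by the grid-median TIC. Fractional labeling is
   invariant to it by construction; it only affects pool-size displays.
7. **Natural-abundance correction**: the forward NA operator is the
   lower-triangular matrix M[i,j] = Binom(n−j, p13) evaluated at i−j
   (p13 = 0.0107; carbon only — the H/N/O contributions are neglected, an
   approximation documented here; tracer isotopic impurity is not modeled).
   Correction solves M·x = a by non-negative least squares rather than
   direct inversion so low-signal pixels cannot go negative, then rescales x
   to conserve the total. When the interference screen has masked channels,
   the image-level correction drops the corresponding *rows* of M from the
   solve: corrupted channels carry no usable information, and including them
   measurably biases the usable ones.
8. **Interference screen**: in an unlabeled control, any NA-corrected
   fractional abundance remaining at k ≥ 1 is signal that natural abundance
   cannot explain. The tissue-mean corrected fraction per isotopologue is
   compared to a threshold (default 0.02); exceeders are excluded from
   labeled-sample analysis. M0 is never flagged. Absence of a control
   produces an explicit "unscreened" status, never a silent pass.
9. **Flux fitting**: per tissue pixel, observed fractions (renormalized over
   the unmasked isotopologues) are fitted by minimizing the sum of squared
   residuals against the model prediction renormalized over the same set, so
   exclusions do not bias the fit. The de novo fit is unconstrained with X
   parameterized by squared-then-normalized components and g through a
   logistic map (all iterates feasible); the elongation fit uses explicitly
   constrained SLSQP (X on the simplex, g, e ≥ 0, g + e ≤ 1). Both
   multi-start over g ∈ {0.1, 0.3, 0.5, 0.7, 0.9} with X initialized
   alternately at N and the uniform monomer, because the eighth/ninth-order
   polynomial objective is multimodal; the de novo fit adds a Nelder-Mead
   polish of the best start. When X ≈ N the flux terms are unidentifiable
   (any g reproduces the pool pattern); a parsimony tie-break returns the
   nested no-synthesis model whenever it explains the data within 1e−12 of
   the best fit. Pixels below a configurable minimum summed intensity are
   skipped rather than fitted to noise; >50% failures aborts with
   diagnostics.

Because SISA runs on NA-corrected fractions, the pre-existing pool defaults
to N = (1, 0, 0); for uncorrected inputs a natural-abundance N =
((1−p)², 2p(1−p), p²) is available. Masked predictions are renormalized over
the unmasked subset (zero-filling was rejected as biasing); note the
equations themselves are sometimes written with either 0- or 1-based
precursor component indices in the literature — both labels are accepted in
configs, the math is identical.

## Error propagation

Unlabeled tissue measures error directly: fatty acids acquire no tracer
label, so the observed uncorrected fractional pattern should equal the
theoretical natural-abundance pattern, and the mean absolute deviation
across isotopologues (averaged over tissue pixels) is the measurement error.
A noise-gradient simulation then maps noise to flux error: for each sigma in
a grid (default 8 log-spaced levels in [0.001, 0.05]) and each of n_reps
(default 200) replicates, parameters are sampled (g, e uniform with
g + e ≤ 1 by rejection; D uniform; T uniform on the simplex — the sampling
ranges are package choices), a forward pattern is generated, independent
Gaussian noise of SD sigma is added to every fraction (clipped nonnegative,
renormalized), and the pattern is refitted. For the de novo model the
classical estimator (known T, D structure) is fitted on the same draws for
comparison. A linear regression of mean |ĝ − g| on sigma, evaluated at the
measured error, gives the projected flux error; the per-level error SDs are
regressed the same way for the ± band. Projections outside the simulated
sigma range warn (extrapolation).

Note that the mean |error| of an individual fraction under this noise model
is slightly below the folded-normal value σ·√(2/π): channels whose true
fraction is near zero clip half of their noise. The closed form holds only
where no channel clips.

## Synthetic phantoms

The generator emulates a coronal brain section with a unilateral tumor:
elliptical tissue on a 60×40 grid (50 µm pixels as metadata), a tumor
ellipse (~15% of tissue) in one hemisphere. Default conditions: palmitate
g = 0.55 (tumor) / 0.20 (healthy); stearate (g, e) = (0.15, 0.25) /
(0.02, 0.03), i.e. total 0.40 / 0.05; monomer labeling X = (0.45, 0.15,
0.40) in tumor and (0.70, 0.10, 0.20) in healthy tissue; base intensity
1000 with region pool scales 1.6 / 1.0 (emulating matrix effects, including
the DESI-vs-MALDI pool-size contradiction as a demonstration); 1%
multiplicative Gaussian intensity noise. Per pixel the forward flux model is
convolved with the NA matrix (applied as the forward operator), scaled,
noised, and optionally contaminated (extra intensity on chosen channels in a
chosen region) or mass-shifted (for recalibration tests). The unlabeled twin
is generated with g = e = 0.

What the phantom does *not* emulate: thousands of background peaks, profile
(non-centroided) spectra, spatially correlated noise, ion-mobility
separation, adduct heterogeneity, and within-region biological gradients.
Passing phantom tests therefore demonstrates correctness of the numerics and
the pipeline plumbing under the stated noise model, not robustness to every
artifact of real acquisitions.

## Problem sizes and numerical choices

The study-scale phantom is 60×40 pixels (~1400 tissue pixels), which the
package fits per-pixel for both targets in a few minutes on one CPU; unit
tests use 20×14 to 30×20 grids. Optimizer tolerances: ftol 1e−14 (L-BFGS-B /
SLSQP), Nelder-Mead polish xatol 1e−10. Noiseless recovery is accurate to
<1e−3 in g and e; masked fits (three excluded channels) carry a small
systematic residual (~5e−3) from the underdetermined masked-row NA solve.
Convergence failures across all starts are reported per pixel, not imputed.

## Known limitations

- Carbon-only NA correction; fine isotope structure and resolving-power
  effects are ignored (the instrument regime where ¹³C and e.g. ²H peaks
  are unresolved is assumed).
- DESI slide-background fatty acid acts as a pure dilution of labeling; g is
  reported as measured, underestimating absolute turnover on such platforms
  (the tumor/healthy comparison is unaffected).
- The error projection depends on the measured error of the actual dataset;
  on phantoms it reflects the injected noise model only.
- Segmentation is two-class (tissue vs background) by design.
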