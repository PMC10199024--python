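"""Ground-truth phantom MSI datasets for end-to-end testing of the pipeline.

The phantom emulates a coronal brain section with a unilateral tumor: an
elliptical tissue region on a rectangular grid, a smaller tumor ellipse inside
one hemisphere, and per-region fractional-turnover parameters for de novo
lipogenesis (palmitate) and elongation (stearate). Per pixel, the forward flux
model produces tracer-label isotopologue fractions, natural-abundance
convolution turns them into observable patterns, region-dependent pool-size
scaling emulates matrix effects, and multiplicative/additive noise emulates
measurement error. An unlabeled twin (g = e = 0) and optional contaminant
peaks support interference screening and error measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .isotopes import P13C_NATURAL, na_correction_matrix
from .msi_io import (
    PALMITATE,
    STEARATE,
    IonImageStack,
    PixelGrid,
    SpectraCollection,
    TargetMetabolite,
)
from .sisa import elongation_forward, sisa_forward

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionFlux:
    """Ground-truth flux parameters of one region for one target."""

    g: float
    e: float = 0.0
    X: tuple = (0.45, 0.15, 0.40)

    def __post_init__(self):
        if not (0 <= self.g <= 1 and 0 <= self.e <= 1 and self.g + self.e <= 1):
            raise ValueError("need 0 <= g, e and g + e <= 1")
        X = np.asarray(self.X, dtype=float)
        if X.shape != (3,) or np.any(X < 0) or abs(X.sum() - 1) > 1e-9:
            raise ValueError("X must be a 3-vector on the simplex")


@dataclass
class Contaminant:
    """A background ion overlapping an isotopologue channel."""

    mz: float
    intensity: float
    region: str = "tissue"  # tissue | tumor | healthy | all


# Default study-like conditions: tumor synthesizes ~55% of its palmitate within
# the 48 h labeling window vs ~20% in healthy tissue; total stearate synthesis
# (g + e) is ~40% vs ~5%, dominated by elongation.
DEFAULT_FLUX = {
    "palmitate": {
        "tumor": RegionFlux(g=0.55, X=(0.45, 0.15, 0.40)),
        "healthy": RegionFlux(g=0.20, X=(0.70, 0.10, 0.20)),
    },
    "stearate": {
        "tumor": RegionFlux(g=0.15, e=0.25, X=(0.45, 0.15, 0.40)),
        "healthy": RegionFlux(g=0.02, e=0.03, X=(0.70, 0.10, 0.20)),
    },
}


@dataclass
class PhantomSpec:
    """Full description of a two-region labeled/unlabeled phantom pair."""

    width: int = 60
    height: int = 40
    pixel_size: float = 50.0
    targets: tuple = (PALMITATE, STEARATE)
    flux: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FLUX.items()})
    p13: float = P13C_NATURAL
    base_intensity: float = 1000.0
    pool_scale: dict = field(default_factory=lambda: {"tumor": 1.6, "healthy": 1.0, "background": 0.0})
    fractional_noise_sd: float = 0.01
    additive_floor_sd: float = 0.0
    contaminants: list = field(default_factory=list)
    labeling_hours: float = 48.0
    seed: int = 0
    # ellipse geometry as (cx, cy, semi_x, semi_y) in fractional grid units
    tissue_ellipse: tuple = (0.5, 0.5, 0.44, 0.42)
    tumor_ellipse: tuple = (0.70, 0.42, 0.16, 0.22)

    def __post_init__(self):
        for t in self.targets:
            regions = self.flux.get(t.name, {})
            for rf in regions.values():
                if t.n_subunits is None:
                    raise ValueError(f"target {t.name} needs a subunit count for the flux model")
                if rf.e > 0 and t.n_subunits < 2:
                    raise ValueError("elongation requires n_subunits >= 2")

    def masks(self):
        """(tissue, tumor) boolean masks; tumor is nested inside tissue."""
        yy, xx = np.mgrid[0:self.height, 0:self.width]

        def ellipse(spec):
            cx, cy, sx, sy = spec
            return (((xx / self.width - cx) / sx) ** 2
                    + ((yy / self.height - cy) / sy) ** 2) <= 1.0

        tissue = ellipse(self.tissue_ellipse)
        tumor = ellipse(self.tumor_ellipse) & tissue
        if not tumor.any() or not (tissue & ~tumor).any():
            raise ValueError("degenerate phantom geometry: empty tumor or healthy region")
        return tissue, tumor


@dataclass
class PhantomResult:
    """Phantom pair plus every ground-truth map needed to verify the pipeline."""

    spec: PhantomSpec
    labeled: IonImageStack
    unlabeled: IonImageStack
    tissue_mask: np.ndarray
    tumor_mask: np.ndarray
    g_truth: dict          # target -> (h, w) map
    e_truth: dict
    pool_truth: dict       # target -> noiseless pool-size image
    clean_tensor: dict     # (labeled flag, target) -> noiseless channel tensor

    @property
    def healthy_mask(self) -> np.ndarray:
        return self.tissue_mask & ~self.tumor_mask


def _target_fractions(target: TargetMetabolite, rf: RegionFlux, labeled: bool) -> np.ndarray:
    """Tracer-label isotopologue fractions (before NA convolution) for a region."""
    N = (1.0, 0.0, 0.0)
    if not labeled:
        f = np.zeros(target.n_carbons + 1)
        f[0] = 1.0
        return f
    if rf.e > 0:
        return elongation_forward(rf.X, N, rf.g, rf.e, target.n_subunits)
    return sisa_forward(rf.X, N, rf.g, target.n_subunits)


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the labeled/unlabeled stack pair and all ground-truth maps.

    Per pixel: forward flux model -> natural-abundance convolution (the
    correction matrix applied as a forward operator) -> pool-size scaling ->
    multiplicative noise (+ additive floor) -> contaminant injection. The
    unlabeled twin uses g = e = 0 with everything else identical.
    """
    tissue, tumor = spec.masks()
    healthy = tissue & ~tumor
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    region_masks = {"tumor": tumor, "healthy": healthy}
    pool_map = np.full((h, w), spec.pool_scale.get("background", 0.0))
    for name, m in region_masks.items():
        pool_map[m] = spec.pool_scale.get(name, 1.0)
    pool_map = pool_map * spec.base_intensity

    g_truth, e_truth, pool_truth, clean = {}, {}, {}, {}
    stacks = {}
    for labeled in (True, False):
        tensors = []
        for t in spec.targets:
            M = na_correction_matrix(t.n_carbons, spec.p13)
            tensor = np.zeros((t.n_carbons + 1, h, w))
            gmap = np.full((h, w), np.nan)
            emap = np.full((h, w), np.nan)
            for rname, rmask in region_masks.items():
                rf = spec.flux[t.name][rname]
                observable = M @ _target_fractions(t, rf, labeled)
                tensor[:, rmask] = observable[:, None]
                gmap[rmask], emap[rmask] = rf.g, rf.e
            tensor = tensor * pool_map[None, :, :]
            clean[(labeled, t.name)] = tensor.copy()
            if labeled:
                g_truth[t.name], e_truth[t.name] = gmap, emap
                pool_truth[t.name] = tensor.sum(axis=0)
            tensors.append(tensor)
        full = np.concatenate(tensors, axis=0)
        if spec.fractional_noise_sd > 0:
            full = full * (1.0 + rng.normal(0.0, spec.fractional_noise_sd, size=full.shape))
        if spec.additive_floor_sd > 0:
            full = full + np.abs(rng.normal(0.0, spec.additive_floor_sd * spec.base_intensity,
                                            size=full.shape))
        full = np.clip(full, 0.0, None)
        stack = IonImageStack(targets=list(spec.targets), tensor=full,
                              grid=_full_grid(spec), labeled_flag=labeled)
        _inject_contaminants(stack, spec.contaminants, tissue, tumor, healthy)
        stacks[labeled] = stack

    return PhantomResult(spec=spec, labeled=stacks[True], unlabeled=stacks[False],
                         tissue_mask=tissue, tumor_mask=tumor,
                         g_truth=g_truth, e_truth=e_truth, pool_truth=pool_truth,
                         clean_tensor=clean)


def _full_grid(spec: PhantomSpec) -> PixelGrid:
    coords = tuple((x, y) for y in range(spec.height) for x in range(spec.width))
    return PixelGrid(width=spec.width, height=spec.height, coordinates=coords,
                     pixel_size=spec.pixel_size)


def _inject_contaminants(stack: IonImageStack, contaminants, tissue, tumor, healthy,
                         tol_ppm: float = 10.0) -> None:
    """Add contaminant intensity to every isotopologue channel it overlaps."""
    if not contaminants:
        return
    region_masks = {"tissue": tissue, "tumor": tumor, "healthy": healthy,
                    "all": np.ones_like(tissue)}
    mzs = stack.all_mzs()
    for c in contaminants:
        mask = region_masks[c.region]
        hit = np.abs(mzs - c.mz) / c.mz * 1e6 <= tol_ppm
        if not hit.any():
            logger.warning("contaminant at m/z %.4f overlaps no extraction channel", c.mz)
        for ch in np.nonzero(hit)[0]:
            stack.tensor[ch][mask] += c.intensity


def palmitate_interference_contaminants(intensity: float = 80.0,
                                        region: str = "tissue") -> list:
    """Background ions at the palmitate M1/M4/M5 channels (the classic DESI case)."""
    ladder = PALMITATE.mz_ladder
    return [Contaminant(mz=float(ladder[k]), intensity=intensity, region=region)
            for k in (1, 4, 5)]


def to_spectra(stack: IonImageStack, ppm_shift=None) -> SpectraCollection:
    """Render a channel stack as centroided per-pixel spectra.

    ``ppm_shift`` is an optional callable ``(x, y, mz) -> ppm`` applied as a
    mass-axis perturbation (for recalibration testing); intensities are never
    altered. Zero-intensity channels are omitted from the peak lists.
    """
    mzs = stack.all_mzs()
    order = np.argsort(mzs)
    mz_arrays, int_arrays = [], []
    for x, y in stack.grid.coordinates:
        ints = stack.tensor[:, y, x][order]
        keep = ints > 0
        mz = mzs[order][keep]
        inten = ints[keep]
        if ppm_shift is not None and len(mz):
            mz = mz * (1.0 + np.array([ppm_shift(x, y, v) for v in mz]) * 1e-6)
            o2 = np.argsort(mz)
            mz, inten = mz[o2], inten[o2]
        mz_arrays.append(mz.astype(float))
        int_arrays.append(inten.astype(float))
    return SpectraCollection(grid=stack.grid, mz_arrays=mz_arrays, intensity_arrays=int_arrays)


def write_imzml(source, path: str, ppm_shift=None) -> None:
    """Write a stack or spectra collection as processed-mode imzML (+ .ibd).

    Both m/z and intensity arrays are stored as float64 so a read/extract
    round trip is bit-identical. Pixels with no peaks are still emitted, using
    a zero (m/z, intensity) placeholder pair that the reader strips — pyimzml
    cannot serialize genuinely empty arrays.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    spectra = to_spectra(source, ppm_shift=ppm_shift) if isinstance(source, IonImageStack) else source
    with ImzMLWriter(path, mode="processed", mz_dtype=np.float64,
                     intensity_dtype=np.float64) as writer:
        for (x, y), mz, inten in zip(spectra.grid.coordinates,
                                     spectra.mz_arrays, spectra.intensity_arrays):
            if len(mz) == 0:
                mz, inten = np.array([0.0]), np.array([0.0])
            writer.addSpectrum(mz, inten, (x + 1, y + 1, 1))


def truth_table(result: PhantomResult):
    """Ground-truth maps as a tidy per-pixel table."""
    import pandas as pd

    rows = []
    h, w = result.tissue_mask.shape
    for t in result.spec.targets:
        g, e = result.g_truth[t.name], result.e_truth[t.name]
        for y in range(h):
            for x in range(w):
                rows.append({
                    "x": x, "y": y, "target": t.name,
                    "tissue": bool(result.tissue_mask[y, x]),
                    "tumor": bool(result.tumor_mask[y, x]),
                    "g_true": g[y, x], "e_true": e[y, x],
                })
    return pd.DataFrame(rows)
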