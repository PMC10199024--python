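"""imzML reading/writing, target m/z ladders, ion-image extraction, mass recalibration.

The central container is :class:`IonImageStack`, a per-target, per-isotopologue
intensity tensor of shape ``(n_channels, height, width)`` over a :class:`PixelGrid`.
Isotopologue channels for a metabolite with ``n`` carbons are the monoisotopic ion
m/z plus ``k * 1.0033548`` (the 13C-12C mass difference) for ``k = 0..n``.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass

logger = logging.getLogger(__name__)

#: Mass difference between 13C and 12C, in Da.
C13_C12_DELTA = 1.0033548

#: Mass of a proton, in Da (for adduct arithmetic).
PROTON_MASS = 1.00727646688

#: Supported adducts: name -> (mass shift in Da, charge magnitude).
ADDUCTS = {
    "[M-H]-": (-PROTON_MASS, 1),
    "[M+H]+": (+PROTON_MASS, 1),
}


class FormatError(RuntimeError):
    """Raised for malformed or inconsistent input files."""


class RecalibrationError(RuntimeError):
    """Raised when mass recalibration cannot proceed."""


@dataclass(frozen=True)
class PixelGrid:
    """Rectangular pixel raster of an MSI acquisition.

    Coordinates are 0-based, x to the right and y down (imzML scan indices
    minus one). ``pixel_size`` (micrometers) is carried as metadata only.
    """

    width: int
    height: int
    coordinates: tuple
    pixel_size: float = 1.0

    def __post_init__(self):
        coords = tuple((int(x), int(y)) for x, y in self.coordinates)
        object.__setattr__(self, "coordinates", coords)
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate pixel coordinates")
        for x, y in coords:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"coordinate {(x, y)} outside {self.width}x{self.height} grid")

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)


def _parse_formula(formula: str) -> dict:
    try:
        comp = _ptmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise ValueError(f"cannot parse molecular formula {formula!r}: {exc}") from exc
    return dict(comp)


def monoisotopic_ion_mz(formula: str, adduct: str = "[M-H]-") -> float:
    """Monoisotopic m/z of the adduct ion of a neutral molecule."""
    if adduct not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}")
    shift, charge = ADDUCTS[adduct]
    try:
        neutral = _ptmass.calculate_mass(formula=formula)
    except Exception as exc:
        raise ValueError(f"cannot compute mass for formula {formula!r}: {exc}") from exc
    return (neutral + shift) / charge


def build_target_ladder(formula: str, adduct: str = "[M-H]-", n_carbons: int | None = None) -> np.ndarray:
    """Theoretical isotopologue m/z ladder M0..Mn for a molecular formula.

    ``ladder[k] = ladder[0] + k * C13_C12_DELTA``; ``ladder[0]`` is the
    monoisotopic adduct-ion m/z.
    """
    comp = _parse_formula(formula)
    n_c = comp.get("C", 0)
    if n_carbons is None:
        n_carbons = n_c
    if n_carbons > n_c:
        raise ValueError(f"n_carbons={n_carbons} exceeds the {n_c} carbons in {formula}")
    m0 = monoisotopic_ion_mz(formula, adduct)
    return m0 + C13_C12_DELTA * np.arange(n_carbons + 1)


@dataclass(frozen=True)
class TargetMetabolite:
    """A metabolite to extract: formula, adduct, carbon count and subunit count.

    ``n_carbons`` is the number of positions that can carry a tracer label
    (the ladder has ``n_carbons + 1`` rungs); ``n_subunits`` is the number of
    two-carbon precursor units for the polymerization flux models (8 for
    palmitate, 9 for stearate), or ``None`` for metabolites not modeled that way.
    """

    name: str
    formula: str
    adduct: str
    n_carbons: int
    n_subunits: int | None = None
    mz_ladder: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.mz_ladder is None:
            object.__setattr__(self, "mz_ladder", build_target_ladder(self.formula, self.adduct, self.n_carbons))
        ladder = np.asarray(self.mz_ladder, dtype=float)
        object.__setattr__(self, "mz_ladder", ladder)
        if len(ladder) != self.n_carbons + 1:
            raise ValueError("mz_ladder length must be n_carbons + 1")
        if np.any(np.diff(ladder) <= 0):
            raise ValueError("mz_ladder must be strictly increasing")
        if self.n_subunits is not None and self.n_subunits > math.ceil(self.n_carbons / 2):
            raise ValueError("n_subunits may not exceed ceil(n_carbons / 2)")


# Built-in targets used throughout the examples and phantom data.
PALMITATE = TargetMetabolite("palmitate", "C16H32O2", "[M-H]-", 16, 8)
STEARATE = TargetMetabolite("stearate", "C18H36O2", "[M-H]-", 18, 9)


@dataclass
class SpectraCollection:
    """Centroided spectra per pixel: parallel lists of m/z and intensity arrays."""

    grid: PixelGrid
    mz_arrays: list
    intensity_arrays: list

    def __post_init__(self):
        if not (len(self.mz_arrays) == len(self.intensity_arrays) == self.grid.n_pixels):
            raise ValueError("one spectrum per grid coordinate required")

    def spectrum(self, x: int, y: int):
        idx = self.grid.coordinates.index((x, y))
        return self.mz_arrays[idx], self.intensity_arrays[idx]


@dataclass
class IonImageStack:
    """Per-target isotopologue intensity tensor over a pixel grid.

    ``tensor`` has shape ``(n_channels, height, width)`` where the channel axis
    concatenates each target's M0..Mn ladder in order. Negative raw intensities
    are clipped to zero (and logged).
    """

    targets: list
    tensor: np.ndarray
    grid: PixelGrid
    labeled_flag: bool = True

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        n_expected = sum(t.n_carbons + 1 for t in self.targets)
        if self.tensor.shape != (n_expected, self.grid.height, self.grid.width):
            raise ValueError(
                f"tensor shape {self.tensor.shape} != ({n_expected}, {self.grid.height}, {self.grid.width})"
            )
        n_neg = int(np.sum(self.tensor < 0))
        if n_neg:
            logger.warning("clipping %d negative intensities to zero", n_neg)
            self.tensor = np.clip(self.tensor, 0.0, None)

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[0]

    def channel_slice(self, target_name: str) -> slice:
        offset = 0
        for t in self.targets:
            width = t.n_carbons + 1
            if t.name == target_name:
                return slice(offset, offset + width)
            offset += width
        raise KeyError(f"target {target_name!r} not in stack")

    def target(self, target_name: str) -> TargetMetabolite:
        for t in self.targets:
            if t.name == target_name:
                return t
        raise KeyError(f"target {target_name!r} not in stack")

    def target_tensor(self, target_name: str) -> np.ndarray:
        """View of shape ``(n_carbons + 1, height, width)`` for one target."""
        return self.tensor[self.channel_slice(target_name)]

    def all_mzs(self) -> np.ndarray:
        return np.concatenate([t.mz_ladder for t in self.targets])

    def tic_image(self) -> np.ndarray:
        return self.tensor.sum(axis=0)


def read_imzml(path: str) -> SpectraCollection:
    """Read an imzML file (processed or continuous mode) into per-pixel spectra.

    The paired ``.ibd`` binary must sit next to the XML; a missing binary is a
    fatal I/O error. Continuous-mode files are expanded to the same in-memory
    representation as processed-mode ones.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise FileNotFoundError(f"imzML file not found: {path}")
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"missing binary data file: {ibd} (required alongside {path})")

    parser = ImzMLParser(path)
    xs = [c[0] - 1 for c in parser.coordinates]
    ys = [c[1] - 1 for c in parser.coordinates]
    width = max(xs) + 1
    height = max(ys) + 1
    pixel_size = 1.0
    try:
        meta = parser.imzmldict or {}
        pixel_size = float(meta.get("pixel size x") or meta.get("pixel size") or 1.0)
    except Exception:
        pass
    try:
        continuous = "continuous" in parser.metadata.file_description.param_by_name
    except Exception:
        continuous = False

    mz_arrays, intensity_arrays, coords = [], [], []
    expected_len = None
    for i, (x, y) in enumerate(zip(xs, ys)):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        if continuous:
            if expected_len is None:
                expected_len = len(mzs)
            elif len(mzs) != expected_len:
                raise FormatError(
                    f"continuous-mode spectrum {i} has {len(mzs)} points, expected {expected_len}"
                )
        # strip the zero-intensity placeholder written for empty pixels
        keep = ~((mzs == 0.0) & (ints == 0.0))
        mzs, ints = mzs[keep], ints[keep]
        order = np.argsort(mzs, kind="stable")
        mz_arrays.append(mzs[order])
        intensity_arrays.append(ints[order])
        coords.append((x, y))

    grid = PixelGrid(width=width, height=height, coordinates=tuple(coords), pixel_size=pixel_size)
    return SpectraCollection(grid=grid, mz_arrays=mz_arrays, intensity_arrays=intensity_arrays)


def extract_ion_images(
    spectra: SpectraCollection,
    targets: list,
    tol_ppm: float = 10.0,
    labeled_flag: bool = True,
) -> IonImageStack:
    """Sum peak intensities within +/- tol_ppm of every ladder m/z, per pixel.

    Pixels absent from the file stay zero. Ladder entries of *different*
    targets closer than ``2 * tol_ppm`` are logged as ambiguous but both are
    still extracted; downstream interference screening is the authoritative
    exclusion mechanism.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    grid = spectra.grid
    all_mzs = np.concatenate([t.mz_ladder for t in targets])
    owners = np.concatenate([[t.name] * (t.n_carbons + 1) for t in targets])
    order = np.argsort(all_mzs)
    for a, b in zip(order[:-1], order[1:]):
        if owners[a] != owners[b]:
            gap_ppm = (all_mzs[b] - all_mzs[a]) / all_mzs[a] * 1e6
            if gap_ppm < 2 * tol_ppm:
                logger.warning(
                    "ambiguous extraction: %s %.4f and %s %.4f are %.1f ppm apart (< 2*tol)",
                    owners[a], all_mzs[a], owners[b], all_mzs[b], gap_ppm,
                )

    tensor = np.zeros((len(all_mzs), grid.height, grid.width))
    lo = all_mzs * (1.0 - tol_ppm * 1e-6)
    hi = all_mzs * (1.0 + tol_ppm * 1e-6)
    for (x, y), mzs, ints in zip(grid.coordinates, spectra.mz_arrays, spectra.intensity_arrays):
        if len(mzs) == 0:
            continue
        i0 = np.searchsorted(mzs, lo, side="left")
        i1 = np.searchsorted(mzs, hi, side="right")
        # per-window direct sums (a cumsum difference would break bit-exactness)
        for c, (a, b) in enumerate(zip(i0, i1)):
            if b > a:
                tensor[c, y, x] = ints[a:b].sum()
    return IonImageStack(targets=list(targets), tensor=tensor, grid=grid, labeled_flag=labeled_flag)


@dataclass
class RecalibrationModel:
    """Per-pixel linear model of the ppm mass shift as a function of m/z.

    ``params[i] = (slope_ppm_per_mz, intercept_ppm)`` for pixel i; the shift of
    an observed m/z is ``slope * mz + intercept`` ppm, and the corrected m/z is
    ``mz / (1 + shift * 1e-6)``.
    """

    params: np.ndarray  # (n_pixels, 2)
    reference_peaks: list  # per pixel: list of (reference m/z, observed m/z)
    grid: PixelGrid

    def shift_ppm(self, pixel_index: int, mz: np.ndarray) -> np.ndarray:
        slope, intercept = self.params[pixel_index]
        return slope * np.asarray(mz, dtype=float) + intercept

    def apply(self, pixel_index: int, mz: np.ndarray) -> np.ndarray:
        return np.asarray(mz, dtype=float) / (1.0 + self.shift_ppm(pixel_index, mz) * 1e-6)

    def invert(self, pixel_index: int, corrected_mz: np.ndarray) -> np.ndarray:
        """Recover observed m/z from corrected m/z (fixed-point; exact to <1e-9 rel)."""
        mz = np.asarray(corrected_mz, dtype=float).copy()
        for _ in range(4):
            mz = corrected_mz * (1.0 + self.shift_ppm(pixel_index, mz) * 1e-6)
        return mz


def recalibrate(
    spectra: SpectraCollection,
    reference_mzs,
    search_tol_ppm: float = 20.0,
) -> tuple:
    """Adaptive per-pixel mass recalibration against annotated reference m/z values.

    For each pixel the nearest observed peak within ``search_tol_ppm`` of each
    reference is matched; a linear ppm-shift-vs-m/z model is fitted over >= 3
    matches, a constant offset over 2, and pixels with fewer matches inherit
    the grid-median model. Intensities are never altered.
    """
    refs = np.sort(np.asarray(reference_mzs, dtype=float))
    if refs.size == 0:
        raise ValueError("reference_mzs is empty")
    n_pix = spectra.grid.n_pixels
    params = np.full((n_pix, 2), np.nan)
    matches_per_pixel = []
    any_match = False
    for i, (mzs, ints) in enumerate(zip(spectra.mz_arrays, spectra.intensity_arrays)):
        pairs = []
        if len(mzs):
            idx = np.searchsorted(mzs, refs)
            for r, j in zip(refs, idx):
                best, best_err = None, np.inf
                for k in (j - 1, j):
                    if 0 <= k < len(mzs):
                        err = abs(mzs[k] - r) / r * 1e6
                        if err < best_err:
                            best, best_err = k, err
                if best is not None and best_err <= search_tol_ppm:
                    pairs.append((r, float(mzs[best])))
        matches_per_pixel.append(pairs)
        if pairs:
            any_match = True
        shifts = np.array([(obs - r) / r * 1e6 for r, obs in pairs])
        obs_mzs = np.array([obs for _, obs in pairs])
        if len(pairs) >= 3:
            slope, intercept = np.polyfit(obs_mzs, shifts, 1)
            params[i] = (slope, intercept)
        elif len(pairs) == 2:
            params[i] = (0.0, float(np.mean(shifts)))
    if not any_match:
        raise RecalibrationError(
            "no reference m/z matched in any pixel; skip recalibration for this dataset"
        )
    fitted = ~np.isnan(params[:, 1])
    median_model = np.nanmedian(params[fitted], axis=0)
    params[~fitted] = median_model

    model = RecalibrationModel(params=params, reference_peaks=matches_per_pixel, grid=spectra.grid)
    new_mzs = []
    for i, mzs in enumerate(spectra.mz_arrays):
        new_mzs.append(model.apply(i, mzs) if len(mzs) else mzs)
    corrected = SpectraCollection(
        grid=spectra.grid,
        mz_arrays=new_mzs,
        intensity_arrays=[a.copy() for a in spectra.intensity_arrays],
    )
    return corrected, model


def save_stack(stack: IonImageStack, path: str) -> None:
    """Serialize an IonImageStack to a .npz archive (tensor + grid + targets)."""
    import json

    meta = [
        {"name": t.name, "formula": t.formula, "adduct": t.adduct,
         "n_carbons": t.n_carbons, "n_subunits": t.n_subunits}
        for t in stack.targets
    ]
    np.savez_compressed(
        path,
        tensor=stack.tensor,
        width=stack.grid.width,
        height=stack.grid.height,
        pixel_size=stack.grid.pixel_size,
        coordinates=np.array(stack.grid.coordinates, dtype=int),
        labeled_flag=stack.labeled_flag,
        targets_json=json.dumps(meta),
    )


def load_stack(path: str) -> IonImageStack:
    import json

    with np.load(path, allow_pickle=False) as z:
        targets = [TargetMetabolite(**m) for m in json.loads(str(z["targets_json"]))]
        grid = PixelGrid(
            width=int(z["width"]), height=int(z["height"]),
            coordinates=tuple(map(tuple, z["coordinates"])),
            pixel_size=float(z["pixel_size"]),
        )
        return IonImageStack(targets=targets, tensor=z["tensor"], grid=grid,
                             labeled_flag=bool(z["labeled_flag"]))


def stack_to_table(stack: IonImageStack):
    """Per-pixel delimited form: x, y, target, isotopologue, intensity."""
    import pandas as pd

    rows = []
    for t in stack.targets:
        sub = stack.target_tensor(t.name)
        for k in range(sub.shape[0]):
            ys, xs = np.nonzero(np.ones_like(sub[k], dtype=bool))
            rows.append(pd.DataFrame({
                "x": xs, "y": ys, "target": t.name, "isotopologue": k,
                "intensity": sub[k].ravel(),
            }))
    return pd.concat(rows, ignore_index=True)


def load_target_list(path: str) -> list:
    """Load a delimited target list (columns: name, formula, adduct, n_carbons[, n_subunits])."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "formula", "adduct", "n_carbons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target list {path} is missing columns: {sorted(missing)}")
    targets = []
    for row in df.to_dict("records"):
        n_sub = row.get("n_subunits")
        n_sub = None if n_sub is None or (isinstance(n_sub, float) and math.isnan(n_sub)) else int(n_sub)
        targets.append(
            TargetMetabolite(
                name=str(row["name"]),
                formula=str(row["formula"]),
                adduct=str(row["adduct"]),
                n_carbons=int(row["n_carbons"]),
                n_subunits=n_sub,
            )
        )
    return targets
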