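import numpy as np
import pytest

from sisaflux.msi_io import (
    C13_C12_DELTA,
    PALMITATE,
    PixelGrid,
    SpectraCollection,
    TargetMetabolite,
    build_target_ladder,
    extract_ion_images,
    read_imzml,
    recalibrate,
    load_stack,
    save_stack,
    RecalibrationError,
)
from sisaflux.synthetic import to_spectra, write_imzml

# Independent monoisotopic-mass oracle from standard atomic masses.
_ATOMIC = {"C": 12.0, "H": 1.00782503207, "O": 15.99491461956, "N": 14.0030740048}
_PROTON = 1.00727646688


def _mono_mz(counts, adduct="[M-H]-"):
    m = sum(_ATOMIC[el] * n for el, n in counts.items())
    return m - _PROTON if adduct == "[M-H]-" else m + _PROTON


class TestTargetLadder:
    def test_palmitate_monoisotopic_mz(self):
        """Deprotonated palmitate ladder starts at the independently computed ion mass."""
        ladder = build_target_ladder("C16H32O2", "[M-H]-", 16)
        expected = _mono_mz({"C": 16, "H": 32, "O": 2})
        assert ladder[0] == pytest.approx(expected, abs=1e-4)
        assert ladder[0] == pytest.approx(255.2330, abs=1e-3)
        assert len(ladder) == 17

    @pytest.mark.parametrize("formula,n", [("C6H12O6", 6), ("C18H36O2", 18)])
    def test_ladder_spacing_and_length(self, formula, n):
        ladder = build_target_ladder(formula, "[M-H]-", n)
        assert len(ladder) == n + 1
        assert np.allclose(np.diff(ladder), C13_C12_DELTA)

    def test_too_many_carbons_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_target_ladder("C6H12O6", "[M-H]-", 7)

    def test_bad_formula_rejected(self):
        with pytest.raises(ValueError, match="formula"):
            build_target_ladder("C6Qq2", "[M-H]-", 6)

    def test_subunit_count_bounded(self):
        with pytest.raises(ValueError, match="n_subunits"):
            TargetMetabolite("bad", "C16H32O2", "[M-H]-", 16, n_subunits=9)


class TestGrid:
    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PixelGrid(width=2, height=2, coordinates=((0, 0), (0, 0)))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PixelGrid(width=2, height=2, coordinates=((2, 0),))


class TestExtraction:
    def _single_pixel_spectra(self, mzs, ints):
        grid = PixelGrid(width=1, height=1, coordinates=((0, 0),))
        order = np.argsort(mzs)
        return SpectraCollection(grid=grid,
                                 mz_arrays=[np.asarray(mzs, float)[order]],
                                 intensity_arrays=[np.asarray(ints, float)[order]])

    def test_window_lookup(self):
        m0 = PALMITATE.mz_ladder[0]
        spectra = self._single_pixel_spectra([m0, m0 + C13_C12_DELTA], [50.0, 5.0])
        stack = extract_ion_images(spectra, [PALMITATE], tol_ppm=10)
        sub = stack.target_tensor("palmitate")
        assert sub[0, 0, 0] == 50.0
        assert sub[1, 0, 0] == 5.0
        assert np.all(sub[2:] == 0)

    def test_peak_outside_tolerance_ignored(self):
        m0 = PALMITATE.mz_ladder[0]
        spectra = self._single_pixel_spectra([m0 * (1 + 20e-6)], [100.0])
        stack = extract_ion_images(spectra, [PALMITATE], tol_ppm=10)
        assert stack.target_tensor("palmitate")[0, 0, 0] == 0.0

    def test_extraction_is_additive(self):
        """Extracting the sum of two spectra equals the sum of the extractions."""
        rng = np.random.default_rng(3)
        mzs = PALMITATE.mz_ladder
        i1, i2 = rng.uniform(0, 100, 17), rng.uniform(0, 100, 17)
        s1 = self._single_pixel_spectra(mzs, i1)
        s2 = self._single_pixel_spectra(mzs, i2)
        s12 = self._single_pixel_spectra(mzs, i1 + i2)
        t1 = extract_ion_images(s1, [PALMITATE]).tensor
        t2 = extract_ion_images(s2, [PALMITATE]).tensor
        t12 = extract_ion_images(s12, [PALMITATE]).tensor
        assert np.allclose(t12, t1 + t2)

    def test_phantom_round_trip_exact(self, noiseless_phantom):
        """write -> read -> extract reproduces the generator tensor exactly."""
        stack = noiseless_phantom.labeled
        spectra = to_spectra(stack)
        extracted = extract_ion_images(spectra, stack.targets, tol_ppm=10)
        assert np.array_equal(extracted.tensor, stack.tensor)


class TestImzmlRoundTrip:
    def test_file_round_trip(self, tmp_path, noiseless_phantom):
        stack = noiseless_phantom.labeled
        path = str(tmp_path / "phantom.imzML")
        write_imzml(stack, path)
        spectra = read_imzml(path)
        assert spectra.grid.n_pixels == stack.grid.n_pixels
        extracted = extract_ion_images(spectra, stack.targets, tol_ppm=10)
        assert np.array_equal(extracted.tensor, stack.tensor)

    def test_empty_pixel_round_trips_to_empty(self, tmp_path):
        grid = PixelGrid(width=2, height=1, coordinates=((0, 0), (1, 0)))
        spectra = SpectraCollection(
            grid=grid,
            mz_arrays=[np.array([255.2330]), np.array([])],
            intensity_arrays=[np.array([100.0]), np.array([])],
        )
        path = str(tmp_path / "single.imzML")
        write_imzml(spectra, path)
        back = read_imzml(path)
        mz, inten = back.spectrum(0, 0)
        assert mz[0] == 255.2330 and inten[0] == 100.0
        mz2, _ = back.spectrum(1, 0)
        assert len(mz2) == 0

    def test_missing_ibd_is_fatal(self, tmp_path, noiseless_phantom):
        path = str(tmp_path / "x.imzML")
        write_imzml(noiseless_phantom.labeled, path)
        (tmp_path / "x.ibd").unlink()
        with pytest.raises(FileNotFoundError, match="x.ibd"):
            read_imzml(path)

    def test_stack_npz_round_trip(self, tmp_path, noiseless_phantom):
        path = str(tmp_path / "stack.npz")
        save_stack(noiseless_phantom.labeled, path)
        back = load_stack(path)
        assert np.array_equal(back.tensor, noiseless_phantom.labeled.tensor)
        assert [t.name for t in back.targets] == ["palmitate", "stearate"]


class TestRecalibration:
    def test_uniform_shift_removed(self, noiseless_phantom):
        """A uniform +5 ppm shift is recovered to < 0.5 ppm residual at references."""
        stack = noiseless_phantom.labeled
        refs = np.concatenate([stack.targets[0].mz_ladder[:3],
                               stack.targets[1].mz_ladder[:2]])
        spectra = to_spectra(stack, ppm_shift=lambda x, y, mz: 5.0)
        corrected, model = recalibrate(spectra, refs)
        errors = []
        for mzs, true_mzs in zip(corrected.mz_arrays,
                                 to_spectra(stack).mz_arrays):
            if len(mzs):
                errors.append(np.abs(mzs - true_mzs) / true_mzs * 1e6)
        assert np.median(np.concatenate(errors)) < 0.5

    def test_identity_when_already_calibrated(self, noiseless_phantom):
        stack = noiseless_phantom.labeled
        refs = stack.targets[0].mz_ladder[:5]
        _, model = recalibrate(to_spectra(stack), refs)
        shifts = [model.shift_ppm(i, np.array([260.0]))[0]
                  for i in range(stack.grid.n_pixels)]
        assert np.max(np.abs(shifts)) < 0.1

    def test_pixelwise_linear_shift_field(self, noiseless_phantom):
        """A pixel- and m/z-dependent linear shift leaves < 1 ppm residual."""
        stack = noiseless_phantom.labeled
        refs = np.concatenate([stack.targets[0].mz_ladder[::4],
                               stack.targets[1].mz_ladder[::4]])

        def shift(x, y, mz):
            return 2.0 + 0.1 * x + 0.01 * (mz - 255.0)

        spectra = to_spectra(stack, ppm_shift=shift)
        corrected, _ = recalibrate(spectra, refs, search_tol_ppm=40)
        errors = []
        for mzs, true_mzs in zip(corrected.mz_arrays, to_spectra(stack).mz_arrays):
            if len(mzs):
                errors.append(np.abs(mzs - true_mzs) / true_mzs * 1e6)
        assert np.median(np.concatenate(errors)) < 1.0

    def test_intensities_untouched(self, noiseless_phantom):
        stack = noiseless_phantom.labeled
        spectra = to_spectra(stack, ppm_shift=lambda x, y, mz: 3.0)
        corrected, _ = recalibrate(spectra, stack.targets[0].mz_ladder[:4])
        for a, b in zip(spectra.intensity_arrays, corrected.intensity_arrays):
            assert np.array_equal(a, b)

    def test_apply_invert_round_trip(self, noiseless_phantom):
        stack = noiseless_phantom.labeled
        spectra = to_spectra(stack, ppm_shift=lambda x, y, mz: 5.0)
        _, model = recalibrate(spectra, stack.targets[0].mz_ladder[:4])
        mz = np.array([250.0, 300.0])
        assert np.allclose(model.invert(0, model.apply(0, mz)), mz, rtol=1e-9)

    def test_no_reference_matches_is_fatal(self, noiseless_phantom):
        spectra = to_spectra(noiseless_phantom.labeled)
        with pytest.raises(RecalibrationError, match="skip recalibration"):
            recalibrate(spectra, [999.999])
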