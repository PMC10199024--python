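from itertools import product

import numpy as np
import pytest

from sisaflux.sisa import (
    FluxImage,
    PrecursorDistribution,
    UnderdeterminedFitError,
    elongation_forward,
    fit_elongation,
    fit_isa,
    fit_sisa,
    flux_image,
    isa_forward,
    monomer_power,
    region_summary,
    sisa_forward,
)
from tests.conftest import na_corrected_stack


def brute_force_power(m, k):
    """Exhaustive enumeration over all 3^k monomer label combinations."""
    out = np.zeros(2 * k + 1)
    for combo in product((0, 1, 2), repeat=k):
        p = np.prod([m[c] for c in combo])
        out[sum(combo)] += p
    return out


def grid_search_sisa(observed, N, n_subunits, g_grid=41, x_grid=21):
    """Dense grid-search oracle over (g, X) for small problems."""
    best, best_sse = None, np.inf
    obs = observed / observed.sum()
    for g in np.linspace(0, 1, g_grid):
        for x1 in np.linspace(0, 1, x_grid):
            for x2 in np.linspace(0, 1 - x1, x_grid):
                X = (1 - x1 - x2, x1, x2)
                pred = sisa_forward(X, N, g, n_subunits)
                sse = np.sum((pred - obs) ** 2)
                if sse < best_sse:
                    best, best_sse = (g, X), sse
    return best, best_sse


class TestMonomerPower:
    def test_unlabeled_monomer(self):
        out = monomer_power((1, 0, 0), 8)
        assert len(out) == 17
        assert out[0] == 1.0 and np.all(out[1:] == 0)

    def test_fully_labeled_monomer(self):
        out = monomer_power((0, 0, 1), 8)
        assert out[16] == 1.0 and out[:16].sum() == 0

    def test_matches_brute_force_enumeration(self):
        m = (0.5, 0.3, 0.2)
        assert np.allclose(monomer_power(m, 3), brute_force_power(m, 3), atol=1e-12)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            monomer_power((0.5, 0.5, 0.5), 2)


class TestForwardModels:
    def test_no_synthesis_is_preexisting_pool(self):
        prec = PrecursorDistribution(N=(0.9, 0.08, 0.02), T=(0, 0, 1), D=0.5)
        assert np.allclose(isa_forward(prec, 0.0, 8),
                           monomer_power(prec.N, 8))

    def test_pure_tracer_synthesis_fully_labeled(self):
        prec = PrecursorDistribution(N=(1, 0, 0), T=(0, 0, 1), D=1.0)
        P = isa_forward(prec, 1.0, 8)
        assert P[16] == pytest.approx(1.0)

    def test_classical_equals_spatial_with_effective_monomer(self):
        """X = (1-D)N + DT reduces the spatial model to the classical one exactly."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = rng.dirichlet(np.ones(3))
            T = rng.dirichlet(np.ones(3))
            D, g = rng.uniform(0, 1, 2)
            prec = PrecursorDistribution(N=tuple(N), T=tuple(T), D=D)
            X = (1 - D) * N + D * T
            assert np.allclose(isa_forward(prec, g, 8),
                               sisa_forward(X, N, g, 8), atol=1e-15)

    def test_seventeen_isotopologues_for_palmitate(self):
        assert len(sisa_forward((0.4, 0.2, 0.4), (1, 0, 0), 0.5, 8)) == 17

    def test_elongation_m2_signature(self):
        """Elongating unlabeled chains with a fully labeled unit yields M2 stearate."""
        e = 0.3
        P = elongation_forward((0, 0, 1), (1, 0, 0), 0.0, e)
        assert P[2] == pytest.approx(e)
        assert P[0] == pytest.approx(1 - e)
        assert P[18] == 0.0

    def test_no_flux_elongation_reduces_to_pool(self):
        N = (0.95, 0.04, 0.01)
        assert np.allclose(elongation_forward((0.5, 0.2, 0.3), N, 0.0, 0.0),
                           monomer_power(N, 9))

    @pytest.mark.parametrize("model", ["isa", "sisa", "elongation"])
    def test_conservation(self, model):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = rng.dirichlet(np.ones(3))
            X = rng.dirichlet(np.ones(3))
            g = rng.uniform(0, 1)
            if model == "isa":
                prec = PrecursorDistribution(N=tuple(N), T=tuple(rng.dirichlet(np.ones(3))),
                                             D=rng.uniform(0, 1))
                P = isa_forward(prec, g, 8)
            elif model == "sisa":
                P = sisa_forward(X, N, g, 8)
            else:
                e = rng.uniform(0, 1 - g)
                P = elongation_forward(X, N, g, e)
            assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_flux_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            elongation_forward((1, 0, 0), (1, 0, 0), 0.7, 0.5)


class TestFitSisa:
    def test_recovers_known_parameters_vs_grid_oracle(self):
        X, g = (0.4, 0.2, 0.4), 0.5
        observed = sisa_forward(X, (1, 0, 0), g, 8)
        fit = fit_sisa(observed)
        assert fit.g == pytest.approx(g, abs=1e-4)
        assert np.allclose(fit.X, X, atol=1e-3)
        (g_grid, X_grid), _ = grid_search_sisa(observed, (1, 0, 0), 8,
                                               g_grid=21, x_grid=11)
        assert abs(fit.g - g_grid) <= 0.05  # within one grid cell of the oracle
        assert fit.converged

    def test_no_synthesis_recovered(self):
        observed = monomer_power((1, 0, 0), 8)
        fit = fit_sisa(observed)
        assert fit.g == pytest.approx(0.0, abs=1e-4)

    def test_masked_fit_consistency(self):
        """Excluding the DESI-interfered M1/M4/M5 barely changes the estimate."""
        X, g = (0.45, 0.15, 0.40), 0.55
        observed = sisa_forward(X, (1, 0, 0), g, 8)
        mask = np.ones(17, dtype=bool)
        mask[[1, 4, 5]] = False
        fit_masked = fit_sisa(observed, mask=mask)
        fit_full = fit_sisa(observed)
        assert fit_masked.g == pytest.approx(fit_full.g, abs=1e-2)
        assert fit_masked.n_unmasked == 14

    def test_too_few_isotopologues_rejected(self):
        observed = sisa_forward((0.4, 0.2, 0.4), (1, 0, 0), 0.5, 8)
        mask = np.zeros(17, dtype=bool)
        mask[:4] = True
        with pytest.raises(UnderdeterminedFitError):
            fit_sisa(observed, mask=mask)

    def test_classical_fit_on_classical_data(self):
        """With the (D, T) structure known, the classical fit recovers (D, g)."""
        N, T = (1.0, 0.0, 0.0), (0.1, 0.2, 0.7)
        D, g = 0.6, 0.35
        prec = PrecursorDistribution(N=N, T=T, D=D)
        observed = isa_forward(prec, g, 8)
        fit = fit_isa(observed, T=T, N=N)
        assert fit.g == pytest.approx(g, abs=1e-4)
        assert fit.D == pytest.approx(D, abs=1e-3)


class TestFitElongation:
    def test_recovers_known_parameters(self):
        X, g, e = (0.5, 0.1, 0.4), 0.3, 0.2
        observed = elongation_forward(X, (1, 0, 0), g, e)
        fit = fit_elongation(observed)
        assert fit.g == pytest.approx(g, abs=1e-3)
        assert fit.e == pytest.approx(e, abs=1e-3)

    def test_no_flux_recovered(self):
        observed = monomer_power((1, 0, 0), 9)
        fit = fit_elongation(observed)
        assert fit.g == pytest.approx(0.0, abs=1e-3)
        assert fit.e == pytest.approx(0.0, abs=1e-3)

    def test_nested_model_sse_inequality(self):
        """Forcing e = 0 on elongation-generated data must fit worse."""
        X, g, e = (0.45, 0.15, 0.40), 0.15, 0.25
        observed = elongation_forward(X, (1, 0, 0), g, e)
        full = fit_elongation(observed)
        sisa_only = fit_sisa(observed, n_subunits=9)
        assert full.sse < sisa_only.sse

    def test_feasibility_of_estimates(self):
        rng = np.random.default_rng(9)
        noisy = np.clip(elongation_forward((0.5, 0.2, 0.3), (1, 0, 0), 0.3, 0.3)
                        + rng.normal(0, 0.01, 19), 0, None)
        fit = fit_elongation(noisy / noisy.sum())
        assert 0 <= fit.g <= 1 and 0 <= fit.e <= 1 and fit.g + fit.e <= 1


class TestNoiseSensitivity:
    def test_error_grows_with_noise(self):
        """Mean |g_hat - g| increases with injected noise SD (positive regression slope)."""
        rng = np.random.default_rng(12)
        sigmas = [0.002, 0.01, 0.03]
        means = []
        for s in sigmas:
            errs = []
            for _ in range(15):
                X = rng.dirichlet(np.ones(3))
                g = rng.uniform(0.2, 0.8)
                clean = sisa_forward(X, (1, 0, 0), g, 8)
                noisy = np.clip(clean + rng.normal(0, s, 17), 0, None)
                errs.append(abs(fit_sisa(noisy / noisy.sum()).g - g))
            means.append(np.mean(errs))
        slope = np.polyfit(sigmas, means, 1)[0]
        assert slope > 0


class TestFluxImage:
    def test_uniform_noiseless_phantom(self, noiseless_phantom):
        corrected = na_corrected_stack(noiseless_phantom.labeled)
        img = flux_image(corrected, "palmitate", tissue_mask=noiseless_phantom.tissue_mask)
        truth = noiseless_phantom.g_truth["palmitate"]
        ok = np.isfinite(img.g)
        assert ok.sum() == noiseless_phantom.tissue_mask.sum()
        assert np.nanmax(np.abs(img.g[ok] - truth[ok])) < 1e-3

    def test_elongation_needs_19_isotopologues(self, small_corrected):
        with pytest.raises(ValueError, match="19"):
            flux_image(small_corrected, "palmitate", model="elongation")

    def test_unknown_model_rejected(self, small_corrected):
        with pytest.raises(ValueError, match="model"):
            flux_image(small_corrected, "palmitate", model="mfa")


class TestRegionSummary:
    @pytest.fixture()
    def flux_maps(self):
        g = np.full((4, 6), np.nan)
        g[:, :3] = 0.55
        g[:, 3:] = 0.20
        return FluxImage(target_name="palmitate", model="sisa", g=g,
                         sse=np.zeros_like(g), converged=np.ones_like(g, dtype=bool))

    def test_region_means(self, flux_maps):
        roi_a = np.zeros((4, 6), dtype=bool)
        roi_b = np.zeros((4, 6), dtype=bool)
        roi_a[:, :3] = True
        roi_b[:, 3:] = True
        cmp = region_summary(flux_maps, roi_a, roi_b)
        assert cmp.mean_a == pytest.approx(0.55)
        assert cmp.mean_b == pytest.approx(0.20)
        assert cmp.ratio == pytest.approx(0.55 / 0.20)

    def test_identical_rois_rejected(self, flux_maps):
        roi = np.ones((4, 6), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            region_summary(flux_maps, roi, roi)

    def test_single_pixel_rois(self, flux_maps):
        roi_a = np.zeros((4, 6), dtype=bool)
        roi_b = np.zeros((4, 6), dtype=bool)
        roi_a[0, 0] = True
        roi_b[0, 5] = True
        cmp = region_summary(flux_maps, roi_a, roi_b)
        assert cmp.mean_a == pytest.approx(0.55)
        assert cmp.sd_a == 0.0

    def test_empty_roi_rejected(self, flux_maps):
        roi_a = np.zeros((4, 6), dtype=bool)
        roi_b = np.ones((4, 6), dtype=bool)
        with pytest.raises(ValueError, match="at least one"):
            region_summary(flux_maps, roi_a, roi_b)

    def test_replicates_use_paired_test(self, flux_maps):
        roi_a = np.zeros((4, 6), dtype=bool)
        roi_b = np.zeros((4, 6), dtype=bool)
        roi_a[:, 0] = True
        roi_b[:, 5] = True
        reps = [flux_maps, flux_maps, flux_maps]
        cmp = region_summary(reps, roi_a, roi_b)
        assert cmp.n_replicates == 3
        assert cmp.test.startswith("paired")
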