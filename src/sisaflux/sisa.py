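"""Isotopologue spectral analysis of polymerization flux, per pixel.

A fatty acid assembled from ``n`` two-carbon (acetyl) units carries 0, 1 or 2
heavy carbons per unit, so its isotopologue pattern is the n-fold convolution
of the monomer labeling 3-vector. Classical ISA models the product pattern as

    P = g * power((1 - D) * N + D * T, n) + (1 - g) * power(N, n)

with known tracer labeling T, tracer dilution D, pre-existing-pool labeling N
and fractional turnover g(t). The spatial variant (SISA) replaces the
(D, T) pair with an inferred monomer labeling X,

    P = g * power(X, n) + (1 - g) * power(N, n)

so that the precursor labeling need not be measurable on the imaging platform;
for n = 8 (palmitate) the 17 isotopologue equations overdetermine the 4
unknowns (X on a 2-dof simplex, plus g). Elongation of palmitate to stearate
adds a term for one labeled unit appended to a pre-existing 8-unit chain:

    P = g * power(X, 9) + e * conv(X, power(N, 8)) + (1 - g - e) * power(N, 9)

Fitting minimizes the sum of squared errors between observed and predicted
fractions over the unmasked isotopologues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .isotopes import LabelingDistribution, UndefinedDistributionError, fractional_labeling
from .msi_io import IonImageStack

logger = logging.getLogger(__name__)

#: Default pre-existing-pool monomer labeling for NA-corrected input fractions.
N_CORRECTED = (1.0, 0.0, 0.0)


class UnderdeterminedFitError(ValueError):
    """Too few unmasked isotopologues to constrain the model parameters."""


def _check_simplex(v, name: str, atol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    if np.any(v < -atol) or abs(v.sum() - 1.0) > atol:
        raise ValueError(f"{name} must be nonnegative and sum to 1 (got {v})")
    return np.clip(v, 0.0, None)


def natural_monomer(p13: float) -> np.ndarray:
    """Monomer labeling of an unlabeled two-carbon unit at natural abundance."""
    return np.array([(1 - p13) ** 2, 2 * p13 * (1 - p13), p13**2])


@dataclass(frozen=True)
class PrecursorDistribution:
    """Monomer-labeling simplex vectors for the flux models.

    ``N`` is the pre-existing (unlabeled) pool, ``T`` the tracer-derived pool
    and ``D`` the fraction of the precursor pool drawn from the tracer
    (classical model); ``X`` is the jointly inferred monomer labeling (spatial
    model).
    """

    N: tuple = N_CORRECTED
    T: tuple = None
    D: float = None
    X: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "N", tuple(_check_simplex(self.N, "N")))
        if self.T is not None:
            object.__setattr__(self, "T", tuple(_check_simplex(self.T, "T")))
        if self.X is not None:
            object.__setattr__(self, "X", tuple(_check_simplex(self.X, "X")))
        if self.D is not None and not (0.0 <= self.D <= 1.0):
            raise ValueError("D must be in [0, 1]")

    @property
    def effective_monomer(self) -> np.ndarray:
        """(1 - D) * N + D * T — the classical model's synthesis-pool labeling."""
        if self.T is None or self.D is None:
            raise ValueError("effective monomer requires both T and D")
        return (1 - self.D) * np.asarray(self.N) + self.D * np.asarray(self.T)


def _self_convolve(m: np.ndarray, k: int) -> np.ndarray:
    out = m
    for _ in range(k - 1):
        out = np.convolve(out, m)
    return out


def monomer_power(m, k: int) -> np.ndarray:
    """Mass distribution of k independent monomers: k-fold self-convolution.

    ``m`` is the (m0, m1, m2) probability of a monomer carrying 0/1/2 heavy
    carbons; the result has length 2k + 1 and sums to 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = _check_simplex(m, "m")
    return _self_convolve(m.copy(), k)


def isa_forward(prec: PrecursorDistribution, g: float, n_subunits: int) -> np.ndarray:
    """Classical ISA predicted isotopologue fractions P_0..P_2n."""
    mono = prec.effective_monomer
    return g * monomer_power(mono, n_subunits) + (1 - g) * monomer_power(prec.N, n_subunits)


def sisa_forward(X, N, g: float, n_subunits: int) -> np.ndarray:
    """Spatial-model predicted fractions with inferred monomer labeling X."""
    return g * monomer_power(X, n_subunits) + (1 - g) * monomer_power(N, n_subunits)


def elongation_forward(X, N, g: float, e: float, n_subunits: int = 9) -> np.ndarray:
    """Elongation-model fractions P_0..P_{2n} (n = 9 for stearate).

    ``g`` is fully de novo synthesis (n labeled-pool units), ``e`` elongation
    of a pre-existing chain by one labeled-pool unit.
    """
    if g + e > 1 + 1e-9:
        raise ValueError("g + e must not exceed 1")
    X = _check_simplex(X, "X")
    N = _check_simplex(N, "N")
    base = monomer_power(N, n_subunits - 1)
    return (
        g * monomer_power(X, n_subunits)
        + e * np.convolve(X, base)
        + (1 - g - e) * monomer_power(N, n_subunits)
    )


@dataclass
class FluxFitResult:
    """Fitted fractional turnover (and elongation) with the inferred precursor."""

    g: float
    X: np.ndarray
    sse: float
    converged: bool
    n_unmasked: int
    e: float = None
    D: float = None

    @property
    def total_flux(self) -> float:
        """g + e: the total fraction newly synthesized during labeling."""
        return self.g + (self.e or 0.0)


def _prepare_observed(observed, mask, n_subunits, min_unmasked):
    observed = np.asarray(observed, dtype=float)
    n_iso = 2 * n_subunits + 1
    if len(observed) != n_iso:
        raise ValueError(f"expected {n_iso} isotopologue fractions, got {len(observed)}")
    m = np.ones(n_iso, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).copy()
    m &= np.isfinite(observed)
    if m.sum() < min_unmasked:
        raise UnderdeterminedFitError(
            f"only {int(m.sum())} unmasked isotopologues; need >= {min_unmasked}"
        )
    obs = observed[m]
    s = obs.sum()
    if s <= 0:
        raise UndefinedDistributionError("observed unmasked fractions sum to zero")
    return obs / s, m


def _masked_sse(pred: np.ndarray, obs_norm: np.ndarray, mask: np.ndarray) -> float:
    p = pred[mask]
    s = p.sum()
    if s <= 0:
        return np.inf
    r = p / s - obs_norm
    return float(r @ r)


_G_STARTS = (0.1, 0.3, 0.5, 0.7, 0.9)


def fit_sisa(observed, N=N_CORRECTED, n_subunits: int = 8, mask=None,
             g_starts=_G_STARTS, ftol: float = 1e-14) -> FluxFitResult:
    """Fit the spatial model (X, g) to observed isotopologue fractions.

    Follows the unconstrained-optimization route: X is parameterized by
    squared-then-normalized components and g through a logistic squashing map,
    so every iterate is feasible without explicit constraints. Observed and
    predicted fractions are both renormalized over the unmasked isotopologue
    set, so exclusions do not bias the fit. Multi-start over a ladder of g
    values with X initialized alternately at N and at the uniform monomer.
    """
    N = _check_simplex(N, "N")
    obs_norm, m = _prepare_observed(observed, mask, n_subunits, min_unmasked=5)
    base = monomer_power(N, n_subunits)
    power_cache = {}

    def predict(theta):
        t = theta[:3]
        w = t * t
        s = w.sum()
        X = w / s if s > 1e-12 else np.full(3, 1 / 3)
        g = expit(theta[3])
        return g * _self_convolve(X, n_subunits) + (1 - g) * base, X, g

    def objective(theta):
        pred, _, _ = predict(theta)
        return _masked_sse(pred, obs_norm, m)

    uniform = np.full(3, 1 / 3)
    best = None
    for i, g0 in enumerate(g_starts):
        X0 = N if i % 2 == 0 else uniform
        theta0 = np.concatenate([np.sqrt(np.asarray(X0) + 1e-3), [logit(np.clip(g0, 1e-6, 1 - 1e-6))]])
        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                options={"ftol": ftol, "gtol": 1e-12, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish sharpens the logistic/simplex reparameterization
    res = optimize.minimize(objective, best.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 600})
    final = res if res.fun <= best.fun else best
    pred, X, g = predict(final.x)
    converged = bool(final.success or final.fun < 1e-8)
    sse_null = _masked_sse(base, obs_norm, m)
    if sse_null <= final.fun + 1e-12:
        # X ~ N leaves g unidentifiable; prefer the nested no-synthesis model
        return FluxFitResult(g=0.0, X=N.copy(), sse=float(sse_null), converged=True,
                             n_unmasked=int(m.sum()))
    return FluxFitResult(g=float(g), X=X, sse=float(final.fun), converged=converged,
                         n_unmasked=int(m.sum()))


def fit_isa(observed, T, N=N_CORRECTED, n_subunits: int = 8, mask=None,
            ftol: float = 1e-14) -> FluxFitResult:
    """Fit the classical model's (D, g) with known tracer labeling T."""
    N = _check_simplex(N, "N")
    T = _check_simplex(T, "T")
    obs_norm, m = _prepare_observed(observed, mask, n_subunits, min_unmasked=3)
    base = monomer_power(N, n_subunits)

    def predict(theta):
        D, g = expit(theta)
        mono = (1 - D) * N + D * T
        return g * _self_convolve(mono, n_subunits) + (1 - g) * base, D, g

    def objective(theta):
        pred, _, _ = predict(theta)
        return _masked_sse(pred, obs_norm, m)

    best = None
    for g0 in (0.2, 0.5, 0.8):
        for d0 in (0.3, 0.7):
            theta0 = logit(np.clip([d0, g0], 1e-6, 1 - 1e-6))
            res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                    options={"ftol": ftol, "gtol": 1e-12, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
    res = optimize.minimize(objective, best.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 1000})
    final = res if res.fun <= best.fun else best
    _, D, g = predict(final.x)
    X = (1 - D) * N + D * T
    return FluxFitResult(g=float(g), X=X, sse=float(final.fun),
                         converged=bool(final.success or final.fun < 1e-8),
                         n_unmasked=int(m.sum()), D=float(D))


def fit_elongation(observed, N=N_CORRECTED, n_subunits: int = 9, mask=None,
                   ftol: float = 1e-14) -> FluxFitResult:
    """Fit (X, g, e) of the elongation model under explicit constraints.

    Constrained minimization (SLSQP): X on the simplex, g >= 0, e >= 0,
    g + e <= 1; residuals over unmasked isotopologues only.
    """
    N = _check_simplex(N, "N")
    obs_norm, m = _prepare_observed(observed, mask, n_subunits, min_unmasked=6)
    base_n = monomer_power(N, n_subunits)
    base_n1 = monomer_power(N, n_subunits - 1)

    def predict(params):
        X = np.clip(params[:3], 0.0, None)
        s = X.sum()
        X = X / s if s > 0 else np.full(3, 1 / 3)
        g, e = params[3], params[4]
        pred = (g * _self_convolve(X, n_subunits) + e * np.convolve(X, base_n1)
                + (1 - g - e) * base_n)
        return pred, X, g, e

    def objective(params):
        pred, _, _, _ = predict(params)
        return _masked_sse(pred, obs_norm, m)

    bounds = [(0, 1)] * 3 + [(0, 1), (0, 1)]
    constraints = [
        {"type": "eq", "fun": lambda p: p[0] + p[1] + p[2] - 1.0,
         "jac": lambda p: np.array([1.0, 1.0, 1.0, 0.0, 0.0])},
        {"type": "ineq", "fun": lambda p: 1.0 - p[3] - p[4],
         "jac": lambda p: np.array([0.0, 0.0, 0.0, -1.0, -1.0])},
    ]
    uniform = np.full(3, 1 / 3)
    starts = [(0.1, 0.05), (0.3, 0.1), (0.5, 0.1), (0.2, 0.3), (0.7, 0.05)]
    best, best_fun = None, np.inf
    for i, (g0, e0) in enumerate(starts):
        X0 = N if i % 2 == 0 else uniform
        p0 = np.concatenate([X0, [g0, e0]])
        res = optimize.minimize(objective, p0, method="SLSQP", bounds=bounds,
                                constraints=constraints,
                                options={"ftol": ftol, "maxiter": 500})
        if res.fun < best_fun:
            best, best_fun = res, res.fun
    pred, X, g, e = predict(best.x)
    g = float(np.clip(g, 0.0, 1.0))
    e = float(np.clip(e, 0.0, 1.0 - g))
    sse = float(best_fun)
    # parsimony tie-break: when X ~ N the flux terms are unidentifiable and the
    # nested no-synthesis model explains the data equally well
    sse_null = _masked_sse(base_n, obs_norm, m)
    if sse_null <= sse + 1e-12:
        return FluxFitResult(g=0.0, X=N.copy(), sse=sse_null, converged=True,
                             n_unmasked=int(m.sum()), e=0.0)
    return FluxFitResult(g=g, X=X, sse=sse,
                         converged=bool(best.success or best_fun < 1e-8),
                         n_unmasked=int(m.sum()), e=e)


@dataclass
class FluxImage:
    """Per-pixel flux-fit maps over the tissue mask.

    ``g`` (and ``e`` for the elongation model) are NaN off-tissue and on
    failed pixels; ``t_hours`` is the labeling duration, carried as metadata
    only (no rate extrapolation is performed).
    """

    target_name: str
    model: str
    g: np.ndarray
    sse: np.ndarray
    converged: np.ndarray
    e: np.ndarray = None
    t_hours: float = None
    n_fitted: int = 0
    n_failed: int = 0

    def total_flux_map(self) -> np.ndarray:
        return self.g if self.e is None else self.g + self.e


def flux_image(stack: IonImageStack, target, model: str = "sisa",
               tissue_mask: np.ndarray = None, iso_mask=None, N=N_CORRECTED,
               min_total: float = 0.0, t_hours: float = None) -> FluxImage:
    """Fit the chosen flux model at every tissue pixel of an NA-corrected stack.

    ``iso_mask`` is the isotopologue usability mask from the interference
    screen. Pixels whose summed intensity falls below ``min_total``, or whose
    fit fails, are recorded as missing; more than 50% failures aborts with
    diagnostics.
    """
    if model not in ("sisa", "elongation"):
        raise ValueError(f"unknown model {model!r}")
    t = stack.target(target if isinstance(target, str) else target.name)
    if t.n_subunits is None:
        raise ValueError(f"target {t.name} has no subunit count")
    n_iso_needed = 2 * t.n_subunits + 1
    if model == "elongation" and n_iso_needed < 19:
        # an elongated chain has >= 9 two-carbon units
        raise ValueError(
            f"elongation model needs 19 isotopologues; target {t.name} provides {t.n_carbons + 1}"
        )
    if t.n_carbons + 1 < n_iso_needed:
        raise ValueError(
            f"{model} model needs {n_iso_needed} isotopologues; target {t.name} has {t.n_carbons + 1}"
        )
    sub = stack.target_tensor(t.name)
    h, w = sub.shape[1:]
    if tissue_mask is None:
        tissue_mask = np.ones((h, w), dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)

    g_map = np.full((h, w), np.nan)
    e_map = np.full((h, w), np.nan) if model == "elongation" else None
    sse_map = np.full((h, w), np.nan)
    conv_map = np.zeros((h, w), dtype=bool)
    n_fitted = n_failed = 0
    for y, x in zip(*np.nonzero(tissue_mask)):
        a = sub[:, y, x]
        if not np.all(np.isfinite(a)):
            logger.warning("pixel (%d, %d): non-finite intensities, skipped", x, y)
            n_failed += 1
            continue
        if a.sum() <= min_total:
            n_failed += 1
            continue
        dist = LabelingDistribution(a=a, n_carbons=t.n_carbons,
                                    mask=iso_mask, corrected_flag=True)
        try:
            f = fractional_labeling(dist)
            if model == "sisa":
                fit = fit_sisa(f[:n_iso_needed], N=N, n_subunits=t.n_subunits,
                               mask=dist.mask[:n_iso_needed])
            else:
                fit = fit_elongation(f[:n_iso_needed], N=N, n_subunits=t.n_subunits,
                                     mask=dist.mask[:n_iso_needed])
        except (UndefinedDistributionError, UnderdeterminedFitError) as exc:
            logger.warning("pixel (%d, %d): %s", x, y, exc)
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        g_map[y, x] = fit.g
        if e_map is not None:
            e_map[y, x] = fit.e
        sse_map[y, x] = fit.sse
        conv_map[y, x] = True
        n_fitted += 1
    n_attempted = n_fitted + n_failed
    if n_attempted and n_failed > 0.5 * n_attempted:
        raise RuntimeError(
            f"flux fitting failed on {n_failed}/{n_attempted} tissue pixels for {t.name}; "
            "check NA correction, interference masks and the minimum-intensity threshold"
        )
    if n_failed:
        logger.info("%s/%s tissue pixels failed for %s", n_failed, n_attempted, t.name)
    return FluxImage(target_name=t.name, model=model, g=g_map, e=e_map, sse=sse_map,
                     converged=conv_map, t_hours=t_hours, n_fitted=n_fitted, n_failed=n_failed)


@dataclass
class RegionComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    ratio: float
    t_statistic: float
    p_value: float
    test: str
    n_replicates: int = 1


def region_summary(flux, roi_a: np.ndarray, roi_b: np.ndarray,
                   use_total: bool = True) -> RegionComparison:
    """Compare flux between two regions of interest.

    ``flux`` is one FluxImage or a list of replicate FluxImages. For a single
    image the comparison is a Welch t-test across pixels; for replicates the
    per-image ROI means are compared with a paired two-tailed t-test.
    """
    images = flux if isinstance(flux, (list, tuple)) else [flux]
    roi_a = np.asarray(roi_a, dtype=bool)
    roi_b = np.asarray(roi_b, dtype=bool)
    if roi_a.sum() == 0 or roi_b.sum() == 0:
        raise ValueError("each ROI must contain at least one pixel")
    if np.any(roi_a & roi_b):
        raise ValueError("ROIs must be disjoint")

    def roi_values(img, roi):
        vals = img.total_flux_map()[roi] if use_total else img.g[roi]
        return vals[np.isfinite(vals)]

    means_a = [roi_values(img, roi_a).mean() for img in images]
    means_b = [roi_values(img, roi_b).mean() for img in images]
    if len(images) > 1:
        tstat, p = stats.ttest_rel(means_a, means_b)
        mean_a, sd_a = float(np.mean(means_a)), float(np.std(means_a, ddof=1))
        mean_b, sd_b = float(np.mean(means_b)), float(np.std(means_b, ddof=1))
        test = "paired t (replicates)"
    else:
        va, vb = roi_values(images[0], roi_a), roi_values(images[0], roi_b)
        if len(va) > 1 and len(vb) > 1:
            tstat, p = stats.ttest_ind(va, vb, equal_var=False)
        else:
            tstat, p = np.nan, np.nan
        mean_a, sd_a = float(va.mean()), float(va.std(ddof=1)) if len(va) > 1 else 0.0
        mean_b, sd_b = float(vb.mean()), float(vb.std(ddof=1)) if len(vb) > 1 else 0.0
        test = "Welch t (pixels)"
    ratio = mean_a / mean_b if mean_b != 0 else np.inf
    return RegionComparison(mean_a=mean_a, sd_a=sd_a, mean_b=mean_b, sd_b=sd_b,
                            ratio=float(ratio), t_statistic=float(tstat),
                            p_value=float(p), test=test, n_replicates=len(images))
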