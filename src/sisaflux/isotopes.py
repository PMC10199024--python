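"""Isotopologue arithmetic: fractional labeling, carbon-atom labeling, pool sizes,
natural-abundance correction and interference screening.

Fractional labeling of isotopologue x is its abundance divided by the summed
abundance of all isotopologues of the metabolite:

    f_x = a_x / sum_j a_j

and the fractional carbon-atom labeling is the fraction of the metabolite's
carbon atoms that carry a heavy label:

    L = sum_j (j * a_j) / (n * sum_j a_j)

Both are invariant to per-pixel multiplicative matrix effects, which is what
makes labeling-based imaging quantitative where pool sizes are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .msi_io import IonImageStack, TargetMetabolite

logger = logging.getLogger(__name__)

#: Terrestrial natural abundance of 13C.
P13C_NATURAL = 0.0107


class UndefinedDistributionError(ValueError):
    """All usable isotopologue abundances are zero; fractions are undefined."""


@dataclass
class LabelingDistribution:
    """Isotopologue abundances a_0..a_n with a usability mask.

    ``mask[k]`` is true when isotopologue k is usable (not excluded by the
    interference screen). Abundances are clipped to be nonnegative.
    """

    a: np.ndarray
    n_carbons: int
    mask: np.ndarray = None
    corrected_flag: bool = False

    def __post_init__(self):
        self.a = np.clip(np.asarray(self.a, dtype=float), 0.0, None)
        if self.mask is None:
            self.mask = np.ones(self.n_carbons + 1, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.a) != self.n_carbons + 1 or len(self.mask) != self.n_carbons + 1:
            raise ValueError("a and mask must have length n_carbons + 1")

    @property
    def total(self) -> float:
        return float(self.a[self.mask].sum())


def fractional_labeling(dist: LabelingDistribution) -> np.ndarray:
    """Fractional abundances f_0..f_n; masked entries are NaN (undefined, not 0)."""
    total = dist.total
    if total <= 0:
        raise UndefinedDistributionError("all unmasked abundances are zero")
    f = np.full(dist.n_carbons + 1, np.nan)
    f[dist.mask] = dist.a[dist.mask] / total
    return f


def carbon_atom_labeling(dist: LabelingDistribution) -> float:
    """Fraction of the metabolite's carbons that are heavy, in [0, 1]."""
    total = dist.total
    if total <= 0:
        raise UndefinedDistributionError("all unmasked abundances are zero")
    j = np.arange(dist.n_carbons + 1)
    return float((j[dist.mask] * dist.a[dist.mask]).sum() / (dist.n_carbons * total))


def pool_size_image(stack: IonImageStack, target: TargetMetabolite | str,
                    mask: np.ndarray = None) -> np.ndarray:
    """Per-pixel sum of (unmasked) isotopologue intensities: relative pool size."""
    name = target if isinstance(target, str) else target.name
    sub = stack.target_tensor(name)
    if mask is None:
        mask = np.ones(sub.shape[0], dtype=bool)
    return sub[np.asarray(mask, dtype=bool)].sum(axis=0)


def na_correction_matrix(n_carbons: int, p13: float = P13C_NATURAL) -> np.ndarray:
    """Natural-abundance convolution matrix M.

    ``M[i, j]`` is the probability that a molecule carrying ``j`` tracer-derived
    heavy carbons is observed with ``i`` total heavy carbons, i.e. the binomial
    probability of ``i - j`` of the remaining ``n - j`` carbons being heavy by
    natural abundance. Columns sum to 1, so the forward map conserves total
    abundance.
    """
    if not (0.0 <= p13 < 1.0):
        raise ValueError("p13 must be in [0, 1)")
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(0, n - j + 1)
        M[j + k, j] = stats.binom.pmf(k, n - j, p13)
    return M


def natural_abundance_pattern(n_carbons: int, p13: float = P13C_NATURAL) -> np.ndarray:
    """Isotopologue fractions of a fully unlabeled molecule (column 0 of M)."""
    return na_correction_matrix(n_carbons, p13)[:, 0]


def na_correct(dist: LabelingDistribution, p13: float = P13C_NATURAL,
               flag_threshold: float = 0.05) -> LabelingDistribution:
    """Remove the natural-abundance contribution from measured abundances.

    Solves ``M x = a`` for nonnegative ``x`` by NNLS (robust to noise where a
    direct inverse would produce negative isotopologues), then rescales so the
    total abundance is conserved. A residual above ``flag_threshold`` of the
    total marks the distribution as inconsistent (logged).
    """
    if dist.corrected_flag:
        raise ValueError("distribution is already natural-abundance corrected")
    a = dist.a.copy()
    if not dist.mask.all():
        logger.warning("correcting a masked distribution; masked entries imputed as 0")
        a[~dist.mask] = 0.0
    M = na_correction_matrix(dist.n_carbons, p13)
    if p13 == 0.0:
        x = a.copy()
    else:
        x, rnorm = optimize.nnls(M, a)
        total = a.sum()
        if total > 0 and rnorm > flag_threshold * total:
            logger.warning("natural-abundance correction residual %.3g exceeds %.0f%% of total",
                           rnorm, 100 * flag_threshold)
        if x.sum() > 0 and total > 0:
            x *= total / x.sum()
    return LabelingDistribution(a=x, n_carbons=dist.n_carbons, mask=dist.mask.copy(),
                                corrected_flag=True)


def na_correct_image(tensor: np.ndarray, p13: float = P13C_NATURAL,
                     mask: np.ndarray = None) -> np.ndarray:
    """Per-pixel NA correction of a ``(n+1, h, w)`` isotopologue tensor.

    When ``mask`` marks interfered channels as unusable, the NNLS solve uses
    only the unmasked rows of the convolution matrix: the corrupted channels
    carry no information and including them would bias the usable ones.
    """
    n_plus1, h, w = tensor.shape
    M = na_correction_matrix(n_plus1 - 1, p13)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        M_rows = M[mask, :]
    else:
        mask = np.ones(n_plus1, dtype=bool)
        M_rows = M
    out = np.zeros_like(tensor, dtype=float)
    flat = tensor.reshape(n_plus1, -1)
    out_flat = out.reshape(n_plus1, -1)
    for i in range(flat.shape[1]):
        a = flat[:, i]
        total = a[mask].sum()
        if total <= 0:
            continue
        x, _ = optimize.nnls(M_rows, a[mask])
        if x.sum() > 0:
            x *= total / x.sum()
        out_flat[:, i] = x
    return out


@dataclass
class InterferenceReport:
    """Per-target isotopologue interference flags from an unlabeled control.

    ``excess[target][k]`` is the tissue-mean NA-corrected fractional abundance
    of isotopologue k in the unlabeled control — signal that natural abundance
    cannot explain. ``flags[target][k]`` marks isotopologues whose excess beats
    the decision threshold; M0 is never flagged.
    """

    flags: dict
    excess: dict
    threshold: float
    status: str = "screened"  # or "unscreened"

    def mask_for(self, target_name: str) -> np.ndarray:
        """Usability mask (true = keep) for a target, for LabelingDistribution."""
        if self.status != "screened":
            n = len(next(iter(self.flags.values()))) if self.flags else 0
            raise ValueError("interference screen was not run; no mask available")
        return ~np.asarray(self.flags[target_name], dtype=bool)

    def flagged_indices(self, target_name: str) -> list:
        return [int(k) for k in np.nonzero(self.flags[target_name])[0]]

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, fl in self.flags.items():
            for k, (f, e) in enumerate(zip(fl, self.excess[name])):
                rows.append({"target": name, "isotopologue": k, "flagged": bool(f),
                             "excess_fraction": float(e), "threshold": self.threshold})
        return pd.DataFrame(rows)


def unscreened_report(targets) -> InterferenceReport:
    """Report representing 'no unlabeled control available' — not a silent pass."""
    flags = {t.name: np.zeros(t.n_carbons + 1, dtype=bool) for t in targets}
    excess = {t.name: np.full(t.n_carbons + 1, np.nan) for t in targets}
    logger.warning("no unlabeled control supplied: interference status is UNSCREENED")
    return InterferenceReport(flags=flags, excess=excess, threshold=np.nan, status="unscreened")


def screen_interferences(unlabeled_stack: IonImageStack, targets=None,
                         threshold: float = 0.02, tissue_mask: np.ndarray = None,
                         p13: float = P13C_NATURAL) -> InterferenceReport:
    """Flag isotopologues whose unlabeled-control signal exceeds natural abundance.

    For each isotopologue k >= 1 the tissue-mean NA-corrected fractional
    abundance in the unlabeled control is computed; anything above ``threshold``
    is residual signal an overlapping background ion must be producing, and the
    isotopologue is excluded from labeled-sample analysis.
    """
    if unlabeled_stack.labeled_flag:
        raise ValueError("interference screening requires an unlabeled control stack")
    if targets is None:
        targets = unlabeled_stack.targets
    if tissue_mask is None:
        tissue_mask = np.ones((unlabeled_stack.grid.height, unlabeled_stack.grid.width), dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)

    flags, excess = {}, {}
    for t in targets:
        sub = unlabeled_stack.target_tensor(t.name)
        vecs = sub[:, tissue_mask]  # (n+1, n_tissue)
        totals = vecs.sum(axis=0)
        usable = totals > 0
        n = t.n_carbons
        if not np.any(usable):
            flags[t.name] = np.zeros(n + 1, dtype=bool)
            excess[t.name] = np.full(n + 1, np.nan)
            continue
        M = na_correction_matrix(n, p13)
        fracs = np.zeros((n + 1, int(usable.sum())))
        for i, col in enumerate(np.nonzero(usable)[0]):
            x, _ = optimize.nnls(M, vecs[:, col])
            s = x.sum()
            fracs[:, i] = x / s if s > 0 else 0.0
        mean_frac = fracs.mean(axis=1)
        fl = mean_frac > threshold
        fl[0] = False  # M0 is the unlabeled species itself, never an interference
        flags[t.name] = fl
        excess[t.name] = mean_frac
        if fl.any():
            logger.info("target %s: interfered isotopologues %s", t.name,
                        np.nonzero(fl)[0].tolist())
    return InterferenceReport(flags=flags, excess=excess, threshold=threshold)
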