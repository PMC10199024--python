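"""Tissue segmentation, denoising and intensity normalization of ion image stacks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .msi_io import IonImageStack

logger = logging.getLogger(__name__)


@dataclass
class SegmentationMask:
    """Boolean tissue mask (true = tissue) with the clustering metadata."""

    mask: np.ndarray
    n_components: int
    k: int = 2
    seed: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D image")

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())


def segment_tissue(stack: IonImageStack, n_components: int = 5, seed: int = 0) -> SegmentationMask:
    """Split pixels into tissue and background by PCA + 2-means clustering.

    Each pixel's channel vector is projected onto the top principal components
    and partitioned into two clusters; the cluster with the higher mean total
    ion intensity is labeled tissue.
    """
    n_ch, h, w = stack.tensor.shape
    if h * w < 2 or n_ch < 2:
        raise ValueError("segmentation needs at least 2 pixels and 2 channels")
    X = stack.tensor.reshape(n_ch, h * w).T
    if np.allclose(X, X[0]):
        raise ValueError("all pixels are identical; no variance to decompose")
    n_comp = min(n_components, n_ch, h * w)
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    labels = KMeans(n_clusters=2, random_state=seed, n_init=10).fit_predict(scores)
    tic = X.sum(axis=1)
    mean_tic = [tic[labels == c].mean() if np.any(labels == c) else -np.inf for c in (0, 1)]
    tissue_cluster = int(np.argmax(mean_tic))
    mask = (labels == tissue_cluster).reshape(h, w)
    return SegmentationMask(mask=mask, n_components=n_comp, k=2, seed=seed)


def gaussian_kernel_3x3(sigma: float = 1.0) -> np.ndarray:
    """Normalized 3x3 Gaussian kernel (sigma in pixels, support truncated to 3x3)."""
    w = np.exp(-np.arange(-1, 2) ** 2 / (2.0 * sigma**2))
    k = np.outer(w, w)
    return k / k.sum()


def gaussian_denoise(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """3x3 Gaussian blur with reflecting boundaries; total intensity preserving."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return ndimage.convolve(image, gaussian_kernel_3x3(sigma), mode="reflect")


def denoise_stack(stack: IonImageStack, sigma: float = 1.0) -> IonImageStack:
    """Apply the 3x3 blur to every isotopologue channel image."""
    tensor = np.stack([gaussian_denoise(ch, sigma) for ch in stack.tensor])
    return IonImageStack(targets=stack.targets, tensor=tensor, grid=stack.grid,
                         labeled_flag=stack.labeled_flag)


def normalize_pixels(stack: IonImageStack, mode: str = "none") -> IonImageStack:
    """Per-pixel intensity normalization.

    ``tic`` divides each pixel's channel vector by its total ion current and
    rescales by the grid-median TIC (so magnitudes stay interpretable);
    zero-TIC pixels are left unchanged and logged. ``none`` is the identity.
    Isotopologue *ratios* are invariant to this operation by construction.
    """
    if mode not in ("none", "tic"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "none":
        return IonImageStack(targets=stack.targets, tensor=stack.tensor.copy(),
                             grid=stack.grid, labeled_flag=stack.labeled_flag)
    tic = stack.tensor.sum(axis=0)
    nonzero = tic > 0
    if not np.all(nonzero):
        logger.warning("%d zero-TIC pixels left unnormalized", int((~nonzero).sum()))
    median_tic = np.median(tic[nonzero]) if np.any(nonzero) else 1.0
    scale = np.ones_like(tic)
    scale[nonzero] = median_tic / tic[nonzero]
    tensor = stack.tensor * scale[None, :, :]
    return IonImageStack(targets=stack.targets, tensor=tensor, grid=stack.grid,
                         labeled_flag=stack.labeled_flag)


def export_mask_png(mask: SegmentationMask, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.imshow(mask.mask, cmap="gray", interpolation="nearest")
    ax.set_title("tissue mask")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mask_to_coordinates(mask: SegmentationMask):
    ys, xs = np.nonzero(mask.mask)
    return list(zip(xs.tolist(), ys.tolist()))
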