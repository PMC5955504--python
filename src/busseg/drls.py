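"""Seeded distance-regularized level-set evolution (DRLSE) baseline.

The comparison algorithm: a contour represented as the zero level of a signed
field phi (negative inside) evolves under

    dphi/dt = mu * div(d_p(|grad phi|) grad phi)                (regularization)
            + lambda * delta_eps(phi) * div(g grad phi/|grad phi|)   (edge length)
            + alpha * g * delta_eps(phi)                        (balloon area)

with the double-well potential regularizer d_p, a smoothed Dirac delta of
width eps, and the edge indicator g = 1/(1 + |grad(G_sigma * I)|^2).  A
negative alpha inflates the contour from a seed strictly inside the lesion
until the edge indicator halts it.  The seed is the ground-truth mask eroded
by a disk: radius 4 for lesions under 500 pixels, radius 8 otherwise —
deliberately favourable seeding that stands in for an expert operator.

Weights lambda = 0.5, alpha = -0.75, eps = 0.5 are the published optima; the
remaining discretization constants (mu = 0.04, timestep 5 so mu*dt = 0.2
satisfies the < 0.25 stability bound, sigma = 1.5 px, 300 iterations, binary
step initialization at +/-2) follow standard DRLSE practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, center_of_mass, gaussian_filter
from skimage.morphology import disk

from .phantom import BModeImage, SegmentationMask

__all__ = [
    "DRLSConfig",
    "LevelSetField",
    "make_seed",
    "edge_indicator",
    "evolve",
    "segment_drls",
    "DRLSSegmenter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DRLSConfig:
    lambda_weight: float = 0.5     # length-term weight
    alpha_weight: float = -0.75    # area (balloon) weight; negative expands
    epsilon_width: float = 0.5     # Dirac/Heaviside smoothing width, px
    mu_weight: float = 0.04        # distance-regularization weight
    timestep: float = 5.0
    sigma_smooth: float = 1.5      # Gaussian pre-smoothing for edge indicator
    n_iterations: int = 1000
    small_lesion_threshold: int = 500  # px; < threshold erode small, else large
    erosion_small: int = 4
    erosion_large: int = 8
    init_height: float = 2.0       # binary-step initialization at +/- this

    def __post_init__(self) -> None:
        if self.mu_weight * self.timestep >= 0.25:
            raise ValueError(
                f"stability requires mu*timestep < 0.25, got "
                f"{self.mu_weight * self.timestep}"
            )
        if self.erosion_small >= self.erosion_large:
            raise ValueError("erosion_small must be < erosion_large")
        if self.epsilon_width <= 0:
            raise ValueError("epsilon_width must be > 0")


@dataclass
class LevelSetField:
    """Signed scalar field; the contour is {phi = 0}, interior is phi < 0."""

    phi: np.ndarray
    iteration: int = 0

    def mask(self) -> SegmentationMask:
        return SegmentationMask((self.phi < 0).astype(np.uint8), role="prediction")


def make_seed(truth_mask, config: DRLSConfig | None = None) -> SegmentationMask:
    """Erode the truth mask into an interior seed.

    Lesions of fewer than ``small_lesion_threshold`` pixels are eroded by a
    disk of radius ``erosion_small``, all others (the threshold itself
    included) by ``erosion_large``.  If erosion empties the mask the seed
    falls back to the single pixel nearest the mask centroid (logged).
    """
    config = config or DRLSConfig()
    m = truth_mask.pixels if isinstance(truth_mask, SegmentationMask) else truth_mask
    m = np.asarray(m).astype(bool)
    area = int(m.sum())
    if area == 0:
        raise ValueError("cannot seed from an empty truth mask")
    radius = config.erosion_small if area < config.small_lesion_threshold \
        else config.erosion_large
    eroded = binary_erosion(m, structure=disk(radius))
    if not eroded.any():
        log.warning("erosion by %d emptied the mask; falling back to centroid seed",
                    radius)
        cr, cc = center_of_mass(m)
        rows, cols = np.nonzero(m)
        i = np.argmin((rows - cr) ** 2 + (cols - cc) ** 2)
        eroded = np.zeros_like(m)
        eroded[rows[i], cols[i]] = True
    return SegmentationMask(eroded.astype(np.uint8), role="seed")


def edge_indicator(image, sigma_smooth: float = 1.5) -> np.ndarray:
    """g = 1 / (1 + |grad(G_sigma * I)|^2): 1 in flat regions, small at edges."""
    arr = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    smoothed = gaussian_filter(arr, sigma_smooth)
    gy, gx = np.gradient(smoothed)
    return 1.0 / (1.0 + gy**2 + gx**2)


def _neumann_bound(phi: np.ndarray) -> np.ndarray:
    """Mirror the outermost ring so the normal derivative vanishes."""
    p = phi.copy()
    p[0, :], p[-1, :] = p[2, :], p[-3, :]
    p[:, 0], p[:, -1] = p[:, 2], p[:, -3]
    return p


def _dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    d = np.zeros_like(phi)
    band = np.abs(phi) <= eps
    d[band] = (1.0 + np.cos(np.pi * phi[band] / eps)) / (2.0 * eps)
    return d


def _div(nx: np.ndarray, ny: np.ndarray) -> np.ndarray:
    _, dxx = np.gradient(nx)
    dyy, _ = np.gradient(ny)
    return dxx + dyy


def _dist_reg_p2(phi: np.ndarray) -> np.ndarray:
    """div(d_p2(|grad phi|) grad phi) for the double-well potential p2."""
    gy, gx = np.gradient(phi)
    s = np.sqrt(gx**2 + gy**2)
    a = (s >= 0) & (s <= 1)
    b = s > 1
    # d_p(s) = p'(s)/s with p2: sin(2 pi s)/(2 pi) on [0,1], (s-1) beyond
    ps = a * np.sin(2 * np.pi * s) / (2 * np.pi) + b * (s - 1)
    dps = np.where(ps != 0, ps, 1.0) / np.where(s != 0, s, 1.0)
    from scipy.ndimage import laplace

    return _div((dps - 1) * gx, (dps - 1) * gy) + laplace(phi, mode="nearest")


def evolve(
    field: LevelSetField,
    g: np.ndarray,
    config: DRLSConfig | None = None,
    steps: int = 1,
) -> LevelSetField:
    """Run ``steps`` explicit-Euler updates of the DRLSE flow in place."""
    config = config or DRLSConfig()
    phi = np.asarray(field.phi, dtype=np.float64)
    if phi.shape != g.shape:
        raise ValueError("phi and edge indicator must share a grid")
    vy, vx = np.gradient(g)
    eps_div = 1e-10
    for step in range(steps):
        phi = _neumann_bound(phi)
        gy, gx = np.gradient(phi)
        s = np.sqrt(gx**2 + gy**2)
        nx, ny = gx / (s + eps_div), gy / (s + eps_div)
        curvature = _div(nx, ny)
        dirac = _dirac(phi, config.epsilon_width)
        edge_term = dirac * (vx * nx + vy * ny) + dirac * g * curvature
        area_term = dirac * g
        phi = phi + config.timestep * (
            config.mu_weight * _dist_reg_p2(phi)
            + config.lambda_weight * edge_term
            + config.alpha_weight * area_term
        )
        if not np.all(np.isfinite(phi)):
            raise FloatingPointError(
                f"level-set evolution diverged at iteration {field.iteration + step + 1}"
            )
    field.phi = phi
    field.iteration += steps
    return field


def segment_drls(
    image,
    truth_mask,
    config: DRLSConfig | None = None,
) -> SegmentationMask:
    """Seeded DRLSE segmentation of one (preprocessed-grid) image.

    Builds the eroded seed from the truth mask, initializes phi as a binary
    step (-c inside the seed, +c outside), evolves for ``n_iterations`` under
    the edge indicator of the image, and returns {phi < 0} as the prediction.

    The image is rescaled internally to the 8-bit intensity range before the
    edge indicator: g = 1/(1+|grad|^2) only brakes the balloon force when
    edge gradients are numerically large, which a standard-scored image
    cannot provide.  Any input scale therefore behaves identically.
    """
    config = config or DRLSConfig()
    arr = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    seed = make_seed(truth_mask, config)
    if seed.shape != arr.shape:
        raise ValueError("image and truth mask must share a grid")
    c = config.init_height
    phi = np.where(seed.pixels > 0, -c, c).astype(np.float64)
    field = LevelSetField(phi)
    g = edge_indicator(arr, config.sigma_smooth)
    evolve(field, g, config, steps=config.n_iterations)
    return field.mask()


class DRLSSegmenter:
    """Configured DRLSE runner (not an estimator: it has nothing to fit,
    and each prediction needs the image's truth mask to construct its seed)."""

    def __init__(self, config: DRLSConfig | None = None):
        self.config = config or DRLSConfig()

    def segment(self, image, truth_mask) -> SegmentationMask:
        return segment_drls(image, truth_mask, self.config)

    def segment_set(self, images, truth_masks) -> list[SegmentationMask]:
        return [self.segment(i, t) for i, t in zip(images, truth_masks)]
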