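"""Single-scale 2D Frangi vesselness filtering and hysteresis segmentation.

Canaliculi are nearly homogeneous in diameter at our resolution, so a single
scale (sigma = 1 px, i.e. a smoothing FWHM of 2.35 px) suffices. The filter
is applied slice-by-slice in the imaging plane — the axial PSF is far wider
than the tubes, so in-plane Hessian geometry carries the signal — and the
response stack is segmented as a whole volume with a dual (hysteresis)
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grid import VoxelGrid


@dataclass
class VesselnessParams:
    """Tube-enhancement parameters.

    ``sigma_px`` is the Gaussian derivative scale in pixels. ``beta``
    penalizes blob-like structures; ``c`` penalizes low second-order
    structureness and may be "auto" (half the maximum Hessian Frobenius
    norm of each slice, the conventional plugin default). Bright polarity
    enhances bright tubes on a dark background.
    """

    sigma_px: float = 1.0
    beta: float = 0.5
    c: float | str = "auto"
    bright: bool = True

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (self.c == "auto" or (isinstance(self.c, (int, float)) and self.c > 0)):
            raise ValueError("c must be positive or 'auto'")


@dataclass
class HysteresisParams:
    """Dual-threshold segmentation parameters.

    Voxels above ``t_high`` seed the mask; connected voxels above ``t_low``
    are linked in. Absolute thresholds may be given directly; otherwise they
    are derived from the response histogram — the reproducible surrogate
    for a visually chosen pair. The default ``quantile`` method anchors
    both thresholds on a high quantile of the nonzero response (the
    ``anchor_pct`` percentile lies inside the brightest tubes, whose
    response amplitude does not depend on how dense the network is):
    ``t_high = high_frac × anchor`` and ``t_low = low_frac × anchor``.
    ``otsu`` (Otsu's threshold of the nonzero response, with
    ``t_low = low_ratio × t_high``) and ``percentile`` methods are also
    available. Linking runs in 3D (26-connectivity) by default, segmenting
    the whole volume; 2D restricts linking to within-slice 8-neighborhoods.
    """

    t_low: float | None = None
    t_high: float | None = None
    method: str = "quantile"  # "quantile", "otsu" or "percentile"
    anchor_pct: float = 99.9  # quantile method: anchor percentile of nonzero response
    high_frac: float = 0.15   # quantile method: t_high as a fraction of the anchor
    low_frac: float = 0.03    # quantile method: t_low as a fraction of the anchor
    low_ratio: float = 0.5    # otsu method: t_low as a fraction of t_high
    low_pct: float = 97.5
    high_pct: float = 99.5
    connectivity: str = "3d"  # "3d" (26) or "2d" (8, within slice)

    def __post_init__(self) -> None:
        if self.t_low is not None and self.t_high is not None and self.t_low > self.t_high:
            raise ValueError("t_low must be <= t_high")
        if self.connectivity not in ("2d", "3d"):
            raise ValueError("connectivity must be '2d' or '3d'")
        if self.method not in ("quantile", "otsu", "percentile"):
            raise ValueError("method must be 'quantile', 'otsu' or 'percentile'")
        if not (0 < self.low_ratio <= 1):
            raise ValueError("low_ratio must lie in (0, 1]")
        if not (0 < self.low_frac <= self.high_frac <= 1):
            raise ValueError("need 0 < low_frac <= high_frac <= 1")

    def resolve(self, response: np.ndarray) -> tuple[float, float]:
        """Absolute (t_low, t_high) for a given response volume."""
        if self.t_low is not None and self.t_high is not None:
            return float(self.t_low), float(self.t_high)
        nz = response[response > 0]
        if nz.size == 0 or np.ptp(nz) == 0:
            return np.inf, np.inf  # no usable histogram -> empty mask
        if self.method == "quantile":
            anchor = float(np.percentile(nz, self.anchor_pct))
            hi = self.high_frac * anchor
            lo = self.low_frac * anchor
        elif self.method == "otsu":
            from skimage.filters import threshold_otsu

            hi = float(threshold_otsu(nz))
            lo = self.low_ratio * hi
        else:
            lo = float(np.percentile(nz, self.low_pct))
            hi = float(np.percentile(nz, self.high_pct))
        if self.t_low is not None:
            lo = float(self.t_low)
        if self.t_high is not None:
            hi = float(self.t_high)
        return min(lo, hi), hi


def hessian_eigen_2d(image: np.ndarray, sigma_px: float = 1.0):
    """Eigenvalues of the Gaussian-scale Hessian of a 2D image.

    Returns ``(lam1, lam2)`` ordered by absolute value (|lam1| <= |lam2|),
    computed with reflective boundary handling. For a bright ridge the
    large-magnitude eigenvalue is negative across the tube.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 5:
        raise ValueError("expected a 2D image of at least 5x5 pixels")
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite input")
    # remove the DC offset: derivatives are unaffected analytically, and the
    # truncated derivative kernels then return exact zeros on constant input
    image = image - image.mean()
    opts = {"mode": "reflect", "sigma": sigma_px}
    hyy = ndi.gaussian_filter(image, order=(2, 0), **opts)
    hxx = ndi.gaussian_filter(image, order=(0, 2), **opts)
    hxy = ndi.gaussian_filter(image, order=(1, 1), **opts)
    mean = 0.5 * (hxx + hyy)
    disc = np.sqrt(0.25 * (hxx - hyy) ** 2 + hxy ** 2)
    e_lo, e_hi = mean - disc, mean + disc
    swap = np.abs(e_lo) > np.abs(e_hi)
    lam1 = np.where(swap, e_hi, e_lo)
    lam2 = np.where(swap, e_lo, e_hi)
    return lam1, lam2


def frangi_2d(image: np.ndarray, params: VesselnessParams | None = None) -> np.ndarray:
    """Single-scale 2D vesselness response in [0, 1].

    v = exp(-R_B²/2β²) · (1 − exp(-S²/2c²)) with R_B = λ1/λ2 (blobness) and
    S = sqrt(λ1² + λ2²) (structureness), set to 0 where λ2 has the wrong
    sign for the chosen polarity (λ2 > 0 for bright tubes).
    """
    params = params or VesselnessParams()
    lam1, lam2 = hessian_eigen_2d(image, params.sigma_px)
    s2 = lam1 ** 2 + lam2 ** 2
    if params.c == "auto":
        smax = np.sqrt(s2.max())
        c = 0.5 * smax if smax > 0 else None
    else:
        c = float(params.c)
    if c is None or c == 0:
        return np.zeros_like(lam1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(lam2 != 0, (lam1 / np.where(lam2 == 0, 1, lam2)) ** 2, 0.0)
    v = np.exp(-rb2 / (2 * params.beta ** 2)) * (1.0 - np.exp(-s2 / (2 * c * c)))
    wrong_sign = (lam2 > 0) if params.bright else (lam2 < 0)
    v[wrong_sign | (lam2 == 0)] = 0.0
    return v


def frangi_stack(grid: VoxelGrid, params: VesselnessParams | None = None) -> VoxelGrid:
    """Apply the 2D vesselness filter to every z-slice of a stack."""
    if grid.shape[0] < 1:
        raise ValueError("stack must contain at least one slice")
    out = np.empty(grid.shape, dtype=float)
    for z in range(grid.shape[0]):
        out[z] = frangi_2d(grid.values[z], params)
    return grid.like(out)


def hysteresis_threshold(grid: VoxelGrid, hp: HysteresisParams | None = None) -> VoxelGrid:
    """Dual-threshold segmentation of a response volume.

    Output = union of connected components of {v >= t_low} containing at
    least one voxel with v >= t_high.
    """
    hp = hp or HysteresisParams()
    values = grid.values
    t_low, t_high = hp.resolve(values)
    low = values >= t_low
    if hp.connectivity == "3d":
        structure = np.ones((3, 3, 3), dtype=bool)
    else:
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1] = True
    labels, n = ndi.label(low, structure=structure)
    if n == 0:
        return grid.like(np.zeros_like(low))
    seeds = np.unique(labels[values >= t_high])
    seeds = seeds[seeds > 0]
    mask = np.isin(labels, seeds)
    return grid.like(mask)
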