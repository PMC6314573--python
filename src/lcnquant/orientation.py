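"""In-plane orientation descriptors from the 2D Fourier modulus.

After vesselness filtering, the modulus of the 2D FFT summarizes the
angular distribution of canalicular orientations: an isotropic network
yields a circular spectrum, a single dominant orientation yields two
antipodal lobes (one folded peak), and two orthogonal orientation families
of unequal weight yield the "butterfly" pattern — lobes plus a sharper
streak at ~90° to them.

Angles are those of the spatial-frequency vector, i.e. the *normal* to the
image structures, folded to [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .grid import VoxelGrid


@dataclass
class AngularSpectrum:
    angles_deg: np.ndarray          # bin centers in [0, 180)
    power: np.ndarray               # normalized, sums to 1
    anisotropy: float               # 1 - circular variance of folded angles, in [0, 1]
    peak_angles_deg: list[float] = field(default_factory=list)
    peak_heights: list[float] = field(default_factory=list)
    label: str | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"angle_deg": self.angles_deg, "power": self.power})


def fft_power(image: np.ndarray) -> np.ndarray:
    """Centered modulus of the 2D FFT of a mean-removed image."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D field")
    return np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean())))


def stack_fft_power(grid: VoxelGrid, mode: str = "slice_mean") -> np.ndarray:
    """Fourier modulus of a stack: per-slice transforms averaged
    (``slice_mean``) or one transform of the z-projection (``projection``)."""
    if mode == "projection":
        return fft_power(grid.values.sum(axis=0))
    if mode != "slice_mean":
        raise ValueError("mode must be 'slice_mean' or 'projection'")
    acc = np.zeros(grid.shape[1:], dtype=float)
    for z in range(grid.shape[0]):
        acc += fft_power(grid.values[z])
    return acc / grid.shape[0]


def _frequency_coords(shape: tuple[int, int]):
    """Normalized frequency grids (Nyquist = 1 per axis) for a centered FFT."""
    ny, nx = shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny)) * 2.0
    fx = np.fft.fftshift(np.fft.fftfreq(nx)) * 2.0
    return np.meshgrid(fy, fx, indexing="ij")


def angular_power(power: np.ndarray, n_bins: int = 36,
                  radial_band: tuple[float, float] = (0.1, 0.8)) -> AngularSpectrum:
    """Integrate spectral power per angular bin within a radial band.

    The band (fractions of Nyquist) excludes the DC region and the
    PSF-dominated high-frequency rim. Angles are folded mod 180°. The
    anisotropy index is the resultant length of the folded (doubled-angle)
    distribution: 0 for a flat spectrum, 1 for a single orientation.
    """
    if n_bins < 8:
        raise ValueError("need at least 8 angular bins")
    power = np.asarray(power, dtype=float)
    fy, fx = _frequency_coords(power.shape)
    r = np.hypot(fy, fx)
    lo, hi = radial_band
    band = (r >= lo) & (r <= hi) & (r > 0)
    if not band.any():
        raise ValueError("empty radial band")
    theta = np.mod(np.arctan2(fy[band], fx[band]), np.pi)  # fold antipodal pairs
    bins = np.clip((theta / np.pi * n_bins).astype(int), 0, n_bins - 1)
    hist = np.bincount(bins, weights=power[band], minlength=n_bins)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    angles = (np.arange(n_bins) + 0.5) * 180.0 / n_bins

    two_theta = np.deg2rad(2.0 * angles)
    resultant = np.abs(np.sum(hist * np.exp(1j * two_theta)))
    anisotropy = float(resultant)

    smooth = ndi.gaussian_filter1d(hist, sigma=max(1.0, n_bins / 36.0), mode="wrap")
    peaks, heights = [], []
    for i in range(n_bins):
        left, right = smooth[(i - 1) % n_bins], smooth[(i + 1) % n_bins]
        if smooth[i] > left and smooth[i] >= right and smooth[i] > 1.05 / n_bins:
            peaks.append(float(angles[i]))
            heights.append(float(smooth[i]))
    order = np.argsort(heights)[::-1]
    peaks = [peaks[i] for i in order]
    heights = [heights[i] for i in order]
    return AngularSpectrum(angles, hist, anisotropy, peaks, heights)


def folded_angle_distance(a_deg: float, b_deg: float) -> float:
    """Distance between orientations folded mod 180°, in [0, 90]."""
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


@dataclass
class MorphologyThresholds:
    """Operational surrogates for the qualitative spectrum reading."""

    isotropic_below: float = 0.1     # anisotropy index
    secondary_ratio: float = 0.3     # secondary/primary peak height
    ortho_tol_deg: float = 15.0      # butterfly: secondary at 90° ± tol


def classify_morphology(spectrum: AngularSpectrum,
                        thresholds: MorphologyThresholds | None = None) -> str:
    """Label a spectrum isotropic, bimodal or butterfly.

    Butterfly requires a secondary folded peak at 90° ± tolerance from the
    primary with relative height above the secondary threshold; below the
    low anisotropy threshold the spectrum is isotropic; otherwise one
    dominant folded peak pair reads as bimodal. Ambiguity resolves
    butterfly > bimodal > isotropic.
    """
    thr = thresholds or MorphologyThresholds()
    if spectrum.peak_angles_deg and spectrum.anisotropy >= thr.isotropic_below:
        primary, p_h = spectrum.peak_angles_deg[0], spectrum.peak_heights[0]
        for angle, h in zip(spectrum.peak_angles_deg[1:], spectrum.peak_heights[1:]):
            if (
                folded_angle_distance(angle, primary) >= 90.0 - thr.ortho_tol_deg
                and h >= thr.secondary_ratio * p_h
            ):
                spectrum.label = "butterfly"
                return "butterfly"
    if spectrum.anisotropy < thr.isotropic_below:
        spectrum.label = "isotropic"
        return "isotropic"
    spectrum.label = "bimodal"
    return "bimodal"


def orientation_descriptor(grid: VoxelGrid, n_bins: int = 36,
                           radial_band: tuple[float, float] = (0.1, 0.8),
                           mode: str = "slice_mean",
                           thresholds: MorphologyThresholds | None = None
                           ) -> AngularSpectrum:
    """Full descriptor for a (vesselness-filtered) stack: FFT modulus →
    angular spectrum → morphology label."""
    power = stack_fft_power(grid, mode=mode)
    spectrum = angular_power(power, n_bins=n_bins, radial_band=radial_band)
    classify_morphology(spectrum, thresholds)
    return spectrum
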