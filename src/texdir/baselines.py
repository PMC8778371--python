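"""Spectral and gradient baselines for tile directionality.

Two classical estimators serve as independent comparison detectors and
as oracles for the synthetic generator's labels:

* ``fourier_direction`` — dominant orientation from the windowed 2-D
  power spectrum: off-DC spectral energy of a directional texture
  concentrates along a line through the origin; its doubled-angle
  power-weighted circular mean gives the orientation.
* ``lgo_direction`` — local gradient orientation: per-pixel Sobel
  gradient angles, weighted by gradient magnitude, accumulated into an
  angular histogram over [0, 180).

Both report angles counter-clockwise from vertical on the displayed
image, matching the synthetic generator's label convention, and reject
structureless tiles (no off-DC energy / no gradient mass).

These are simplified reimplementations of widely used plugin methods,
not bit-compatible with any particular distribution of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mapper import DirectionEstimate


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "fourier"  # 'fourier' | 'lgo'
    bin_width_deg: float = 1.0
    fft_pad: int = 2          # spectrum zero-padding factor
    min_radius: float = 1.0   # cycles/tile below which spectrum is excluded
    min_confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("fourier", "lgo"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if 180.0 % self.bin_width_deg != 0:
            raise ValueError("bin width must divide 180")


def _circular_mean_180(angles_deg: np.ndarray, weights: np.ndarray) -> float:
    """Power-weighted mean direction on the 180-degree circle (doubled angles)."""
    theta2 = np.radians(2.0 * angles_deg)
    c = float((weights * np.cos(theta2)).sum())
    s = float((weights * np.sin(theta2)).sum())
    return (np.degrees(np.arctan2(s, c)) / 2.0) % 180.0


def fourier_direction(tile: np.ndarray,
                      config: BaselineConfig = BaselineConfig("fourier")) -> DirectionEstimate:
    """Dominant orientation of a square tile from its windowed power spectrum.

    The tile is mean-subtracted, Hann-windowed and zero-padded before the
    FFT; spectral samples below ``min_radius`` cycles/tile (DC and the
    window's main lobe) are excluded. The returned angle is the image-domain
    orientation; confidence is the peak fraction of a 1-degree angular
    power histogram. A tile with no off-DC energy is rejected.
    """
    tile = np.asarray(tile, dtype=np.float64)
    if tile.ndim != 2 or tile.shape[0] != tile.shape[1]:
        raise ValueError(f"fourier_direction expects a square tile, got {tile.shape}")
    n = tile.shape[0]
    if n < 16:
        raise ValueError(f"tile side must be >= 16, got {n}")
    win = np.outer(np.hanning(n), np.hanning(n))
    size = n * config.fft_pad
    power = np.abs(np.fft.fft2((tile - tile.mean()) * win, s=(size, size))) ** 2
    freq = np.fft.fftfreq(size)
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    radius = np.hypot(fx, fy) * n  # cycles per tile side
    power = np.where(radius >= config.min_radius, power, 0.0)
    total = power.sum()
    if total <= 0:
        return DirectionEstimate(0.0, 0.0, False)
    # spectral angle -> image orientation measured CCW-from-vertical on screen
    angles = (-np.degrees(np.arctan2(fy, fx))) % 180.0
    nbins = int(round(180.0 / config.bin_width_deg))
    bins = np.minimum((angles / config.bin_width_deg).astype(int), nbins - 1)
    hist = np.bincount(bins.ravel(), weights=power.ravel(), minlength=nbins)
    confidence = float(hist.max() / total)
    angle = _circular_mean_180(angles.ravel(), power.ravel())
    return DirectionEstimate(angle, confidence, confidence > config.min_confidence)


def lgo_direction(tile: np.ndarray,
                  config: BaselineConfig = BaselineConfig("lgo")) -> DirectionEstimate:
    """Local-gradient-orientation estimate of a tile's dominant direction.

    Sobel gradients; each pixel votes for the structure orientation
    (perpendicular to its gradient, which on the from-vertical scale equals
    the negated gradient angle) with weight equal to the squared gradient
    magnitude; votes accumulate into 1-degree bins over [0, 180). The
    returned angle refines the peak bin by a doubled-angle circular mean;
    confidence is the peak bin's mass fraction. Zero gradient mass rejects.
    """
    tile = np.asarray(tile, dtype=np.float64)
    if tile.ndim != 2 or min(tile.shape) < 3:
        raise ValueError(f"lgo_direction expects a 2-D tile of side >= 3, got {tile.shape}")
    gy = ndimage.sobel(tile, axis=0, mode="mirror")
    gx = ndimage.sobel(tile, axis=1, mode="mirror")
    weight = (gx ** 2 + gy ** 2).ravel()
    total = weight.sum()
    if total <= 0:
        return DirectionEstimate(0.0, 0.0, False)
    angles = (-np.degrees(np.arctan2(gy, gx))) % 180.0
    angles = angles.ravel()
    nbins = int(round(180.0 / config.bin_width_deg))
    bins = np.minimum((angles / config.bin_width_deg).astype(int), nbins - 1)
    hist = np.bincount(bins, weights=weight, minlength=nbins)
    peak = int(hist.argmax())
    confidence = float(hist[peak] / total)
    peak_deg = (peak + 0.5) * config.bin_width_deg
    # refine within +/- 5 bins of the peak on the periodic axis
    delta = np.abs((angles - peak_deg + 90.0) % 180.0 - 90.0)
    sel = delta <= 5.0 * config.bin_width_deg
    angle = _circular_mean_180(angles[sel], weight[sel]) if sel.any() else float(peak_deg)
    return DirectionEstimate(angle, confidence, confidence > config.min_confidence)


def direction_from_config(config: BaselineConfig):
    """Detector callable (tile -> DirectionEstimate) for a BaselineConfig."""
    fn = fourier_direction if config.method == "fourier" else lgo_direction
    return lambda tile: fn(tile, config)
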