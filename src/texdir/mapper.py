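"""Tile-based directionality mapping of arbitrary grayscale images.

A trained orientation classifier is slid over an image on a regular
tile grid; each complete tile gets an argmax direction with a
confidence (the top class probability). Estimates whose confidence
falls below a probability threshold tau (default 0.011, about twice
the uniform probability 1/180) are rejected as having no meaningful
direction. Accepted estimates feed an overlay rendering and a
one-degree polar histogram with a doubled-angle circular mean
("dominant direction") and circular spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Model
from .synthesis import BACKGROUND, FOREGROUND
from .training import prepare_inputs

DEFAULT_THRESHOLD = 0.011  # ~ 2/180


@dataclass(frozen=True)
class TileGrid:
    """Regular grid of square tiles; spacing < tile_size means overlap."""

    tile_size: int = 64
    spacing: int = 64
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.tile_size < 1 or self.spacing < 1:
            raise ValueError("tile_size and spacing must be >= 1")

    def origins(self, height: int, width: int) -> list[tuple[int, int]]:
        """Top-left corners of every complete tile; partial border tiles are skipped."""
        oy, ox = self.offset
        ys = range(oy, height - self.tile_size + 1, self.spacing)
        xs = range(ox, width - self.tile_size + 1, self.spacing)
        return [(y, x) for y in ys for x in xs]


@dataclass
class DirectionEstimate:
    """Per-tile direction: argmax angle, confidence, accept/reject vs tau."""

    angle_deg: float
    confidence: float
    accepted: bool
    x: int = 0  # tile top-left column
    y: int = 0  # tile top-left row
    probabilities: np.ndarray | None = None


def normalize_for_inference(image: np.ndarray) -> np.ndarray:
    """Map any 8/16-bit grayscale image into the training intensity regime.

    Intensities are linearly rescaled from the image's [min, max] onto
    [16384, 49151] and then divided by 65,535 — the same affine family the
    synthetic corpus lives in. A constant image maps to the background
    level. Returns float32, shape unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            "expected a single-channel image; select a channel explicitly first")
    x = image.astype(np.float32)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        mapped = np.full_like(x, float(BACKGROUND))
    else:
        mapped = (x - lo) / (hi - lo) * (FOREGROUND - BACKGROUND) + BACKGROUND
    return mapped / 65535.0


def estimate_from_probs(probs: np.ndarray, tau: float = DEFAULT_THRESHOLD,
                        x: int = 0, y: int = 0,
                        keep_probs: bool = False) -> DirectionEstimate:
    """Turn one 180-class probability vector into a DirectionEstimate.

    Ties at the maximum resolve to the lowest angle index (argmax order).
    """
    probs = np.asarray(probs)
    angle = int(probs.argmax())
    conf = float(probs[angle])
    return DirectionEstimate(
        angle_deg=angle, confidence=conf, accepted=conf >= tau,
        x=x, y=y, probabilities=probs.copy() if keep_probs else None)


def predict_tile(model: Model, tile: np.ndarray,
                 tau: float = DEFAULT_THRESHOLD) -> DirectionEstimate:
    """Predict the direction of one raw 16-bit-regime tile (no renormalization)."""
    probs = model.predict_proba(prepare_inputs(tile[None]))[0]
    return estimate_from_probs(probs, tau)


def map_image(
    image: np.ndarray,
    model: Model,
    grid: TileGrid = TileGrid(),
    tau: float = DEFAULT_THRESHOLD,
    batch_size: int = 256,
) -> list[DirectionEstimate]:
    """Predict a direction for every complete grid tile of a grayscale image.

    The image is intensity-normalized once (see ``normalize_for_inference``),
    then each tile goes through the model in batches. Returns one estimate
    per tile in row-major grid order.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("map_image expects a single-channel image")
    h, w = image.shape
    if h < grid.tile_size or w < grid.tile_size:
        raise ValueError(
            f"image {h}x{w} is smaller than one {grid.tile_size}x{grid.tile_size} tile")
    norm = normalize_for_inference(image)
    origins = grid.origins(h, w)
    stack = np.stack([norm[y:y + grid.tile_size, x:x + grid.tile_size]
                      for (y, x) in origins])[..., None]
    probs = model.predict_proba(stack, batch_size=batch_size)
    return [estimate_from_probs(probs[i], tau, x=x0, y=y0)
            for i, (y0, x0) in enumerate(origins)]


def render_overlay(image: np.ndarray, estimates: list[DirectionEstimate],
                   grid: TileGrid = TileGrid(), line_fraction: float = 0.8):
    """Draw a centered direction segment on each accepted tile (red lines).

    Angles are counter-clockwise from vertical on the displayed image.
    Returns a PIL RGB image.
    """
    from PIL import Image, ImageDraw

    x = np.asarray(image, dtype=np.float64)
    lo, hi = x.min(), x.max()
    gray = np.zeros_like(x, dtype=np.uint8) if hi - lo < 1e-12 else \
        np.rint((x - lo) / (hi - lo) * 255).astype(np.uint8)
    img = Image.fromarray(gray).convert("RGB")
    draw = ImageDraw.Draw(img)
    half = grid.tile_size * line_fraction / 2.0
    for est in estimates:
        if not est.accepted:
            continue
        cy = est.y + grid.tile_size / 2.0
        cx = est.x + grid.tile_size / 2.0
        theta = math.radians(est.angle_deg)
        # angle 0 = vertical; CCW on screen with the row axis pointing down
        dx, dy = -half * math.sin(theta), -half * math.cos(theta)
        draw.line([(cx - dx, cy - dy), (cx + dx, cy + dy)], fill=(255, 0, 0), width=1)
    return img


@dataclass
class PolarHistogram:
    """One-degree direction histogram over accepted estimates.

    ``dominant_deg`` is the doubled-angle circular mean (angles doubled,
    vector-averaged, halved) and ``spread_deg`` the circular standard
    deviation on the doubled scale, halved back. ``reliable`` is False when
    the histogram is empty or the mean resultant length is negligible.
    """

    bins: np.ndarray  # (180,)
    dominant_deg: float | None
    spread_deg: float | None
    resultant_length: float
    n_accepted: int
    weighted: bool = False
    reliable: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_deg": np.arange(180), "count": self.bins})


def polar_histogram(estimates: list[DirectionEstimate],
                    weighted: bool = False,
                    min_resultant: float = 0.05) -> PolarHistogram:
    """Build the polar histogram of accepted estimates.

    ``weighted=True`` weights each estimate by its confidence instead of
    counting it once. An empty or near-uniform direction distribution is
    flagged unreliable and carries no dominant direction.
    """
    accepted = [e for e in estimates if e.accepted]
    bins = np.zeros(180, dtype=np.float64)
    for e in accepted:
        w = e.confidence if weighted else 1.0
        bins[int(e.angle_deg) % 180] += w
    total = bins.sum()
    if total <= 0:
        return PolarHistogram(bins, None, None, 0.0, len(accepted), weighted, False)
    theta2 = np.radians(2.0 * np.arange(180))
    c = float((bins * np.cos(theta2)).sum() / total)
    s = float((bins * np.sin(theta2)).sum() / total)
    r = math.hypot(c, s)
    dominant = (math.degrees(math.atan2(s, c)) / 2.0) % 180.0
    spread = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(max(min(r, 1.0), 1e-300))))) / 2.0
    reliable = r >= min_resultant
    return PolarHistogram(bins, dominant if reliable else None,
                          spread if reliable else None, r,
                          len(accepted), weighted, reliable)


def estimates_to_frame(estimates: list[DirectionEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"x": e.x, "y": e.y, "angle_deg": e.angle_deg,
         "confidence": e.confidence, "accepted": e.accepted}
        for e in estimates])


def save_polar_plot(hist: PolarHistogram, path: str | Path) -> None:
    """Render the histogram as a polar bar plot (mirrored to the full circle)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.radians(np.concatenate([np.arange(180), np.arange(180) + 180]))
    counts = np.concatenate([hist.bins, hist.bins])
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(theta, counts, width=np.radians(1.0), color="tab:red")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    if hist.dominant_deg is not None:
        ax.set_title(f"dominant {hist.dominant_deg:.1f} deg, "
                     f"spread {hist.spread_deg:.1f} deg", fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
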