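"""Synthetic directional-texture corpus generation.

The corpus is built from periodic vertical-bar gratings: a 16-bit
1000x1000 image of evenly spaced vertical bars (background 16,384,
foreground 49,151) is rotated to an integer angle in [0, 179], the
central 500x500 region is cropped, an optional perturbation (additive
Gaussian noise or mean blur) is applied, and the result is cut into 49
non-overlapping 64x64 tiles that all inherit the rotation angle as
their direction label.

Angles are measured counter-clockwise from the vertical bar direction
as the image is displayed (origin in the upper-left corner), with 180
degree periodicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

BACKGROUND = 16384
FOREGROUND = 49151

#: the nine sanctioned thickness/period combinations of the canonical corpus
CANONICAL_PATTERNS: tuple[tuple[int, int], ...] = (
    (2, 8), (3, 6), (4, 8), (6, 12), (8, 16),
    (16, 32), (20, 40), (24, 48), (32, 64),
)
CANONICAL_NOISE_STDS: tuple[float, ...] = (2000.0, 4000.0, 6000.0, 8000.0)
CANONICAL_BLUR_KERNELS: tuple[int, ...] = (3, 5, 7, 9)

TILE_SIZE = 64
TILE_GRID = 7  # 7x7 = 49 tiles per 500x500 texture
TEXTURE_SIZE = 500
BASE_SIZE = 1000


class PatternError(ValueError):
    """A bar pattern violates its constraints."""


@dataclass(frozen=True)
class BarPattern:
    """Unrotated bar grating: bar ``thickness`` and rising-edge ``period``, in pixels."""

    thickness: int
    period: int

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise PatternError(f"thickness must be >= 1, got {self.thickness}")
        if self.period <= self.thickness:
            raise PatternError(
                f"period ({self.period}) must be larger than thickness ({self.thickness})"
            )


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation applied to a whole 500x500 texture before tiling.

    ``gaussian_noise`` adds zero-mean i.i.d. noise of the given standard
    deviation (16-bit intensity units), then clips to [0, 65535] and rounds.
    ``mean_blur`` applies a normalized box filter of odd ``kernel_size``.
    """

    kind: str = "none"
    noise_std: float | None = None
    kernel_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "none":
            pass
        elif self.kind == "gaussian_noise":
            if self.noise_std is None or self.noise_std <= 0:
                raise ValueError("gaussian_noise requires a positive noise_std")
        elif self.kind == "mean_blur":
            k = self.kernel_size
            if k is None or k < 1 or k % 2 == 0:
                raise ValueError("mean_blur requires an odd kernel_size >= 1")
        else:
            raise ValueError(f"unknown perturbation kind: {self.kind!r}")

    @property
    def magnitude(self) -> float:
        if self.kind == "gaussian_noise":
            return float(self.noise_std)
        if self.kind == "mean_blur":
            return float(self.kernel_size)
        return 0.0

    def describe(self) -> str:
        if self.kind == "none":
            return "none"
        return f"{self.kind}:{self.magnitude:g}"


@dataclass
class SyntheticTexture:
    """A 500x500 16-bit rotated (and possibly perturbed) bar texture."""

    pixels: np.ndarray
    angle_deg: int
    pattern: BarPattern
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)


@dataclass
class TextureTile:
    """A 64x64 patch carrying its parent texture's direction label."""

    pixels: np.ndarray
    label_deg: int
    pattern: BarPattern
    perturbation: PerturbationSpec
    tile_row: int
    tile_col: int


def make_bar_image(pattern: BarPattern, size: int = BASE_SIZE) -> np.ndarray:
    """Render a ``size`` x ``size`` 16-bit image of evenly spaced vertical bars.

    Column ``c`` is foreground (49,151) when ``c % period < thickness``,
    background (16,384) otherwise; every row is identical.
    """
    if size < pattern.period:
        raise PatternError(f"image size {size} smaller than period {pattern.period}")
    cols = np.arange(size) % pattern.period
    row = np.where(cols < pattern.thickness, FOREGROUND, BACKGROUND).astype(np.uint16)
    return np.tile(row, (size, 1))


def rotate_and_crop(image: np.ndarray, angle_deg: int) -> np.ndarray:
    """Rotate a 1000x1000 image counter-clockwise by ``angle_deg`` and crop
    the central 500x500 region.

    Bilinear interpolation; the crop stays inside the rotated support for
    any angle (1000 / sqrt(2) > 500), so no blank pixels appear.
    """
    if image.shape != (BASE_SIZE, BASE_SIZE):
        raise ValueError(f"expected a {BASE_SIZE}x{BASE_SIZE} image, got {image.shape}")
    if not 0 <= int(angle_deg) <= 179:
        raise ValueError(f"angle must be an integer in [0, 179], got {angle_deg}")
    if angle_deg == 0:
        rot = image.astype(np.float32)
    else:
        rot = ndimage.rotate(
            image.astype(np.float32), float(angle_deg),
            reshape=False, order=1, mode="constant", cval=float(BACKGROUND),
        )
    lo = (BASE_SIZE - TEXTURE_SIZE) // 2
    crop = rot[lo:lo + TEXTURE_SIZE, lo:lo + TEXTURE_SIZE]
    return np.clip(np.rint(crop), 0, 65535).astype(np.uint16)


def apply_perturbation(
    image: np.ndarray,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply a perturbation to a 16-bit image.

    Noise requires ``rng``; blur uses reflect-101 (mirror) border handling,
    which only matters outside the tiled interior.
    """
    if spec.kind == "none":
        return image.copy()
    if spec.kind == "gaussian_noise":
        if rng is None:
            raise ValueError("gaussian_noise perturbation requires an rng")
        noisy = image.astype(np.float64) + rng.normal(0.0, spec.noise_std, image.shape)
        return np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    if spec.kind == "mean_blur":
        blurred = ndimage.uniform_filter(
            image.astype(np.float64), size=spec.kernel_size, mode="mirror"
        )
        return np.clip(np.rint(blurred), 0, 65535).astype(np.uint16)
    raise ValueError(f"unknown perturbation kind: {spec.kind!r}")


def tile_origin(row: int, col: int) -> tuple[int, int]:
    """Top-left pixel of tile (row, col) in the centered 7x7 grid."""
    margin = (TEXTURE_SIZE - TILE_GRID * TILE_SIZE) // 2  # 26 px
    return margin + row * TILE_SIZE, margin + col * TILE_SIZE


def tile_texture(texture: SyntheticTexture) -> list[TextureTile]:
    """Cut a 500x500 texture into 49 non-overlapping 64x64 tiles.

    The 7x7 grid is centered (26 px margin on each side); every tile
    inherits the parent's angle label and provenance.
    """
    if texture.pixels.shape != (TEXTURE_SIZE, TEXTURE_SIZE):
        raise ValueError(
            f"expected a {TEXTURE_SIZE}x{TEXTURE_SIZE} texture, got {texture.pixels.shape}"
        )
    tiles = []
    for r in range(TILE_GRID):
        for c in range(TILE_GRID):
            y0, x0 = tile_origin(r, c)
            tiles.append(TextureTile(
                pixels=texture.pixels[y0:y0 + TILE_SIZE, x0:x0 + TILE_SIZE].copy(),
                label_deg=texture.angle_deg,
                pattern=texture.pattern,
                perturbation=texture.perturbation,
                tile_row=r,
                tile_col=c,
            ))
    return tiles


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus configuration. The defaults reproduce the canonical corpus:
    9 patterns x 180 angles x (1 + 4 noise + 4 blur) perturbation variants
    x 49 tiles = 714,420 tiles, split 1/2 : 1/4 : 1/4.
    """

    patterns: tuple[tuple[int, int], ...] = CANONICAL_PATTERNS
    angles: tuple[int, ...] = tuple(range(180))
    noise_stds: tuple[float, ...] = CANONICAL_NOISE_STDS
    blur_kernels: tuple[int, ...] = CANONICAL_BLUR_KERNELS
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split_fractions}")
        for t, p in self.patterns:
            BarPattern(t, p)  # validate
        for a in self.angles:
            if not 0 <= int(a) <= 179:
                raise ValueError(f"angle out of range [0, 179]: {a}")

    def perturbations(self) -> list[PerturbationSpec]:
        specs = [PerturbationSpec("none")]
        specs += [PerturbationSpec("gaussian_noise", noise_std=s) for s in self.noise_stds]
        specs += [PerturbationSpec("mean_blur", kernel_size=k) for k in self.blur_kernels]
        return specs


def corpus_counts(config: GeneratorConfig) -> dict[str, int]:
    """Exact corpus size arithmetic for a configuration, without generating pixels."""
    n_base = len(config.patterns) * len(config.angles)
    n_variants = 1 + len(config.noise_stds) + len(config.blur_kernels)
    n_textures = n_base * n_variants
    n_tiles = n_textures * TILE_GRID * TILE_GRID
    n_val = int(n_tiles * config.split_fractions[1])
    n_test = int(n_tiles * config.split_fractions[2])
    n_train = n_tiles - n_val - n_test
    return {
        "base_textures": n_base,
        "textures": n_textures,
        "tiles": n_tiles,
        "train": n_train,
        "validation": n_val,
        "test": n_test,
    }


@dataclass
class TileSet:
    """One split: tile pixels (N, 64, 64) uint16 (or None when not
    materialized), integer labels, and per-tile metadata."""

    pixels: np.ndarray | None
    labels: np.ndarray
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class DatasetSplits:
    train: TileSet
    validation: TileSet
    test: TileSet
    seed: int

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.concat(
            [self.train.manifest, self.validation.manifest, self.test.manifest],
            ignore_index=True,
        )


def iter_textures(
    config: GeneratorConfig, rng: np.random.Generator
) -> Iterator[SyntheticTexture]:
    """Yield every texture of the corpus in a fixed deterministic order:
    pattern-major, then angle, then perturbation variant."""
    perturbations = config.perturbations()
    for (t, p) in config.patterns:
        pattern = BarPattern(t, p)
        base = make_bar_image(pattern)
        for angle in config.angles:
            clean = rotate_and_crop(base, angle)
            for spec in perturbations:
                pixels = apply_perturbation(clean, spec, rng=rng)
                yield SyntheticTexture(pixels, int(angle), pattern, spec)


def _split_sizes(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    # validation and test sizes round down; train takes the remainder
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    return n - n_val - n_test, n_val, n_test


def build_dataset(
    config: GeneratorConfig,
    seed: int,
    materialize: bool = True,
) -> DatasetSplits:
    """Generate the corpus and shuffle it into train/validation/test splits.

    Deterministic given ``seed`` (one generator drives both the noise and
    the shuffle, consumed in a fixed order). With ``materialize=False``
    only the manifest is built — counts, labels and split assignment are
    exact, but no pixels are stored; useful for full-corpus bookkeeping.
    """
    rng = np.random.default_rng(seed)
    perturbations = config.perturbations()
    records = []
    pixel_blocks: list[np.ndarray] = []
    n_tiles_per_texture = TILE_GRID * TILE_GRID

    if materialize:
        for texture in iter_textures(config, rng):
            for tile in tile_texture(texture):
                records.append(_tile_record(tile))
                pixel_blocks.append(tile.pixels)
    else:
        for (t, p) in config.patterns:
            for angle in config.angles:
                for spec in perturbations:
                    for idx in range(n_tiles_per_texture):
                        records.append({
                            "label_deg": int(angle),
                            "thickness": t,
                            "period": p,
                            "perturbation": spec.kind,
                            "magnitude": spec.magnitude,
                            "tile_row": idx // TILE_GRID,
                            "tile_col": idx % TILE_GRID,
                        })

    manifest = pd.DataFrame.from_records(records)
    n = len(manifest)
    order = rng.permutation(n)
    n_train, n_val, n_test = _split_sizes(n, config.split_fractions)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_val]] = "validation"
    split[order[n_train + n_val:]] = "test"
    manifest["split"] = split

    pixels = np.stack(pixel_blocks) if materialize else None

    def subset(name: str) -> TileSet:
        mask = (manifest["split"] == name).to_numpy()
        sub = manifest[mask].reset_index(drop=True)
        return TileSet(
            pixels=pixels[mask] if pixels is not None else None,
            labels=sub["label_deg"].to_numpy(),
            manifest=sub,
        )

    return DatasetSplits(subset("train"), subset("validation"), subset("test"), seed)


def _tile_record(tile: TextureTile) -> dict:
    return {
        "label_deg": tile.label_deg,
        "thickness": tile.pattern.thickness,
        "period": tile.pattern.period,
        "perturbation": tile.perturbation.kind,
        "magnitude": tile.perturbation.magnitude,
        "tile_row": tile.tile_row,
        "tile_col": tile.tile_col,
    }


def write_corpus(splits: DatasetSplits, out_dir: str | Path, image_format: str = "tiff") -> Path:
    """Write tiles as 16-bit grayscale images plus a CSV manifest.

    ``image_format``: 'tiff', 'png', or 'npz' (single packed array archive,
    much faster for large corpora).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, ts in (("train", splits.train), ("validation", splits.validation),
                     ("test", splits.test)):
        if ts.pixels is None:
            raise ValueError("corpus was built with materialize=False; no pixels to write")
        sub = ts.manifest.copy()
        if image_format == "npz":
            np.savez_compressed(out / f"{name}.npz", pixels=ts.pixels, labels=ts.labels)
            sub["file"] = f"{name}.npz"
        else:
            tile_dir = out / name
            tile_dir.mkdir(exist_ok=True)
            for i in range(len(ts)):
                fname = f"{name}/tile_{i:06d}_a{ts.labels[i]:03d}.{'tif' if image_format == 'tiff' else 'png'}"
                _write_image(out / fname, ts.pixels[i], image_format)
                sub.loc[i, "file"] = fname
        frames.append(sub)
    manifest = pd.concat(frames, ignore_index=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "counts.json").write_text(json.dumps(
        {"train": len(splits.train), "validation": len(splits.validation),
         "test": len(splits.test), "seed": splits.seed}, indent=2))
    return out


def _write_image(path: Path, pixels: np.ndarray, image_format: str) -> None:
    if image_format == "tiff":
        import tifffile
        tifffile.imwrite(path, pixels)
    elif image_format == "png":
        from PIL import Image
        Image.fromarray(pixels, mode="I;16").save(path)
    else:
        raise ValueError(f"unknown image format {image_format!r}")
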