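"""Desk-scale study protocols.

The full corpus (714,420 tiles, 200 epochs, 84 network/activation
combinations, three replicates) is a cluster-scale computation. This
module packages a reduced version of the same protocol that runs on a
single CPU in minutes while preserving the study conditions: the same
generator, the same tile geometry, all 180 angle classes, the same
batch size and loss, and the same evaluation metric.

Reduced protocol defaults: one thick-bar pattern (8/16), all 180
rotation angles, no perturbation (8,820 tiles split 4,410/2,205/2,205),
SN1 with the ELU activation trained for 6 epochs with batch 32 and a
single replicate. Robustness is then probed by regenerating the test
split's parent textures with mean-blur perturbations and scoring the
identical tile positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architectures import build_architecture
from .evaluation import angular_error, rmse

from .nn import Model
from .synthesis import (
    BarPattern,
    GeneratorConfig,
    PerturbationSpec,
    SyntheticTexture,
    apply_perturbation,
    build_dataset,
    make_bar_image,
    rotate_and_crop,
    tile_texture,
    DatasetSplits,
)
from .training import prepare_inputs, train, TrainingRun

REDUCED_PATTERNS: tuple[tuple[int, int], ...] = ((8, 16),)
REDUCED_EPOCHS = 6


def reduced_corpus(seed: int, patterns=REDUCED_PATTERNS) -> DatasetSplits:
    """Unperturbed reduced corpus: given patterns x all 180 angles x 49 tiles."""
    config = GeneratorConfig(patterns=tuple(patterns), angles=tuple(range(180)),
                             noise_stds=(), blur_kernels=())
    return build_dataset(config, seed=seed)


def train_reduced(
    splits: DatasetSplits,
    seed: int,
    epochs: int = REDUCED_EPOCHS,
    arch_id: str = "SN1",
    activation: str = "ELU",
    verbose: bool = False,
) -> tuple[Model, TrainingRun]:
    """Train the reduced protocol's network; returns the model with
    best-validation weights and its training run."""
    _, model = build_architecture(arch_id, activation, seed=seed)
    runs = train(model, splits, batch_size=32, epochs=epochs, replicates=1,
                 seed=seed, architecture_id=arch_id, activation=activation,
                 verbose=verbose)
    return model, runs[0]


def clean_test_rmse(model: Model, splits: DatasetSplits, batch_size: int = 256) -> float:
    """Angular-error RMSE (degrees) of the model on the test split."""
    probs = model.predict_proba(prepare_inputs(splits.test.pixels), batch_size=batch_size)
    pred = probs.argmax(axis=1)
    return rmse(angular_error(splits.test.labels, pred))


def blurred_test_tiles(
    splits: DatasetSplits, kernel_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the test split's tiles from mean-blurred parent textures.

    Each test tile's provenance (pattern, angle, tile position) is replayed
    with a mean-blur perturbation of the given kernel applied to the whole
    500x500 texture before tiling, exactly as in corpus generation.
    Returns (tiles, labels) aligned with the test manifest order.
    """
    manifest = splits.test.manifest
    if (manifest["perturbation"] != "none").any():
        raise ValueError("blur sweep expects an unperturbed base corpus")
    spec = PerturbationSpec("mean_blur", kernel_size=kernel_size)
    tiles = np.empty((len(manifest), 64, 64), dtype=np.uint16)
    labels = manifest["label_deg"].to_numpy()
    for (t, p, angle), sub in manifest.groupby(["thickness", "period", "label_deg"]):
        pattern = BarPattern(int(t), int(p))
        texture = rotate_and_crop(make_bar_image(pattern), int(angle))
        blurred = apply_perturbation(texture, spec)
        tile_list = tile_texture(SyntheticTexture(blurred, int(angle), pattern, spec))
        by_pos = {(tl.tile_row, tl.tile_col): tl.pixels for tl in tile_list}
        for i, row in sub.iterrows():
            tiles[i] = by_pos[(row["tile_row"], row["tile_col"])]
    return tiles, labels


def blur_sweep(model: Model, splits: DatasetSplits,
               kernels=(3, 5, 7, 9), batch_size: int = 256) -> pd.DataFrame:
    """RMSE of the model on blurred variants of the test tiles, per kernel."""
    rows = [{"blur_kernel": 0,
             "rmse_deg": clean_test_rmse(model, splits, batch_size), "n_tiles": len(splits.test)}]
    for k in kernels:
        tiles, labels = blurred_test_tiles(splits, k)
        probs = model.predict_proba(prepare_inputs(tiles), batch_size=batch_size)
        err = angular_error(labels, probs.argmax(axis=1))
        rows.append({"blur_kernel": k, "rmse_deg": rmse(err), "n_tiles": len(labels)})
    return pd.DataFrame(rows)


@dataclass
class ReducedStudy:
    """Results of one reduced training/evaluation cycle."""

    run: TrainingRun
    model: Model
    splits: DatasetSplits
    clean_rmse_deg: float
    blur_table: pd.DataFrame


def run_reduced_study(seed: int, epochs: int = REDUCED_EPOCHS,
                      blur_kernels=(3, 5, 7, 9), verbose: bool = False) -> ReducedStudy:
    """End-to-end reduced study: generate, train SN1-ELU, evaluate clean and
    blurred test RMSE."""
    splits = reduced_corpus(seed)
    model, run = train_reduced(splits, seed=seed, epochs=epochs, verbose=verbose)
    clean = clean_test_rmse(model, splits)
    table = blur_sweep(model, splits, kernels=blur_kernels)
    return ReducedStudy(run, model, splits, clean, table)
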