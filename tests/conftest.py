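import numpy as np
import pytest

from texdir.experiments import run_reduced_study
from texdir.synthesis import (
    BarPattern,
    GeneratorConfig,
    build_dataset,
    make_bar_image,
    rotate_and_crop,
)

#: one seed drives every stochastic fixture in the suite
SUITE_SEED = 1


@pytest.fixture(scope="session")
def tiny_splits():
    """Small materialized corpus: one pattern, 10 angles, one noise and one
    blur level -> 10 x 3 x 49 = 1,470 tiles."""
    config = GeneratorConfig(
        patterns=((8, 16),),
        angles=tuple(range(0, 180, 18)),
        noise_stds=(4000.0,),
        blur_kernels=(5,),
    )
    return build_dataset(config, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def bar_texture_53():
    """Unperturbed 500x500 texture of 8/16 bars rotated to 53 degrees."""
    return rotate_and_crop(make_bar_image(BarPattern(8, 16)), 53)


@pytest.fixture(scope="session")
def reduced_study():
    """The desk-scale training study: SN1-ELU on the unperturbed 8/16 corpus
    (8,820 tiles, all 180 angles), plus the mean-blur robustness sweep.

    This is the expensive fixture of the suite (several minutes); every test
    that needs a trained network shares it.
    """
    return run_reduced_study(seed=SUITE_SEED)
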