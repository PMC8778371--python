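"""The twelve orientation-classification CNN architectures.

Four shallow networks (SN1–SN4: one unpadded convolution, global max
pool, dropout, softmax output over 180 one-degree direction classes)
and eight deep networks (DN1–DN8: three unpadded convolutions, the
first two followed by 2x2 max pooling, then global max pooling, a
90-unit dense layer and the 180-class softmax output).

Global max pooling makes every network accept any input at or above
its minimum size. For the deep networks that minimum is

    minImSize = (cf8 * mp6 + (cf5 - 1)) * mp3 + (cf2 - 1)

where cf_k is the convolution kernel size at layer k and mp_k the max
pool size at layer k; for the shallow networks it is simply the
convolution kernel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

N_CLASSES = 180

#: hidden-layer activations; 'SM' (softmax) is reserved for the output layer
ACTIVATIONS = ("ReLU", "ELU", "SELU", "Si", "SP", "SS", "TanH")

SHALLOW_IDS = ("SN1", "SN2", "SN3", "SN4")
DEEP_IDS = ("DN1", "DN2", "DN3", "DN4", "DN5", "DN6", "DN7", "DN8")
ARCHITECTURE_IDS = SHALLOW_IDS + DEEP_IDS


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # input | convolution | max_pool | global_max_pool | dropout | dense | output
    kernel_size: int | None = None
    filters: int | None = None
    pool_size: int | None = None
    rate: float | None = None
    units: int | None = None
    activation: str | None = None


def _shallow(kernel: int, filters: int) -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("input"),
        LayerSpec("convolution", kernel_size=kernel, filters=filters),
        LayerSpec("global_max_pool"),
        LayerSpec("dropout", rate=0.25),
        LayerSpec("output", units=N_CLASSES, activation="SM"),
    )


def _deep(first_kernel: int, first_filters: int, second_filters: int) -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("input"),
        LayerSpec("convolution", kernel_size=first_kernel, filters=first_filters),
        LayerSpec("max_pool", pool_size=2),
        LayerSpec("dropout", rate=0.25),
        LayerSpec("convolution", kernel_size=5, filters=second_filters),
        LayerSpec("max_pool", pool_size=2),
        LayerSpec("dropout", rate=0.25),
        LayerSpec("convolution", kernel_size=3, filters=90),
        LayerSpec("global_max_pool"),
        LayerSpec("dropout", rate=0.25),
        LayerSpec("dense", units=90),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("output", units=N_CLASSES, activation="SM"),
    )


_LAYOUTS: dict[str, tuple[LayerSpec, ...]] = {
    "SN1": _shallow(17, 180),
    "SN2": _shallow(17, 90),
    "SN3": _shallow(13, 180),
    "SN4": _shallow(13, 90),
    "DN1": _deep(17, 16, 16),
    "DN2": _deep(17, 16, 32),
    "DN3": _deep(17, 90, 16),
    "DN4": _deep(17, 90, 32),
    "DN5": _deep(7, 16, 16),
    "DN6": _deep(7, 16, 32),
    "DN7": _deep(7, 90, 16),
    "DN8": _deep(7, 90, 32),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """One of the twelve architectures with a chosen hidden activation."""

    id: str
    activation: str
    layers: tuple[LayerSpec, ...] = field(repr=False)

    @property
    def is_shallow(self) -> bool:
        return self.id in SHALLOW_IDS

    @property
    def parameter_count(self) -> int:
        return parameter_count(self)

    @property
    def min_input_size(self) -> int:
        return min_input_size(self)


def architecture_spec(arch_id: str, activation: str = "ELU") -> ArchitectureSpec:
    if arch_id not in _LAYOUTS:
        raise ValueError(f"unknown architecture id {arch_id!r}; choose from {ARCHITECTURE_IDS}")
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"activation must be one of {ACTIVATIONS} (softmax 'SM' is output-only), "
            f"got {activation!r}")
    # hidden activation applies to every convolution and the dense layer
    layers = tuple(
        LayerSpec(**{**vars(ls), "activation": activation})
        if ls.kind in ("convolution", "dense") else ls
        for ls in _LAYOUTS[arch_id]
    )
    return ArchitectureSpec(arch_id, activation, layers)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> nn.Model:
    """Instantiate a trainable model from an architecture spec."""
    layers: list[nn.Layer] = []
    seen_conv = False
    for ls in spec.layers:
        if ls.kind == "input":
            continue
        if ls.kind == "convolution":
            layers.append(nn.Conv2D(ls.kernel_size, ls.filters, ls.activation,
                                    is_input_layer=not seen_conv))
            seen_conv = True
        elif ls.kind == "max_pool":
            layers.append(nn.MaxPool2D(ls.pool_size))
        elif ls.kind == "global_max_pool":
            layers.append(nn.GlobalMaxPool())
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(ls.rate))
        elif ls.kind in ("dense", "output"):
            layers.append(nn.Dense(ls.units, ls.activation))
        else:
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    return nn.Model(layers, input_channels=1, seed=seed)


def build_architecture(arch_id: str, activation: str = "ELU",
                       seed: int = 0) -> tuple[ArchitectureSpec, nn.Model]:
    """Build one of the twelve architectures with the given hidden activation."""
    spec = architecture_spec(arch_id, activation)
    return spec, build_model(spec, seed=seed)


def parameter_count(spec: ArchitectureSpec) -> int:
    """Exact trainable parameter count (weights + biases), per-layer arithmetic."""
    total = 0
    channels = 1
    for ls in spec.layers:
        if ls.kind == "convolution":
            total += ls.kernel_size * ls.kernel_size * channels * ls.filters + ls.filters
            channels = ls.filters
        elif ls.kind in ("dense", "output"):
            total += channels * ls.units + ls.units
            channels = ls.units
    return total


def min_input_size(spec: ArchitectureSpec) -> int:
    """Smallest square input side that yields a valid prediction.

    Computed by walking the spatial layers backwards from a 1x1 map in
    front of global max pooling: a k-conv needs k-1 extra pixels, a p-pool
    multiplies by p. For the deep layouts this reproduces
    (cf8*mp6 + (cf5-1))*mp3 + (cf2-1); for the shallow ones, the kernel size.
    """
    size = 1
    spatial = [ls for ls in spec.layers if ls.kind in ("convolution", "max_pool")]
    for ls in reversed(spatial):
        if ls.kind == "convolution":
            size += ls.kernel_size - 1
        else:
            size *= ls.pool_size
    return size


def export_filters(model: nn.Model, layer_index: int = 0,
                   pad: int = 1, scale: int = 1) -> np.ndarray:
    """Render a convolutional layer's filters as one tiled grayscale image.

    Each filter is min-max normalized independently to [0, 255] (a constant
    filter renders as mid-gray 128); multi-channel filters are averaged over
    input channels before normalization. Returns a uint8 image.
    """
    if not 0 <= layer_index < len(model.layers) or not isinstance(
            model.layers[layer_index], nn.Conv2D):
        raise ValueError(f"layer index {layer_index} is not a convolutional layer")
    layer = model.layers[layer_index]
    w = layer.params[0].reshape(layer.k, layer.k, layer.in_channels, layer.filters)
    w = w.mean(axis=2)  # (k, k, filters)
    n = layer.filters
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    k = layer.k * scale
    grid = np.zeros((nrows * (k + pad) + pad, ncols * (k + pad) + pad), dtype=np.uint8)
    for i in range(n):
        patch = w[:, :, i]
        lo, hi = patch.min(), patch.max()
        if hi - lo < 1e-12:
            img = np.full((layer.k, layer.k), 128, dtype=np.uint8)
        else:
            img = np.rint((patch - lo) / (hi - lo) * 255).astype(np.uint8)
        if scale > 1:
            img = np.kron(img, np.ones((scale, scale), dtype=np.uint8))
        r, c = divmod(i, ncols)
        y0, x0 = pad + r * (k + pad), pad + c * (k + pad)
        grid[y0:y0 + k, x0:x0 + k] = img
    return grid
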