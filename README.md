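# texdir — CNN-based texture directionality detection

`texdir` estimates the dominant local orientation ("texture
directionality") of grayscale images — e.g. fiber-like structures in
microscopy — by classifying small image tiles with a convolutional
network into 180 one-degree direction classes. The package contains
the complete pipeline:

* **Synthetic corpus generator** (`texdir.synthesis`): 16-bit images of
  evenly spaced bars (nine thickness/period combinations from 2/8 to
  32/64, background 16,384, foreground 49,151) rotated to every integer
  angle in [0°, 179°], optionally perturbed with zero-mean Gaussian
  noise (σ ∈ {2000, 4000, 6000, 8000}) or mean blur (kernels 3–9), and
  cut into 49 non-overlapping 64×64 tiles per texture. The full
  configuration yields 714,420 labelled tiles split 1/2 : 1/4 : 1/4
  into train/validation/test.
* **Twelve CNN architectures** (`texdir.architectures`): four shallow
  (SN1–SN4: one unpadded convolution → global max pool → dropout →
  softmax over 180 classes) and eight deep (DN1–DN8: three unpadded
  convolutions with 2×2 max pooling → global max pool → dense 90 →
  softmax), with seven selectable hidden activations (ReLU, ELU, SELU,
  sigmoid, softplus, softsign, tanh). Exact parameter counting and the
  minimum admissible input size

      minImSize = (cf8·mp6 + (cf5 − 1))·mp3 + (cf2 − 1)

  are exposed as functions. The networks run on a compact numpy engine
  (`texdir.nn`) with im2col/GEMM convolutions, Adam, and full backprop.
* **Training & evaluation** (`texdir.training`, `texdir.evaluation`):
  categorical cross-entropy on one-hot direction labels, batch 32,
  per-epoch loss curves, best-validation weight retention, replicates;
  scoring with the 180°-periodic angular error
  `error = acos(|cos(α − β)|)` (degrees, bounded by 90°) and RMSE
  grouped by bar thickness, noise level, or blur kernel.
* **Baselines** (`texdir.baselines`): Fourier power-spectrum orientation
  and local-gradient-orientation (Sobel histogram) detectors, used both
  as comparison methods and as independent oracles for the generator.
* **Directionality mapper** (`texdir.mapper`): tiles an arbitrary 8/16-bit
  grayscale image on a regular grid, predicts a direction per tile,
  rejects low-confidence tiles (threshold τ = 0.011 ≈ 2/180 by default),
  renders red-line overlays, and summarizes accepted directions in a
  one-degree polar histogram with a doubled-angle circular mean
  (dominant direction) and circular spread.

## Worked example

```python
import numpy as np
from texdir import (BarPattern, make_bar_image, rotate_and_crop,
                    build_architecture, map_image, polar_histogram,
                    parameter_count, min_input_size, architecture_spec)
from texdir.experiments import run_reduced_study

spec = architecture_spec("SN1", "ELU")
print(parameter_count(spec), min_input_size(spec))
# 84780 17

# desk-scale study: 8/16 bars, all 180 angles, 8,820 tiles, SN1-ELU, 6 epochs
study = run_reduced_study(seed=1)
print(f"clean test RMSE: {study.clean_rmse_deg:.2f} deg")
# clean test RMSE: 1.90 deg
print(study.blur_table.to_string(index=False))
#  blur_kernel  rmse_deg  n_tiles
#            0  1.901306     2205
#            3  2.308714     2205
#            5  2.460020     2205
#            7  2.820801     2205
#            9  3.774422     2205

# map a fresh texture rotated to 53 degrees
image = rotate_and_crop(make_bar_image(BarPattern(8, 16)), 53)
estimates = map_image(image, study.model)
hist = polar_histogram(estimates)
print(f"dominant {hist.dominant_deg:.1f} deg, spread {hist.spread_deg:.1f} deg, "
      f"{hist.n_accepted}/{len(estimates)} tiles accepted")
# dominant 52.0 deg, spread 0.0 deg, 49/49 tiles accepted
```

The clean RMSE says the trained network recovers the rotation label of
held-out tiles to within about two degrees RMS after only six epochs;
the blur sweep shows the robustness fall-off as the mean-blur kernel
grows. The mapper output gives the image-level dominant direction with
its circular spread (here 1° off the true 53° — consistent with the
network's RMSE at this training scale).

A command-line interface wraps the same pipeline:

```bash
texdir generate --config gen.cfg --seed 0 --out corpus --format npz
texdir train --corpus corpus --arch SN1 --activation ELU --epochs 6 --out model.npz
texdir map --model model.npz --image cells.tif --tile 64 --spacing 64 \
           --threshold 0.011 --out mapped/
```

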