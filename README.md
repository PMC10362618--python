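# foveaseg

Importance-aware semantic segmentation of histopathology lesion tiles with
**Fovea Pooling** — an adaptive-radius pooling operator inspired by the
retinal fovea — on top of a lightweight **Ghost-convolution** encoder whose
intrinsic feature maps are diversified by a normalized **HSIC** penalty.

The package is for researchers studying lesion segmentation in
hematoxylin–eosin stained tissue (e.g. lymph-node metastases of colorectal
cancer), where the regions of interest have irregular outlines and low
contrast against the surrounding tissue, and where standard U-Net encoders
lose exactly the detail that matters when they pool uniformly.

## The method in brief

A pointwise spatial attention module (collect + distribute branches) assigns
every position of an encoder feature map an importance score Z ∈ [0, 1].
Each position is then pooled (stride 1, reflect padding) over a square window
of side 2r − 1 whose radius follows the importance inversely:

    r_k = ⌊ exp( ς · (1 − Z_k) ) ⌋,   ς = ln(s · w),

so the most important positions keep full resolution (r = 1) and the least
important aggregate up to the *pooling boundary* fraction s of the stage
width w.  Four such modules replace the identity skip connections of a U-Net
whose encoder is a four-bottleneck Ghost network; training minimizes

    L = L_focal + λ · L_nHSIC,        λ = 0.75,

a focal loss on the foreground probability plus a normalized
Hilbert–Schmidt independence criterion between the encoder's intrinsic
feature channels, which suppresses channel redundancy (visible as a drop in
pairwise CKA).  Details, design decisions and numerical conventions are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a seeded synthetic dataset of HE-like tiles (40 train / 10 test,
96×96, irregular low-contrast blobs), train the width-reduced model for 20
epochs, and evaluate:

```bash
foveaseg generate --out data --seed 7
foveaseg train --data data --out run --iterations 20 --seed 1
foveaseg evaluate --checkpoint run/model.npz --data data --out run/metrics.csv
foveaseg predict --checkpoint run/model.npz --out run/pred data/test/images/0000.png
```

Training prints one line per epoch (this is the actual output of the run
above; ~2 minutes on one CPU):

```
epoch   0  loss 0.1212  focal 0.0257  nhsic 0.1273  test DSC 0.0000
epoch 2: unfreezing backbone (step 20)
...
epoch  16  loss 0.0134  focal 0.0048  nhsic 0.0115  test DSC 0.9056
epoch  19  loss 0.0123  focal 0.0045  nhsic 0.0104  test DSC 0.8705
finished in 121.4s; monitored mean off-diagonal CKA 0.0226
```

`loss` is the composite objective, `focal`/`nhsic` its two components, and
`test DSC` the Dice coefficient on the held-out tiles (1.0 = perfect
overlap).  The final line reports the redundancy statistic among monitored
intrinsic channels; the same run with `--no-nhsic` ends at CKA 0.1084 —
the diversity penalty roughly quarters channel redundancy at identical seed.

The evaluate step writes per-image and micro-averaged IoU / DSC /
sensitivity / specificity / precision; predict writes binary masks and
red-tinted overlays.

Parameter accounting of the full-scale reference architecture:

```bash
$ foveaseg param-report
module              params        MB
backbone             26304      0.10
fp1                 739302      2.82
...
total              6098157     23.26
```

The identity-skip ablation (`foveaseg param-report --fp-method identity`)
prints 11.98 MB; the difference is exactly the four Fovea Pooling modules.

## Library API

```python
from foveaseg import (SynthConfig, generate_dataset, NetworkConfig,
                      TrainConfig, train, adaptive_pool, radius_map, nhsic)
```

Everything the CLI does is a thin wrapper over these functions; see the
module docstrings.

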