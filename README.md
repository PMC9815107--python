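# msfnet

A multi-scale fusion convolutional classifier for leaf-disease images, with
channel/spatial attention gating, focal-loss training, confusion-matrix
evaluation, and Grad-CAM explanations.

The package is aimed at plant-pathology image work of the cassava kind: a
directory-per-class folder of RGB photographs (e.g. the five classes CBB —
bacterial blight, CBSD — brown streak disease, CGM — green mottle, CMD —
mosaic disease, and healthy leaves), where the diagnostic signal is lesion
colour, texture and spatial context, and where class frequencies are far
from balanced. Everything runs on a plain CPU: the neural-network stack
(reverse-mode autograd, im2col convolutions, batch norm, Adam) is
implemented in numpy inside `msfnet.nn`, and a synthetic leaf-image
generator means no dataset download is ever required to exercise or test
the full pipeline.

## The model

The classifier is an EfficientNet-B6-shaped backbone (stem → seven MBConv
stages → 1×1 head → global average pooling → K-way linear head) augmented in
two ways:

**CBAM** (convolutional block attention) recalibrates a feature map
`F ∈ R^{C×H×W}` in two sequential multiplicative gates,

```
F′ = F ⊙ σ(MLP(maxpool(F)) + MLP(avgpool(F)))        — channel gate (1×1×C)
F″ = F′ ⊙ σ(conv7×7([max_c F′ ; mean_c F′]))          — spatial gate (H×W)
```

with one shared two-layer bottleneck MLP (reduction ratio 16, ReLU middle).

**MSFM** (multi-scale fusion module) sits after a shallow stage: CBAM
recalibration followed by three parallel dilated 3×3 convolutions at rates
r ∈ {1, 2, 4}, concatenated and reduced by a 1×1 convolution. A dilated
kernel spans a window of side

```
k_d = k + (k − 1)(r − 1)
```

so the rate-2 branch covers the same 5×5 neighbourhood as a dense 5×5
kernel with only 9 weights, and the rate-4 branch a 9×9 neighbourhood —
multi-scale context without extra parameters.

Training uses the **focal loss**

```
FL(p_t) = −a_t (1 − p_t)^γ log(p_t)
```

which reduces to weighted cross-entropy at γ = 0 and progressively
down-weights easy examples as γ grows; `a_t` defaults to inverse-frequency
class weights computed on the training split.

## Worked example

```python
import numpy as np
from msfnet.data import generate_synthetic_manifest
from msfnet.model import tiny_config, build_model
from msfnet.training import TrainConfig, train
from msfnet.losses import LossConfig

manifest = generate_synthetic_manifest(n_per_class=50, image_size=(64, 64), seed=7)
model = build_model(tiny_config(), seed=1)          # width x0.1 preset, 64 px
cfg = TrainConfig(epochs=10, learning_rate=1e-3, batch_size=16, seed=1,
                  loss=LossConfig(kind="focal", gamma=2.0))
model, history = train(model, manifest, None, cfg)
for h in history:
    print(h.epoch, round(h.train_loss, 4), round(h.train_accuracy, 3))
```

prints (one row per epoch: epoch, mean focal loss, training accuracy)

```
1 0.8451 0.42
2 0.5923 0.504
3 0.4602 0.636
...
10 0.12 0.908
```

i.e. on the seeded five-class synthetic set the scaled-down model climbs
from chance (0.2) to above 90% training accuracy within ten epochs — the
colour/texture motifs that distinguish the classes are being learned.

The same workflow is available from the shell:

```bash
msfnet generate --n-per-class 50 --size 64 --seed 7 --out data/
msfnet train --data-root data/ --out run/ --epochs 30 --learning-rate 1e-3 \
             --width-multiplier 0.1 --depth-multiplier 0.12 --resolution 64
msfnet evaluate --checkpoint run/model.npz --data-root data/ --out report/
msfnet explain  --checkpoint run/model.npz --image data/cmd/cmd_0000.png \
                --target-class 3 --out overlay.png
```

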