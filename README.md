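# teadet

Real-time dense small-object detection for multimodal plant imagery —
the motivating case is tea-shoot detection, where a single 512×360 frame
contains 200–400 bud-like targets of roughly 15–30 px whose colour is
close to the canopy background.  A short-range RGB-D sensor provides
three pixel-aligned modalities per frame: an 8-bit RGB image, a 16-bit
infrared reflectance image and an 8-bit depth image, all sharing one set
of box annotations.

The package implements, end to end and in pure scientific Python
(NumPy + SciPy, with its own compact reverse-mode autodiff):

* **A one-stage CSP detector family** (`teadet.model_zoo`,
  `teadet.blocks`) built from a declarative config — slicing (Focus) or
  single 6×6 stem, four CSP1_n backbone stages with nominal repeats
  scaled by a depth multiple, SPP, PANet or pure top-down FPN neck,
  optional quantised-kernel DSConv neck convolutions — with *exact*
  parameter and FLOP accounting.  Parameters are reported in deployment
  (BN-fused) form, `Σ (C_in·C_out·K² + C_out)`; compute as
  `Σ 2·C_in·K²·H_out·W_out·C_out` (the 2×multiply-accumulate
  convention), with the `(2·C_in·K²−1)·H_out·W_out·C_out` form also
  available.
* **Multimodal fusion** at the data layer (`teadet.fusion`): weighted
  pixel summation `0.6·RGB + 0.2·IR + 0.2·D`, an RGBA stack whose alpha
  is `0.5·IR + 0.5·D`, and the `D_IR_IR` composite; and at the feature
  layer (`teadet.ffa`): a dual-stream detector whose streams exchange
  information through a frequency-domain cross-modal attention block
  (FFA) — per-channel FFT, channel attention on pooled magnitude
  spectra, per-frequency attention, inverse FFT, and cross-wired 1×1
  re-enhancement.  Attention multiplies complex spectra by real weights
  in (0,1), so phase (spatial structure) is preserved.
* **Object-based scale matching** (`teadet.scale_match`): align one
  dataset's object-scale distribution to another's by cut–resample–paste
  with nearest-pixel hole filling, where relative scale is
  `sqrt(w·h / (W·H))` and one global factor `a = s_target / s_source`
  applies to every over-threshold object.
* **Training and evaluation** (`teadet.train_eval`): the three-term loss
  `L = L_confidence + L_classification + L_box` (BCE objectness/class,
  complete-IoU box, ratio-test anchor assignment), SGD with momentum
  warm-up 0.8→0.937, cosine lr 1e-2→1e-5, weight decay 5e-3, online
  flip/rotation/colour/mosaic augmentation; greedy matching,
  precision/recall, all-point-interpolated AP, mAP50 and mAP95.
* **A seeded synthetic scene generator** (`teadet.synthetic`) that
  renders aligned RGB/IR/depth triplets with dense, tiny, elongated
  two-lobe objects, depth voids and IR speckle, so every component is
  testable without field data.

## Worked example

Architecture statistics come from the declarative configs:

```
$ teadet summarize --preset baseline --img 640
parameters (fused): 7,012,822
parameters (train): 7,022,326
GFLOPs @640 (2xMAC): 15.8
GFLOPs @640 (2CK^2-1): 15.7

$ teadet summarize --preset improved --img 640
parameters (fused): 5,715,670
GFLOPs @640 (2xMAC): 14.4
```

The baseline single-class detector has 7,012,822 deployment parameters
and costs 15.8 GFLOPs at 640×640; the improved variant (6×6 stem, stage
repeats 8,8,3,3, FPN neck, DSConv neck kernels) drops to 5,715,670
parameters.  The "train" count additionally includes the normalisation
affine pairs that fold away at deployment.

A synthetic corpus and its scale report:

```
$ teadet synth --n 4 --seed 7 --mean-scale 0.05 --out demo
$ teadet scale-stats --data demo
objects: 1114   mean relative scale: 0.0517
```

Four 512×360 frames received 1,114 objects whose mean relative scale
(0.0517) sits on the configured 0.05 target; `teadet scale-match --src
<ds> --ref <ds> --out <ds>` rescales a corpus to a reference scale, and
`teadet train` / `teadet eval` run the detector on any corpus directory
with a `manifest.tsv`.

Python API in one breath:

```python
from teadet.model_zoo import build_detector, summarize
from teadet.synthetic import SceneConfig, generate_scene

model = build_detector("improved")
print(summarize(model, 640).parameter_count)   # 5715670
triplet, boxes = generate_scene(SceneConfig(), seed=1)
```

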