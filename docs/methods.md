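# Methods

This note documents the models, algorithms and numerical choices behind
`uwdet`, and what its desk-scale experiments do and do not demonstrate.

## Numerical core

All networks run on a compact reverse-mode automatic-differentiation engine
over float64 numpy arrays (`uwdet.tensor`). Convolution is evaluated as a
strided-window contraction (einsum over `as_strided` views); its backward
pass scatters gradients through the same window geometry. Max pooling splits
gradient evenly across tied maxima; binary cross-entropy is computed in the
stable `log1p` form with the exact `sigmoid(x) − y` gradient. Every op is
validated against central finite differences in the test suite. Float64 is
deliberate: the models exercised here are small, and the extra width removes
step-size/epsilon tuning from gradient checks.

Batch normalization uses batch statistics in training and running statistics
(momentum 0.1, eps 1e-5) in evaluation. After short, fast training runs the
running averages lag the weights badly enough to corrupt evaluation, so
`train()` ends with a calibration pass that pins the running statistics to
the exact training-set statistics (momentum forced to 1 for one forward).

## Detector architecture

Both variants share compound scaling (`scale` letter → depth/width
multiples, YOLOv5 convention), base widths (64, 128, 256, 512, 1024), an
FPN+PAN neck and three anchor-based 1×1 prediction heads at strides 8/16/32
(3 anchors per scale, `n_anchors·(5+nc)` channels per cell). Anchor priors
are the canonical COCO set stated at a 640 reference and scaled linearly to
the working input size.

**Baseline**: 6×6 stride-2 stem convolution, C3 blocks of depth 4/8/12/4 at
x-scale, SPPF after stage 4. With an 80-class head at 640×640 it counts
86.75 M parameters and 205.4 GFLOPs (FLOPs = 2 × multiply-accumulates,
convolutions only), matching the published convention for this architecture
within rounding.

**Improved**: the backbone is replaced by an RTMDet-style design — a stem of
three 3×3 convolutions with strides (2, 1, 1) (half width, half width, full
width), then four stages of stride-2 convolution + CSPLayer, with SPPF
between the stage-4 convolution and its CSPLayer. Each CSPLayer uses a
half-width hidden split (hidden = out/2, the C3/CSP convention), one
residual CSPNeXt block (3×3 then dense 5×5 convolution), channel attention
on the concatenation, and a 1×1 fuse. The 5×5 convolution is dense by
default for efficiency on dense-convolution hardware; a depth-wise variant
sits behind `depthwise_cspnext`. In the neck, exactly one BoT3 block is
inserted on the stride-16 branch after the PAN fusion, so both the medium
detection head and the downsampling path to the large head consume its
output.

The BoT3 hidden width is out/2; its inner BoT block is extraction 1×1 conv →
MHSA → expansion 1×1 conv with a residual sum. MHSA uses 4 heads, q/k/v from
1×1 projections, logits scaled by 1/sqrt(d/heads), softmax over the H·W
positions, and **no positional encodings** of any kind — attention is purely
content-based, which also keeps the block insertable at any spatial size.

Activations are SiLU throughout, except the hard-sigmoid gate
(clip(x/6 + 0.5, 0, 1)) inside channel attention. The channel-attention
projection uses no squeeze ratio (a single full-width 1×1 convolution).
Prediction-head objectness biases start at −5 so that untrained models are
pessimistic rather than flooded with false positives.

### Accounting

Parameter counts are exact sums of learnable scalars; FLOPs are analytic
(2·k²·C_in·C_out·H_out·W_out per convolution; projection plus score/mix
matmul terms for attention) propagated along the wiring, and are verified
against independent closed-form layer sums in the tests. Under this plan the
improved x-scale model counts 77.8 M parameters / 173.1 GFLOPs: one CSPNeXt
block per stage (the design's stated depth) is far lighter than the 4–12
C3 bottlenecks it replaces, and no defensible width plan we examined
(including widening the CSP hidden split to full width, ≈ +66 M) reaches the
208.0 M / 432.8 G sometimes quoted for this architecture family. The counts
above are therefore the package's reference numbers; the accounting method
itself is anchored by the baseline's published 86.7 M / 205.7 G.

## Training loss

YOLOv5-style three-term loss. Targets are assigned per level to anchors with
width/height ratio within 4 (both directions), in the box's own grid cell
plus up to two neighbouring cells nearest the center (offset 0.5). Boxes
decode as `xy = 2σ(t) − 0.5 + cell`, `wh = (2σ(t))²·anchor`; the box term is
1 − CIoU (complete IoU: IoU minus center-distance and aspect-ratio
penalties, with the aspect weight detached). Objectness targets equal the
clamped CIoU of the assigned prediction, weighted 4.0/1.0/0.4 across the
three levels; classification is one-hot BCE. Default gains: box 0.05,
objectness 1.0, classification 0.5; optimizer defaults are SGD with learning
rate 0.01, momentum 0.937, weight decay 0.0005.

## Enhancement and UDA

Step 1 (color): the dominant channel is the one with the largest global
mean; each other channel is shifted by
`strength · max(local_mean_dom − local_mean_c, 0)` (uniform window of radius
16 px, strength 0.9). The dominant channel never moves, a gray image is a
fixed point, and the channel-mean spread shrinks. Step 2 (contrast): each
channel is remapped around its local mean with gain
`clip(target_std / local_std, 1, 8)` computed on the gray image
(target_std 0.12). The bounds were chosen so one pass reaches the contrast
target on degraded imagery — making the pipeline contractive (a second
application changes the image less than the first) — while flat regions of
already-crisp images are left alone by the unit lower bound.

UDA copies the raw training split and writes an enhanced duplicate of every
image with a byte-identical label file (enhancement is per-pixel/
per-neighbourhood, so geometry and boxes are invariant); the result is a
plain YOLO-layout dataset of twice the size. Only the training split is an
input to the operation, so validation/test data cannot be enhanced by
construction, and the evaluation CLI never calls the enhancer.

## Synthetic scenes

Scenes emulate the statistics of shallow-water benthic imagery: a sandy
seafloor with smooth large-scale texture, 5 organism classes drawn as
class-distinct parametric shapes (spiky disc, five-armed star, elongated
ellipse, scalloped fan, wavy blade), then a fixed degradation chain —
blue-green cast (blend toward an ambient water color, strength 0.4),
contrast compression toward mid-gray (factor 0.5), Gaussian blur (σ 1.2 px)
and additive noise (σ 0.03). Boxes are the exact mask bounding boxes, and
all degradations are photometric, so labels are exact by construction.
Defaults: 416 px scenes, 3–10 objects of 8–28 % image diameter, occlusion
probability 0.3.

What the generator does **not** emulate: real organism texture and
appearance variation, perspective and lighting geometry, class-imbalanced
long-tailed distributions, and label noise. Passing tests therefore
demonstrate that the architecture, loss, augmentation and evaluation
machinery are correct and can fit data of this structure — not that the
model reaches any particular accuracy on real survey imagery.

## Evaluation

Greedy confidence-descending one-to-one matching per class; 0/0 precision
and recall are 0. AP defaults to COCO-style 101-point interpolation of the
precision envelope, with an exact envelope-integral mode (`continuous`)
behind a flag; mAP@0.5:0.95 averages the ten IoU thresholds 0.5:0.05:0.95.
The confusion matrix is (nc+1)² with a background row/column, rows = truth.
NMS is class-aware greedy suppression. Inference defaults: confidence 0.001
and NMS IoU 0.6 for mAP evaluation, 0.25/0.45 for deployment-style output.

## Desk-scale experiment sizes

All built-in experiments are sized for a single CPU: unit fixtures use
64–160 px images and nano-scale models; the learning smoke test overfits
four 160 px scenes (1–3 large objects, 3 classes, no occlusion) for 150
optimizer steps with lr 0.02, box gain 0.2 and NMS IoU 0.45, reaching
mAP@0.5 ≈ 0.94–1.0 on those images in about two minutes. The x-scale models
are assembled only for accounting, never trained.

## Known limitations

* No EMA, warmup/cosine schedules, multi-GPU or mixed precision; the
  training loop is intentionally minimal.
* Mosaic augmentation is provided and tested as a data operation but is not
  wired into the default training loop (determinism of the smoke runs takes
  priority at desk scale).
* Numeric fidelity to the original MLLE formulation is out of scope; the
  enhancement implements the two named steps at contract level.
* The synthetic-scene shortcut of exact masks means box regression never
  sees annotation noise.
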