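# Methods

## Problem and data model

A mixed-sward breeding trial is laid out as plots sown with a grass
(timothy, `TY`) and a legume (white clover, `WC`). Each plot is photographed
from directly above at roughly 1 mm/pixel and cropped to about
2,000 × 3,000 pixels. For ground truth, one binary *category map* per
category is painted over the image, pixel-aligned with it; the painted-pixel
fraction of a map is the plot's **measured coverage** for that category
(`Bg`, background, covers soil and litter). Because the maps are painted
independently, per-plot sums across categories need not equal 100%, and the
package never renormalizes them. A plot may also carry a **scored coverage**:
a visual percentage assigned in the field.

## Patch pipeline

Working unit is a 64 × 64-pixel window ("piece"):

- **Training pieces** — 4,000 per plot by default, cut uniformly at random
  (with replacement) from the region excluding a 128-pixel strip on the
  image's right side. Sampling with replacement over the ~5.5 M valid
  positions of a full-size plot is statistically indistinguishable from
  without-replacement at n = 4,000 and keeps the sampler trivially uniform.
- **Validation pieces** — the right-hand 128-pixel strip tiled row-major
  from its top-left without overlap; partial windows are dropped. Counts
  therefore follow from geometry (a 128-wide strip on a 1,536-tall image
  yields 2 × 24 = 48 pieces) rather than being hard-coded.
- **Evaluation pieces** — the full image tiled row-major without overlap,
  ⌊W/64⌋ × ⌊H/64⌋ windows; the right/bottom remainder is unused. A
  2,000 × 3,000 image gives 31 × 46 = 1,426 pieces.

For each piece and category the painted-pixel rate r_p ∈ [0, 1] is computed
on the category map and discretized to one of 21 **class values**
{0, 5, …, 100}% as `5 · round(20 · r_p)` with round-half-to-even. The
half-even rule generates the canonical class table's asymmetric boundaries
(0.125 → 10 since 2.5 rounds to 2; 0.175 → 20 since 3.5 rounds to 4). An
explicit 21-row interval table is shipped alongside the closed form and the
two are asserted equal on a 0.001-step grid, guarding against platform
rounding drift. Pieces destined for a deep backbone are upscaled 64 → 256 by
nearest neighbour (each input pixel becomes an exact 4 × 4 block).

## Classifier training

One 21-class softmax classifier is trained per category per dataset with
mini-batch momentum SGD: learning rate 0.01, batch size 32, momentum 0.9,
500 epochs (one iteration = one batch of 32, so 4,000 pieces × 500 epochs =
62,500 iterations). Validation accuracy is evaluated every 1,000 iterations
(plus once at the final iteration when it is not a multiple) and the
checkpoint with the highest validation accuracy is kept; ties keep the
earliest event. The loss is softmax cross-entropy; no learning-rate
schedule, weight decay or augmentation is applied. Argmax ties at prediction
time resolve to the lowest class index. Runs are deterministic for a fixed
seed under single-threaded numpy.

The backbone is pluggable behind a registry. The shipped **tiny backbone**
is a small MLP over pooled colour features: the patch is mean-pooled onto an
8 × 8 grid of RGB cells plus whole-patch channel means (195 features), then
one 48-unit ReLU layer feeds the 21-way head. Coverage class is largely
determined by how much of a piece shows the category's colour/texture, so
pooled colour statistics carry that signal well on rendered swards and train
in seconds on one CPU. The study-scale configuration — an inception-style
deep network fine-tuned from natural-image pretraining on the 256 × 256
pieces — is the documented default of the protocol, not bundled here; the
registry accepts such a backbone unchanged because training, checkpoint
selection and prediction only consume `features`/`logits`/`loss_and_grads`.
What the tiny backbone cannot do is generalize across real leaf-shape
variation (e.g. red vs. white clover); conclusions from the synthetic tests
concern the pipeline, not field-scale CNN accuracy.

## Evaluation

A *one-model-to-one-plot prediction* compares predicted class values P_j
against observed class values O_j (same binning as training labels) over the
full evaluation tiling:

    MBE = (1/n) Σ (P_j − O_j)      MAE = (1/n) Σ |P_j − O_j|

MBE > 0 means over-estimation; |MBE| ≤ MAE always. Across plots a model is
summarized by MMBE/MMAE, the means of its per-plot MBEs/MAEs over the N
plots **not** used in its training. Averaging a model's predicted class
values over a plot's tiling yields the plot's **estimated coverage**; the
tiling includes the validation strip, since estimation-time prediction does
not re-exclude it. Pearson product-moment correlations are computed between
scored, measured and estimated coverage over the plots left after removing
the model's training plots — including for the scored-vs-measured pair, so
those correlations are model-specific.

A ground-truth-lookup *oracle model* (predicts each piece's true class
value) is used as a reference: its per-piece error is zero, so its estimated
coverage can deviate from the tiled region's measured coverage only through
binning (≤ 2.5 points, half a class bin) and the unused remainder strip.

Display rounding in summary tables is decimal round-half-up to one decimal
(so a mean of 51.25 prints as 51.3).

## ExG − ExR baseline

The non-learning comparator estimates background coverage from the image
alone. On chromatic coordinates r = R/(R+G+B) etc., ExG = 2g − r − b and
ExR = 1.4r − g; a pixel is background when ExG − ExR ≤ 0 (threshold
inclusive: zero-index pixels count as background). Black pixels, whose
chromatic coordinates are undefined, are classified as background since
zero-reflectance pixels are not vegetation. The estimator is invariant to
pixel permutation and to positive rescaling of all channels.

## Synthetic sward generator

Tests and desk-scale experiments run on rendered plots: grass blades are
hard-edged rotated rectangles (length 30–60 px, width 1–3 px), clover is a
trifoliate union of three discs (radius 8–14 px), background is soil with
scattered litter patches and per-pixel colour noise. Hard edges make the
category maps exactly the rasterized organ footprints — no anti-aliasing
ambiguity — and the background map is the complement of the vegetation
union. Organs are added one at a time to whichever category is furthest
below its target coverage; later organs occlude earlier ones, as leaves do.
A single organ covers far less than 1% of a plot, so achieved coverage lands
within 3 points of target (asserted at generation time); vegetation targets
summing above 1 are rejected. An optional withered-grass mode draws part of
the grass in a senescent brown palette and can leave those blades out of the
`TY` map, reproducing the grass/background labelling ambiguity of autumn
imagery. Palettes are chosen so ExG − ExR separates vegetation from
soil/litter, as it does on real imagery.

The default 12-plot study mirrors the trial layout: four groups of three
plots, with the three plots of each group spanning low/mid/high legume
coverage (targets 8/18/32% WC, 44/40/36% TY — inside the measured ranges of
the reference trial) so that group-vs-single-plot training comparisons are
meaningful. Plot images default to 640 × 960 px for the study generator
(150 evaluation pieces per plot) — a desk-scale choice; single plots default
to the full 2,000 × 3,000 and any size ≥ 256 × 256 can be requested.

What the generator does **not** emulate: illumination and shadow, 3-D canopy
structure and perspective, leaf-shape variation within a category, image
noise/compression, and painting error in the maps. Passing tests therefore
demonstrate correctness of the pipeline's mechanics and the direction of its
comparative findings (multi-plot training generalizes better than
extreme-single-plot training), not field-scale accuracy figures.

## Numerical and design choices

- Map binarization: any nonzero channel value counts as painted (exported
  hand-painted layers may carry antialiased edge values).
- Measured coverage uses the full image extent, including the validation
  strip.
- Coordinates are 0-based, top-left origin; windows are half-open.
- Group datasets concatenate the member plots' samples (12,000 pieces for a
  group of three), with per-plot provenance kept in the label table.
- Checkpoint and tie rules as above; training labels outside 0–20 abort
  before any optimization.
- Desk-scale experiment sizes used by the test-suite: 640 × 960 plots,
  1,500 training pieces per plot, 3,000 iterations with validation every
  500. These are the package's own desk-scale defaults for the synthetic
  study; the full protocol values (4,000 pieces, 62,500 iterations) remain
  the configuration defaults.

## Known limitations

- The tiny backbone is colour-driven; categories distinguished only by
  shape at equal colour would defeat it. It exists to exercise the pipeline,
  not to replace a deep backbone for field imagery.
- The generator's coverage guarantee is per category against its own map;
  it does not model painting disagreement between observers.
- Correlation analysis requires ≥ 3 retained plots and non-degenerate
  variance; degenerate inputs raise rather than returning NaN.
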