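# Methods

## Scope and model

`calmorph` measures intracellular Ca²⁺ dynamics from a time-ordered
grayscale sequence of fluorescently stained cells. Its working assumptions
are those of a typical stained-follicular-cell acquisition: cells are
static over the sequence; each has a dark nucleus (a few pixels radius)
surrounded by brighter cytoplasm; illumination varies smoothly in space;
and each measured volume trace decomposes as `V_n = V_n* + N_n`, a
noise-free signal plus additive zero-mean noise. The fluorescence volume
(sum of intensities over the cell's region) is the calcium proxy: after a
stimulus it rises to a global maximum and decays roughly exponentially
toward the resting level.

## Morphological layer

All operators are flat (structuring elements carry no gray weights), so
results are exact min/max algebra and preserve the input dtype. The
elementary element is the 3×3 square (8-connectivity) in 2-D and the
3-sample line in 1-D; a size-μ element is the (2μ+1)-wide homothetic;
size 0 is the identity. Discs are available, but the square is the default
elementary shape.

**Borders.** Window operators (erosion, dilation, and the plain
opening/closing composed from them) replicate edge values, which avoids
spurious extrema at the frame border. The *by-reconstruction* composites
(γ̃, φ̃, and everything built on them: ASF, medium filter) are evaluated
on the edge-replicated extension of the input — pad by the element radius,
compose, crop. The distinction matters: replicating only the intermediate
erosion truncates monotone slopes that run into the border (the first
samples of every decay window would lose up to the element radius of
height), whereas on the extension monotone signals are exact fixed points,
matching the operators' behavior on an unbounded domain. Idempotence, the
envelope sandwich γ̃ ≤ f ≤ φ̃, duality, and order preservation all hold
exactly under this convention and are asserted exactly in the tests.

**Reconstruction** is defined as unit geodesic steps iterated until
idempotence. The fixpoint is unique on finite grids, so the efficient
propagation used in production (scikit-image) is bit-identical to the
naive iterator, which the test suite keeps as an independent oracle.

## Marker detection

Per frame: white top-hat at scale `tophat_scale` (default 10× the
expected nucleus radius, so the opening tracks the illumination field and
not the cells), a unitary closing by reconstruction (fills dark noise pits
narrower than 3 samples), then regional minima (8-connected flat zones
with no lower neighbor). A perfectly constant frame is a single regional
minimum spanning it.

Because a single frame can miss nuclei (the cytoplasm ring is not always
closed), minima are accumulated over the sequence into per-pixel
occurrence counts. True nuclei recur in mostly the same pixels; noise
minima wander. The final mask thresholds the counts at
`occurrence_threshold` (default 0.5 — a pixel must be a minimum in at
least half the accumulated frames), closes at size 3 to fill holes and
connect fragments, subtracts the binary opening by reconstruction at size
6 (removing any component wide enough to contain a 13×13 element — large
background plateaus), and keeps components with area in
`[π(r/2)², π(3r)²]` for nucleus radius r. Binary morphology is the
grayscale operators on {0,1}; there is no separate code path.
Accumulation defaults to the whole sequence; a frame range is
configurable.

## Segmentation

The segmentation image is the top-hat-corrected per-pixel temporal
maximum projection of the sequence — cells at peak fluorescence show the
sharpest cytoplasm/background boundary — configurable to any single
frame. The relief is the internal gradient `f − ε(f)` by default (thin,
well-localized borders; morphological and external variants are
selectable). Markers are imposed as the relief's only minima via the dual
reconstruction R*(g′, f): the indicator f is 0 on markers and max_value
off them; g′ is 0 on markers and `grad + 1` off them (capped at
max_value). The +1 makes every off-marker pixel strictly positive; with
the raw gradient, zero-gradient plateaus touching a marker would join its
minimum and the minima-equal-markers contract (asserted exactly in the
tests for every gradient kind) would fail. max_value is the dtype maximum
for integer reliefs and max+1 for floats. The watershed floods from the
labeled marker components (scikit-image, 8-connectivity); crest pixels
keep label 0 by default, or are assigned to the first-arriving basin in
"no-lines" mode.

## Traces

`V_n(i)` sums the ORIGINAL (uncorrected) intensities over region n —
the top-hat changes absolute intensities, and it is raw luminance that
tracks calcium. Regions are the watershed regions excluding line pixels,
fixed over time; an optional dilation by r px includes the immediate
neighborhood (overlaps stay with the lower label). Volumes are additive
over region splits by construction.

## Decay modeling

The global maximum is located on the trace smoothed by a 1-D alternating
sequential filter by reconstruction (γ̃ then φ̃ at scales 1..k, default
k = ⌈2% of the trace length⌉). Among the samples attaining the maximum the
largest connected plateau is taken and its center (rounded mean index)
returned; the filter can displace the plateau by roughly its scale, which
bounds the localization error. A fully constant signal has no unique
maximum and errors out.

The decay window (maximum to end) is fitted with an LS polynomial on
abscissae standardized to [−1, 1] — on raw frame indices `(XᵀX)⁻¹`
overflows for moderate degrees — with predictions mapped back to frame
indices. The degree is the smallest n′ whose leading singular values of
`(XᵀX)⁻¹` (degree-n_max design, default n_max = 8) carry > 99.99% of the
cumulative singular-value sum. The design always includes the intercept
column, so fit residuals sum to zero; any remaining BIAS of a reported
model is model-family bias, not fit bias. BIAS is `Σ(x − x*)` (negative =
undermodeling); RMSE is the mean squared residual *without* square root,
the convention used in this line of work for these diagnostics —
`root_mean_squared_error` provides the rooted version separately.

By default the medium filter is applied to the decay window (the data the
fit consumes), not the whole trace: on the full trace the opening envelope
truncates the sharp stimulus peak itself — structure narrower than the
element, not noise — which biases residuals and inflates the filtered-fit
RMSE. On the monotone-dominated decay the filter is near-identity on clean
structure and removes only the high-frequency noise. The residual
consistency report (mean, SD, skewness, two-sided t-test of mean 0 at
5%, |skewness| < 0.5) is computed on that window. Normality is
deliberately operationalized as zero-centering plus bounded skewness: the
filter's residuals are bounded mixtures and would fail any omnibus
normality test at large n, while the property that matters for LS
consistency is a residual distribution centered at the origin.

## Medium reconstruction filter

`f_μ(V) = α₁·γ̃_μ(V) + α₂·φ̃_μ(V)` with α₁ + α₂ = 1, default 0.5/0.5
(the symmetric case when both envelopes use the same element; asymmetric
weights are exposed for elements of differing geometry). The sequential
variant composes stages over a schedule of sizes, smallest first (by
analogy with alternating sequential filters; the composition order is
otherwise free), default 1..k with the same k as the ASF. The mix is not
idempotent; what each stage guarantees is envelope containment
γ̃ ≤ f_μ ≤ φ̃ of its input. Pure-envelope residuals are one-sided
(opening ≤ 0, closing ≥ 0) exactly.

## Synthetic data generator

Scenes emulate the target acquisition: cells placed ≥ max(4r, 2R+3) apart
(r = nucleus radius 4 px, R = cytoplasm radius 10 px) inside a 128×128
frame; flat cytoplasm discs (gain 120 counts at peak) with flat darker
cores (depth 60) on a background of 30 plus a smooth 8-count illumination
plane; per-cell dynamics at resting level 0.15 of peak, a 10-frame linear
rise to a stimulus peak in [15%, 30%] of the 200-frame sequence, and
exponential decay with τ in [15%, 35%] of the sequence; additive Gaussian
noise (σ = 0.5 counts) and quantization to uint16. The defaults model a
well-exposed, high-SNR acquisition in which nucleus floors are flat at
the quantization scale — that is what makes per-frame regional minima
recur in the same pixels, the property the occurrence-accumulation
detector exploits. 200 frames (rather than the thousand-frame acquisitions
the pipeline is sized for) keep a full end-to-end run around a second.

Not emulated: photobleaching, cell motion or division, occlusion,
Poisson (signal-dependent) noise, out-of-focus blur. Passing tests
therefore demonstrate the correctness of the operators and the recovery
behavior of the chain under the stated model, not robustness to those
effects. Noise levels for the 1-D modeling studies are set separately
(σ = 5 on amplitude-100 traces, i.e. 5%) and are deliberately harsher
than the image scenes' trace-level noise.

## Numerical choices and degenerate inputs

Flat morphology uses exact comparisons — no tolerances anywhere in the
operator layer. Reconstruction carries an iteration cap only as a bug
guard. `select_order` requires at least n_max + 2 points and raises on
rank-deficient designs; fits require more points than coefficients.
Empty marker sets: `impose_minima` raises, while the pipeline completes
with empty tables and a warning. Traces shorter than 12 frames skip
modeling with a warning. Seeds fully determine generator output;
re-running the pipeline with the same input and configuration produces
byte-identical CSVs.

## Problem sizes

The test suite and the acceptance script use the generator defaults above:
the default 8-cell, 200-frame scene (plus 20-seed sweeps of it) for
segmentation and peak localization, and 100 seeded traces of n = 500
(n = 1000 for residual statistics) for the modeling and filtering studies.

## Known limitations

Peak localization is biased late by about the ASF scale when the decay is
shallow relative to the noise (the maximal plateau extends into the flat
side); the error bound is the filter scale under the default conditions,
not universally. The polynomial family only approximates an exponential;
its approximation bias dominates model error when noise is very small.
Cells that move, divide, overlap, or whose cytoplasm ring is too dim to
close will not be detected reliably; there is no per-frame segmentation
consolidation — the temporal-projection segmentation stands in for it.
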