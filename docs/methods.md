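# Methods

## Problem and model

`structage` estimates the biological "age" of individual brain structures
from their surface geometry. Each structure (cortex and seven subcortical
structures per hemisphere) is represented as a template-registered
triangulated mesh: every subject's surface carries the same fixed
triangulation, so vertex *k* corresponds anatomically across subjects and
vertex order is node identity. The mesh is treated as a graph — nodes are
vertices, edges are triangle edges — and a convolutional network operates
on per-node coordinate features through spectral filters of the graph
Laplacian. The prediction target is chronological age; the residual
(predicted − actual), after bias correction, indexes deviation from
normative aging, and its group structure is analyzed with linear models.

## Graphs, Laplacians and features

Edges are unweighted by default (weight 1 per unique triangle edge), which
keeps the Laplacian purely combinatorial and reproducible;
inverse-edge-length weights are available via
`mesh_to_graph(..., weighting="inverse_length")`. The operator filtered by
the network is the symmetric-normalized Laplacian
L = I − D^(−1/2) A D^(−1/2), linearly rescaled to
L̃ = (2/λ_max) L − I so its spectrum lies in [−1, 1], the natural domain
of Chebyshev polynomials. λ_max is computed by Lanczos iteration
(`scipy.sparse.linalg.eigsh`, deterministic start vector, tolerance 1e−10;
dense solve below 33 nodes) — plain power iteration stalls on sphere-like
mesh graphs whose top eigenvalues are nearly degenerate, and the rescaled
spectrum must stay inside [−1, 1] to ~1e−8. An edgeless graph falls back
to λ_max = 2, the normalized-Laplacian upper bound, giving L̃ = −I.

Input features are vertex coordinates in millimetres, centered on the
origin and divided by 100. Centering uses the per-scan mean over all
structures fed to a network, preserving their relative positions.
Subcortical nodes carry 3 features; cortical nodes carry 6 (inner and
outer surface coordinates). When structures with different widths are
merged into one graph (disjoint union, block-diagonal adjacency), narrower
feature matrices are zero-padded on the right so a single convolution
stack handles both node types.

## Multiscale binary partitioning

Stride-2 1D pooling requires that consecutive feature rows be graph
neighbors. Node counts of all templates are powers of two, so each scale
admits a perfect pairing and no fake-node padding is needed. The pairing
is constructed by greedy heavy-edge matching (nodes visited by ascending
degree, ties by index; each pairs with its heaviest free neighbor),
followed by an alternating-path repair: an iterative DFS from each
unmatched node over (unmatched, matched) edge alternations, augmenting
when another free node is reached. The DFS performs no blossom
contraction; on triangulated sphere-like graphs this reaches a perfect
matching at every scale of every template (asserted by tests). A
maximum-cardinality blossom matching (networkx) is kept as a last resort,
and if even that leaves free nodes they are paired non-adjacently with a
logged warning. Pairs collapse into coarse nodes; coarse adjacency sums
cross-pair weights (heavy-edge aggregation). Orderings are assigned
top-down — the coarsest scale keeps index order, and the two children of
the coarse node at position *i* occupy positions 2*i*, 2*i*+1 — so pooling
is a plain reshape-and-reduce at every depth. Construction is
deterministic and seed-free.

## Network architecture

The regressor is a residual Chebyshev graph CNN. A Chebyshev filter of
order K computes Y = Σ_{k<K} T_k(L̃) X θ_k + b via the three-term
recursion (T_0 = I, T_1 = L̃, T_k = 2 L̃ T_{k−1} − T_{k−2}) applied to the
signal, never materializing dense polynomial matrices; the backward pass
evaluates the adjoint sum Σ_k T_k(L̃)(∂Y θ_kᵀ) with a Clenshaw recurrence.
The layout is:

1. Chebyshev convolution (order `K_first`, default 9; 64 filters) with a
   large receptive field, immediately followed by max pooling;
2. three pre-activation residual blocks
   (BN → ReLU → conv(K_block, 64) → BN → ReLU → conv + identity), each
   followed by max pooling — four pooling events in total;
3. batch normalization, a final convolution with 128 filters, and global
   average pooling over nodes;
4. a dual-branch soft-bin head: a dense(75) + ReLU branch emits 75
   nonnegative *bin ages* (input-dependent and fully learnable — no fixed
   bin grid), and a dense(75) + dropout(0.75) + Softmax branch emits bin
   probabilities; their elementwise product is combined by a final
   dense(1) layer into the age estimate.

Kernel orders per layer, batch size and residual-block internals are
configurable; the defaults (K_first 9, K_block 6, batch 16, standard
pre-activation blocks, max pooling) are reasonable choices where the
design was open, and mean pooling is available by configuration. Weights
use variance-scaling uniform initialization under a per-network seed.
All layers are implemented directly on NumPy arrays with hand-written
backward passes; gradient correctness is verified against numerical
differentiation in the test suite.

## Training, augmentation and inference

Training minimizes MSE plus an L2 weight penalty (λ = 1e−12, which is
deliberately near-vanishing) with RMSprop at initial learning rate 0.001.
The monitored metric is validation MAE, computed with rotation
test-time augmentation (TTA = 3, ±5°); the learning rate is divided by 10
after 15 non-improving epochs and training stops after 30, returning the
best-validation weights. Augmentation applies one random rotation per scan
(Euler Z-Y-X, each angle uniform in ±15° during training, ±5° during
validation and test) to every coordinate triple, preserving all inter-node
distances. The output-layer bias is initialized to the train-set mean age
so optimization starts from the no-information prediction rather than
zero; without this the first tens of epochs are spent climbing the output
scale. At test time an ensemble of independently seeded networks is
combined with TTA: every (network, augmented copy) estimate is kept
(20 × 20 = 400 per scan at full scale) and the arithmetic mean is the raw
prediction.

## Bias correction

Age regressors overestimate young and underestimate old subjects
(regression to the mean). The bias is estimated on validation residuals
(predicted − true) with LOWESS against true age (fraction 0.3, 2
robustness iterations) and the curve is parametrized by a cubic smoothing
spline (`make_smoothing_spline`, penalty λ = 0.1 — the "smoothing
parameter" is interpreted on the penalty scale) for fast evaluation;
outside the validation age range the bias is clamped to its boundary
values. At application time the reference age defaults to the raw
predicted age (in deployment the true age is the quantity being
estimated); a `reference_age` argument supports evaluation-style
correction at the true age. The workflow's statistical stage uses the
true-age-referenced variant: correction exists precisely to linearize the
prediction-vs-age calibration before group comparisons, and referencing at
the noisy predicted age re-introduces local calibration distortions at
desk-scale validation sizes. The predictions CSV records both variants.

## Statistical analyses

*Cross-sectional* (baseline scans, one per subject): per structure,
ordinary least squares of predicted age on true age and diagnosis with
healthy as the reference level, so the MCI and ADD coefficients are extra
predicted years at equal chronological age.

*Longitudinal*: subjects with repeated scans, healthy at baseline, at
least 70 at the last scan, grouped by last diagnosis into non-converters,
MCI converters and ADD converters. Per structure, a linear mixed model
with fixed effects for group (converter intercept offsets, non-converter
reference), baseline age, and one time-since-baseline slope per group (no
shared time main effect), plus correlated per-subject random intercept and
slope, fit by REML. The group main effects are essential: without them,
converter level differences leak into the slope coefficients through the
pooled design and corrupt the slope ratios. The *aging pace* of a
converter group is (β_group / β_non−converter − 1) × 100, a signed
percentage. statsmodels' default gradient optimizers often stall on these
REML surfaces, so a Powell retry runs on non-convergence, and a singular
random-effect covariance triggers a refit with uncorrelated random
effects. Inference on fixed effects and contrasts is normal-theory (Wald);
p-values are Benjamini–Hochberg FDR-corrected across all structures ×
contrasts of one analysis table.

## Synthetic data generator

Templates are golden-angle (Fibonacci) point lattices on the sphere,
triangulated by their convex hull, with exactly the per-structure node
counts (256–16,384, powers of two), placed at plausible anatomical
positions and scaled so mean edge lengths are below 2 units (subcortical)
and 3 units (cortical-scale) — matching the spacing constraints of real
surface templates. Each template owns a basis of smooth radial
displacement fields (low-order polynomial harmonics of the vertex
direction, unit RMS).

A subject's latent trajectory is
`effective_age(t) = baseline_age + aging_pace · t + age_offset`, and a
scan's mesh is the base mesh plus basis displacements affine in effective
age (gain 0.03 units/field/year, an optional quadratic term available to
bend the shape–age link) plus smooth basis-correlated noise (RMS 0.5
units, ≈2.7 years of age-equivalent noise per scan given the default
gain — comparable to the 3.3–3.6-year MAEs such models reach on real
data). Non-converters have offset 0 and pace 1. Converter effects default
to the longitudinal (pre-conversion) scale — offsets +1.2 (MCI) / +2.5
(ADD) years, paces ×1.12 / ×1.31 — because subjects still healthy at
baseline run only a few structural years ahead; cross-sectional cohorts of
already-diagnosed patients are simulated with larger offsets (≈+3.5 / +8
years) and `baseline_diagnosed=True`. The single-scan training pool draws
baseline ages from 45–95 (population-cohort-like), while longitudinal
groups draw from 62–82 (conversion cohorts are old-skewed, ≈72 ± 6): the
longitudinal cohort must sit inside the training-age span, otherwise
network extrapolation beyond the training support distorts pace ratios.
Converters switch diagnosis labels at a configurable fraction of
follow-up. All randomness flows through seeded generators; identical
config + seed reproduces manifests and meshes byte for byte, and every
cohort ships a truth table of its generating parameters.

What the generator does *not* emulate: anatomically realistic cortical
folding or subcortical shapes, scanner/site effects, heteroscedastic or
age-dependent noise, diagnosis-specific *spatial patterns* of deformation
(all effects act through the same smooth basis), and dropout/irregular
visit schedules. Passing tests therefore demonstrate that the machinery —
filters, pooling, training, correction, models — is correct and can
recover known effects from shape, not that the trained networks transfer
to real MRI-derived surfaces.

## Problem sizes and known limitations

The test suite and the acceptance script run desk-scale versions of the
full design: networks with 16 filters and 2 residual blocks on the
256-node structure, cohorts of 250–800 subjects, ensembles of 1–3 seeds
with TTA 2–5, and 100–200 simulation replicates for the statistical
recovery checks. At these sizes the end-to-end pipeline reaches held-out
MAE ≈ 2.4–2.6 years against a ≈12-year mean-age baseline (r ≈ 0.95) — the
age-noise floor of the generator — and recovers converter intercept
offsets within their confidence intervals.

Aging-pace *ratios* are the most delicate quantity: they divide two small
slopes, each scaled multiplicatively by the local slope of the network's
prediction-vs-age calibration curve over the effective-age band the group
traverses. The ADD converter band reaches ~4 years higher than the
non-converter band, into the upper region of the training-age support
where the trained calibration slope fluctuates (dips or overshoots of
±0.2/year between ensembles). At desk scale this distorts the recovered
ADD pace by up to ±30 percentage points in either direction, on top of a
sampling SE of ≈10 points at 300 longitudinal subjects; the MCI pace and
both converter intercept offsets are recovered well. Bias correction
fitted on a few hundred validation points cannot linearize the curve
finely enough to remove this. It is a scale limitation, not a model
defect: the real study trains on four orders of magnitude more scans and
fits the bias curve on thousands of validation subjects. The mixed-model inference is normal-theory rather
than a finite-sample (Satterthwaite/Kenward–Roger) approximation, which is
mildly anticonservative for small longitudinal cohorts.
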