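# Methods

This note documents the models implemented in `emolearn`, the choices
made where the design was genuinely open, and what the bundled synthetic
benchmark does and does not establish.

## Synthetic expression corpus

No public dataset backs the five-class task (excited, happy, calm,
frustrated, angry), so all recognition experiments run on a parametric
surrogate. Each class maps to a fixed facial geometry
(`class_prototype`): brow angle encodes tension (+15° excited … −25°
angry), eye openness encodes arousal (1.0 … 0.3), mouth curvature
encodes valence monotonically (+1.0 … −1.0) and mouth openness encodes
intensity. The renderer draws a head ellipse, two eyes whose height
follows eye openness, two brow bars rotated by the brow angle, and a
parabolic mouth arc whose bend *and* vertical position follow the
curvature — so a smile and a frown paint largely disjoint pixel regions,
which is what lets spatially localized features discriminate classes.

Degradations: i.i.d. Gaussian pixel noise (default sd 0.3 on the [0, 1]
intensity scale, a heavy corruption) and a random affine pose jitter
(translation and scale up to ±8 % by default). Defaults were chosen so
the corpus behaves like a usable small recognition benchmark: the
noise-free, jitter-free geometry is perfectly linearly separable, probe
accuracy decays monotonically as noise grows through {0, 0.1, 0.3, 0.6},
and at the default settings holistic matching is measurably hurt by
pose variation while localized features remain informative. The default
benchmark corpus is 5 × 50 images at 32 × 32, balanced round-robin over
five evaluation groups, generated from seed 20220811.

What the surrogate does **not** emulate: identity variation across
subjects, illumination, 3-D pose, photo-realistic texture. Accuracies
measured on it say nothing quantitative about real face corpora; they
establish the relative behaviour of the methods under controlled noise.

## LDA

Scatter matrices follow the standard definitions; each class mean
divides by its own count N_i (required for the identity S_m = S_w + S_b,
which `scatter_matrices` verifies to 1e−9 on every call). The Fisher
problem is solved as a symmetric generalized eigenproblem of (S_b,
S_w + λI). The ridge default λ = 1e−6 · tr(S_w)/d handles the singular
within-class scatter typical of image data (d ≫ n); when S_w is exactly
zero (degenerate noise-free corpora) the fallback is 1e−6 · tr(S_m)/d.
Eigenvector signs are fixed (largest-magnitude entry positive) so
refits are bit-reproducible under sample permutation. Classification
uses the shared-covariance Gaussian score with priors defaulting to
empirical class frequencies; ties break to the lexicographically first
label, as everywhere in the package.

## ICA

Whitening is PCA-based; directions below `eigenvalue_floor` (fraction of
the leading eigenvalue, default 1e−6) are dropped, and the retained
dimension is additionally capped at the number of requested components.
The cap matters: whitening equalises variances, so retaining the full
spectrum amplifies the sampling-noise floor to unit scale and the
fixed-point search locks onto spurious kurtotic noise directions.

The contrast is G(u) = log cosh u by default (a Gaussian-weighted
exponential is available); E{G(ν)} for the standard Gaussian reference
is computed once by adaptive quadrature and cached. Negentropy is used
only comparatively (screening restarts, diagnostics), so the
approximation's scale constants are fixed to one. Extraction is
deflationary — one unit vector at a time, Gram–Schmidt against previous
rows, stopping when successive iterates align to within `tol` (default
1e−6 for the generic API, 1e−4 in the image pipeline, where component
direction noise is dominated by sampling anyway). Non-convergence sets a
flag rather than raising: on Gaussian-dominated data the direction is
genuinely unidentifiable and a partial basis is still useful.

### Localized basis images

For face corpora the pipeline runs the same machinery on the transposed
matrix: pixels are the samples, images the mixed variables. The
extracted sources are then *basis images* — sparse, spatially localized
detectors (mouth region, brow edges, eye area) rather than holistic
eigenface-like modes — and an image is represented by its loadings
(pseudo-inverse of the basis applied to the mean-centred image). This
is the classic architecture for independent facial features, and it is
what makes single-component thresholds class-informative: each detector
responds to one local facial feature that one or two expressions
activate. The extraction restarts from `restarts` (default 5) seeded
initialisations and keeps the solution with the largest total
negentropy, i.e. the sparsest basis; this is standard FastICA practice
and removes most seed-to-seed variance.

## ICABoost

Screening: component j is admitted for class k iff strictly more than
half of the class-k samples lie beyond the threshold u_j(k), defined as
the midpoint between the class-k mean activation and the rest mean, with
polarity putting the class mean on the positive side. The midpoint rule
is parameter-free and scale-equivariant; the majority test mirrors the
weak-learner requirement of accuracy above chance.

Boosting is one-vs-rest per class over ±1 targets. The stump search is
exhaustive over admissible components, candidate thresholds (midpoints
of consecutive distinct activations plus ±∞) and both polarities; ties
break deterministically to (lower component, lower threshold, positive
polarity), with 1e−12 slack so float summation order cannot flip a tie.
A round whose best stump has weighted error ≥ 0.5 stops that class
early. Perfect stumps (ε = 0) get α capped via ε_min = 1/(2n), the
standard smoothing. Weights renormalise to Σ D = 1 every round. The
multi-class decision is the argmax of per-class signed vote sums; no
cross-class calibration is applied.

The comparison baseline assigns the class with the nearest mean
activation in Euclidean distance, after expressing both the query and
the class means relative to the calm-class mean (the neutral reference
frame). Note this subtraction leaves distances unchanged; it defines
the reference frame rather than altering the decision rule.

## Emotion-state model

Five discrete states with calm as the neutral centre. The HMM layer uses
the scaled forward algorithm (log-likelihood equals the log of the
summed final-step forward variables; zero-probability sequences return
−∞), one-step filtering for sessions, and Baum–Welch with seeded random
initialisation, optional restarts, and re-estimation of π, A, B from the
pair posteriors; the state posteriors are obtained from the same pair
posteriors, keeping the two consistent by construction. EM monotonicity
is asserted in tests to 1e−8 slack.

Affect dynamics: dE/dt = β(E* − E(t)) in closed form,
E(t) = E* + (E0 − E*)e^{−βt}, with β ≥ 0 per unit session step
(default 0.3 — affect halves in roughly two steps). TEA is the dot
product of the state posterior with valence weights C, default
(+1, +0.5, 0, −0.5, −1) — positive emotions positive, neutral zero.
Strategy bands are half-open: soothe below −0.25, encourage in
[−0.25, +0.25), none above; a learner exactly at the lower boundary is
encouraged, not soothed. Under these bands a perfectly calm posterior
(TEA = 0) receives gentle encouragement, a deliberate property of the
band definition.

In simulated sessions the observed TEA pulls E with gain 0.5 at each
capture, and a triggered intervention moves E halfway back toward E*.
Background mode samples every `interval` steps; frontend samples every
step. The face-detection stage of a deployed system is a pass-through
here — synthetic images are pre-cropped.

## Evaluation protocol

`evaluate` fits the unsupervised basis once on the full corpus, then
trains every classifier on the 70 % training fraction of each of 10
stratified splits and scores the held-out 30 %, reporting means over
splits. A single 75-image test set has ±5-point sampling noise, so the
averaged comparison is the meaningful one at this corpus size; per-split
numbers are retained in the report. The dataset is canonically re-sorted
on entry, making results invariant to manifest row order. All reported
problem sizes (250-image corpus, 20 components, 30 rounds, 10 splits)
were chosen as the package's standard benchmark scale.

## Survey tables

The bundled cohort tables are count tables; row percentages divide by
the full cohort (189) and round half-up to one decimal. Using the full
cohort as denominator for the severity rows makes the four bands sum to
~100 %, which is how the source tables are reported.

## Known limitations

- The surrogate corpus is schematic; absolute accuracies do not
  transfer to photographic data.
- One-vs-rest vote sums are uncalibrated across classes; a class with
  larger total α can dominate ambiguous samples.
- The HMM observes hard labels only; classifier confidences are
  discarded at the emotion layer.
- Deflationary ICA accumulates orthogonalisation error in late
  components; symmetric decorrelation is not implemented.
- E(t) is a single scalar valence, not a per-state quantity.
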