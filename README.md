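# emolearn

Affective computing for interactive health education: a tested Python
implementation of an expression-driven emotion-monitoring stack for
learning environments.

Adolescent mental-health screening is usually a one-off questionnaire. A
bundled cohort survey of 189 junior high school students illustrates the
motivation: only 18.5 % of the cohort is assessed as mentally healthy,
while 29.6 % falls in the most severe band. `emolearn` implements the
computational core of a system that instead monitors a learner's
emotional state continuously from facial expressions and selects an
intervention strategy (encourage / soothe / none) in response.

## What is inside

The stack has four statistical layers, each a library module:

**Fisher discriminant analysis** (`emolearn.lda`). Between-, within- and
mixed-class scatter matrices

S_b = Σᵢ Nᵢ (μᵢ − ā)(μᵢ − ā)ᵀ,  S_w = Σᵢ Σ_{j∈Cᵢ} (aⱼ − μᵢ)(aⱼ − μᵢ)ᵀ,  S_m = S_w + S_b,

the transformation W maximising |Wᵀ S_b W| / |Wᵀ S_w W| via a ridge-regularised
generalized eigenproblem, and a shared-covariance Gaussian classifier
score μ_cᵀ Σ⁻¹ a′ − ½ μ_cᵀ Σ⁻¹ μ_c + log p_c in the projected space.

**Negentropy-based ICA** (`emolearn.ica`). PCA whitening followed by the
fixed-point iteration w⁺ = E{x g(wᵀx)} − E{g′(wᵀx)} w with deflation;
independence is judged by the negentropy approximation
J_G(b) ≈ [E{G(b)} − E{G(ν)}]², G = log cosh by default. For face
corpora, `fit_basis_image_ica` runs the extraction on the transposed
matrix, producing sparse spatially *localized* independent basis images
(mouth, brows, eyes); an image is represented by its loadings on them.

**ICABoost** (`emolearn.boost`), the core classifier. Components are
screened per expression class by a majority test at the class-vs-rest
midpoint threshold u_j(k); admitted components feed one-vs-rest AdaBoost
with ±1 label encoding: each round picks the decision stump (component ×
threshold × polarity) minimising the weighted error ε_t (required
< 0.5), weights update as D′ᵢ ∝ Dᵢ exp(−α_t yᵢ h_t(xᵢ)) with
α_t = ½ ln((1 − ε_t)/ε_t), and the strong classifier predicts
argmax_k Σ_t α_t h_t. A Euclidean nearest-class-mean baseline in the
same ICA space (with the calm-class mean as neutral reference) provides
the comparison method.

**Emotion-state model** (`emolearn.emotion`). The learner's hidden state
lives on five basic emotions {excited, happy, calm, frustrated, angry};
a discrete HMM (π, A, B) links it to the classifier's outputs, with the
scaled forward algorithm for filtering and Baum–Welch re-estimation.
Affect is summarised by the TEA score tea(π) = π · C with valence
weights C = (+1, +0.5, 0, −0.5, −1), decays toward the ideal level as
dE/dt = β(E* − E(t)), and drives strategy selection by thresholds on TEA.

Because no public five-class schematic-expression benchmark exists, the
package ships a parametric generator (`emolearn.synthetic`): per-class
facial geometry prototypes rendered as 32×32 grayscale images with
Gaussian pixel noise and pose jitter, balanced across five evaluation
groups, plus ancestral sampling of HMM observation sequences.

## Worked example

```python
import emolearn as el

corpus = el.generate_dataset(n_per_class=50, size=32, noise_sd=0.3, seed=20220811)
reports = el.evaluate(corpus, split_seed=1, ica_seed=1, n_splits=10, m=20, T=30)
for method, rep in reports.items():
    print(f"{method:12s} mean accuracy {rep.macro:.3f}")
```

prints

```
icaboost     mean accuracy 0.849
ica_nearest  mean accuracy 0.772
lda          mean accuracy 0.915
```

i.e. on the 250-image surrogate corpus the boosted classifier recognises
the five expressions at 84.9 % (mean per-class accuracy over ten
stratified 70/30 splits) and beats the plain Euclidean ICA matcher by
about eight points — the feature-selective booster ignores the
pose-jitter components that corrupt the Euclidean metric. A monitoring
session then couples the classifier to the emotion layer:

```python
arts = el.run_training()
log = el.simulate_session(arts.features, arts.strong, T=30,
                          mode="background", interval=5, seed=3)
print(log.captures()[["t", "hidden", "obs", "tea", "E", "strategy"]])
```

```
 t  hidden     obs      tea        E  strategy
 0 excited excited 0.600000 0.300000      none
 5 excited excited 0.904110 0.485524      none
10   happy   happy 0.481723 0.295029      none
15    calm    calm 0.085141 0.037743 encourage
20    calm    calm 0.005549 0.003493 encourage
25 excited excited 0.621328 0.311054      none
```

Each capture row shows the true hidden emotion, the classified
expression, the TEA valence of the filtered posterior, the affect level
E(t) and the selected strategy. The `examples/` directory holds one
short script per capability; a thin CLI (`emolearn generate | train |
evaluate | simulate-session | summarize`) wraps the same functions.

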