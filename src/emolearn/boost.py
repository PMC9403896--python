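"""ICABoost: multi-class AdaBoost over independent-component features.

Each independent component can act as a one-dimensional threshold rule
(decision stump) for a given expression class.  Components are first
*screened*: component j is admitted for class k only if, at the
class-vs-rest midpoint threshold u_j(k), strictly more than half of the
class-k samples land on the class-k side — a majority test mirroring the
requirement that a weak classifier beat chance.  Boosting then runs
one-vs-rest per class with +-1 label encoding: each round selects the
stump (admissible component x threshold x polarity) with the lowest
weighted error, requires that error to be < 0.5, reweights the samples by
exp(-alpha * margin) and renormalises the weights to sum to one.  The
strong classifier scores each class by the signed alpha-weighted vote of
its stumps and predicts the argmax.

A nearest-class-mean baseline in the same ICA feature space, with the
neutral (calm) class mean as the reference frame, serves as the
comparison method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emotion import NEUTRAL_CLASS

__all__ = [
    "WeakClassifier",
    "SampleWeights",
    "StrongClassifier",
    "NoWeakLearnerError",
    "ScreeningError",
    "screen_components",
    "encode_labels",
    "best_weak",
    "update_weights",
    "train_icaboost",
    "predict",
    "NearestMeanClassifier",
    "ica_nearest_baseline",
]


class NoWeakLearnerError(RuntimeError):
    """Raised when no stump achieves weighted error < 0.5."""


class ScreeningError(RuntimeError):
    """Raised when a class admits no component at screening time."""


@dataclass(frozen=True)
class WeakClassifier:
    """A decision stump on one ICA component for one class.

    Outputs +1 when ``polarity * (activation - threshold) > 0``, else -1.
    ``alpha`` is the boosting round weight 1/2 ln((1-eps)/eps) and
    ``weighted_error`` the weighted 0/1 error eps at selection time.
    """

    component_j: int
    class_k: str
    threshold: float
    polarity: int
    alpha: float
    weighted_error: float

    def decide(self, activations: np.ndarray) -> np.ndarray:
        """Signed +-1 output for each row of ``activations``."""
        a = np.atleast_2d(activations)[:, self.component_j]
        return np.where(self.polarity * (a - self.threshold) > 0, 1.0, -1.0)

    def to_dict(self) -> dict:
        return {
            "component_j": self.component_j,
            "class_k": self.class_k,
            "threshold": self.threshold,
            "polarity": self.polarity,
            "alpha": self.alpha,
            "weighted_error": self.weighted_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeakClassifier":
        return cls(
            component_j=int(d["component_j"]),
            class_k=str(d["class_k"]),
            threshold=float(d["threshold"]),
            polarity=int(d["polarity"]),
            alpha=float(d["alpha"]),
            weighted_error=float(d["weighted_error"]),
        )


@dataclass
class SampleWeights:
    """Normalised per-sample boosting distribution D_t."""

    D: np.ndarray
    round_t: int = 0

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < 0):
            raise ValueError("sample weights must be non-negative")
        if abs(self.D.sum() - 1.0) > 1e-12:
            raise ValueError("sample weights must sum to 1")

    @classmethod
    def uniform(cls, n: int) -> "SampleWeights":
        return cls(D=np.full(n, 1.0 / n), round_t=0)


@dataclass(frozen=True)
class ScreeningResult:
    """Components admitted for one class, with the screening thresholds
    u_j(k) and polarities used by the majority test."""

    class_k: str
    components: np.ndarray  # admitted component indices, ascending
    u: np.ndarray  # screening threshold per admitted component
    polarity: np.ndarray  # +-1 per admitted component


def screen_components(activations, labels, class_k: str) -> ScreeningResult:
    """Admit components that pass the class-k majority test.

    For component j the screening threshold u_j(k) is the midpoint of the
    class-k mean activation and the rest mean, with polarity chosen so the
    class-k mean lies on the "1" side.  The component is admitted iff the
    number of class-k samples with indicator f = 1 (strictly beyond the
    threshold) strictly exceeds Q_k / 2.
    """
    A = np.asarray(activations, dtype=float)
    y = np.asarray(labels).astype(str)
    mask = y == class_k
    Q_k = int(mask.sum())
    if Q_k == 0:
        raise ValueError(f"class {class_k!r} not present in labels")
    if Q_k == len(y):
        raise ValueError(f"class {class_k!r} needs at least one rest sample")
    mean_k = A[mask].mean(axis=0)
    mean_rest = A[~mask].mean(axis=0)
    u = (mean_k + mean_rest) / 2.0
    pol = np.where(mean_k > mean_rest, 1.0, -1.0)
    f = pol[None, :] * (A[mask] - u[None, :]) > 0  # strict inequality
    passed = f.sum(axis=0) > Q_k / 2.0
    idx = np.flatnonzero(passed)
    return ScreeningResult(
        class_k=class_k, components=idx, u=u[idx], polarity=pol[idx].astype(int)
    )


def encode_labels(labels, class_k: str) -> np.ndarray:
    """+-1 encoding: +1 where the label equals class_k, else -1."""
    y = np.asarray(labels).astype(str)
    return np.where(y == class_k, 1.0, -1.0)


def _alpha_from_error(eps: float, n: int) -> float:
    # cap alpha for perfect stumps with the standard smoothing eps_min = 1/(2n)
    eps_min = 1.0 / (2.0 * n)
    eps_eff = min(max(eps, eps_min), 1.0 - eps_min)
    return 0.5 * np.log((1.0 - eps_eff) / eps_eff)


def best_weak(
    activations,
    targets,
    weights: SampleWeights,
    screening: ScreeningResult,
    class_k: str | None = None,
) -> WeakClassifier:
    """Exhaustive stump search over admissible components.

    Candidate thresholds on each component are the midpoints between
    consecutive distinct sorted activations plus -inf and +inf; both
    polarities are tried.  Returns the minimiser of the weighted 0/1
    error; ties break to the lower component index, then the lower
    threshold, then polarity +1.  Raises :class:`NoWeakLearnerError` if
    the minimum weighted error is >= 0.5 (the admission rule).
    """
    A = np.asarray(activations, dtype=float)
    t = np.asarray(targets, dtype=float)
    D = weights.D
    if abs(D.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be normalised")
    n = A.shape[0]
    best = None  # (err, comp, threshold, polarity)
    for j in screening.components:
        a = A[:, j]
        order = np.argsort(a, kind="stable")
        a_s, t_s, D_s = a[order], t[order], D[order]
        pos_w = np.where(t_s > 0, D_s, 0.0)
        neg_w = np.where(t_s < 0, D_s, 0.0)
        cum_pos = np.concatenate([[0.0], np.cumsum(pos_w)])
        cum_neg = np.concatenate([[0.0], np.cumsum(neg_w)])
        total_pos, total_neg = cum_pos[-1], cum_neg[-1]
        # cut after position i (i = 0 means "before everything": thr = -inf)
        cuts = [0] + [i + 1 for i in range(n - 1) if a_s[i + 1] > a_s[i]] + [n]
        for c in cuts:
            if c == 0:
                thr = -np.inf
            elif c == n:
                thr = np.inf
            else:
                thr = (a_s[c - 1] + a_s[c]) / 2.0
            # polarity +1: predict +1 where a > thr
            err_p = cum_pos[c] + (total_neg - cum_neg[c])
            err_m = (total_pos - cum_pos[c]) + cum_neg[c]
            for pol, err in ((1, err_p), (-1, err_m)):
                # 1e-12 slack: cumulative-sum and direct summation routes
                # differ at float precision, and ties must break to the
                # earlier candidate (lower component, lower threshold)
                if best is None or err < best[0] - 1e-12:
                    best = (err, int(j), float(thr), pol)
    if best is None or best[0] >= 0.5:
        raise NoWeakLearnerError(
            f"no stump beats chance for class {class_k or screening.class_k!r}"
            f" (best weighted error {best[0]:.3f})" if best else "no candidate stumps"
        )
    err, j, thr, pol = best
    return WeakClassifier(
        component_j=j,
        class_k=class_k or screening.class_k,
        threshold=thr,
        polarity=pol,
        alpha=_alpha_from_error(err, n),
        weighted_error=float(err),
    )


def update_weights(
    weights: SampleWeights, weak: WeakClassifier, correctness
) -> SampleWeights:
    """Boosting reweighting with renormalisation.

    ``correctness`` is the margin target_i * h_i in {+1, -1}.  The new
    distribution is D'_i proportional to D_i exp(-alpha * correctness_i),
    renormalised to sum to one.
    """
    c = np.asarray(correctness, dtype=float)
    D_new = weights.D * np.exp(-weak.alpha * c)
    s = D_new.sum()
    if s <= 0:
        raise ValueError("all sample weights vanished during update")
    return SampleWeights(D=D_new / s, round_t=weights.round_t + 1)


@dataclass
class StrongClassifier:
    """One-vs-rest boosted ensemble: an ordered stump list per class."""

    classes: list[str]
    stumps: dict[str, list[WeakClassifier]]
    T: int
    ica_ref: str = ""

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "stumps": {
                k: [w.to_dict() for w in v] for k, v in self.stumps.items()
            },
            "T": self.T,
            "ica_ref": self.ica_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrongClassifier":
        return cls(
            classes=list(d["classes"]),
            stumps={
                k: [WeakClassifier.from_dict(w) for w in v]
                for k, v in d["stumps"].items()
            },
            T=int(d["T"]),
            ica_ref=str(d.get("ica_ref", "")),
        )


def train_icaboost(
    activations, labels, T: int, seed: int | None = None, ica_ref: str = ""
) -> StrongClassifier:
    """Train the one-vs-rest boosted classifier.

    For every class: screen the components, then run up to T rounds of
    stump selection and weight updates on the +-1 encoded targets.  A
    round that finds no weak learner stops that class early, keeping the
    stumps found so far.  A class admitting no component at screening is
    an error naming the class.  Training is deterministic given its
    inputs; ``seed`` is accepted for interface symmetry and unused.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    A = np.asarray(activations, dtype=float)
    classes = sorted(set(np.asarray(labels).astype(str)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    stumps: dict[str, list[WeakClassifier]] = {}
    for class_k in classes:
        screening = screen_components(A, labels, class_k)
        if screening.components.size == 0:
            raise ScreeningError(
                f"no admissible component for class {class_k!r} at screening"
            )
        targets = encode_labels(labels, class_k)
        weights = SampleWeights.uniform(A.shape[0])
        learned: list[WeakClassifier] = []
        for _ in range(T):
            try:
                weak = best_weak(A, targets, weights, screening)
            except NoWeakLearnerError:
                break
            preds = weak.decide(A)
            weights = update_weights(weights, weak, targets * preds)
            learned.append(weak)
        if not learned:
            raise ScreeningError(
                f"class {class_k!r} produced no weak classifier in round 1"
            )
        stumps[class_k] = learned
    return StrongClassifier(classes=classes, stumps=stumps, T=T, ica_ref=ica_ref)


def predict(strong: StrongClassifier, activations) -> tuple[list[str], np.ndarray]:
    """Classify activation rows.

    Returns ``(labels, confidences)`` where ``confidences[i, c]`` is the
    signed vote sum_t alpha_t h_t for class c on sample i; the label is
    the argmax with lexicographic tie-break (classes are stored sorted).
    Accepts a single m-vector too (returns one label and a (1, c) array).
    """
    A = np.atleast_2d(np.asarray(activations, dtype=float))
    m_needed = max(
        (w.component_j for v in strong.stumps.values() for w in v), default=0
    )
    if A.shape[1] <= m_needed:
        raise ValueError(
            f"activations have {A.shape[1]} components; classifier needs "
            f"component index {m_needed}"
        )
    conf = np.zeros((A.shape[0], len(strong.classes)))
    for c, class_k in enumerate(strong.classes):
        for w in strong.stumps[class_k]:
            conf[:, c] += w.alpha * w.decide(A)
    labels = [strong.classes[i] for i in np.argmax(conf, axis=1)]
    return labels, conf


@dataclass
class NearestMeanClassifier:
    """Nearest class-mean classifier in ICA activation space.

    The neutral (calm) class mean acts as the reference frame: both the
    query and the stored class means are expressed relative to it before
    the Euclidean distance is taken.  Ties break lexicographically.
    """

    classes: list[str]
    means: np.ndarray  # (c, m), relative to the neutral reference
    neutral_ref: np.ndarray  # (m,)

    def predict(self, activations) -> list[str]:
        A = np.atleast_2d(np.asarray(activations, dtype=float)) - self.neutral_ref
        d2 = ((A[:, None, :] - self.means[None, :, :]) ** 2).sum(axis=2)
        return [self.classes[i] for i in np.argmin(d2, axis=1)]


def ica_nearest_baseline(
    activations, labels, neutral_class: str = NEUTRAL_CLASS
) -> NearestMeanClassifier:
    """Fit the Euclidean nearest-class-mean baseline with the neutral
    class mean subtracted as reference."""
    A = np.asarray(activations, dtype=float)
    y = np.asarray(labels).astype(str)
    classes = sorted(set(y))
    if neutral_class not in classes:
        raise ValueError(f"neutral class {neutral_class!r} missing from labels")
    neutral = A[y == neutral_class].mean(axis=0)
    means = np.vstack([A[y == c].mean(axis=0) - neutral for c in classes])
    return NearestMeanClassifier(classes=classes, means=means, neutral_ref=neutral)
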