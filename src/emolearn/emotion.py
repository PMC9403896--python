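"""Emotion-state modelling for interactive learning sessions.

The learner's affect is modelled as a discrete hidden state over the five
expression classes.  A hidden Markov model links the (noisy) expression
labels emitted by the face classifier to the underlying emotional state;
the filtered state posterior is summarised into a scalar valence score
(TEA, "teaching emotional affect"), which drives the choice of an
intervention strategy.  Between observations the scalar affect level
relaxes exponentially toward an ideal set point (emotion dilution).

Components:

* :class:`EmotionStateSpace` — a probability vector over the five states.
* :class:`HMMParams` — (pi, A, B) of a discrete-emission HMM, with the
  :func:`forward` algorithm and :func:`baum_welch` re-estimation.
* :func:`decay` — closed-form solution of dE/dt = beta (E* - E(t)).
* :func:`tea` — dot product of the state posterior with per-state valence
  weights.
* :func:`select_strategy` — threshold rule mapping TEA to an intervention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASSES",
    "NEUTRAL_CLASS",
    "DEFAULT_VALENCE",
    "EmotionStateSpace",
    "HMMParams",
    "ValenceWeights",
    "EmotionTrajectory",
    "validate_state_space",
    "forward",
    "forward_step",
    "baum_welch",
    "decay",
    "tea",
    "select_strategy",
]

#: The five basic emotional states, ordered from most positive to most
#: negative valence.  "calm" is the designated neutral state.
CLASSES: tuple[str, ...] = ("excited", "happy", "calm", "frustrated", "angry")

NEUTRAL_CLASS = "calm"

#: Default per-state valence weights C: positive states get positive weight,
#: negative states negative weight, the neutral state zero.
DEFAULT_VALENCE: dict[str, float] = {
    "excited": 1.0,
    "happy": 0.5,
    "calm": 0.0,
    "frustrated": -0.5,
    "angry": -1.0,
}

_PROB_TOL = 1e-6


@dataclass(frozen=True)
class EmotionStateSpace:
    """Probability distribution over the discrete emotional states.

    ``probs[i]`` is the probability of ``states[i]``; the vector is
    normalised on construction via :func:`validate_state_space`.
    """

    states: tuple[str, ...]
    probs: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probs)}


def validate_state_space(
    probs, states: tuple[str, ...] = CLASSES
) -> EmotionStateSpace:
    """Validate and normalise a state-probability vector.

    Raises ``ValueError`` if any entry is negative or the sum deviates from
    one by more than 1e-6.  The returned object is exactly normalised.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.shape[0] != len(states):
        raise ValueError(
            f"expected {len(states)} state probabilities, got shape {p.shape}"
        )
    if np.any(p < 0):
        raise ValueError(f"negative state probability in {p.tolist()}")
    total = p.sum()
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"state probabilities sum to {total}, not 1")
    return EmotionStateSpace(states=tuple(states), probs=p / total)


@dataclass(frozen=True)
class ValenceWeights:
    """Per-state scalar valence weights C used by the TEA score."""

    states: tuple[str, ...] = CLASSES
    weights: tuple[float, ...] = tuple(DEFAULT_VALENCE[s] for s in CLASSES)

    def __post_init__(self):
        if len(self.weights) != len(self.states):
            raise ValueError("one weight per state required")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _check_stochastic(v: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if np.any(np.asarray(v) < -tol):
        raise ValueError(f"{name} has negative entries")
    sums = np.asarray(v).sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError(f"rows of {name} must sum to 1 (got {sums})")


@dataclass
class HMMParams:
    """Parameters (pi, A, B) of a discrete-emission hidden Markov model.

    N hidden emotional states, M observation symbols (the classifier's
    output labels).  ``pi`` is the initial distribution, ``A[i, j]`` the
    transition probability i -> j, and ``B[i, m]`` the probability that
    state i emits symbol m.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        n = self.pi.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {self.A.shape}")
        if self.B.shape[0] != n:
            raise ValueError("B must have one row per state")
        _check_stochastic(self.pi, "pi")
        _check_stochastic(self.A, "A")
        _check_stochastic(self.B, "B")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(pi=np.array(d["pi"]), A=np.array(d["A"]), B=np.array(d["B"]))


def _check_symbols(hmm: HMMParams, obs: np.ndarray) -> None:
    if obs.size and (obs.min() < 0 or obs.max() >= hmm.n_symbols):
        raise ValueError(
            f"observation symbols must lie in [0, {hmm.n_symbols}), got "
            f"range [{obs.min()}, {obs.max()}]"
        )


def forward(hmm: HMMParams, obs) -> tuple[float, np.ndarray]:
    """Scaled forward algorithm.

    Returns ``(loglik, alpha)`` where ``alpha[t]`` is the *normalised*
    forward distribution P(state_t | o_1..o_t) and ``loglik`` is
    log P(O | lambda), the log of the summed final-step forward variables.
    A sequence with zero likelihood returns ``-inf``.
    """
    obs = np.asarray(obs, dtype=int)
    _check_symbols(hmm, obs)
    T = obs.shape[0]
    alpha = np.zeros((T, hmm.n_states))
    loglik = 0.0
    for t in range(T):
        if t == 0:
            a = hmm.pi * hmm.B[:, obs[0]]
        else:
            a = (alpha[t - 1] @ hmm.A) * hmm.B[:, obs[t]]
        scale = a.sum()
        if scale == 0.0:
            alpha[t:] = 0.0
            return float("-inf"), alpha
        alpha[t] = a / scale
        loglik += np.log(scale)
    return float(loglik), alpha


def forward_step(
    hmm: HMMParams, posterior: np.ndarray | None, symbol: int
) -> np.ndarray:
    """One step of forward filtering: update the state posterior with one
    observed symbol.  ``posterior=None`` starts from the initial
    distribution pi."""
    obs = np.asarray([symbol], dtype=int)
    _check_symbols(hmm, obs)
    if posterior is None:
        a = hmm.pi * hmm.B[:, symbol]
    else:
        a = (np.asarray(posterior, dtype=float) @ hmm.A) * hmm.B[:, symbol]
    s = a.sum()
    if s == 0.0:
        # impossible observation under the model: fall back to uniform
        return np.full(hmm.n_states, 1.0 / hmm.n_states)
    return a / s


def _forward_backward(hmm: HMMParams, obs: np.ndarray):
    """Scaled forward-backward pass; returns (loglik, gamma, xi_sum).

    gamma[t, i] = P(state_t = i | O); xi_sum[i, j] = sum_t xi_t(i, j).
    The per-step state posterior gamma is obtained by summing the joint
    pair posteriors xi over the successor state, so the two are consistent
    by construction.
    """
    T = obs.shape[0]
    N = hmm.n_states
    alpha = np.zeros((T, N))
    scales = np.zeros(T)
    for t in range(T):
        a = hmm.pi * hmm.B[:, obs[0]] if t == 0 else (alpha[t - 1] @ hmm.A) * hmm.B[:, obs[t]]
        scales[t] = a.sum()
        if scales[t] == 0.0:
            raise FloatingPointError("zero-likelihood sequence in Baum-Welch")
        alpha[t] = a / scales[t]
    beta = np.zeros((T, N))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (hmm.A @ (hmm.B[:, obs[t + 1]] * beta[t + 1])) / scales[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((N, N))
    for t in range(T - 1):
        xi = (
            alpha[t][:, None]
            * hmm.A
            * (hmm.B[:, obs[t + 1]] * beta[t + 1])[None, :]
        ) / scales[t + 1]
        xi_sum += xi
    return float(np.log(scales).sum()), gamma, xi_sum


def _random_hmm(N: int, M: int, rng: np.random.Generator) -> HMMParams:
    def rows(shape):
        r = rng.uniform(0.1, 1.0, size=shape)
        return r / r.sum(axis=-1, keepdims=True)

    return HMMParams(pi=rows(N), A=rows((N, N)), B=rows((N, M)))


def baum_welch(
    sequences,
    N: int,
    M: int,
    iters: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 1,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch (EM) estimation of an N-state, M-symbol HMM.

    ``sequences`` is a list of integer symbol sequences.  Parameters are
    initialised at random (seeded); EM runs until the log-likelihood gain
    drops below ``tol`` or ``iters`` iterations.  With ``n_init > 1`` the
    fit is restarted and the highest-likelihood solution returned.

    Returns ``(params, loglik_trace)``; the trace is non-decreasing up to
    numerical slack — each EM step can only improve the data likelihood.
    """
    seqs = [np.asarray(s, dtype=int) for s in sequences]
    if not seqs or all(s.size == 0 for s in seqs):
        raise ValueError("baum_welch requires at least one non-empty sequence")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    for s in seqs:
        if s.size and (s.min() < 0 or s.max() >= M):
            raise ValueError("observation symbol out of range")

    rng = np.random.default_rng(seed)
    best: tuple[HMMParams, list[float]] | None = None
    for _ in range(n_init):
        hmm = _random_hmm(N, M, rng)
        trace: list[float] = []
        for _ in range(iters):
            ll_total = 0.0
            pi_acc = np.zeros(N)
            xi_acc = np.zeros((N, N))
            gamma_trans_acc = np.zeros(N)  # sum of gamma over t < T-1
            emis_num = np.zeros((N, M))
            gamma_all_acc = np.zeros(N)
            for s in seqs:
                if s.size == 0:
                    continue
                ll, gamma, xi_sum = _forward_backward(hmm, s)
                ll_total += ll
                pi_acc += gamma[0]
                xi_acc += xi_sum
                gamma_trans_acc += gamma[:-1].sum(axis=0) if s.size > 1 else 0.0
                for m in range(M):
                    emis_num[:, m] += gamma[s == m].sum(axis=0)
                gamma_all_acc += gamma.sum(axis=0)
            trace.append(ll_total)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break
            pi_new = pi_acc / pi_acc.sum()
            A_new = np.where(
                gamma_trans_acc[:, None] > 0,
                xi_acc / np.maximum(gamma_trans_acc[:, None], 1e-300),
                hmm.A,
            )
            A_new /= A_new.sum(axis=1, keepdims=True)
            B_new = np.where(
                gamma_all_acc[:, None] > 0,
                emis_num / np.maximum(gamma_all_acc[:, None], 1e-300),
                hmm.B,
            )
            B_new /= B_new.sum(axis=1, keepdims=True)
            hmm = HMMParams(pi=pi_new, A=A_new, B=B_new)
        if best is None or trace[-1] > best[1][-1]:
            best = (hmm, trace)
    assert best is not None
    return best


def decay(E0: float, E_star: float, beta: float, t):
    """Emotion dilution: closed-form solution of dE/dt = beta (E* - E(t)).

    E(t) = E* + (E0 - E*) exp(-beta t).  ``t`` may be a scalar or array of
    non-negative times; ``beta`` is the fade factor per unit time (>= 0).
    """
    if beta < 0:
        raise ValueError("fade factor beta must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = E_star + (E0 - E_star) * np.exp(-beta * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass
class EmotionTrajectory:
    """Scalar affect E(t) relaxing toward the ideal level E* with fade
    factor beta, plus the TEA score recorded at each sample time."""

    E_star: float
    E0: float
    beta: float
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tea_series: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def from_decay(cls, E0: float, E_star: float, beta: float, times):
        times = np.asarray(times, dtype=float)
        return cls(
            E_star=E_star,
            E0=E0,
            beta=beta,
            times=times,
            values=decay(E0, E_star, beta, times),
        )


def tea(space: EmotionStateSpace, C: ValenceWeights | None = None) -> float:
    """TEA score: dot product of the state posterior with the valence
    weights C.  Positive values indicate positive affect."""
    if C is None:
        C = ValenceWeights()
    if C.states != space.states:
        raise ValueError("valence weights and state space use different states")
    return float(space.probs @ C.as_array())


def select_strategy(
    tea_value: float, lo: float = -0.25, hi: float = 0.25
) -> str:
    """Map a TEA score to an intervention strategy.

    Half-open bands: ``soothe`` for tea < lo, ``encourage`` for
    lo <= tea < hi, ``none`` for tea >= hi.  A learner at the lower
    boundary exactly is encouraged, not soothed.
    """
    if lo >= hi:
        raise ValueError("thresholds must satisfy lo < hi")
    if tea_value < lo:
        return "soothe"
    if tea_value < hi:
        return "encourage"
    return "none"
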