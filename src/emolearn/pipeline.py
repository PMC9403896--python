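"""End-to-end orchestration of the expression-recognition stack.

This module wires the pieces together the way the monitoring system uses
them: generate (or load) a labelled face corpus, whiten and extract ICA
components, train the boosted classifier plus the LDA and nearest-mean
baselines, evaluate them as per-class x per-group accuracy tables, and
run a simulated monitoring session in which an emotion HMM drives face
renders, the classifier's outputs update the state posterior, and the
TEA score selects intervention strategies while the scalar affect level
decays between captures.

It also bundles the printed cohort survey tables (189 junior high school
students, three grades) and the row-percentage summary used to report
them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import boost as _boost
from . import ica as _ica
from . import lda as _lda
from .emotion import (
    CLASSES,
    HMMParams,
    ValenceWeights,
    decay,
    forward_step,
    select_strategy,
    tea,
    validate_state_space,
)
from .synthetic import LabeledImageDataset, class_prototype, generate_dataset, load_dataset, render_face

__all__ = [
    "SurveyTable",
    "MENTAL_HEALTH_TABLE",
    "DEMOGRAPHICS_TABLE",
    "COHORT_SIZE",
    "summarize_survey",
    "default_config",
    "validate_config",
    "TrainingArtifacts",
    "run_training",
    "stratified_split",
    "EvaluationReport",
    "evaluate",
    "default_emotion_hmm",
    "SessionLog",
    "simulate_session",
]


# ---------------------------------------------------------------------------
# Survey tables


@dataclass(frozen=True)
class SurveyTable:
    """A small printed count table: rows x columns of non-negative ints."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        for row in self.counts:
            if len(row) != len(self.col_labels):
                raise ValueError("each count row must match the column labels")
            if any(c < 0 for c in row):
                raise ValueError("counts must be non-negative")
        if len(self.counts) != len(self.row_labels):
            raise ValueError("one count row per row label required")

    def row_sums(self) -> dict[str, int]:
        return {r: sum(c) for r, c in zip(self.row_labels, self.counts)}

    def total(self) -> int:
        return sum(sum(c) for c in self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.counts), index=list(self.row_labels), columns=list(self.col_labels)
        )


#: Cohort size of the school survey the tables come from.
COHORT_SIZE = 189

#: Mental-health status of the surveyed students by grade.
MENTAL_HEALTH_TABLE = SurveyTable(
    row_labels=("healthy", "mildly severe", "moderately severe", "severely severe"),
    col_labels=("first grade", "second grade", "third grade"),
    counts=((11, 11, 13), (15, 17, 20), (16, 14, 16), (17, 19, 20)),
)

#: Basic demographics of the surveyed cohort (single count column).
DEMOGRAPHICS_TABLE = SurveyTable(
    row_labels=("age 13-15", "age 15-17", "male", "female"),
    col_labels=("count",),
    counts=((90,), (99,), (95,), (94,)),
)


def summarize_survey(table: SurveyTable, denominator: int) -> dict[str, float]:
    """Row percentages of a survey table: 100 * row_sum / denominator,
    rounded half-up to one decimal place (matching printed percentages)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    out = {}
    for label, s in table.row_sums().items():
        pct = Decimal(100 * s) / Decimal(denominator)
        out[label] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


# ---------------------------------------------------------------------------
# Training configuration


def default_config() -> dict:
    """The default experiment configuration: the 5x50-image surrogate
    corpus, 20 ICA components and 30 boosting rounds per class."""
    return {
        "generator": {
            "n_per_class": 50,
            "size": 32,
            "noise_sd": 0.3,
            "n_groups": 5,
            "seed": 20220811,
            "jitter": 0.08,
        },
        "manifest": None,
        "ica": {
            "m": 20,
            "tol": 1e-4,
            "max_iter": 400,
            "seed": 0,
            "contrast": "logcosh",
            "eigenvalue_floor": 1e-6,
            "restarts": 5,
        },
        "boost": {"T": 30},
        "lda": {"r": 4, "ridge": None},
        "evaluation": {"train_fraction": 0.7, "n_splits": 10},
    }


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys.

    Raises ``ValueError`` listing every offending key.
    """
    merged = default_config()
    bad: list[str] = []
    for key, val in config.items():
        if key not in merged:
            bad.append(key)
            continue
        if key == "manifest":
            merged[key] = val
        elif isinstance(val, dict):
            for sub, sv in val.items():
                if sub not in merged[key]:
                    bad.append(f"{key}.{sub}")
                else:
                    merged[key][sub] = sv
        else:
            bad.append(key)
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class TrainingArtifacts:
    """Everything produced by one training run."""

    config: dict
    dataset: LabeledImageDataset
    features: _ica.BasisImageICA
    strong: _boost.StrongClassifier
    lda_model: _lda.LDAModel
    baseline: _boost.NearestMeanClassifier
    activations: np.ndarray
    metrics: dict


def _load_or_generate(config: dict) -> LabeledImageDataset:
    if config.get("manifest"):
        return load_dataset(config["manifest"])
    return generate_dataset(**config["generator"])


def run_training(config: dict | None = None, out_dir=None) -> TrainingArtifacts:
    """Full training path: corpus -> whiten -> extract localized ICA
    basis images -> project to loadings -> train ICABoost, with LDA and
    nearest-mean baselines fitted on the same activations.

    With ``out_dir`` set, the three model JSONs and a metrics JSON
    (including all seeds, a config hash and the package version) are
    written; a rerun with the same config reproduces them bit-exactly.
    """
    from . import __version__

    config = validate_config(config or {})
    dataset = _load_or_generate(config)
    X = dataset.flat()
    features = _ica.fit_basis_image_ica(X, **config["ica"])
    acts = features.transform(X)
    strong = _boost.train_icaboost(
        acts, dataset.labels, T=config["boost"]["T"], ica_ref=_config_hash(config)
    )
    lda_model = _lda.fit_lda(acts, dataset.labels, **config["lda"])
    baseline = _boost.ica_nearest_baseline(acts, dataset.labels)

    y = np.asarray(dataset.labels)
    pred_boost, _ = _boost.predict(strong, acts)
    metrics = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "seeds": {
            "generator": config["generator"]["seed"],
            "ica": config["ica"]["seed"],
        },
        "n_images": len(dataset),
        "ica_converged": features.ica.converged,
        "train_accuracy": {
            "icaboost": float(np.mean(np.asarray(pred_boost) == y)),
            "lda": float(np.mean(np.asarray(_lda.lda_predict(lda_model, acts)) == y)),
            "ica_nearest": float(np.mean(np.asarray(baseline.predict(acts)) == y)),
        },
        "face_detection": "pass-through (synthetic images are pre-cropped)",
    }
    arts = TrainingArtifacts(
        config=config,
        dataset=dataset,
        features=features,
        strong=strong,
        lda_model=lda_model,
        baseline=baseline,
        activations=acts,
        metrics=metrics,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, payload in (
            ("ica_model.json", features.to_dict()),
            ("icaboost_model.json", strong.to_dict()),
            ("lda_model.json", lda_model.to_dict()),
            ("metrics.json", metrics),
        ):
            (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return arts


# ---------------------------------------------------------------------------
# Evaluation


def stratified_split(
    dataset: LabeledImageDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split on the class labels.

    Within each class the samples are put in a canonical order (sorted by
    subject id then group) before the seeded shuffle, so the split is
    invariant to the row order of the manifest.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(dataset.labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cl in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == cl)
        key = sorted(range(len(idx)), key=lambda i: (dataset.subject_id[idx[i]], dataset.group[idx[i]]))
        idx = idx[np.asarray(key, dtype=int)]
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        if n_train < 2 or len(idx) - n_train < 2:
            raise ValueError(f"class {cl!r} needs >= 2 samples in each split")
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


@dataclass
class EvaluationReport:
    """Per (class x group) accuracy table for one method.

    ``cells`` holds the held-out accuracy fraction per class row and
    group column (averaged over splits; NaN where a cell is always
    empty); ``overall`` is the count-weighted mean of the cells (equal to
    plain accuracy), ``macro`` the unweighted mean of the per-class
    accuracies.  With ``n_splits > 1`` all quantities are means over the
    repeated stratified splits and ``per_split`` holds the per-split
    overall/macro accuracies.
    """

    method: str
    cells: pd.DataFrame
    cell_counts: pd.DataFrame
    per_class: pd.Series
    overall: float
    macro: float
    split_seed: int
    n_splits: int = 1
    per_split: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index_label="class")


def _report_from_predictions(
    method: str, y_true, y_pred, groups, split_seed: int
) -> EvaluationReport:
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    groups = np.asarray(groups)
    classes = sorted(set(y_true.tolist()))
    group_ids = sorted(set(groups.tolist()))
    cells = pd.DataFrame(index=classes, columns=group_ids, dtype=float)
    counts = pd.DataFrame(0, index=classes, columns=group_ids, dtype=int)
    for cl in classes:
        for g in group_ids:
            mask = (y_true == cl) & (groups == g)
            counts.loc[cl, g] = int(mask.sum())
            if mask.any():
                cells.loc[cl, g] = float(np.mean(y_pred[mask] == y_true[mask]))
    per_class = pd.Series(
        {cl: float(np.mean(y_pred[y_true == cl] == cl)) for cl in classes}
    )
    overall = float(np.mean(y_pred == y_true))
    return EvaluationReport(
        method=method,
        cells=cells,
        cell_counts=counts,
        per_class=per_class,
        overall=overall,
        macro=float(per_class.mean()),
        split_seed=split_seed,
    )


def _merge_reports(method: str, reports: list[EvaluationReport]) -> EvaluationReport:
    if len(reports) == 1:
        return reports[0]
    cells = pd.concat([r.cells for r in reports]).groupby(level=0).mean()
    counts = pd.concat([r.cell_counts for r in reports]).groupby(level=0).sum()
    per_class = pd.concat([r.per_class for r in reports], axis=1).mean(axis=1)
    per_split = pd.DataFrame(
        {
            "split": range(len(reports)),
            "overall": [r.overall for r in reports],
            "macro": [r.macro for r in reports],
        }
    )
    return EvaluationReport(
        method=method,
        cells=cells.loc[reports[0].cells.index],
        cell_counts=counts.loc[reports[0].cells.index],
        per_class=per_class,
        overall=float(np.mean([r.overall for r in reports])),
        macro=float(np.mean([r.macro for r in reports])),
        split_seed=reports[0].split_seed,
        n_splits=len(reports),
        per_split=per_split,
    )


def evaluate(
    dataset: LabeledImageDataset,
    methods=("icaboost", "ica_nearest", "lda"),
    split_seed: int = 0,
    train_fraction: float = 0.7,
    n_splits: int = 10,
    m: int = 20,
    T: int = 30,
    ica_seed: int = 0,
    ica_tol: float = 1e-4,
    ica_restarts: int = 5,
) -> dict[str, EvaluationReport]:
    """Compare the classifiers on repeated stratified splits.

    The localized ICA basis is fitted once on the whole corpus (the
    feature extraction is unsupervised, so no label information leaks);
    the classifiers are then trained on the training fraction of each of
    ``n_splits`` stratified splits and scored on the corresponding
    held-out fraction.  Reported accuracies are means over the splits,
    which tames the sampling noise of a single small test set.
    """
    known = {"icaboost", "ica_nearest", "lda"}
    unknown = set(methods) - known
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    # canonical sample order makes the whole evaluation invariant to the
    # row order of the manifest
    order = sorted(
        range(len(dataset)),
        key=lambda i: (dataset.labels[i], dataset.subject_id[i], dataset.group[i]),
    )
    dataset = LabeledImageDataset(
        images=dataset.images[order],
        labels=[dataset.labels[i] for i in order],
        group=[dataset.group[i] for i in order],
        subject_id=[dataset.subject_id[i] for i in order],
        seed=dataset.seed,
    )
    X = dataset.flat()
    y = np.asarray(dataset.labels)
    groups = np.asarray(dataset.group)
    features = _ica.fit_basis_image_ica(
        X, m=m, seed=ica_seed, tol=ica_tol, restarts=ica_restarts
    )
    acts = features.transform(X)

    split_rng = np.random.default_rng(split_seed)
    collected: dict[str, list[EvaluationReport]] = {meth: [] for meth in methods}
    for _ in range(n_splits):
        sub_seed = int(split_rng.integers(0, 2**31 - 1))
        train_idx, test_idx = stratified_split(dataset, train_fraction, sub_seed)
        acts_train, acts_test = acts[train_idx], acts[test_idx]
        y_train, y_test = y[train_idx], y[test_idx]
        for method in methods:
            if method == "icaboost":
                strong = _boost.train_icaboost(acts_train, y_train, T=T)
                pred, _ = _boost.predict(strong, acts_test)
            elif method == "ica_nearest":
                pred = _boost.ica_nearest_baseline(acts_train, y_train).predict(
                    acts_test
                )
            else:
                model = _lda.fit_lda(acts_train, y_train)
                pred = _lda.lda_predict(model, acts_test)
            collected[method].append(
                _report_from_predictions(
                    method, y_test, pred, groups[test_idx], split_seed
                )
            )
    return {meth: _merge_reports(meth, reps) for meth, reps in collected.items()}


# ---------------------------------------------------------------------------
# Session simulation


def default_emotion_hmm() -> HMMParams:
    """A sticky five-state emotion HMM centred on the neutral state.

    Emotions persist (self-transition 0.6) and the classifier observes
    the true state with probability 0.8, confusing it uniformly
    otherwise.  The session starts most likely calm.
    """
    n = len(CLASSES)
    pi = np.full(n, 0.1)
    pi[CLASSES.index("calm")] = 0.6
    A = np.full((n, n), 0.1) + np.eye(n) * 0.5
    B = np.full((n, n), 0.05) + np.eye(n) * 0.75
    return HMMParams(pi=pi, A=A, B=B)


@dataclass
class SessionLog:
    """Log of one simulated monitoring session.

    ``frame`` has one row per time step with the observed label (empty on
    non-capture steps in background mode), the filtered state posterior,
    the TEA score, the affect level E(t) and the selected strategy.
    """

    frame: pd.DataFrame
    mode: str
    interval: int
    states: tuple[str, ...] = CLASSES

    def captures(self) -> pd.DataFrame:
        return self.frame[self.frame["captured"]]

    def to_csv(self, path) -> None:
        cols = (
            ["t", "obs"]
            + [f"state_posterior_{i + 1}" for i in range(len(self.states))]
            + ["tea", "strategy", "E"]
        )
        self.frame[cols].to_csv(path, index=False)


def simulate_session(
    features: _ica.BasisImageICA,
    strong: _boost.StrongClassifier,
    hmm: HMMParams | None = None,
    T: int = 20,
    mode: str = "background",
    interval: int = 5,
    noise_sd: float = 0.3,
    seed: int = 0,
    beta: float = 0.3,
    E0: float = 0.0,
    E_star: float = 0.0,
    observation_gain: float = 0.5,
    strategies_enabled: bool = True,
    strategy_strength: float = 0.5,
    thresholds: tuple[float, float] = (-0.25, 0.25),
    valence: ValenceWeights | None = None,
    pinned_state: str | None = None,
    jitter: float = 0.05,
) -> SessionLog:
    """Simulate a monitoring session of T steps.

    A hidden emotional trajectory is sampled from the HMM (or pinned to
    one state); at each *capture* step a face is rendered for the hidden
    state, classified through the ICA + boosting stack, and the observed
    label updates the filtered state posterior by one forward step.  The
    TEA score of the posterior selects an intervention strategy.  The
    scalar affect E relaxes toward E_star with fade factor ``beta``
    between steps, is pulled toward the observed TEA by
    ``observation_gain`` at captures, and interventions move it a
    fraction ``strategy_strength`` back toward E_star.

    ``mode="frontend"`` captures every step; ``mode="background"``
    captures every ``interval`` steps (ceil(T / interval) captures).
    """
    if mode not in ("frontend", "background"):
        raise ValueError("mode must be 'frontend' or 'background'")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if hmm is None:
        hmm = default_emotion_hmm()
    if hmm.n_states != len(CLASSES):
        raise ValueError("session HMM must have one state per expression class")
    if valence is None:
        valence = ValenceWeights()
    lo, hi = thresholds
    size = int(math.isqrt(features.mean_image.shape[0]))
    if size * size != features.mean_image.shape[0]:
        raise ValueError("feature model was not fitted on square images")

    rng = np.random.default_rng(seed)
    rows = []
    posterior: np.ndarray | None = None
    last_posterior = hmm.pi.copy()
    E = float(E0)
    hidden_prev: int | None = None
    for t in range(T):
        if pinned_state is not None:
            hidden = CLASSES.index(pinned_state)
        elif hidden_prev is None:
            hidden = int(rng.choice(hmm.n_states, p=hmm.pi))
        else:
            hidden = int(rng.choice(hmm.n_states, p=hmm.A[hidden_prev]))
        hidden_prev = hidden

        if t > 0:
            E = decay(E, E_star, beta, 1.0)

        captured = mode == "frontend" or t % interval == 0
        obs_label = ""
        strategy = "none"
        if captured:
            img_seed = int(rng.integers(0, 2**31 - 1))
            img = render_face(
                class_prototype(CLASSES[hidden]),
                size=size,
                noise_sd=noise_sd,
                jitter=jitter,
                seed=img_seed,
            )
            act = features.transform(img.ravel())
            pred, _ = _boost.predict(strong, act)
            obs_label = pred[0]
            symbol = CLASSES.index(obs_label)
            posterior = forward_step(hmm, posterior, symbol)
            last_posterior = posterior
        space = validate_state_space(last_posterior)
        tea_t = tea(space, valence)
        if captured:
            E = E + observation_gain * (tea_t - E)
            strategy = select_strategy(tea_t, lo, hi)
            if strategies_enabled and strategy in ("soothe", "encourage"):
                E = E + strategy_strength * (E_star - E)
            elif not strategies_enabled:
                strategy = "none"
        row = {
            "t": t,
            "captured": captured,
            "hidden": CLASSES[hidden],
            "obs": obs_label,
            "tea": tea_t,
            "strategy": strategy,
            "E": E,
        }
        for i, s in enumerate(CLASSES):
            row[f"state_posterior_{i + 1}"] = float(last_posterior[i])
        rows.append(row)
    return SessionLog(frame=pd.DataFrame(rows), mode=mode, interval=interval)
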