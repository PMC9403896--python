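"""Parametric synthetic facial-expression corpus.

No public benchmark backs the five-class expression task this package
targets, so every recognition experiment runs on a parametric surrogate:
schematic grayscale faces whose geometry encodes the expression class.
Valence is encoded monotonically in the mouth curvature (smile vs frown)
and arousal in the eye/mouth openness, so that linear and ICA-based
features can separate the classes; Gaussian pixel noise and a small pose
jitter control the task difficulty.

The module also samples discrete observation sequences from an emotion
HMM, providing fixtures for the emotion-model layer.

Everything here is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .emotion import CLASSES, HMMParams

__all__ = [
    "FaceParams",
    "LabeledImageDataset",
    "EmotionSequence",
    "class_prototype",
    "render_face",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "sample_emotion_sequence",
]


@dataclass(frozen=True)
class FaceParams:
    """Geometric parameters of a schematic face.

    brow_angle: brow rotation in degrees, positive = raised (range -30..30)
    eye_openness: fraction of maximal eye height, in [0, 1]
    mouth_curvature: signed smile/frown bend, in [-1, 1] (positive = smile)
    mouth_openness: fraction of maximal mouth thickness, in [0, 1]
    """

    brow_angle: float
    eye_openness: float
    mouth_curvature: float
    mouth_openness: float

    def __post_init__(self):
        if not -30.0 <= self.brow_angle <= 30.0:
            raise ValueError("brow_angle must be in [-30, 30] degrees")
        if not 0.0 <= self.eye_openness <= 1.0:
            raise ValueError("eye_openness must be in [0, 1]")
        if not -1.0 <= self.mouth_curvature <= 1.0:
            raise ValueError("mouth_curvature must be in [-1, 1]")
        if not 0.0 <= self.mouth_openness <= 1.0:
            raise ValueError("mouth_openness must be in [0, 1]")


# Fixed class -> geometry mapping. Valence runs monotonically through
# mouth_curvature (+1 excited .. -1 angry); arousal through eye and mouth
# openness. The mapping is injective so a noise-free corpus is separable.
_PROTOTYPES: dict[str, FaceParams] = {
    "excited": FaceParams(15.0, 1.0, 1.0, 0.8),
    "happy": FaceParams(5.0, 0.8, 0.7, 0.3),
    "calm": FaceParams(0.0, 0.6, 0.0, 0.1),
    "frustrated": FaceParams(-10.0, 0.5, -0.6, 0.1),
    "angry": FaceParams(-25.0, 0.3, -1.0, 0.5),
}


def class_prototype(label: str) -> FaceParams:
    """Return the fixed facial geometry for an expression class."""
    try:
        return _PROTOTYPES[label]
    except KeyError:
        raise ValueError(
            f"unknown expression class {label!r}; expected one of {CLASSES}"
        ) from None


def render_face(
    params: FaceParams,
    size: int = 32,
    noise_sd: float = 0.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a schematic grayscale face as a ``size x size`` float matrix.

    Draws a face ellipse, two eyes (height scaled by ``eye_openness``), two
    brow segments (rotated by ``brow_angle``) and a mouth arc (bend set by
    ``mouth_curvature``, thickness by ``mouth_openness``) on a coordinate
    grid spanning [-1, 1]^2.  ``jitter`` applies a random translation and
    scale of up to +-jitter; ``noise_sd`` adds Gaussian pixel noise.  The
    output is clipped to [0, 1] and is deterministic given the seed.
    """
    if size < 16:
        raise ValueError("size must be >= 16 pixels")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    dx, dy = rng.uniform(-jitter, jitter, size=2) if jitter > 0 else (0.0, 0.0)
    scale = 1.0 + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)

    # pixel-centre grid in face coordinates; y grows downward (image rows)
    coords = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    x = (coords[None, :] - dx) / scale
    y = (coords[:, None] - dy) / scale

    img = np.zeros((size, size))
    # head
    face = (x / 0.85) ** 2 + (y / 0.95) ** 2 <= 1.0
    img[face] = 0.45

    # eyes: ellipses at (+-0.38, -0.28), height scaled by eye_openness
    eye_h = 0.03 + 0.34 * params.eye_openness
    for cx in (-0.38, 0.38):
        eye = ((x - cx) / 0.24) ** 2 + ((y + 0.28) / eye_h) ** 2 <= 1.0
        img[eye] = 1.0

    # brows: thick segments above the eyes, rotated by brow_angle; the
    # rotation is mirrored so both brows raise or knit symmetrically
    th = np.deg2rad(params.brow_angle)
    for s, cx in ((-1.0, -0.38), (1.0, 0.38)):
        ang = s * th
        u = np.cos(ang) * (x - cx) + np.sin(ang) * (y + 0.62)
        v = -np.sin(ang) * (x - cx) + np.cos(ang) * (y + 0.62)
        brow = (np.abs(u) <= 0.24) & (np.abs(v) <= 0.09)
        img[brow] = 0.95

    # mouth: parabolic arc around (0, 0.50); positive curvature bends the
    # corners upward and raises the mouth line (smile), negative bends
    # them downward and lowers it (frown), so opposing expressions paint
    # largely disjoint pixel regions
    half_w = 0.40
    thick = 0.08 + 0.26 * params.mouth_openness
    xm = x / half_w
    y_arc = (
        0.50
        - 0.10 * params.mouth_curvature
        + 0.50 * params.mouth_curvature * (xm**2 - 0.5)
    )
    mouth = (np.abs(xm) <= 1.0) & (np.abs(y - y_arc) <= thick / 2.0)
    img[mouth] = 0.95

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


@dataclass
class LabeledImageDataset:
    """A labelled grayscale expression corpus.

    ``images`` is an (n, H, W) array with values in [0, 1]; ``labels`` the
    expression class per image, ``group`` the evaluation-group id and
    ``subject_id`` a synthetic subject tag.  ``seed`` records the generator
    seed (or -1 for datasets loaded from disk without a sidecar).
    """

    images: np.ndarray
    labels: list[str]
    group: list[int]
    subject_id: list[str]
    seed: int = -1

    def __post_init__(self):
        n = len(self.images)
        if not (len(self.labels) == len(self.group) == len(self.subject_id) == n):
            raise ValueError("images, labels, group, subject_id lengths differ")
        if n and (self.images.shape[1] < 16 or self.images.shape[2] < 16):
            raise ValueError("images must be at least 16x16")

    def __len__(self) -> int:
        return len(self.labels)

    def flat(self) -> np.ndarray:
        """Images flattened row-major to an (n, H*W) design matrix."""
        n = len(self.images)
        return self.images.reshape(n, -1)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [f"img_{i:04d}.png" for i in range(len(self))],
                "label": self.labels,
                "group": self.group,
                "subject_id": self.subject_id,
            }
        )


def generate_dataset(
    n_per_class: int,
    size: int = 32,
    noise_sd: float = 0.3,
    n_groups: int = 5,
    seed: int = 0,
    jitter: float = 0.08,
) -> LabeledImageDataset:
    """Generate a balanced 5-class expression corpus.

    Produces ``5 * n_per_class`` images; within each class the i-th image
    is assigned to evaluation group ``i % n_groups`` (round-robin), so
    every group is class-balanced whenever ``n_per_class`` is divisible by
    ``n_groups``.  Per-image render seeds are drawn from a generator seeded
    with ``seed``, making the whole corpus a pure function of its
    arguments.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, groups, subjects = [], [], [], []
    for label in CLASSES:
        proto = class_prototype(label)
        for i in range(n_per_class):
            img_seed = int(rng.integers(0, 2**31 - 1))
            images.append(
                render_face(proto, size=size, noise_sd=noise_sd, jitter=jitter, seed=img_seed)
            )
            labels.append(label)
            groups.append(i % n_groups)
            subjects.append(f"subj{i:03d}")
    arr = np.asarray(images) if images else np.zeros((0, size, size))
    return LabeledImageDataset(
        images=arr, labels=labels, group=groups, subject_id=subjects, seed=seed
    )


def save_dataset(dataset: LabeledImageDataset, out_dir, config: dict | None = None) -> Path:
    """Write a dataset as 8-bit grayscale PNGs plus a CSV manifest and a
    JSON sidecar echoing the generation config (including the seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = dataset.manifest()
    for path, img in zip(man["path"], dataset.images):
        arr8 = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(out / path)
    man.to_csv(out / "manifest.csv", index=False)
    sidecar = {"seed": dataset.seed, "n_images": len(dataset)}
    if config:
        sidecar.update(config)
    (out / "generation.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out / "manifest.csv"


def load_dataset(manifest_path) -> LabeledImageDataset:
    """Load a dataset from a CSV manifest (`path,label,group,subject_id`);
    image paths are resolved relative to the manifest's directory."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    man = pd.read_csv(manifest_path)
    required = {"path", "label", "group", "subject_id"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    images = []
    for p in man["path"]:
        full = base / p
        if not full.exists():
            raise FileNotFoundError(f"manifest references missing image: {full}")
        images.append(np.asarray(Image.open(full).convert("L"), dtype=float) / 255.0)
    sidecar = base / "generation.json"
    seed = -1
    if sidecar.exists():
        seed = json.loads(sidecar.read_text()).get("seed", -1)
    arr = np.asarray(images) if images else np.zeros((0, 32, 32))
    return LabeledImageDataset(
        images=arr,
        labels=[str(l) for l in man["label"]],
        group=[int(g) for g in man["group"]],
        subject_id=[str(s) for s in man["subject_id"]],
        seed=seed,
    )


@dataclass
class EmotionSequence:
    """A sampled HMM trajectory: hidden state indices and observed symbol
    indices of equal length."""

    hidden: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.hidden = np.asarray(self.hidden, dtype=int)
        self.observed = np.asarray(self.observed, dtype=int)
        if self.hidden.shape != self.observed.shape:
            raise ValueError("hidden and observed must have equal length")

    def __len__(self) -> int:
        return len(self.hidden)


def sample_emotion_sequence(hmm: HMMParams, T: int, seed: int = 0) -> EmotionSequence:
    """Ancestral sampling of a length-T trajectory from (pi, A, B)."""
    if T < 0:
        raise ValueError("T must be >= 0")
    rng = np.random.default_rng(seed)
    hidden = np.zeros(T, dtype=int)
    observed = np.zeros(T, dtype=int)
    for t in range(T):
        probs = hmm.pi if t == 0 else hmm.A[hidden[t - 1]]
        hidden[t] = rng.choice(hmm.n_states, p=probs)
        observed[t] = rng.choice(hmm.n_symbols, p=hmm.B[hidden[t]])
    return EmotionSequence(hidden=hidden, observed=observed)
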