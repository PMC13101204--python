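"""Task-discriminant component analysis (TDCA) for SSMVEP decoding.

The decoder learns one spatial filter bank shared across stimulus
frequencies:

1. sine-cosine references Y_i (sin/cos at f_i and 2 f_i, t = 1/fs .. Np/fs)
   per class;
2. orthogonal projectors P_i = Q_i Q_i^T onto the row space of Y_i, with
   Q_i from the economy QR factorization of Y_i^T;
3. delay augmentation (l delayed copies, zero-padded) and concatenation of
   the raw and projected blocks along time: X_aug = [X_d, X_d P_i];
4. a Fisher-criterion spatial filter W maximizing
   tr(W^T S_b W) / tr(W^T S_w W) over between/within-class channel scatter
   of the augmented trials, solved as a generalized symmetric
   eigenproblem with a small ridge on S_w;
5. class templates mu_i = mean over training trials of W^T X_aug, and
   classification by the Pearson correlation between the projected test
   trial (augmented per candidate class) and each template.

Under the study conditions l = 0 and no filter bank is used; both remain
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, signal

from .containers import EpochSet

#: Occipital/parietal channels the decoder operates on, in canonical order.
DECODING_CHANNELS = ["P7", "P3", "P4", "P8", "POz", "O1", "Oz", "O2"]

DECODING_BAND = (3.0, 30.0)


def preprocess_for_decoding(
    epochs: EpochSet,
    segment_length: float = 3.0,
    band: tuple[float, float] = DECODING_BAND,
    order: int = 4,
    channels: list[str] | None = None,
) -> EpochSet:
    """Restrict to the eight occipital/parietal channels, bandpass with a
    zero-phase Butterworth filter, and crop to the first ``segment_length``
    seconds of the stimulus phase (1500 samples for 3 s at 500 Hz)."""
    if channels is None:
        channels = DECODING_CHANNELS
    sub = epochs.pick_channels(channels)
    sos = signal.butter(order, band, btype="bandpass", output="sos", fs=epochs.fs)
    sub.data = signal.sosfiltfilt(sos, sub.data, axis=-1)
    return sub.crop(0.0, segment_length)


@dataclass
class ReferenceSet:
    """Per-class sine-cosine references (4 x Np each)."""

    freqs: np.ndarray  # class order = label order 1..4
    fs: float
    n_samples: int
    Y: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def classes(self) -> list[int]:
        return sorted(self.Y)


def build_references(freqs, fs: float, n_samples: int) -> ReferenceSet:
    """Y_i rows: sin(2 pi f_i t), cos(2 pi f_i t), sin(4 pi f_i t),
    cos(4 pi f_i t) over t = [1/fs, ..., Np/fs]."""
    freqs = np.asarray(freqs, dtype=float)
    t = np.arange(1, n_samples + 1) / fs
    refs = ReferenceSet(freqs=freqs, fs=fs, n_samples=n_samples)
    for i, f in enumerate(freqs, start=1):
        refs.Y[i] = np.vstack(
            [
                np.sin(2 * np.pi * f * t),
                np.cos(2 * np.pi * f * t),
                np.sin(4 * np.pi * f * t),
                np.cos(4 * np.pi * f * t),
            ]
        )
    return refs


@dataclass
class ProjectionSet:
    """Orthogonal projectors onto each class's reference row space, held in
    factored form P_i = Q_i Q_i^T (Q_i: Np x rank, orthonormal columns)."""

    Q: dict[int, np.ndarray] = field(default_factory=dict)

    def matrix(self, i: int) -> np.ndarray:
        q = self.Q[i]
        return q @ q.T

    def project(self, X: np.ndarray, i: int) -> np.ndarray:
        """X @ P_i computed through the factored form."""
        q = self.Q[i]
        return (X @ q) @ q.T


def orthogonal_projection(refs: ReferenceSet) -> ProjectionSet:
    """Economy QR factorization of Y_i^T; raises on rank deficiency."""
    proj = ProjectionSet()
    for i, y in refs.Y.items():
        q, r = np.linalg.qr(y.T, mode="reduced")
        if np.min(np.abs(np.diag(r))) < 1e-10 * max(abs(np.diag(r)).max(), 1.0):
            raise ValueError(f"reference matrix for class {i} is rank deficient")
        proj.Q[i] = q
    return proj


def augment(X: np.ndarray, n_delays: int, proj: ProjectionSet, cls: int) -> np.ndarray:
    """Delay-stack X (zero-padded tails) and concatenate the projected block
    along time: output shape (channels * (n_delays + 1), 2 * Np)."""
    n_ch, n_p = X.shape
    if n_delays < 0:
        raise ValueError("number of delays must be nonnegative")
    if n_delays >= n_p:
        raise ValueError("number of delays must be smaller than the trial length")
    if n_delays == 0:
        xd = X
    else:
        blocks = [X]
        for d in range(1, n_delays + 1):
            shifted = np.zeros_like(X)
            shifted[:, : n_p - d] = X[:, d:]
            blocks.append(shifted)
        xd = np.vstack(blocks)
    return np.hstack([xd, proj.project(xd, cls)])


@dataclass
class TDCAModel:
    W: np.ndarray  # (aug channels, n_components)
    templates: dict[int, np.ndarray]  # class -> (n_components, aug samples)
    eigenvalues: np.ndarray
    channel_names: list[str]
    band: tuple[float, float]
    n_delays: int
    n_components: int
    fs: float
    class_freqs: np.ndarray

    # -- serialization: binary arrays + JSON metadata ----------------------

    def save(self, directory: str | Path) -> Path:
        import json

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "W.npy", self.W)
        np.save(d / "eigenvalues.npy", self.eigenvalues)
        for i, mu in self.templates.items():
            np.save(d / f"template_{i}.npy", mu)
        meta = {
            "channel_names": self.channel_names,
            "band": list(self.band),
            "n_delays": self.n_delays,
            "n_components": self.n_components,
            "fs": self.fs,
            "class_freqs": list(map(float, self.class_freqs)),
            "classes": sorted(self.templates),
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        return d

    @staticmethod
    def load(directory: str | Path) -> "TDCAModel":
        import json

        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        return TDCAModel(
            W=np.load(d / "W.npy"),
            templates={i: np.load(d / f"template_{i}.npy") for i in meta["classes"]},
            eigenvalues=np.load(d / "eigenvalues.npy"),
            channel_names=meta["channel_names"],
            band=tuple(meta["band"]),
            n_delays=meta["n_delays"],
            n_components=meta["n_components"],
            fs=meta["fs"],
            class_freqs=np.array(meta["class_freqs"]),
        )


def _normalize_eigenvectors(W: np.ndarray) -> np.ndarray:
    """Unit 2-norm columns with the largest-magnitude entry positive, so the
    filter is independent of the eigensolver's arbitrary scaling."""
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    flips = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flips[flips == 0] = 1.0
    return W * flips


def fit(
    train: EpochSet,
    refs: ReferenceSet,
    n_delays: int = 0,
    n_components: int = 4,
) -> TDCAModel:
    """Fit the Fisher-criterion spatial filter and the class templates.

    Each training trial is augmented with its own class's projector. S_b is
    the scatter of class means about the grand mean, S_w the pooled scatter
    of trials about their class mean; W holds the leading generalized
    eigenvectors of (S_b, S_w + eps I) with eps = 1e-6 tr(S_w)/dim.
    """
    proj = orthogonal_projection(refs)
    classes = refs.classes
    aug_by_class: dict[int, np.ndarray] = {}
    for c in classes:
        idx = np.flatnonzero(train.labels == c)
        if len(idx) < 2:
            raise ValueError(f"need at least 2 training trials for class {c}")
        aug_by_class[c] = np.stack(
            [augment(train.data[k], n_delays, proj, c) for k in idx]
        )

    means = {c: a.mean(axis=0) for c, a in aug_by_class.items()}
    grand = np.mean([means[c] for c in classes], axis=0)
    dim = grand.shape[0]
    s_b = np.zeros((dim, dim))
    s_w = np.zeros((dim, dim))
    for c in classes:
        d = means[c] - grand
        s_b += d @ d.T
        resid = aug_by_class[c] - means[c]
        for r in resid:
            s_w += r @ r.T

    eps = 1e-6 * np.trace(s_w) / dim
    s_w_reg = s_w + eps * np.eye(dim)
    evals, evecs = linalg.eigh(s_b, s_w_reg)
    order = np.argsort(evals)[::-1]
    k = min(n_components, dim)
    W = _normalize_eigenvectors(evecs[:, order[:k]])

    templates = {c: W.T @ means[c] for c in classes}
    return TDCAModel(
        W=W,
        templates=templates,
        eigenvalues=evals[order[:k]],
        channel_names=list(train.channel_names),
        band=DECODING_BAND,
        n_delays=n_delays,
        n_components=k,
        fs=train.fs,
        class_freqs=refs.freqs,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of flattened arrays; 0 if either is constant."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def classify(
    X: np.ndarray, model: TDCAModel, refs: ReferenceSet
) -> tuple[int, np.ndarray]:
    """Label one preprocessed trial (channels x Np).

    The trial is augmented once per candidate class i with that class's
    projector, mapped through W, and correlated with template mu_i; the
    class with the maximum correlation wins (ties to the smallest index).
    """
    proj = orthogonal_projection(refs)
    classes = refs.classes
    rho = np.empty(len(classes))
    for j, c in enumerate(classes):
        z = model.W.T @ augment(X, model.n_delays, proj, c)
        rho[j] = _pearson(z, model.templates[c])
    return classes[int(np.argmax(rho))], rho


def predict(epochs: EpochSet, model: TDCAModel, refs: ReferenceSet) -> np.ndarray:
    """Labels for every trial of a preprocessed epoch set."""
    proj = orthogonal_projection(refs)
    classes = refs.classes
    out = np.empty(epochs.n_trials, dtype=int)
    for t in range(epochs.n_trials):
        rho = np.empty(len(classes))
        for j, c in enumerate(classes):
            z = model.W.T @ augment(epochs.data[t], model.n_delays, proj, c)
            rho[j] = _pearson(z, model.templates[c])
        out[t] = classes[int(np.argmax(rho))]
    return out


def confusion_matrix(
    true_labels: np.ndarray, predicted: np.ndarray, classes=(1, 2, 3, 4)
) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: k for k, c in enumerate(classes)}
    for t, p in zip(true_labels, predicted):
        cm[index[int(t)], index[int(p)]] += 1
    return cm
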