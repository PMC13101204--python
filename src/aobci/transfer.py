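"""Cross-paradigm training schemes and run-wise cross-validation.

Four ways of building the TDCA training set for a target-session (TS)
paradigm, given source-session (SS) paradigms:

* M1 (baseline): TS training runs only.
* M2 (naive cross-paradigm): SS trials only.
* M3 (naive transfer): SS trials concatenated with the TS training runs.
* M4 (LST transfer): SS trials aligned to the TS class templates by a
  per-class least-squares transformation (LST) P = x xt^T (xt xt^T)^{-1},
  then concatenated with the TS training runs.

Evaluation is leave-one-run-out cross-validation over the TS runs; source
data always enters in full and never includes the held-out run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tdca
from .containers import EpochSet

METHODS = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class SchemeSpec:
    """One cross-paradigm training configuration."""

    method: str
    target_paradigm: str
    source_paradigms: tuple[str, ...] = ()
    segment_length: float = 3.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method == "M1" and self.source_paradigms:
            raise ValueError("M1 takes no source paradigms")
        if self.method != "M1" and not self.source_paradigms:
            raise ValueError(f"{self.method} needs at least one source paradigm")
        if self.target_paradigm in self.source_paradigms:
            raise ValueError("source paradigms must differ from the target")

    @property
    def key(self) -> str:
        src = "+".join(self.source_paradigms)
        return f"{self.method}({self.target_paradigm}" + (f"<-{src})" if src else ")")


@dataclass
class LSTTransform:
    """Per-class channel-space map aligning source data to target templates."""

    P: dict[int, np.ndarray] = field(default_factory=dict)
    residual: dict[int, float] = field(default_factory=dict)


def class_templates(epochs: EpochSet, classes=(1, 2, 3, 4)) -> dict[int, np.ndarray]:
    """Trial-average matrix (channels x samples) per class."""
    out = {}
    for c in classes:
        idx = np.flatnonzero(epochs.labels == c)
        if len(idx) == 0:
            raise ValueError(f"class {c} missing")
        out[c] = epochs.data[idx].mean(axis=0)
    return out


def lst_fit(
    source: EpochSet,
    target_templates: dict[int, np.ndarray],
    ridge: float = 1e-8,
) -> LSTTransform:
    """Closed-form least-squares map per class.

    With xt the source class average and x the target class average,
    P = x xt^T (xt xt^T)^{-1}; a near-singular Gram matrix falls back to a
    ridge solve with lambda = ridge * trace / dim. The stored residual is
    the Frobenius norm of P xt - x.
    """
    src = class_templates(source, classes=sorted(target_templates))
    out = LSTTransform()
    for c, x in target_templates.items():
        xt = src[c]
        if xt.shape != x.shape:
            raise ValueError("source/target template shapes differ")
        gram = xt @ xt.T
        lam = ridge * np.trace(gram) / gram.shape[0]
        try:
            p = np.linalg.solve(gram, xt @ x.T).T
            if not np.all(np.isfinite(p)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            p = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), xt @ x.T).T
        out.P[c] = p
        out.residual[c] = float(np.linalg.norm(p @ xt - x))
    return out


def lst_apply(transforms: LSTTransform, source: EpochSet) -> EpochSet:
    """Map every source trial through its class's transformation."""
    out = source.subset(np.arange(source.n_trials))
    for t in range(out.n_trials):
        c = int(out.labels[t])
        if c not in transforms.P:
            raise ValueError(f"no transform for class {c}")
        out.data[t] = transforms.P[c] @ out.data[t]
    return out


def build_training_set(
    scheme: SchemeSpec,
    ts_train: EpochSet,
    sources: dict[str, EpochSet] | None = None,
) -> EpochSet:
    """Assemble the training epochs for one scheme and one CV fold.

    ``ts_train`` is the target paradigm's training partition for the fold;
    ``sources`` maps paradigm id to that paradigm's full (preprocessed)
    epoch set. For M4 the alignment templates come from ``ts_train`` only.
    """
    if scheme.method == "M1":
        if ts_train.n_trials == 0:
            raise ValueError("empty target training partition")
        return ts_train
    src_sets = [sources[p] for p in scheme.source_paradigms]
    if any(s.n_trials == 0 for s in src_sets):
        raise ValueError("empty source partition")
    if scheme.method == "M2":
        return EpochSet.concatenate(src_sets)
    if scheme.method == "M3":
        return EpochSet.concatenate(src_sets + [ts_train])
    # M4: LST-align each source to the fold's target templates, then concat
    templates = class_templates(ts_train)
    aligned = [lst_apply(lst_fit(s, templates), s) for s in src_sets]
    return EpochSet.concatenate(aligned + [ts_train])


@dataclass
class EvalResult:
    scheme: SchemeSpec
    fold_accuracies: list[float]  # percent
    confusion: np.ndarray  # (4, 4) pooled counts, rows = true

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        if len(self.fold_accuracies) < 2:
            return 0.0
        return float(np.std(self.fold_accuracies, ddof=1))


def crossval(
    scheme: SchemeSpec,
    ts: EpochSet,
    sources: dict[str, EpochSet] | None = None,
    k: int | None = None,
    n_components: int = 4,
    n_delays: int = 0,
    class_freqs=None,
    preprocessed: bool = False,
) -> EvalResult:
    """Leave-one-run-out cross-validation of one scheme.

    ``ts`` (and each source set) is reduced to the decoding channels,
    filtered and cropped to ``scheme.segment_length`` unless
    ``preprocessed`` is set. ``k`` must equal the number of TS runs; each
    run is held out once as the test fold.
    """
    if class_freqs is None:
        from .synthetic import make_paradigms

        class_freqs = make_paradigms()[0].frequencies
    if not preprocessed:
        ts = tdca.preprocess_for_decoding(ts, scheme.segment_length)
        if sources:
            sources = {
                p: tdca.preprocess_for_decoding(s, scheme.segment_length)
                for p, s in sources.items()
            }
    runs = np.unique(ts.run)
    if k is None:
        k = len(runs)
    if k != len(runs):
        raise ValueError(f"k = {k} but the target set has {len(runs)} runs")

    refs = tdca.build_references(class_freqs, ts.fs, ts.n_samples)
    fold_acc = []
    confusion = np.zeros((4, 4), dtype=int)
    for held in runs:
        test = ts.subset(ts.run == held)
        ts_train = ts.subset(ts.run != held)
        train = build_training_set(scheme, ts_train, sources)
        model = tdca.fit(train, refs, n_delays=n_delays, n_components=n_components)
        pred = tdca.predict(test, model, refs)
        fold_acc.append(100.0 * float(np.mean(pred == test.labels)))
        confusion += tdca.confusion_matrix(test.labels, pred)
    return EvalResult(scheme=scheme, fold_accuracies=fold_acc, confusion=confusion)
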