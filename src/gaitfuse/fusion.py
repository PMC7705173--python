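"""Bayesian belief fusion of the EEG and EMG classifiers.

The reliability of each classifier is summarized by its confusion matrix on
the validation split: ``n[i, j]`` counts windows truly in class ``i``
predicted as class ``j``. Column-normalizing gives the conditional
reliability table ``P(true = c_i | predicted = c_j)``. At run time, given the
hard predictions ``e_EEG`` and ``e_EMG``, the belief of each fused class is

    Bel(c_i) = P_EEG(map(c_i) | e_EEG) * P_EMG(c_i | e_EMG) * P(c_i)

where the class mapping repeats the EEG SWING conditional for both RIGHT and
LEFT: the EEG network arbitrates swing-vs-stance regardless of the moving
leg, while only the EMG network discriminates the leg. The fused decision is
the class of highest belief; exact ties resolve by the deterministic
preference STANCE > RIGHT > LEFT, so ambiguity never commands a step.

Priors are uniform by default (walking speed unknown to the classifier). The
general multi-classifier belief formula carries prior factors that collapse
to a single ``P(c_i)`` under uniform priors; ``literal_prior_weighting``
exposes the uncollapsed weighting ``prod_k P(c_i|e_k) / P(c_i)^(K-1)`` for
non-uniform priors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal import EEG_CLASSES, GAIT_CLASSES

__all__ = [
    "ConfusionMatrix",
    "ClassMapping",
    "FusionModel",
    "BeliefVector",
    "estimate_confusion",
    "conditionals_from_confusion",
    "fuse",
    "fuse_sequence",
]


@dataclass
class ConfusionMatrix:
    """M x M counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]
    classifier_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        m = len(self.classes)
        if self.counts.shape != (m, m):
            raise ValueError("counts must be square over the class set")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.n_samples, 1))


@dataclass(frozen=True)
class ClassMapping:
    """Fused classes and, per classifier, the index of its class for each fused class."""

    fused_classes: tuple[str, ...] = GAIT_CLASSES
    eeg_classes: tuple[str, ...] = EEG_CLASSES
    # fused (RIGHT, LEFT, STANCE) -> EEG (SWING, SWING, STANCE)
    eeg_index: tuple[int, ...] = (0, 0, 1)
    # fused -> EMG identity
    emg_index: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if len(self.eeg_index) != len(self.fused_classes):
            raise ValueError("eeg_index must map every fused class")
        if len(self.emg_index) != len(self.fused_classes):
            raise ValueError("emg_index must map every fused class")


@dataclass
class BeliefVector:
    beliefs: np.ndarray              # one belief per fused class
    decision: int                    # code into classes
    classes: tuple[str, ...] = GAIT_CLASSES

    @property
    def decision_name(self) -> str:
        return self.classes[self.decision]


def estimate_confusion(true_labels, predicted_labels, classes: tuple[str, ...],
                       classifier_id: str = "") -> ConfusionMatrix:
    """Count (true, predicted) pairs over equal-length code sequences."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    m = len(classes)
    if t.size and (t.min() < 0 or t.max() >= m or p.min() < 0 or p.max() >= m):
        raise ValueError("labels outside the class set")
    counts = np.zeros((m, m), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, classes=tuple(classes),
                           classifier_id=classifier_id)


def conditionals_from_confusion(cm: ConfusionMatrix, alpha: float = 1.0) -> np.ndarray:
    """Column-normalized conditional reliabilities with add-alpha smoothing.

    ``cond[i, j] = (n_ij + alpha) / sum_i (n_ij + alpha)``; every column sums
    to 1. With ``alpha = 0`` the raw normalization is reproduced and an
    all-zero column (a class the classifier never predicted on validation) is
    undefined and raises.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    counts = cm.counts.astype(np.float64) + alpha
    col_sums = counts.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError(
            "confusion matrix has an all-zero column and alpha=0: "
            "conditional probabilities undefined"
        )
    return counts / col_sums


@dataclass
class FusionModel:
    """Calibrated per-classifier reliabilities + class mapping + priors."""

    eeg_conditionals: np.ndarray          # 2 x 2, columns sum to 1
    emg_conditionals: np.ndarray          # 3 x 3, columns sum to 1
    priors: np.ndarray | None = None      # over fused classes; uniform if None
    mapping: ClassMapping = field(default_factory=ClassMapping)
    alpha: float = 1.0
    literal_prior_weighting: bool = False
    tie_order: tuple[str, ...] = ("STANCE", "RIGHT", "LEFT")

    def __post_init__(self) -> None:
        self.eeg_conditionals = np.asarray(self.eeg_conditionals, dtype=np.float64)
        self.emg_conditionals = np.asarray(self.emg_conditionals, dtype=np.float64)
        m = len(self.mapping.fused_classes)
        if self.priors is None:
            self.priors = np.full(m, 1.0 / m)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if self.priors.size != m or not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1 over the fused classes")
        for name, cond in (("eeg", self.eeg_conditionals), ("emg", self.emg_conditionals)):
            if not np.allclose(cond.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError(f"{name} conditional columns must sum to 1")
            if np.any(cond < 0):
                raise ValueError(f"{name} conditionals must be non-negative")

    @classmethod
    def calibrate(
        cls,
        eeg_true, eeg_pred, emg_true, emg_pred,
        alpha: float = 1.0,
        priors: np.ndarray | None = None,
        **kwargs,
    ) -> "FusionModel":
        """Estimate both conditional tables from validation-split predictions."""
        cm_eeg = estimate_confusion(eeg_true, eeg_pred, EEG_CLASSES, "EEG")
        cm_emg = estimate_confusion(emg_true, emg_pred, GAIT_CLASSES, "EMG")
        return cls(
            eeg_conditionals=conditionals_from_confusion(cm_eeg, alpha),
            emg_conditionals=conditionals_from_confusion(cm_emg, alpha),
            priors=priors, alpha=alpha, **kwargs,
        )

    def _tie_pref(self) -> np.ndarray:
        order = [self.mapping.fused_classes.index(c) for c in self.tie_order]
        return np.asarray(order)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "eeg_conditionals": self.eeg_conditionals.tolist(),
            "emg_conditionals": self.emg_conditionals.tolist(),
            "priors": self.priors.tolist(),
            "alpha": self.alpha,
            "literal_prior_weighting": self.literal_prior_weighting,
            "tie_order": list(self.tie_order),
            "mapping": {
                "fused_classes": list(self.mapping.fused_classes),
                "eeg_classes": list(self.mapping.eeg_classes),
                "eeg_index": list(self.mapping.eeg_index),
                "emg_index": list(self.mapping.emg_index),
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FusionModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        mapping = ClassMapping(
            fused_classes=tuple(d["mapping"]["fused_classes"]),
            eeg_classes=tuple(d["mapping"]["eeg_classes"]),
            eeg_index=tuple(d["mapping"]["eeg_index"]),
            emg_index=tuple(d["mapping"]["emg_index"]),
        )
        return cls(
            eeg_conditionals=np.asarray(d["eeg_conditionals"]),
            emg_conditionals=np.asarray(d["emg_conditionals"]),
            priors=np.asarray(d["priors"]),
            mapping=mapping, alpha=d["alpha"],
            literal_prior_weighting=d["literal_prior_weighting"],
            tie_order=tuple(d["tie_order"]),
        )


def _belief_matrix(model: FusionModel, eeg_pred: np.ndarray,
                   emg_pred: np.ndarray) -> np.ndarray:
    """Beliefs for every window: shape (n, n_fused_classes)."""
    eeg_map = np.asarray(model.mapping.eeg_index)
    emg_map = np.asarray(model.mapping.emg_index)
    eeg_term = model.eeg_conditionals[eeg_map[:, None], eeg_pred[None, :]]  # (M, n)
    emg_term = model.emg_conditionals[emg_map[:, None], emg_pred[None, :]]  # (M, n)
    if model.literal_prior_weighting:
        # Bel = P(ci) * prod_k P(ci|ek) / prod_k P(ci), K = 2
        bel = eeg_term * emg_term / model.priors[:, None]
    else:
        bel = eeg_term * emg_term * model.priors[:, None]
    return bel.T


def _decide(model: FusionModel, beliefs: np.ndarray) -> np.ndarray:
    """Argmax with exact-tie resolution by the model's preference order."""
    pref = model._tie_pref()
    reordered = beliefs[:, pref]           # argmax takes the first max -> preference
    return pref[np.argmax(reordered, axis=1)].astype(np.int8)


def fuse(e_eeg: int, e_emg: int, model: FusionModel) -> BeliefVector:
    """Fuse one pair of hard predictions into a belief vector and decision."""
    n_eeg = len(model.mapping.eeg_classes)
    n_emg = len(model.mapping.fused_classes)
    if not 0 <= int(e_eeg) < n_eeg:
        raise ValueError("EEG prediction outside its class set")
    if not 0 <= int(e_emg) < n_emg:
        raise ValueError("EMG prediction outside its class set")
    beliefs = _belief_matrix(model, np.asarray([e_eeg]), np.asarray([e_emg]))
    decision = _decide(model, beliefs)[0]
    return BeliefVector(beliefs=beliefs[0], decision=int(decision),
                        classes=model.mapping.fused_classes)


def fuse_sequence(eeg_predictions, emg_predictions,
                  model: FusionModel) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise fusion of index-aligned prediction streams.

    Returns (decisions, beliefs) with one row per window at the decision rate.
    """
    eeg_pred = np.asarray(eeg_predictions)
    emg_pred = np.asarray(emg_predictions)
    if eeg_pred.shape != emg_pred.shape:
        raise ValueError("prediction sequences must be index-aligned (equal length)")
    beliefs = _belief_matrix(model, eeg_pred, emg_pred)
    return _decide(model, beliefs), beliefs
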