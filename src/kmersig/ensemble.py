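"""AUC-weighted voting ensemble over the four base classifiers.

Each model's hard vote (score > 0.5) is weighted by its ROC AUC,
normalized so weights sum to one; a sample is called positive when the
weighted votes for the positive class exceed those for the negative class.
The continuous weighted-vote score doubles as the ensemble's ranking score
for ROC/PR curves. A soft variant (weighted mean of calibrated
probabilities) is available behind a flag but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

WEIGHT_RULES = ("proportional", "excess")
AUC_SOURCES = ("inner-validation", "fold-validation")


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized non-negative per-model weights and their raw AUC provenance."""

    weights: tuple[float, ...]
    raw_auc: tuple[float, ...]
    auc_source: str = "inner-validation"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if (w < 0).any():
            raise ParameterError("ensemble weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ParameterError(f"ensemble weights must sum to 1, got {w.sum()}")


def compute_weights(
    aucs: "list[float] | np.ndarray",
    source: str = "inner-validation",
    rule: str = "proportional",
) -> EnsembleWeights:
    """Scale per-model ROC AUCs into voting weights.

    ``rule="proportional"`` (default): w_m = auc_m / Σ auc.
    ``rule="excess"``: w_m ∝ max(auc_m − 0.5, 0), so a chance-level model
    gets no vote. If every raw weight is zero, weights are uniform.
    """
    a = np.asarray(aucs, dtype=np.float64)
    if a.size < 2:
        raise ParameterError(f"ensemble needs >= 2 models, got {a.size}")
    if ((a < 0) | (a > 1)).any():
        raise ParameterError(f"AUCs must lie in [0, 1], got {a}")
    if source not in AUC_SOURCES:
        raise ParameterError(f"auc_source must be one of {AUC_SOURCES}, got {source!r}")
    if rule not in WEIGHT_RULES:
        raise ParameterError(f"weight rule must be one of {WEIGHT_RULES}, got {rule!r}")
    raw = a if rule == "proportional" else np.maximum(a - 0.5, 0.0)
    total = raw.sum()
    w = raw / total if total > 0 else np.full(a.size, 1.0 / a.size)
    return EnsembleWeights(weights=tuple(w), raw_auc=tuple(a), auc_source=source)


def weighted_vote(
    hard_votes: np.ndarray, weights: EnsembleWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-model 0/1 votes into ensemble labels and vote scores.

    ``hard_votes`` has shape (n_samples, n_models). The vote score is
    Σ_m w_m · vote_m ∈ [0, 1]; the label is positive when the score exceeds
    0.5, with an exact tie resolved to the positive class. The continuous
    vote score is what the ensemble's ROC/PR curves are computed on.
    """
    votes = np.asarray(hard_votes, dtype=np.float64)
    w = np.asarray(weights.weights)
    if votes.ndim != 2 or votes.shape[1] != w.size:
        raise ParameterError(
            f"vote matrix shape {votes.shape} does not match {w.size} model weights"
        )
    scores = votes @ w
    labels = (scores >= 0.5).astype(int)  # > 0.5 positive; == 0.5 breaks to positive
    return labels, scores


def ensemble_scores_soft(model_scores: np.ndarray, weights: EnsembleWeights) -> np.ndarray:
    """Weighted mean of calibrated probabilities (soft voting; optional)."""
    s = np.asarray(model_scores, dtype=np.float64)
    w = np.asarray(weights.weights)
    if s.ndim != 2 or s.shape[1] != w.size:
        raise ParameterError(
            f"score matrix shape {s.shape} does not match {w.size} model weights"
        )
    return s @ w
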