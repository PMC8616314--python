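"""Level-2 model fusion: accuracy-weighted consensus over top models.

The screened top-k models act like the specialists of a
multi-disciplinary team. Each member i contributes its class-1
probability c_i(x), weighted by its cross-validated accuracy:

    w_i = acc_i / sum_k acc_k,        consensus(x) = sum_i w_i c_i(x)

The consensus score stays inside the convex hull of the member scores;
the predicted class is 1 when the score reaches the decision threshold
(default 0.5, ">=" on the boundary). A plurality (majority-vote)
baseline is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .feature_io import FeatureTable
from .model_zoo import TrainedModel

__all__ = [
    "ConsensusModel",
    "compute_weights",
    "weighted_consensus_predict",
    "majority_vote_predict",
]


def compute_weights(accuracies) -> np.ndarray:
    """w_i = acc_i / sum(acc); requires non-negative, not-all-zero input."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("no accuracies given")
    if np.any(acc < 0):
        raise ValueError("accuracies must be non-negative")
    total = acc.sum()
    if total == 0:
        raise ValueError("all accuracies are zero; weights undefined")
    return acc / total


@dataclass
class ConsensusModel:
    """Weighted soft-voting consensus over trained member models."""

    members: list[TrainedModel]
    weights: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) == 0:
            raise ValueError("consensus needs at least one member")
        if self.weights.shape != (len(self.members),):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    @classmethod
    def from_members(cls, members: list[TrainedModel],
                     threshold: float = 0.5) -> "ConsensusModel":
        """Weights from the members' stored CV accuracies."""
        return cls(members=list(members),
                   weights=compute_weights([m.cv_accuracy for m in members]),
                   threshold=threshold)

    def member_scores(self, table: FeatureTable) -> np.ndarray:
        """(k, n) matrix of member class-1 probabilities."""
        rows = []
        for m in self.members:
            try:
                rows.append(m.predict_scores(table))
            except Exception as exc:
                raise RuntimeError(
                    f"member {m.spec.model_id!r} failed to score"
                ) from exc
        return np.vstack(rows)

    def predict(self, table: FeatureTable):
        """(scores, classes) of the weighted consensus."""
        scores = self.weights @ self.member_scores(table)
        return scores, (scores >= self.threshold).astype(int)

    def predict_majority(self, table: FeatureTable) -> np.ndarray:
        """Majority-vote baseline over the same members."""
        votes = (self.member_scores(table) >= self.threshold).astype(int)
        return majority_vote_predict(votes)

    def as_dict(self) -> dict:
        return {
            "members": [m.spec.model_id for m in self.members],
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
        }


def weighted_consensus_predict(model: ConsensusModel, table: FeatureTable):
    """Functional alias of :meth:`ConsensusModel.predict`."""
    return model.predict(table)


def majority_vote_predict(votes: np.ndarray) -> np.ndarray:
    """Plurality over member hard votes; (k, n) in, (n,) out.

    Ties (even member counts split evenly) break toward the positive
    class, with a warning.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.ndim == 1:
        votes = votes[:, None]
    if votes.shape[0] == 0:
        raise ValueError("majority vote needs at least one member")
    ones = votes.sum(axis=0)
    zeros = votes.shape[0] - ones
    if np.any(ones == zeros):
        warnings.warn("vote tie broken toward the positive class", stacklevel=2)
    return (ones >= zeros).astype(int)
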