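"""Pool-based active learning by breaking ties.

With calibrated class probabilities, the two-class "tie score" of an
unlabeled instance is |P+ - P-| = |2 P+ - 1|: the gap between the two best
class probabilities.  Instances with the smallest gap are the ones the
current model is least certain about, and those are the queries sent to
the labeling oracle each round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class QueryBatch:
    """Pool indices selected for expert labeling, with their tie scores
    sorted non-decreasing."""

    indices: list[int]
    tie_scores_: list[float]


class GoldLabelOracle:
    """Oracle answering queries from a gold label array (simulated expert);
    counts every call for labeling-cost accounting."""

    def __init__(self, labels: Sequence[int] | Mapping[int, int]):
        self._labels = labels
        self.n_calls = 0

    def query(self, index: int) -> int:
        self.n_calls += 1
        lab = int(self._labels[index])
        if lab not in (-1, 1):
            raise ValueError(f"oracle has no definite label for index {index}")
        return lab


class StdinOracle:
    """Interactive oracle: prints the instance and reads +1/-1 from stdin."""

    def __init__(self, sentences=None):
        self.sentences = sentences
        self.n_calls = 0

    def query(self, index: int) -> int:  # pragma: no cover - interactive
        self.n_calls += 1
        if self.sentences is not None:
            print(f"[{index}] {self.sentences[index].text}")
        while True:
            ans = input(f"label for pool index {index} (+1/-1): ").strip()
            if ans in ("+1", "1", "p", "pos"):
                return 1
            if ans in ("-1", "n", "neg"):
                return -1


def tie_scores(p_pos: np.ndarray) -> np.ndarray:
    """|2 P+ - 1| for each pool instance (0 = perfect tie, 1 = certain)."""
    p = np.asarray(p_pos, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return np.abs(2.0 * p - 1.0)


def select_queries(pool_probs: np.ndarray, budget: int) -> QueryBatch:
    """The ``budget`` pool instances with the smallest tie scores.

    Ties on score are broken by ascending pool index so selection is
    deterministic; a budget exceeding the pool returns the whole pool
    with a warning.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    scores = tie_scores(pool_probs)
    if budget > len(scores):
        logger.warning("budget %d exceeds pool size %d; returning whole pool",
                       budget, len(scores))
        budget = len(scores)
    order = np.lexsort((np.arange(len(scores)), scores))[:budget]
    return QueryBatch(indices=[int(i) for i in order],
                      tie_scores_=[float(scores[i]) for i in order])


def split_by_confidence(
    pool_probs: np.ndarray, theta: float = 0.9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition the pool by confidence threshold ``theta`` > 0.5.

    Returns ``(fuzzy_idx, confident_idx, machine_labels)`` where the
    confident set is {i : P+ >= theta or P+ <= 1-theta} with machine label
    sign(2 P+ - 1), and the fuzzy set is its exact complement.
    """
    if not theta > 0.5:
        raise ValueError("theta must exceed 0.5")
    p = np.asarray(pool_probs, dtype=float)
    confident = (p >= theta) | (p <= 1.0 - theta)
    machine = np.where(p[confident] >= 0.5, 1, -1)
    idx = np.arange(len(p))
    return idx[~confident], idx[confident], machine
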