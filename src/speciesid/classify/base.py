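"""Shared classifier types: predictions, the ambiguity sentinel, parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

#: Sentinel call for a classifier that declines to assign a species.
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class Prediction:
    """Per-accession classifier output.

    ``call`` is either a species present in the training labels or
    :data:`AMBIGUOUS`. ``support`` carries free-form diagnostics (vote
    counts, subtree level, OOB vote fractions) for curator-facing reports.
    """

    accession_id: str
    call: str
    support: dict[str, Any] = field(default_factory=dict)

    @property
    def is_ambiguous(self) -> bool:
        return self.call == AMBIGUOUS


@dataclass
class KnnParams:
    """Conservative 3-NN settings.

    The rule fixes k=3 with the query itself among the neighbours, requires
    ``min_votes`` (l) votes for a winner, and includes every accession tied
    with the third-nearest neighbour in the vote.
    """

    k: int = 3
    min_votes: int = 2
    include_all_ties: bool = True

    def __post_init__(self) -> None:
        if self.min_votes > self.k:
            raise ValueError("min_votes (l) must be <= k")


@dataclass
class ForestParams:
    """Random-Forest settings: bootstrap with replacement, gini splits.

    ``mtry=None`` resolves to floor(sqrt(p)) at fit time. The default forest
    size of 10,000 trees leaves each sample out-of-bag for roughly
    0.368 x n_trees trees, giving a stable OOB vote.
    """

    n_trees: int = 10_000
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class NbParams:
    """Categorical Naive Bayes settings (Laplace smoothing)."""

    laplace_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.laplace_alpha < 0:
            raise ValueError("laplace_alpha must be >= 0")


def majority(votes: dict[str, float]) -> str | None:
    """Strict-majority winner (> half the total), or None."""
    if not votes:
        return None
    total = sum(votes.values())
    top = max(votes.values())
    if top * 2 > total:
        winners = [s for s, v in votes.items() if v == top]
        return winners[0] if len(winners) == 1 else None
    return None


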