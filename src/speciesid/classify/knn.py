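"""Nearest-neighbour classification rules.

Both rules run in leave-one-out fashion over a precomputed distance matrix:
1-NN adopts the label of the single most similar other accession (divergent
sites distance, following the field's practice), while the conservative 3-NN
variant (Euclidean distance on imputed codes) counts the query itself among
its three neighbours. The self-vote raises the burden of evidence to
*overturn* an a-priori label — two dissenting neighbours are needed — while a
single agreeing neighbour suffices to confirm it, which also lowers the
minimum species size for an unambiguous confirmation from 3 to 2.
"""

from __future__ import annotations

import numpy as np

from speciesid.classify.base import AMBIGUOUS, KnnParams, Prediction, majority
from speciesid.distance import DistanceMatrix
from speciesid.genotype_data import LabelSet


def _check_labels(dist: DistanceMatrix, labels: LabelSet) -> list[str]:
    missing = [a for a in dist.accession_ids if a not in labels.labels]
    if missing:
        raise ValueError(f"unlabelled accessions: {missing[:5]}")
    return [labels[a] for a in dist.accession_ids]


def classify_1nn(dist: DistanceMatrix, labels: LabelSet) -> list[Prediction]:
    """Assign each accession the species of its nearest other accession.

    The query's own a-priori label is never consulted. When several
    neighbours tie for nearest, the strict majority label among the tied set
    wins; with no majority the call is AMBIGUOUS.
    """
    if dist.n < 2:
        raise ValueError("need at least 2 accessions")
    y = _check_labels(dist, labels)
    preds: list[Prediction] = []
    for i, acc in enumerate(dist.accession_ids):
        row = dist.d[i].copy()
        row[i] = np.inf
        dmin = row.min()
        tied = np.flatnonzero(row == dmin)
        votes: dict[str, float] = {}
        for j in tied:
            votes[y[j]] = votes.get(y[j], 0) + 1
        if len(tied) == 1:
            call = y[tied[0]]
        else:
            call = majority(votes) or AMBIGUOUS
        preds.append(
            Prediction(
                acc,
                call,
                support={
                    "distance": float(dmin),
                    "neighbours": [dist.accession_ids[j] for j in tied],
                    "votes": votes,
                },
            )
        )
    return preds


def classify_3nn_conservative(
    dist: DistanceMatrix, labels: LabelSet, params: KnnParams | None = None
) -> list[Prediction]:
    """Conservative 3-NN: the query votes for itself alongside 2 neighbours.

    Neighbour multiset per query = the query itself (distance 0, carrying its
    current label as one vote) plus its two nearest other accessions, plus —
    when ``include_all_ties`` — every accession tied with the third-nearest.
    The winning species needs at least ``min_votes`` (l, default 2) votes and
    must be the unique top scorer; otherwise the call is AMBIGUOUS.
    """
    params = params or KnnParams()
    if dist.n < params.k:
        raise ValueError(f"need at least {params.k} accessions")
    y = _check_labels(dist, labels)
    n_others = params.k - 1  # neighbours beyond the query itself
    preds: list[Prediction] = []
    for i, acc in enumerate(dist.accession_ids):
        row = dist.d[i].copy()
        row[i] = np.inf
        order = np.argsort(row, kind="stable")
        boundary = row[order[n_others - 1]]
        if params.include_all_ties:
            chosen = np.flatnonzero(row <= boundary)
        else:
            chosen = order[:n_others]
        votes: dict[str, float] = {y[i]: 1.0}  # the query's own current label
        for j in chosen:
            votes[y[j]] = votes.get(y[j], 0) + 1
        top = max(votes.values())
        winners = sorted(s for s, v in votes.items() if v == top)
        if top >= params.min_votes and len(winners) == 1:
            call = winners[0]
        else:
            call = AMBIGUOUS
        preds.append(
            Prediction(
                acc,
                call,
                support={
                    "votes": votes,
                    "neighbours": [dist.accession_ids[j] for j in chosen],
                },
            )
        )
    return preds
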