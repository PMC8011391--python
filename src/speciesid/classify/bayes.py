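"""Categorical Naive Bayes over genotype codes.

Each marker is treated as a categorical variable over its observed alphabet;
class-conditional cell probabilities get Laplace smoothing (alpha added to
every cell of the marker's alphabet), priors are class frequencies, and the
posterior is accumulated in log space. Marker independence is assumed — for
genotype data this amounts to disregarding linkage between markers.

Two prediction modes exist: plain resubstitution, and leave-one-out, which
refits the model without the query before scoring it (used to obtain an
unbiased accuracy estimate on complete collections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from speciesid.classify.base import AMBIGUOUS, NbParams, Prediction
from speciesid.genotype_data import GenotypeMatrix, LabelSet


@dataclass
class NBModel:
    species: list[str]
    class_counts: np.ndarray       # (k,)
    counts: np.ndarray             # (k, m, V) category counts per class/marker
    alphabet_sizes: np.ndarray     # (m,) observed alphabet size per marker
    alphabet_mask: np.ndarray      # (m, V) True where the code was observed
    alpha: float
    train_class: dict[str, int]    # training accession -> class code (for loo)

    @property
    def n_classes(self) -> int:
        return len(self.species)


def fit_nb(
    gm_imputed: GenotypeMatrix, labels: LabelSet, params: NbParams | None = None
) -> NBModel:
    """Tabulate class-conditional category counts and class priors."""
    params = params or NbParams()
    if gm_imputed.has_missing():
        raise ValueError("Naive Bayes requires a complete matrix; impute first")
    labels.validate_against(gm_imputed)
    species = labels.species()
    code = {s: c for c, s in enumerate(species)}
    y = np.array([code[labels[a]] for a in gm_imputed.accession_ids])
    X = gm_imputed.calls
    k = len(species)
    v = int(X.max()) + 1
    m = gm_imputed.n_markers
    counts = np.zeros((k, m, v), dtype=np.float64)
    for c in range(k):
        rows = X[y == c]
        for val in range(v):
            counts[c, :, val] = (rows == val).sum(axis=0)
    observed = counts.sum(axis=0) > 0  # (m, v)
    return NBModel(
        species=species,
        class_counts=np.bincount(y, minlength=k).astype(np.float64),
        counts=counts,
        alphabet_sizes=observed.sum(axis=1).astype(np.float64),
        alphabet_mask=observed,
        alpha=params.laplace_alpha,
        train_class={a: code[labels[a]] for a in gm_imputed.accession_ids},
    )


def _log_posteriors(model: NBModel, X: np.ndarray) -> np.ndarray:
    """(n, k) unnormalised log posteriors; -inf marks zero-probability classes."""
    k, m, v = model.counts.shape
    total = model.class_counts.sum()
    with np.errstate(divide="ignore"):
        log_prior = np.log(model.class_counts / total)
        denom = model.class_counts[:, None] + model.alpha * model.alphabet_sizes[None, :]
        log_cond = np.where(
            model.alphabet_mask[None, :, :],
            np.log(np.maximum(model.counts + model.alpha, 0.0)) - np.log(denom)[:, :, None],
            -np.inf,  # code never observed at this marker: outside the alphabet
        )
    n = X.shape[0]
    out = np.empty((n, k))
    marker_idx = np.arange(m)
    for i in range(n):
        out[i] = log_prior + log_cond[:, marker_idx, X[i]].sum(axis=1)
    return out


def _calls_from_logpost(
    accession_ids: list[str], logpost: np.ndarray, species: list[str]
) -> list[Prediction]:
    preds = []
    for i, acc in enumerate(accession_ids):
        row = logpost[i]
        if not np.isfinite(row).any():
            preds.append(Prediction(acc, AMBIGUOUS, support={"log_posterior": {}}))
            continue
        call = species[int(np.argmax(row))]  # argmax -> lexicographic on ties
        preds.append(
            Prediction(
                acc,
                call,
                support={"log_posterior": {s: float(row[c]) for c, s in enumerate(species)}},
            )
        )
    return preds


def classify_nb(
    model: NBModel, gm_imputed: GenotypeMatrix, mode: str = "resubstitution"
) -> list[Prediction]:
    """Maximum-posterior calls; ``mode`` is "resubstitution" or "loo".

    In leave-one-out mode the query's own genotype is subtracted from the
    count tables (and its class prior decremented) before scoring, so the
    model never sees the sample it predicts. A class emptied by the removal
    simply drops out. Posterior ties break toward the lexicographically
    first species; a query with zero posterior mass under every class (only
    possible with alpha=0) is AMBIGUOUS.
    """
    if gm_imputed.has_missing():
        raise ValueError("Naive Bayes requires a complete matrix; impute first")
    X = gm_imputed.calls
    if mode == "resubstitution":
        logpost = _log_posteriors(model, X)
        return _calls_from_logpost(gm_imputed.accession_ids, logpost, model.species)
    if mode != "loo":
        raise ValueError(f"unknown mode {mode!r}")
    # leave-one-out: peel each query's own counts out of the tables before
    # scoring it (equivalent to refitting without the query, with the
    # observed alphabet held fixed at the full-data one). Requires that the
    # matrix is the one the model was fitted on.
    unseen = [a for a in gm_imputed.accession_ids if a not in model.train_class]
    if unseen:
        raise ValueError(
            f"loo mode requires the training matrix; unknown accessions {unseen[:5]}"
        )
    X = gm_imputed.calls
    marker_idx = np.arange(gm_imputed.n_markers)
    preds: list[Prediction] = []
    for i, acc in enumerate(gm_imputed.accession_ids):
        c = model.train_class[acc]
        model.counts[c, marker_idx, X[i]] -= 1
        model.class_counts[c] -= 1
        logpost = _log_posteriors(model, X[i : i + 1])
        preds.extend(_calls_from_logpost([acc], logpost, model.species))
        model.counts[c, marker_idx, X[i]] += 1
        model.class_counts[c] += 1
    return preds
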