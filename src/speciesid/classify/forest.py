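"""Random Forest out-of-bag classification.

The forest is grown as an explicit bagging loop over CART trees (gini
impurity, mtry = floor(sqrt(p)) features per split, bootstrap with
replacement), so that per-tree bootstrap membership is first-class: the OOB
vote aggregation here and the proximity computation in the outlier module
both need to know exactly which trees a sample was out of bag for. With the
default 10,000 trees each sample is out of bag for about
(1 - 1/n)^n x n_trees ~ 3,680 trees, which is why the default is that large.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from speciesid.classify.base import AMBIGUOUS, ForestParams, Prediction
from speciesid.genotype_data import GenotypeMatrix, LabelSet


def _resolve_mtry(mtry: int | None, p: int) -> int:
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    if not (1 <= mtry <= p):
        raise ValueError(f"mtry must be in [1, {p}]")
    return mtry


def grow_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int | None, seed: int
):
    """Yield (fitted_tree, bootstrap_indices) for each tree in the forest."""
    n, p = X.shape
    mtry = _resolve_mtry(mtry, p)
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        yield tree, boot


def classify_rf_oob(
    gm_imputed: GenotypeMatrix, labels: LabelSet, params: ForestParams | None = None
) -> list[Prediction]:
    """Classify each accession by plurality vote of its out-of-bag trees.

    Only trees whose bootstrap sample excluded the accession vote for it, so
    the call is an unbiased prediction despite the accession having been part
    of training. Plurality ties break toward the lexicographically first
    species; an accession left in-bag by every tree (possible only for tiny
    forests) is reported AMBIGUOUS with a diagnostic.
    """
    params = params or ForestParams()
    if gm_imputed.has_missing():
        raise ValueError("Random Forest requires a complete matrix; impute first")
    labels.validate_against(gm_imputed)
    species = labels.species()
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    code = {s: c for c, s in enumerate(species)}
    y = np.array([code[labels[a]] for a in gm_imputed.accession_ids])
    X = gm_imputed.calls
    n = gm_imputed.n_accessions
    votes = np.zeros((n, len(species)), dtype=np.int64)
    oob_trees = np.zeros(n, dtype=np.int64)
    for tree, boot in grow_forest(X, y, params.n_trees, params.mtry, params.seed):
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        idx = np.flatnonzero(oob)
        if idx.size == 0:
            continue
        pred = tree.predict(X[idx])
        votes[idx, pred.astype(int)] += 1
        oob_trees[idx] += 1
    preds: list[Prediction] = []
    for i, acc in enumerate(gm_imputed.accession_ids):
        if oob_trees[i] == 0:
            preds.append(
                Prediction(acc, AMBIGUOUS, support={"oob_trees": 0, "oob_votes": {}})
            )
            continue
        fractions = votes[i] / oob_trees[i]
        call = species[int(np.argmax(votes[i]))]  # argmax -> lexicographic on ties
        preds.append(
            Prediction(
                acc,
                call,
                support={
                    "oob_trees": int(oob_trees[i]),
                    "oob_votes": {s: float(fractions[c]) for s, c in code.items()},
                },
            )
        )
    return preds


def simulate_oob_exposure(n_samples: int, n_trees: int, seed: int = 0) -> np.ndarray:
    """Per-sample count of OOB trees under pure bootstrap resampling.

    Draws the bootstrap membership only (no trees are fit); the mean count
    approaches n_trees x (1 - 1/n)^n ~ 0.368 x n_trees for large n.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_samples, dtype=np.int64)
    for _ in range(n_trees):
        boot = rng.integers(0, n_samples, size=n_samples)
        in_bag = np.bincount(boot, minlength=n_samples) > 0
        counts += ~in_bag
    return counts
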