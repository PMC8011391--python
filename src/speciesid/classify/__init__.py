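"""The five species classifiers and their shared prediction types.

Distance pairing follows the comparison design this toolkit implements:
divergent-site counts (pairwise deletion) feed 1-NN and Neighbour-Joining;
Euclidean distance on most-common-allele-imputed codes feeds the conservative
3-NN; Random Forest and Naive Bayes consume the imputed matrix directly.
:func:`run_classifier` wires those pipelines together by name.
"""

from __future__ import annotations

import pandas as pd

from speciesid.classify.base import (
    AMBIGUOUS,
    ForestParams,
    KnnParams,
    NbParams,
    Prediction,
    majority,
)
from speciesid.classify.bayes import NBModel, classify_nb, fit_nb
from speciesid.classify.forest import classify_rf_oob, grow_forest, simulate_oob_exposure
from speciesid.classify.knn import classify_1nn, classify_3nn_conservative
from speciesid.classify.njtree import NJTree, Node, build_nj, classify_nj
from speciesid.distance import divergent_sites, euclidean
from speciesid.genotype_data import GenotypeMatrix, LabelSet, impute_most_common

#: Canonical classifier names, in the order reports print them.
CLASSIFIER_NAMES = ("rf", "nb", "nj", "1nn", "3nn")


def run_classifier(
    name: str,
    gm: GenotypeMatrix,
    labels: LabelSet,
    seed: int = 0,
    n_trees: int | None = None,
    nb_mode: str = "resubstitution",
) -> list[Prediction]:
    """Run one classifier end to end on a labelled genotype matrix.

    Handles the classifier's full pipeline (imputation where required,
    distance computation, tree building). ``seed`` only affects the Random
    Forest; ``n_trees`` overrides its default of 10,000. ``nb_mode`` selects
    resubstitution (the curated-benchmark convention) or leave-one-out for
    Naive Bayes.
    """
    if name == "1nn":
        return classify_1nn(divergent_sites(gm), labels)
    if name == "3nn":
        return classify_3nn_conservative(euclidean(impute_most_common(gm)), labels)
    if name == "nj":
        return classify_nj(build_nj(divergent_sites(gm)), labels)
    if name == "rf":
        params = ForestParams(seed=seed) if n_trees is None else ForestParams(
            n_trees=n_trees, seed=seed
        )
        return classify_rf_oob(impute_most_common(gm), labels, params)
    if name == "nb":
        gmi = impute_most_common(gm)
        model = fit_nb(gmi, labels)
        return classify_nb(model, gmi, mode=nb_mode)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def predictions_to_frame(preds: list[Prediction], labels: LabelSet) -> pd.DataFrame:
    """Tabulate predictions next to the a-priori labels for TSV export."""
    return pd.DataFrame(
        {
            "accession": [p.accession_id for p in preds],
            "a_priori": [labels[p.accession_id] for p in preds],
            "predicted": [p.call for p in preds],
            "support": [repr(p.support) for p in preds],
        }
    )


__all__ = [
    "AMBIGUOUS",
    "CLASSIFIER_NAMES",
    "ForestParams",
    "KnnParams",
    "NBModel",
    "NbParams",
    "NJTree",
    "Node",
    "Prediction",
    "build_nj",
    "classify_1nn",
    "classify_3nn_conservative",
    "classify_nb",
    "classify_nj",
    "classify_rf_oob",
    "fit_nb",
    "grow_forest",
    "majority",
    "predictions_to_frame",
    "run_classifier",
    "simulate_oob_exposure",
]
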