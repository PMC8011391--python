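"""Random-Forest proximity screening for potentially misclassified accessions.

Proximity between two accessions is the fraction of trees in which they land
in the same terminal node. An accession with small proximities to the rest of
its labelled class — relative to the proximities those classmates have to
each other — is a candidate misclassification. Scores above the conventional
threshold of 10 are flagged.

Caveat for practice: when missing data were imputed with the most common
allele, low-coverage accessions of minority species are dragged toward the
majority species' genotype and show up as spurious outliers. The screen is
therefore advisory; treat flags as prompts for re-examination, not verdicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from speciesid.classify.forest import grow_forest
from speciesid.genotype_data import GenotypeMatrix, LabelSet


@dataclass
class ProximityMatrix:
    """Accessions x accessions co-termination fractions in [0, 1], diagonal 1."""

    accession_ids: list[str]
    prox: np.ndarray

    def __post_init__(self) -> None:
        self.prox = np.asarray(self.prox, dtype=np.float64)
        n = len(self.accession_ids)
        if self.prox.shape != (n, n):
            raise ValueError("proximity shape does not match accession ids")
        if not np.allclose(self.prox, self.prox.T):
            raise ValueError("proximity matrix is not symmetric")
        if (self.prox < -1e-9).any() or (self.prox > 1 + 1e-9).any():
            raise ValueError("proximities outside [0, 1]")


@dataclass
class OutlierScores:
    """Per-accession outlyingness on the scaled (median/MAD) scale.

    ``scores`` may contain NaN for accessions whose class has a single
    member (score undefined there — reported, never flagged).
    """

    accession_ids: list[str]
    classes: list[str]
    scores: np.ndarray
    threshold: float = 10.0

    @property
    def flagged(self) -> list[str]:
        return [
            a
            for a, s in zip(self.accession_ids, self.scores)
            if not np.isnan(s) and s > self.threshold
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": self.accession_ids,
                "class": self.classes,
                "score": self.scores,
                "flagged": [
                    bool(not np.isnan(s) and s > self.threshold) for s in self.scores
                ],
            }
        )


def rf_proximity(
    gm_imputed: GenotypeMatrix,
    labels: LabelSet,
    n_trees: int = 50_000,
    seed: int = 0,
    mtry: int | None = None,
    pairs: str = "all",
) -> ProximityMatrix:
    """Grow a supervised forest and accumulate terminal-node co-occupancy.

    ``pairs="all"`` counts every tree for every pair (normalised by the
    number of trees); ``pairs="oob"`` counts only trees where both accessions
    were out of bag (normalised per pair by the number of such trees) — both
    conventions are in circulation, so both are offered.
    """
    if pairs not in ("all", "oob"):
        raise ValueError("pairs must be 'all' or 'oob'")
    if gm_imputed.has_missing():
        raise ValueError("proximity requires a complete matrix; impute first")
    labels.validate_against(gm_imputed)
    species = labels.species()
    code = {s: c for c, s in enumerate(species)}
    y = np.array([code[labels[a]] for a in gm_imputed.accession_ids])
    X = gm_imputed.calls
    n = gm_imputed.n_accessions
    hits = np.zeros((n, n), dtype=np.float64)
    denom = np.zeros((n, n), dtype=np.float64) if pairs == "oob" else None
    for tree, boot in grow_forest(X, y, n_trees, mtry, seed):
        leaf = tree.apply(X)
        same = leaf[:, None] == leaf[None, :]
        if pairs == "all":
            hits += same
        else:
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            both = oob[:, None] & oob[None, :]
            hits += same & both
            denom += both
    if pairs == "all":
        prox = hits / n_trees
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            prox = np.where(denom > 0, hits / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(prox, 1.0)
    return ProximityMatrix(list(gm_imputed.accession_ids), prox)


def outlier_scores(
    prox: ProximityMatrix, labels: LabelSet, threshold: float = 10.0
) -> OutlierScores:
    """Class-relative outlyingness from a proximity matrix.

    Raw outlyingness of accession i is n_class / sum_j prox(i, j)^2 over its
    classmates j != i (self-proximity excluded; n_class counts the accession
    itself). Within each class the raw scores are centred by the class median
    and scaled by the class MAD with the standard consistency constant; a
    zero MAD falls back to centring only, with a warning. Flag = score above
    ``threshold`` (default 10, the conventional cut-off). Classes of size 1
    get an undefined (NaN) score: reported, never flagged.
    """
    missing = [a for a in prox.accession_ids if a not in labels.labels]
    if missing:
        raise ValueError(f"unlabelled accessions: {missing[:5]}")
    classes = [labels[a] for a in prox.accession_ids]
    arr = np.asarray(classes)
    scores = np.full(len(classes), np.nan)
    for cls in sorted(set(classes)):
        idx = np.flatnonzero(arr == cls)
        if idx.size < 2:
            continue  # undefined for singleton classes
        sub = prox.prox[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        ss = (sub**2).sum(axis=1)
        with np.errstate(divide="ignore"):
            raw = np.where(ss > 0, idx.size / ss, np.inf)
        med = np.median(raw[np.isfinite(raw)]) if np.isfinite(raw).any() else 0.0
        mad = median_abs_deviation(
            raw[np.isfinite(raw)], scale="normal"
        ) if np.isfinite(raw).any() else 0.0
        centred = raw - med
        if mad > 0:
            centred = centred / mad
        else:
            warnings.warn(
                f"class {cls!r}: zero MAD of raw outlyingness; scores left unscaled",
                stacklevel=2,
            )
        scores[idx] = centred
    return OutlierScores(list(prox.accession_ids), classes, scores, threshold=threshold)
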