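"""Pairwise dissimilarities between accessions.

Two measures are used downstream: the raw count of divergent sites with
pairwise deletion of missing data (1-NN and Neighbour-Joining), and Euclidean
distance on imputed integer codes (conservative 3-NN). Divergent-site counts
are deliberately *not* normalised by the number of comparable sites — this
reproduces the behaviour of the classic implementations, at the price of a
known downward bias for accession pairs with high missingness (documented in
the user guide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from speciesid.genotype_data import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative accession distances with zero diagonal.

    ``comparable_sites`` is populated only for pairwise-deletion distances
    and counts, per pair, the markers non-missing in both accessions.
    """

    accession_ids: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.accession_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match accession ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def index_of(self, accession: str) -> int:
        return self.accession_ids.index(accession)

    def to_tsv(self, path: str) -> None:
        """Square PHYLIP-like TSV export with a header row of accession ids."""
        import pandas as pd

        pd.DataFrame(self.d, index=self.accession_ids, columns=self.accession_ids).to_csv(
            path, sep="\t"
        )


def divergent_sites(gm: GenotypeMatrix) -> DistanceMatrix:
    """Count of divergent sites per pair, ignoring sites missing in either.

    d[i,j] = number of markers where both calls are non-missing and unequal
    (pairwise deletion). Raw counts are kept; ``comparable_sites`` records the
    per-pair denominator a user could normalise by. A pair with zero
    comparable sites has no defined distance and raises, naming the pair.
    """
    if gm.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    calls = gm.calls
    observed = calls != MISSING
    n = gm.n_accessions
    d = np.zeros((n, n), dtype=np.float64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = observed[i] & observed  # (n, m)
        diff = both & (calls != calls[i])
        comp[i] = both.sum(axis=1)
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(comp, gm.n_markers)
    zero = np.argwhere(comp == 0)
    if zero.size:
        i, j = zero[0]
        raise ValueError(
            f"no comparable sites between {gm.accession_ids[i]!r} and "
            f"{gm.accession_ids[j]!r}; distance undefined"
        )
    return DistanceMatrix(list(gm.accession_ids), d, comparable_sites=comp)


def euclidean(gm_imputed: GenotypeMatrix) -> DistanceMatrix:
    """Euclidean distance on integer genotype codes; requires imputed data."""
    if gm_imputed.has_missing():
        raise ValueError(
            "Euclidean distance requires a complete matrix; run impute_most_common first"
        )
    d = squareform(pdist(gm_imputed.calls.astype(np.float64), metric="euclidean"))
    return DistanceMatrix(list(gm_imputed.accession_ids), d)
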