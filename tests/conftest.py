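"""Shared fixtures: small hand-built matrices and synthetic collections."""

import numpy as np
import pytest

from speciesid.genotype_data import MISSING, GenotypeMatrix, LabelSet
from speciesid.synth import SynthParams, generate


@pytest.fixture
def tiny_dosage():
    """4 accessions x 5 markers with one missing call."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, 1, 2, 0, 0],
            [2, 1, 0, 2, MISSING],
            [2, 1, 0, 2, 2],
        ]
    )
    gm = GenotypeMatrix([f"a{i}" for i in range(4)], [f"m{j}" for j in range(5)], calls)
    labels = LabelSet({"a0": "A", "a1": "A", "a2": "B", "a3": "B"})
    return gm, labels


@pytest.fixture(scope="session")
def separated_collection():
    """Well-separated synthetic collection: 4 species x 8, high divergence."""
    gm, labels, truth = generate(
        SynthParams(
            n_species=4,
            accessions_per_species=8,
            n_markers=500,
            divergence=0.6,
            missing_rate=0.02,
            seed=11,
        )
    )
    return gm, labels, truth


def make_spread_matrix(m_target: int, others: dict[str, int]):
    """Target species of identical accessions far from distinct other accessions.

    The target species "A" has ``m_target`` all-zero rows. Every other
    species gets a 10-marker block of dosage 2, and every non-target
    accession additionally carries a globally unique number of extra derived
    alleles — so no two non-target accessions are equidistant from the
    target (no ties at the 3-NN boundary).
    """
    n_others = sum(others.values())
    base_region = 10 * len(others)
    extra_region = n_others * (n_others + 1) // 2
    n_markers = base_region + extra_region
    rows, ids, labels = [], [], {}
    for i in range(m_target):
        rows.append(np.zeros(n_markers, dtype=int))
        ids.append(f"A{i}")
        labels[f"A{i}"] = "A"
    pos = base_region
    uid = 0
    for b, (sp, count) in enumerate(sorted(others.items())):
        base = np.zeros(n_markers, dtype=int)
        base[b * 10 : b * 10 + 10] = 2
        for i in range(count):
            row = base.copy()
            row[pos : pos + uid + 1] = 1  # uid+1 unique extra ones
            pos += uid + 1
            uid += 1
            rows.append(row)
            ids.append(f"{sp}{i}")
            labels[f"{sp}{i}"] = sp
    gm = GenotypeMatrix(ids, [f"m{j}" for j in range(n_markers)], np.array(rows))
    return gm, LabelSet(labels)
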