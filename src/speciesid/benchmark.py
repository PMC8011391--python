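"""Misclassification-injection benchmark on curated collections.

The experiment this module reproduces: curate a collection down to species
with enough accessions, subsample each species to a fixed representation
(10, 8, 6, 4 or 2 accessions), randomly corrupt a fraction of the labels
(6.25%, 12.5% or 18.75%), let every classifier predict from the *corrupted*
labels, and score the predictions against the true pre-corruption labels.
Repeated thousands of times over the representation x rate grid, this
measures whether a classifier can improve the quality of a bad dataset.

Seeding is counter-based: the master seed plus the cell coordinates
(representation index, rate index, replicate) feed ``numpy``'s SeedSequence,
so any cell is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from speciesid.classify.base import Prediction
from speciesid.evaluate import accuracy
from speciesid.genotype_data import GenotypeMatrix, LabelSet

Classifier = Callable[[GenotypeMatrix, LabelSet, int], list[Prediction]]


@dataclass
class SimDesign:
    """Factorial benchmark design.

    Defaults are the full published-scale experiment: representations
    (2, 4, 6, 8, 10) x rates (6.25%, 12.5%, 18.75%) x 5,000 replicates =
    75,000 perturbed datasets. Scale ``replicates`` down for exploratory
    runs; the grid itself stays the stated world.
    """

    representations: tuple[int, ...] = (2, 4, 6, 8, 10)
    rates: tuple[float, ...] = (0.0625, 0.125, 0.1875)
    replicates: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 2 for r in self.representations):
            raise ValueError("representations must be >= 2")
        if any(not (0.0 < r < 1.0) for r in self.rates):
            raise ValueError("rates must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.representations) * len(self.rates) * self.replicates


@dataclass
class BenchmarkResult:
    """Long-format per-replicate accuracies plus the perturbation count."""

    table: pd.DataFrame  # columns: representation, rate, replicate, classifier, accuracy
    n_datasets: int
    design: SimDesign

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def medians(self) -> pd.DataFrame:
        """Representation x rate x classifier median accuracy (wide layout)."""
        return (
            self.table.pivot_table(
                index=["representation", "rate"],
                columns="classifier",
                values="accuracy",
                aggfunc="median",
            )
            .sort_index()
        )


def curate(
    gm: GenotypeMatrix,
    labels: LabelSet,
    min_species_size: int = 10,
    exclude: Iterable[str] = (),
) -> tuple[GenotypeMatrix, LabelSet]:
    """Drop under-represented species and explicitly excluded accessions.

    Exclusions (e.g. flagged outliers) are removed first; any species whose
    count then falls below ``min_species_size`` is dropped entirely — so a
    species can be eliminated by its own exclusions. Raises if fewer than two
    species survive.
    """
    labels.validate_against(gm)
    excluded = set(exclude)
    kept = [a for a in gm.accession_ids if a in labels.labels and a not in excluded]
    counts: dict[str, int] = {}
    for a in kept:
        counts[labels[a]] = counts.get(labels[a], 0) + 1
    ok_species = {s for s, c in counts.items() if c >= min_species_size}
    final = [a for a in kept if labels[a] in ok_species]
    if len(ok_species) < 2:
        raise ValueError(
            f"fewer than 2 species with >= {min_species_size} accessions survive curation"
        )
    idx = [gm.accession_ids.index(a) for a in final]
    return gm.take_accessions(idx), labels.subset(final)


def subsample(
    gm: GenotypeMatrix,
    labels: LabelSet,
    n_per_species: int,
    seed: int | np.random.Generator,
) -> tuple[GenotypeMatrix, LabelSet]:
    """Uniform random selection of exactly n accessions per species."""
    labels.validate_against(gm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_species: dict[str, list[int]] = {}
    for i, a in enumerate(gm.accession_ids):
        by_species.setdefault(labels[a], []).append(i)
    chosen: list[int] = []
    for sp in sorted(by_species):
        pool = by_species[sp]
        if len(pool) < n_per_species:
            raise ValueError(
                f"species {sp!r} has {len(pool)} accessions, fewer than {n_per_species}"
            )
        pick = rng.choice(len(pool), size=n_per_species, replace=False)
        chosen.extend(pool[k] for k in sorted(pick))
    chosen.sort()
    sub = gm.take_accessions(chosen)
    return sub, labels.subset(sub.accession_ids)


def inject_misclassifications(
    labels: LabelSet, rate: float, seed: int | np.random.Generator
) -> LabelSet:
    """Randomly corrupt round(rate x N) labels to a different species.

    Each corrupted accession receives a species drawn uniformly from the
    *other* species present, so every altered label differs from its
    original. The returned set has provenance "perturbed" and retains the
    originals. Rounding is half-up; a rate that rounds to zero alterations
    returns the labels unchanged, with a warning.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    accs = list(labels.labels)
    species = labels.species()
    if len(species) < 2:
        raise ValueError("need at least 2 species to inject misclassifications")
    n = len(accs)
    n_alter = int(np.floor(rate * n + 0.5))  # half-up; exact for sixteenth rates
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_alter == 0:
        warnings.warn("rate x N rounds to 0: no labels altered", stacklevel=2)
        return LabelSet(dict(labels.labels), provenance="perturbed",
                        original=dict(labels.labels))
    targets = rng.choice(n, size=n_alter, replace=False)
    new = dict(labels.labels)
    k = len(species)
    for t in targets:
        acc = accs[t]
        others = [s for s in species if s != labels[acc]]
        new[acc] = others[int(rng.integers(0, k - 1))]
    return LabelSet(new, provenance="perturbed", original=dict(labels.labels))


def _cell_rng(master_seed: int, *counters: int) -> np.random.Generator:
    """Counter-based child generator: reproducible per cell in isolation."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=counters))


def run_grid(
    gm: GenotypeMatrix,
    labels: LabelSet,
    design: SimDesign,
    classifiers: dict[str, Classifier] | None = None,
    score_against: str = "true",
    progress: Callable[[str], None] | None = None,
) -> BenchmarkResult:
    """Run the full representation x rate x replicate grid.

    For every cell: subsample the curated collection, inject
    misclassifications, and hand each classifier the *identical* perturbed
    label set; predictions are scored against the true pre-perturbation
    labels (``score_against="perturbed"`` scores against the corrupted
    labels instead, for diagnostics). Classifier exceptions are recorded as
    NaN accuracy for that cell rather than aborting the grid. With an empty
    classifier dict the grid still generates every perturbed dataset — used
    to audit the design size cheaply.

    Classifier callables receive ``(gm_subsample, perturbed_labels, seed)``.
    """
    if score_against not in ("true", "perturbed"):
        raise ValueError("score_against must be 'true' or 'perturbed'")
    classifiers = classifiers or {}
    rows: list[tuple] = []
    n_datasets = 0
    for ri, rep in enumerate(design.representations):
        for qi, rate in enumerate(design.rates):
            for rr in range(design.replicates):
                rng = _cell_rng(design.seed, ri, qi, rr)
                sub_gm, sub_labels = subsample(gm, labels, rep, rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    perturbed = inject_misclassifications(sub_labels, rate, rng)
                n_datasets += 1
                target = sub_labels if score_against == "true" else perturbed
                for name, clf in classifiers.items():
                    cell_seed = int(rng.integers(0, 2**31 - 1))
                    try:
                        preds = clf(sub_gm, perturbed, cell_seed)
                        report = accuracy(preds, target)
                        acc = report.overall  # may be None if all ambiguous
                    except Exception as exc:  # recorded, not fatal to the grid
                        if progress:
                            progress(f"cell ({rep},{rate},{rr}) {name}: {exc!r}")
                        acc = None
                    rows.append(
                        (rep, rate, rr, name, np.nan if acc is None else acc)
                    )
            if progress:
                progress(f"representation={rep} rate={rate}: done")
    table = pd.DataFrame(
        rows, columns=["representation", "rate", "replicate", "classifier", "accuracy"]
    )
    return BenchmarkResult(table=table, n_datasets=n_datasets, design=design)
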