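"""Synthetic multi-species genotype collections.

Species structure follows the Balding–Nichols model: each marker draws an
ancestral allele frequency p uniformly from a range, and each species s draws
its own frequency p_s ~ Beta(p (1-F)/F, (1-p)(1-F)/F), where F plays the role
of the divergence (FST) between species. Genotypes are then Binomial(2, p_s)
ALT dosages (or Bernoulli(p_s) presence calls in dominant mode), with an iid
missingness mask. This yields tunable, realistic species clustering from two
parameters — it is a stand-in for real collections, not a demographic claim
about any particular genus; in particular no linkage is simulated and
within-species structure is pure Hardy–Weinberg noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from speciesid.genotype_data import DOMINANT, DOSAGE, MISSING, GenotypeMatrix, LabelSet


@dataclass
class SynthParams:
    """Generator settings.

    Defaults emulate the curated-collection scale the benchmark targets:
    8 species of 10 accessions each, 2,000 informative markers, moderate
    divergence (F=0.3), ancestral frequencies away from fixation, and 5%
    missing data.
    """

    n_species: int = 8
    accessions_per_species: int | list[int] = 10
    n_markers: int = 2000
    divergence: float = 0.3
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.05
    ploidy_mode: str = DOSAGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_markers < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence F must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        if self.ploidy_mode not in (DOSAGE, DOMINANT):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")

    @property
    def counts(self) -> list[int]:
        if isinstance(self.accessions_per_species, int):
            return [self.accessions_per_species] * self.n_species
        if len(self.accessions_per_species) != self.n_species:
            raise ValueError("accessions_per_species list length must equal n_species")
        return list(self.accessions_per_species)


def generate(params: SynthParams) -> tuple[GenotypeMatrix, LabelSet, dict[str, Any]]:
    """Generate a labelled collection plus a truth record.

    The truth record stores the ancestral and per-species allele frequencies
    (arrays of shape (m,) and (S, m)) so tests can check the generator
    against population-genetic estimators.
    """
    rng = np.random.default_rng(params.seed)
    counts = params.counts
    f = params.divergence
    lo, hi = params.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=params.n_markers)
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    p_species = rng.beta(a, b, size=(params.n_species, params.n_markers))
    species_names = [f"sp{str(s + 1).zfill(2)}" for s in range(params.n_species)]
    blocks = []
    accession_ids: list[str] = []
    label_map: dict[str, str] = {}
    for s, (name, c) in enumerate(zip(species_names, counts)):
        if params.ploidy_mode == DOSAGE:
            block = rng.binomial(2, p_species[s], size=(c, params.n_markers))
        else:
            block = rng.binomial(1, p_species[s], size=(c, params.n_markers))
        blocks.append(block)
        for i in range(c):
            acc = f"{name}_a{str(i + 1).zfill(3)}"
            accession_ids.append(acc)
            label_map[acc] = name
    calls = np.vstack(blocks).astype(np.int16)
    if params.missing_rate > 0:
        mask = rng.random(calls.shape) < params.missing_rate
        calls[mask] = MISSING
    marker_ids = [f"m{str(j + 1).zfill(5)}" for j in range(params.n_markers)]
    gm = GenotypeMatrix(accession_ids, marker_ids, calls, ploidy_mode=params.ploidy_mode)
    truth = {
        "ancestral_freq": p_anc,
        "species_freq": p_species,
        "species_names": species_names,
        "params": params,
    }
    return gm, LabelSet(label_map), truth


def write_vcf(gm: GenotypeMatrix, path: str, depth: int = 20) -> None:
    """Write a minimal synthetic VCF (GT + per-genotype DP) for dosage data.

    Markers become biallelic A/T SNPs on one contig at consecutive
    positions; missing calls become ./. with DP 0. Intended for exercising
    the VCF reader, not for interchange with callers.
    """
    if gm.ploidy_mode != DOSAGE:
        raise ValueError("VCF export requires dosage data")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accession_ids)
            + "\n"
        )
        for j, marker in enumerate(gm.marker_ids):
            cells = []
            for i in range(gm.n_accessions):
                call = int(gm.calls[i, j])
                dp = 0 if call == MISSING else depth
                cells.append(f"{gt_codes[call]}:{dp}")
            fh.write(
                f"1\t{j + 1}\t{marker}\tA\tT\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )
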