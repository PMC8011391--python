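"""Labelled genotype matrices: reading, filtering, thinning and imputation.

The data model is shared by every downstream stage. Calls are integer coded:
diploid SNPs as ALT-allele dosage (0/1/2), dominant markers (e.g. AFLP
presence/absence) as 0/1. Missing data use the reserved sentinel
:data:`MISSING` (-1), distinct from any valid dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing call. Never a valid dosage.
MISSING: int = -1

#: Token used for missing cells in delimited matrix files.
NA_TOKEN = "NA"

DOSAGE = "dosage"
DOMINANT = "dominant"

_ALPHABET = {DOSAGE: (0, 1, 2), DOMINANT: (0, 1)}


class EmptyResultError(ValueError):
    """No markers (or accessions) survived an operation that required some.

    Raised as a distinct condition so callers (and the CLI) can tell an empty
    result apart from malformed input.
    """


@dataclass
class GenotypeMatrix:
    """Accessions x markers integer-coded genotype calls.

    Parameters
    ----------
    accession_ids : list of str
        Row labels; unique, order preserved.
    marker_ids : list of str
        Column labels; unique, order preserved.
    calls : ndarray of int
        Shape ``(n_accessions, n_markers)``. Non-missing values must lie in
        {0,1,2} for ``dosage`` mode or {0,1} for ``dominant`` mode; missing
        cells hold :data:`MISSING`.
    ploidy_mode : {"dosage", "dominant"}
    het_flagged : set of str
        Dominant-mode markers in which a heterozygous call (cell value 2) was
        observed at read time — an anomaly for a dominant marker system. The
        offending cells are stored as :data:`MISSING`; the flag marks the
        whole marker for removal by :func:`filter_dominant_markers`.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    ploidy_mode: str = DOSAGE
    het_flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n, m = self.calls.shape
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ValueError("calls shape does not match id lists")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if self.ploidy_mode not in _ALPHABET:
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        observed = self.calls[self.calls != MISSING]
        if observed.size and not np.isin(observed, _ALPHABET[self.ploidy_mode]).all():
            bad = sorted(set(observed.tolist()) - set(_ALPHABET[self.ploidy_mode]))
            raise ValueError(
                f"calls outside the {self.ploidy_mode} alphabet: {bad}"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def take_accessions(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Row subset in the given order."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            accession_ids=[self.accession_ids[i] for i in idx],
            calls=self.calls[idx],
        )

    def take_markers(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Column subset in the given order."""
        idx = np.asarray(indices, dtype=int)
        kept = [self.marker_ids[i] for i in idx]
        return replace(
            self,
            marker_ids=kept,
            calls=self.calls[:, idx],
            het_flagged=self.het_flagged & set(kept),
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame with MISSING rendered as NA."""
        df = pd.DataFrame(
            self.calls, index=self.accession_ids, columns=self.marker_ids
        ).astype("Int64")
        return df.mask(df == MISSING)


@dataclass
class LabelSet:
    """Accession -> species assignments with provenance.

    ``provenance`` records whether the labels are the collection's a-priori
    classifications, a perturbed (noise-injected) copy, or classifier output.
    For perturbed sets, ``original`` retains the pre-perturbation labels so
    benchmark scoring can target the truth.
    """

    labels: dict[str, str]
    provenance: str = "a_priori"
    original: dict[str, str] | None = None

    PROVENANCES = ("a_priori", "perturbed", "predicted")

    def __post_init__(self) -> None:
        if self.provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        for acc, sp in self.labels.items():
            if not sp:
                raise ValueError(f"empty species label for accession {acc!r}")

    def __getitem__(self, accession: str) -> str:
        return self.labels[accession]

    def __len__(self) -> int:
        return len(self.labels)

    def species(self) -> list[str]:
        """Sorted unique species names."""
        return sorted(set(self.labels.values()))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.labels.values():
            out[sp] = out.get(sp, 0) + 1
        return out

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = set(self.labels) - set(gm.accession_ids)
        if missing:
            raise ValueError(f"labelled accessions absent from matrix: {sorted(missing)[:5]}")

    def subset(self, accessions: list[str]) -> "LabelSet":
        return LabelSet(
            {a: self.labels[a] for a in accessions},
            provenance=self.provenance,
            original={a: self.original[a] for a in accessions} if self.original else None,
        )


@dataclass
class FilterSpec:
    """Site- and call-level filters applied while reading variant data.

    Defaults mirror common practice for reduced-representation collections:
    keep sites with >80% call rate and >1% minor allele frequency, drop
    indels, and mask individual genotype calls supported by fewer than
    ``min_call_depth`` reads (0 disables the depth mask).
    """

    min_call_rate: float = 0.8
    min_maf: float = 0.01
    drop_indels: bool = True
    min_call_depth: int = 0
    drop_heterozygous_markers: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must be in [0, 1]")
        if not (0.0 <= self.min_maf <= 1.0):
            raise ValueError("min_maf must be in [0, 1]")
        if self.min_call_depth < 0:
            raise ValueError("min_call_depth must be >= 0")


def read_vcf(path: str, filter_spec: FilterSpec | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into an ALT-dosage matrix.

    Indel and multiallelic records are dropped when ``drop_indels`` is set
    (multiallelic sites are treated like indels: outside the biallelic dosage
    model). When ``min_call_depth > 0`` genotype calls with per-sample DP
    below the threshold become MISSING *before* the site-level call-rate and
    MAF filters, mirroring the usual depth-then-site filtering order.

    Raises
    ------
    EmptyResultError
        If no sites survive filtering.
    """
    from cyvcf2 import VCF

    spec = filter_spec or FilterSpec()
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path!r} contains no samples")
    n = len(samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            if spec.drop_indels:
                continue
            if len(var.ALT) != 1:
                continue  # multiallelic records never fit the dosage code
        dosage = np.full(n, MISSING, dtype=np.int16)
        gts = var.genotypes  # [[a0, a1, phased], ...]
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            dosage[i] = sum(1 for a in alleles if a > 0)
        if spec.min_call_depth > 0:
            depths = var.format("DP")
            if depths is None:
                raise ValueError(
                    f"min_call_depth={spec.min_call_depth} requires per-genotype DP "
                    f"(absent at {var.CHROM}:{var.POS})"
                )
            low = depths.reshape(-1)[:n] < spec.min_call_depth
            dosage[low] = MISSING
        called = dosage != MISSING
        if called.sum() / n < spec.min_call_rate:
            continue
        if called.sum() == 0:
            continue
        p_alt = dosage[called].sum() / (2 * called.sum())
        if min(p_alt, 1.0 - p_alt) < spec.min_maf:
            continue
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        marker_ids.append(name)
        columns.append(dosage)
    if not columns:
        raise EmptyResultError(f"no sites in {path!r} survive the filters")
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(samples, _dedupe(marker_ids), calls, ploidy_mode=DOSAGE)


def _dedupe(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}.{seen[x]}")
        else:
            seen[x] = 0
            out.append(x)
    return out


def read_matrix(path: str, ploidy_mode: str = DOSAGE) -> GenotypeMatrix:
    """Read a delimited genotype matrix (TSV/CSV).

    Dialect: header row of marker ids, first column of accession ids, cells
    integer or the token ``NA``. In dominant mode a cell value of 2 — the
    "heterozygous" anomaly of a dominant marker system — is accepted at read
    time: the cell becomes MISSING and the marker is flagged so
    :func:`filter_dominant_markers` can drop it.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=[NA_TOKEN], keep_default_na=False
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty matrix file {path!r}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"matrix file {path!r} has no data cells")
    accession_ids = [str(a) for a in df.index]
    marker_ids = [str(m) for m in df.columns]
    if len(set(accession_ids)) != len(accession_ids):
        raise ValueError("duplicate accession ids in matrix file")
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError("duplicate marker ids in matrix file")
    values = df.to_numpy()
    calls = np.full(df.shape, MISSING, dtype=np.int16)
    mask = ~pd.isna(values)
    try:
        flat = values[mask].astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path!r}") from exc
    if not np.all(flat == np.floor(flat)):
        raise ValueError(f"non-integer cell in {path!r}")
    calls[mask] = flat.astype(np.int16)
    het_flagged: set[str] = set()
    if ploidy_mode == DOMINANT:
        het_cells = calls == 2
        if het_cells.any():
            for j in np.flatnonzero(het_cells.any(axis=0)):
                het_flagged.add(marker_ids[j])
            calls[het_cells] = MISSING
    allowed = set(_ALPHABET[ploidy_mode]) | {MISSING}
    bad = set(np.unique(calls).tolist()) - allowed
    if bad:
        raise ValueError(f"calls outside the {ploidy_mode} alphabet: {sorted(bad)}")
    return GenotypeMatrix(
        accession_ids, marker_ids, calls, ploidy_mode=ploidy_mode, het_flagged=het_flagged
    )


def write_matrix(gm: GenotypeMatrix, path: str) -> None:
    """Write the delimited matrix dialect read by :func:`read_matrix`."""
    sep = "," if str(path).endswith(".csv") else "\t"
    gm.to_frame().to_csv(path, sep=sep, na_rep=NA_TOKEN)


def read_labels(path: str) -> LabelSet:
    """Read a two-column TSV (accession, species) into a LabelSet."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "species"], dtype=str)
    if df["accession"].duplicated().any():
        raise ValueError(f"duplicate accessions in label file {path!r}")
    return LabelSet(dict(zip(df["accession"], df["species"])))


def write_labels(labels: LabelSet, path: str) -> None:
    with open(path, "w") as fh:
        for acc, sp in labels.labels.items():
            fh.write(f"{acc}\t{sp}\n")


def filter_dominant_markers(gm: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Drop heterozygous-flagged markers, then low-MAF markers (dominant data).

    Heterozygous-flagged markers are removed first; MAF is then computed over
    the remaining markers from the presence frequency p of non-missing calls,
    MAF = min(p, 1-p), and markers with MAF strictly below ``min_maf`` are
    removed. May return zero markers (reported via a warning, not an error).
    """
    if gm.ploidy_mode != DOMINANT:
        raise ValueError("filter_dominant_markers requires dominant-mode data")
    keep = [j for j, m in enumerate(gm.marker_ids) if m not in gm.het_flagged]
    out = gm.take_markers(keep)
    if min_maf > 0 and out.n_markers:
        calls = out.calls
        present = (calls == 1).sum(axis=0)
        non_missing = (calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(non_missing > 0, present / np.maximum(non_missing, 1), 0.0)
        maf = np.minimum(p, 1.0 - p)
        out = out.take_markers(np.flatnonzero(maf >= min_maf))
    if out.n_markers == 0:
        warnings.warn("no markers survive dominant-marker filtering", stacklevel=2)
    return out


def thin_markers(gm: GenotypeMatrix, max_sites: int, seed: int) -> GenotypeMatrix:
    """Random uniform subset of min(max_sites, n_markers) markers, order kept."""
    if max_sites < 1:
        raise ValueError("max_sites must be >= 1")
    if max_sites >= gm.n_markers:
        return gm
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(gm.n_markers, size=max_sites, replace=False))
    return gm.take_markers(chosen)


def filter_accession_missingness(
    gm: GenotypeMatrix, labels: LabelSet | None, max_missing_rate: float
) -> tuple[GenotypeMatrix, LabelSet | None]:
    """Drop accessions whose fraction of missing calls exceeds a threshold.

    Offered as a marker-level proxy for raw-read-count accession filters that
    operate upstream of variant calling (low sequencing effort shows up as
    high missingness after depth masking).
    """
    if not (0.0 <= max_missing_rate <= 1.0):
        raise ValueError("max_missing_rate must be in [0, 1]")
    rate = gm.missing_mask.mean(axis=1)
    keep = np.flatnonzero(rate <= max_missing_rate)
    out = gm.take_accessions(keep)
    if out.n_accessions == 0:
        raise EmptyResultError("no accessions survive the missingness filter")
    return out, labels.subset(out.accession_ids) if labels is not None else None


def impute_most_common(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each MISSING cell with its marker's modal non-missing call.

    Modal ties are broken toward the lowest code, making the operation
    deterministic. Idempotent; raises on an all-missing marker column (named
    in the message). Note that for collections dominated by one species this
    imputation pulls rare species toward the majority genotype — downstream
    outlier screens treat it as a known false-positive source.
    """
    calls = gm.calls.copy()
    n_codes = max(_ALPHABET[gm.ploidy_mode]) + 1
    for j in range(calls.shape[1]):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"marker {gm.marker_ids[j]!r} has no non-missing calls")
        counts = np.bincount(obs, minlength=n_codes)
        col[miss] = int(np.argmax(counts))  # argmax -> lowest code on ties
    return replace(gm, calls=calls)
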