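"""Accuracy metrics and nonparametric classifier comparison.

Prediction accuracy here excludes ambiguous calls from both numerator and
denominator — a classifier that abstains is neither rewarded nor punished
for those accessions, which matters for the conservative rules that abstain
by design. The omnibus comparison across classifiers uses Friedman Aligned
Ranks (better behaved than plain Friedman for <= 4-5 classifiers), with
Finner step-down correction of the p-values and, when the omnibus rejects,
a multiple comparison of every classifier against the one with the highest
mean accuracy as control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from speciesid.classify.base import AMBIGUOUS, Prediction
from speciesid.genotype_data import LabelSet


@dataclass
class AccuracyReport:
    """Overall and per-species accuracy with ambiguity exclusion.

    ``overall`` is None when every prediction was ambiguous (undefined, not
    zero). Per-species entries may individually be None for the same reason.
    """

    overall: float | None
    per_species: dict[str, float | None]
    n_ambiguous: int
    n_total: int


def accuracy(preds: list[Prediction], true_labels: LabelSet) -> AccuracyReport:
    """Correct / (N - ambiguous), overall and within each true species."""
    missing = [p.accession_id for p in preds if p.accession_id not in true_labels.labels]
    if missing:
        raise ValueError(f"predictions for unlabelled accessions: {missing[:5]}")
    n_total = len(preds)
    n_amb = sum(1 for p in preds if p.is_ambiguous)
    scored = [(true_labels[p.accession_id], p.call) for p in preds if not p.is_ambiguous]
    overall = (
        sum(1 for t, c in scored if t == c) / len(scored) if scored else None
    )
    per: dict[str, float | None] = {}
    for sp in sorted({true_labels[p.accession_id] for p in preds}):
        sp_scored = [(t, c) for t, c in scored if t == sp]
        per[sp] = (
            sum(1 for t, c in sp_scored if t == c) / len(sp_scored)
            if sp_scored
            else None
        )
    return AccuracyReport(overall=overall, per_species=per, n_ambiguous=n_amb, n_total=n_total)


def confusion(
    preds: list[Prediction], true_labels: LabelSet, focus_species: list[str]
) -> pd.DataFrame:
    """Fractional confusion rows for a focus species set.

    Rows are the focus species (true labels); columns are each focus species,
    "Other" (any non-focus predicted species) and "AMBIGUOUS". Each row sums
    to 1 over that species' accessions. Raises if a focus species has no
    predicted accessions.
    """
    if not focus_species:
        raise ValueError("focus list must be non-empty")
    by_species: dict[str, list[str]] = {sp: [] for sp in focus_species}
    for p in preds:
        t = true_labels[p.accession_id]
        if t in by_species:
            by_species[t].append(p.call)
    cols = list(focus_species) + ["Other", AMBIGUOUS]
    rows = {}
    for sp in focus_species:
        calls = by_species[sp]
        if not calls:
            raise ValueError(f"no predictions for focus species {sp!r}")
        n = len(calls)
        row = {c: 0.0 for c in cols}
        for call in calls:
            if call == AMBIGUOUS:
                row[AMBIGUOUS] += 1
            elif call in by_species:
                row[call] += 1
            else:
                row["Other"] += 1
        rows[sp] = {c: v / n for c, v in row.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


@dataclass
class StatResult:
    """Friedman-Aligned-Ranks omnibus result (and hooks for the post-hoc)."""

    classifiers: list[str]
    rank_sums: np.ndarray        # aligned-rank sums per classifier, R_.j
    problem_rank_sums: np.ndarray  # aligned-rank sums per problem, R_i.
    mean_ranks: np.ndarray       # R_.j / n
    statistic: float
    df: int
    pvalue: float
    n_problems: int
    mean_accuracy: np.ndarray = field(default=None)  # type: ignore[assignment]


def friedman_aligned_ranks(table: pd.DataFrame | np.ndarray) -> StatResult:
    """Friedman Aligned Ranks omnibus test on a problems x classifiers table.

    Observations are aligned by subtracting each problem's mean, then all
    k*n aligned values are ranked jointly (mid-ranks on ties). The statistic

        T = (k-1) [ sum_j R_.j^2 - (k n^2 / 4)(k n + 1)^2 ]
            / { [k n (k n + 1)(2 k n + 1)] / 6 - (1/k) sum_i R_i.^2 }

    is referred to chi-squared with k-1 degrees of freedom. A degenerate
    denominator (all problems internally constant) yields T=0, p=1.
    """
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        names = [f"clf{j}" for j in range(values.shape[1])]
    if values.ndim != 2:
        raise ValueError("table must be 2-D (problems x classifiers)")
    n, k = values.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 classifiers and 2 problems")
    if np.isnan(values).any():
        raise ValueError("table must be complete (no NaN)")
    aligned = values - values.mean(axis=1, keepdims=True)
    ranks = stats.rankdata(aligned, axis=None).reshape(n, k)  # mid-ranks on ties
    col_sums = ranks.sum(axis=0)
    row_sums = ranks.sum(axis=1)
    kn = k * n
    num = (k - 1) * (np.sum(col_sums**2) - (k * n**2 / 4.0) * (kn + 1) ** 2)
    den = kn * (kn + 1) * (2 * kn + 1) / 6.0 - np.sum(row_sums**2) / k
    if den <= 1e-12:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = float(num / den)
        t_stat = max(t_stat, 0.0)
        p = float(stats.chi2.sf(t_stat, k - 1))
    return StatResult(
        classifiers=names,
        rank_sums=col_sums,
        problem_rank_sums=row_sums,
        mean_ranks=col_sums / n,
        statistic=t_stat,
        df=k - 1,
        pvalue=p,
        n_problems=n,
        mean_accuracy=values.mean(axis=0),
    )


def finner_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Finner step-down multiple-testing adjustment.

    With p-values sorted ascending, adjusted_(i) = max_{j<=i} min(1,
    1 - (1 - p_(j))^(m/j)); results return in the original order and are
    monotone non-decreasing in the ordered inputs.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order, start=1):
        val = min(1.0, 1.0 - (1.0 - p[idx]) ** (m / i))
        running = max(running, val)
        adj_sorted[i - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class PosthocResult:
    """Control comparison after a significant omnibus test."""

    performed: bool
    control: str | None = None
    comparisons: pd.DataFrame | None = None  # classifier, z, p, p_adjusted, reject
    reason: str | None = None


def posthoc_vs_control(
    stat: StatResult, alpha: float = 0.05, omnibus_p: float | None = None
) -> PosthocResult:
    """Aligned-rank multiple comparison against the best classifier.

    Performed only when the (possibly already-corrected) omnibus p-value is
    below ``alpha``; otherwise a no-comparison marker is returned. The
    control is the classifier with the highest mean accuracy. Each other
    classifier j is compared via

        z_j = (mean aligned rank_j - mean aligned rank_control)
              / sqrt(k (n + 1) / 6)

    with two-sided normal p-values, Finner-adjusted over the k-1
    comparisons.
    """
    p_omni = stat.pvalue if omnibus_p is None else omnibus_p
    if p_omni >= alpha:
        return PosthocResult(
            performed=False, reason=f"omnibus p={p_omni:.4g} >= alpha={alpha}"
        )
    k = len(stat.classifiers)
    n = stat.n_problems
    if stat.mean_accuracy is None:
        raise ValueError("StatResult lacks mean accuracies; rerun the omnibus test")
    control_idx = int(np.argmax(stat.mean_accuracy))
    se = np.sqrt(k * (n + 1) / 6.0)
    rows = []
    for j in range(k):
        if j == control_idx:
            continue
        z = (stat.mean_ranks[j] - stat.mean_ranks[control_idx]) / se
        rows.append((stat.classifiers[j], float(z), float(2 * stats.norm.sf(abs(z)))))
    df = pd.DataFrame(rows, columns=["classifier", "z", "p"])
    df["p_adjusted"] = finner_adjust(df["p"].to_numpy())
    df["reject"] = df["p_adjusted"] < alpha
    return PosthocResult(
        performed=True, control=stat.classifiers[control_idx], comparisons=df
    )


def compare_benchmark(
    medians: pd.DataFrame, alpha: float = 0.05, per_group: bool = True
) -> list[tuple[str, StatResult, PosthocResult]]:
    """Run the omnibus + post-hoc stack on a median-accuracy table.

    ``medians`` is the (representation, rate) x classifier layout produced by
    ``BenchmarkResult.medians()``. With ``per_group=True`` (the default,
    matching the grouped analysis) the test runs once per misclassification
    rate, treating representations as problems; otherwise once over all
    cells. Omnibus p-values across groups are Finner-corrected before the
    post-hoc gate.
    """
    groups: list[tuple[str, pd.DataFrame]]
    if per_group:
        groups = [
            (f"rate={rate}", sub.droplevel("rate"))
            for rate, sub in medians.groupby(level="rate")
        ]
    else:
        groups = [("all", medians)]
    stats_list = [(name, friedman_aligned_ranks(tbl)) for name, tbl in groups]
    adj = finner_adjust([s.pvalue for _, s in stats_list])
    out = []
    for (name, s), p_adj in zip(stats_list, adj):
        out.append((name, s, posthoc_vs_control(s, alpha=alpha, omnibus_p=float(p_adj))))
    return out
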