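"""Differential quantification of DIA reports, without imputation.

Input is the long-format report of a DIA search engine (one row per
run x protein group with a quantity column, default ``PG.MaxLFQ``). The
pipeline pivots it to a protein x run matrix, median-centers each run on
the log2 scale, and compares two groups of runs with Welch's unequal-
variance t-test. Missing values stay missing at every step — a protein
absent from a run contributes nothing to means, variances or tests, and is
never zero-filled; proteins observed in only one group are instead called
"exclusive" to that group when seen in enough replicates.

Volcano-style classification uses a raw-p and fold-change double gate
(defaults p < 0.05, |log2FC| > 1 as used for alternative proteins; a
stricter p < 0.01 gate is conventional for deep canonical proteomes).
Benjamini-Hochberg FDR is reported alongside for information but plays no
part in the classification.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_REPORT_COLUMNS = ("Run", "Protein.Group")
DEFAULT_QUANTITY_COLUMN = "PG.MaxLFQ"

DEFAULT_P_CUT = 0.05
DEFAULT_FC_CUT = 1.0
DEFAULT_MIN_N_EXCLUSIVE = 3


class DifferentialClass(str, Enum):
    UP_IN_GROUP1 = "up_in_group1"
    UP_IN_GROUP2 = "up_in_group2"
    NOT_SIGNIFICANT = "not_significant"
    EXCLUSIVE_GROUP1 = "exclusive_group1"
    EXCLUSIVE_GROUP2 = "exclusive_group2"
    UNTESTABLE = "untestable"


@dataclass
class QuantTable:
    """Protein-group x run intensity matrix with two-group run labels.

    ``intensity`` is linear-scale with NaN for missing cells; ``group_of_run``
    maps every run to one of exactly two labels.
    """

    intensity: pd.DataFrame
    group_of_run: dict[str, str]

    def __post_init__(self) -> None:
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("negative intensities in quant table")
        unknown = set(self.intensity.columns) - set(self.group_of_run)
        if unknown:
            raise ValueError(f"runs without group label: {sorted(unknown)}")
        labels = {self.group_of_run[r] for r in self.intensity.columns}
        if len(labels) != 2:
            raise ValueError(f"expected exactly two group labels, got {sorted(labels)}")

    @property
    def runs(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def protein_groups(self) -> list[str]:
        return list(self.intensity.index)

    def runs_of_group(self, label: str) -> list[str]:
        return [r for r in self.runs if self.group_of_run[r] == label]

    def group_labels(self, group1: str | None = None) -> tuple[str, str]:
        """The two group labels, optionally forcing which one is group 1
        (the fold-change numerator); default order follows first appearance
        in run column order."""
        seen: list[str] = []
        for r in self.runs:
            g = self.group_of_run[r]
            if g not in seen:
                seen.append(g)
        if group1 is not None:
            if group1 not in seen:
                raise ValueError(f"unknown group label {group1!r}")
            if seen[0] != group1:
                seen.reverse()
        return seen[0], seen[1]


def read_dia_report(
    path: str | Path,
    group_of_run: Mapping[str, str],
    quantity_column: str = DEFAULT_QUANTITY_COLUMN,
) -> QuantTable:
    """Pivot a long-format DIA report to a protein x run matrix.

    A (protein, run) pair absent from the report stays a missing cell.
    Duplicate (protein, run) rows are an error, as is a missing column.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (*REQUIRED_REPORT_COLUMNS, quantity_column):
        if col not in df.columns:
            raise ValueError(f"DIA report is missing required column {col!r}")
    dup = df.duplicated(subset=["Run", "Protein.Group"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate report row for protein {first['Protein.Group']!r} "
            f"in run {first['Run']!r}"
        )
    matrix = df.pivot(index="Protein.Group", columns="Run", values=quantity_column)
    matrix.index.name = None
    matrix.columns.name = None
    return QuantTable(intensity=matrix, group_of_run=dict(group_of_run))


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``run<TAB>group`` file (with header)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or set(reader.fieldnames) < {"run", "group"}:
            raise ValueError("groups TSV needs columns 'run' and 'group'")
        return {row["run"]: row["group"] for row in reader}


def normalize_median(table: QuantTable) -> QuantTable:
    """Median-center each run on the log2 scale.

    Every run's log2 intensities are shifted so that all run medians equal
    the grand median of the original run medians; missing cells are left
    untouched. A run with no observed values is an error.
    """
    log2 = np.log2(table.intensity)
    medians = log2.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"run(s) with no observed values: {bad}")
    grand = float(medians.median())
    centered = log2.sub(medians, axis=1) + grand
    return QuantTable(intensity=2.0 ** centered, group_of_run=dict(table.group_of_run))


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value from the Student t distribution. Requires at
    least two observations per group; two groups with zero variance are
    untestable (both raise ``ValueError``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_test needs >= 2 observations per group")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("untestable: both sample variances are zero")
    se2_1 = v1 / n1
    se2_2 = v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2_1 + se2_2)
    df = (se2_1 + se2_2) ** 2 / (
        se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class DifferentialResult:
    accession: str
    n_group1: int
    n_group2: int
    mean_group1: float  # linear-scale mean of observed values (NaN if none)
    mean_group2: float
    log2fc: float  # log2(mean_group1 / mean_group2); NaN when undefined
    t_stat: float
    df: float
    p_value: float
    bh_fdr: float
    klass: DifferentialClass


def classify_differential(
    log2fc: float,
    p_value: float,
    n_group1: int,
    n_group2: int,
    p_cut: float = DEFAULT_P_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
    min_n: int = DEFAULT_MIN_N_EXCLUSIVE,
) -> DifferentialClass:
    """Volcano classification of one protein group.

    Presence/absence calls take precedence: a protein observed in at least
    ``min_n`` runs of one group and none of the other is exclusive to that
    group. Otherwise groups with fewer than two observations each are
    untestable; the remainder is gated on raw p-value and symmetric
    log2 fold-change cut-offs.
    """
    if p_cut <= 0 or fc_cut <= 0:
        raise ValueError("thresholds must be positive")
    if n_group1 >= min_n and n_group2 == 0:
        return DifferentialClass.EXCLUSIVE_GROUP1
    if n_group2 >= min_n and n_group1 == 0:
        return DifferentialClass.EXCLUSIVE_GROUP2
    if n_group1 < 2 or n_group2 < 2 or math.isnan(p_value):
        return DifferentialClass.UNTESTABLE
    if p_value < p_cut and log2fc > fc_cut:
        return DifferentialClass.UP_IN_GROUP1
    if p_value < p_cut and log2fc < -fc_cut:
        return DifferentialClass.UP_IN_GROUP2
    return DifferentialClass.NOT_SIGNIFICANT


def differential_analysis(
    table: QuantTable,
    p_cut: float = DEFAULT_P_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
    min_n: int = DEFAULT_MIN_N_EXCLUSIVE,
    group1: str | None = None,
) -> list[DifferentialResult]:
    """Two-group differential analysis of every protein group in the table.

    ``group1`` names the fold-change numerator group (default: the group of
    the first run in column order). Welch's test runs on log2 intensities,
    where replicate noise is near-Gaussian; fold changes are ratios of
    linear-scale means over observed values only. BH FDR is computed across
    the testable proteins and reported for information.
    """
    from statsmodels.stats.multitest import multipletests

    g1, g2 = table.group_labels(group1)
    runs1 = table.runs_of_group(g1)
    runs2 = table.runs_of_group(g2)

    rows = []
    for acc in table.protein_groups:
        x = table.intensity.loc[acc, runs1].dropna().to_numpy(dtype=float)
        y = table.intensity.loc[acc, runs2].dropna().to_numpy(dtype=float)
        mean1 = float(x.mean()) if len(x) else float("nan")
        mean2 = float(y.mean()) if len(y) else float("nan")
        if len(x) and len(y) and mean2 > 0:
            log2fc = math.log2(mean1 / mean2)
        else:
            log2fc = float("nan")
        # test on the log2 scale, where replicate noise is near-Gaussian
        try:
            t, df, p = welch_test(np.log2(x), np.log2(y))
        except ValueError:
            t = df = p = float("nan")
        rows.append((acc, len(x), len(y), mean1, mean2, log2fc, t, df, p))

    pvals = [r[8] for r in rows]
    testable = [i for i, p in enumerate(pvals) if not math.isnan(p)]
    fdr = [float("nan")] * len(rows)
    if testable:
        _, corrected, _, _ = multipletests(
            [pvals[i] for i in testable], method="fdr_bh"
        )
        for i, q in zip(testable, corrected):
            fdr[i] = float(q)

    results = []
    for (acc, n1, n2, mean1, mean2, log2fc, t, df, p), q in zip(rows, fdr):
        results.append(
            DifferentialResult(
                accession=acc,
                n_group1=n1,
                n_group2=n2,
                mean_group1=mean1,
                mean_group2=mean2,
                log2fc=log2fc,
                t_stat=t,
                df=df,
                p_value=p,
                bh_fdr=q,
                klass=classify_differential(
                    log2fc, p, n1, n2, p_cut=p_cut, fc_cut=fc_cut, min_n=min_n
                ),
            )
        )
    return results


def write_differential_tsv(
    results: Sequence[DifferentialResult], path: str | Path
) -> None:
    def fmt(v: float) -> str:
        return "" if math.isnan(v) else f"{v:.6g}"

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "accession",
                "n_group1",
                "n_group2",
                "mean_group1",
                "mean_group2",
                "log2fc",
                "t_stat",
                "df",
                "p_value",
                "bh_fdr",
                "class",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.accession,
                    r.n_group1,
                    r.n_group2,
                    fmt(r.mean_group1),
                    fmt(r.mean_group2),
                    fmt(r.log2fc),
                    fmt(r.t_stat),
                    fmt(r.df),
                    fmt(r.p_value),
                    fmt(r.bh_fdr),
                    r.klass.value,
                ]
            )
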