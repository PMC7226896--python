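"""Pooled tiling-screen dropout analysis by regulatory-element class.

Negative selection is quantified as the log2 fold change (LFC) in
per-timepoint relative sgRNA abundance (counts-per-million, with a
pseudocount) against the earliest timepoint. sgRNA LFCs are aggregated
per targeted element by the median (robust to single bad guides), and
element classes — promoter, intra-TAD super enhancer, TAD-boundary CTCF
site, typical enhancer, outside-TAD SE, control — are compared with both
a Welch t test and a Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import RankSumResult, WelchResult, mann_whitney, welch_t


class ScreenError(ValueError):
    pass


def normalize_screen(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-timepoint relative abundance in counts-per-million.

    abundance = 1e6 * (count + pseudocount) / sum(count + pseudocount)
    column-wise; the pseudocount keeps fully dropped-out guides finite in
    log space.
    """
    if counts.empty:
        raise ScreenError("empty screen count matrix")
    shifted = counts.astype(float) + pseudocount
    total = shifted.sum(axis=0)
    if (total <= 0).any():
        raise ScreenError("timepoint with non-positive total count")
    return shifted.div(total, axis=1) * 1e6


def sgrna_lfc(
    abundance: pd.DataFrame, day: str, reference: str | None = None
) -> pd.Series:
    """Per-sgRNA log2 fold change of a timepoint against the reference.

    ``reference`` defaults to the first (earliest) column.
    """
    reference = reference if reference is not None else abundance.columns[0]
    for col in (day, reference):
        if col not in abundance.columns:
            raise ScreenError(f"timepoint {col!r} not in abundance matrix")
    ref = abundance[reference]
    if (ref <= 0).any() or (abundance[day] <= 0).any():
        raise ScreenError("zero abundance; normalize with a positive pseudocount")
    return np.log2(abundance[day] / ref).rename("lfc")


def lfc_matrix(abundance: pd.DataFrame, reference: str | None = None) -> pd.DataFrame:
    """LFC of every timepoint against the reference (reference column = 0)."""
    reference = reference if reference is not None else abundance.columns[0]
    return pd.DataFrame(
        {col: sgrna_lfc(abundance, col, reference) for col in abundance.columns}
    )


def aggregate_elements(
    lfc: pd.DataFrame | pd.Series,
    annotations: pd.DataFrame,
    method: str = "median",
) -> pd.DataFrame:
    """Aggregate per-sgRNA LFCs to per-element scores.

    ``annotations`` is indexed by sgRNA id with columns ``element_id`` and
    ``element_class``. Median aggregation is the default; ``method="mean"``
    is available. For an LFC matrix, the last column is carried as
    ``terminal_lfc``.
    """
    if method not in ("median", "mean"):
        raise ScreenError(f"unknown aggregation method {method!r}")
    if isinstance(lfc, pd.Series):
        lfc = lfc.to_frame()
    missing = lfc.index.difference(annotations.index)
    if len(missing):
        raise ScreenError(f"sgRNAs without annotation: {list(missing)[:5]}")
    joined = lfc.join(annotations.loc[lfc.index, ["element_id", "element_class"]])
    grouped = joined.groupby(["element_id", "element_class"], sort=True)
    agg = grouped.median() if method == "median" else grouped.mean()
    agg = agg.reset_index()
    agg["n_sgrnas"] = grouped.size().to_numpy()
    agg["terminal_lfc"] = agg[lfc.columns[-1]]
    return agg


@dataclass(frozen=True)
class ClassComparison:
    class_a: str
    class_b: str
    n_a: int
    n_b: int
    welch: WelchResult
    ranksum: RankSumResult


def compare_element_classes(
    scores: pd.DataFrame,
    class_a: str,
    class_b: str,
    column: str = "terminal_lfc",
) -> ClassComparison:
    """Welch t and Mann-Whitney U between two element classes' scores."""
    a = scores.loc[scores["element_class"] == class_a, column].to_numpy(dtype=float)
    b = scores.loc[scores["element_class"] == class_b, column].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ScreenError(
            f"classes need n >= 2 elements (got {class_a}: {a.size}, {class_b}: {b.size})"
        )
    return ClassComparison(
        class_a=class_a,
        class_b=class_b,
        n_a=int(a.size),
        n_b=int(b.size),
        welch=welch_t(a, b),
        ranksum=mann_whitney(a, b),
    )


def screen_analysis(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    pseudocount: float = 0.5,
    reference: str | None = None,
    method: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full dropout analysis: (per-sgRNA LFC matrix, per-element scores)."""
    abundance = normalize_screen(counts, pseudocount)
    lfc = lfc_matrix(abundance, reference)
    scores = aggregate_elements(lfc, annotations, method=method)
    return lfc, scores


def class_comparison_table(
    scores: pd.DataFrame, pairs: "list[tuple[str, str]]", column: str = "terminal_lfc"
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        c = compare_element_classes(scores, a, b, column=column)
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "welch_t": c.welch.statistic,
                "welch_df": c.welch.df,
                "welch_p": c.welch.pvalue,
                "mannwhitney_u": c.ranksum.statistic,
                "mannwhitney_p": c.ranksum.pvalue,
            }
        )
    return pd.DataFrame(rows)
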