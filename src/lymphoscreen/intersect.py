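"""Cross-study differential-expression intersection.

Implements the marker-discovery front end used to nominate candidate
proteins: call each gene up/down/ns in two case-control studies by
per-gene t-test, then ask whether the up (or down) calls co-occur across
the studies more often than chance via a 2x2 enrichment test (chi-squared,
or Fisher's exact when expected cells are small), reporting the p-value,
odds ratio and the list of genes significant in both.  A variant
intersects one study's calls with a fixed gene list (e.g. the genes that
harbour a LINE-1 retrotransposon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionStudy",
    "IntersectionResult",
    "call_genes",
    "intersect_studies",
    "intersect_with_list",
    "shared_upregulated",
]


@dataclass
class ExpressionStudy:
    """A two-group expression matrix: genes x samples with case/control labels."""

    gene_ids: list[str]
    matrix: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x samples)")
        if len(self.gene_ids) != self.matrix.shape[0]:
            raise ValueError("gene_ids length must match matrix rows")
        if len(self.group_labels) != self.matrix.shape[1]:
            raise ValueError("group_labels length must match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        bad = set(self.group_labels) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if "case" not in self.group_labels or "control" not in self.group_labels:
            raise ValueError("both case and control samples are required")

    @property
    def n_case(self) -> int:
        return self.group_labels.count("case")

    @property
    def n_control(self) -> int:
        return self.group_labels.count("control")


@dataclass
class IntersectionResult:
    """2x2 co-occurrence of a differential call across two call sets.

    Cells partition the shared gene universe: ``in_both``, ``a_only``,
    ``b_only``, ``neither``.  ``odds_ratio`` uses a Haldane–Anscombe +0.5
    correction when any cell is zero (``haldane_applied``); ``test`` records
    whether the p-value came from a chi-squared or Fisher exact test.
    """

    in_both: int
    a_only: int
    b_only: int
    neither: int
    p_value: float
    odds_ratio: float
    test: str
    direction: str
    gene_list_in_both: list[str] = field(default_factory=list)
    haldane_applied: bool = False
    degenerate_margin: bool = False

    @property
    def universe_size(self) -> int:
        return self.in_both + self.a_only + self.b_only + self.neither

    def as_table(self) -> np.ndarray:
        return np.array([[self.in_both, self.a_only], [self.b_only, self.neither]])


def call_genes(
    study: ExpressionStudy,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test with direction calls.

    Returns a frame indexed by gene id with columns ``direction``
    (``up``/``down``/``ns``), ``p_value``, ``mean_case``, ``mean_control``.
    ``up`` means p < alpha and a higher case mean. No multiple-testing
    correction is applied: each study's alpha is per gene, matching the
    convention of the published intersection tool this reimplements.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if study.n_case < 2 or study.n_control < 2:
        raise ValueError("need at least 2 samples per group")
    labels = np.asarray(study.group_labels)
    cases = study.matrix[:, labels == "case"]
    controls = study.matrix[:, labels == "control"]
    res = stats.ttest_ind(cases, controls, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue)
    mean_case = cases.mean(axis=1)
    mean_control = controls.mean(axis=1)
    # constant genes give nan p-values; they are never significant
    p = np.where(np.isnan(p), 1.0, p)
    direction = np.where(
        p < alpha, np.where(mean_case > mean_control, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {
            "direction": direction,
            "p_value": p,
            "mean_case": mean_case,
            "mean_control": mean_control,
        },
        index=pd.Index(study.gene_ids, name="gene_id"),
    )


def _enrichment_2x2(
    in_both: int, a_only: int, b_only: int, neither: int
) -> tuple[float, float, str, bool, bool]:
    """p-value and odds ratio for a 2x2 co-occurrence table.

    Chi-squared without continuity correction when all expected cells are at
    least 5, otherwise Fisher's exact test; Haldane +0.5 on all cells for the
    odds ratio when any observed cell is zero.
    """
    table = np.array([[in_both, a_only], [b_only, neither]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    degenerate = bool(np.any(row == 0) or np.any(col == 0))
    if degenerate:
        # a margin of zero carries no association information
        p_value = 1.0
        test = "degenerate"
    else:
        expected = np.outer(row, col) / n
        if (expected >= 5).all():
            chi2, p_value, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi2"
        else:
            _, p_value = stats.fisher_exact(table.astype(int))
            test = "fisher"
    haldane = bool((table == 0).any())
    if haldane:
        table = table + 0.5
    odds_ratio = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(p_value), float(odds_ratio), test, haldane, degenerate


def intersect_studies(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    direction: str = "up",
) -> IntersectionResult:
    """Cross-tabulate one direction's calls over the shared gene universe.

    Genes absent from either study are dropped (universe = intersection of
    ids). Returns the 2x2, the enrichment p-value and odds ratio, and the
    sorted list of genes called in the chosen direction in both studies.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between the two call tables")
    a_hit = calls_a.loc[shared, "direction"] == direction
    b_hit = calls_b.loc[shared, "direction"] == direction
    in_both = int((a_hit & b_hit).sum())
    a_only = int((a_hit & ~b_hit).sum())
    b_only = int((~a_hit & b_hit).sum())
    neither = int((~a_hit & ~b_hit).sum())
    p, odds, test, haldane, degen = _enrichment_2x2(in_both, a_only, b_only, neither)
    return IntersectionResult(
        in_both=in_both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        p_value=p,
        odds_ratio=odds,
        test=test,
        direction=direction,
        gene_list_in_both=sorted(shared[(a_hit & b_hit).to_numpy()]),
        haldane_applied=haldane,
        degenerate_margin=degen,
    )


def intersect_with_list(
    calls: pd.DataFrame,
    gene_list: Sequence[str],
    direction: str = "up",
) -> IntersectionResult:
    """Cross-tabulate one study's calls against a fixed gene list.

    The list is restricted to the study universe first; an empty restricted
    list is an error. A list covering the whole universe gives a degenerate
    margin — flagged, with the Haldane-corrected odds ratio still reported.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    members = set(gene_list) & set(calls.index)
    if not members:
        raise ValueError("gene list has no overlap with the study universe")
    hit = calls["direction"] == direction
    in_list = calls.index.isin(members)
    in_both = int((hit & in_list).sum())
    a_only = int((hit & ~in_list).sum())
    b_only = int((~hit & in_list).sum())
    neither = int((~hit & ~in_list).sum())
    p, odds, test, haldane, degen = _enrichment_2x2(in_both, a_only, b_only, neither)
    return IntersectionResult(
        in_both=in_both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        p_value=p,
        odds_ratio=odds,
        test=test,
        direction=direction,
        gene_list_in_both=sorted(calls.index[(hit & in_list)]),
        haldane_applied=haldane,
        degenerate_margin=degen,
    )


def shared_upregulated(gene_lists: Iterable[Sequence[str]]) -> list[str]:
    """Symbols present in every supplied gene list, sorted.

    This is the final marker-candidate step: the genes recurrently
    up-regulated across all intersection results.
    """
    lists = [set(g) for g in gene_lists]
    if len(lists) < 2:
        raise ValueError("need at least 2 gene lists")
    common = set.intersection(*lists)
    return sorted(common)
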