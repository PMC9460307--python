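"""Agreement between data-driven and cut-off-derived cluster memberships.

Cluster labels from the two methods are arbitrary, so they are first
aligned by the bijection that maximises the number of co-labelled
participants (optimal assignment on the crosstab).  Per-cluster overlap
is then the percentage of each cut-off cluster's members found in the
matched data-driven cluster; the paper-style convention uses cut-off
cluster sizes as denominators, with the transposed convention available
via ``denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = ["OverlapReport", "align_labels", "overlap_percentages", "crosstab"]


def crosstab(labels_a, labels_b) -> pd.DataFrame:
    """Count matrix: rows = labels_a values, columns = labels_b values."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))


def _optimal_value(counts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    rows, cols = linear_sum_assignment(-counts)
    return float(counts[rows, cols].sum()), rows, cols


def align_labels(labels_a, labels_b) -> dict:
    """Bijection from labels_a values to labels_b values maximising matches.

    Among equally optimal assignments, ties break lexicographically:
    each source label, in increasing order, takes the smallest target
    label that still allows an optimal completion of the rest.
    """
    tab = crosstab(labels_a, labels_b)
    counts = tab.to_numpy(dtype=float)
    n_rows, n_cols = counts.shape
    square = max(n_rows, n_cols)
    padded = np.zeros((square, square))
    padded[:n_rows, :n_cols] = counts
    best, _, _ = _optimal_value(padded)

    row_labels = list(tab.index)
    col_labels = list(tab.columns)
    assigned_cols: list[int] = []
    for r in range(square):
        for c in range(square):
            if c in assigned_cols:
                continue
            fixed = sum(padded[rr, cc] for rr, cc in zip(range(r), assigned_cols))
            rest_rows = [rr for rr in range(square) if rr > r]
            rest_cols = [cc for cc in range(square) if cc != c and cc not in assigned_cols]
            rest = padded[np.ix_(rest_rows, rest_cols)] if rest_rows else np.zeros((0, 0))
            rest_val = _optimal_value(rest)[0] if rest.size else 0.0
            if fixed + padded[r, c] + rest_val >= best - 1e-9:
                assigned_cols.append(c)
                break
    mapping = {}
    for r, c in enumerate(assigned_cols):
        if r < n_rows and c < n_cols:
            mapping[row_labels[r]] = col_labels[c]
    return mapping


@dataclass
class OverlapReport:
    """Cluster-membership agreement between two labelings."""

    mapping: dict
    crosstab: pd.DataFrame
    per_cluster_overlap_pct: dict
    total_agreement_pct: float
    ari: float
    denominator: str = "cutoff"

    def to_dict(self) -> dict:
        return {
            "mapping": {str(k): str(v) for k, v in self.mapping.items()},
            "crosstab": self.crosstab.to_dict(),
            "per_cluster_overlap_pct": {
                str(k): v for k, v in self.per_cluster_overlap_pct.items()
            },
            "total_agreement_pct": self.total_agreement_pct,
            "ari": self.ari,
            "denominator": self.denominator,
        }


def overlap_percentages(
    labels_cutoff,
    labels_datadriven,
    mapping: dict | None = None,
    denominator: str = "cutoff",
) -> OverlapReport:
    """Per-cluster and total overlap between two labelings.

    For each cut-off cluster c, overlap = 100 * (members of c whose
    data-driven label is mapping[c]) / (size of c).  An empty cluster's
    overlap is reported as NaN.  ``denominator="datadriven"`` divides by
    the matched data-driven cluster size instead.
    """
    if denominator not in ("cutoff", "datadriven"):
        raise ValueError("denominator must be 'cutoff' or 'datadriven'")
    if mapping is None:
        mapping = align_labels(labels_cutoff, labels_datadriven)
    tab = crosstab(labels_cutoff, labels_datadriven)
    n = int(tab.to_numpy().sum())
    per = {}
    matched_total = 0
    for c in tab.index:
        target = mapping.get(c)
        hits = int(tab.loc[c, target]) if target in tab.columns else 0
        matched_total += hits
        size = int(tab.loc[c].sum()) if denominator == "cutoff" else (
            int(tab[target].sum()) if target in tab.columns else 0
        )
        per[c] = 100.0 * hits / size if size > 0 else float("nan")
    report = OverlapReport(
        mapping=mapping,
        crosstab=tab,
        per_cluster_overlap_pct=per,
        total_agreement_pct=100.0 * matched_total / n,
        ari=float(adjusted_rand_score(labels_cutoff, labels_datadriven)),
        denominator=denominator,
    )
    return report
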