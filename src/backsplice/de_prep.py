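"""Multi-library count-matrix assembly for differential expression.

The matrix carries raw fragment counts (normalization is left to the
downstream DE tool, which expects raw counts plus size factors); library
sizes and condition labels travel in a sidecar.  Rows are restricted to a
supplied true list when given, and rows whose raw counts total fewer than
``min_reads`` across the matrix are dropped.  A per-sample total circRNA
load comparison (Welch two-sample t-test on CPM totals, reference-group
mean scaled to 1) is provided for global-abundance contrasts such as
ageing designs.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import CountTable


def normalize_cpm(table: CountTable, column: str = "circ_count") -> pd.Series:
    """Counts per million placed reads: count / library_size * 1e6."""
    if table.library_size <= 0:
        raise ValueError(f"library {table.library_id!r} has zero library_size")
    return table.counts[column] / table.library_size * 1e6


def build_de_matrix(
    count_tables: Sequence[CountTable],
    true_list: Optional[Sequence[str]] = None,
    min_reads: int = 2,
    per_sample: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the circRNA x library raw-count matrix plus its sidecar.

    ``min_reads`` drops rows whose raw counts total below the threshold
    across all libraries (``per_sample=True`` instead requires every
    library to reach it).  An empty ``true_list`` filter keeps all rows.
    """
    ids = [t.library_id for t in count_tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicated library_id among {ids}")
    mat = pd.concat(
        {t.library_id: t.counts["circ_count"] for t in count_tables}, axis=1
    ).fillna(0).astype(int)
    mat.index.name = "circ_id"
    if true_list:
        mat = mat.loc[mat.index.intersection(list(true_list))]
    if per_sample:
        keep = (mat >= min_reads).all(axis=1)
    else:
        keep = mat.sum(axis=1) >= min_reads
    mat = mat.loc[keep]
    sidecar = {
        "library_sizes": {t.library_id: int(t.library_size) for t in count_tables},
        "min_reads": int(min_reads),
        "min_reads_scope": "per_sample" if per_sample else "total",
    }
    return mat, sidecar


def total_circ_load(
    count_tables: Sequence[CountTable],
    conditions: Mapping[str, str],
    true_list: Optional[Sequence[str]] = None,
    reference_condition: Optional[str] = None,
) -> dict:
    """Per-sample total circRNA load and a two-group Welch t-test.

    Each sample's load is the sum of CPM over the true circles; group
    means are rescaled so the reference group's mean equals 1.
    """
    totals = {}
    for t in count_tables:
        cpm = normalize_cpm(t)
        if true_list:
            cpm = cpm.loc[cpm.index.intersection(list(true_list))]
        totals[t.library_id] = float(cpm.sum())
    groups: dict[str, list[float]] = {}
    for lib, total in totals.items():
        if lib not in conditions:
            raise ValueError(f"no condition label for library {lib!r}")
        groups.setdefault(conditions[lib], []).append(total)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 conditions, got {sorted(groups)}")
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
    names = sorted(groups)
    ref = reference_condition or names[0]
    if ref not in groups:
        raise ValueError(f"unknown reference condition {ref!r}")
    other = next(n for n in names if n != ref)
    a, b = np.asarray(groups[other], float), np.asarray(groups[ref], float)
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    ref_mean = b.mean()
    scale = ref_mean if ref_mean != 0 else 1.0
    return {
        "per_sample_total": totals,
        "reference_condition": ref,
        "group_means": {ref: float(b.mean() / scale), other: float(a.mean() / scale)},
        "group_sem": {
            ref: float(stats.sem(b) / scale),
            other: float(stats.sem(a) / scale),
        },
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
    }
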