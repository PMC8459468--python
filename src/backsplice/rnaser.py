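"""RNase R resistance classification of circRNA candidates.

RNase R is a 3'->5' exonuclease that degrades linear RNA but spares
covalently closed circles.  For every candidate we form the ratio of its
normalized backsplice-junction signal in the RNase R-treated library to
that in the matched mock library (counts per million placed reads, CPM).
False-positive "circles" are linear molecules, so their ratios should be
distributed like the canonical linear-junction ratios of the host genes.
The classification threshold tau is therefore taken as an empirical
quantile of the pooled linear-junction ratio sample: a cutoff ``c = 0.90``
declares 90% of linear junctions RNase R-sensitive and accepts as *true*
every candidate whose ratio strictly exceeds tau.

The threshold uses the nearest-rank (upper) quantile so that exactly
``ceil(c * n)`` of the ``n`` linear ratios fall at or below tau, making the
contract exact and testable; because it is rank-based, classification is
invariant to any monotone transform applied to all ratios at once.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .quant import CountTable

log = logging.getLogger(__name__)


def _cpm(count, library_size: int):
    return count / library_size * 1e6


def compute_ratios(
    mock: CountTable,
    rnaser: CountTable,
    candidate_meta: Optional[pd.DataFrame] = None,
    min_mock: int = 1,
    raw: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-candidate RNaseR/mock ratios plus the pooled linear ratio sample.

    Candidates are restricted to those expressed in the mock library
    (``mock circ_count >= min_mock``).  The linear sample pools the
    linear_left and linear_right junction ratios of the candidates' host
    genes, again requiring the mock count to reach ``min_mock``.

    ``candidate_meta`` may carry an ``n_pipelines`` column indexed by
    circ_id (provenance from the merge step); ``raw=True`` skips CPM
    normalization and divides raw counts.

    Returns ``(circ_records, linear_ratios)``.
    """
    if mock.library_size <= 0 or rnaser.library_size <= 0:
        raise ValueError("library_size must be > 0 in both mock and RNaseR tables")
    ids = mock.counts.index
    if not ids.equals(rnaser.counts.index):
        raise ValueError("mock and RNaseR tables must share the same circ_id universe")

    def norm(col: str, table: CountTable) -> pd.Series:
        v = table.counts[col].astype(float)
        return v if raw else _cpm(v, table.library_size)

    mock_circ = mock.counts["circ_count"]
    keep = mock_circ >= min_mock
    mock_cpm = norm("circ_count", mock)[keep]
    rnaser_cpm = norm("circ_count", rnaser)[keep]
    records = pd.DataFrame(
        {
            "mock_count": mock.counts.loc[keep, "circ_count"],
            "rnaser_count": rnaser.counts.loc[keep, "circ_count"],
            "mock_cpm": mock_cpm,
            "rnaser_cpm": rnaser_cpm,
            "ratio": rnaser_cpm / mock_cpm,
        }
    )
    records.index.name = "circ_id"
    if candidate_meta is not None and "n_pipelines" in candidate_meta:
        records["n_pipelines"] = candidate_meta["n_pipelines"].reindex(records.index)
    else:
        records["n_pipelines"] = 1

    linear: list[float] = []
    for col in ("linear_left_count", "linear_right_count"):
        mo = mock.counts[col]
        mask = mo >= min_mock
        if mask.any():
            ratios = norm(col, rnaser)[mask] / norm(col, mock)[mask]
            linear.extend(ratios.tolist())
    return records, np.asarray(linear, dtype=float)


def select_threshold(linear_ratios: Sequence[float], c: float) -> float:
    """Nearest-rank empirical quantile of the linear ratio sample.

    tau is the ``ceil(c * n)``-th smallest linear ratio, so exactly
    ``ceil(c * n)`` linear junctions fall at or below tau.  Downstream,
    candidates with ratio strictly above tau are classified true.
    """
    x = np.sort(np.asarray(linear_ratios, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError(
            f"linear ratio sample too small (n={n} < 10); pool tissues or lower min_mock"
        )
    if not 0.0 < c < 1.0:
        raise ValueError(f"cutoff c must be in (0, 1), got {c}")
    rank = math.ceil(c * n)
    return float(x[rank - 1])


def classify(records: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Set ``classification`` = true iff ratio > tau (strict; ties go false,
    pending rescue)."""
    out = records.copy()
    out["classification"] = np.where(out["ratio"] > tau, "true", "false")
    return out


def classify_fold_change(records: pd.DataFrame, fold: float = 5.0) -> pd.DataFrame:
    """Fixed fold-enrichment rule (candidate true iff ratio >= fold).

    Provided for comparison with the quantile cutoff; a predetermined fold
    threshold ignores between-sample variability in RNase R efficiency and
    sequencing depth and tends to discard genuine circles.
    """
    out = records.copy()
    out["classification"] = np.where(out["ratio"] >= fold, "true", "false")
    return out


def cutoff_sweep(
    records: pd.DataFrame,
    linear_ratios: Sequence[float],
    cutoff_grid: Sequence[float],
) -> pd.DataFrame:
    """Diagnostic sweep: per cutoff, the threshold, true/false totals, the
    number of true calls at each pipeline-support level, and the true
    fraction among maximum-support candidates."""
    max_support = int(records["n_pipelines"].max()) if len(records) else 0
    rows = []
    for c in cutoff_grid:
        tau = select_threshold(linear_ratios, c)
        cls = classify(records, tau)
        is_true = cls["classification"] == "true"
        row = {
            "cutoff": c,
            "tau": tau,
            "n_true": int(is_true.sum()),
            "n_false": int((~is_true).sum()),
        }
        for level, grp in cls.groupby("n_pipelines"):
            row[f"n_true_support_{int(level)}"] = int(
                (grp["classification"] == "true").sum()
            )
        if max_support:
            top = cls[cls["n_pipelines"] == max_support]
            row["true_fraction_max_support"] = (
                float((top["classification"] == "true").mean()) if len(top) else float("nan")
            )
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0)
    return df


def _normalize_classification(df: pd.DataFrame) -> pd.DataFrame:
    """Map boolean classification values (e.g. from a TSV round trip) back
    to the canonical 'true'/'false' strings."""
    out = df.copy()
    out["classification"] = out["classification"].map(
        {True: "true", False: "false"}
    ).fillna(out["classification"].astype(str).str.lower())
    return out


def collapse_rescue(
    per_tissue: Mapping[str, pd.DataFrame],
    external_true_lists: Optional[Mapping[str, Iterable[str]]] = None,
) -> dict[str, pd.DataFrame]:
    """Rescue false calls that are true in another tissue or external list.

    The union of all per-tissue true circ_ids plus any externally validated
    ids forms the collapsed reference; every false record whose id appears
    there becomes ``rescued``, with the first tissue/list that supports it
    recorded as provenance.  True calls are never demoted, so the final
    per-tissue true list (true plus rescued) grows monotonically.
    """
    per_tissue = {t: _normalize_classification(df) for t, df in per_tissue.items()}
    support: dict[str, str] = {}
    for tissue, df in per_tissue.items():
        for circ_id in df.index[df["classification"] == "true"]:
            support.setdefault(circ_id, f"tissue:{tissue}")
    for name, ids in (external_true_lists or {}).items():
        for circ_id in ids:
            if not isinstance(circ_id, str) or not circ_id:
                log.warning("external list %s: malformed key %r skipped", name, circ_id)
                continue
            support.setdefault(circ_id, f"external:{name}")

    out = {}
    for tissue, df in per_tissue.items():
        res = df.copy()
        res["rescue_provenance"] = ""
        for circ_id in res.index:
            if (
                res.loc[circ_id, "classification"] == "false"
                and circ_id in support
                and support[circ_id] != f"tissue:{tissue}"
            ):
                res.loc[circ_id, "classification"] = "rescued"
                res.loc[circ_id, "rescue_provenance"] = support[circ_id]
        out[tissue] = res
    return out


def true_list(records: pd.DataFrame) -> list[str]:
    """Final true list: candidates classified true or rescued."""
    records = _normalize_classification(records)
    return list(records.index[records["classification"].isin(["true", "rescued"])])


def expression_strata(records: pd.DataFrame) -> pd.DataFrame:
    """Annotate records with within-sample mock-expression terciles.

    Boundaries are the 1/3 and 2/3 quantiles of mock CPM: strictly below
    the lower boundary is ``low``, strictly above the upper is ``high``,
    everything else ``mid`` (a degenerate all-equal sample is entirely
    mid).  Diagnostic only; classification is unaffected.
    """
    out = records.copy()
    x = out["mock_cpm"].to_numpy(dtype=float)
    if len(x) == 0:
        out["expression_stratum"] = pd.Series(dtype=object)
        return out
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    strata = np.full(len(x), "mid", dtype=object)
    strata[x < q1] = "low"
    strata[x > q2] = "high"
    out["expression_stratum"] = strata
    return out
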