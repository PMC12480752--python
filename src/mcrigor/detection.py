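"""Size-conditional thresholding of divergence scores and dubious calls.

The threshold for a metacell of size ``m`` is the ``q`` quantile (default
0.95, linear/type-7 interpolation) of the null scores of all metacells whose
sizes fall within ``[m - h, m + h]`` (default bandwidth h = 10).  Null score
distributions shift with metacell size, so a single global quantile would
mis-calibrate small and large metacells.  Windows holding fewer than
``min_window_nulls`` null values are widened symmetrically in +5 steps; if
the widest window still falls short the global quantile is used.

A metacell is dubious iff its score strictly exceeds its threshold.
Metacells that could not be scored (too small, too few usable features) are
classified trustworthy by convention and flagged.

``null="double"`` thresholds mcDiv against the double-permutation null;
``null="within_feature"`` reproduces the naive baseline that thresholds the
raw correlation deviation against within-feature-permutation deviations
only — kept for diagnostics, it ignores library-size variation and badly
over-flags homogeneous metacells.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .divergence import STATUS_OK, PermutationPlan, divergence_table
from .io import UNASSIGNED, MetacellPartition
from .preprocess import NormalizedMatrix

_NULL_COLUMNS = {
    "double": ("mcdiv", "mcdiv_null"),
    "within_feature": ("dev_raw", "dev_feature_perm"),
}


def compute_thresholds(
    records: pd.DataFrame,
    h: float = 10.0,
    q: float = 0.95,
    min_window_nulls: int = 5,
    null: str = "double",
) -> pd.DataFrame:
    """Per-metacell thresholds from size-windowed null-score quantiles.

    Returns a copy of ``records`` with ``threshold`` and
    ``window_null_count`` columns.
    """
    stat_col, null_col = _NULL_COLUMNS[null]
    ok = records[records["status"] == STATUS_OK]
    if ok.empty:
        raise ValueError("no scored metacells to derive thresholds from")
    null_sizes = ok["size"].to_numpy(float)
    null_vals = ok[null_col].to_numpy(float)
    size_span = float(null_sizes.max() - null_sizes.min())

    thresholds = np.full(len(records), np.nan)
    window_counts = np.zeros(len(records), dtype=int)
    for i, (_, rec) in enumerate(records.iterrows()):
        if rec["status"] != STATUS_OK:
            continue
        m = float(rec["size"])
        h_eff = h
        while True:
            mask = np.abs(null_sizes - m) <= h_eff
            if mask.sum() >= min_window_nulls or h_eff > size_span:
                break
            h_eff += 5.0
        if mask.sum() < min_window_nulls:
            mask = np.ones_like(mask)  # global fallback
        thresholds[i] = np.quantile(null_vals[mask], q)  # linear (type 7)
        window_counts[i] = int(mask.sum())
    out = records.copy()
    out["threshold"] = thresholds
    out["window_null_count"] = window_counts
    return out


def classify_metacells(with_thresholds: pd.DataFrame, null: str = "double") -> pd.DataFrame:
    """Add ``is_dubious``: statistic strictly above threshold, status ok.

    Equality with the threshold, and unscored metacells, classify as
    trustworthy (the latter carry their status flag).
    """
    stat_col, _ = _NULL_COLUMNS[null]
    out = with_thresholds.copy()
    stat = out[stat_col].to_numpy(float)
    thr = out["threshold"].to_numpy(float)
    ok = (out["status"] == STATUS_OK).to_numpy()
    out["is_dubious"] = ok & np.isfinite(stat) & np.isfinite(thr) & (stat > thr)
    return out


def detect(
    norm: NormalizedMatrix,
    partition: MetacellPartition,
    seed: int = 0,
    h: float = 10.0,
    q: float = 0.95,
    min_metacell_size: int = 3,
    min_window_nulls: int = 5,
    null: str = "double",
    bin_size: int | None = 2,
) -> pd.DataFrame:
    """Full detection pipeline: divergence table -> thresholds -> calls."""
    table = divergence_table(
        norm, partition, PermutationPlan(seed),
        min_metacell_size=min_metacell_size, bin_size=bin_size,
    )
    table = compute_thresholds(
        table, h=h, q=q, min_window_nulls=min_window_nulls, null=null
    )
    return classify_metacells(table, null=null)


def two_step_refine(
    norm: NormalizedMatrix,
    partition: MetacellPartition,
    partitioner: Callable[[NormalizedMatrix, int, int], MetacellPartition],
    gamma_opt: int,
    seed: int = 0,
    q_relaxed: float = 0.85,
    h: float = 10.0,
) -> MetacellPartition:
    """Re-partition the cells of dubious metacells at the optimized granularity.

    Detection runs once at the relaxed quantile (default the 85th percentile
    of size-conditional null scores); cells of flagged metacells are pooled
    and re-partitioned at ``gamma_opt`` while trustworthy metacells pass
    through untouched.  Pools smaller than ``gamma_opt`` become a single
    metacell.  The assigned cell set is conserved.
    """
    result = detect(norm, partition, seed=seed, h=h, q=q_relaxed)
    dubious_ids = set(result.loc[result["is_dubious"], "metacell_id"])
    if not dubious_ids:
        return partition

    pool = [
        cell
        for cell, label in partition.assignment.items()
        if label in dubious_ids
    ]
    assignment = {
        cell: (label if label not in dubious_ids else UNASSIGNED)
        for cell, label in partition.assignment.items()
    }

    pos = {c: i for i, c in enumerate(norm.cell_ids)}
    pool_idx = np.array([pos[c] for c in pool], dtype=np.intp)
    sub = NormalizedMatrix(
        norm.values[pool_idx], pool, list(norm.feature_ids), norm.scale_factor
    )
    if len(pool) < max(gamma_opt, 2):
        sub_part = MetacellPartition({c: "refined_0" for c in pool})
    else:
        sub_part = partitioner(sub, gamma_opt, seed)
        sub_part = MetacellPartition(
            {
                c: (f"refined_{label}" if label != UNASSIGNED else UNASSIGNED)
                for c, label in sub_part.assignment.items()
            }
        )
    for cell, label in sub_part.assignment.items():
        assignment[cell] = label
    keep = [m for m in partition.metacell_ids if m not in dubious_ids]
    return MetacellPartition(assignment, keep + sub_part.metacell_ids)
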