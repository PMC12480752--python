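"""Partition evaluation (DubRate / ZeroRate / Score) and granularity sweeps.

A partition is scored by

    Score = 1 - w * DubRate - (1 - w) * ZeroRate        (w in (0,1), default 0.5)

where DubRate is the fraction of all single cells (unassigned included in
the denominator) that sit in dubious metacells, and ZeroRate is the fraction
of zeros in the M x p metacell expression matrix obtained by aggregating
counts over the selected features.  Smaller granularity means fewer dubious
metacells but sparser profiles; the Score makes that trade-off explicit and
the configuration maximizing it is selected.

Partitioners plug in via a simple callable protocol
``(NormalizedMatrix, gamma, seed) -> MetacellPartition`` so that any
metacell construction method can be swept; a self-contained baseline
(PCA -> kNN-connectivity Ward clustering) is provided.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .config import RunConfig
from .detection import detect
from .io import CountMatrix, MetacellPartition
from .preprocess import NormalizedMatrix, normalize_and_select

logger = logging.getLogger("mcrigor")

Partitioner = Callable[[NormalizedMatrix, int, int], MetacellPartition]


def dub_rate(
    partition: MetacellPartition, detection: pd.DataFrame, n_total_cells: int
) -> float:
    """Fraction of all cells assigned to dubious metacells."""
    if n_total_cells == 0:
        raise ValueError("n_total_cells must be positive")
    sizes = partition.sizes()
    dubious = detection.loc[detection["is_dubious"], "metacell_id"]
    return sum(sizes[m] for m in dubious) / n_total_cells


def zero_rate(
    counts: CountMatrix,
    partition: MetacellPartition,
    feature_subset: list[str],
) -> float:
    """Fraction of zeros in the metacell-by-feature aggregate matrix.

    Counts are summed within each metacell over ``feature_subset``; the zero
    pattern of sums equals that of averages, so the choice of aggregate does
    not matter here.
    """
    if not feature_subset:
        raise ValueError("empty feature subset")
    if partition.n_metacells == 0:
        raise ValueError("partition has no metacells")
    col = {f: j for j, f in enumerate(counts.feature_ids)}
    fidx = np.array([col[f] for f in feature_subset], dtype=np.intp)
    groups = partition.member_indices(counts.cell_ids)
    n_zero = 0
    for mc_id in partition.metacell_ids:
        agg = counts.values[groups[mc_id]][:, fidx].sum(axis=0)
        n_zero += int((agg == 0).sum())
    return n_zero / (partition.n_metacells * len(fidx))


def score(dub: float, zero: float, w: float = 0.5) -> float:
    """``1 - w*DubRate - (1-w)*ZeroRate``; lies in [0, 1]."""
    if not 0.0 <= dub <= 1.0 or not 0.0 <= zero <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    if not 0.0 < w < 1.0:
        raise ValueError("w must lie in (0, 1)")
    return 1.0 - w * dub - (1.0 - w) * zero


def evaluate_partition(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    partition: MetacellPartition,
    config: RunConfig,
) -> dict:
    """Detection + rates + Score for one partition."""
    detection = detect(
        norm,
        partition,
        seed=config.seed,
        h=config.bandwidth,
        q=config.quantile,
        min_metacell_size=config.min_metacell_size,
        min_window_nulls=config.min_window_nulls,
    )
    dub = dub_rate(partition, detection, counts.n_cells)
    zero = zero_rate(counts, partition, list(norm.feature_ids))
    return {
        "M": partition.n_metacells,
        "n_dubious": int(detection["is_dubious"].sum()),
        "DubRate": dub,
        "ZeroRate": zero,
        "Score": score(dub, zero, config.weight),
    }


def sweep_configurations(
    counts: CountMatrix,
    partitioners: Mapping[str, Partitioner],
    gamma_grid: tuple[int, ...] | list[int],
    config: RunConfig,
) -> pd.DataFrame:
    """Score every (method, gamma) configuration.

    HVG selection and normalization happen once per dataset; each
    configuration builds its partition from the shared normalized matrix.  A
    partitioner failure at some gamma logs a warning and leaves a row with
    missing scores rather than aborting the sweep.  Rows are sorted by
    (method, gamma).
    """
    if not partitioners:
        raise ValueError("need at least one partitioner")
    if not gamma_grid:
        raise ValueError("empty gamma grid")
    norm = normalize_and_select(counts, config.n_features, config.scale_factor)
    rows = []
    for method in sorted(partitioners):
        for gamma in sorted(gamma_grid):
            row = {"method": method, "gamma": int(gamma), "M": np.nan,
                   "n_dubious": np.nan, "DubRate": np.nan, "ZeroRate": np.nan,
                   "Score": np.nan}
            try:
                partition = partitioners[method](norm, int(gamma), config.seed)
                row.update(evaluate_partition(counts, norm, partition, config))
            except Exception as exc:  # noqa: BLE001 - sweep must survive one failure
                logger.warning("%s at gamma=%d failed: %s", method, gamma, exc)
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["method", "gamma"], ignore_index=True)


def select_best(records: pd.DataFrame) -> tuple[str, int, pd.Series]:
    """Configuration maximizing Score; ties -> smaller gamma, then method name."""
    valid = records.dropna(subset=["Score"])
    if valid.empty:
        raise ValueError("no scored configurations")
    ordered = valid.sort_values(
        ["Score", "gamma", "method"], ascending=[False, True, True]
    )
    best = ordered.iloc[0]
    return str(best["method"]), int(best["gamma"]), best


def baseline_partitioner(
    norm: NormalizedMatrix, gamma: int, seed: int = 0
) -> MetacellPartition:
    """Self-contained reference partitioner: PCA -> kNN graph -> Ward merging.

    Produces exactly ``M = floor(n / gamma)`` metacells covering all cells,
    deterministically for a fixed seed.  It is a test harness and a template
    for plugging in dedicated metacell methods, not a competitor to them.
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    n = norm.n_cells
    if gamma < 2 or n < gamma:
        raise ValueError("need n >= gamma >= 2")
    m_target = n // gamma
    n_comp = min(30, n - 1, norm.n_features)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(
        norm.values
    )
    if m_target == 1:
        labels = np.zeros(n, dtype=int)
    else:
        k = min(15, n - 1)
        conn = kneighbors_graph(pcs, n_neighbors=k, include_self=False)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # disconnected graphs are repaired
            labels = AgglomerativeClustering(
                n_clusters=m_target, connectivity=conn, linkage="ward"
            ).fit_predict(pcs)
    assignment = {c: f"mc{label}" for c, label in zip(norm.cell_ids, labels)}
    order = [f"mc{j}" for j in range(m_target)]
    return MetacellPartition(assignment, order)
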