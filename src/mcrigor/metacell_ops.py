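"""Metacell-level utilities: profile aggregation, purity, F-score, covariance, cTET.

Aggregation averages per-cell relative abundances (optionally log1p
transformed) within each metacell; with the identity transform every profile
row sums to one and, for a homogeneous metacell, is an unbiased estimate of
the shared relative-abundance vector.  The covariance of two features across
metacell profiles is the plain sample covariance — unbiased on pure
partitions, biased by a closed-form term when metacells mix states.

cTET (continuous tumor exposure time) summarizes a metacell's time-stamp
distribution over K ordered time points as one minus the normalized area
under the CDF: 0 when all cells carry the earliest stamp, 1 when all carry
the latest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, MetacellPartition


@dataclass
class MetacellProfileMatrix:
    """M x p aggregated expression profiles."""

    values: np.ndarray
    metacell_ids: list[str]
    feature_ids: list[str]
    psi: str = "identity"


def aggregate_profiles(
    counts: CountMatrix,
    partition: MetacellPartition,
    psi: str = "identity",
    scale_factor: float = 1e4,
) -> MetacellProfileMatrix:
    """Average psi-transformed relative abundances within each metacell.

    ``psi`` is ``"identity"`` (rows sum to 1) or ``"log1p-normalized"``
    (``ln(1 + x * scale_factor)`` applied to each relative abundance).
    """
    lib = counts.library_sizes().astype(float)
    groups = partition.member_indices(counts.cell_ids)
    for mc_id, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"metacell {mc_id!r} is empty")
        if np.any(lib[idx] == 0):
            raise ValueError(f"zero library size in metacell {mc_id!r}")
    rel_all = counts.values.astype(float)
    profiles = np.empty((partition.n_metacells, counts.n_features))
    for k, mc_id in enumerate(partition.metacell_ids):
        idx = groups[mc_id]
        rel = rel_all[idx] / lib[idx][:, None]
        if psi == "identity":
            profiles[k] = rel.mean(axis=0)
        elif psi == "log1p-normalized":
            profiles[k] = np.log1p(rel * scale_factor).mean(axis=0)
        else:
            raise ValueError(f"unknown psi {psi!r}")
    return MetacellProfileMatrix(
        profiles, list(partition.metacell_ids), list(counts.feature_ids), psi
    )


def purity(partition: MetacellPartition, true_labels: dict[str, str]) -> dict[str, float]:
    """Per-metacell highest fraction of cells sharing one source label."""
    out = {}
    for mc_id in partition.metacell_ids:
        cells = partition.members(mc_id)
        if not cells:
            raise ValueError(f"metacell {mc_id!r} is empty")
        counts: dict[str, int] = {}
        for cell in cells:
            lab = str(true_labels[cell])
            counts[lab] = counts.get(lab, 0) + 1
        out[mc_id] = max(counts.values()) / len(cells)
    return out


def classification_fscore(
    predicted_dubious: list[bool] | np.ndarray, true_dubious: list[bool] | np.ndarray
) -> float:
    """F-score with "dubious" as the positive class; 0 when either side empty."""
    pred = np.asarray(predicted_dubious, dtype=bool)
    true = np.asarray(true_dubious, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("flag lists must have equal length")
    tp = int(np.sum(pred & true))
    if tp == 0:
        return 0.0
    precision = tp / int(pred.sum())
    recall = tp / int(true.sum())
    return 2 * precision * recall / (precision + recall)


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 when both are empty."""
    if not set_a and not set_b:
        return 1.0
    return len(set_a & set_b) / len(set_a | set_b)


def covariance_from_metacells(z: MetacellProfileMatrix, j: int, l: int) -> float:
    """Sample covariance of features ``j`` and ``l`` across metacell profiles."""
    if z.values.shape[0] < 2:
        raise ValueError("need at least two metacells")
    a = z.values[:, j]
    b = z.values[:, l]
    m = len(a)
    return float((a @ b - a.sum() * b.sum() / m) / (m - 1))


def ctet(time_counts: list[float] | np.ndarray) -> float:
    """Continuous exposure time of a metacell from ordered time-point counts.

    With CDF ``F`` over the K time points, ``AUC = mean(F)`` and

        cTET = 1 - (AUC - 1/K) / (1 - 1/K)  in [0, 1].

    All mass at the earliest point gives AUC 1 and cTET 0; all mass at the
    latest gives cTET 1.  Shifting mass later never decreases cTET.
    """
    c = np.asarray(time_counts, dtype=float)
    if c.ndim != 1 or len(c) < 2:
        raise ValueError("need counts for at least two ordered time points")
    if np.any(c < 0) or c.sum() == 0:
        raise ValueError("counts must be nonnegative with positive sum")
    k = len(c)
    cdf = np.cumsum(c) / c.sum()
    auc = float(cdf.mean())
    normalized = (auc - 1.0 / k) / (1.0 - 1.0 / k)
    return 1.0 - normalized
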