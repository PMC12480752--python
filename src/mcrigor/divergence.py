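"""Per-metacell divergence scores and their double-permutation null.

For a metacell of ``m`` cells with normalized feature block ``X`` (m x p),
the divergence score is

    mcDiv = ||R - I||_F / ||R~ - I||_F

where ``R`` is the Pearson feature-correlation matrix of ``X`` and ``R~`` the
one obtained after independently shuffling each feature column
(within-feature permutation); the denominator is the no-correlation baseline
for that block.  The null score repeats the same construction starting from
a within-cell permuted block (each cell's values shuffled across features,
which preserves every cell's row sum and hence its library-size footprint):

    mcDiv_null = ||Pi - I||_F / ||Pi~ - I||_F

with ``Pi`` from the within-cell permuted block and ``Pi~`` from a subsequent
within-feature permutation of it.  Conditioning the null on library sizes is
what makes the comparison fair: a plain within-feature baseline under-states
the deviation expected from depth variation alone and over-flags homogeneous
metacells.

The within-cell shuffle is abundance-stratified (values move only between
features of matched mean abundance, in rank bins of two by default): this
additionally preserves each feature's marginal profile, which carries the
feature's response to cell-depth variation.  See
:func:`permute_within_cell` for the rationale.

Each permutation is drawn once per metacell; sub-seeds derive
deterministically from (seed, metacell id) so that scores do not change when
other metacells are added or removed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MetacellPartition
from .preprocess import NormalizedMatrix

STATUS_OK = "ok"
STATUS_SMALL = "insufficient_size"
STATUS_FEATURES = "insufficient_features"


@dataclass
class PermutationPlan:
    """Deterministic per-metacell random streams keyed to a global seed."""

    seed: int

    def rng_for(self, metacell_id: str) -> np.random.Generator:
        digest = hashlib.blake2b(
            str(metacell_id).encode(), digest_size=8
        ).digest()
        sub = int.from_bytes(digest, "little")
        return np.random.default_rng(np.random.SeedSequence([self.seed, sub]))


def permute_within_feature(
    block: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independently shuffle each column (feature) across cells."""
    m = block.shape[0]
    out = np.empty_like(block)
    for j in range(block.shape[1]):
        out[:, j] = block[rng.permutation(m), j]
    return out


def permute_within_cell(
    block: np.ndarray,
    rng: np.random.Generator,
    bin_size: int | None = 2,
    ref_means: np.ndarray | None = None,
) -> np.ndarray:
    """Shuffle each row (cell) across features, stratified by feature abundance.

    Each output row is a permutation of the corresponding input row, so every
    cell's row sum — the normalized-value analogue of its library size — is
    preserved exactly.

    By default the shuffle is abundance-stratified: features are grouped into
    bins of ``bin_size`` consecutive ranks of ``ref_means`` (the block's
    per-feature means unless given), and each cell's values are permuted only
    within bins.  A valid negative control must retain the technical
    structure of the block — not just its row sums but also the marginal
    profile of each feature, since a feature's response to cell-depth
    variation is a function of its abundance.  An unrestricted row shuffle
    homogenizes feature marginals and therefore understates the correlation
    deviation expected from technical variation alone, over-flagging
    homogeneous metacells whenever feature abundances are heterogeneous.
    Swapping only abundance-matched features keeps that structure while
    still destroying feature-feature dependence beyond matched pairs.

    ``bin_size=None`` (or >= number of features) gives the unrestricted
    shuffle.
    """
    p = block.shape[1]
    if bin_size is None or bin_size >= p:
        out = np.empty_like(block)
        for i in range(block.shape[0]):
            out[i, :] = block[i, rng.permutation(p)]
        return out
    if ref_means is None:
        ref_means = block.mean(axis=0)
    order = np.argsort(ref_means, kind="stable")
    out = block.copy()
    for start in range(0, p - p % bin_size, bin_size):
        idx = order[start : start + bin_size]
        out[:, idx] = rng.permuted(block[:, idx], axis=1)
    return out


def corr_deviation(block: np.ndarray) -> tuple[float, int]:
    """Frobenius deviation of the feature correlation matrix from identity.

    Features constant within the block (zero variance) have undefined
    correlations and are dropped; the retained count is returned alongside.
    Returns ``(nan, count)`` when fewer than two features remain.
    """
    sd = block.std(axis=0)
    # relative tolerance guards against features constant up to float rounding
    keep = sd > 1e-10 * (np.abs(block).max(axis=0) + 1e-30)
    eff = int(keep.sum())
    if eff < 2:
        return float("nan"), eff
    sub = block[:, keep]
    r = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(r, 1.0)
    dev = float(np.linalg.norm(r - np.eye(eff)))
    return dev, eff


def compute_mcdiv(
    block: np.ndarray, rng: np.random.Generator
) -> tuple[float, float, float, int]:
    """Divergence score of one block.

    Returns ``(mcdiv, dev_raw, dev_feature_perm, effective_features)`` where
    the two deviations are the numerator and denominator of the ratio.  The
    within-feature permutation preserves each column's multiset, so the
    non-constant feature set of numerator and denominator coincides and the
    ratio is well defined.
    """
    dev_raw, eff = corr_deviation(block)
    permuted = permute_within_feature(block, rng)
    dev_perm, _ = corr_deviation(permuted)
    if not np.isfinite(dev_raw) or not np.isfinite(dev_perm) or dev_perm == 0:
        return float("nan"), dev_raw, dev_perm, eff
    return dev_raw / dev_perm, dev_raw, dev_perm, eff


def compute_mcdiv_null(
    block: np.ndarray,
    rng: np.random.Generator,
    bin_size: int | None = 2,
) -> tuple[float, np.ndarray]:
    """Null divergence score of one block via the double permutation.

    Returns the score and the intermediate within-cell permuted block (whose
    row sums equal the input's exactly).  ``bin_size`` controls the abundance
    stratification of the within-cell step (see
    :func:`permute_within_cell`).
    """
    within_cell = permute_within_cell(block, rng, bin_size=bin_size)
    dev_pi, eff = corr_deviation(within_cell)
    doubled = permute_within_feature(within_cell, rng)
    dev_pi_tilde, _ = corr_deviation(doubled)
    if not np.isfinite(dev_pi) or not np.isfinite(dev_pi_tilde) or dev_pi_tilde == 0:
        return float("nan"), within_cell
    return dev_pi / dev_pi_tilde, within_cell


def divergence_table(
    norm: NormalizedMatrix,
    partition: MetacellPartition,
    plan: PermutationPlan,
    min_metacell_size: int = 3,
    bin_size: int | None = 2,
) -> pd.DataFrame:
    """Score every metacell of a partition.

    Returns one row per metacell, in ``partition.metacell_ids`` order, with
    columns ``metacell_id, size, mcdiv, mcdiv_null, dev_raw,
    dev_feature_perm, effective_features, status``.  Metacells smaller than
    ``min_metacell_size`` get status ``insufficient_size`` and no scores;
    blocks without at least two non-constant features get
    ``insufficient_features``.
    """
    if partition.n_metacells == 0:
        raise ValueError("empty partition")
    groups = partition.member_indices(norm.cell_ids)
    rows = []
    for mc_id in partition.metacell_ids:
        idx = groups[mc_id]
        m = len(idx)
        row = {
            "metacell_id": mc_id,
            "size": m,
            "mcdiv": np.nan,
            "mcdiv_null": np.nan,
            "dev_raw": np.nan,
            "dev_feature_perm": np.nan,
            "effective_features": 0,
            "status": STATUS_OK,
        }
        if m < min_metacell_size:
            row["status"] = STATUS_SMALL
            rows.append(row)
            continue
        block = norm.block(idx)
        rng = plan.rng_for(mc_id)
        mcdiv, dev_raw, dev_perm, eff = compute_mcdiv(block, rng)
        null, _ = compute_mcdiv_null(block, rng, bin_size=bin_size)
        row.update(
            mcdiv=mcdiv,
            mcdiv_null=null,
            dev_raw=dev_raw,
            dev_feature_perm=dev_perm,
            effective_features=eff,
        )
        if not np.isfinite(mcdiv) or not np.isfinite(null):
            row["status"] = STATUS_FEATURES
        rows.append(row)
    return pd.DataFrame(rows)
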