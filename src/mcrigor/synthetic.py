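"""Semi-synthetic data generation with ground-truth metacells, plus theory oracles.

The generator emulates the standard hierarchical view of droplet count data.
Each true metacell represents one cell state with per-feature mean ``mu`` and
a biological multiplier ``theta ~ Gamma(sigma, 1/sigma)`` (mean 1, variance
1/sigma) drawn once per metacell — optionally with a Gaussian copula coupling
features.  All cells of a metacell therefore share the relative-abundance
vector ``lambda ∝ mu * theta``, and observed counts are

    y_ij ~ Poisson(omega_i * mu_j * theta_j)

with a per-cell amplification factor ``omega_i`` (log-normal) producing
library-size spread.  Marginally each feature is Negative Binomial; within a
metacell, conditioning on the library size makes the counts multinomial in
``lambda`` — the exact null of the divergence test.

States are made "well separated" by multiplying a random subset of features
by state-specific fold changes.  Sizes of true metacells are integers in
[20, 80] adjusted so their mean equals the true granularity ``gamma_star``
(default 50).

Also provided: an exact multinomial sampler for trustworthy blocks, mixed
(truly dubious) partitions, an oracle partitioner with a sharp purity elbow
at ``gamma_star``, and closed-form values for the within-metacell
correlation induced by the sum constraint and for the covariance bias caused
by 50/50-mixed metacells — used as independent oracles in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .io import CountMatrix, MetacellPartition


@dataclass
class GeneratorConfig:
    """Parameters of the semi-synthetic generator.

    ``n_states=None`` gives every true metacell its own state (the default
    sampling scheme); an integer shares states across metacells.  The copula
    correlation defaults to identity (independent ``theta`` across features);
    ``copula_block_size``/``copula_rho`` add equicorrelated feature blocks.
    """

    p: int = 2000
    gamma_star: int = 50
    size_range: tuple[int, int] = (20, 80)
    sigma: float = 5.0
    base_meanlog: float = float(np.log(0.2))
    base_sdlog: float = 1.5
    de_fraction: float = 0.1
    de_fold_range: tuple[float, float] = (2.0, 8.0)
    omega_sdlog: float = 0.4
    n_states: int | None = None
    copula_block_size: int = 0
    copula_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not lo <= self.gamma_star <= hi:
            raise ValueError("gamma_star must lie inside size_range")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class GroundTruth:
    """True metacell structure underlying a simulated dataset."""

    cell_ids: list[str]
    metacell_of: dict[str, str]
    metacell_ids: list[str]
    state_of_metacell: dict[str, int]
    lambda_matrix: np.ndarray  # M x p, rows sum to 1
    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            sizes = {m: 0 for m in self.metacell_ids}
            for label in self.metacell_of.values():
                sizes[label] += 1
            self.sizes = sizes

    def partition(self) -> MetacellPartition:
        return MetacellPartition(dict(self.metacell_of), list(self.metacell_ids))

    def lambda_of(self, metacell_id: str) -> np.ndarray:
        return self.lambda_matrix[self.metacell_ids.index(metacell_id)]

    def state_labels(self) -> dict[str, int]:
        """Per-cell state label."""
        return {
            c: self.state_of_metacell[m] for c, m in self.metacell_of.items()
        }


def _draw_sizes(
    m: int, gamma_star: int, size_range: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Integer sizes in ``size_range`` whose mean equals ``gamma_star`` exactly."""
    lo, hi = size_range
    sizes = None
    for _ in range(200):
        cand = rng.integers(lo, hi + 1, size=m)
        if round(cand.mean()) == gamma_star:
            sizes = cand.astype(int)
            break
    if sizes is None:
        sizes = np.full(m, gamma_star, dtype=int)
    # nudge extremes by +/-1 until the sum is exact
    target = m * gamma_star
    while sizes.sum() != target:
        if sizes.sum() < target:
            j = int(np.argmin(sizes))
            sizes[j] += 1
        else:
            j = int(np.argmax(sizes))
            sizes[j] -= 1
    return sizes


def _state_means(config: GeneratorConfig, n_states: int, rng: np.random.Generator) -> np.ndarray:
    """Per-state mean vectors: shared log-normal baseline with fold-changes."""
    base = rng.lognormal(config.base_meanlog, config.base_sdlog, size=config.p)
    n_de = max(1, int(round(config.de_fraction * config.p)))
    lo, hi = np.log(config.de_fold_range[0]), np.log(config.de_fold_range[1])
    mu = np.tile(base, (n_states, 1))
    for s in range(n_states):
        idx = rng.choice(config.p, size=n_de, replace=False)
        mu[s, idx] *= np.exp(rng.uniform(lo, hi, size=n_de))
    return mu


def _sample_theta(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """One metacell's biological multipliers, Gamma(sigma, 1/sigma) marginals."""
    p, sigma = config.p, config.sigma
    if config.copula_block_size <= 1 or config.copula_rho == 0.0:
        return rng.gamma(shape=sigma, scale=1.0 / sigma, size=p)
    # Gaussian copula with equicorrelated blocks: z = sqrt(rho)*shared + sqrt(1-rho)*own
    b = config.copula_block_size
    rho = config.copula_rho
    z = np.empty(p)
    for start in range(0, p, b):
        stop = min(start + b, p)
        shared = rng.standard_normal()
        own = rng.standard_normal(stop - start)
        z[start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    u = scipy.stats.norm.cdf(z)
    return scipy.stats.gamma.ppf(u, a=sigma, scale=1.0 / sigma)


def simulate_dataset(
    config: GeneratorConfig, n_cells: int
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate counts with ``floor(n_cells / gamma_star)`` true metacells."""
    rng = np.random.default_rng(config.seed)
    m_total = n_cells // config.gamma_star
    if m_total < 1:
        raise ValueError("n_cells too small for one metacell at gamma_star")
    sizes = _draw_sizes(m_total, config.gamma_star, config.size_range, rng)

    n_states = config.n_states if config.n_states is not None else m_total
    mu = _state_means(config, n_states, rng)
    if config.n_states is None:
        states = np.arange(m_total)
    else:
        states = rng.integers(0, n_states, size=m_total)

    metacell_ids = [f"true_{k}" for k in range(m_total)]
    lam = np.empty((m_total, config.p))
    cell_ids: list[str] = []
    metacell_of: dict[str, str] = {}
    blocks = []
    cell_counter = 0
    for k in range(m_total):
        theta = _sample_theta(config, rng)
        rate = mu[states[k]] * theta
        lam[k] = rate / rate.sum()
        m_k = sizes[k]
        omega = rng.lognormal(0.0, config.omega_sdlog, size=m_k)
        block = rng.poisson(omega[:, None] * rate[None, :])
        blocks.append(block)
        for _ in range(m_k):
            cid = f"cell_{cell_counter}"
            cell_ids.append(cid)
            metacell_of[cid] = metacell_ids[k]
            cell_counter += 1
    counts = CountMatrix(
        np.vstack(blocks).astype(np.int64),
        cell_ids,
        [f"feat_{j}" for j in range(config.p)],
    )
    truth = GroundTruth(
        cell_ids=cell_ids,
        metacell_of=metacell_of,
        metacell_ids=metacell_ids,
        state_of_metacell={metacell_ids[k]: int(states[k]) for k in range(m_total)},
        lambda_matrix=lam,
    )
    return counts, truth


def sample_trustworthy_metacell(
    lam: np.ndarray, library_sizes: list[int] | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact null block: independent multinomial rows with the given totals."""
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 1 or np.any(lam < 0) or not np.isclose(lam.sum(), 1.0):
        raise ValueError("lam must be a probability vector")
    lib = np.asarray(library_sizes, dtype=int)
    if np.any(lib < 1):
        raise ValueError("library sizes must be >= 1")
    return np.vstack([rng.multinomial(t, lam) for t in lib])


def make_mixed_partition(
    truth: GroundTruth, mix_fraction: float, rng: np.random.Generator
) -> tuple[MetacellPartition, dict[str, bool]]:
    """Partition with a fraction of metacells replaced by 50/50 cross-state mixes.

    Pairs of distinct-state true metacells (A, B) are each replaced by two
    mixed metacells: one holding half of A and half of B, the other holding
    the remaining halves.  All other metacells pass through intact.  Returns
    the partition and a per-metacell truly-dubious flag (mixed => True).
    """
    if not 0.0 <= mix_fraction < 1.0:
        raise ValueError("mix_fraction must lie in [0, 1)")
    m_total = len(truth.metacell_ids)
    if m_total < 2:
        raise ValueError("need at least two true metacells")
    n_pairs = int(round(mix_fraction * m_total / 2))
    if mix_fraction > 0 and n_pairs == 0:
        n_pairs = 1

    order = rng.permutation(m_total)
    used: list[tuple[str, str]] = []
    pool = [truth.metacell_ids[i] for i in order]
    while len(used) < n_pairs and len(pool) >= 2:
        a = pool.pop(0)
        partner = next(
            (
                b
                for b in pool
                if truth.state_of_metacell[b] != truth.state_of_metacell[a]
            ),
            None,
        )
        if partner is None:
            continue
        pool.remove(partner)
        used.append((a, partner))

    members = {m: [] for m in truth.metacell_ids}
    for cell, label in truth.metacell_of.items():
        members[label].append(cell)

    assignment: dict[str, str] = {}
    flags: dict[str, bool] = {}
    mixed_sources = {m for pair in used for m in pair}
    for label in truth.metacell_ids:
        if label not in mixed_sources:
            for cell in members[label]:
                assignment[cell] = label
            flags[label] = False
    order_ids = [m for m in truth.metacell_ids if m not in mixed_sources]
    for i, (a, b) in enumerate(used):
        cells_a = list(members[a])
        cells_b = list(members[b])
        rng.shuffle(cells_a)
        rng.shuffle(cells_b)
        ha, hb = len(cells_a) // 2, len(cells_b) // 2
        first, second = f"mixed_{i}a", f"mixed_{i}b"
        for cell in cells_a[:ha] + cells_b[:hb]:
            assignment[cell] = first
        for cell in cells_a[ha:] + cells_b[hb:]:
            assignment[cell] = second
        flags[first] = flags[second] = True
        order_ids.extend([first, second])
    return MetacellPartition(assignment, order_ids), flags


def oracle_partitioner(
    truth: GroundTruth, gamma: int, rng: np.random.Generator
) -> MetacellPartition:
    """Partition with a purity elbow exactly at the true granularity.

    At ``gamma == gamma_star`` this is the ground-truth partition.  Below it,
    each true metacell is split into random sub-groups of average size
    ``gamma`` (all pure).  Above it, nearest true metacells (Euclidean
    distance between lambda vectors) are greedily merged, so impurity
    appears only past the true granularity.
    """
    if gamma < 2:
        raise ValueError("gamma must be >= 2")
    sizes = truth.sizes
    gamma_star = int(round(np.mean(list(sizes.values()))))
    members = {m: [] for m in truth.metacell_ids}
    for cell, label in truth.metacell_of.items():
        members[label].append(cell)

    if gamma == gamma_star:
        return truth.partition()

    assignment: dict[str, str] = {}
    order_ids: list[str] = []
    if gamma < gamma_star:
        for label in truth.metacell_ids:
            cells = list(members[label])
            rng.shuffle(cells)
            n_sub = max(1, int(round(len(cells) / gamma)))
            chunks = np.array_split(np.array(cells), n_sub)
            for s, chunk in enumerate(chunks):
                sub = f"{label}_s{s}"
                for cell in chunk:
                    assignment[str(cell)] = sub
                order_ids.append(sub)
        return MetacellPartition(assignment, order_ids)

    # gamma > gamma_star: greedy nearest-lambda merging of whole true metacells
    group_size = max(2, int(round(gamma / gamma_star)))
    remaining = list(range(len(truth.metacell_ids)))
    lam = truth.lambda_matrix
    g = 0
    while remaining:
        seed_idx = remaining.pop(0)
        group = [seed_idx]
        while len(group) < group_size and remaining:
            dists = [float(np.linalg.norm(lam[j] - lam[seed_idx])) for j in remaining]
            nearest = remaining[int(np.argmin(dists))]
            remaining.remove(nearest)
            group.append(nearest)
        merged = f"merged_{g}"
        for idx in group:
            for cell in members[truth.metacell_ids[idx]]:
                assignment[cell] = merged
        order_ids.append(merged)
        g += 1
    return MetacellPartition(assignment, order_ids)


def theoretical_within_correlation(lam_j: float, lam_l: float) -> float:
    """Closed-form within-metacell correlation between two features under the
    multinomial null: ``-sqrt(l_j/(1-l_j)) * sqrt(l_l/(1-l_l))``.

    The sum constraint makes it slightly negative; it vanishes as the
    relative abundances shrink (large p) and reaches -1 at p=2 with equal
    abundances.
    """
    if not 0.0 < lam_j < 1.0 or not 0.0 < lam_l < 1.0:
        raise ValueError("relative abundances must lie strictly in (0, 1)")
    return -float(
        np.sqrt(lam_j / (1.0 - lam_j)) * np.sqrt(lam_l / (1.0 - lam_l))
    )


def theoretical_mixture_bias(
    lam1: np.ndarray, lam2: np.ndarray, m_metacells: int, j: int, l: int
) -> float:
    """Closed-form bias of the metacell covariance estimator when two
    metacells are 50/50 mixtures of states with abundances ``lam1``, ``lam2``:

        (lam1_j*lam2_l + lam2_j*lam1_l - lam1_j*lam1_l - lam2_j*lam2_l) / (2(M-1))
    """
    if m_metacells < 2:
        raise ValueError("need at least two metacells")
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    bracket = (
        lam1[j] * lam2[l]
        + lam2[j] * lam1[l]
        - lam1[j] * lam1[l]
        - lam2[j] * lam2[l]
    )
    return float(bracket / (2.0 * (m_metacells - 1)))
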