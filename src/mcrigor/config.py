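"""Run configuration shared by the detection and optimization pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Hyperparameters of the dubious-metacell detection and granularity sweep.

    Attributes
    ----------
    n_features :
        Number of highly variable features retained for the divergence
        statistic.  If the data holds fewer non-constant features, all of
        them are used.
    quantile :
        Quantile of the null divergence scores used as the dubious/trustworthy
        threshold.
    bandwidth :
        Half-width (in cells) of the metacell-size window over which null
        scores are pooled when computing size-conditional thresholds.
    weight :
        Weight ``w`` on the dubious rate in ``Score = 1 - w*DubRate -
        (1-w)*ZeroRate``.
    gamma_grid :
        Candidate granularity levels (average cells per metacell) swept during
        optimization.
    seed :
        Seed for every stochastic step (permutations, partitioners).
    min_metacell_size :
        Metacells smaller than this are not scored: with two cells every
        pairwise correlation is +/-1 and the divergence ratio is identically
        one, carrying no signal.
    min_window_nulls :
        Minimum number of null scores required in a size window before the
        window is accepted; sparser windows are widened, then fall back to
        the global quantile.
    scale_factor :
        Library-size scale factor of the log-normalization.
    """

    n_features: int = 2000
    quantile: float = 0.95
    bandwidth: float = 10.0
    weight: float = 0.5
    gamma_grid: tuple[int, ...] = field(default_factory=lambda: tuple(range(2, 101)))
    seed: int = 0
    min_metacell_size: int = 3
    min_window_nulls: int = 5
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        if not 0.0 < self.weight < 1.0:
            raise ValueError("weight must lie in (0, 1)")
        if any(g < 2 for g in self.gamma_grid):
            raise ValueError("all granularity levels must be >= 2")
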