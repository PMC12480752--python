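"""Recover the true metacell granularity with the Score sweep.

Simulates data whose true metacells average gamma* = 50 cells, then sweeps
the granularity gamma of an oracle partitioner (pure sub-splits below
gamma*, cross-state merges above it).  DubRate stays near zero up to gamma*
and jumps once metacells start merging distinct states, while ZeroRate
(sparsity of the aggregated profiles) keeps falling; the Score
1 - w*DubRate - (1-w)*ZeroRate peaks at the true granularity.
"""

import numpy as np

import mcrigor as mr

config = mr.GeneratorConfig(p=500, gamma_star=50, seed=2)
counts, truth = mr.simulate_dataset(config, 1_500)
norm = mr.normalize_and_select(counts, p=500)
run = mr.RunConfig(n_features=500, seed=2)

print(f"{'gamma':>6} {'M':>4} {'DubRate':>8} {'ZeroRate':>9} {'Score':>7}")
rows = {}
for gamma in (10, 25, 50, 75, 100):
    partition = mr.oracle_partitioner(truth, gamma, np.random.default_rng(2))
    res = mr.evaluate_partition(counts, norm, partition, run)
    rows[gamma] = res
    print(
        f"{gamma:>6} {res['M']:>4} {res['DubRate']:>8.3f} "
        f"{res['ZeroRate']:>9.3f} {res['Score']:>7.3f}"
    )

best = max(rows, key=lambda g: rows[g]["Score"])
print(f"\nScore-optimal granularity: gamma = {best} (true gamma* = 50)")
print(
    "Below gamma* metacells are pure but sparse; above it they merge distinct"
    "\nstates and the dubious rate jumps — the Score peaks at the balance point."
)
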