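"""Closed-form results behind the method, checked by Monte Carlo.

Within a homogeneous metacell, counts given the library size are multinomial
in the shared relative abundances lambda.  Two consequences:

  * any two features carry a slight negative correlation
    -sqrt(l_j/(1-l_j)) * sqrt(l_l/(1-l_l)), vanishing as abundances shrink;
  * aggregated metacell profiles estimate covariances across states without
    bias — unless metacells mix states, which adds a known bias term.
"""

import numpy as np

import mcrigor as mr

rng = np.random.default_rng(0)

# 1. within-metacell correlation vs its closed form
p = 50
lam = np.full(p, 1 / p)
block = mr.sample_trustworthy_metacell(lam, [300] * 4000, rng).astype(float)
r = np.corrcoef(block, rowvar=False)
observed = r[np.triu_indices(p, 1)].mean()
expected = mr.theoretical_within_correlation(1 / p, 1 / p)
print(f"mean pairwise correlation, multinomial block : {observed:+.5f}")
print(f"closed form -l/(1-l) at l = 0.02             : {expected:+.5f}")

# 2. covariance bias from 50/50 mixed metacells
states = np.array(
    [
        [0.40, 0.10, 0.25, 0.25],
        [0.10, 0.40, 0.25, 0.25],
        [0.30, 0.30, 0.20, 0.20],
        [0.20, 0.20, 0.30, 0.30],
        [0.25, 0.15, 0.35, 0.25],
        [0.15, 0.25, 0.25, 0.35],
    ]
)
omega_true = float(np.cov(states[:, 0], states[:, 1], ddof=1)[0, 1])
bias = mr.theoretical_mixture_bias(states[0], states[1], m_metacells=6, j=0, l=1)


def mean_cov_estimate(mixed: bool, reps: int = 300) -> float:
    vals = []
    for _ in range(reps):
        profiles = []
        for k in range(6):
            if mixed and k < 2:
                members = [states[0]] * 10 + [states[1]] * 10
            else:
                members = [states[k]] * 20
            rel = [rng.multinomial(2000, lam_i) / 2000 for lam_i in members]
            profiles.append(np.mean(rel, axis=0))
        z = mr.MetacellProfileMatrix(
            np.array(profiles), [f"m{i}" for i in range(6)], list("abcd")
        )
        vals.append(mr.covariance_from_metacells(z, 0, 1))
    return float(np.mean(vals))


print(f"\ntrue covariance of features 1,2 across states : {omega_true:+.5f}")
print(f"estimate from pure metacells (MC mean)        : {mean_cov_estimate(False):+.5f}")
print(f"estimate from mixed metacells (MC mean)       : {mean_cov_estimate(True):+.5f}")
print(f"closed-form mixture bias                      : {bias:+.5f}")
print(
    "\nMixing two states into 50/50 metacells shifts the covariance estimate"
    "\nby exactly the closed-form bias — the reason dubious metacells distort"
    "\ndownstream co-expression analysis."
)
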