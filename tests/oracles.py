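"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own numerical routes: the bivariate
normal CDF comes from scipy's multivariate-normal integration (not Owen's T),
the tetrachoric likelihood is maximized by grid search (not a 1-D optimizer),
and Youden cutoffs are found by exhaustive enumeration.
"""

import numpy as np
from scipy.stats import multivariate_normal, norm


def bvn_cdf_reference(h: float, k: float, rho: float) -> float:
    return float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([h, k])
    )


def grid_tetrachoric(n11, n10, n01, n00, coarse=0.01, fine=0.0005):
    """Maximize the two-step tetrachoric likelihood by two-stage grid search."""
    cells = [n11, n10, n01, n00]
    if min(cells) == 0:
        cells = [c + 0.5 for c in cells]
    n11, n10, n01, n00 = cells
    n = sum(cells)
    h = norm.ppf((n01 + n00) / n)
    k = norm.ppf((n10 + n00) / n)

    def loglik(rho):
        p00 = bvn_cdf_reference(h, k, rho)
        p01 = norm.cdf(h) - p00
        p10 = norm.cdf(k) - p00
        p11 = 1.0 - norm.cdf(h) - norm.cdf(k) + p00
        probs = np.clip([p11, p10, p01, p00], 1e-300, None)
        return float(np.dot([n11, n10, n01, n00], np.log(probs)))

    grid = np.arange(-0.999, 0.999 + 1e-9, coarse)
    best = grid[int(np.argmax([loglik(r) for r in grid]))]
    lo, hi = max(best - coarse, -0.9995), min(best + coarse, 0.9995)
    grid2 = np.arange(lo, hi + fine / 2, fine)
    grid2 = grid2[np.abs(grid2) < 0.9999]
    return float(grid2[int(np.argmax([loglik(r) for r in grid2]))])


def exhaustive_youden_cutoff(scores, obs):
    """Best Youden-J cutoff over all midpoints, ties toward 0.5 (enumeration)."""
    scores = np.asarray(scores, float)
    obs = np.asarray(obs)
    distinct = np.unique(scores)
    if distinct.size < 2:
        return 0.5, None
    cands = (distinct[:-1] + distinct[1:]) / 2
    pos, neg = obs == 1, obs == 0

    def j(c):
        sens = (scores[pos] >= c).mean()
        spec = (scores[neg] < c).mean()
        return sens + spec - 1.0

    js = np.array([j(c) for c in cands])
    best = js.max()
    ties = cands[js == best]
    return float(ties[np.argmin(np.abs(ties - 0.5))]), float(best)
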