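"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools

import numpy as np
from scipy import stats as sps


def brute_force_link(p1, p2, max_disp):
    """Minimum-cost partial matching by exhaustive enumeration: summed
    squared displacement plus max_disp² per unmatched detection."""
    b = max_disp**2
    n1, n2 = len(p1), len(p2)
    best_cost, best_pairs = None, None
    for m in range(min(n1, n2) + 1):
        for rows in itertools.combinations(range(n1), m):
            for cols in itertools.permutations(range(n2), m):
                cost = 0.0
                ok = True
                for r, c in zip(rows, cols):
                    d2 = float(np.sum((np.asarray(p1[r]) - p2[c]) ** 2))
                    if d2 > b:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += b * (n1 - m) + b * (n2 - m)
                if best_cost is None or cost < best_cost - 1e-12:
                    best_cost = cost
                    best_pairs = set(zip(rows, cols))
    return best_cost, best_pairs


def wilcoxon_enumeration_oracle(diffs):
    """Two-sided exact signed-rank p over all 2^n sign assignments."""
    diffs = np.asarray([d for d in diffs if d != 0], dtype=float)
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    return min(1.0, 2 * min(p_ge, p_le))


def poisson_weighted_slope_t(profile):
    """Slope t-statistic of shell density vs shell-center radius, weighted
    by the Poisson variance of each shell's count (heteroscedasticity-
    correct test of 'no radial trend')."""
    centers = 0.5 * (profile.shell_edges_um[:-1] + profile.shell_edges_um[1:])
    d = np.asarray(profile.densities)
    var = np.maximum(np.asarray(profile.n_beads), 1) \
        / np.asarray(profile.volumes_um3) ** 2
    w = 1.0 / var
    X = np.c_[np.ones_like(centers), centers]
    wx = X * w[:, None]
    cov = np.linalg.inv(X.T @ wx)
    beta = cov @ (wx.T @ d)
    return float(beta[1] / np.sqrt(cov[1, 1]))


def ring_mean_oracle(img, dfield, lo, hi):
    """Per-pixel loop with the same half-open membership rule.

    Membership is decided pixel by pixel; the final mean is taken over the
    collected values in the same row-major order (so agreement is bit-exact,
    not merely close)."""
    vals = []
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            if dfield.interior[y, x]:
                continue
            d = dfield.distances_um[y, x]
            if lo <= d < hi:
                vals.append(img[y, x])
    return np.asarray(vals).mean()
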