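"""Nonparametric inference layer for fold-change and hole-size metrics.

Each spheroid's fold change is compared to 1 (no change) with a
two-tailed one-sample Wilcoxon signed-rank test; the resulting family of
p-values is corrected with Benjamini–Hochberg at a 5% false discovery
rate.  Treatment conditions are compared with a Kruskal–Wallis test
followed by Dunn's post-hoc pairwise comparisons.  Error bars are the
standard error of the mean; significance labels follow the */**
convention (p < 0.05 / p < 0.01).

The Wilcoxon test is exact (full 2^n sign enumeration) for n <= 12 and
uses the normal approximation with tie and continuity corrections above
that.  Zero differences are dropped by default (Wilcoxon's rule); Pratt's
method keeps them in the ranking via ``zero_policy="pratt"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSampleError, ParameterError

EXACT_MAX_N = 12


@dataclass
class StatResult:
    """One test outcome: statistic, raw/adjusted p, significance label."""

    test: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    label: str = ""
    n_per_group: tuple = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.p_value, self.p_adjusted):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ParameterError(f"p-value out of [0, 1]: {p}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ParameterError("adjusted p must be >= raw p")


def significance_label(p: float) -> str:
    """"**" for p < 0.01, "*" for p < 0.05, "" otherwise."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p-value out of [0, 1]: {p}")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sem(values) -> float:
    """Standard error of the mean: sample sd (n−1 denominator) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("sem needs n >= 2")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def _signed_ranks(diffs: np.ndarray, zero_policy: str):
    """Ranks of |d| (average ties) and the sign vector, per zero policy."""
    if zero_policy == "drop":
        diffs = diffs[diffs != 0]
        if diffs.size == 0:
            raise DegenerateSampleError("degenerate_sample")
        ranks = sps.rankdata(np.abs(diffs))
        return diffs, ranks
    if zero_policy == "pratt":
        if np.all(diffs == 0):
            raise DegenerateSampleError("degenerate_sample")
        ranks = sps.rankdata(np.abs(diffs))
        keep = diffs != 0
        return diffs[keep], ranks[keep]
    raise ParameterError(f"unknown zero_policy {zero_policy!r}")


def wilcoxon_one_sample(
    values,
    null_value: float = 1.0,
    alternative: str = "two-sided",
    zero_policy: str = "drop",
) -> StatResult:
    """Two-tailed (by default) one-sample Wilcoxon signed-rank test of the
    values against ``null_value`` — e.g. fold changes against 1.

    Exact p by enumeration of all 2^n sign assignments for n <= 12;
    normal approximation with tie and continuity corrections otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateSampleError("degenerate_sample")
    diffs = v - null_value
    diffs, ranks = _signed_ranks(diffs, zero_policy)
    n = diffs.size
    w_plus = float(ranks[diffs > 0].sum())

    if n <= EXACT_MAX_N:
        # distribution of W+ over all 2^n equally likely sign assignments
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        w_all = signs @ ranks
        p_ge = float((w_all >= w_plus - 1e-9).mean())
        p_le = float((w_all <= w_plus + 1e-9).mean())
        method = "exact"
    else:
        mean = ranks.sum() / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        sd = np.sqrt(var)
        z_ge = (w_plus - mean - 0.5) / sd
        z_le = (w_plus - mean + 0.5) / sd
        p_ge = float(sps.norm.sf(z_ge))
        p_le = float(sps.norm.cdf(z_le))
        method = "normal"

    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    elif alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return StatResult(
        test="wilcoxon_one_sample", statistic=w_plus, p_value=p,
        label=significance_label(p), n_per_group=(int(n),),
        extra={"method": method, "null_value": null_value},
    )


def bh_adjust(pvalues, fdr: float = 0.05):
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(adjusted, reject)`` in the input order; rejection where the
    adjusted p is <= ``fdr``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adj, adj <= fdr


def kruskal_wallis(groups) -> StatResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square p on k−1 df)."""
    if len(groups) < 2:
        raise ParameterError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ParameterError("every group needs n >= 1")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return StatResult(
        test="kruskal_wallis", statistic=float(h), p_value=float(p),
        label=significance_label(float(p)),
        n_per_group=tuple(int(a.size) for a in arrays),
    )


def dunn_posthoc(groups, adjust: str = "none") -> list[list[StatResult | None]]:
    """Dunn's pairwise post-hoc comparisons after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1)))·(1/n_i + 1/n_j))
    with T = Σ(t³ − t) over tie groups of the pooled ranks; two-sided
    normal p per pair, optionally BH-adjusted across pairs
    (``adjust="bh"``; unadjusted by default).
    Returns a symmetric k×k matrix (list of lists) with None on the
    diagonal.
    """
    if len(groups) < 2:
        raise ParameterError("dunn_posthoc needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ParameterError("every group needs n >= 1")
    k = len(arrays)
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    N = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    base_var = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1)) if N > 1 else 0.0

    mean_ranks, sizes, idx = [], [], 0
    for a in arrays:
        mean_ranks.append(float(ranks[idx: idx + a.size].mean()))
        sizes.append(a.size)
        idx += a.size

    pairs, zs, ps = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
            pairs.append((i, j))
            zs.append(float(z))
            ps.append(min(p, 1.0))
    adj = [None] * len(ps)
    if adjust == "bh":
        adj = list(bh_adjust(ps)[0])
    elif adjust != "none":
        raise ParameterError(f"unknown adjust {adjust!r}")

    matrix: list[list[StatResult | None]] = [
        [None for _ in range(k)] for _ in range(k)
    ]
    for (i, j), z, p, a in zip(pairs, zs, ps, adj):
        label_p = a if a is not None else p
        res = StatResult(
            test="dunn", statistic=z, p_value=p,
            p_adjusted=None if a is None else float(a),
            label=significance_label(float(label_p)),
            n_per_group=(sizes[i], sizes[j]),
        )
        matrix[i][j] = res
        matrix[j][i] = res
    return matrix


def fold_change_family(
    groups: dict, null_value: float = 1.0, fdr: float = 0.05,
    zero_policy: str = "drop",
) -> dict[str, StatResult]:
    """The full one-sample testing procedure over a family of groups:
    Wilcoxon of each group's fold changes against ``null_value``, BH
    correction across the family, labels from the adjusted p."""
    names = list(groups)
    results = {
        name: wilcoxon_one_sample(groups[name], null_value=null_value,
                                  zero_policy=zero_policy)
        for name in names
    }
    adj, _ = bh_adjust([results[n].p_value for n in names], fdr=fdr)
    for name, a in zip(names, adj):
        r = results[name]
        r.p_adjusted = float(a)
        r.label = significance_label(float(a))
    return results
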