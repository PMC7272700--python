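"""Two-group negative-binomial differential expression.

A per-feature Wald-type test on the log2 ratio of group mean normalized
counts, with a moment-based NB dispersion estimate (variance = mu + alpha
mu^2) and Benjamini-Hochberg FDR control. This is deliberately a light,
calibrated NB test rather than a clone of any particular DE package: no
dispersion shrinkage across features, no outlier refitting. The reference
distribution for the Wald statistic is Student t with ``n1 + n2 - 2``
degrees of freedom by default, which accounts for the handful of residual
degrees of freedom behind the variance estimate at typical two-group
designs (4 vs 6 samples); a plain normal reference is available but is
anticonservative at such sample sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import (
    CASE,
    CONTROL,
    DEFAULT_PSEUDOCOUNT,
    CountMatrix,
    normalize,
)

#: dispersion floor for Poisson-like features
ALPHA_MIN = 1e-8


def nb_wald_test(
    cm: CountMatrix,
    size_factors: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    reference: str = "t",
) -> pd.DataFrame:
    """Per-feature NB Wald test of case vs control mean normalized counts.

    Returns a DataFrame indexed by feature with columns ``base_mean``,
    ``log2fc``, ``se``, ``stat`` and ``p_value``. ``log2fc`` is
    ``log2((mean_case + eps) / (mean_control + eps))``. The standard error
    comes from the delta method under NB sampling with a pooled
    moment-based dispersion ``alpha = max(excess variance / mu^2,
    ALPHA_MIN)``. Features that are all-zero in a group are handled by the
    pseudo-count (no special casing, no crash).
    """
    if reference not in ("t", "normal"):
        raise ValueError("reference must be 't' or 'normal'")
    ctrl = cm.samples_of(CONTROL)
    case = cm.samples_of(CASE)
    n1, n2 = len(ctrl), len(case)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    norm = cm.counts.div(size_factors, axis=1)
    c = norm[ctrl].values
    t = norm[case].values
    mc, mt = c.mean(axis=1), t.mean(axis=1)
    vc, vt = c.var(axis=1, ddof=1), t.var(axis=1, ddof=1)

    # pooled moment estimate of the NB dispersion across both groups
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (n1 - 1) * (vc - mc) + (n2 - 1) * (vt - mt)
        den = (n1 - 1) * mc**2 + (n2 - 1) * mt**2
        alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    alpha = np.maximum(alpha, ALPHA_MIN)

    eps = pseudocount
    log2fc = np.log2((mt + eps) / (mc + eps))
    ln2sq = np.log(2.0) ** 2
    var_mc = (mc + alpha * mc**2) / n1
    var_mt = (mt + alpha * mt**2) / n2
    se = np.sqrt(
        var_mc / ((mc + eps) ** 2 * ln2sq) + var_mt / ((mt + eps) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    if reference == "t":
        p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where((mc == 0) & (mt == 0), 1.0, p)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1).values,
            "log2fc": log2fc,
            "se": se,
            "stat": z,
            "p_value": p,
        },
        index=cm.counts.index,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values, capped
    at 1, mapped back to the input order (stable under permutation).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> tuple[set, set]:
    """Partition DE calls into up and down sets.

    A feature is differentially expressed when its linear-scale group fold
    change satisfies ``max(FC, 1/FC) >= fc_threshold`` and its adjusted
    (or, with ``use_fdr=False``, raw) p-value is ``<= alpha``; both
    thresholds are inclusive.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    stat = table["q_value"] if use_fdr else table["p_value"]
    de = (np.abs(table["log2fc"]) >= np.log2(fc_threshold)) & (stat <= alpha)
    up = set(table.index[de & (table["log2fc"] > 0)])
    down = set(table.index[de & (table["log2fc"] < 0)])
    return up, down


def run_de(
    cm: CountMatrix,
    size_factors: pd.Series | None = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    use_fdr: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    reference: str = "t",
) -> pd.DataFrame:
    """Full DE table: Wald test, BH q-values and a direction call.

    ``direction`` is ``up``/``down`` for features passing both the fold
    change and significance thresholds, ``ns`` otherwise.
    """
    nm = normalize(cm, size_factors)
    table = nb_wald_test(cm, nm.size_factors, pseudocount, reference)
    table["q_value"] = benjamini_hochberg(table["p_value"].values)
    up, down = call_degs(table, fc_threshold, alpha, use_fdr)
    direction = pd.Series("ns", index=table.index)
    direction[list(up)] = "up"
    direction[list(down)] = "down"
    table["direction"] = direction
    return table
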