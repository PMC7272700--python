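"""Expression-stability clustering and sample-structure analysis.

Z-scores DEG expression, groups genes by k-means into expression blocks,
quantifies per-cluster stability as the %CV of per-sample fold changes
within the case group, builds cumulative log2-FC distributions, runs a
sample-level PCA, and recovers the case-sample subgroup closest to the
controls ("cluster A") for re-calling the uniformly regulated DEG set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .de import call_degs, run_de
from .normalize import CASE, CONTROL, CountMatrix


def zscore_rows(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each row to mean 0 and SD 1 (population SD by default).

    Zero-variance rows are mapped to all-zeros with a warning.
    """
    x = matrix.values.astype(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance rows z-scored to zeros",
            stacklevel=2,
        )
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterResult:
    labels: pd.Series  # gene -> 1..k
    sizes: pd.Series  # cluster -> n genes
    wcss: float
    stability: pd.DataFrame | None = None


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = 4,
    n_init: int = 100,
    seed: int = 0,
    order_by: pd.Series | None = None,
) -> ClusterResult:
    """Best-of-``n_init`` random-restart k-means with Euclidean distance.

    Deterministic given ``seed``. When ``order_by`` (typically per-gene
    log2 FC) is supplied, cluster labels 1..k are assigned in descending
    order of the cluster mean of that quantity, so label 1 is the most
    up-regulated block -- the published I..IV ordering is otherwise
    arbitrary.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {matrix.shape[0]}")
    km = KMeans(n_clusters=k, init="random", n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix.values)
    if order_by is not None:
        means = pd.Series(order_by).loc[matrix.index].groupby(raw).mean()
        rank = {c: i + 1 for i, c in enumerate(means.sort_values(ascending=False).index)}
    else:
        rank = {c: c + 1 for c in range(k)}
    labels = pd.Series([rank[c] for c in raw], index=matrix.index, name="cluster")
    sizes = labels.value_counts().sort_index()
    return ClusterResult(labels, sizes, float(km.inertia_))


def fold_change_cv(
    per_sample_fc: pd.DataFrame,
    case_samples: list[str],
    gene_set=None,
    ddof: int = 1,
) -> pd.Series:
    """Per-gene %CV of fold changes across case samples.

    ``%CV_g = 100 * SD(FC_g) / mean(FC_g)`` over the case samples, the
    expression-stability measure separating uniformly from variably
    regulated genes. Sample SD (ddof=1) by default.
    """
    fc = per_sample_fc[list(case_samples)]
    if gene_set is not None:
        fc = fc.loc[list(gene_set)]
    return 100.0 * fc.std(axis=1, ddof=ddof) / fc.mean(axis=1)


def cv_summary(cv: pd.Series) -> tuple[float, float]:
    """Mean +/- SD summary of a %CV vector."""
    return float(cv.mean()), float(cv.std(ddof=1))


def cluster_stability(
    result: ClusterResult,
    per_sample_fc: pd.DataFrame,
    case_samples: list[str],
) -> pd.DataFrame:
    """Per-cluster mean +/- SD of the fold-change %CV."""
    cv = fold_change_cv(per_sample_fc, case_samples, result.labels.index)
    rows = []
    for c in result.sizes.index:
        vals = cv[result.labels == c]
        rows.append(
            {"cluster": c, "n": int(result.sizes[c]),
             "cv_mean": float(vals.mean()),
             "cv_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        )
    table = pd.DataFrame(rows).set_index("cluster")
    result.stability = table
    return table


def cumulative_fc_distribution(
    log2fc: pd.Series, labels: pd.Series
) -> dict[int, pd.DataFrame]:
    """Per-cluster ECDF of log2 fold change (cumulative %, last = 100)."""
    out: dict[int, pd.DataFrame] = {}
    for c in sorted(labels.unique()):
        vals = np.sort(log2fc.loc[labels.index[labels == c]].values)
        cum = 100.0 * np.arange(1, len(vals) + 1) / len(vals)
        out[int(c)] = pd.DataFrame({"log2fc": vals, "cumulative_pct": cum})
    return out


def sample_pca(
    matrix: pd.DataFrame, log: bool = True, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples on (log-scale) normalized expression.

    Returns per-sample scores and the explained-variance fractions.
    """
    x = matrix.values.T
    if log:
        x = np.log2(x + 1.0)
    n_components = max(1, min(n_components, x.shape[0] - 1, x.shape[1]))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0, keepdims=True))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def nearest_subgroup(matrix: pd.DataFrame, groups: pd.Series) -> list[str]:
    """Case-sample subgroup closest to the control group ("cluster A").

    Case samples are clustered by average-linkage hierarchical clustering
    on Euclidean distance over the supplied (z-scored DEG) expression;
    of the two top-level case subtrees, the one whose centroid is nearest
    the control centroid is returned; singleton subtrees are only chosen
    when no multi-sample subtree exists, since a one-sample subgroup
    cannot support re-calling DE. Identical case samples (degenerate
    tree) return the whole case group.
    """
    case = [s for s in matrix.columns if groups[s] == CASE]
    ctrl = [s for s in matrix.columns if groups[s] == CONTROL]
    if len(case) < 2:
        raise ValueError("need >= 2 case samples")
    x = matrix[case].values.T
    z = linkage(x, method="average", metric="euclidean")
    if z[-1, 2] == 0:  # all case samples identical
        return case
    halves = fcluster(z, t=2, criterion="maxclust")
    ctrl_centroid = matrix[ctrl].values.mean(axis=1)
    candidates = []
    for c in (1, 2):
        members = [s for s, h in zip(case, halves) if h == c]
        if not members:
            continue
        d = np.linalg.norm(matrix[members].values.mean(axis=1) - ctrl_centroid)
        candidates.append((d, members))
    usable = [c for c in candidates if len(c[1]) >= 2] or candidates
    return min(usable, key=lambda c: c[0])[1]


def subgroup_degs(
    cm: CountMatrix,
    deg_set: set,
    subgroup_samples: list[str],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> tuple[set, pd.DataFrame]:
    """Re-call DE using only the subgroup case samples vs all controls.

    Returns the intersection with the full DEG list -- the uniformly
    regulated set -- together with the subgroup DE table.
    """
    keep = cm.samples_of(CONTROL) + list(subgroup_samples)
    sub = cm.subset_samples(keep)
    table = run_de(sub, fc_threshold=fc_threshold, alpha=alpha, use_fdr=use_fdr)
    up, down = call_degs(table, fc_threshold, alpha, use_fdr)
    return (up | down) & set(deg_set), table
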