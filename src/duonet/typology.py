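"""Two-stage cluster typology of couple networks.

Couples are clustered on the 10 standardized criterion measures: Ward's
minimum-variance hierarchical clustering proposes a partition, k-means
refines it (seeded from the Ward centroids by default). Cluster-count
diagnostics aggregate five validity indices by majority vote; the final k is
ultimately an analyst decision informed by those diagnostics and by the
t-score profiles, which express each cluster's mean on every variable on a
common mean-100/SD-10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

from .measures import CRITERION_VARS


class ScalingError(ValueError):
    """A criterion column cannot be standardized (zero variance)."""


@dataclass
class TypologyResult:
    labels: pd.Series  # couple_id -> cluster id (0..k-1)
    k: int
    method: str
    within_cluster_means: pd.DataFrame  # k x 10, raw scale
    tscores: pd.DataFrame  # k x 10
    anova: pd.DataFrame  # per-variable eta_squared, F, p
    diagnostics: pd.DataFrame | None = None
    excluded: list | None = None  # couple_ids dropped for missing measures


def standardize(profiles: pd.DataFrame, variables=CRITERION_VARS) -> pd.DataFrame:
    """Z-score the criterion columns (population-SD convention).

    Rows with any missing criterion value are excluded listwise; callers can
    diff the index to see who was dropped. Standardizing an already
    standardized matrix is a no-op up to floating error.
    """
    cols = profiles[list(variables)].astype(float)
    complete = cols.dropna()
    if len(complete) < 2:
        raise ValueError("need at least 2 complete profiles to standardize")
    sd = complete.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ScalingError(f"zero-variance column(s): {zero}")
    return (complete - complete.mean()) / sd


def ward_cluster(z: pd.DataFrame, k: int):
    """Ward's-method agglomerative labels for k clusters, plus the linkage.

    Merge heights of the returned linkage matrix are monotone nondecreasing
    (a property of Ward's error-sum-of-squares criterion on Euclidean
    distances).
    """
    n = len(z)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    lk = linkage(z.to_numpy(), method="ward")
    labels = fcluster(lk, t=k, criterion="maxclust") - 1
    return pd.Series(labels, index=z.index, name="cluster"), lk


def kmeans_cluster(z: pd.DataFrame, k: int, restarts: int = 10, seed: int = 0,
                   init_centroids: np.ndarray | None = None):
    """Best-of-restarts k-means; deterministic given the seed.

    ``init_centroids`` switches to a single run initialized there — the
    second stage of the two-stage design, refining a Ward partition.
    """
    n = len(z)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if init_centroids is not None:
        km = KMeans(n_clusters=k, init=np.asarray(init_centroids), n_init=1,
                    random_state=seed)
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(z.to_numpy())
    return pd.Series(km.labels_, index=z.index, name="cluster"), km.cluster_centers_


def ward_then_kmeans(z: pd.DataFrame, k: int, seed: int = 0):
    """Two-stage clustering: k-means seeded from the Ward-partition centroids."""
    ward_labels, _ = ward_cluster(z, k)
    centroids = np.vstack([
        z.to_numpy()[ward_labels.to_numpy() == c].mean(axis=0) for c in range(k)
    ])
    return kmeans_cluster(z, k, seed=seed, init_centroids=centroids)


def _wss(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def _gap_statistic(x: np.ndarray, k: int, seed: int, b: int, restarts: int) -> tuple:
    """Gap statistic against uniform draws over the data's bounding box."""
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x)
    log_w = np.log(_wss(x, km.labels_))
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref_log_w = np.empty(b)
    for i in range(b):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_km = KMeans(n_clusters=k, n_init=1,
                        random_state=int(rng.integers(2**31 - 1))).fit(ref)
        ref_log_w[i] = np.log(_wss(ref, ref_km.labels_))
    gap = ref_log_w.mean() - log_w
    sk = ref_log_w.std(ddof=0) * np.sqrt(1 + 1 / b)
    return gap, sk


def select_k(z: pd.DataFrame, k_range=range(2, 9), seed: int = 0, restarts: int = 10,
             gap_b: int = 50) -> pd.DataFrame:
    """Cluster-count diagnostics over a range of k, with a majority vote.

    Five indices are computed per k — total within-cluster sum of squares
    (elbow, judged by the largest second difference), mean silhouette (max),
    Calinski–Harabasz (max), Davies–Bouldin (min), and the gap statistic
    (smallest k with gap(k) >= gap(k+1) − s(k+1)). The returned frame has one
    row per k, a ``votes`` column counting how many indices prefer that k,
    and attrs["majority_k"].
    """
    x = z.to_numpy()
    ks = [k for k in k_range if 2 <= k <= len(z) - 1]
    if not ks:
        raise ValueError("k_range leaves no admissible k")
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x)
        labels = km.labels_
        gap, sk = _gap_statistic(x, k, seed=seed + k, b=gap_b, restarts=restarts)
        rows.append({
            "k": k,
            "wss": _wss(x, labels),
            "silhouette": silhouette_score(x, labels) if len(np.unique(labels)) > 1 else np.nan,
            "calinski_harabasz": calinski_harabasz_score(x, labels),
            "davies_bouldin": davies_bouldin_score(x, labels),
            "gap": gap,
            "gap_se": sk,
        })
    diag = pd.DataFrame(rows).set_index("k")

    best = {}
    best["silhouette"] = diag["silhouette"].idxmax()
    best["calinski_harabasz"] = diag["calinski_harabasz"].idxmax()
    best["davies_bouldin"] = diag["davies_bouldin"].idxmin()
    if len(ks) >= 3:
        second_diff = np.diff(diag["wss"].to_numpy(), 2)
        best["wss_elbow"] = ks[int(np.argmax(second_diff)) + 1]
    gap_choice = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if diag.loc[k, "gap"] >= diag.loc[ks[i + 1], "gap"] - diag.loc[ks[i + 1], "gap_se"]:
            gap_choice = k
            break
    best["gap"] = gap_choice

    votes = pd.Series(0, index=diag.index)
    for k in best.values():
        votes.loc[k] += 1
    diag["votes"] = votes
    diag.attrs["best_k_by_index"] = best
    diag.attrs["majority_k"] = int(votes[votes == votes.max()].index.min())
    return diag


def cluster_tscores(raw_profiles: pd.DataFrame, labels: pd.Series,
                    variables=CRITERION_VARS) -> pd.DataFrame:
    """Within-cluster means re-expressed on a mean-100, SD-10 scale.

        t(c, v) = 100 + 10 * (mean_c(v) − mean(v)) / sd(v)

    with the overall sample mean and (n−1) SD. By construction the
    sample-size-weighted mean of each t-score column is 100 and its weighted
    SD is the ratio of between-cluster to total spread times 10.
    """
    data = raw_profiles.loc[labels.index, list(variables)].astype(float)
    overall_mean = data.mean()
    overall_sd = data.std(ddof=1)
    zero = overall_sd[overall_sd == 0].index.tolist()
    if zero:
        raise ScalingError(f"zero overall SD for column(s): {zero}")
    cluster_means = data.groupby(labels).mean()
    return 100 + 10 * (cluster_means - overall_mean) / overall_sd


def anova_by_cluster(raw_profiles: pd.DataFrame, labels: pd.Series,
                     variables=CRITERION_VARS) -> pd.DataFrame:
    """One-way ANOVA of each criterion variable across clusters.

    Reports eta-squared (SS_between / SS_total), the F statistic, and its
    p-value. Degenerate separation (zero within-cluster variance) reports
    F = inf with p = 0 and a ``degenerate`` flag rather than failing.
    """
    data = raw_profiles.loc[labels.index, list(variables)].astype(float)
    groups = labels.to_numpy()
    uniq = np.unique(groups)
    k = len(uniq)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 clusters")
    n = len(data)
    rows = []
    for v in variables:
        y = data[v].to_numpy()
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        ss_between = sum(
            (y[groups == c].mean() - grand) ** 2 * (groups == c).sum() for c in uniq
        )
        ss_within = ss_total - ss_between
        eta2 = ss_between / ss_total if ss_total > 0 else 0.0
        degenerate = ss_within <= 1e-12 * max(ss_total, 1.0)
        if degenerate:
            f_val, p = np.inf, 0.0
        else:
            f_val = (ss_between / (k - 1)) / (ss_within / (n - k))
            p = stats.f.sf(f_val, k - 1, n - k)
        rows.append({"variable": v, "eta_squared": eta2, "F": f_val, "p": p,
                     "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("variable")


def run_typology(profiles: pd.DataFrame, k: int, method: str = "ward_then_kmeans",
                 seed: int = 0, variables=CRITERION_VARS) -> TypologyResult:
    """Cluster, profile, and test in one call.

    ``profiles`` must be indexed by couple_id and contain the criterion
    columns; rows with missing measures are excluded listwise.
    """
    z = standardize(profiles, variables)
    excluded = sorted(set(profiles.index) - set(z.index))
    if method == "ward":
        labels, _ = ward_cluster(z, k)
    elif method == "kmeans":
        labels, _ = kmeans_cluster(z, k, seed=seed)
    elif method == "ward_then_kmeans":
        labels, _ = ward_then_kmeans(z, k, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    raw = profiles.loc[z.index]
    return TypologyResult(
        labels=labels,
        k=k,
        method=method,
        within_cluster_means=raw[list(variables)].groupby(labels).mean(),
        tscores=cluster_tscores(raw, labels, variables),
        anova=anova_by_cluster(raw, labels, variables),
        excluded=excluded,
    )


def linkage_to_newick(lk: np.ndarray, leaf_names) -> str:
    """Serialize a linkage matrix as a Newick tree (merge heights as lengths)."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(lk)
    names = list(leaf_names)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def plot_tscores(tscores: pd.DataFrame, path, cluster_names: dict | None = None):
    """Bar-chart the t-score profile of every cluster (one panel per cluster)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(tscores)
    fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (cluster, row) in zip(axes, tscores.iterrows()):
        ordered = row.sort_values()
        ax.barh(range(len(ordered)), ordered.to_numpy() - 100, left=100, color="steelblue")
        ax.set_yticks(range(len(ordered)), ordered.index)
        ax.axvline(100, color="black", lw=0.8)
        title = cluster_names.get(cluster, f"cluster {cluster}") if cluster_names else f"cluster {cluster}"
        ax.set_title(f"{title}")
        ax.set_xlabel("t-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
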