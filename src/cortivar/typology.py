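"""Farm typology: standardized PCA, Ward clustering on component scores,
and v.test characterization of clusters.

The active matrix holds, per farm, the mean and SD of each of its two
batches. Columns are centered and scaled with the population convention
(denominator N), the correlation matrix is eigendecomposed, and farms are
clustered by Ward's criterion on all component scores. Clusters are then
described by v.test statistics: a standardized deviation of the cluster
mean for quantitative variables, and a signed normal quantile of the exact
hypergeometric tail for categorical levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from cortivar.cohort import BatchSummary

__all__ = [
    "ActiveMatrix",
    "TypologyModel",
    "build_active_matrix",
    "standardized_pca",
    "ward_hcpc",
    "vtest_quantitative",
    "vtest_categorical",
]

ACTIVE_COLUMNS = ("mean_batch1", "mean_batch2", "sd_batch1", "sd_batch2")


@dataclass
class ActiveMatrix:
    """Farms x 4 matrix of per-batch HCC means and SDs (pg/mg)."""

    farm_ids: list[str]
    values: np.ndarray  # shape (n_farms, 4), column order ACTIVE_COLUMNS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.farm_ids), 4):
            raise ValueError(
                f"active matrix must be (n_farms, 4), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("active matrix has missing cells")


@dataclass
class TypologyModel:
    """PCA eigenstructure, component scores, and (optionally) cluster labels."""

    farm_ids: list[str]
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    loadings: np.ndarray  # variables x components
    scores: np.ndarray  # farms x components
    labels: dict[str, int] = field(default_factory=dict)
    vtests: dict = field(default_factory=dict)


def build_active_matrix(summaries: list[BatchSummary]) -> ActiveMatrix:
    """Assemble the farm x (mean1, mean2, sd1, sd2) matrix.

    Row order is sorted farm id; every farm must contribute exactly two
    batch summaries (ordered by batch id).
    """
    per_farm: dict[str, list[BatchSummary]] = {}
    for s in summaries:
        per_farm.setdefault(s.farm_id, []).append(s)
    bad = {f: len(v) for f, v in per_farm.items() if len(v) != 2}
    if bad:
        raise ValueError(f"farms without exactly 2 batch summaries: {bad}")
    farm_ids = sorted(per_farm)
    rows = []
    for f in farm_ids:
        s1, s2 = sorted(per_farm[f], key=lambda s: s.batch_id)
        rows.append([s1.mean, s2.mean, s1.sd, s2.sd])
    return ActiveMatrix(farm_ids=farm_ids, values=np.asarray(rows))


def standardized_pca(matrix: ActiveMatrix | np.ndarray) -> TypologyModel:
    """PCA of the correlation matrix of the active variables.

    Columns are standardized with the population convention (denominator N).
    Component signs are fixed by making each component's largest-magnitude
    loading positive. Scores are the standardized data projected on the
    loadings, so the population variance of each score column equals its
    eigenvalue. A plain 2-D array is accepted in place of an
    :class:`ActiveMatrix` (rows then get positional ids).
    """
    if isinstance(matrix, ActiveMatrix):
        X, row_ids, col_names = matrix.values, matrix.farm_ids, ACTIVE_COLUMNS
    else:
        X = np.asarray(matrix, dtype=float)
        row_ids = [str(i) for i in range(X.shape[0])]
        col_names = [f"col{j}" for j in range(X.shape[1])]
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least 3 farms")
    sd = X.std(axis=0, ddof=0)
    zero = [col_names[j] for j in range(X.shape[1]) if sd[j] == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return TypologyModel(
        farm_ids=list(row_ids),
        eigenvalues=eigvals,
        variance_explained=eigvals / eigvals.sum(),
        loadings=eigvecs,
        scores=Z @ eigvecs,
    )


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for k in np.unique(labels):
        pts = scores[labels == k]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def ward_hcpc(
    model: TypologyModel,
    k: int | str = "auto",
    *,
    n_components: int | None = None,
    consolidate: bool = False,
    consolidate_iter: int = 10,
) -> dict[str, int]:
    """Cluster farms by Ward's criterion on their component scores.

    Parameters
    ----------
    k :
        Number of clusters, or ``"auto"`` to pick the cut with the largest
        relative between-cluster inertia gain (ratio of successive
        within-inertia drops over k in [2, min(10, n-1)]).
    n_components :
        Number of leading components to cluster on; default all.
    consolidate :
        If True, refine the Ward partition with a k-means pass seeded at
        the cluster centroids (off by default to keep determinism trivial).

    Returns a farm_id -> cluster id map; cluster ids are renumbered 1..k by
    lexicographically smallest member farm so labels do not depend on input
    order.
    """
    scores = model.scores if n_components is None else model.scores[:, :n_components]
    n = scores.shape[0]
    if isinstance(k, int) and not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")

    Zlink = hierarchy.ward(pdist(scores))

    if k == "auto":
        kmax = min(10, n - 1)
        within = {kk: _within_inertia(scores, hierarchy.fcluster(Zlink, kk, "maxclust"))
                  for kk in range(1, min(kmax + 2, n + 1))}
        best_k, best_gain = 2, -np.inf
        for kk in range(2, kmax + 1):
            drop = within[kk - 1] - within[kk]
            nxt = within[kk] - within.get(kk + 1, 0.0)
            gain = drop / nxt if nxt > 0 else np.inf
            if gain > best_gain:
                best_k, best_gain = kk, gain
        k = best_k

    raw = hierarchy.fcluster(Zlink, k, criterion="maxclust")

    if consolidate:
        # k-means refinement seeded at the Ward centroids
        assign = np.unique(raw, return_inverse=True)[1]
        for _ in range(consolidate_iter):
            centroids = np.stack(
                [scores[assign == c].mean(axis=0) for c in np.unique(assign)]
            )
            dist = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            new = np.unique(dist.argmin(axis=1), return_inverse=True)[1]
            if np.array_equal(new, assign):
                break
            assign = new
        raw = assign + 1

    # renumber clusters 1..k by their lexicographically smallest farm
    members: dict[int, list[str]] = {}
    for farm, c in zip(model.farm_ids, raw):
        members.setdefault(int(c), []).append(farm)
    ordered = sorted(members, key=lambda c: min(members[c]))
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    return {farm: remap[int(c)] for farm, c in zip(model.farm_ids, raw)}


def vtest_quantitative(
    values: dict[str, float], labels: dict[str, int], *, variance: str = "population"
) -> dict[int, dict]:
    """v.test of a quantitative farm-level variable per cluster.

    v = (mean_k - mean) / sqrt((s^2 / n_k) * (N - n_k) / (N - 1)) with the
    overall variance s^2 computed with denominator N (population
    convention; ``variance="sample"`` switches to N - 1). The two-sided p
    comes from the standard normal. Invariant under affine rescaling of the
    variable.
    """
    if variance not in ("population", "sample"):
        raise ValueError("variance must be 'population' or 'sample'")
    farms = sorted(labels)
    if set(values) < set(farms):
        raise ValueError("values missing for some labeled farms")
    x = np.asarray([values[f] for f in farms], dtype=float)
    lab = np.asarray([labels[f] for f in farms])
    N = len(farms)
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ValueError("v.test needs at least 2 clusters (a single cluster has zero denominator)")
    s2 = x.var(ddof=0 if variance == "population" else 1)
    out: dict[int, dict] = {}
    for c in clusters:
        nk = int((lab == c).sum())
        denom2 = (s2 / nk) * (N - nk) / (N - 1)
        if denom2 == 0:
            v = 0.0 if x[lab == c].mean() == x.mean() else float("inf")
        else:
            v = float((x[lab == c].mean() - x.mean()) / np.sqrt(denom2))
        out[int(c)] = {"v": v, "p": float(2 * stats.norm.sf(abs(v))), "n": nk}
    return out


def vtest_categorical(
    levels: dict[str, str], labels: dict[str, int]
) -> dict[tuple[str, int], dict]:
    """v.test of categorical level enrichment per cluster.

    For level L with overall count K among N farms and in-cluster count x
    out of n_k, the one-sided exact hypergeometric tail
    p1 = min(P(X >= x), P(X <= x)) is converted to a signed normal
    quantile v = sign * Phi^-1(1 - p1 / 2), positive when the level is
    over-represented. The reported p is the doubled tail capped at 1.
    """
    farms = sorted(labels)
    if set(levels) < set(farms):
        raise ValueError("levels missing for some labeled farms")
    lab = np.asarray([labels[f] for f in farms])
    lev = np.asarray([levels[f] for f in farms], dtype=object)
    N = len(farms)
    out: dict[tuple[str, int], dict] = {}
    for level in sorted({str(v) for v in lev}):
        K = int((lev == level).sum())
        for c in np.unique(lab):
            nk = int((lab == c).sum())
            x = int(((lev == level) & (lab == c)).sum())
            hg = stats.hypergeom(N, K, nk)
            p_over = float(hg.sf(x - 1))
            p_under = float(hg.cdf(x))
            p1 = min(p_over, p_under, 1.0)
            sign = 1.0 if x / nk > K / N else (-1.0 if x / nk < K / N else 0.0)
            v = 0.0 if sign == 0.0 else float(sign * stats.norm.isf(p1 / 2.0))
            out[(level, int(c))] = {
                "v": v,
                "p": min(1.0, 2.0 * p1),
                "count_in_cluster": x,
                "count_overall": K,
                "cluster_size": nk,
            }
    return out
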