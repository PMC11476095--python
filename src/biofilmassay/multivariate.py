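"""Rank-product timepoint comparison, PCA, and UPGMA producer dendrogram.

The rank-product statistic compares biofilm production between two incubation
times without distributional assumptions: within every biological replicate
the isolates are ranked by their 48 h / 24 h production ratio, and each
isolate's statistic is the geometric mean of its ranks across replicates.
Small rank products in the descending ranking flag consistently up-shifted
isolates; small products in the ascending ranking flag down-shifted ones.
Significance comes from a permutation null in which ranks are reshuffled
independently within each replicate, so an isolate's null rank in a replicate
is uniform over that replicate's observed rank values.

PCA and the Euclidean-distance UPGMA dendrogram summarise the full isolate x
(condition x timepoint x method) feature matrix; the dendrogram is cut into k
clusters ranked best-to-worst producers by mean crystal-violet signal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control, rankdata
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

_LOG_EPS = 1e-9  # slack when counting null rank products <= observed (float logs)


# ---------------------------------------------------------------------------
# 24 h vs 48 h production ratios
# ---------------------------------------------------------------------------

def ratio_24_48(cv_by_biorep: pd.DataFrame, timepoint_a: float = 24.0,
                timepoint_b: float = 48.0) -> pd.DataFrame:
    """Per-biological-replicate production ratio between two timepoints.

    ``cv_by_biorep`` is a per-bio-rep aggregate (see ``aggregate_wells`` with
    ``by_bio_rep=True``) restricted to a single condition.  Pairs with a
    missing or non-positive denominator are dropped with a warning.
    """
    cond = cv_by_biorep[["factor", "level"]].drop_duplicates()
    if len(cond) > 1:
        raise ValueError("ratio_24_48 expects a single condition; filter first")
    wide = cv_by_biorep.pivot_table(index=["isolate_id", "bio_rep"], columns="timepoint_h",
                                    values="mean_od")
    for tp in (timepoint_a, timepoint_b):
        if tp not in wide.columns:
            raise ValueError(f"timepoint {tp} h absent from the summary")
    wide = wide.reset_index()
    bad = wide[timepoint_a].isna() | wide[timepoint_b].isna() | (wide[timepoint_a] <= 0)
    if bad.any():
        logger.warning("dropping %d isolate x replicate pair(s) with missing or "
                       "non-positive %g h denominator", int(bad.sum()), timepoint_a)
    good = wide[~bad].copy()
    good["ratio"] = good[timepoint_b] / good[timepoint_a]
    return good[["isolate_id", "bio_rep", "ratio"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rank-product permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RPResult:
    isolate_id: str
    rp_up: float
    rp_down: float
    p_up: float
    p_down: float
    p_value: float
    direction: str
    significant: bool


def _null_log_rp(rank_columns: list[np.ndarray], B: int,
                 rng: np.random.Generator | None) -> np.ndarray:
    """Sorted null distribution of log rank products for a single item.

    Exact enumeration over the Cartesian product of the observed per-replicate
    rank values when that product has at most ``B`` elements, else ``B`` Monte
    Carlo draws (one independent uniform rank per replicate).
    """
    sizes = np.prod([len(c) for c in rank_columns])
    if sizes <= B:
        null = np.zeros(1)
        for col in rank_columns:
            null = (null[:, None] + np.log(col)[None, :]).ravel()
    else:
        if rng is None:
            raise ValueError("a seed is required for the Monte Carlo null")
        null = np.zeros(B)
        for col in rank_columns:
            # sort so draws depend only on the rank multiset, not row order
            null += np.log(rng.choice(np.sort(col), size=B, replace=True))
    return np.sort(null)


def _one_sided_p(obs_log: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    counts = np.searchsorted(null_sorted, obs_log + _LOG_EPS, side="right")
    return (counts + 1.0) / (null_sorted.size + 1.0)


def rank_product_test(ratios: pd.DataFrame | np.ndarray, B: int = 10_000,
                      seed: int | None = None, alpha: float = 0.05,
                      correction: str | None = None) -> pd.DataFrame:
    """Two one-sided rank-product permutation tests per isolate.

    ``ratios`` is either a long table (isolate_id, bio_rep, ratio) or an
    isolate x replicate matrix.  Ties receive mid-ranks.  For each direction
    the one-sided p-value is ``(count of null RP <= observed + 1) / (N + 1)``
    where N is the null size (exact enumeration when the rank grid has at most
    B points, otherwise B Monte Carlo permutations).  The reported two-sided
    ``p_value`` doubles the smaller one-sided p (capped at 1) so that the test
    keeps its nominal level; ``direction`` records which side was smaller.
    No across-isolate multiplicity correction is applied by default;
    ``correction="bh"`` switches on Benjamini-Hochberg.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("rank_product_test requires an explicit seed")
    if isinstance(ratios, pd.DataFrame) and "ratio" in ratios.columns:
        wide = ratios.pivot_table(index="isolate_id", columns="bio_rep", values="ratio")
        labels = [str(i) for i in wide.index]
        X = wide.to_numpy(dtype=float)
    else:
        X = np.asarray(ratios, dtype=float)
        if isinstance(ratios, pd.DataFrame):
            labels = [str(i) for i in ratios.index]
        else:
            labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need an isolate x replicate matrix with >= 2 isolates")
    if np.isnan(X).any():
        raise ValueError("ratio matrix contains missing values")

    n, k = X.shape
    ranks_up = rankdata(-X, axis=0, method="average")   # rank 1 = largest ratio
    ranks_down = rankdata(X, axis=0, method="average")  # rank 1 = smallest ratio
    rng = np.random.default_rng(seed)

    results = {}
    for name, ranks in (("up", ranks_up), ("down", ranks_down)):
        obs_log = np.log(ranks).sum(axis=1)
        null = _null_log_rp([ranks[:, j] for j in range(k)], B, rng)
        results[name] = {"rp": np.exp(obs_log / k), "p": _one_sided_p(obs_log, null)}

    p_up, p_down = results["up"]["p"], results["down"]["p"]
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    direction = np.where(p_up <= p_down, "up", "down")
    p_report = p_two if correction is None else false_discovery_control(p_two, method="bh")

    out = pd.DataFrame({
        "isolate_id": labels,
        "rp_up": results["up"]["rp"], "rp_down": results["down"]["rp"],
        "p_up": p_up, "p_down": p_down,
        "p_value": p_report, "direction": direction,
        "significant": p_report < alpha,
    })
    return out.sort_values("isolate_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores, loadings and per-component explained-variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray


def pca(matrix: pd.DataFrame | np.ndarray, n_components: int = 3,
        standardize: bool = True) -> PCAResult:
    """Principal components of an isolate x variable matrix.

    Columns are centered and, when ``standardize`` is on, scaled to unit
    variance (zero-variance columns are left at zero rather than divided by
    zero).  Components are sorted by explained variance; the sign of each
    component is fixed so its largest-magnitude loading is positive.  Raises
    when ``n_components`` exceeds the rank of the processed matrix.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        row_labels, col_labels = list(matrix.index), list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        row_labels = list(range(X.shape[0]))
        col_labels = list(range(X.shape[1]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; impute first")

    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    rank = int(np.linalg.matrix_rank(Xc))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds the matrix rank {rank}")

    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xc)
    loadings = model.components_.T.copy()
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=row_labels, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=col_labels, columns=comp_names),
        variance_fraction=model.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Merge:
    a: int
    b: int
    height: float


@dataclass
class Dendrogram:
    """UPGMA merge structure: leaves 0..n-1, merge i creates cluster n+i.

    Heights are the average inter-cluster distances at each merge and are
    non-decreasing (average linkage is reducible, so no inversions occur).
    """

    merges: list[Merge]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> list[float]:
        return [m.height for m in self.merges]

    def members(self) -> dict[int, frozenset[str]]:
        """Leaf-label set under every cluster id."""
        out = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        for i, m in enumerate(self.merges):
            out[self.n_leaves + i] = out[m.a] | out[m.b]
        return out

    def leaf_sets(self, ndigits: int = 9) -> set[tuple[frozenset[str], float]]:
        """Canonical (cluster members, height) pairs for topology comparison."""
        members = self.members()
        return {(members[self.n_leaves + i], round(m.height, ndigits))
                for i, m in enumerate(self.merges)}


def upgma_from_distances(distances: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage agglomeration of a square distance matrix.

    At each step the closest pair of clusters merges at a height equal to
    their average inter-cluster distance; ties are broken deterministically in
    favour of the pair containing the lexicographically smallest leaf label
    (then the smallest partner label).
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match the labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")

    dist: dict[tuple[int, int], float] = {(i, j): float(D[i, j])
                                          for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    min_label = {i: labels[i] for i in range(n)}
    active = set(range(n))
    merges: list[Merge] = []

    for step in range(n - 1):
        best = None
        for (i, j), d in dist.items():
            la, lb = sorted((min_label[i], min_label[j]))
            key = (d, la, lb)
            if best is None or key < best[0]:
                best = (key, (i, j))
        (d, _, _), (i, j) = best
        new = n + step
        merges.append(Merge(i, j, d))
        for other in active - {i, j}:
            di = dist.pop((min(i, other), max(i, other)))
            dj = dist.pop((min(j, other), max(j, other)))
            dist[(min(other, new), max(other, new))] = (
                (size[i] * di + size[j] * dj) / (size[i] + size[j]))
        del dist[(i, j)]
        active -= {i, j}
        active.add(new)
        size[new] = size[i] + size[j]
        min_label[new] = min(min_label[i], min_label[j])
    return Dendrogram(merges, list(labels))


def upgma(matrix: pd.DataFrame | np.ndarray, labels: list[str] | None = None,
          standardize: bool = False) -> Dendrogram:
    """UPGMA dendrogram of rows under Euclidean distance."""
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index] if labels is None else labels
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(X.shape[0])] if labels is None else labels
    if X.shape[0] < 2:
        raise ValueError("UPGMA needs at least two rows")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    condensed = pdist(X, metric="euclidean")
    if np.isnan(condensed).any():
        raise ValueError("NaN distance encountered")
    return upgma_from_distances(squareform(condensed), labels)


@dataclass
class ClusterLabels:
    """Partition of dendrogram leaves into k clusters.

    Cluster ids run 1..k ordered best-to-worst mean production when production
    values are supplied; ``quality`` then tags the ordered clusters as best /
    intermediate / worst.
    """

    assignments: dict[str, int]
    quality: dict[int, str] | None = None

    def cluster_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for leaf, cid in self.assignments.items():
            out.setdefault(cid, set()).add(leaf)
        return out


def cut_clusters(dendrogram: Dendrogram, k: int,
                 production: dict[str, float] | pd.Series | None = None) -> ClusterLabels:
    """Cut the dendrogram at the height yielding exactly k clusters.

    Raises when tied merge heights make a cut into exactly k clusters
    impossible.  With per-leaf production values the clusters are ranked by
    mean production (descending) and tagged best / intermediate / worst.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    heights = dendrogram.heights
    n_apply = n - k
    if k == n:
        if n > 1 and heights and heights[0] <= 0:
            raise ValueError("cannot cut into n singleton clusters: zero-height merge")
    elif k > 1 and heights[n_apply] <= heights[n_apply - 1]:
        raise ValueError(f"tied merge heights make a cut into exactly {k} clusters impossible")

    members = dendrogram.members()
    roots = set(range(n))
    for i in range(n_apply):
        m = dendrogram.merges[i]
        roots -= {m.a, m.b}
        roots.add(n + i)

    groups = [sorted(members[r]) for r in roots]
    if production is not None:
        prod = pd.Series(production)
        groups.sort(key=lambda g: (-float(prod.loc[g].mean()), g[0]))
    else:
        groups.sort(key=lambda g: g[0])

    assignments = {leaf: cid for cid, group in enumerate(groups, start=1) for leaf in group}
    quality = None
    if production is not None:
        quality = {}
        for cid in range(1, k + 1):
            if cid == 1:
                quality[cid] = "best"
            elif cid == k:
                quality[cid] = "worst"
            else:
                quality[cid] = "intermediate"
    return ClusterLabels(assignments, quality)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def to_newick(dendrogram: Dendrogram) -> str:
    """Ultrametric Newick string: every leaf sits at depth (root height)/2.

    A cluster merged at height h is placed at depth h/2, so the patristic
    distance between any two leaves equals their merge height.
    """
    n = dendrogram.n_leaves
    depth = {i: 0.0 for i in range(n)}
    for i, m in enumerate(dendrogram.merges):
        depth[n + i] = m.height / 2.0

    def render(cid: int, parent_depth: float) -> str:
        if cid < n:
            return f"{dendrogram.labels[cid]}:{parent_depth - 0.0:.17g}"
        m = dendrogram.merges[cid - n]
        inner = ",".join(render(c, depth[cid]) for c in (m.a, m.b))
        return f"({inner}):{parent_depth - depth[cid]:.17g}"

    root = n + len(dendrogram.merges) - 1
    m = dendrogram.merges[-1]
    inner = ",".join(render(c, depth[root]) for c in (m.a, m.b))
    return f"({inner});"


def newick_leaf_sets(text: str, ndigits: int = 9) -> set[tuple[frozenset[str], float]]:
    """Parse a Newick string into canonical (cluster members, height) pairs.

    The inverse view of :func:`to_newick` for round-trip checks: each internal
    node of an ultrametric tree corresponds to a merge at twice its
    depth-above-leaves.  Parsing is delegated to Bio.Phylo.
    """
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(text), "newick")
    out: set[tuple[frozenset[str], float]] = set()

    def walk(clade) -> tuple[frozenset[str], float]:
        if not clade.clades:
            return frozenset([clade.name]), 0.0
        parts = [walk(c) for c in clade.clades]
        depths = [ch[1] + (c.branch_length or 0.0) for ch, c in zip(parts, clade.clades)]
        if max(depths) - min(depths) > 10.0 ** -ndigits * max(1.0, max(depths)):
            raise ValueError("Newick tree is not ultrametric")
        depth = sum(depths) / len(depths)
        members = frozenset().union(*(p[0] for p in parts))
        out.add((members, round(2.0 * depth, ndigits)))
        return members, depth

    walk(tree.root)
    return out
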