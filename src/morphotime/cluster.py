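"""Two-clade morphological clustering with stability cross-validation.

The mature interneuron question — do the cells split into discrete basket
and stellate classes, or form one continuum? — is addressed by Ward
hierarchical clustering of zero-mean standardized feature tables, cut into
two clades, plus three robustness tools: subsample cross-validation
(recluster random subsets, score against the full-data clade labels),
recursive feature elimination (drop or keep named feature groups, measure
adjusted agreement with the baseline split), and low-dimensional embeddings
(UMAP / t-SNE / diffusion components) for visual confirmation.

`MorphologyClustering` is the model object; `fit()` returns a
:class:`ClusteringResults` carrying labels, the dendrogram, leaf order and
the diagnostic methods.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as _linkage, to_tree
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .io import FeatureTable

__all__ = [
    "standardize",
    "hcluster",
    "ClusterResult",
    "leaf_rank",
    "dpt_rank",
    "subsample_cv",
    "SubsampleCVResult",
    "feature_elimination",
    "embed",
    "dendrogram_to_newick",
    "bimodality_screen",
    "MorphologyClustering",
    "ClusteringResults",
]

# Recorded embedding parameter sets (kept verbatim from the analysis record).
UMAP_DEFAULTS = {"n_neighbors": 7, "min_dist": 0.1, "metric": "euclidean"}
TSNE_DEFAULTS = {"perplexity": 7, "max_iter": 10_000, "random_state": 510}


def standardize(table: FeatureTable, ddof: int = 0) -> FeatureTable:
    """Zero-mean, unit-variance standardization of every feature column.

    Uses the population (1/n) standard deviation by default (``ddof=1`` for
    the sample convention).  Constant columns carry no information and are
    dropped with a warning.
    """
    if table.n_cells < 2:
        raise ValueError("standardization requires at least 2 cells")
    X = table.features
    sd = X.std(axis=0, ddof=ddof)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}")
        X = X.drop(columns=constant)
        sd = sd.drop(index=constant)
    Z = (X - X.mean(axis=0)) / sd
    return FeatureTable(Z, table.metadata.copy())


@dataclass
class ClusterResult:
    """Hierarchical clustering of one feature table, cut into clades."""

    labels: pd.Series  # per-cell clade letter ('A', 'B', ...)
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]  # cell ids left-to-right along the dendrogram
    params: dict = field(default_factory=dict)

    @property
    def clades(self) -> list[str]:
        return sorted(self.labels.unique())

    def members(self, clade: str) -> list[str]:
        return self.labels.index[self.labels == clade].tolist()


def hcluster(table: FeatureTable, linkage: str = "ward",
             metric: str = "euclidean", n_clades: int = 2) -> ClusterResult:
    """Agglomerative clustering (Ward/Euclidean by default) cut into clades.

    Cells are processed in lexicographic cell-id order so results do not
    depend on input row order; clade letters follow dendrogram leaf order
    left to right.
    """
    if n_clades > table.n_cells:
        raise ValueError(
            f"n_clades={n_clades} exceeds the number of cells ({table.n_cells})"
        )
    order = sorted(table.cell_ids, key=str)
    X = table.features.loc[order].to_numpy()
    Z = _linkage(X, method=linkage, metric=metric)
    leaves = leaves_list(Z)
    leaf_ids = [order[i] for i in leaves]
    raw = fcluster(Z, t=n_clades, criterion="maxclust")
    # stable letter assignment: 'A' is the clade of the leftmost leaf
    letters = {}
    for leaf in leaves:
        if raw[leaf] not in letters:
            letters[raw[leaf]] = string.ascii_uppercase[len(letters)]
    labels = pd.Series([letters[c] for c in raw], index=pd.Index(order, name="cell_id"))
    return ClusterResult(
        labels=labels.loc[table.cell_ids],
        linkage=Z,
        leaf_order=leaf_ids,
        params={"linkage": linkage, "metric": metric, "n_clades": n_clades},
    )


def leaf_rank(result: ClusterResult, reference_clade_members: Iterable[str]) -> pd.Series:
    """Rank cells 1..n along the dendrogram, reference clade first.

    The clade holding the majority of ``reference_clade_members`` occupies
    ranks 1..|clade|; within each clade ranks follow dendrogram leaf order.
    """
    ref = set(reference_clade_members)
    if not ref:
        raise ValueError("reference clade member set is empty")
    counts = {c: len(ref & set(result.members(c))) for c in result.clades}
    first = max(sorted(counts), key=lambda c: counts[c])
    ordered = [cid for cid in result.leaf_order if result.labels[cid] == first]
    ordered += [cid for cid in result.leaf_order if result.labels[cid] != first]
    return pd.Series(range(1, len(ordered) + 1),
                     index=pd.Index(ordered, name="cell_id")).loc[result.labels.index]


def dpt_rank(pseudotime: pd.Series) -> pd.Series:
    """Rank cells by pseudotime, smallest first; ties broken by cell id."""
    values = pseudotime.astype(float)
    if not np.all(np.isfinite(values)):
        raise ValueError("pseudotime values must be finite")
    order = sorted(values.index, key=lambda cid: (values[cid], str(cid)))
    return pd.Series(range(1, len(order) + 1),
                     index=pd.Index(order, name="cell_id")).loc[values.index]


# ---------------------------------------------------------------------------
# Subsample cross-validation


@dataclass
class SubsampleCVResult:
    """Reclustering accuracy over random subsamples at several sizes."""

    sizes: list[int]
    accuracies: np.ndarray  # (n_sizes, trials)
    seed: int | None

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def sem(self) -> np.ndarray:
        return self.accuracies.std(axis=1, ddof=1) / np.sqrt(self.accuracies.shape[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "mean_accuracy": self.mean,
            "sem": self.sem,
            "trials": self.accuracies.shape[1],
        })


def _majority_label(ref: pd.Series, members: Sequence[str]) -> str:
    counts = ref.loc[list(members)].value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) > 1:
        warnings.warn("clade with tied reference majority; using smaller label")
    return sorted(top)[0]


def subsample_cv(table: FeatureTable, ref_labels: pd.Series,
                 sizes: Sequence[int], trials: int = 20,
                 seed: int | None = None, linkage: str = "ward",
                 restandardize: bool = True) -> SubsampleCVResult:
    """Recluster random subsamples and score them against reference labels.

    Per trial: draw cells without replacement, recluster into two clades,
    name each clade after the majority reference label of its members, and
    count the fraction of cells whose clade name matches their own reference
    label.  Reports the per-size mean and SEM (SD/sqrt(trials)).
    """
    sizes = [int(s) for s in sizes]
    if any(s > table.n_cells for s in sizes):
        raise ValueError("subsample size exceeds the number of cells")
    if any(s < 2 for s in sizes):
        raise ValueError("subsample sizes must be >= 2")
    rng = np.random.default_rng(seed)
    ref = ref_labels.astype(str)
    acc = np.empty((len(sizes), trials))
    ids = np.asarray(table.cell_ids)
    for si, size in enumerate(sizes):
        for t in range(trials):
            pick = rng.choice(ids, size=size, replace=False)
            sub = table.subset_cells(pick)
            if restandardize:
                sub = standardize(sub)
            res = hcluster(sub, linkage=linkage, n_clades=2)
            assigned = pd.Series(index=res.labels.index, dtype=object)
            for clade in res.clades:
                members = res.members(clade)
                assigned.loc[members] = _majority_label(ref, members)
            acc[si, t] = float((assigned == ref.loc[assigned.index]).mean())
    return SubsampleCVResult(sizes=sizes, accuracies=acc, seed=seed)


# ---------------------------------------------------------------------------
# Recursive feature elimination


def feature_elimination(table: FeatureTable, groups: Mapping[str, Sequence[str]],
                        baseline_labels: pd.Series, n_clades: int = 2,
                        linkage: str = "ward",
                        modes: Sequence[str] = ("drop", "keep")) -> pd.DataFrame:
    """Drop or keep named feature groups, recluster, score the agreement.

    For each group two ablations run by default: ``drop`` (remove the group)
    and ``keep`` (cluster on the group alone).  Agreement with the baseline
    labels is the adjusted Rand index.  Returns a tidy DataFrame; the
    reclustered labels are in the ``labels`` column.
    """
    records = []
    all_names = table.feature_names
    for gname, members in groups.items():
        members = list(members)
        missing = [m for m in members if m not in all_names]
        if missing:
            raise KeyError(f"group {gname!r} has unknown features {missing}")
        for mode in modes:
            keep = ([n for n in all_names if n not in members]
                    if mode == "drop" else members)
            if len(keep) < 2:
                raise ValueError(
                    f"ablation {mode}:{gname} leaves {len(keep)} feature(s); "
                    "need at least 2"
                )
            sub = standardize(table.subset_features(keep))
            res = hcluster(sub, linkage=linkage, n_clades=n_clades)
            ari = adjusted_rand_score(
                baseline_labels.loc[res.labels.index], res.labels)
            records.append({
                "ablation": f"{mode}:{gname}",
                "mode": mode,
                "group": gname,
                "n_features": len(keep),
                "ari": float(ari),
                "labels": res.labels,
            })
    return pd.DataFrame.from_records(records).set_index("ablation")


# ---------------------------------------------------------------------------
# Embeddings


def embed(table: FeatureTable, method: str = "umap",
          params: Mapping | None = None, seed: int | None = None) -> pd.DataFrame:
    """2-D embedding of a standardized table (umap | tsne | diffusion).

    Parameters default to the recorded analysis values (UMAP neighbors=7,
    min_dist=0.1; t-SNE perplexity=7, exact gradients, 10000 iterations,
    seed 510).  The ``diffusion`` method uses the package's own diffusion
    maps and needs no third-party embedding library.
    """
    params = dict(params or {})
    n = table.n_cells
    X = table.values()
    if method == "umap":
        opts = {**UMAP_DEFAULTS, **params}
        if opts["n_neighbors"] >= n:
            raise ValueError(
                f"n_neighbors={opts['n_neighbors']} must be < n_cells={n}")
        import umap  # deferred: heavy import

        reducer = umap.UMAP(n_components=2, random_state=seed if seed is not None else 0,
                            **opts)
        coords = reducer.fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        opts = {**TSNE_DEFAULTS, **params}
        if seed is not None:
            opts["random_state"] = seed
        if opts["perplexity"] >= n:
            raise ValueError(f"perplexity={opts['perplexity']} must be < n_cells={n}")
        coords = TSNE(n_components=2, method="exact", init="pca",
                      **opts).fit_transform(X)
    elif method == "diffusion":
        from scipy.sparse.csgraph import connected_components

        from .trajectory import diffusion_components, knn_graph

        k = int(params.pop("knn", 10))
        # every cell needs coordinates: densify the graph until connected
        while True:
            graph, ids = knn_graph(table, k=k)
            if connected_components(graph, directed=False)[0] == 1 or k >= n - 1:
                break
            k = min(2 * k, n - 1)
        comps, _ = diffusion_components(graph, ids, n_components=max(
            2, int(params.pop("n_components", 2))))
        coords = comps.iloc[:, :2].to_numpy()
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=table.cell_ids, columns=["dim1", "dim2"])


# ---------------------------------------------------------------------------
# Dendrogram export


def dendrogram_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Newick string with branch lengths = differences in merge height."""
    tree = to_tree(Z)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Single-feature bimodality screening (optional diagnostic)


def bimodality_screen(x: np.ndarray, reps: int = 200,
                      seed: int | None = None) -> tuple[float, float]:
    """Parametric-bootstrap test of one Gaussian vs a two-component mixture.

    Returns (log-likelihood-ratio statistic, bootstrap p-value).  A small p
    flags a feature whose marginal distribution is better described as
    bimodal.  Used to confirm that no single feature carries the clade split
    by itself.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if len(x) < 8:
        raise ValueError("bimodality screen needs at least 8 observations")

    def lrt(sample: np.ndarray, rs: int) -> float:
        g1 = GaussianMixture(1, random_state=rs).fit(sample)
        g2 = GaussianMixture(2, n_init=3, random_state=rs).fit(sample)
        return 2.0 * (g2.score(sample) - g1.score(sample)) * len(sample)

    stat = lrt(x, 0)
    rng = np.random.default_rng(seed)
    mu, sd = float(x.mean()), float(x.std())
    null = np.array([
        lrt(rng.normal(mu, sd, size=len(x)).reshape(-1, 1), 0)
        for _ in range(reps)
    ])
    p = float((np.sum(null >= stat) + 1) / (reps + 1))
    return float(stat), p


# ---------------------------------------------------------------------------
# Model / Results


class MorphologyClustering:
    """Hierarchical two-clade clustering model for a morphometric table.

    Parameters
    ----------
    table : FeatureTable
        Raw (unstandardized) cells x features table.
    features : sequence of str, optional
        Restrict to these feature columns (e.g. a schema clustering subset).
    linkage, metric : str
        Agglomeration method and distance (Ward/Euclidean by default).
    n_clades : int
        Number of clades the merge tree is cut into.
    """

    def __init__(self, table: FeatureTable, features: Sequence[str] | None = None,
                 linkage: str = "ward", metric: str = "euclidean",
                 n_clades: int = 2):
        self.raw_table = table.subset_features(features) if features else table
        self.linkage = linkage
        self.metric = metric
        self.n_clades = n_clades

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "MorphologyClustering":
        return cls(FeatureTable.from_frame(frame), **kwargs)

    def fit(self) -> "ClusteringResults":
        table = standardize(self.raw_table)
        result = hcluster(table, linkage=self.linkage, metric=self.metric,
                          n_clades=self.n_clades)
        return ClusteringResults(self, table, result)


class ClusteringResults:
    """Fitted clustering: clade labels, dendrogram and diagnostics."""

    def __init__(self, model: MorphologyClustering, table: FeatureTable,
                 result: ClusterResult):
        self.model = model
        self.table = table  # standardized
        self.result = result
        self.labels_ = result.labels
        self.linkage_ = result.linkage
        self.leaf_order_ = result.leaf_order

    # -- diagnostics ---------------------------------------------------
    def leaf_rank(self, reference_clade_members: Iterable[str]) -> pd.Series:
        return leaf_rank(self.result, reference_clade_members)

    def subsample_cv(self, sizes: Sequence[int], trials: int = 20,
                     seed: int | None = None,
                     ref_labels: pd.Series | None = None) -> SubsampleCVResult:
        ref = self.labels_ if ref_labels is None else ref_labels
        return subsample_cv(self.model.raw_table, ref, sizes, trials=trials,
                            seed=seed, linkage=self.model.linkage)

    def feature_elimination(self, groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
        return feature_elimination(self.model.raw_table, groups, self.labels_,
                                   n_clades=self.model.n_clades,
                                   linkage=self.model.linkage)

    def embed(self, method: str = "umap", params: Mapping | None = None,
              seed: int | None = None) -> pd.DataFrame:
        return embed(self.table, method=method, params=params, seed=seed)

    def subcluster(self, clade: str) -> MorphologyClustering:
        """New model restricted to one clade (e.g. the stellate subclades)."""
        return MorphologyClustering(
            self.model.raw_table.subset_cells(self.result.members(clade)),
            linkage=self.model.linkage, metric=self.model.metric,
            n_clades=self.model.n_clades)

    def to_newick(self) -> str:
        order = sorted(self.labels_.index, key=str)
        return dendrogram_to_newick(self.linkage_, order)

    def silhouette(self) -> float:
        return float(silhouette_score(self.table.values(), self.labels_))

    def summary(self) -> str:
        sizes = self.labels_.value_counts().sort_index()
        lines = [
            "Morphological clustering",
            "=" * 40,
            f"cells:            {self.table.n_cells}",
            f"features:         {len(self.table.feature_names)}",
            f"linkage/metric:   {self.model.linkage}/{self.model.metric}",
            f"clades:           {self.model.n_clades}",
        ]
        for clade, n in sizes.items():
            lines.append(f"  clade {clade}: {n} cells")
        lines.append(f"silhouette:       {self.silhouette():.3f}")
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        order = sorted(self.labels_.index, key=str)
        dendrogram(self.linkage_, labels=order, ax=ax, color_threshold=None)
        ax.set_ylabel("merge height")
        return ax
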