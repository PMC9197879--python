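"""Diffusion-map pseudotime ordering of developmental snapshots.

Developing neurons imaged at a fixed age form a mixture of maturation
states; pseudotime re-orders the snapshots along an inferred maturation
axis instead.  The machinery is the single-cell standard: a k-nearest-
neighbor affinity graph with an adaptive Gaussian kernel, the top right
eigenvectors of its row-normalized transition operator (diffusion
components), diffusion distance from a designated start cell (min-max
normalized to [0, 1]), Louvain communities on the same graph as discrete
morphological states, and binned per-feature trend curves with bootstrap
confidence intervals.

`PseudotimeModel` wraps the pipeline; `fit()` returns
:class:`PseudotimeResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .io import FeatureTable
from .cluster import standardize

__all__ = [
    "knn_graph",
    "diffusion_components",
    "diffusion_pseudotime",
    "community_states",
    "stage_concordance",
    "feature_trends",
    "PseudotimeModel",
    "PseudotimeResults",
]


def knn_graph(table: FeatureTable | np.ndarray, k: int,
              ids: Sequence | None = None) -> tuple[sp.csr_matrix, pd.Index]:
    """Symmetric kNN affinity graph with an adaptive Gaussian kernel.

    The per-cell bandwidth is the Euclidean distance to the k-th neighbor;
    affinities are exp(-d^2 / (sigma_i sigma_j)) symmetrized by averaging.
    Duplicate rows (zero distances) get capped affinity 1.  Self-loops are
    excluded.
    """
    if isinstance(table, FeatureTable):
        X = table.values()
        index = pd.Index(table.cell_ids)
    else:
        X = np.asarray(table, dtype=float)
        index = pd.Index(ids if ids is not None else range(len(X)))
    n = len(X)
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n ({k=} vs {n=})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self by identity: duplicate rows can displace it from column 0
    keep = idx != np.arange(n)[:, None]
    keep[keep.all(axis=1), -1] = False
    idx = idx[keep].reshape(n, k)
    dist = dist[keep].reshape(n, k)
    sigma = dist[:, -1].copy()
    tiny = np.finfo(float).tiny
    sigma[sigma <= 0] = tiny
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    bw = sigma[rows] * sigma[cols]
    vals = np.exp(-(dist.ravel() ** 2) / np.maximum(bw, tiny))
    vals = np.minimum(vals, 1.0)
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    W = (K + K.T) * 0.5
    W.setdiag(0.0)
    W.eliminate_zeros()
    return W.tocsr(), index


def diffusion_components(graph: sp.spmatrix, ids: Sequence,
                         n_components: int = 5,
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Eigenvalue-scaled right eigenvectors of the transition operator.

    Rows outside the largest connected component come back NaN (with a
    warning); eigenvalues are sorted descending and bounded by 1.
    """
    ids = pd.Index(ids)
    W = sp.csr_matrix(graph)
    n = W.shape[0]
    ncomp, labels = connected_components(W, directed=False)
    keep = np.arange(n)
    if ncomp > 1:
        largest = np.bincount(labels).argmax()
        keep = np.flatnonzero(labels == largest)
        warnings.warn(
            f"affinity graph has {ncomp} components; restricting to the "
            f"largest ({len(keep)}/{n} cells)"
        )
        W = W[keep][:, keep]
    deg = np.asarray(W.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("graph has isolated vertices with zero degree")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    M = sp.diags(d_inv_sqrt) @ W @ sp.diags(d_inv_sqrt)
    # a few extra pairs make ARPACK resolve degenerate multiplicities
    k = min(n_components + 3, W.shape[0] - 1)
    try:
        # fixed pseudorandom start vector keeps the decomposition
        # deterministic run-to-run without seeding on an exact eigenvector
        v0 = np.random.default_rng(0).standard_normal(M.shape[0])
        evals, evecs = eigsh(M, k=k, which="LA", v0=v0)
    except Exception as exc:  # pragma: no cover - eigensolver failure path
        raise RuntimeError(
            f"diffusion eigendecomposition failed ({exc}); the graph may be "
            "ill-conditioned"
        )
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary component; weight each eigenvector by
    # lambda/(1-lambda), the multiscale diffusion-distance weighting (sums
    # the operator over all diffusion times, damping higher harmonics)
    stop = min(n_components + 1, evecs.shape[1])
    psi = evecs[:, 1:stop] * d_inv_sqrt[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    lam = np.clip(evals[1:stop], -1.0, 1.0 - 1e-10)
    scaled = psi * (lam / (1.0 - lam))[None, :]
    full = np.full((n, scaled.shape[1]), np.nan)
    full[keep] = scaled
    cols = [f"DC{i + 1}" for i in range(scaled.shape[1])]
    return pd.DataFrame(full, index=ids, columns=cols), lam


def diffusion_pseudotime(components: pd.DataFrame, start_cell) -> pd.Series:
    """Diffusion distance from the start cell, min-max normalized to [0, 1]."""
    if start_cell not in components.index:
        raise KeyError(f"start cell {start_cell!r} not in the component table")
    C = components.to_numpy()
    start = components.index.get_loc(start_cell)
    if np.any(np.isnan(C[start])):
        raise ValueError(f"start cell {start_cell!r} lies outside the "
                         "connected component")
    d = np.linalg.norm(C - C[start], axis=1)
    finite = np.isfinite(d)
    rng = d[finite].max() - d[finite].min()
    if rng == 0:
        pt = np.zeros_like(d)
        pt[~finite] = np.nan
    else:
        pt = (d - d[finite].min()) / rng
    return pd.Series(pt, index=components.index, name="pseudotime")


def community_states(graph: sp.spmatrix, ids: Sequence,
                     seed: int | None = 0) -> pd.Series:
    """Louvain modularity communities on the affinity graph.

    Deterministic under a fixed seed; community labels are integers ordered
    by each community's smallest member index.
    """
    ids = pd.Index(ids)
    G = nx.from_scipy_sparse_array(sp.csr_matrix(graph))
    if G.number_of_nodes() == 1:
        return pd.Series([0], index=ids)
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    comms = sorted(comms, key=min)
    labels = np.empty(len(ids), dtype=int)
    for ci, members in enumerate(comms):
        for m in members:
            labels[m] = ci
    return pd.Series(labels, index=ids, name="community")


def stage_concordance(pseudotime: pd.Series, expert_stage: pd.Series,
                      ) -> tuple[float, pd.DataFrame]:
    """Spearman rank agreement of pseudotime with expert maturation stages.

    Also returns per-stage pseudotime summaries (median, IQR, n).
    """
    df = pd.DataFrame({"pt": pseudotime, "stage": expert_stage}).dropna()
    stages = df["stage"].unique()
    if len(stages) < 2:
        raise ValueError("need at least 2 distinct expert stages")
    rho = float(spearmanr(df["pt"], df["stage"]).statistic)
    summaries = df.groupby("stage")["pt"].agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        n="size",
    )
    return rho, summaries


def feature_trends(table: FeatureTable, pseudotime: pd.Series,
                   features: Sequence[str], n_bins: int = 5,
                   groups: pd.Series | None = None, ci: float = 0.95,
                   reps: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Binned mean feature values along pseudotime with bootstrap CIs.

    One row per (feature, group, bin); empty bins are omitted (gaps in the
    curve).  ``groups`` is typically the fate cohort; without it all cells
    form one group.
    """
    from .cosorting import bin_pseudotime

    rng = np.random.default_rng(seed)
    width = 1.0 / n_bins
    bins = bin_pseudotime(pseudotime.dropna(), width=width)
    if groups is None:
        groups = pd.Series("all", index=table.cell_ids)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for feat in features:
        col = table.features[feat]
        for gname in sorted(groups.dropna().unique()):
            gcells = groups.index[groups == gname]
            for b in range(n_bins):
                cells = bins.index[(bins == b)].intersection(gcells)
                vals = col.loc[cells].dropna().to_numpy()
                if len(vals) == 0:
                    continue
                mean = float(vals.mean())
                if reps > 0 and len(vals) > 1:
                    boot = rng.choice(vals, size=(reps, len(vals))).mean(axis=1)
                    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
                else:
                    lo = hi = mean
                rows.append({
                    "feature": feat, "group": gname, "bin": b,
                    "bin_mid": (b + 0.5) * width, "mean": mean,
                    "ci_lo": float(lo), "ci_hi": float(hi), "n": len(vals),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results


class PseudotimeModel:
    """Diffusion-pseudotime model for a developmental feature table.

    Parameters
    ----------
    table : FeatureTable
        Raw feature table; standardized internally unless ``standardize_input``
        is False.
    knn : int
        Neighbors for the affinity graph (default 10: small enough to stay
        local, large enough to keep realistic tables connected).
    n_components : int
        Diffusion components retained (default 5).
    start_cell : optional
        Cell id where pseudotime is anchored at 0.  Default: among cells with
        expert stage 1 (when annotated), the one with the smallest
        ``axon_length``; otherwise the globally smallest.
    pseudotime_space : {'embedding', 'components'}
        Coordinate space for the diffusion distance.  'embedding' (default)
        uses the same 2-D coordinates the neighbor statistics see, keeping
        the per-bin fate nulls calibrated against the neighbor fractions;
        'components' uses all retained diffusion components.
    """

    def __init__(self, table: FeatureTable, knn: int = 10, n_components: int = 5,
                 start_cell=None, standardize_input: bool = True,
                 pseudotime_space: str = "embedding", community_k: int = 20):
        if pseudotime_space not in ("embedding", "components"):
            raise ValueError("pseudotime_space must be 'embedding' or 'components'")
        self.raw_table = table
        self.knn = knn
        self.n_components = n_components
        self.start_cell = start_cell
        self.standardize_input = standardize_input
        self.pseudotime_space = pseudotime_space
        self.community_k = community_k

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "PseudotimeModel":
        return cls(FeatureTable.from_frame(frame), **kwargs)

    def _default_start(self, table: FeatureTable, valid: pd.Index) -> str:
        """Expert-stage-1 cell with minimal axon length, restricted to cells
        on the main graph component."""
        meta = table.metadata
        candidates = valid
        if "expert_stage" in meta.columns and meta["expert_stage"].notna().any():
            stage1 = meta.index[meta["expert_stage"] == 1].intersection(valid)
            if len(stage1):
                candidates = stage1
        if "axon_length" in self.raw_table.features.columns:
            score = self.raw_table.features.loc[candidates, "axon_length"]
        else:
            score = self.raw_table.features.loc[candidates].sum(axis=1)
        return score.idxmin()

    def fit(self, seed: int | None = 0) -> "PseudotimeResults":
        table = standardize(self.raw_table) if self.standardize_input else self.raw_table
        graph, ids = knn_graph(table, k=self.knn)
        comps, evals = diffusion_components(graph, ids, self.n_components)
        valid = comps.dropna().index
        start = self.start_cell if self.start_cell is not None \
            else self._default_start(table, valid)
        if self.pseudotime_space == "embedding":
            e = comps.iloc[:, :2]
            pt_coords = (e - e.mean()) / e.std()
        else:
            pt_coords = comps
        pt = diffusion_pseudotime(pt_coords, start)
        if self.community_k != self.knn and self.community_k < table.n_cells:
            cgraph, cids = knn_graph(table, k=self.community_k)
        else:
            cgraph, cids = graph, ids
        communities = community_states(cgraph, cids, seed=seed)
        return PseudotimeResults(self, table, graph, comps, evals, pt,
                                 communities, start)


class PseudotimeResults:
    """Fitted pseudotime ordering with its graph, components and states."""

    def __init__(self, model: PseudotimeModel, table: FeatureTable,
                 graph: sp.csr_matrix, components: pd.DataFrame,
                 eigenvalues: np.ndarray, pseudotime: pd.Series,
                 communities: pd.Series, start_cell):
        self.model = model
        self.table = table
        self.graph_ = graph
        self.components_ = components
        self.eigenvalues_ = eigenvalues
        self.pseudotime_ = pseudotime
        self.communities_ = communities
        self.start_cell_ = start_cell

    @property
    def embedding_(self) -> pd.DataFrame:
        """2-D embedding for neighbor statistics and plots.

        The first two diffusion components with each axis standardized to
        unit scale, as 2-D layout embeddings conventionally provide; this
        keeps neighborhoods two-dimensional rather than collapsing onto the
        dominant component.
        """
        emb = self.components_.iloc[:, :2].copy()
        emb = (emb - emb.mean()) / emb.std()
        emb.columns = ["dim1", "dim2"]
        return emb

    def stage_concordance(self, expert_stage: pd.Series | None = None,
                          ) -> tuple[float, pd.DataFrame]:
        if expert_stage is None:
            meta = self.model.raw_table.metadata
            if "expert_stage" not in meta.columns:
                raise ValueError("no expert_stage metadata on the table")
            expert_stage = meta["expert_stage"]
        return stage_concordance(self.pseudotime_, expert_stage)

    def feature_trends(self, features: Sequence[str], n_bins: int = 5,
                       groups: pd.Series | None = None, ci: float = 0.95,
                       reps: int = 1000, seed: int | None = None) -> pd.DataFrame:
        if groups is None:
            meta = self.model.raw_table.metadata
            if "fate_label" in meta.columns:
                groups = meta["fate_label"]
        return feature_trends(self.model.raw_table, self.pseudotime_, features,
                              n_bins=n_bins, groups=groups, ci=ci, reps=reps,
                              seed=seed)

    def cosort(self, fate: pd.Series | None = None, k: int = 5,
               bin_width: float = 0.2):
        """Build the fate co-sorting model on this embedding (see cosorting)."""
        from .cosorting import FateCosorting

        if fate is None:
            meta = self.model.raw_table.metadata
            if "fate_label" not in meta.columns:
                raise ValueError("no fate_label metadata on the table")
            fate = meta["fate_label"]
        return FateCosorting(self.embedding_, fate, self.pseudotime_, k=k,
                             bin_width=bin_width)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "pseudotime": self.pseudotime_,
            "community": self.communities_,
        })
        return pd.concat([out, self.components_], axis=1)

    def summary(self) -> str:
        pt = self.pseudotime_.dropna()
        lines = [
            "Diffusion pseudotime",
            "=" * 40,
            f"cells:             {len(self.pseudotime_)} "
            f"({len(pt)} on the main component)",
            f"knn / components:  {self.model.knn} / {self.model.n_components}",
            f"start cell:        {self.start_cell_}",
            f"eigenvalues:       {np.array2string(self.eigenvalues_, precision=3)}",
            f"communities:       {self.communities_.nunique()}",
            f"pseudotime range:  [{pt.min():.3f}, {pt.max():.3f}]",
        ]
        return "\n".join(lines)

    def plot_embedding(self, color: pd.Series | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        emb = self.embedding_
        c = self.pseudotime_ if color is None else color
        if c.dtype == object:
            for val in sorted(c.dropna().unique()):
                m = c == val
                ax.scatter(emb.loc[m, "dim1"], emb.loc[m, "dim2"], s=12, label=str(val))
            ax.legend(frameon=False)
        else:
            sc = ax.scatter(emb["dim1"], emb["dim2"], c=c, s=12, cmap="viridis")
            plt.colorbar(sc, ax=ax, label=c.name or "value")
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        return ax
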