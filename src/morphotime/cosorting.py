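"""Nearest-neighbor fate co-sorting along a pseudotime axis.

If two birthdate cohorts (early-born basket-fated vs late-born
stellate-fated cells) have already diverged morphologically at a given
maturation stage, a cell's nearest neighbors in the feature embedding
should share its fate more often than the cohort frequencies alone
predict.  The statistic: bin the unit pseudo-timeline into 0.2-wide
intervals; for every cell, take the fraction of its 5 nearest embedding
neighbors with the same fate; per (fate, bin), compare the mean fraction
against the bin's fate-frequency null with a one-sided one-sample t-test
and a percentile bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import ttest_1samp

__all__ = [
    "bin_pseudotime",
    "knn_same_fate_fraction",
    "per_bin_null",
    "cosort_test",
    "CosortResult",
    "FateCosorting",
    "CosortResults",
]


def bin_pseudotime(pseudotime: pd.Series, width: float = 0.2) -> pd.Series:
    """Half-open bins [0, w), [w, 2w), ... with the last bin closed at 1.0."""
    pt = pseudotime.astype(float)
    if ((pt < 0) | (pt > 1)).any():
        bad = pt[(pt < 0) | (pt > 1)].index[0]
        raise ValueError(f"pseudotime outside [0, 1] for cell {bad!r}")
    if not (0 < width <= 1):
        raise ValueError("bin width must be in (0, 1]")
    n_bins = int(np.ceil(round(1.0 / width, 9)))
    idx = np.floor(pt.to_numpy() / width).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # 1.0 falls in the last (closed) bin
    return pd.Series(idx, index=pt.index, name="bin")


def knn_same_fate_fraction(coords: pd.DataFrame | np.ndarray, fate: pd.Series,
                           k: int = 5) -> pd.Series:
    """Per-cell fraction of its k nearest neighbors sharing its fate label.

    Euclidean distances, self excluded; exact ties at the k-th distance are
    broken deterministically by cell order (logged).
    """
    if isinstance(coords, pd.DataFrame):
        X = coords.to_numpy()
        index = coords.index
    else:
        X = np.asarray(coords, dtype=float)
        index = fate.index
    n = len(X)
    if n <= k:
        raise ValueError(f"need more than k={k} cells (got {n})")
    labels = fate.loc[index].to_numpy()
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    # stable tie-break on the column index
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
    neigh = order[:, :k]
    ties = 0
    kth = np.take_along_axis(D, order[:, k - 1:k], axis=1)
    nxt = np.take_along_axis(D, order[:, k:k + 1], axis=1)
    ties = int(np.sum(kth == nxt))
    if ties:
        warnings.warn(f"{ties} cells had distance ties at the k-th neighbor; "
                      "broken by cell order")
    same = labels[neigh] == labels[:, None]
    return pd.Series(same.mean(axis=1), index=index, name="same_fate_fraction")


def per_bin_null(fate: pd.Series, bin_index: pd.Series, target_fate) -> pd.Series:
    """Per-bin chance level: count of the target fate over the bin size.

    Empty bins are omitted.
    """
    df = pd.DataFrame({"fate": fate, "bin": bin_index}).dropna()
    out = df.groupby("bin")["fate"].agg(lambda s: float((s == target_fate).mean()))
    out.name = f"null_{target_fate}"
    return out


@dataclass
class CosortResult:
    """Per (fate, bin) co-sorting statistics."""

    table: pd.DataFrame  # columns: fate, bin, n_cells, mean_fraction, ci_lo,
    #          ci_hi, null, t, p
    k: int
    bin_width: float
    bootstrap_reps: int
    seed: int | None

    def for_fate(self, fate) -> pd.DataFrame:
        return self.table[self.table["fate"] == fate].set_index("bin")


def cosort_test(fractions: pd.Series, fate: pd.Series, bin_index: pd.Series,
                nulls=None, reps: int = 1000, seed: int | None = None,
                alternative: str = "greater", k: int = 5,
                bin_width: float = 0.2, holm: bool = False) -> CosortResult:
    """Bootstrap CIs and per-bin t-tests of same-fate fractions vs the null.

    For each fate and pseudotime bin: the mean per-cell same-fate fraction,
    a percentile bootstrap CI over cells (``reps=0`` suppresses CIs), and a
    one-sample t-test of the per-cell fractions against the bin's
    fate-frequency null (one-sided 'greater' by default).  ``nulls`` may
    supply explicit per-bin null fractions (a flat {bin: null} mapping, or
    {fate: {bin: null}}); by default they are computed from the fate/bin
    composition.  Bins with fewer than 2 cells of a fate are reported with
    the CI and test suppressed.  An optional Holm adjustment across bins is
    off by default.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"frac": fractions, "fate": fate, "bin": bin_index}).dropna()
    rows = []
    for f in sorted(df["fate"].unique()):
        if nulls is None:
            fate_nulls = per_bin_null(df["fate"], df["bin"], f)
        elif f in nulls:
            fate_nulls = nulls[f]
        else:
            fate_nulls = nulls
        sub = df[df["fate"] == f]
        for b in sorted(df["bin"].unique()):
            vals = sub.loc[sub["bin"] == b, "frac"].to_numpy()
            null = float(fate_nulls.get(b, np.nan))
            row = {
                "fate": f, "bin": int(b), "n_cells": len(vals),
                "mean_fraction": float(vals.mean()) if len(vals) else np.nan,
                "null": null, "ci_lo": np.nan, "ci_hi": np.nan,
                "t": np.nan, "p": np.nan,
            }
            if len(vals) >= 2:
                if reps > 0:
                    boot = rng.choice(vals, size=(reps, len(vals))).mean(axis=1)
                    row["ci_lo"], row["ci_hi"] = (
                        float(v) for v in np.quantile(boot, [0.025, 0.975]))
                if np.isfinite(null):
                    if np.allclose(vals, vals[0]):
                        # zero-variance sample: the t statistic degenerates to
                        # a sign comparison with the null
                        diff = float(vals.mean() - null)
                        if diff == 0:
                            row["t"], row["p"] = np.nan, np.nan
                        else:
                            row["t"] = np.inf * np.sign(diff)
                            if alternative == "greater":
                                row["p"] = 0.0 if diff > 0 else 1.0
                            elif alternative == "less":
                                row["p"] = 0.0 if diff < 0 else 1.0
                            else:
                                row["p"] = 0.0
                    else:
                        res = ttest_1samp(vals, null, alternative=alternative)
                        row["t"], row["p"] = float(res.statistic), float(res.pvalue)
            rows.append(row)
    table = pd.DataFrame(rows)
    if holm:
        table["p_holm"] = _holm(table["p"].to_numpy())
    return CosortResult(table=table, k=k, bin_width=bin_width,
                        bootstrap_reps=reps, seed=seed)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    mask = np.isfinite(p)
    m = int(mask.sum())
    adj = np.full_like(p, np.nan)
    if m == 0:
        return adj
    order = np.argsort(p[mask])
    sorted_p = p[mask][order]
    stepped = np.maximum.accumulate((m - np.arange(m)) * sorted_p)
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    adj[mask] = out
    return adj


# ---------------------------------------------------------------------------
# Model / Results


class FateCosorting:
    """Fate co-sorting model over an embedding and a pseudotime axis.

    Parameters
    ----------
    coords : DataFrame (cells x 2+)
        Embedding coordinates (the pseudotime embedding by default upstream).
    fate : Series
        Per-cell fate cohort labels.
    pseudotime : Series
        Per-cell pseudotime in [0, 1].
    k : int
        Neighbors per cell (default 5).
    bin_width : float
        Pseudotime bin width (default 0.2).
    """

    def __init__(self, coords: pd.DataFrame, fate: pd.Series,
                 pseudotime: pd.Series, k: int = 5, bin_width: float = 0.2):
        common = coords.index.intersection(fate.index).intersection(pseudotime.index)
        mask = pseudotime.loc[common].notna() & fate.loc[common].notna() \
            & coords.loc[common].notna().all(axis=1)
        self.coords = coords.loc[common[mask]]
        self.fate = fate.loc[self.coords.index]
        self.pseudotime = pseudotime.loc[self.coords.index]
        self.k = k
        self.bin_width = bin_width

    def fit(self, reps: int = 1000, seed: int | None = None,
            alternative: str = "greater", holm: bool = False) -> "CosortResults":
        fractions = knn_same_fate_fraction(self.coords, self.fate, k=self.k)
        bins = bin_pseudotime(self.pseudotime, width=self.bin_width)
        result = cosort_test(fractions, self.fate, bins, reps=reps, seed=seed,
                             alternative=alternative, k=self.k,
                             bin_width=self.bin_width)
        if holm:
            result.table["p_holm"] = _holm(result.table["p"].to_numpy())
        return CosortResults(self, fractions, bins, result)


class CosortResults:
    """Fitted co-sorting statistics with per-cell fractions and bins."""

    def __init__(self, model: FateCosorting, fractions: pd.Series,
                 bins: pd.Series, result: CosortResult):
        self.model = model
        self.fractions_ = fractions
        self.bins_ = bins
        self.result = result
        self.table = result.table

    def earliest_bin(self) -> pd.DataFrame:
        b0 = int(self.table["bin"].min())
        return self.table[self.table["bin"] == b0]

    def summary(self) -> str:
        lines = [
            "Fate co-sorting (k nearest neighbors per pseudotime bin)",
            "=" * 60,
            f"cells: {len(self.fractions_)}   k: {self.model.k}   "
            f"bin width: {self.model.bin_width}   "
            f"bootstrap reps: {self.result.bootstrap_reps}",
            "",
            f"{'fate':<12}{'bin':>4}{'n':>6}{'mean':>8}{'null':>8}"
            f"{'CI':>18}{'p':>10}",
        ]
        for _, r in self.table.iterrows():
            ci = (f"[{r.ci_lo:.3f}, {r.ci_hi:.3f}]"
                  if np.isfinite(r.ci_lo) else "--")
            p = f"{r.p:.2g}" if np.isfinite(r.p) else "--"
            mean = f"{r.mean_fraction:.3f}" if np.isfinite(r.mean_fraction) else "--"
            lines.append(
                f"{str(r.fate):<12}{int(r.bin):>4}{int(r.n_cells):>6}"
                f"{mean:>8}{r.null:>8.3f}{ci:>18}{p:>10}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f in sorted(self.table["fate"].unique()):
            sub = self.table[self.table["fate"] == f]
            mid = (sub["bin"] + 0.5) * self.model.bin_width
            ax.plot(mid, sub["mean_fraction"], marker="o", label=str(f))
            ax.fill_between(mid, sub["ci_lo"], sub["ci_hi"], alpha=0.2)
            ax.plot(mid, sub["null"], ls="--", color="gray")
        ax.set_xlabel("pseudotime")
        ax.set_ylabel("same-fate neighbor fraction")
        ax.legend(frameon=False)
        return ax
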