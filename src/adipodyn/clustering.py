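"""Slope-space k-means clustering and congruence classification.

Each gene contributes one observation per condition: the vector of
finite-difference slopes of its condition-mean trajectory (central
differences at interior days, one-sided at the endpoints).  Both
conditions' slope vectors are pooled into a single k-means model (k = 8
by default), so "same cluster in both conditions" is well defined.  A
gene whose two condition profiles land in the same cluster has congruent
dynamics (same shape, possibly different level); different clusters mean
divergent dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import MeanCurves
from .patterns import auto_epsilon, label_pattern

__all__ = [
    "slope_vectors",
    "SlopeKMeans",
    "SlopeClusterResults",
    "congruence_classification",
    "bss_tss_profile",
    "label_pattern",
]


def slope_vectors(curves: MeanCurves) -> pd.DataFrame:
    """Per-(gene, condition) slope vectors of the condition-mean profiles.

    Interior days use the central difference
    (x[i+1] - x[i-1]) / (day[i+1] - day[i-1]); the endpoints use one-sided
    differences, giving one slope per day (log2 units per day).

    Returns a DataFrame indexed by (gene, condition) with one column per
    day.
    """
    days = curves.days
    if len(days) < 3:
        raise ValueError("slope vectors need at least 3 days")
    if len(np.unique(days)) != len(days):
        raise ValueError("duplicate days in the grid")
    frames = []
    for cond in curves.conditions:
        mat = curves.curves[cond].to_numpy(dtype=float)
        slopes = np.gradient(mat, days, axis=1)
        idx = pd.MultiIndex.from_product(
            [curves.curves[cond].index, [cond]], names=["gene", "condition"]
        )
        frames.append(pd.DataFrame(slopes, index=idx, columns=days))
    return pd.concat(frames)


class SlopeKMeans:
    """K-means over pooled per-condition slope vectors.

    Lloyd's algorithm with k-means++ initialization, best of
    ``n_restarts`` by within-cluster sum of squares, deterministic under
    ``seed``.
    """

    def __init__(self, profiles: pd.DataFrame, k: int = 8, n_restarts: int = 25):
        if len(profiles) < k:
            raise ValueError("need at least k observations")
        self.profiles = profiles
        self.k = k
        self.n_restarts = n_restarts

    def fit(self, seed: int = 0) -> "SlopeClusterResults":
        x = self.profiles.to_numpy(dtype=float)
        tss = float(((x - x.mean(axis=0)) ** 2).sum())
        if tss == 0:
            raise ValueError(
                "all slope observations are identical: total sum of squares "
                "is zero, BSS/TSS undefined"
            )
        km = KMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=seed,
            algorithm="lloyd",
        ).fit(x)
        labels = pd.Series(km.labels_ + 1, index=self.profiles.index, name="cluster")
        centroids = pd.DataFrame(
            km.cluster_centers_,
            index=pd.RangeIndex(1, self.k + 1, name="cluster"),
            columns=self.profiles.columns,
        )
        bss_tss = 1.0 - float(km.inertia_) / tss
        return SlopeClusterResults(
            model=self,
            centroids=centroids,
            assignments=labels,
            inertia=float(km.inertia_),
            bss_tss=bss_tss,
            seed=seed,
        )


@dataclass
class SlopeClusterResults:
    """Fitted slope clusters: centroids, assignments and diagnostics."""

    model: SlopeKMeans
    centroids: pd.DataFrame
    assignments: pd.Series
    inertia: float
    bss_tss: float
    seed: int

    def pattern_labels(self, epsilon: float | None = None) -> dict[int, str]:
        """Schematic rise/constant/fall pattern of each centroid."""
        if epsilon is None:
            epsilon = auto_epsilon(self.model.profiles.to_numpy())
        return {
            int(c): label_pattern(self.centroids.loc[c].to_numpy(), epsilon)
            for c in self.centroids.index
        }

    def congruence(
        self, conditions: tuple[str, str] | None = None, epsilon: float | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        return congruence_classification(self, conditions=conditions, epsilon=epsilon)

    def summary(self) -> str:
        patterns = self.pattern_labels()
        lines = [
            "Slope-vector k-means",
            "====================",
            f"k = {self.model.k}, restarts = {self.model.n_restarts}, "
            f"seed = {self.seed}",
            f"observations = {len(self.assignments)}",
            f"BSS/TSS = {self.bss_tss:.3f}",
            "",
            "cluster  n  pattern",
        ]
        counts = self.assignments.value_counts().sort_index()
        for c in self.centroids.index:
            lines.append(f"{c:>7}  {counts.get(c, 0):>2}  {patterns[int(c)]}")
        return "\n".join(lines)

    def plot_centroids(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in self.centroids.index:
            ax.plot(self.centroids.columns, self.centroids.loc[c], label=f"cluster {c}")
        ax.set_xlabel("day")
        ax.set_ylabel("slope (log2/day)")
        ax.legend(fontsize="small")
        return ax


def congruence_classification(
    results: SlopeClusterResults,
    conditions: tuple[str, str] | None = None,
    epsilon: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each gene's cluster combination as congruent or divergent.

    Returns ``(records, combination_counts)``.  ``records`` has one row
    per gene: cluster and pattern per condition, ``congruent`` (equal
    cluster ids) and ``constant_one_side`` (exactly one condition in an
    all-constant-pattern cluster — a gene responding to the stimulus in
    one depot only).  ``combination_counts`` tallies genes per
    (cluster_a, cluster_b) combination.
    """
    labels = results.assignments
    conds = tuple(labels.index.get_level_values("condition").unique())
    if conditions is None:
        conditions = conds  # order as observed
    if len(conditions) != 2:
        raise ValueError("congruence needs exactly two conditions")
    wide = labels.unstack("condition")
    if wide[list(conditions)].isna().any().any():
        bad = wide.index[wide[list(conditions)].isna().any(axis=1)]
        raise ValueError(f"genes missing a condition assignment: {list(bad)[:5]}")
    a, b = conditions
    patterns = results.pattern_labels(epsilon)
    constant_clusters = {c for c, p in patterns.items() if p == "constant"}
    records = pd.DataFrame(
        {
            f"cluster_{a}": wide[a].astype(int),
            f"cluster_{b}": wide[b].astype(int),
        }
    )
    records["congruent"] = records[f"cluster_{a}"] == records[f"cluster_{b}"]
    records[f"pattern_{a}"] = records[f"cluster_{a}"].map(lambda c: patterns[int(c)])
    records[f"pattern_{b}"] = records[f"cluster_{b}"].map(lambda c: patterns[int(c)])
    records["constant_one_side"] = (
        records[f"cluster_{a}"].isin(constant_clusters)
        ^ records[f"cluster_{b}"].isin(constant_clusters)
    )
    counts = (
        records.groupby([f"cluster_{a}", f"cluster_{b}"])
        .size()
        .rename("n_genes")
        .reset_index()
    )
    counts["congruent"] = counts[f"cluster_{a}"] == counts[f"cluster_{b}"]
    counts = counts.sort_values("n_genes", ascending=False).reset_index(drop=True)
    return records, counts


def bss_tss_profile(
    profiles: pd.DataFrame,
    ks=range(2, 13),
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.Series:
    """BSS/TSS across candidate k — the elbow diagnostic behind k = 8."""
    out = {}
    for k in ks:
        if k > len(profiles):
            break
        out[k] = SlopeKMeans(profiles, k=k, n_restarts=n_restarts).fit(seed).bss_tss
    return pd.Series(out, name="bss_tss").rename_axis("k")
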