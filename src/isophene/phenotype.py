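"""Turning cluster solutions into isotope-phenotype deliverables.

A raw partition's cluster indices are arbitrary; phenotypes are made
comparable across solutions (and against the published characterisation) by
matching cluster centers one-to-one to named archetype centers (``a``–``e``)
with the Hungarian algorithm.  On top of canonical labels this module
builds per-phenotype summary tables, FISH cross-tabulations, ratio-subset
consistency comparisons and spatial projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import presets as _p
from .cluster import ClusterSolution, FeatureMatrix, build_features, cluster_means, fuzzy_cmeans, kmeans, pam, hclust
from .isotope import KEY_COLUMNS


@dataclass
class ArchetypeSet:
    """Named reference centers in ratio space (raw units)."""

    names: list[str]
    centers: pd.DataFrame      # index = names, columns = ratio columns

    def restrict(self, columns: list[str]) -> "ArchetypeSet":
        return ArchetypeSet(self.names, self.centers[list(columns)])


def day7_archetypes() -> ArchetypeSet:
    """Default archetypes: the day-7 per-phenotype mean ratios."""
    block = _p.PRESET_BLOCKS["day7"]
    centers = pd.DataFrame(
        {name: block[name][1] for name in _p.CLUSTER_NAMES}).T
    centers = centers[list(_p.CLUSTERING_RATIOS)]
    return ArchetypeSet(list(_p.CLUSTER_NAMES), centers)


def archetypes_for(preset: str) -> ArchetypeSet:
    key = _p.PRESET_ALIASES[preset]
    block = _p.PRESET_BLOCKS[key]
    names = [n for n in _p.CLUSTER_NAMES if block[n][0] > 0]
    centers = pd.DataFrame({name: block[name][1] for name in names}).T
    return ArchetypeSet(names, centers[list(_p.CLUSTERING_RATIOS)])


def canonicalize_labels(solution: ClusterSolution, archetypes: ArchetypeSet,
                        features: FeatureMatrix) -> dict[int, str]:
    """Bijective mapping cluster index -> archetype name.

    Solution centers (cluster means for non-center methods) are matched to
    the archetype centers — mapped into the feature space's scaling — by
    minimising the total Euclidean distance over all one-to-one assignments.
    """
    if solution.k != len(archetypes.names):
        raise ValueError(f"solution k={solution.k} != {len(archetypes.names)} archetypes")
    centers = solution.centers
    if centers is None:
        centers = cluster_means(features.data, solution.labels, solution.k)
    arch = archetypes.centers[features.columns].to_numpy(dtype=float)
    arch_scaled = features.to_scaled(arch)
    cost = np.sqrt(((centers[:, None, :] - arch_scaled[None]) ** 2).sum(axis=2))
    rows, cols = linear_sum_assignment(cost)
    return {int(r) + 1: archetypes.names[c] for r, c in zip(rows, cols)}


def apply_canonical(solution: ClusterSolution, mapping: dict[int, str],
                    index: pd.Index) -> pd.Series:
    """Per-ROI canonical phenotype labels as a Series aligned to the ROIs."""
    return pd.Series([mapping[int(l)] for l in solution.labels],
                     index=index, name="cluster")


def summarize_clusters(ratios: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-phenotype n / mean / sd for each ratio column, plus an All column.

    Standard deviations use the sample convention (n−1); singleton clusters
    report sd 0.
    """
    ratio_cols = [c for c in ratios.columns if c.startswith("r")]
    labels = labels.reindex(ratios.index)
    groups = {"All": ratios[ratio_cols]}
    for name in sorted(labels.dropna().unique()):
        groups[name] = ratios.loc[labels == name, ratio_cols]
    rows = {}
    rows[("n", "")] = {g: len(df) for g, df in groups.items()}
    for col in ratio_cols:
        rows[(col, "mean")] = {g: df[col].mean() for g, df in groups.items()}
        rows[(col, "sd")] = {g: (df[col].std(ddof=1) if len(df) > 1 else 0.0)
                             for g, df in groups.items()}
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["ratio", "stat"])
    return out


def crosstab_fish(labels: pd.Series, fish: pd.DataFrame) -> pd.DataFrame:
    """Taxon × phenotype contingency counts.

    FISH rows are joined on (session, region, roi_id); ROIs without a FISH
    record count as taxon ``unknown``.  Column percentages are available via
    :func:`crosstab_percentages`.
    """
    f = fish.set_index(KEY_COLUMNS) if not isinstance(fish.index, pd.MultiIndex) else fish
    taxon = f["taxon"].reindex(labels.index).fillna("unknown")
    ct = pd.crosstab(taxon, labels)
    ct.index.name = "taxon"
    return ct


def crosstab_percentages(crosstab: pd.DataFrame) -> pd.DataFrame:
    """Per-phenotype taxon composition (%) from a contingency table."""
    return 100.0 * crosstab / crosstab.sum(axis=0)


#: The default ratio-subset menu used in the 1/2/3-label comparison.
DEFAULT_SUBSETS: dict[str, list[str]] = {
    "13C": ["r13C"],
    "15N": ["r15N"],
    "33S": ["r33S"],
    "13C+15N+C/CN": ["r13C", "r15N", "rC_CN"],
    "13C+33S+C/S": ["r13C", "r33S", "rC_CN", "rS_CN"],
    "15N+33S+S/CN": ["r15N", "r33S", "rS_CN"],
    "all5": ["r13C", "r15N", "r33S", "rC_CN", "rS_CN"],
}


@dataclass
class SubsetComparison:
    labels: pd.DataFrame           # ROI × subset canonical labels
    consistent: pd.Series          # bool per ROI
    consistent_count: int
    consistent_fraction: float


def _fit(method, X, k, seed, restarts):
    if method == "fuzzy_cmeans":
        return fuzzy_cmeans(X, k, seed=seed, restarts=restarts)
    if method == "kmeans":
        return kmeans(X, k, seed=seed, restarts=restarts)
    if method == "pam":
        return pam(X, k, seed=seed)
    return hclust(X, method, k)


def compare_ratio_subsets(ratios: pd.DataFrame,
                          subsets: dict[str, list[str]] | None = None,
                          method: str = "fuzzy_cmeans", k: int = 5,
                          seed: int = 0, restarts: int = 20,
                          archetypes: ArchetypeSet | None = None) -> SubsetComparison:
    """Cluster each ratio subset independently and count label-consistent ROIs.

    Every subset is clustered with the same method/k/seed, canonicalized
    against the archetypes restricted to the subset's columns, and an ROI is
    *consistent* when its canonical phenotype is identical across all
    subsets.
    """
    if subsets is None:
        subsets = DEFAULT_SUBSETS
    if archetypes is None:
        archetypes = day7_archetypes()
    cols = {}
    for name, columns in subsets.items():
        if not columns:
            raise ValueError(f"subset {name!r} is empty")
        feats = build_features(ratios, columns, scaling="zscore")
        if len(np.unique(feats.data, axis=0)) < k:
            raise ValueError(f"subset {name!r} has fewer than k distinct rows")
        sol = _fit(method, feats.data, k, seed, restarts)
        mapping = canonicalize_labels(sol, archetypes.restrict(feats.columns), feats)
        cols[name] = apply_canonical(sol, mapping, ratios.index)
    labels = pd.DataFrame(cols)
    consistent = labels.nunique(axis=1) == 1
    return SubsetComparison(labels, consistent, int(consistent.sum()),
                            float(consistent.mean()))


PHENOTYPE_PALETTE = {"a": "#1b9e77", "b": "#d95f02", "c": "#7570b3",
                     "d": "#e7298a", "e": "#66a61e"}
TAXON_PALETTE = {"gamma": "#33a02c", "delta": "#6a3d9a", "unknown": "#b0b0b0"}


def export_spatial_map(coords: pd.DataFrame, labels: pd.Series,
                       fish: pd.DataFrame | None = None, path=None):
    """Spatial (x, y) projection of phenotypes, optionally beside FISH taxa.

    ``coords`` needs ``centroid_x``/``centroid_y`` indexed like ``labels``.
    Returns (figure, tidy DataFrame); when ``path`` is given, writes
    ``<path>.png`` and ``<path>.tsv``.  ROIs without coordinates are
    omitted with a warning.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = coords[["centroid_x", "centroid_y"]].join(labels.rename("cluster"), how="inner")
    if fish is not None:
        f = fish.set_index(KEY_COLUMNS) if not isinstance(fish.index, pd.MultiIndex) else fish
        df["taxon"] = f["taxon"].reindex(df.index).fillna("unknown")
    n_panels = 2 if fish is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 5), squeeze=False)
    ax = axes[0, 0]
    for name, sub in df.groupby("cluster"):
        ax.scatter(sub["centroid_x"], sub["centroid_y"], s=12,
                   color=PHENOTYPE_PALETTE.get(name, "#333333"), label=str(name))
    ax.set_title("isotope phenotypes")
    ax.invert_yaxis()
    ax.legend(markerscale=1.5, fontsize=8)
    if fish is not None:
        ax2 = axes[0, 1]
        for name, sub in df.groupby("taxon"):
            ax2.scatter(sub["centroid_x"], sub["centroid_y"], s=12,
                        color=TAXON_PALETTE.get(name, "#333333"), label=str(name))
        ax2.set_title("FISH taxa")
        ax2.invert_yaxis()
        ax2.legend(markerscale=1.5, fontsize=8)
    for a in axes.ravel():
        a.set_xlabel("x (px)")
        a.set_ylabel("y (px)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(f"{path}.png", dpi=150)
        df.reset_index().to_csv(f"{path}.tsv", sep="\t", index=False)
    return fig, df
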