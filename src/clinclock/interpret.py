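"""Phenotype interpretation in PC space: k-means clustering, cluster-specific
aging rates, top-weighted PC features, and thresholded partial-correlation
networks of clinical parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .cohort import CohortTable
from .pca import PCModel


class InterpretError(ValueError):
    pass


@dataclass
class ClusterModel:
    """k-means partition of subjects in a selected-PC subspace."""

    pc_subset: list[int]           # 1-based PC indices used
    k: int
    centroids: np.ndarray          # k x len(pc_subset)
    assignments: pd.Series         # subject -> 1..k
    wcss: float
    seed: int
    n_restarts: int


def kmeans_clusters(
    pc_scores: pd.DataFrame,
    pc_subset: Sequence[int],
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterModel:
    """Best-of-``n_restarts`` k-means (k-means++ inits, Euclidean distance) on
    the named PC columns; deterministic given the seed."""
    if k < 2:
        raise InterpretError("k must be at least 2")
    if k > len(pc_scores):
        raise InterpretError("k cannot exceed the number of subjects")
    cols = [f"PC{i}" for i in pc_subset]
    missing = [c for c in cols if c not in pc_scores.columns]
    if missing:
        raise InterpretError(f"PC scores lack columns {missing}")
    X = pc_scores[cols].to_numpy(float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels = km.fit_predict(X)
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        raise InterpretError("k-means produced an empty cluster; "
                             "reduce k or increase restarts")
    return ClusterModel(
        pc_subset=list(pc_subset), k=k, centroids=km.cluster_centers_,
        assignments=pd.Series(labels + 1, index=pc_scores.index, name="cluster"),
        wcss=float(km.inertia_), seed=seed, n_restarts=n_restarts)


def cluster_aging_rate(
    cluster: ClusterModel,
    chron_age: pd.Series,
    biological_age: pd.Series,
) -> pd.DataFrame:
    """Per-cluster OLS slope of BA on CA (years of BA per calendar year),
    with R^2 and the two-sided slope p-value."""
    rows = []
    for c in range(1, cluster.k + 1):
        ids = cluster.assignments.index[cluster.assignments == c]
        ca = chron_age.loc[ids].to_numpy(float)
        ba = biological_age.loc[ids].to_numpy(float)
        if len(ids) < 10:
            import warnings
            warnings.warn(f"cluster {c} has only {len(ids)} subjects; "
                          "slope estimate unstable", UserWarning)
        if np.ptp(ca) == 0:
            raise InterpretError(f"constant chronological age in cluster {c}")
        fit = stats.linregress(ca, ba)
        rows.append({"cluster": c, "n": len(ids), "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.rvalue**2,
                     "p_value": fit.pvalue})
    return pd.DataFrame(rows).set_index("cluster")


def pc_top_features(
    pc_model: PCModel,
    pc_index: int,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Top ceil(fraction * n_features) features of a PC by |loading|, with
    signed weights.  Ties at the cutoff break lexicographically by name."""
    if not 1 <= pc_index <= pc_model.V.shape[1]:
        raise InterpretError(f"PC index {pc_index} out of range")
    if not 0 < top_fraction <= 1:
        raise InterpretError("top_fraction must lie in (0, 1]")
    loadings = pd.Series(pc_model.V[:, pc_index - 1],
                         index=pc_model.feature_names, name="weight")
    n_top = math.ceil(top_fraction * len(loadings))
    frame = loadings.to_frame()
    frame["abs_weight"] = frame["weight"].abs()
    frame = frame.sort_values(["abs_weight", "weight"],
                              ascending=[False, True])
    # lexicographic tie-break at equal |weight|
    frame = frame.reset_index(names="feature") \
        .sort_values(["abs_weight", "feature"], ascending=[False, True],
                     kind="stable")
    out = frame.head(n_top)[["feature", "weight", "abs_weight"]]
    return out.reset_index(drop=True)


@dataclass
class PartialCorrNetwork:
    """Thresholded Gaussian partial-correlation network over clinical features."""

    nodes: list[str]
    partial_corr: pd.DataFrame     # full symmetric matrix before thresholding
    threshold: float
    graph: nx.Graph

    def edge_list(self) -> pd.DataFrame:
        rows = [{"feature_a": a, "feature_b": b,
                 "partial_r": d["weight"], "sign": int(np.sign(d["weight"]))}
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["feature_a", "feature_b",
                                           "partial_r", "sign"])

    def write_edges_tsv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def partial_correlation_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise partial correlations conditioning on all other columns,
    via the scaled inverse covariance: rho_ij = -Omega_ij/sqrt(Omega_ii*Omega_jj)."""
    cov = np.cov(X.to_numpy(float), rowvar=False)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise InterpretError("singular covariance matrix; prune collinear "
                             "features before building the network")
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pd.DataFrame(pc, index=X.columns, columns=X.columns)


def partial_correlation_network(
    cohort: CohortTable,
    node_features: Sequence[str],
    threshold: float = 0.1,
) -> PartialCorrNetwork:
    """Partial-correlation network over the named features; edges whose
    |partial correlation| falls below the hard threshold are removed, signs
    are retained as edge attributes."""
    nodes = list(node_features)
    missing = [f for f in nodes if f not in cohort.X.columns]
    if missing:
        raise InterpretError(f"cohort lacks node feature(s) {missing}")
    if cohort.n_subjects <= len(nodes) + 2:
        raise InterpretError("need more subjects than node features + 2 for "
                             "well-defined partial correlations")
    pc = partial_correlation_matrix(cohort.X[nodes])
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            r = float(pc.loc[a, b])
            if abs(r) >= threshold:
                g.add_edge(a, b, weight=r, sign=int(np.sign(r)))
    return PartialCorrNetwork(nodes=nodes, partial_corr=pc,
                              threshold=threshold, graph=g)
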