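"""Relative-expression scaling, Ward-D2 linkage and k-means ROI classes.

The heatmap input is the per-probe z-score of log2 expression across ROIs
("relative expression"). ROIs are ordered by Ward's minimum-variance
agglomeration in its squared-distance (D2) formulation and then grouped
into k classes by k-means (k defaults to 3: in practice a normal-tissue
dominated class, a low-expression tumour/TME class, and a heterogeneous
class tend to emerge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .normalize import NormalizedMatrix, log2_transform

logger = logging.getLogger("dspforge")


class ClusterError(ValueError):
    pass


def relative_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Per-probe z-score across ROIs (sample sd); constant probes dropped."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    constant = (sd == 0) | ~np.isfinite(sd)
    if constant.any():
        logger.warning("dropping constant probe(s) from relative expression: %s",
                       list(values.columns[constant]))
    keep = values.columns[~constant]
    arr = arr[:, ~constant]
    z = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=1)
    return pd.DataFrame(z, index=values.index, columns=keep)


def ward_d2(scaled: pd.DataFrame, on: str = "rois") -> np.ndarray:
    """Ward minimum-variance linkage on Euclidean distances (D2 form).

    Heights are on the distance scale (square root of the merge criterion)
    and are nondecreasing. Returns a scipy-format linkage matrix.
    """
    if on not in ("rois", "probes"):
        raise ClusterError("on must be 'rois' or 'probes'")
    X = scaled.to_numpy(dtype=float)
    if on == "probes":
        X = X.T
    if X.shape[0] < 2:
        raise ClusterError("ward_d2 requires >=2 items")
    if not np.isfinite(X).all():
        raise ClusterError("ward_d2 requires finite values")
    return hierarchy.linkage(X, method="ward")


def dendrogram_order(linkage: np.ndarray) -> list[int]:
    return hierarchy.leaves_list(linkage).tolist()


def kmeans_classes(scaled: pd.DataFrame, k: int = 3, seed: int = 0,
                   restarts: int = 10) -> pd.Series:
    """Best-of-``restarts`` Lloyd k-means with k-means++ seeding.

    Labels are 1..k, deterministic given the seed.
    """
    X = scaled.to_numpy(dtype=float)
    if k < 2:
        raise ClusterError("k must be >= 2")
    if k > X.shape[0]:
        raise ClusterError(f"k={k} exceeds the number of items ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(X) + 1
    return pd.Series(labels, index=scaled.index, name="kmeans_class")


@dataclass
class ClusterResult:
    linkage: np.ndarray = field(repr=False)
    order: list[int] = field(repr=False)
    labels: pd.Series = field(repr=False)
    scaled: pd.DataFrame = field(repr=False)
    k: int = 3
    seed: int = 0
    scaling: str = "zscore"


class ExpressionClustering(BaseEstimator):
    """Ward-D2 ordering plus k-means class assignment of ROIs.

    Parameters
    ----------
    k : int, default 3
        Number of k-means classes.
    seed : int, default 0
    restarts : int, default 10
        k-means restarts; the best inertia wins.
    scale : bool, default True
        Apply per-probe z-scoring before clustering.

    Attributes
    ----------
    scaled_, linkage_, order_, labels_ : fitted artifacts.
    """

    def __init__(self, k: int = 3, seed: int = 0, restarts: int = 10,
                 scale: bool = True):
        self.k = k
        self.seed = seed
        self.restarts = restarts
        self.scale = scale

    def fit(self, X, y=None) -> "ExpressionClustering":
        if isinstance(X, NormalizedMatrix):
            X = X.values if X.log2 else log2_transform(X).values
        self.scaled_ = relative_expression(X) if self.scale else X.copy()
        self.linkage_ = ward_d2(self.scaled_, on="rois")
        self.order_ = dendrogram_order(self.linkage_)
        self.labels_ = kmeans_classes(self.scaled_, k=self.k, seed=self.seed,
                                      restarts=self.restarts)
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_

    def result(self) -> ClusterResult:
        return ClusterResult(linkage=self.linkage_, order=self.order_,
                             labels=self.labels_, scaled=self.scaled_,
                             k=self.k, seed=self.seed,
                             scaling="zscore" if self.scale else "none")


def linkage_frame(linkage: np.ndarray) -> pd.DataFrame:
    """Linkage matrix as a tidy merge list (child ids, height, size)."""
    return pd.DataFrame(linkage, columns=["child_a", "child_b", "height", "size"])
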