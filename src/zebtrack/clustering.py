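"""Hierarchical clustering of swim-bout kinematics with silhouette selection.

Bouts are summarized by four features -- mean tail-beat frequency, bout
integral, bout standard deviation and max tail amplitude -- with the
left-right direction removed by taking absolute values of the integral and
max amplitude.  Agglomerative (Ward, Euclidean) clustering is fitted for
each candidate cluster count and the count with the maximal mean silhouette
score wins.  Features are z-scored by default so the Hz-scaled frequency
does not dominate the Euclidean metric; linkage, metric and standardization
are all configurable.  Cluster naming (forward swim / routine turn /
J-turn) is a reporting step done by comparison to reference kinematics, not
an algorithmic output.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

__all__ = [
    "BoutClusterer",
    "ClusteringResult",
    "cluster_bouts",
    "features_to_matrix",
    "normalize_bout_kinematics_per_fish",
    "split_jturn_direction",
]


def features_to_matrix(features) -> np.ndarray:
    """Stack bout features into an (n, 4) array in the clustering space:
    (mean TBF, |integral|, SD, |max amplitude|)."""
    if isinstance(features, np.ndarray):
        x = np.asarray(features, float)
    else:
        x = np.array(
            [[f.mean_tbf, f.integral, f.sd, f.max_amplitude] for f in features],
            float,
        )
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("expected an (n, 4) bout-feature matrix")
    out = x.copy()
    out[:, 1] = np.abs(out[:, 1])
    out[:, 3] = np.abs(out[:, 3])
    return out


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    chosen_k: int
    silhouette_by_k: dict[int, float]
    degenerate: bool = False


class BoutClusterer(BaseEstimator, ClusterMixin):
    """Silhouette-selected agglomerative clustering of bout features.

    scikit-learn style estimator: ``fit(X)`` accepts an (n, 4) raw
    bout-feature matrix (signed integrals are fine; absolute values are
    taken internally) and exposes ``labels_``, ``k_`` and
    ``silhouette_by_k_``.

    Parameters
    ----------
    k_min, k_max : candidate cluster-count range (2..10 by default); shrunk
        with a warning when there are fewer bouts than ``k_max + 1``.
    standardize : z-score the features before clustering (default True).
    linkage, metric : passed to :class:`AgglomerativeClustering`.
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 10,
        standardize: bool = True,
        linkage: str = "ward",
        metric: str = "euclidean",
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.standardize = standardize
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        x = features_to_matrix(X)
        n = x.shape[0]
        if n < 12:
            raise ValueError("need at least 12 bouts to cluster")
        k_max = self.k_max
        if k_max > n - 1:
            k_max = n - 1
            warnings.warn(f"shrinking cluster range to 2..{k_max}: too few bouts")
        z = x
        if self.standardize:
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            z = (x - x.mean(axis=0)) / sd
        if np.allclose(z, z[0]):
            # all bouts identical: silhouette undefined; degenerate result
            self.labels_ = np.zeros(n, int)
            self.k_ = 1
            self.silhouette_by_k_ = {}
            self.degenerate_ = True
            return self
        scores: dict[int, float] = {}
        labels_by_k: dict[int, np.ndarray] = {}
        for k in range(self.k_min, k_max + 1):
            model = AgglomerativeClustering(
                n_clusters=k, linkage=self.linkage, metric=self.metric
            )
            lab = model.fit_predict(z)
            if len(np.unique(lab)) < 2:
                continue
            scores[k] = float(silhouette_score(z, lab, metric=self.metric))
            labels_by_k[k] = lab
        self.k_ = max(scores, key=scores.get)
        self.labels_ = labels_by_k[self.k_]
        self.silhouette_by_k_ = scores
        self.degenerate_ = False
        return self


def cluster_bouts(features, **kwargs) -> ClusteringResult:
    """Functional wrapper over :class:`BoutClusterer`."""
    est = BoutClusterer(**kwargs).fit(features)
    return ClusteringResult(
        labels=est.labels_,
        chosen_k=est.k_,
        silhouette_by_k=est.silhouette_by_k_,
        degenerate=est.degenerate_,
    )


def split_jturn_direction(
    integrals: np.ndarray,
    yaw_at_start: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Split one cluster's bouts into left- and right-biased swims.

    Direction comes from the sign of the *unnormalized* bout integral:
    positive integrals (tail bending to the fish's left in the reporting
    convention) are "left", negative "right".  Zero-integral bouts fall to
    "right" by the tie rule and are flagged.  When a stimulus log is
    supplied, ``yaw`` carries the per-bout prey yaw angle at bout start.
    """
    integ = np.asarray(integrals, float)
    side = np.where(integ > 0, "left", "right")
    out: dict[str, np.ndarray] = {
        "side": side,
        "tie_flag": integ == 0,
    }
    if yaw_at_start is not None:
        out["yaw"] = np.asarray(yaw_at_start, float)
    return out


def normalize_bout_kinematics_per_fish(df: pd.DataFrame, fish_col: str = "fish") -> pd.DataFrame:
    """Divide each fish's bout kinematics by that fish's across-trial mean.

    Every numeric column except ``fish_col`` is normalized; after
    normalization the per-fish mean of each feature is exactly 1 (where the
    fish's mean was nonzero).
    """
    cols = [c for c in df.columns if c != fish_col and np.issubdtype(df[c].dtype, np.number)]
    out = df.copy()
    means = df.groupby(fish_col)[cols].transform("mean")
    out[cols] = df[cols] / means
    return out
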