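"""Response subtype clustering.

Standardizes the three phenotype features — average phenylephrine infusion
rate, mean SBP, SD of SBP — and partitions episodes with k-means. With
k = 3 the clusters are given their pharmacological semantics: *resistant*
(highest infusion-rate centroid: high dose yet low pressure), *sensitive*
(of the remaining two, the higher mean-SBP centroid: adequate pressure at
low dose) and *intermediate* (low dose, low pressure).

k-means uses k-means++ initialization with the best of ``n_init`` restarts
by within-cluster sum of squares (Lloyd iterations, empty clusters
reseeded) — delegated to scikit-learn, whose documented defaults
(n_init=10, max_iter=300) are the ones used here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "FEATURES",
    "standardize_features",
    "kmeans_fit",
    "label_clusters",
    "evaluate_k",
    "assign_labels",
]

FEATURES = ("avg_rate", "mean_sbp", "sd_sbp")


@dataclass
class ClusterModel:
    """Fitted k-means model plus the standardization constants.

    centroids live in standardized feature space; ``label_map`` attaches the
    resistant/intermediate/sensitive semantics (k = 3 only).
    """

    k: int
    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    centroids: np.ndarray  # k x n_features, standardized space
    inertia: float
    seed: int
    n_init: int = 10
    max_iter: int = 300
    label_map: dict[int, str] = field(default_factory=dict)

    def centroids_unstandardized(self) -> np.ndarray:
        return self.centroids * self.feature_sds + self.feature_means

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment of standardized rows (lowest index wins ties)."""
        z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        d2 = ((z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "feature_names": list(self.feature_names),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "centroids": self.centroids.tolist(),
            "inertia": self.inertia,
            "seed": self.seed,
            "n_init": self.n_init,
            "max_iter": self.max_iter,
            "label_map": {str(k): v for k, v in self.label_map.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            k=d["k"],
            feature_names=tuple(d["feature_names"]),
            feature_means=np.array(d["feature_means"]),
            feature_sds=np.array(d["feature_sds"]),
            centroids=np.array(d["centroids"]),
            inertia=d["inertia"],
            seed=d["seed"],
            n_init=d["n_init"],
            max_iter=d["max_iter"],
            label_map={int(k): v for k, v in d["label_map"].items()},
        )


def standardize_features(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring with the sample-SD (n-1) convention.

    Returns (standardized matrix, means, sds); raises on a zero-variance
    column, since a constant feature cannot be standardized.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("missing values in feature matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        raise ValueError(f"zero-variance feature column(s): {zero.tolist()}")
    return (X - means) / sds, means, sds


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    feature_names: tuple[str, ...] = FEATURES,
) -> ClusterModel:
    """Standardize ``X`` and fit k-means (k-means++, best of ``n_init``)."""
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    z, means, sds = standardize_features(X)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
    ).fit(z)
    return ClusterModel(
        k=k,
        feature_names=tuple(feature_names),
        feature_means=means,
        feature_sds=sds,
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        max_iter=max_iter,
    )


def label_clusters(model: ClusterModel, tol: float = 1e-9) -> dict[int, str]:
    """Attach response semantics to a k=3 model.

    resistant = the cluster with the highest unstandardized average-rate
    centroid; of the remaining two, sensitive = the one with the higher
    mean-SBP centroid, intermediate = the other. Near-ties in the rate
    centroid (within ``tol``) are resolved toward the lower cluster index.
    The map is stored on the model and returned.
    """
    if model.k != 3:
        raise ValueError("semantic labels are defined for k = 3 only")
    cent = model.centroids_unstandardized()
    rate_col = model.feature_names.index("avg_rate")
    sbp_col = model.feature_names.index("mean_sbp")
    rates = cent[:, rate_col]
    order = np.argsort(-rates, kind="stable")
    if abs(rates[order[0]] - rates[order[1]]) <= tol:
        resistant = int(min(order[0], order[1]))
    else:
        resistant = int(order[0])
    rest = [i for i in range(3) if i != resistant]
    if cent[rest[0], sbp_col] >= cent[rest[1], sbp_col]:
        sensitive, intermediate = rest[0], rest[1]
    else:
        sensitive, intermediate = rest[1], rest[0]
    model.label_map = {
        resistant: "resistant",
        intermediate: "intermediate",
        sensitive: "sensitive",
    }
    return model.label_map


def assign_labels(
    model: ClusterModel, table: pd.DataFrame, label_col: str = "label"
) -> pd.DataFrame:
    """Predict cluster for each row of an episode feature table and attach
    the semantic label column."""
    X = table[list(model.feature_names)].to_numpy(dtype=float)
    idx = model.predict(X)
    out = table.copy()
    out["cluster"] = idx
    if model.label_map:
        out[label_col] = [model.label_map[i] for i in idx]
    return out


def evaluate_k(
    X: np.ndarray,
    k_list: tuple[int, ...] = (2, 3),
    seed: int = 0,
    rate_col: int = 0,
) -> pd.DataFrame:
    """Fit each k and report sizes, inertia, and the poor-responder fraction.

    The poor-responder fraction is the share of rows assigned to the cluster
    with the highest unstandardized average-rate centroid — the natural
    analogue of a 'requires-high-dose' group at any k. Deterministic given
    the seed.
    """
    X = np.asarray(X, dtype=float)
    rows = []
    for k in k_list:
        model = kmeans_fit(X, k, seed=seed)
        assign = model.predict(X)
        sizes = np.bincount(assign, minlength=k)
        cent = model.centroids_unstandardized()
        poor = int(np.argmax(cent[:, rate_col]))
        rows.append(
            {
                "k": k,
                "inertia": model.inertia,
                "sizes": ",".join(map(str, sizes.tolist())),
                "poor_responder_fraction": sizes[poor] / len(X),
            }
        )
    return pd.DataFrame(rows)
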