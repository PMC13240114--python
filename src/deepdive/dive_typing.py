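"""K-means dive typing with silhouette-based selection of K.

Dives are clustered on the raw (deliberately unscaled) feature vector
(duration s, maximum depth m, ascent rate, descent rate); with mixed units
the Euclidean distance relies more heavily on depth and duration than on
the rates, which mirrors how the dive types were originally defined and
keeps results comparable across studies.  The silhouette coefficient (SC,
the mean silhouette width; > 0.5 reasonable structure, > 0.7 strong) picks
the number of clusters, ties resolved toward the smaller K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .dive_segmentation import DiveMetrics
from .errors import InsufficientDataError, UndefinedStatisticError

__all__ = ["DiveTypeModel", "fit_dive_types", "silhouette_coefficient", "subsample_robustness"]

_NAMES = {2: ("short_shallow", "long_deep"), 3: ("short_shallow", "mid_depth", "long_deep")}


@dataclass
class DiveTypeModel:
    """Fitted K-means typing with silhouette diagnostics.

    ``type_names[label]`` gives the depth-ordered name of a cluster
    (short_shallow < mid_depth < long_deep by centroid depth; generic
    ``type_k`` names for other K).
    """

    k: int
    centroids: np.ndarray  # (k, 4): duration s, depth m, ascent, descent
    labels: np.ndarray
    silhouette_widths: np.ndarray
    sc: float
    sc_by_k: dict[int, float]
    type_names: list[str] = field(default_factory=list)

    def label_names(self) -> list[str]:
        return [self.type_names[i] for i in self.labels]


def _feature_matrix(metrics: list[DiveMetrics]) -> np.ndarray:
    X = np.array([m.feature_vector() for m in metrics], dtype=float)
    if not np.all(np.isfinite(X)):
        raise InsufficientDataError("non-finite clustering features")
    return X


def silhouette_coefficient(features, labels) -> tuple[float, np.ndarray]:
    """Mean silhouette width and the per-point widths.

    s(i) = (b - a) / max(a, b) with a the mean distance to the other points
    of i's cluster and b the smallest mean distance to another cluster;
    singleton clusters score 0.  Requires at least two clusters.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedStatisticError("silhouette undefined for a single cluster")
    D = cdist(X, X)
    s = np.zeros(len(X))
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(np.count_nonzero(masks[c])) for c in uniq}
    for i in range(len(X)):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(D[i, masks[o]].mean() for o in uniq if o != c)
        s[i] = (b - a) / max(a, b)
    return float(np.mean(s)), s


def fit_dive_types(
    metrics: list[DiveMetrics],
    k_range=(2, 3, 4, 5, 6),
    seed: int = 0,
    restarts: int = 50,
) -> DiveTypeModel:
    """Fit K-means over candidate K and keep the silhouette-best model.

    Features stay unscaled (a deliberate, documented choice — multiplying
    depth by a constant changes the model).  Each K runs ``restarts``
    seeded initialisations; sklearn re-seeds empty clusters from the points
    farthest from their centroids.
    """
    k_range = sorted(set(int(k) for k in k_range))
    X = _feature_matrix(metrics)
    if len(X) < max(k_range) + 1:
        raise InsufficientDataError(
            f"need at least {max(k_range) + 1} dives for k_range up to {max(k_range)}"
        )
    best = None
    sc_by_k: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(X)
        sc, widths = silhouette_coefficient(X, labels)
        sc_by_k[k] = sc
        if best is None or sc > best[0]:
            best = (sc, k, km.cluster_centers_, labels, widths)
    sc, k, centroids, labels, widths = best
    order = np.argsort(centroids[:, 1])  # by centroid depth
    names = _NAMES.get(k, tuple(f"type_{j + 1}" for j in range(k)))
    type_names = [""] * k
    for rank, cluster in enumerate(order):
        type_names[cluster] = names[rank]
    return DiveTypeModel(
        k=k,
        centroids=centroids,
        labels=labels,
        silhouette_widths=widths,
        sc=sc,
        sc_by_k=sc_by_k,
        type_names=type_names,
    )


def subsample_robustness(
    metrics: list[DiveMetrics],
    n_deployments: int = 6,
    reps: int = 30,
    seed: int = 0,
    k_range=(2, 3, 4, 5, 6),
    restarts: int = 50,
) -> pd.DataFrame:
    """SC-versus-K over repeated deployment subsamples.

    Each repetition selects ``n_deployments`` deployments without
    replacement, refits over ``k_range`` on their pooled dives and records
    SC for every K — a check that the chosen number of dive types is not an
    artefact of dataset size.  Returns a frame with one row per rep.
    """
    deployments = sorted({m.deployment_id for m in metrics})
    if n_deployments > len(deployments):
        raise InsufficientDataError("n_deployments exceeds available deployments")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        chosen = set(rng.choice(deployments, size=n_deployments, replace=False))
        sub = [m for m in metrics if m.deployment_id in chosen]
        model = fit_dive_types(sub, k_range=k_range, seed=seed + rep, restarts=restarts)
        row = {"rep": rep, "n_dives": len(sub)}
        row.update({f"sc_k{k}": v for k, v in model.sc_by_k.items()})
        row["best_k"] = model.k
        rows.append(row)
    return pd.DataFrame(rows)
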