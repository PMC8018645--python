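"""Multivariate structure: PCA, the per-variety triangle-area variability
metric, Ward clustering, and a delegated discriminant-compound screen.

The triangle-area metric quantifies how differently a variety responds to
three environments: each variety contributes three points (one per
environment) in the space of the first three principal components, and the
area of that triangle — ½‖(L−A) × (S−A)‖ — measures its multivariate
spread.  A weighted variant stretches each PC axis according to the
inertia it explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "PcaModel",
    "pca",
    "variety_area",
    "variety_areas",
    "WardClustering",
    "ward_clustering",
    "MarkerScreenResult",
    "marker_screen",
]


# --------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: pd.DataFrame      # sample x component
    loadings: pd.DataFrame    # compound x component
    inertia: np.ndarray       # explained-inertia fraction per component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame) -> PcaModel:
    """Principal component analysis of a (scaled) sample × compound matrix.

    Columns are re-centred defensively; on pre-scaled data this is
    correlation PCA.  Component signs follow a deterministic convention:
    the largest-|loading| coordinate of each component is positive.
    Trailing zero eigenvalues of rank-deficient input are retained as
    zero-inertia components.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("pca needs >= 3 samples and >= 2 compounds")
    if np.isnan(x).any():
        raise ValueError("pca requires complete data")
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| element positive per component
    flips = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flips[flips == 0] = 1.0
    u, vt = u * flips, vt * flips[:, None]
    eig = s**2 / (x.shape[0] - 1)
    inertia = eig / eig.sum()
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PcaModel(
        scores=pd.DataFrame(u * s, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comp),
        inertia=inertia,
    )


# --------------------------------------------------------------------------
# Triangle areas


def _area_weights(inertia3: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "normalized":
        # inertia fractions scaled by their own mean: keeps the weighted
        # area on the same magnitude as the raw one
        return inertia3 / inertia3.mean()
    if weighting == "raw":
        return inertia3.copy()
    raise ValueError(f"unknown weighting {weighting!r}")


def variety_area(
    points: np.ndarray,
    inertia: np.ndarray | None = None,
    weighting: str = "normalized",
) -> tuple[float, float | None]:
    """Triangle area of one variety's three environment points on PC1–3.

    area = ½‖(L−A) × (S−A)‖, zero iff the points are collinear.  When
    inertia fractions are given, the weighted area is computed identically
    after multiplying coordinate axis k by a per-axis weight (default: the
    axis' inertia fraction divided by the mean fraction of the three axes).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 3):
        raise ValueError("variety_area needs exactly 3 environment points with 3 coordinates")
    a, l, s = pts
    area = 0.5 * float(np.linalg.norm(np.cross(l - a, s - a)))
    weighted = None
    if inertia is not None:
        w = _area_weights(np.asarray(inertia, dtype=float)[:3], weighting)
        aw, lw, sw = pts * w
        weighted = 0.5 * float(np.linalg.norm(np.cross(lw - aw, sw - aw)))
    return area, weighted


def variety_areas(
    model: PcaModel, weighting: str = "normalized"
) -> pd.DataFrame:
    """Per-variety triangle areas from a PCA of (variety, environment) samples.

    The score index must be a (variety, environment) MultiIndex and every
    variety must appear in exactly three environments.
    """
    scores = model.scores.iloc[:, :3]
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 principal components")
    rows = {}
    for variety, sub in scores.groupby(level=0, sort=True):
        if len(sub) != 3:
            raise ValueError(
                f"variety {variety!r} has {len(sub)} environment points; the area "
                "metric is defined only for the 3-environment design"
            )
        area, weighted = variety_area(sub.to_numpy(), model.inertia[:3], weighting)
        rows[variety] = {"area": area, "weighted_area": weighted}
    out = pd.DataFrame(rows).T.sort_values("area", ascending=False)
    out.index.name = "variety"
    return out


# --------------------------------------------------------------------------
# Ward clustering


@dataclass
class WardClustering:
    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster memberships at k clusters."""
        if k > len(self.labels):
            raise ValueError(f"cannot cut {len(self.labels)} leaves into {k} clusters")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.get_left(), node.dist)
            right = walk(node.get_right(), node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({walk(tree.get_left(), tree.dist)},{walk(tree.get_right(), tree.dist)});"


def ward_clustering(matrix: pd.DataFrame) -> WardClustering:
    """Agglomerative Ward linkage on Euclidean distances between rows."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs >= 2 rows")
    x = matrix.to_numpy(dtype=float)
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    labels = ["|".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in matrix.index]
    return WardClustering(linkage=z, labels=labels)


# --------------------------------------------------------------------------
# Discriminant-compound screen (delegated classifier)


@dataclass
class MarkerScreenResult:
    table: pd.DataFrame        # per compound: importance, p_value, selected
    oob_error: float
    n_trees: int
    n_permutations: int

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _raw_gini_importance(forest: RandomForestClassifier, n_samples: int) -> np.ndarray:
    # unnormalized mean impurity decrease per feature, on the scale of the
    # classical "mean decrease in Gini" (sum of weighted node impurity
    # decreases, weights in sample counts rather than fractions)
    imp = np.zeros(forest.n_features_in_)
    for est in forest.estimators_:
        imp += est.tree_.compute_feature_importances(normalize=False) * n_samples
    return imp / len(forest.estimators_)


def marker_screen(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 500,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    importance_floor: float = 1.0,
    seed: int = 0,
) -> MarkerScreenResult:
    """Variety-discriminant compounds via a random-forest importance screen.

    Fits a random-forest classifier of variety labels on compound profiles
    (the classifier itself is delegated to scikit-learn), computes the
    raw-scale Gini importance of each compound, and estimates a permutation
    p-value per compound by refitting on label-permuted data.  A compound
    is selected when p < alpha and its importance exceeds
    ``importance_floor``.  Classification error is estimated out-of-bag.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("marker_screen needs >= 2 classes")
    x = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def fit(yy: np.ndarray, rs: int) -> RandomForestClassifier:
        f = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=rs, n_jobs=1
        )
        f.fit(x, yy)
        return f

    forest = fit(y, int(rng.integers(2**31 - 1)))
    obs = _raw_gini_importance(forest, len(y))
    oob_error = 1.0 - float(forest.oob_score_)

    exceed = np.zeros_like(obs)
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        null = _raw_gini_importance(fit(y_perm, int(rng.integers(2**31 - 1))), len(y))
        exceed += null >= obs
    p = (1.0 + exceed) / (1.0 + n_permutations)

    table = pd.DataFrame(
        {"importance": obs, "p_value": p}, index=matrix.columns
    ).sort_values("importance", ascending=False)
    table["selected"] = (table["p_value"] < alpha) & (table["importance"] > importance_floor)
    table.index.name = "compound"
    return MarkerScreenResult(
        table=table, oob_error=oob_error, n_trees=n_trees, n_permutations=n_permutations
    )
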