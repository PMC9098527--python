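"""Multivariate chemotyping: PCA, PCoA, correspondence analysis, UPGMA.

All ordinations report descending eigenvalues and % variance alongside
observation scores (and variable loadings where defined), mirroring the
eigenvalue/%-variance tables that desktop packages such as PAST print.
Component signs follow a fixed convention — the largest-magnitude loading
(or score, for PCoA) of each axis is positive — so outputs are reproducible
across runs and platforms.

PCA and classical scaling (PCoA) are implemented directly via SVD /
eigendecomposition; hierarchical clustering delegates to SciPy's
average-linkage (UPGMA) agglomeration. Tree node heights are ultrametric:
half the cophenetic merge distance, so two leaves merging at distance 1 sit
under a node of height 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .profiling import PanelMatrix

__all__ = [
    "OrdinationResult",
    "ClusterTree",
    "DegenerateInputError",
    "pca",
    "pcoa",
    "correspondence_analysis",
    "hclust",
]


class DegenerateInputError(ValueError):
    """Input matrix carries no usable variation for the requested analysis."""


@dataclass(frozen=True)
class OrdinationResult:
    """Eigenvalues, % variance, scores and loadings of one ordination.

    ``eigenvalues`` includes every computed eigenvalue in descending order
    (negative PCoA eigenvalues included for diagnosis); ``pct_variance``
    covers the retained non-negative axes and sums to 100. ``scores`` holds
    observation coordinates (rows = observations), ``loadings`` variable
    coordinates for PCA/CA (None for PCoA).
    """

    method: str
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "eigenvalues", ev)
        object.__setattr__(
            self, "pct_variance", np.asarray(self.pct_variance, dtype=float)
        )
        if np.any(np.diff(ev) > 1e-9 * max(abs(ev).max(initial=0.0), 1.0)):
            raise ValueError("eigenvalues must be descending")

    def to_csv(self, prefix: str) -> None:
        pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "pct_variance": np.concatenate(
                    [
                        self.pct_variance,
                        np.full(len(self.eigenvalues) - len(self.pct_variance), np.nan),
                    ]
                ),
            }
        ).to_csv(f"{prefix}_eigenvalues.csv", index_label="axis")
        self.scores.to_csv(f"{prefix}_scores.csv")
        if self.loadings is not None:
            self.loadings.to_csv(f"{prefix}_loadings.csv")


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, PanelMatrix):
        return matrix.conc
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr)


def _fix_signs(components: np.ndarray, scores: np.ndarray | None = None) -> None:
    """Flip axes in place so each component's largest |loading| is positive."""
    for j in range(components.shape[1]):
        i = int(np.argmax(np.abs(components[:, j])))
        if components[i, j] < 0:
            components[:, j] *= -1
            if scores is not None and scores is not components:
                scores[:, j] *= -1


def pca(matrix, scale: str = "center") -> OrdinationResult:
    """Principal component analysis of a lines × metabolites table.

    ``scale='center'`` analyses the covariance structure (the default for
    concentration data on a common mg/g scale); ``scale='autoscale'``
    z-scores columns first, i.e. analyses the correlation structure. Scores
    are the projections of the centered (scaled) data onto the component
    axes; at full rank they reproduce the input losslessly.
    """
    X = _as_frame(matrix)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    if X.isna().to_numpy().any():
        raise ValueError("missing values not allowed (absent = 0)")
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    if scale == "autoscale":
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [X.columns[i] for i in np.flatnonzero(sd == 0)]
            raise DegenerateInputError(f"constant columns under autoscale: {zero}")
        A = A / sd
    elif scale != "center":
        raise ValueError("scale must be 'center' or 'autoscale'")
    if not np.any(A):
        raise DegenerateInputError("matrix is constant; no variance to analyse")

    n = A.shape[0]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    eig = s**2 / (n - 1)
    k = int(np.sum(s > s[0] * 1e-12))
    k = min(k, n - 1, A.shape[1])
    U, s, V, eig = U[:, :k], s[:k], Vt[:k].T, eig[:k]
    scores = U * s
    _fix_signs(V, scores)
    pct = 100.0 * eig / eig.sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="PCA",
        eigenvalues=eig,
        pct_variance=pct,
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        loadings=pd.DataFrame(V, index=X.columns, columns=cols),
    )


def pcoa(distances, labels=None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers −½D² and eigendecomposes; coordinates are returned for
    positive eigenvalues only, each scaled by √λ. Negative eigenvalues
    (non-Euclidean distances) are reported in ``eigenvalues`` but excluded
    from ``pct_variance``. On Euclidean distances of a data matrix the
    coordinates equal covariance-PCA scores up to column sign.
    """
    if isinstance(distances, pd.DataFrame):
        labels = labels if labels is not None else list(distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    labels = labels if labels is not None else list(range(n))

    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = 0.5 * (G + G.T)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = max(abs(vals).max(initial=0.0), 1.0) * 1e-10
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if coords.size:
        _fix_signs(coords)
    pct = (
        100.0 * vals[pos] / vals[pos].sum()
        if pos.any()
        else np.empty(0)
    )
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        method="PCoA",
        eigenvalues=vals,
        pct_variance=pct,
        scores=pd.DataFrame(coords, index=labels, columns=cols),
        loadings=None,
    )


def correspondence_analysis(matrix) -> OrdinationResult:
    """Correspondence analysis of a non-negative contingency-style table.

    Decomposes the standardized residuals (observed − expected over
    √expected, on the table scaled to unit grand total) by SVD. Eigenvalues
    are squared singular values (principal inertias); their sum is the total
    inertia χ²/N. Scores/loadings are row/column principal coordinates.
    """
    X = _as_frame(matrix)
    N = X.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("table entries must be non-negative")
    total = N.sum()
    if total <= 0:
        raise ValueError("table must have a positive grand total")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("zero row or column sums not allowed")
    E = np.outer(r, c)
    S = (P - E) / np.sqrt(E)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s > max(s.max(initial=0.0), 1.0) * 1e-12
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    eig = s**2
    row_coords = (U / np.sqrt(r)[:, None]) * s
    col_coords = (V / np.sqrt(c)[:, None]) * s
    if s.size:
        _fix_signs(col_coords, row_coords)
    pct = 100.0 * eig / eig.sum() if eig.size else np.empty(0)
    cols = [f"CA{i + 1}" for i in range(s.size)]
    return OrdinationResult(
        method="CA",
        eigenvalues=eig,
        pct_variance=pct,
        scores=pd.DataFrame(row_coords, index=X.index, columns=cols),
        loadings=pd.DataFrame(col_coords, index=X.columns, columns=cols),
    )


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge sequence with ultrametric node heights.

    Wraps a SciPy linkage matrix; ``heights`` (merge distance / 2) are
    non-decreasing for UPGMA. Serializable to Newick with branch lengths
    equal to parent−child height differences.
    """

    linkage: np.ndarray
    leaf_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage, dtype=float)
        object.__setattr__(self, "linkage", Z)
        if Z.shape[0] != len(self.leaf_labels) - 1:
            raise ValueError("linkage rows must equal n_leaves - 1")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Leaf label → cluster id (1..n_clusters) at a flat cut."""
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return {lab: int(cl) for lab, cl in zip(self.leaf_labels, flat)}

    def to_newick(self) -> str:
        n = len(self.leaf_labels)
        heights = self.heights

        def node_height(i: int) -> float:
            return 0.0 if i < n else float(heights[i - n])

        def render(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.leaf_labels[i]}:{parent_h:.6g}"
            a, b = int(self.linkage[i - n, 0]), int(self.linkage[i - n, 1])
            h = node_height(i)
            inner = f"({render(a, h)},{render(b, h)})"
            return f"{inner}:{parent_h - h:.6g}"

        root = 2 * n - 2
        h = node_height(root)
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return f"({render(a, h)},{render(b, h)});"


def hclust(
    data,
    metric: str = "euclidean",
    linkage: str = "average",
    labels=None,
    precomputed: bool = False,
) -> ClusterTree:
    """Agglomerative clustering of panel lines (UPGMA on Euclidean default).

    ``data`` is an observations × variables table (PanelMatrix, DataFrame or
    array), or a square distance matrix when ``precomputed=True``. Ties in
    merge distance resolve deterministically (SciPy's lowest-index-first
    order). Relabeling observations permutes leaves without changing
    topology or heights.
    """
    if precomputed:
        D = np.asarray(
            data.to_numpy() if isinstance(data, pd.DataFrame) else data, dtype=float
        )
        if labels is None and isinstance(data, pd.DataFrame):
            labels = list(data.index)
        condensed = squareform(D, checks=True)
        n = D.shape[0]
    else:
        X = _as_frame(data)
        if labels is None:
            labels = list(X.index)
        condensed = pdist(X.to_numpy(dtype=float), metric=metric)
        n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if labels is None:
        labels = list(range(n))
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage=Z, leaf_labels=tuple(str(x) for x in labels))
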