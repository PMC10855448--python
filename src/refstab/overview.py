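"""Expression-overview ordination: centered PCA and correlation clustering.

Mirrors the ClustVis-style settings used for qRT-PCR overview figures: no
transformation, per-gene (column) centering, no unit scaling for the PCA;
1 − Pearson correlation as the distance and average linkage for the
hierarchical clustering, with the tighter (lower-height) cluster placed
first when ordering the tree.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .qpcr_data import CtMatrix, DatasetSlice, ValidationError


@dataclasses.dataclass
class PcaResult:
    """Sample scores and explained-variance percentages."""

    scores: pd.DataFrame          # samples × components (PC1, PC2, ...)
    variance_pct: np.ndarray      # full-precision percentages per component

    @property
    def variance_pct_rounded(self) -> np.ndarray:
        """Percent variance per component, reported to 1 decimal."""
        return np.round(self.variance_pct, 1)

    def to_frame(self) -> pd.DataFrame:
        return self.scores


@dataclasses.dataclass
class ClusterTree:
    """Average-linkage tree on 1 − Pearson correlation distances."""

    labels: list[str]
    linkage_matrix: np.ndarray     # scipy (n−1) × 4 linkage
    merges: list[tuple[frozenset, float]]  # leaf-label sets per merge, by height
    leaf_order: list[str]          # tighter-cluster-first ordering

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def first_merge(self) -> frozenset:
        """Leaf labels joined at the lowest node of the tree."""
        return self.merges[0][0]


def _as_frame(m) -> pd.DataFrame:
    if isinstance(m, (CtMatrix, DatasetSlice)):
        return m.values
    return pd.DataFrame(m)


def pca_overview(m) -> PcaResult:
    """Column-centered, unscaled PCA of a samples × genes matrix.

    Accepts a :class:`CtMatrix`, a slice, or a plain DataFrame (e.g. a
    group-mean Ct matrix).  Each gene is centered across samples; no
    variance scaling is applied, so high-variance genes weigh more — the
    convention of the overview figures this reproduces.  A constant matrix
    yields an all-zero score matrix with 0 % variance per component.
    """
    x = _as_frame(m)
    if x.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if x.isna().to_numpy().any():
        raise ValidationError("PCA input contains missing values")
    arr = x.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        pct = np.zeros(len(s))
        scores = np.zeros_like(u)
    else:
        pct = s**2 / total * 100.0
        scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=x.index, columns=cols),
        variance_pct=pct,
    )


def hier_cluster(m, axis: str = "samples") -> ClusterTree:
    """Average-linkage clustering on 1 − Pearson correlation distances.

    ``axis="samples"`` clusters rows; ``axis="genes"`` clusters columns.
    Rows with zero variance have undefined correlation and are rejected by
    name.
    """
    x = _as_frame(m)
    if axis == "genes":
        x = x.T
    elif axis != "samples":
        raise ValidationError(f"axis must be 'samples' or 'genes', not {axis!r}")
    if x.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 profiles")
    arr = x.to_numpy(dtype=float)
    sds = arr.std(axis=1)
    if (sds == 0).any():
        bad = [str(x.index[i]) for i in np.flatnonzero(sds == 0)]
        raise ValidationError(
            f"zero-variance profile(s) {bad}: correlation distance undefined"
        )
    corr = np.corrcoef(arr)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")

    labels = [str(i) for i in x.index]
    merges = _merge_sets(z, labels)
    order = _tighter_first_order(z, labels)
    return ClusterTree(labels=labels, linkage_matrix=z, merges=merges, leaf_order=order)


def _merge_sets(z: np.ndarray, labels: list[str]) -> list[tuple[frozenset, float]]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    merges = []
    for i, (a, b, h, _cnt) in enumerate(z):
        s = members[int(a)] | members[int(b)]
        members[n + i] = s
        merges.append((s, float(h)))
    return merges


def _tighter_first_order(z: np.ndarray, labels: list[str]) -> list[str]:
    """Leaf order with the tighter (lower merge height) subtree first."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h, _cnt) in enumerate(z):
        node = n + i
        height[node] = float(h)
        children[node] = (int(a), int(b))

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if height[a] <= height[b] else (b, a)
        return walk(first) + walk(second)

    root = n + len(z) - 1
    return [labels[i] for i in walk(root)]


def row_centered(m) -> pd.DataFrame:
    """Per-gene row-centered values for heat-map style reporting: negative
    means lower Ct (higher expression) than that gene's mean."""
    x = _as_frame(m).T  # genes as rows
    return x.sub(x.mean(axis=1), axis=0)
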