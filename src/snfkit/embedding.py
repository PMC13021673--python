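"""Low-dimensional embedding and hierarchical clustering of region profiles.

PCA is applied to the row-centered fingerprint matrix in its *Gram*
(region-by-region) form: Sigma = X~ X~^T / (|S| - 1), eigendecomposed as
Sigma v_i = lambda_i v_i, with region scores v_i * sqrt(lambda_i)
(principal-coordinate convention).  The non-zero eigenvalues of this Gram
form coincide with those of the conventional |S| x |S| feature covariance
X~^T X~ / (|S| - 1) (singular-value duality), and because every row of X~
is centered, the all-ones study vector is a null direction — at most
|S| - 1 eigenvalues are non-zero.

Clustering uses agglomerative Ward linkage over Euclidean distances
between region rows, implemented via the Lance-Williams recurrence with a
deterministic tie-break (lowest cluster-index pair), so merge trees are
reproducible to the bit.  Cluster-versus-network agreement is summarised
by the adjusted Rand index against dominant-network labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core import FingerprintMatrix, NetworkScheme

__all__ = [
    "CenteredMatrix",
    "EmbeddingResult",
    "ClusteringResult",
    "row_center",
    "gram_covariance",
    "feature_covariance",
    "eigendecompose",
    "region_scores",
    "embed",
    "ward_dendrogram",
    "cluster_network_agreement",
    "export_newick",
]

_EIG_TOL = 1e-9  # eigenvalues below this are treated as zero


@dataclass(frozen=True)
class CenteredMatrix:
    """Row-centered matrix X~ together with the subtracted row means."""

    values: np.ndarray     # |R| x |S| float
    row_means: np.ndarray  # |R|
    roi_ids: tuple[str, ...]

    @property
    def n_studies(self) -> int:
        return self.values.shape[1]

    def uncenter(self) -> np.ndarray:
        """Add the row means back, recovering the original matrix."""
        return self.values + self.row_means[:, None]


@dataclass(frozen=True)
class EmbeddingResult:
    """Gram matrix, eigenpairs and 2-D (or n-D) region scores."""

    sigma: np.ndarray                     # |R| x |R|
    eigenvalues: np.ndarray               # descending
    eigenvectors: np.ndarray              # columns match eigenvalue order
    explained_variance_ratio: np.ndarray
    scores: np.ndarray                    # |R| x n_components
    roi_ids: tuple[str, ...]
    networks: tuple[str, ...]             # dominant network per region ("" if no scheme)


@dataclass(frozen=True)
class ClusteringResult:
    """Ward merge tree over region rows.

    ``merge_tree`` records ``(cluster_a, cluster_b, height, new_size)``
    per step; leaves are clusters ``0 .. n-1`` (row order), the cluster
    formed at step ``t`` has id ``n + t``.  Heights are Euclidean Ward
    merge distances and are non-decreasing along the sequence.
    """

    merge_tree: tuple[tuple[int, int, float, int], ...]
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def labels_at_k(self, k: int) -> np.ndarray:
        """Flat partition with exactly ``k`` clusters (1 <= k <= n).

        Labels are renumbered ``0 .. k-1`` by each cluster's smallest leaf
        index, so the labelling is deterministic.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t, (a, b, _h, _sz) in enumerate(self.merge_tree[: n - k]):
            parent[find(a)] = parent[find(b)] = n + t
        roots = [find(i) for i in range(n)]
        first_leaf: dict[int, int] = {}
        for i, r in enumerate(roots):
            first_leaf.setdefault(r, i)
        order = {r: lbl for lbl, r in enumerate(sorted(first_leaf, key=first_leaf.get))}
        return np.array([order[r] for r in roots], dtype=int)


def row_center(m: FingerprintMatrix) -> CenteredMatrix:
    """Subtract each region row's mean, emphasising relative abnormality
    profiles across studies over absolute reporting frequency."""
    if m.n_studies < 2:
        raise ValueError(f"row centering requires >= 2 studies, got {m.n_studies}")
    x = m.entries.astype(float)
    means = x.mean(axis=1)
    return CenteredMatrix(values=x - means[:, None], row_means=means,
                          roi_ids=m.roi_ids)


def gram_covariance(x: CenteredMatrix) -> np.ndarray:
    """Region-by-region Gram matrix Sigma = X~ X~^T / (|S| - 1)."""
    if x.n_studies < 2:
        raise ValueError("covariance requires >= 2 studies")
    return (x.values @ x.values.T) / (x.n_studies - 1)


def feature_covariance(x: CenteredMatrix) -> np.ndarray:
    """Conventional |S| x |S| covariance X~^T X~ / (|S| - 1).

    Its non-zero eigenvalues equal those of :func:`gram_covariance` — the
    duality that makes the Gram formulation an exact PCA."""
    if x.n_studies < 2:
        raise ValueError("covariance requires >= 2 studies")
    return (x.values.T @ x.values) / (x.n_studies - 1)


def eigendecompose(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a symmetric matrix, sorted by descending eigenvalue.

    Each eigenvector is unit-norm with its largest-magnitude component
    made positive (first occurrence on a magnitude tie), fixing the sign
    ambiguity for reproducible plots.  Degenerate eigenvalues keep their
    post-sort index order.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-9):
        raise ValueError("matrix is not symmetric within 1e-9")
    values, vectors = np.linalg.eigh(sigma)
    order = np.argsort(values, kind="stable")[::-1]
    values, vectors = values[order], vectors[:, order]
    for i in range(vectors.shape[1]):
        pivot = int(np.argmax(np.abs(vectors[:, i])))
        if vectors[pivot, i] < 0:
            vectors[:, i] = -vectors[:, i]
    return values, vectors


def region_scores(
    x: CenteredMatrix,
    eigenvalues: np.ndarray,
    eigenvectors: np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """Region coordinates on the leading components: v_i * sqrt(lambda_i).

    Requires ``n_components`` at most the number of positive eigenvalues
    (at most |S| - 1 after row centering).  Under this principal-
    coordinate convention, full-rank score distances reproduce Euclidean
    distances between centered rows up to the global 1/sqrt(|S| - 1)
    factor carried by the covariance normalisation.
    """
    n_pos = int(np.sum(eigenvalues > _EIG_TOL))
    if n_components > n_pos:
        raise ValueError(
            f"n_components={n_components} exceeds the number of positive "
            f"eigenvalues ({n_pos})"
        )
    lam = np.clip(eigenvalues[:n_components], 0.0, None)
    return eigenvectors[:, :n_components] * np.sqrt(lam)[None, :]


def embed(
    m: FingerprintMatrix,
    scheme: NetworkScheme | None = None,
    n_components: int = 2,
) -> EmbeddingResult:
    """Row-center, form the Gram covariance, eigendecompose and score.

    Convenience composition of :func:`row_center`, :func:`gram_covariance`,
    :func:`eigendecompose` and :func:`region_scores`.
    """
    x = row_center(m)
    sigma = gram_covariance(x)
    values, vectors = eigendecompose(sigma)
    positive = np.clip(values, 0.0, None)
    total = positive.sum()
    ratio = positive / total if total > 0 else np.zeros_like(positive)
    scores = region_scores(x, values, vectors, n_components)
    networks = tuple(
        scheme.dominant(r.roi_id) if scheme is not None else ""
        for r in m.regions
    )
    return EmbeddingResult(
        sigma=sigma,
        eigenvalues=values,
        eigenvectors=vectors,
        explained_variance_ratio=ratio,
        scores=scores,
        roi_ids=m.roi_ids,
        networks=networks,
    )


def _ward_merge_tree(points: np.ndarray) -> list[tuple[int, int, float, int]]:
    # Lance-Williams recurrence on squared Euclidean distances.
    # Tie-break: the lexicographically smallest active (i, j) pair among
    # minimal distances (exact float comparison; ternary inputs tie exactly).
    n = points.shape[0]
    size = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((points[i] - points[j]) ** 2))
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = d2[(i, j)]
                if best is None or dij < best[0]:
                    best = (dij, i, j)
        dij, i, j = best
        new = n + step
        merges.append((i, j, float(np.sqrt(max(dij, 0.0))), size[i] + size[j]))
        size[new] = size[i] + size[j]
        active = [c for c in active if c not in (i, j)]
        for k in active:
            dki = d2[(min(i, k), max(i, k))]
            dkj = d2[(min(j, k), max(j, k))]
            d2[(k, new)] = (
                (size[i] + size[k]) * dki
                + (size[j] + size[k]) * dkj
                - size[k] * dij
            ) / (size[i] + size[j] + size[k])
        active.append(new)
    return merges


def ward_dendrogram(
    m: FingerprintMatrix, use_centered: bool = False
) -> ClusteringResult:
    """Agglomerative Ward clustering of region rows.

    By default each raw ternary row is the feature vector; with
    ``use_centered=True`` the row-centered matrix is used instead, for
    consistency with the PCA view.  Identical rows merge first at height
    0; heights never decrease (Ward is reducible).
    """
    if m.n_regions < 2:
        raise ValueError(f"clustering requires >= 2 regions, got {m.n_regions}")
    points = row_center(m).values if use_centered else m.entries.astype(float)
    return ClusteringResult(
        merge_tree=tuple(_ward_merge_tree(points)), leaf_ids=m.roi_ids
    )


def cluster_network_agreement(
    c: ClusteringResult, scheme: NetworkScheme, k: int
) -> float:
    """Adjusted Rand index between the k-cluster partition and the
    dominant-network labels (1 = identical partitions, ~0 at chance)."""
    if not 2 <= k <= c.n_leaves:
        raise ValueError(f"k must be in [2, {c.n_leaves}], got {k}")
    labels = c.labels_at_k(k)
    reference = [scheme.dominant(roi) for roi in c.leaf_ids]
    return float(adjusted_rand_score(reference, labels))


def export_newick(c: ClusteringResult) -> str:
    """Serialise the merge tree as Newick, leaves named by roi_id.

    Each branch length is the parent's merge height minus the child's own
    height (leaves sit at height 0), so root-to-leaf path lengths equal
    the root merge height (an ultrametric tree).
    """
    n = c.n_leaves
    if n == 1:
        return f"{c.leaf_ids[0]}:0;"
    if len(c.merge_tree) != n - 1:
        raise ValueError(
            f"malformed merge tree: expected {n - 1} merges, got {len(c.merge_tree)}"
        )
    height = {i: 0.0 for i in range(n)}
    children = {}
    for t, (a, b, h, _sz) in enumerate(c.merge_tree):
        node = n + t
        if a not in height or b not in height or a == b:
            raise ValueError(f"malformed merge tree at step {t}: ({a}, {b})")
        height[node] = h
        children[node] = (a, b)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{c.leaf_ids[node]}:{length:.9g}"
        a, b = children[node]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{length:.9g}"

    root = n + len(c.merge_tree) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"
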