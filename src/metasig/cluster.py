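"""Signature-restricted hierarchical clustering and class-purity scoring.

Samples are clustered on Pearson distance (1 - r) and genes on absolute
Pearson distance (1 - |r|), both computed over the signature features only.
Linkage is Ward's method applied with the Lance-Williams update directly to
the supplied dissimilarities (the behavior of R's hcluster "ward"), rather
than on a Euclidean embedding.  Validation cuts the dendrogram into k
clusters, labels each cluster by its majority tissue code, and counts the
samples whose own code matches their cluster's label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix
from .signature import Signature

__all__ = [
    "sample_distance", "gene_distance", "ward_cluster", "score_classes",
    "ClassReport", "restrict_matrix_to_signature",
]


def _pearson_distance(mat: np.ndarray, ids, absolute: bool) -> pd.DataFrame:
    """1 - r (or 1 - |r|) between the *columns* of ``mat``."""
    sd = mat.std(axis=0)
    if np.any(sd == 0):
        bad = [str(i) for i, s in zip(ids, sd) if s == 0]
        raise ValueError(f"zero-variance items: {bad[:5]}")
    r = np.corrcoef(mat, rowvar=False)
    d = 1.0 - (np.abs(r) if absolute else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)   # symmetrize away rounding
    return pd.DataFrame(d, index=ids, columns=ids)


def sample_distance(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson distance 1 - r between samples over the matrix's features."""
    vals = m.values if isinstance(m, ExpressionMatrix) else pd.DataFrame(m)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 features to correlate samples")
    return _pearson_distance(vals.to_numpy(dtype=float), list(vals.columns),
                             absolute=False)


def gene_distance(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson distance 1 - |r| between features."""
    vals = m.values if isinstance(m, ExpressionMatrix) else pd.DataFrame(m)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate genes")
    return _pearson_distance(vals.to_numpy(dtype=float).T, list(vals.index),
                             absolute=True)


def ward_cluster(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward (Lance-Williams) agglomeration on a dissimilarity matrix.

    Returns a linkage matrix in scipy format: each of the n-1 rows holds
    (cluster_i, cluster_j, merge_height, new_size), with original items
    numbered 0..n-1 and merged clusters n, n+1, ...  At each step the pair
    at minimal current dissimilarity merges (ties resolved toward the
    lexicographically smallest index pair), and distances to the new
    cluster follow the Ward update

        d(k, ij) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)]
                   / (n_i + n_j + n_k).
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least 2 items")

    size = np.ones(n)
    cluster_id = np.arange(n)     # current scipy id of each active row
    active = np.ones(n, dtype=bool)
    np.fill_diagonal(d, np.inf)
    d[~np.isfinite(d) & ~np.isinf(d)] = np.inf

    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], d, np.inf)
        np.fill_diagonal(masked, np.inf)
        # argmin is first occurrence in row-major order -> lexicographic ties
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        h = d[i, j]
        ni, nj = size[i], size[j]
        lo, hi = sorted((cluster_id[i], cluster_id[j]))
        Z[step] = (lo, hi, h, ni + nj)

        # Lance-Williams Ward update into row/col i
        k = active.copy()
        k[i] = k[j] = False
        nk = size[k]
        new = ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * h) \
            / (ni + nj + nk)
        d[i, k] = new
        d[k, i] = new
        size[i] = ni + nj
        active[j] = False
        cluster_id[i] = next_id
        next_id += 1
    return Z


@dataclass
class ClassReport:
    """Per-tissue correct-classification counts at a k-cluster cut."""

    per_class: pd.DataFrame          # index tissue code: n_samples, n_correct, accuracy
    cluster_labels: dict[int, str]   # cluster -> majority tissue code
    assignments: pd.Series           # sample -> cluster
    misclassified: list[str]

    @property
    def overall_accuracy(self) -> float:
        tot = self.per_class["n_samples"].sum()
        return float(self.per_class["n_correct"].sum() / tot) if tot else float("nan")


def score_classes(Z: np.ndarray, labels: pd.Series | dict, k: int) -> ClassReport:
    """Cut the dendrogram into k clusters and score majority-label purity.

    Each cluster is labeled by its majority tissue code (ties break toward
    the code with more samples overall, then lexicographically); a sample
    is correct iff its own code matches its cluster's label.
    """
    labels = pd.Series(labels)
    n = Z.shape[0] + 1
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} clustered samples")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n} samples")
    flat = fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(flat, index=labels.index, name="cluster")

    totals = labels.value_counts()
    cluster_labels: dict[int, str] = {}
    for c in np.unique(flat):
        members = labels[assignments == c]
        counts = members.value_counts()
        top = counts[counts == counts.max()].index
        # deterministic tie-break: larger class overall, then lexicographic
        cluster_labels[int(c)] = sorted(
            top, key=lambda code: (-totals[code], code))[0]

    correct = labels == assignments.map(cluster_labels)
    rows = []
    for code in sorted(labels.unique()):
        mask = labels == code
        rows.append({"tissue_code": code,
                     "n_samples": int(mask.sum()),
                     "n_correct": int((mask & correct).sum())})
    per_class = pd.DataFrame(rows).set_index("tissue_code")
    per_class["accuracy"] = per_class["n_correct"] / per_class["n_samples"]
    return ClassReport(per_class=per_class, cluster_labels=cluster_labels,
                       assignments=assignments,
                       misclassified=list(labels.index[~correct]))


def restrict_matrix_to_signature(m: ExpressionMatrix, sig: Signature
                                 ) -> ExpressionMatrix:
    """Subset to the signature features present in the matrix."""
    present = [f for f in sig.feature_ids if f in m.values.index]
    if not present:
        raise ValueError("no signature feature present in the matrix")
    return m.subset_probes(present)
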