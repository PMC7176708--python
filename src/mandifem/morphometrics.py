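"""Landmark shape analysis and phylogenetic comparative statistics.

Shape is captured by 12 two-dimensional landmarks per mandible.  A
generalized Procrustes analysis (GPA) removes translation, scale and
rotation; principal components of the aligned coordinates describe the
main axes of shape variation.  Two comparative statistics connect shape
to the phylogeny under a Brownian-motion (BM) model of trait evolution:

* ``kmult`` — the multivariate generalisation of Blomberg's K.  It
  compares the observed ratio of mean-centred to phylogenetically
  GLS-transformed sums of squares with its BM expectation computed from
  the phylogenetic covariance matrix C, so K = 1 for data evolved by BM
  on the tree, K < 1 for less phylogenetic signal than BM.
* ``phylo_pls`` — two-block partial least squares on phylogenetically
  transformed data (both blocks premultiplied by C^(-1/2) after GLS mean
  centring), giving the correlation r_PLS of the first pair of singular
  axes of the cross-block covariance.

Both are assessed by permuting specimen rows across tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateResultError, InvalidArgumentError
from .synth import Phylogeny

__all__ = [
    "ShapeData",
    "PcaResult",
    "gpa",
    "procrustes_distance",
    "pca",
    "kmult",
    "phylo_pls",
]


@dataclass
class ShapeData:
    """GPA output: aligned coordinates, centroid sizes, consensus."""

    procrustes_coords: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    ids: list = None

    def flat(self) -> np.ndarray:
        n = self.procrustes_coords.shape[0]
        return self.procrustes_coords.reshape(n, -1)


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, c)
    loadings: np.ndarray  # (c, p)
    explained_variance_fraction: np.ndarray  # (c,)


def _center_scale(config: np.ndarray) -> tuple:
    centroid = config.mean(axis=0)
    centered = config - centroid
    cs = float(np.linalg.norm(centered))
    return centered, cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimising ||x R - target||."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa(
    landmarks: np.ndarray,
    ids=None,
    tol: float = 1e-10,
    max_iter: int = 200,
    tangent_projection: bool = False,
) -> ShapeData:
    """Generalized Procrustes superimposition of landmark configurations.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated (rotation only — reflections are not allowed) to
    the running consensus until the consensus changes by less than
    ``tol``.  ``tangent_projection=True`` additionally projects the
    aligned coordinates orthogonally into the tangent space at the
    consensus; for small shape variation the difference is negligible,
    so the default keeps the raw aligned coordinates.
    """
    x = np.asarray(landmarks, dtype=float)
    if x.ndim != 3 or x.shape[2] != 2:
        raise InvalidArgumentError("landmarks must have shape (n, k, 2)")
    n = x.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least two configurations")
    aligned = np.empty_like(x)
    sizes = np.empty(n)
    for i in range(n):
        centered, cs = _center_scale(x[i])
        if cs < 1e-12:
            name = ids[i] if ids is not None else f"#{i}"
            raise InvalidArgumentError(f"degenerate configuration: {name}")
        aligned[i] = centered / cs
        sizes[i] = cs

    consensus = aligned[0]
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new = aligned.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.linalg.norm(new)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new

    if tangent_projection:
        c = consensus.ravel()
        flat = aligned.reshape(n, -1)
        flat = flat - np.outer(flat @ c - 1.0, c)
        aligned = flat.reshape(n, -1, 2)

    return ShapeData(
        procrustes_coords=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        ids=list(ids) if ids is not None else None,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations."""
    s = gpa(np.stack([np.asarray(a, float), np.asarray(b, float)]))
    return float(np.linalg.norm(s.procrustes_coords[0] - s.procrustes_coords[1]))


def pca(data, n_components: int = None) -> PcaResult:
    """PCA of aligned shape coordinates (or any specimen x variable matrix).

    Eigendecomposition of the covariance of the (column-centred) data via
    SVD; components are ordered by decreasing explained variance and the
    explained fractions over all non-null components sum to 1.  Requesting
    more components than the matrix rank truncates with a warning.
    """
    if isinstance(data, ShapeData):
        x = data.flat()
    else:
        x = np.asarray(data, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise InvalidArgumentError("need at least three specimens")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tolr = s.max() * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tolr))
    if n_components is None:
        n_components = rank
    if n_components > rank:
        import warnings

        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    var = s**2 / (n - 1)
    frac = var[:rank] / var[:rank].sum()
    scores = u[:, :n_components] * s[:n_components]
    return PcaResult(
        scores=scores,
        loadings=vt[:n_components],
        explained_variance_fraction=frac[:n_components],
    )


def _match_tree(data, tree: Phylogeny, labels):
    """Align data rows with tree tips; prune both to the intersection."""
    if isinstance(data, pd.DataFrame):
        labels = list(data.index)
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        if labels is None:
            labels = list(tree.tip_labels)
            if x.shape[0] != len(labels):
                raise InvalidArgumentError(
                    "labels required when data rows do not match tree tips"
                )
        labels = list(labels)
    common = [l for l in labels if l in set(tree.tip_labels)]
    if len(common) < 4:
        raise InvalidArgumentError(
            f"only {len(common)} tips shared between data and tree (>= 4 required)"
        )
    keep = [labels.index(l) for l in common]
    x = x[keep]
    sub = tree if len(common) == tree.n_tips else tree.prune_to(common)
    c, _ = sub.vcv(common)
    return x, c, common


def _gls_residuals(x: np.ndarray, c_inv: np.ndarray) -> np.ndarray:
    ones = np.ones((x.shape[0], 1))
    denom = (ones.T @ c_inv @ ones).item()
    a = (ones.T @ c_inv @ x) / denom  # (1, p) GLS phylogenetic mean
    return x - a


def kmult(
    data,
    tree: Phylogeny,
    labels=None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Multivariate phylogenetic signal K for trait data on a tree.

    K is the ratio of the observed (mean-centred over GLS-transformed)
    sum of squares to its Brownian-motion expectation
    ``(tr C - n / sum(C^-1)) / (n - 1)``; the permutation p-value shuffles
    specimen rows across tips, ``p = (#{K_perm >= K_obs} + 1)/(n_perm+1)``.

    Returns ``{"K": ..., "p": ..., "n": ...}``.
    """
    x, c, common = _match_tree(data, tree, labels)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    c_inv = np.linalg.inv(c)
    ones = np.ones(n)
    denom = float(ones @ c_inv @ ones)
    expected = (np.trace(c) - n / denom) / (n - 1)

    def k_stat(y):
        r = _gls_residuals(y, c_inv)
        num = float(np.sum(r * r))
        den = float(np.sum(r * (c_inv @ r)))
        return (num / den) / expected

    k_obs = k_stat(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if k_stat(x[perm]) >= k_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"K": float(k_obs), "p": float(p), "n": n}


def _inv_sqrt(c: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric C^(-1/2) with an eigenvalue floor for near-singular C."""
    w, v = np.linalg.eigh(c)
    w = np.maximum(w, floor)
    return (v / np.sqrt(w)) @ v.T


def phylo_pls(
    block1,
    block2,
    tree: Phylogeny,
    labels=None,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Phylogenetic two-block partial least squares under Brownian motion.

    Both blocks are GLS mean-centred and premultiplied by C^(-1/2); the
    first singular-vector pair of the between-block cross-covariance
    gives projected scores whose correlation is r_PLS.  The permutation
    test shuffles the rows of the second transformed block.

    Returns ``{"r_pls": ..., "p": ..., "n": ...}``.
    """
    if isinstance(block1, pd.DataFrame) and isinstance(block2, pd.DataFrame):
        common = [l for l in block1.index if l in set(block2.index)]
        block1 = block1.loc[common]
        block2 = block2.loc[common]
        x1, c, tips = _match_tree(block1, tree, None)
        x2 = block2.loc[tips].to_numpy(dtype=float)
    else:
        x1, c, tips = _match_tree(block1, tree, labels)
        x2, _, _ = _match_tree(block2, tree, labels)
    if x1.shape[0] != x2.shape[0]:
        raise InvalidArgumentError("blocks must cover the same specimens")
    n = x1.shape[0]
    c_inv = np.linalg.inv(c)
    p_mat = _inv_sqrt(c)
    z1 = p_mat @ _gls_residuals(x1, c_inv)
    z2 = p_mat @ _gls_residuals(x2, c_inv)

    def r_stat(a, b):
        cross = a.T @ b / (n - 1)
        u, s, vt = np.linalg.svd(cross, full_matrices=False)
        if s.size == 0 or s[0] <= 0:
            raise DegenerateResultError("rank-0 cross-covariance between blocks")
        sa = a @ u[:, 0]
        sb = b @ vt[0]
        denom = np.linalg.norm(sa - sa.mean()) * np.linalg.norm(sb - sb.mean())
        if denom == 0:
            raise DegenerateResultError("degenerate projected scores")
        num = float((sa - sa.mean()) @ (sb - sb.mean()))
        return abs(num) / denom

    r_obs = r_stat(z1, z2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r_stat(z1, z2[perm]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"r_pls": float(r_obs), "p": float(p), "n": n}
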