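"""Metastable decompositions from dominant generator eigenfunctions (PCCA).

Given the values of the K dominant eigenfunctions at a set of evaluation
points (the first being the near-constant stationary eigenfunction), the
inner-simplex construction picks K rows of the eigenfunction matrix as
simplex vertices and maps every point to barycentric-like membership weights
chi_j with sum_j chi_j = 1.  Crisp metastable states are the argmax labels;
points where no membership exceeds a threshold form the transition region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["PCCAResult", "PCCA", "pcca"]


@dataclass
class PCCAResult:
    memberships: np.ndarray     # (n_points, K), row-stochastic in [0, 1]
    K: int
    crisp_labels: np.ndarray    # argmax state per point
    transition_mask: np.ndarray  # True where max membership < threshold
    violation: float            # largest pre-clip box-constraint violation
    transform_matrix: np.ndarray  # (K, K): memberships = eigfuns @ transform


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Indices of K rows of X spanning a maximal simplex (vertex seeking).

    Deterministic: the first vertex is the row farthest from the centroid;
    each following vertex maximizes the residual after orthogonal projection
    onto the span of the directions found so far.
    """
    n, K = X.shape
    Y = X - X.mean(axis=0)
    idx = np.empty(K, dtype=int)
    idx[0] = int(np.argmax(np.einsum("ij,ij->i", Y, Y)))
    Y = Y - Y[idx[0]]
    for k in range(1, K):
        norms = np.einsum("ij,ij->i", Y, Y)
        idx[k] = int(np.argmax(norms))
        v = Y[idx[k]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(
                f"degenerate simplex: eigenfunction {k} adds no independent "
                "direction (collinear vertices)")
        v = v / nv
        Y = Y - np.outer(Y @ v, v)
    return idx


def pcca(eigfun_values: np.ndarray, K: int, threshold: float = 0.6) -> PCCAResult:
    """Membership functions of K metastable states from eigenfunction values.

    ``eigfun_values`` is a (points x >= K) matrix whose first column is the
    (near-)constant eigenfunction.  Negative memberships caused by sampling
    noise are clipped to [0, 1] and rows renormalized; the largest pre-clip
    violation is reported.
    """
    X = np.atleast_2d(np.asarray(eigfun_values, dtype=float))
    if K < 1:
        raise ValueError("K must be at least 1")
    if X.shape[1] < K:
        raise ValueError(f"need at least {K} eigenfunctions, got {X.shape[1]}")
    X = X[:, :K]
    if K == 1:
        memb = np.ones((X.shape[0], 1))
        return PCCAResult(memberships=memb, K=1,
                          crisp_labels=np.zeros(X.shape[0], dtype=int),
                          transition_mask=np.zeros(X.shape[0], dtype=bool),
                          violation=0.0, transform_matrix=np.ones((1, 1)))
    # the stationary eigenfunction is constant up to arbitrary sign/scale:
    # replace it by exactly one so rows of the simplex transform sum to 1
    if abs(np.median(X[:, 0])) < 1e-12:
        raise ValueError("first eigenfunction is not (near-)constant")
    X = X.copy()
    X[:, 0] = 1.0
    verts = _inner_simplex_vertices(X)
    A = X[verts]
    cond = np.linalg.cond(A)
    if cond > 1e12:
        raise ValueError("degenerate simplex: vertex matrix is numerically "
                         f"singular (cond = {cond:.2g})")
    T = np.linalg.solve(A.T, np.eye(K)).T  # inv(A), memberships = X @ inv(A)
    memb = X @ T
    violation = float(max(0.0, -memb.min(), memb.max() - 1.0))
    memb = np.clip(memb, 0.0, 1.0)
    memb /= memb.sum(axis=1, keepdims=True)
    return PCCAResult(memberships=memb, K=K,
                      crisp_labels=np.argmax(memb, axis=1),
                      transition_mask=memb.max(axis=1) < threshold,
                      violation=violation, transform_matrix=T)


class PCCA(BaseEstimator):
    """Inner-simplex PCCA as a scikit-learn style transformer.

    ``fit(X)`` expects eigenfunction values (points x >= n_states, constant
    first); ``transform`` maps new eigenfunction values to memberships with
    the fitted simplex.
    """

    def __init__(self, n_states=2, threshold=0.6):
        self.n_states = n_states
        self.threshold = threshold

    def fit(self, X, y=None):
        res = pcca(X, self.n_states, threshold=self.threshold)
        self.result_ = res
        self.memberships_ = res.memberships
        self.crisp_labels_ = res.crisp_labels
        self.transition_mask_ = res.transition_mask
        self.violation_ = res.violation
        self.transform_matrix_ = res.transform_matrix
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, :self.n_states]
        X = X.copy()
        X[:, 0] = 1.0
        memb = np.clip(X @ self.transform_matrix_, 0.0, 1.0)
        return memb / memb.sum(axis=1, keepdims=True)

    def predict(self, X):
        return np.argmax(self.transform(X), axis=1)
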