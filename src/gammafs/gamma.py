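"""Class-separability score from per-class covariance ellipsoids.

Each class ``k`` of a labeled sample is summarised by the ellipsoid of its
sample covariance matrix: the ellipsoid is centred at the class mean ``mu_k``
and has principal semi-axes of length ``sqrt(lambda_{k,j})`` along the
covariance eigenvectors ``u_{k,j}``.  For a pair of classes the separability
is the algebraic (signed) distance along the mean-mean axis,

    d_{k1,k2} = ( ||mu_k2 - mu_k1|| - (d_{k1,k1k2} + d_{k2,k1k2}) ) / alpha,

where ``d_{k,k1k2}`` is the distance from ``mu_k`` to the border of its own
ellipsoid along that axis and ``alpha = sqrt(sum lambda_1) + sqrt(sum
lambda_2)`` is a scale normalisation.  The total score ("gamma metric") for K
classes is the sum over all unordered class pairs.  Positive values mean the
class clouds are separated along their mean-mean axes; negative values mean
they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateClassError, DegenerateGeometryError, ValidationError

__all__ = [
    "ClassEllipsoid",
    "PairwiseSeparation",
    "SeparationResult",
    "fit_class_ellipsoid",
    "border_distance",
    "pairwise_separation",
    "gamma_metric",
]

#: below this, a squared eigen-coordinate or a mean-mean gap counts as zero
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ClassEllipsoid:
    """Covariance ellipsoid of one class.

    Attributes
    ----------
    center : (p,) ndarray
        Class mean vector.
    eigenvalues : (p,) ndarray
        Eigenvalues of the sample covariance, sorted descending, clipped at 0.
    basis : (p, p) ndarray
        Orthonormal matrix whose columns are the matching eigenvectors.
    n_obs : int
        Number of observations the ellipsoid was fitted on.
    """

    center: np.ndarray
    eigenvalues: np.ndarray
    basis: np.ndarray
    n_obs: int

    @property
    def dim(self) -> int:
        return self.center.shape[0]

    def covariance(self) -> np.ndarray:
        """Reconstruct the covariance matrix ``U diag(lambda) U^T``."""
        return self.basis @ np.diag(self.eigenvalues) @ self.basis.T


@dataclass(frozen=True)
class PairwiseSeparation:
    """Algebraic distance between two class ellipsoids, with its ingredients."""

    distance: float
    mean_gap: float          # ||mu_2 - mu_1||
    alpha: float             # normalization factor
    border_1: float          # distance mean-to-border of class 1 along the axis
    border_2: float
    mu_tilde_1: np.ndarray   # unit mean-mean axis in class 1's eigenbasis
    mu_tilde_2: np.ndarray


@dataclass(frozen=True)
class SeparationResult:
    """Gamma metric of a labeled sample: per-pair detail plus the total."""

    gamma: float
    pairwise: dict = field(default_factory=dict)   # (k1, k2) -> PairwiseSeparation
    ellipsoids: dict = field(default_factory=dict)  # class label -> ClassEllipsoid


def _sign_fix(U: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the first non-negligible component is > 0.

    Makes the eigendecomposition reproducible across LAPACK builds.
    """
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        nz = np.nonzero(np.abs(col) > _ZERO_TOL)[0]
        if nz.size and col[nz[0]] < 0:
            U[:, j] = -col
    return U


def ellipsoid_from_moments(center, covariance, n_obs: int = 0) -> ClassEllipsoid:
    """Build a :class:`ClassEllipsoid` from an explicit mean and covariance.

    Used both by :func:`fit_class_ellipsoid` (sample moments) and for
    population-level scores where the covariance is given analytically.
    """
    center = np.asarray(center, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if cov.shape != (center.size, center.size):
        raise ValidationError(
            f"covariance shape {cov.shape} does not match mean of length {center.size}"
        )
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValidationError("covariance matrix is not symmetric")
    w, U = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        raise ValidationError("covariance matrix is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    order = np.argsort(-w, kind="stable")
    return ClassEllipsoid(
        center=center,
        eigenvalues=w[order],
        basis=_sign_fix(U[:, order]),
        n_obs=int(n_obs),
    )


def fit_class_ellipsoid(points) -> ClassEllipsoid:
    """Fit the covariance ellipsoid of one class.

    Parameters
    ----------
    points : (n_k, p) array_like
        Observations of a single class; ``n_k >= 2`` required.

    Notes
    -----
    The covariance uses the ``n - 1`` denominator.  Round-off negative
    eigenvalues are clamped to zero; eigenvalues are returned descending with
    a deterministic eigenvector sign convention.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValidationError("points must be a 2-D (n, p) array")
    if X.shape[0] < 2:
        raise DegenerateClassError(
            f"need at least 2 observations to fit an ellipsoid, got {X.shape[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValidationError("points contain non-finite values")
    center = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    return ellipsoid_from_moments(center, cov, n_obs=X.shape[0])


def border_distance(ellipsoid: ClassEllipsoid, direction) -> float:
    """Distance from the ellipsoid centre to its border along ``direction``.

    ``direction`` must be a unit vector.  With ``mu~ = U^T direction`` (the
    basis is orthonormal, so the inverse is the transpose) the distance is
    ``1 / sqrt(sum_j mu~_j^2 / lambda_j)``.

    A zero eigenvalue means the ellipsoid has no extent along that principal
    axis: if the direction has a component there the border distance is 0
    (the term is +inf in the limit); a 0/0 term (no component either) is
    skipped, matching the continuous limit ``lambda_j -> 0``.
    """
    d = np.asarray(direction, dtype=float).ravel()
    if d.shape[0] != ellipsoid.dim:
        raise ValidationError("direction dimension does not match ellipsoid")
    nrm = np.linalg.norm(d)
    if abs(nrm - 1.0) > 1e-9:
        raise ValidationError(f"direction must be a unit vector, got norm {nrm}")
    mu_t = ellipsoid.basis.T @ d
    s = 0.0
    for lam, m in zip(ellipsoid.eigenvalues, mu_t):
        if lam <= 0.0:
            if abs(m) > _ZERO_TOL:
                return 0.0
            continue  # 0/0 limit
        s += (m * m) / lam
    if s <= 0.0:
        # direction lies entirely in skipped null directions; the ellipsoid
        # places no constraint there (unreachable for unit directions)
        return float("inf")
    return 1.0 / np.sqrt(s)


def pairwise_separation(e1: ClassEllipsoid, e2: ClassEllipsoid) -> PairwiseSeparation:
    """Signed separability of two class ellipsoids along the mean-mean axis.

    Positive iff the distance between the centres exceeds the sum of the two
    directed border distances.  When the centres coincide the axis is
    undefined; the first eigenvector of ``e1`` is used as a deterministic
    direction (the numerator is then ``<= 0`` for any choice, so the sign is
    unaffected).
    """
    if e1.dim != e2.dim:
        raise ValidationError("ellipsoids have different dimensions")
    alpha = float(np.sqrt(e1.eigenvalues.sum()) + np.sqrt(e2.eigenvalues.sum()))
    if alpha < _ZERO_TOL:
        raise DegenerateGeometryError(
            "both classes are point masses: normalization factor is zero"
        )
    delta = e2.center - e1.center
    gap = float(np.linalg.norm(delta))
    if gap <= _ZERO_TOL:
        u = e1.basis[:, 0]
    else:
        u = delta / gap
    b1 = border_distance(e1, u)
    b2 = border_distance(e2, u)  # border terms are even in the direction sign
    dist = (gap - (b1 + b2)) / alpha
    return PairwiseSeparation(
        distance=float(dist),
        mean_gap=gap,
        alpha=alpha,
        border_1=float(b1),
        border_2=float(b2),
        mu_tilde_1=e1.basis.T @ u,
        mu_tilde_2=e2.basis.T @ u,
    )


def _as_matrix(features, subset):
    """Extract (X, used_names) from a DataFrame or array + optional subset."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        if subset is None:
            subset = names
        subset = list(subset)
        if not subset:
            raise ValidationError("feature subset is empty")
        missing = [f for f in subset if f not in names]
        if missing:
            raise ValidationError(f"unknown feature name(s): {missing}")
        return features.loc[:, subset].to_numpy(dtype=float), subset
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = [f"f{j}" for j in range(X.shape[1])]
    if subset is None:
        return X, names
    subset = list(subset)
    if not subset:
        raise ValidationError("feature subset is empty")
    try:
        idx = [names.index(f) for f in subset]
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc
    return X[:, idx], subset


def gamma_metric(features, labels, subset=None) -> SeparationResult:
    """Gamma metric of a labeled sample restricted to a feature subset.

    Parameters
    ----------
    features : DataFrame or (n, p) array_like
        Feature table.  With a DataFrame, ``subset`` selects columns by name;
        with an array, positional names ``f0..f{p-1}`` apply.
    labels : (n,) array_like
        Class labels; at least two distinct classes, each with >= 2 rows.
    subset : sequence of str, optional
        Feature names to restrict to (default: all).

    Returns
    -------
    SeparationResult
        Total gamma, the per-pair breakdown, and the fitted ellipsoids.
    """
    X, used = _as_matrix(features, subset)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("labels length does not match feature rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    ellipsoids = {}
    for k in classes:
        pts = X[y == k]
        if pts.shape[0] < 2:
            raise DegenerateClassError(f"class {k!r} has fewer than 2 observations")
        ellipsoids[k] = fit_class_ellipsoid(pts)
    pairwise = {}
    total = 0.0
    for i in range(classes.size):
        for j in range(i + 1, classes.size):
            k1, k2 = classes[i], classes[j]
            sep = pairwise_separation(ellipsoids[k1], ellipsoids[k2])
            pairwise[(k1, k2)] = sep
            total += sep.distance
    return SeparationResult(gamma=float(total), pairwise=pairwise, ellipsoids=ellipsoids)
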