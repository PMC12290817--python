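"""Direct linear discriminant analysis (DLDA) subspaces.

Trial responses live in an Ndim = Nt * Nvox dimensional space with Ndim in
the hundreds to thousands while only a few thousand trials are available, so
the classical Fisher LDA generalized eigenproblem is ill-posed.  Direct LDA
sidesteps it by (1) keeping only the (at most kappa-1 dimensional) column
space of the between-class scatter and whitening it there, then (2) whitening
the within-class scatter inside that low-dimensional space.  The resulting
(kappa-1)-dimensional subspace simultaneously maximizes between-class and
minimizes within-class variance.

Each retained dimension is finally standardized to unit variance on the
training data, so that Euclidean distances in the subspace are standardized
(Mahalanobis-like) distances and the normalized amplitude/distance regime
<a> ~ 1, <d> ~ 1.40 holds by construction for unrelated responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiscriminantSubspace", "VarianceReport", "fit_dlda", "project", "variance_report"]

#: rank tolerance for the between-class scatter, relative to its leading eigenvalue
BETWEEN_RANK_TOL = 1e-10
#: ridge added to within-class eigenvalues, relative to their mean
WITHIN_REG = 1e-6


@dataclass
class DiscriminantSubspace:
    """A fitted (kappa-1)-dimensional discriminative projection.

    ``basis`` maps Ndim -> n_components (columns are projection directions,
    between- and within-class whitening included); ``scaling`` holds the
    final per-dimension standardization factors.  ``class_means`` are the
    training class centroids in standardized subspace coordinates.
    ``fitted_on`` is an arbitrary identifier recorded for leakage audits.
    """

    basis: np.ndarray
    scaling: np.ndarray
    kappa: int
    classes: np.ndarray
    class_means: np.ndarray
    offset: np.ndarray = field(default_factory=lambda: np.empty(0))
    fitted_on: str = ""

    @property
    def n_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


@dataclass
class VarianceReport:
    """PCA-comparison summary for a fitted subspace on given data."""

    pca_frac_14: float
    subspace_overlap: float
    per_dim_frac: np.ndarray = field(default_factory=lambda: np.empty(0))


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (determinism)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def fit_dlda(
    X: np.ndarray,
    labels: np.ndarray,
    kappa: int | None = None,
    fitted_on: str = "",
) -> DiscriminantSubspace:
    """Fit the direct-LDA discriminative subspace.

    Parameters
    ----------
    X:
        (n_trials, Ndim) training responses (recurring trials only).
    labels:
        Object id per trial; every class needs at least two trials.
    kappa:
        Expected class count (defaults to the number of distinct labels).

    Notes
    -----
    Between-class scatter is eigendecomposed via the SVD of the weighted,
    centered class-mean matrix, which never materializes an Ndim x Ndim
    matrix.  Eigenvectors are ordered by descending eigenvalue with a
    deterministic sign convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(labels):
        raise ValueError("X must be (n_trials, Ndim) aligned with labels")
    classes, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    k = len(classes)
    if kappa is None:
        kappa = k
    elif k != kappa:
        raise ValueError(f"found {k} classes, expected kappa={kappa}")
    if np.any(counts < 2):
        bad = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 trials: {bad}")
    n, n_dim = X.shape
    if n_dim < kappa - 1:
        raise ValueError("Ndim must be at least kappa - 1")

    grand = X.mean(axis=0)
    class_means = np.vstack([X[inv == c].mean(axis=0) for c in range(k)])

    # between-class scatter S_b = M^T M with M the weighted centered means
    M = np.sqrt(counts / n)[:, None] * (class_means - grand)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig_b = s**2
    if eig_b[0] <= 0:
        raise ValueError("degenerate between-class scatter: all class means identical")
    keep = eig_b > BETWEEN_RANK_TOL * eig_b[0]
    keep &= np.arange(len(eig_b)) < kappa - 1
    Vb = Vt[keep].T                              # Ndim x m, m <= kappa-1
    # whiten between-class scatter
    Wb = Vb / s[keep]

    # within-class scatter in the whitened between space (m x m)
    Z = (X - class_means[inv]) @ Wb
    Sw = Z.T @ Z / n
    eig_w, Vw = np.linalg.eigh(Sw)
    eig_w = eig_w[::-1]
    Vw = Vw[:, ::-1]
    reg = WITHIN_REG * max(eig_w.mean(), np.finfo(float).tiny)
    Ww = Vw / np.sqrt(eig_w + reg)

    basis = _fix_signs(Wb @ Ww)

    # standardize each retained dimension to unit variance on training data
    Y = (X - grand) @ basis
    sd = Y.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scaling = 1.0 / sd

    return DiscriminantSubspace(
        basis=basis,
        scaling=scaling,
        kappa=kappa,
        classes=classes,
        class_means=(class_means - grand) @ basis * scaling,
        offset=grand,
        fitted_on=fitted_on,
    )


def project(subspace: DiscriminantSubspace, X: np.ndarray) -> np.ndarray:
    """Project responses into standardized subspace coordinates.

    Works for any trials — training, held-out, or singular-object responses
    (the subspace is generic and does not require class labels).
    """
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[None, :]
    if X.shape[1] != subspace.n_dim:
        raise ValueError(
            f"X has {X.shape[1]} columns, subspace was fit on {subspace.n_dim}"
        )
    offset = subspace.offset if subspace.offset.size else np.zeros(subspace.n_dim)
    Y = (X - offset) @ subspace.basis * subspace.scaling
    return Y[0] if squeeze else Y


def variance_report(
    subspace: DiscriminantSubspace, X: np.ndarray, labels: np.ndarray | None = None
) -> VarianceReport:
    """Compare the discriminant subspace with the leading principal components.

    Reports, on the given data: the fraction of total variance captured by
    the first kappa-1 principal components; the fraction of subspace variance
    lying within the span of those components; and the distribution of
    variance over subspace dimensions.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    n_pc = subspace.n_components

    # PCA via SVD; variance fractions
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    pca_frac = float(np.sum(s[:n_pc] ** 2) / total_var)

    # subspace variance and its overlap with the leading-PC span
    Y = Xc @ subspace.basis            # unscaled subspace coordinates
    sub_var = float(np.sum(Y**2))
    P = Vt[:n_pc]                      # PC basis rows
    # orthonormalize subspace basis to measure overlap of the projected data
    Q, _ = np.linalg.qr(subspace.basis)
    Yq = Xc @ Q
    Yq_in_pc = (Xc @ P.T) @ (P @ Q)
    overlap = float(np.sum(Yq_in_pc**2) / max(np.sum(Yq**2), np.finfo(float).tiny))

    Ys = Y * subspace.scaling
    dim_var = np.sum(Ys**2, axis=0)
    per_dim = dim_var / dim_var.sum()
    return VarianceReport(
        pca_frac_14=pca_frac, subspace_overlap=overlap, per_dim_frac=per_dim
    )
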