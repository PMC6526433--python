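"""Eigen-analysis of superpixels and distance-from-average saliency.

Each equalized superpixel is an M-vector; the set of N superpixels is
summarized by its average S_a and the covariance

    C_s = 1/(N+1) * Y_c @ Y_c.T,      Y_c = S - S_a 1^T,

whose eigenvectors ("eigensuperpixels") are the principal modes of
superpixel intensity variation. The deliberately unusual 1/(N+1) factor
is retained from the method's formulation: every quantity consumed
downstream (eigenvector directions, cumulative variance fractions, and
hence K) is invariant to a positive rescaling of C_s, so the choice of
normalization is immaterial and fidelity costs nothing.

The top K components carrying at least ``variance_fraction`` (default
95%) of the total variance define the principal-component coordinate
system; each centered superpixel is projected into it and scored by its
L1 distance from the origin (= from the average superpixel). Tumor
superpixels, whose internal statistics differ sharply from the bulk,
land far from the origin.

Numerically the eigenpairs come from an SVD of the centered matrix
rather than forming C_s, which is better conditioned and bounds the
number of eigenpairs by rank <= min(M, N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equalize import SuperpixelMatrix
from .errors import DegenerateInputError, ValidationError

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class PCAModel:
    """Fitted eigen-model of a superpixel matrix.

    Attributes
    ----------
    S_a : (M,) average superpixel.
    C_s : (M, M) covariance with the 1/(N+1) normalization.
    P : (M, R) orthonormal eigensuperpixels, R = min(M, N) retained pairs.
    eigenvalues : (R,) non-increasing, clamped at 0.
    total_variance : sum of eigenvalues (= trace of C_s).
    K : number of leading components reaching the variance target.
    variance_fraction : cumulative fraction actually captured at K.
    """

    S_a: np.ndarray = field(repr=False)
    C_s: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    total_variance: float
    K: int
    variance_fraction: float


def average_superpixel(S: SuperpixelMatrix | np.ndarray) -> np.ndarray:
    """Column mean of the superpixel matrix: the average superpixel S_a."""
    mat = S.S if isinstance(S, SuperpixelMatrix) else np.asarray(S, dtype=np.float64)
    return mat.mean(axis=1)


def covariance(S: SuperpixelMatrix | np.ndarray, S_a: np.ndarray) -> np.ndarray:
    """Superpixel covariance C_s = 1/(N+1) * Y_c Y_c^T (columns centered by S_a)."""
    mat = S.S if isinstance(S, SuperpixelMatrix) else np.asarray(S, dtype=np.float64)
    S_a = np.asarray(S_a, dtype=np.float64)
    if mat.shape[0] != S_a.shape[0]:
        raise ValidationError(
            f"average length {S_a.shape[0]} does not match matrix rows {mat.shape[0]}"
        )
    Yc = mat - S_a[:, None]
    n = mat.shape[1]
    return (Yc @ Yc.T) / (n + 1)


def _fix_signs(P: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector positive."""
    idx = np.argmax(np.abs(P), axis=0)
    signs = np.sign(P[idx, np.arange(P.shape[1])])
    signs[signs == 0] = 1.0
    return P * signs


def eigendecompose(C_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a symmetric PSD matrix, sorted by descending eigenvalue.

    Eigenvalues below zero (numerical noise) are clamped to 0; each
    eigenvector's largest-magnitude entry is made positive so the
    decomposition is deterministic.
    """
    C_s = np.asarray(C_s, dtype=np.float64)
    scale = max(1.0, float(np.abs(C_s).max()))
    if not np.allclose(C_s, C_s.T, atol=_SYM_TOL * scale):
        raise ValidationError("covariance matrix is not symmetric within tolerance")
    vals, vecs = np.linalg.eigh(C_s)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    return _fix_signs(vecs), vals


def select_components(eigenvalues: np.ndarray, fraction: float = 0.95) -> int:
    """Smallest K whose leading eigenvalues reach ``fraction`` of total variance."""
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if np.any(np.diff(lam) > 1e-12 * max(1.0, float(lam[0]) if len(lam) else 1.0)):
        raise ValidationError("eigenvalues must be sorted non-increasing")
    V = float(lam.sum())
    if V <= 0.0:
        raise DegenerateInputError(
            "total variance is zero (constant image): segmentation is "
            "undefined — every superpixel is identical to the average"
        )
    cum = np.cumsum(lam) / V
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def fit_pca(S: SuperpixelMatrix, variance_fraction: float = 0.95) -> PCAModel:
    """Fit the eigen-model via SVD of the centered superpixel matrix."""
    S_a = average_superpixel(S)
    Yc = S.S - S_a[:, None]
    U, sv, _ = np.linalg.svd(Yc, full_matrices=False)
    lam = sv**2 / (S.N + 1)
    U = _fix_signs(U)
    K = select_components(lam, variance_fraction)
    total = float(lam.sum())
    frac = float(lam[:K].sum() / total)
    return PCAModel(
        S_a=S_a,
        C_s=covariance(S, S_a),
        P=U,
        eigenvalues=lam,
        total_variance=total,
        K=K,
        variance_fraction=frac,
    )


def project(S: SuperpixelMatrix | np.ndarray, model: PCAModel) -> np.ndarray:
    """Project centered superpixels onto the top K eigensuperpixels.

    Returns the K x N coordinate matrix; the average superpixel maps to
    the origin by construction.
    """
    mat = S.S if isinstance(S, SuperpixelMatrix) else np.asarray(S, dtype=np.float64)
    if mat.shape[0] != model.S_a.shape[0]:
        raise ValidationError("matrix dimensionality does not match the fitted model")
    Yc = mat - model.S_a[:, None]
    return model.P[:, : model.K].T @ Yc


def l1_distances(Y_proj: np.ndarray) -> np.ndarray:
    """Per-superpixel L1 norm in principal-component coordinates."""
    Y_proj = np.asarray(Y_proj, dtype=np.float64)
    if not np.all(np.isfinite(Y_proj)):
        raise ValidationError("projected coordinates contain non-finite values")
    return np.abs(Y_proj).sum(axis=0)


def scatter_coordinates(Y_proj: np.ndarray) -> np.ndarray:
    """(N+1) x K point cloud for the PC scatter plot.

    One row per superpixel plus a final all-zero row for the average
    superpixel, which sits at the origin of the PC coordinate system.
    """
    Y_proj = np.asarray(Y_proj, dtype=np.float64)
    return np.vstack([Y_proj.T, np.zeros((1, Y_proj.shape[0]))])
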