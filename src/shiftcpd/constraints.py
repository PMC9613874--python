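"""Spatial constraints for complex-valued shared spatial maps.

In complex-valued fMRI, BOLD-related voxels carry small phase values (the
task-induced phase change is below ~pi/9), while noise voxels spread over
the full (-pi, pi] range.  Each estimated spatial map also carries an
arbitrary global phase rotation (the usual component indeterminacy), so
before any phase-based operation the rotation is resolved by *phase
de-ambiguity*: pick the rotation angle on a uniform grid that maximizes the
squared correlation magnitude between the small-phase-masked rotated map
and its own magnitude image.

With phases aligned, a smoothed-l0 penalty ``1 - exp(-|s|^2 / 2 sigma^2)``
is applied to the voxels with the largest third of absolute phases,
shrinking large-phase (noise) voxels toward zero while leaving small-phase
voxels untouched; ``sigma`` is annealed geometrically across iterations.
A separate orthonormality projection maps S to the nearest matrix with
orthonormal columns (polar factor), suppressing crosstalk between maps.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import scipy.linalg

from .tensor_core import pinv

logger = logging.getLogger(__name__)

__all__ = [
    "phase_mask",
    "phase_deambiguate",
    "theta_threshold",
    "sparsity_penalty",
    "sparsity_gradient",
    "sparse_update_S",
    "orthonormalize",
]

#: half-width of the small-phase band of BOLD-related voxels (radians)
PHASE_BAND = np.pi / 4


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - angles, 2 * np.pi)


def phase_mask(s: np.ndarray) -> np.ndarray:
    """Binary mask of voxels with phase in [-pi/4, pi/4] (BOLD band)."""
    return (np.abs(np.angle(s)) <= PHASE_BAND).astype(np.int8)


def phase_deambiguate(
    s: np.ndarray, n_angles: int = 128
) -> tuple[float, np.ndarray]:
    """Resolve the global phase rotation of one spatial map.

    Evaluates the candidate angles ``theta = 2 pi k / n_angles`` for
    ``k = 1..n_angles`` and returns the angle maximizing the squared
    magnitude of the Pearson correlation between the rotated, small-phase
    masked map and the magnitude image ``|s|``, together with the rotated
    map ``exp(i theta) * s``.

    The global factor ``exp(i theta)`` cancels in the correlation
    *magnitude*, so only the masked voxel set varies with theta: the mask
    at angle theta selects the voxels with original phase inside the
    circular interval ``[-pi/4 - theta, pi/4 - theta]``.  The scores are
    therefore computed from prefix sums over the phase-sorted map, one
    O(1) window query per candidate angle.  Exact score ties are broken
    toward the largest angle, so an already-aligned map selects the
    identity rotation ``theta = 2 pi``.  A constant-magnitude map has an
    undefined correlation: the identity rotation is returned and a
    warning logged.
    """
    s = np.asarray(s, dtype=np.complex128)
    V = s.size
    y = np.abs(s)
    var_y = float(np.sum((y - y.mean()) ** 2))
    if var_y == 0.0:
        logger.warning("phase de-ambiguity on a constant-magnitude map; identity")
        return 2 * np.pi, s.copy()

    thetas = 2 * np.pi * np.arange(1, n_angles + 1) / n_angles
    phi = np.angle(s)
    order = np.argsort(phi, kind="stable")
    phi_sorted = phi[order]
    s_sorted = s[order]
    y_sorted = y[order]

    def prefix(arr):
        out = np.zeros(V + 1, dtype=arr.dtype)
        np.cumsum(arr, out=out[1:])
        return out

    P_s = prefix(s_sorted)
    P_csy = prefix(np.conj(s_sorted) * y_sorted)
    P_y2 = prefix(y_sorted * y_sorted)

    lo = _wrap(-PHASE_BAND - thetas)
    hi = _wrap(PHASE_BAND - thetas)
    i_lo = np.searchsorted(phi_sorted, lo, side="left")
    i_hi = np.searchsorted(phi_sorted, hi, side="right")

    def window(P):
        plain = P[i_hi] - P[i_lo]
        wrapped = (P[V] - P[i_lo]) + P[i_hi]
        return np.where(lo <= hi, plain, wrapped)

    sum_s = window(P_s)
    sum_csy = window(P_csy)
    sum_s2 = np.real(window(P_y2))

    ybar = y.mean()
    num = sum_csy - np.conj(sum_s) * ybar
    var_x = sum_s2 - np.abs(sum_s) ** 2 / V
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(var_x > 0, np.abs(num) ** 2 / (var_x * var_y), 0.0)

    # ties -> largest angle (argmax on the reversed array)
    idx = n_angles - 1 - int(np.argmax(scores[::-1]))
    theta_hat = float(thetas[idx])
    return theta_hat, np.exp(1j * theta_hat) * s


def _phase_deambiguate_direct(
    s: np.ndarray, n_angles: int = 128
) -> tuple[float, np.ndarray]:
    """Reference implementation of :func:`phase_deambiguate` that forms the
    dense angle-by-voxel mask matrix; used as a cross-check in tests."""
    s = np.asarray(s, dtype=np.complex128)
    V = s.size
    y = np.abs(s)
    var_y = float(np.sum((y - y.mean()) ** 2))
    if var_y == 0.0:
        return 2 * np.pi, s.copy()
    thetas = 2 * np.pi * np.arange(1, n_angles + 1) / n_angles
    phi = np.angle(s)
    masks = (np.abs(_wrap(phi[None, :] + thetas[:, None])) <= PHASE_BAND)
    masks = masks.astype(np.float64)
    ybar = y.mean()
    sum_s = masks @ s
    num = masks @ (np.conj(s) * y) - np.conj(sum_s) * ybar
    var_x = masks @ (y * y) - np.abs(sum_s) ** 2 / V
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(var_x > 0, np.abs(num) ** 2 / (var_x * var_y), 0.0)
    idx = n_angles - 1 - int(np.argmax(scores[::-1]))
    theta_hat = float(thetas[idx])
    return theta_hat, np.exp(1j * theta_hat) * s


def theta_threshold(s: np.ndarray) -> float:
    """Phase threshold segmenting the largest third of absolute phases.

    Returns the ``ceil(V/3)``-th largest value of ``|angle(s)|``, so that
    exactly the top third (by count, boundary inclusive) of voxels satisfy
    ``|angle| >= threshold``.
    """
    a = np.abs(np.angle(np.asarray(s)))
    V = a.size
    m = math.ceil(V / 3)
    return float(np.partition(a, V - m)[V - m])


def _penalized(S: np.ndarray, theta_th: np.ndarray) -> np.ndarray:
    """Boolean (V, R) support of the sparsity penalty: |phase| >= threshold."""
    theta_th = np.atleast_1d(theta_th)
    return np.abs(np.angle(S)) >= theta_th[None, :]


def sparsity_penalty(S: np.ndarray, sigma: float, theta_th) -> float:
    """Smoothed-l0 phase-sparsity penalty, averaged over voxels.

    Large-phase voxels contribute ``1 - exp(-|s|^2 / 2 sigma^2)``; voxels
    inside the small-phase band contribute the constant 1 (reported but
    gradient-free).  The sum is divided by V.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    S = np.atleast_2d(np.asarray(S, dtype=np.complex128).T).T
    pen = _penalized(S, theta_th)
    f = np.where(pen, 1.0 - np.exp(-np.abs(S) ** 2 / (2 * sigma**2)), 1.0)
    return float(f.sum() / S.shape[0])


def sparsity_gradient(S: np.ndarray, sigma: float, theta_th) -> np.ndarray:
    """Per-voxel gradient of the smoothed-l0 penalty w.r.t. the map entries.

    ``delta = exp(i angle(s)) * (|s| / sigma^2) * exp(-|s|^2 / 2 sigma^2)``
    on the penalized (large-phase) voxels and exactly 0 elsewhere; the
    phasor directs the step along each voxel's own phase so the penalty
    shrinks the magnitude.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    S = np.atleast_2d(np.asarray(S, dtype=np.complex128).T).T
    pen = _penalized(S, theta_th)
    mag = np.abs(S)
    radial = (mag / sigma**2) * np.exp(-(mag**2) / (2 * sigma**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        phasor = np.where(mag > 0, S / mag, 0.0)
    return np.where(pen, phasor * radial, 0.0)


def sparse_update_S(
    X1: np.ndarray, M: np.ndarray, dS: np.ndarray, lam: float
) -> np.ndarray:
    """Sparsity-constrained rank-R LS update of the shared spatial maps.

    ``S <- X1 @ pinv(M).T - lam * dS @ inv(M^H M)``: the plain LS estimate
    minus the penalty gradient preconditioned by the mixing-matrix Gram
    metric (a steepest-descent step in the LS geometry).  An ill-conditioned
    Gram matrix falls back to a tolerance pseudoinverse with a warning.
    """
    S_ls = X1 @ pinv(M, "mixing matrix M").T
    if lam == 0.0 or not np.any(dS):
        return S_ls
    G = M.conj().T @ M
    return S_ls - lam * dS @ pinv(G, "mixing Gram matrix M^H M")


def orthonormalize(S: np.ndarray) -> np.ndarray:
    """Project S onto the nearest matrix with orthonormal columns.

    Economy SVD ``S = U Sigma D^H`` followed by ``S <- U D^H`` (the polar
    factor), the Frobenius-closest semi-unitary matrix.  Rank deficiency is
    flagged: the smallest singular directions are then filled in by the
    SVD's arbitrary-but-orthonormal basis vectors.
    """
    S = np.asarray(S, dtype=np.complex128)
    U, sv, Dh = scipy.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    if sv.size and sv[-1] <= tol:
        logger.warning(
            "rank-deficient S in orthonormalization (%d small singular values)",
            int(np.sum(sv <= tol)),
        )
    return U @ Dh
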