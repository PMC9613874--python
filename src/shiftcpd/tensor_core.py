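"""Complex three-way tensor algebra for multi-subject fMRI data.

A multi-subject complex-valued fMRI dataset is viewed as a three-way tensor
``X`` of shape ``(V, J, K)`` — in-brain voxels x time points x subjects.
The canonical polyadic decomposition (CPD, also called PARAFAC) expresses
``X`` as a sum of R rank-1 terms ``s_r o b_r o c_r`` whose factors are the
shared spatial maps (SMs, columns of ``S``), shared time courses (TCs,
columns of ``B``) and subject-specific intensities (columns of ``C``).

This module provides matricization (unfolding/folding), the Khatri-Rao
product, the classical alternating-least-squares (ALS) CPD updates, model
reconstruction and fit metrics.  The mode-1 column ordering is fixed so that
``unfold(sum_r s_r o b_r o c_r, 1) == S @ khatri_rao(C, B).T`` holds exactly,
with the time index varying fastest and the subject index slowest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FmriTensor",
    "FactorSet",
    "FitReport",
    "unfold",
    "fold",
    "khatri_rao",
    "pinv",
    "als_update",
    "run_als",
    "reconstruct",
    "squared_error",
]


@dataclass
class FmriTensor:
    """Three-way complex tensor (voxels x time x subjects).

    Parameters
    ----------
    data : ndarray, shape (V, J, K), complex
        Tensor entries ``x[v, j, k]``; time points are ``tr`` seconds apart.
    tr : float, optional
        Repetition time in seconds (metadata only).
    voxel_coords : ndarray, shape (V, d), optional
        Grid indices of each voxel, for writing maps back to volumes.
    """

    data: np.ndarray
    tr: float = 2.0
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-way tensor, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tensor entries must be finite")
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords)
            if self.voxel_coords.shape[0] != self.data.shape[0]:
                raise ValueError("voxel_coords must have one row per voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[2]


@dataclass
class FactorSet:
    """CPD loading matrices: shared SMs, shared TCs, subject intensities.

    ``delays`` holds the subject-specific integer time delays ``tau[k, r]``
    of the shift-invariant model; it is ``None`` for a plain CPD.
    """

    S: np.ndarray  # (V, R) complex, shared spatial maps
    B: np.ndarray  # (J, R) complex, shared time courses
    C: np.ndarray  # (K, R) complex, subject intensities
    delays: np.ndarray | None = None  # (K, R) int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.complex128)
        self.B = np.asarray(self.B, dtype=np.complex128)
        self.C = np.asarray(self.C, dtype=np.complex128)
        R = self.S.shape[1]
        if self.B.shape[1] != R or self.C.shape[1] != R:
            raise ValueError("S, B, C must have the same number of columns")
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=np.int64)
            if self.delays.shape != self.C.shape:
                raise ValueError("delays must be K x R like C")

    @property
    def rank(self) -> int:
        return self.S.shape[1]

    def copy(self) -> "FactorSet":
        return FactorSet(
            self.S.copy(),
            self.B.copy(),
            self.C.copy(),
            None if self.delays is None else self.delays.copy(),
        )


@dataclass
class FitReport:
    """Per-iteration cost trace and convergence summary of a solver run."""

    cost_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    final_fit: float = 0.0
    #: mean *unsquared* residual modulus (the printed-norm variant of the
    #: cost), evaluated once at the end of the run.
    final_fit_abs: float | None = None
    notes: str = ""


# ---------------------------------------------------------------------------
# matricization


def unfold(X: FmriTensor | np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization of a (V, J, K) tensor.

    Column orderings are fixed so the CPD factor identities hold with the
    Khatri-Rao convention of :func:`khatri_rao` (second argument's index
    fastest):

    - mode 1: (V, J*K), column ``k*J + j``  -> ``S @ khatri_rao(C, B).T``
    - mode 2: (J, V*K), column ``k*V + v``  -> ``B @ khatri_rao(C, S).T``
    - mode 3: (K, V*J), column ``j*V + v``  -> ``C @ khatri_rao(B, S).T``
    """
    data = X.data if isinstance(X, FmriTensor) else np.asarray(X)
    V, J, K = data.shape
    if mode == 1:
        return data.transpose(0, 2, 1).reshape(V, K * J)
    if mode == 2:
        return data.transpose(1, 2, 0).reshape(J, K * V)
    if mode == 3:
        return data.transpose(2, 1, 0).reshape(K, J * V)
    raise ValueError(f"mode must be 1, 2 or 3, got {mode}")


def fold(mat: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: restore the (V, J, K) tensor."""
    V, J, K = shape
    if mode == 1:
        return mat.reshape(V, K, J).transpose(0, 2, 1)
    if mode == 2:
        return mat.reshape(J, K, V).transpose(2, 0, 1)
    if mode == 3:
        return mat.reshape(K, J, V).transpose(2, 1, 0)
    raise ValueError(f"mode must be 1, 2 or 3, got {mode}")


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Columnwise Kronecker product: column r is ``kron(A[:, r], B[:, r])``.

    For ``khatri_rao(C, B)`` with C (K, R) and B (J, R), row block k
    (rows ``k*J .. (k+1)*J - 1``) of column r equals ``B[:, r] * C[k, r]`` —
    the aggregating-mixing-matrix layout with all delays zero.
    """
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"column counts must agree, got {A.shape[1]} and {B.shape[1]}"
        )
    return (A[:, None, :] * B[None, :, :]).reshape(A.shape[0] * B.shape[0], -1)


# ---------------------------------------------------------------------------
# least squares


def pinv(A: np.ndarray, warn_label: str = "matrix") -> np.ndarray:
    """Moore-Penrose pseudoinverse via SVD with cutoff max(dims)*eps*sigma_max.

    Logs a warning when the numerical rank falls short of the column count.
    """
    A = np.asarray(A)
    U, s, Vh = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros_like(A.conj().T)
    tol = max(A.shape) * np.finfo(s.dtype).eps * s[0]
    rank = int(np.count_nonzero(s > tol))
    if rank < min(A.shape):
        logger.warning(
            "rank-deficient %s (rank %d < %d); tolerance pseudoinverse applied",
            warn_label, rank, min(A.shape),
        )
    inv_s = np.zeros_like(s)
    inv_s[:rank] = 1.0 / s[:rank]
    return (Vh.conj().T * inv_s) @ U.conj().T


def als_update(X: FmriTensor | np.ndarray, F: FactorSet, mode: int) -> FactorSet:
    """One ALS half-step: replace the mode's factor by its LS solution.

    The updated factor is ``X_(n) @ pinv(KR).T`` with KR the Khatri-Rao
    product of the other two factors; the transpose is the plain
    (non-conjugating) transpose — conjugation lives inside the
    pseudoinverse — so the CPD identity ``X_(1) = S @ (C (kr) B).T`` is
    solved exactly in the least-squares sense.
    """
    out = F.copy()
    Xn = unfold(X, mode)
    if mode == 1:
        KR = khatri_rao(F.C, F.B)
        out.S = Xn @ pinv(KR, "khatri_rao(C, B)").T
    elif mode == 2:
        KR = khatri_rao(F.C, F.S)
        out.B = Xn @ pinv(KR, "khatri_rao(C, S)").T
    elif mode == 3:
        KR = khatri_rao(F.B, F.S)
        out.C = Xn @ pinv(KR, "khatri_rao(B, S)").T
    else:
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    return out


def run_als(
    X: FmriTensor | np.ndarray,
    R: int,
    n_iter: int = 200,
    tol: float = 1e-6,
    rng: np.random.Generator | int | None = None,
    init: FactorSet | None = None,
) -> tuple[FactorSet, FitReport]:
    """Baseline rank-R CPD by classical ALS sweeps (modes 1, 2, 3).

    Stops when the relative change of the mean-squared error between sweeps
    drops below ``tol``.  ``init`` overrides the random initialization.
    """
    data = X.data if isinstance(X, FmriTensor) else np.asarray(X)
    V, J, K = data.shape
    if init is None:
        rng = np.random.default_rng(rng)
        F = FactorSet(
            S=_crandn(rng, (V, R)),
            B=_crandn(rng, (J, R)),
            C=_crandn(rng, (K, R)),
        )
    else:
        F = init.copy()
    report = FitReport()
    prev = np.inf
    for it in range(n_iter):
        for mode in (1, 2, 3):
            F = als_update(data, F, mode)
        err = squared_error(data, F)
        report.cost_trace.append(err)
        report.n_iter = it + 1
        if np.isfinite(prev) and prev > 0 and abs(prev - err) / prev < tol:
            report.converged = True
            prev = err
            break
        prev = err
    report.final_fit = float(prev)
    return F, report


def _crandn(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Complex array with i.i.d. standard-normal real and imaginary parts."""
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


# ---------------------------------------------------------------------------
# model evaluation


def reconstruct(F: FactorSet, shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Evaluate the CPD model ``sum_r s_r o b_r o c_r`` as a dense tensor.

    With delays present, component r of subject k uses the cyclically
    shifted time course ``shift(b_r, tau[k, r])`` (shift-invariant model).
    """
    V, J, K = F.S.shape[0], F.B.shape[0], F.C.shape[0]
    if F.delays is None:
        M = khatri_rao(F.C, F.B)  # (K*J, R)
        return fold(F.S @ M.T, 1, (V, J, K))
    from .shift_invariant import cyclic_shift

    X = np.zeros((V, J, K), dtype=np.complex128)
    for r in range(F.rank):
        for k in range(K):
            bk = cyclic_shift(F.B[:, r], int(F.delays[k, r]))
            X[:, :, k] += np.outer(F.S[:, r], bk) * F.C[k, r]
    return X


def squared_error(X: FmriTensor | np.ndarray, F: FactorSet) -> float:
    """Mean squared residual modulus, ``sum |x - model|^2 / (V*J*K)``."""
    data = X.data if isinstance(X, FmriTensor) else np.asarray(X)
    resid = data - reconstruct(F, data.shape)
    return float(np.mean(np.abs(resid) ** 2))
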