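"""Alternating rank-R and rank-1 least squares (unconstrained).

Instead of the three full rank-R ALS updates of classical CPD, this update
rule solves a rank-R least-squares problem only for the spatial maps ``S``
and for the aggregating mixing matrix ``M = C (kr) B`` (JK x R), and then
fits each component's time course and subject intensities by a *rank-1*
least squares on the J x K matrix reshaped from the corresponding column of
``M``.  Because each column of ``M`` is fit by a free rank-1 matrix plus
crosstalk, the rule relaxes the strict trilinear CPD coupling and tolerates
data that only approximately follow the model.
"""

from __future__ import annotations

import logging

import numpy as np

from .tensor_core import FactorSet, FitReport, FmriTensor, pinv

logger = logging.getLogger(__name__)

__all__ = [
    "MixingMatrix",
    "update_mixing",
    "column_to_rank1",
    "rank1_ls",
    "run_arr_r1ls",
]


class MixingMatrix:
    """Aggregating mixing matrix ``M`` (JK x R) with its reshape geometry.

    Column r stacks, subject block by subject block, the component's time
    course scaled by that subject's intensity; rows ``k*J .. (k+1)*J - 1``
    form block k.
    """

    def __init__(self, M: np.ndarray, J: int, K: int):
        M = np.asarray(M, dtype=np.complex128)
        if M.shape[0] != J * K:
            raise ValueError(f"M has {M.shape[0]} rows, expected J*K = {J * K}")
        self.M = M
        self.J = J
        self.K = K

    @property
    def rank(self) -> int:
        return self.M.shape[1]

    def component(self, r: int) -> np.ndarray:
        """J x K rank-1-plus-crosstalk matrix of component r."""
        return column_to_rank1(self.M[:, r], self.J, self.K)


def update_mixing(X1: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Rank-R LS update of the mixing matrix: ``M = (pinv(S) @ X1).T``.

    ``M`` solves ``X1 ~ S @ M.T`` in the least-squares sense; the transpose
    is plain (non-conjugating), conjugation lives in the pseudoinverse.
    """
    return (pinv(S, "shared SM matrix S") @ X1).T


def column_to_rank1(m: np.ndarray, J: int, K: int) -> np.ndarray:
    """Reshape a JK-vector into the J x K matrix whose column k is the
    k-th length-J block of ``m``."""
    m = np.asarray(m)
    if m.shape != (J * K,):
        raise ValueError(f"vector of length {m.size}, expected J*K = {J * K}")
    return m.reshape(K, J).T


def stack_rank1(Mr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`column_to_rank1`: restack columns into a JK-vector."""
    return Mr.T.reshape(-1)


def rank1_ls(
    Mr: np.ndarray,
    b0: np.ndarray,
    c0: np.ndarray,
    n_sweeps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating rank-1 least squares on a J x K matrix.

    One sweep performs ``b <- Mr @ conj(c) / ||c||^2`` (the LS solution of
    ``Mr ~ b c^T`` in b) followed by the symmetric LS step for ``c``.  The
    Frobenius residual ``||Mr - b c^T||`` is non-increasing per half-step.
    No normalization is applied (the constrained variant normalizes).
    """
    Mr = np.asarray(Mr, dtype=np.complex128)
    b = np.asarray(b0, dtype=np.complex128).copy()
    c = np.asarray(c0, dtype=np.complex128).copy()
    for _ in range(n_sweeps):
        nc = float(np.sum(np.abs(c) ** 2))
        if nc == 0.0:
            b, c = _reinit_from_dominant(Mr)
            nc = float(np.sum(np.abs(c) ** 2))
            if nc == 0.0:  # Mr identically zero
                return b, c
        b = Mr @ np.conj(c) / nc
        nb = float(np.sum(np.abs(b) ** 2))
        if nb == 0.0:
            logger.warning("rank-1 LS hit a zero b vector; reinitializing")
            b, c = _reinit_from_dominant(Mr)
            nb = float(np.sum(np.abs(b) ** 2))
            if nb == 0.0:
                return b, c
        c = Mr.T @ np.conj(b) / nb
    return b, c


def _reinit_from_dominant(Mr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restart a degenerate rank-1 fit from the largest-norm column of Mr."""
    norms = np.linalg.norm(Mr, axis=0)
    if norms.max() == 0.0:
        logger.warning("rank-1 LS on an all-zero matrix; flagged degenerate")
        return np.zeros(Mr.shape[0], complex), np.zeros(Mr.shape[1], complex)
    k = int(np.argmax(norms))
    b = Mr[:, k].copy()
    c = np.zeros(Mr.shape[1], complex)
    c[k] = 1.0
    return b, c


def run_arr_r1ls(
    X: FmriTensor | np.ndarray,
    R: int,
    config=None,
    **overrides,
) -> tuple[FactorSet, FitReport]:
    """Run the unconstrained alternating rank-R / rank-1 LS decomposition.

    Per outer iteration: S by rank-R LS on the mode-1 matrix, M by rank-R
    LS given S, then one (b_r, c_r) rank-1 alternation per component.
    Stops when the relative change of the mean-squared error falls below
    ``eps`` or after ``iter_max`` iterations; ``n_runs`` random restarts are
    run and the best final cost is returned.

    ``config`` is a :class:`~shiftcpd.solver.SolverConfig`; keyword
    overrides (e.g. ``seed=0, n_runs=1``) are applied on top.  Constraint
    toggles are forced off: this entry point shares its iteration core with
    the constrained solver, whose all-constraints-off trajectory it defines.
    """
    from .solver import SolverConfig, _run_multi

    if config is None:
        config = SolverConfig(R=R)
    cfg = config.replace(
        R=R,
        use_sparsity=False,
        use_orthonormality=False,
        use_shift=False,
        **overrides,
    )
    return _run_multi(X, cfg)
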