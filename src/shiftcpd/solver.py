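"""Constrained shift-invariant CPD solver for complex-valued fMRI tensors.

Each iteration performs four steps:

1. rank-R LS update of the shared spatial maps with the phase-sparsity
   constraint, after per-component phase de-ambiguity;
2. orthonormality projection of the spatial maps (nearest semi-unitary);
3. rank-R LS update of the aggregating mixing matrix;
4. per component: reshape the mixing column to a J x K matrix, re-estimate
   the subject delays, then the shift-invariant rank-1 LS refit of the
   time course and subject intensities (both returned unit-norm).

The smoothing width of the sparsity penalty is annealed geometrically
(``sigma_iter = gamma * sigma_{iter-1}``).  The three constraints can be
toggled independently for ablation; with all three off the iteration
reduces exactly to the unconstrained alternating rank-R/rank-1 LS rule of
:mod:`shiftcpd.arr_r1ls` (same code path, bitwise-identical trajectory
from the same seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from . import constraints
from .arr_r1ls import column_to_rank1, rank1_ls, update_mixing
from .shift_invariant import cyclic_shift, estimate_delays, shift_rank1_update
from .tensor_core import (
    FactorSet,
    FitReport,
    FmriTensor,
    _crandn,
    khatri_rao,
    pinv,
    unfold,
)

logger = logging.getLogger(__name__)

__all__ = ["SolverConfig", "build_mixing_from_factors", "cost", "run_sarrr1lspo"]


@dataclass(frozen=True)
class SolverConfig:
    """Configuration of the constrained decomposition.

    Parameters
    ----------
    R : int
        Number of components (always user-supplied; never estimated).
    lam : float
        Weight of the phase-sparsity penalty (default 4).
    sigma0 : float
        Initial smoothing width of the smoothed-l0 penalty (default 2).
    gamma : float
        Geometric annealing rate of sigma, in (0.9, 1) (default 0.99).
    n_angles : int
        Phase de-ambiguity grid resolution (default 128).
    max_delay : int
        Delay search half-window in samples (default 10).
    eps : float
        Relative cost-change convergence threshold (default 1e-6).
    iter_max : int
        Maximum outer iterations (default 200).
    n_runs : int
        Random restarts; the best final cost wins (default 20).
    seed : int or None
        Master seed; restarts draw child seeds deterministically.
    use_sparsity, use_orthonormality, use_shift : bool
        Constraint toggles for ablation studies.
    """

    R: int
    lam: float = 4.0
    sigma0: float = 2.0
    gamma: float = 0.99
    n_angles: int = 128
    max_delay: int = 10
    eps: float = 1e-6
    iter_max: int = 200
    n_runs: int = 20
    seed: int | None = None
    use_sparsity: bool = True
    use_orthonormality: bool = True
    use_shift: bool = True

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be a positive integer")
        for name in ("lam", "sigma0", "n_angles", "max_delay", "eps",
                     "iter_max", "n_runs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.9 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0.9, 1), got {self.gamma}")

    def replace(self, **kw) -> "SolverConfig":
        return dataclasses.replace(self, **kw)


def build_mixing_from_factors(
    B: np.ndarray, C: np.ndarray, delays: np.ndarray | None
) -> np.ndarray:
    """Aggregating mixing matrix (JK x R) from TCs, intensities and delays.

    Row block k of column r is ``shift(b_r, tau[k, r]) * c[k, r]``; with
    all delays zero this is exactly ``khatri_rao(C, B)``.
    """
    B = np.asarray(B)
    C = np.asarray(C)
    if delays is None or not np.any(delays):
        return khatri_rao(C, B)
    J, R = B.shape
    K = C.shape[0]
    M = np.empty((J * K, R), dtype=np.complex128)
    j = np.arange(J)
    for r in range(R):
        idx = (j[:, None] + delays[None, :, r]) % J  # (J, K) shifted views
        M[:, r] = (B[idx, r] * C[None, :, r]).T.reshape(-1)
    return M


def cost(
    X: FmriTensor | np.ndarray,
    S: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    delays: np.ndarray | None,
    lam: float = 0.0,
    sigma: float = 2.0,
    theta_th=None,
) -> float:
    """Constrained-model cost: mean squared residual + lam * sparsity penalty.

    The residual term is the mean squared modulus of the shift-invariant
    model residual; the penalty term is the voxel-averaged smoothed-l0
    penalty (itself already divided by V) weighted by ``lam``.
    """
    data = X.data if isinstance(X, FmriTensor) else np.asarray(X)
    V, J, K = data.shape
    M = build_mixing_from_factors(B, C, delays)
    resid = unfold(data, 1) - S @ M.T
    val = float(np.mean(np.abs(resid) ** 2))
    if lam != 0.0:
        if theta_th is None:
            theta_th = np.array(
                [constraints.theta_threshold(S[:, r]) for r in range(S.shape[1])]
            )
        val += lam * constraints.sparsity_penalty(S, sigma, theta_th)
    return val


def run_sarrr1lspo(
    X: FmriTensor | np.ndarray, config: SolverConfig
) -> tuple[FactorSet, FitReport]:
    """Run the constrained decomposition; best of ``config.n_runs`` restarts.

    Returns the factor set of the restart with the lowest final cost and
    its fit report.  Runs whose cost diverges (grows beyond 10x the initial
    cost) are discarded with a warning.
    """
    return _run_multi(X, config)


# ---------------------------------------------------------------------------
# shared iteration core (also backs arr_r1ls.run_arr_r1ls with toggles off)


def _run_multi(
    X: FmriTensor | np.ndarray, cfg: SolverConfig
) -> tuple[FactorSet, FitReport]:
    data = X.data if isinstance(X, FmriTensor) else np.asarray(X, dtype=np.complex128)
    V, J, K = data.shape
    if cfg.R > min(V, J * K):
        raise ValueError(f"R={cfg.R} exceeds min(V, J*K) = {min(V, J * K)}")
    X1 = unfold(data, 1)
    norm_sq = float(np.sum(np.abs(X1) ** 2))

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    best: tuple[FactorSet, FitReport] | None = None
    for i, ss in enumerate(seeds):
        F, rep = _run_single(X1, (V, J, K), norm_sq, cfg, np.random.default_rng(ss))
        rep.notes = f"restart {i + 1}/{cfg.n_runs}"
        if not np.isfinite(rep.final_fit):
            logger.warning("restart %d discarded (divergent cost)", i + 1)
            continue
        logger.info("restart %d/%d: cost %.6g after %d iterations",
                    i + 1, cfg.n_runs, rep.final_fit, rep.n_iter)
        if best is None or rep.final_fit < best[1].final_fit:
            best = (F, rep)
    if best is None:
        raise RuntimeError("all restarts diverged")
    F, rep = best
    # printed-norm residual variant, evaluated once on the returned factors
    M = build_mixing_from_factors(F.B, F.C, F.delays)
    rep.final_fit_abs = float(np.mean(np.abs(X1 - F.S @ M.T)))
    return F, rep


def _run_single(
    X1: np.ndarray,
    shape: tuple[int, int, int],
    norm_sq: float,
    cfg: SolverConfig,
    rng: np.random.Generator,
) -> tuple[FactorSet, FitReport]:
    V, J, K = shape
    R = cfg.R
    B = _crandn(rng, (J, R))
    C = _crandn(rng, (K, R))
    delays = np.zeros((K, R), dtype=np.int64)
    S = np.zeros((V, R), dtype=np.complex128)
    theta_th = np.full(R, np.nan)
    sigma = cfg.sigma0
    report = FitReport()
    prev = np.inf
    initial = np.inf

    for it in range(cfg.iter_max):
        M = build_mixing_from_factors(B, C, delays if cfg.use_shift else None)

        # (1) spatial maps: rank-R LS, then phase machinery if enabled
        S = X1 @ pinv(M, "mixing matrix M").T
        if cfg.use_sparsity:
            for r in range(R):
                _, S[:, r] = constraints.phase_deambiguate(S[:, r], cfg.n_angles)
                theta_th[r] = constraints.theta_threshold(S[:, r])
            dS = constraints.sparsity_gradient(S, sigma, theta_th)
            Gm = M.conj().T @ M
            S = S - cfg.lam * dS @ pinv(Gm, "mixing Gram matrix")

        # (2) orthonormality projection
        if cfg.use_orthonormality:
            S = constraints.orthonormalize(S)
            # semi-unitary S: pinv(S) = S^H, so reuse the projection product
            P = S.conj().T @ X1  # (R, JK)
            Mmix = P.T
        else:
            Mmix = update_mixing(X1, S)
            P = None

        # (4) per-component delay + rank-1 updates
        for r in range(R):
            Mr = column_to_rank1(Mmix[:, r], J, K)
            if cfg.use_shift:
                delays[:, r] = estimate_delays(Mr, B[:, r], C[:, r], cfg.max_delay)
                B[:, r], C[:, r] = shift_rank1_update(Mr, B[:, r], C[:, r], delays[:, r])
                # anchor the per-component lag indeterminacy: shifting b_r
                # while offsetting all its delays leaves the model invariant
                # (a pure index permutation), so keep the median delay at 0
                # and the +/- max_delay window centered on the estimates
                d0 = int(np.round(np.median(delays[:, r])))
                if d0 != 0:
                    delays[:, r] -= d0
                    B[:, r] = cyclic_shift(B[:, r], d0)
            else:
                B[:, r], C[:, r] = rank1_ls(Mr, B[:, r], C[:, r])

        # cost of the updated factors (Gram shortcut, no dense residual)
        Ms = build_mixing_from_factors(B, C, delays if cfg.use_shift else None)
        if P is None:
            P = S.conj().T @ X1
        cross = np.sum(np.conj(P) * Ms.T)
        Gs = S.conj().T @ S
        Gms = Ms.conj().T @ Ms
        resid_sq = max(
            norm_sq - 2.0 * float(np.real(cross))
            + float(np.real(np.sum(Gs * np.conj(Gms).T))),
            0.0,
        ) / (V * J * K)
        c_val = resid_sq
        if cfg.use_sparsity:
            c_val += cfg.lam * constraints.sparsity_penalty(S, sigma, theta_th)
        report.cost_trace.append(c_val)
        report.n_iter = it + 1
        if cfg.use_shift:
            logger.debug("iter %d: cost %.6g sigma %.4g", it + 1, c_val, sigma)

        if it == 0:
            initial = c_val
        elif c_val > 10.0 * initial:
            report.final_fit = np.inf
            report.notes = "diverged"
            return FactorSet(S, B, C, delays if cfg.use_shift else None), report
        exact_fit = c_val <= 1e-14 * (norm_sq / (V * J * K))
        if exact_fit or (
            np.isfinite(prev) and prev > 0 and abs(prev - c_val) / prev < cfg.eps
        ):
            prev = c_val
            report.converged = True
            break
        prev = c_val
        if cfg.use_sparsity:
            sigma = cfg.gamma * sigma

    report.final_fit = float(prev if np.isfinite(prev) else report.cost_trace[-1])
    if cfg.use_sparsity:
        # resolve the residual global phase of each returned map
        for r in range(R):
            _, S[:, r] = constraints.phase_deambiguate(S[:, r], cfg.n_angles)
    return FactorSet(S, B, C, delays if cfg.use_shift else None), report
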