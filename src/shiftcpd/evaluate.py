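"""Performance indices: component matching, correlations, delay accuracy.

CPD factors are identified only up to component permutation, complex
column scaling, and — in the shift-invariant model — a constant cyclic lag
per component (shifting ``b_r`` by d while subtracting d from every
``tau[k, r]`` leaves the model unchanged).  Scoring therefore (a) matches
estimated to reference components by maximizing summed SM-magnitude
correlation with an optimal assignment, (b) aligns each matched time
course by its best circular lag before comparing, and (c) compensates the
same lag on the estimated delays before exact-match counting.  The
Pearson correlation of delays is invariant to the constant lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .constraints import phase_mask
from .shift_invariant import cyclic_shift
from .simulate import GroundTruth
from .tensor_core import FactorSet

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "pearson_abs", "match_components", "activation_counts"]


def pearson_abs(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation |corr(x, y)| of two real vectors.

    Returns NaN (flagged, excluded from means) if either input has zero
    variance.  Complex quantities must be reduced to magnitude or phase by
    the caller.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        logger.warning("pearson_abs undefined: zero-variance input")
        return float("nan")
    return float(abs(np.dot(xc, yc)) / (nx * ny))


@dataclass
class MatchResult:
    """Matched-component metrics of one decomposition against ground truth."""

    permutation: np.ndarray  # ref component index per estimate component
    sm_magnitude: np.ndarray  # |rho| per matched pair
    sm_phase: np.ndarray  # |rho| of estimate phase mask vs reference mask
    tc_magnitude: np.ndarray
    tc_phase: np.ndarray
    intensity: np.ndarray
    delay_rho: np.ndarray  # |rho| of aligned estimated vs true delays
    n_correct_delays: np.ndarray  # exact integer matches per component
    alignment_lags: np.ndarray  # circular TC lag removed per component
    v_all: np.ndarray
    v_in: np.ndarray
    v_out: np.ndarray
    v_ratio: np.ndarray
    excluded: list = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        """NaN-excluding means of the per-pair metrics."""
        out = {}
        for name in (
            "sm_magnitude", "sm_phase", "tc_magnitude", "tc_phase",
            "intensity", "delay_rho",
        ):
            vals = getattr(self, name)
            out[name] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        out["n_correct_delays"] = float(np.sum(self.n_correct_delays))
        return out


def _wrap_delay(tau: np.ndarray, J: int) -> np.ndarray:
    """Map delays into the signed window (-J/2, J/2]."""
    t = np.mod(tau, J)
    return np.where(t > J // 2, t - J, t)


def _align_lag(b_est: np.ndarray, b_ref: np.ndarray) -> int:
    """Circular lag d maximizing |<shift(b_est, d), b_ref>|."""
    J = b_est.shape[0]
    # c[t] = sum_j conj(b_est[j]) * b_ref[(j+t) % J]; the wanted inner
    # product <shift(b_est, d), b_ref> equals c[-d]
    c = np.fft.ifft(np.conj(np.fft.fft(b_est)) * np.fft.fft(b_ref))
    d = (-int(np.argmax(np.abs(c)))) % J
    return d if d <= J // 2 else d - J


def match_components(
    est: FactorSet,
    ref: GroundTruth,
    z_threshold: float = 2.0,
) -> MatchResult:
    """Score an estimated factor set against simulator ground truth.

    Components are paired by an optimal assignment maximizing summed
    SM-magnitude |rho|.  Per pair: SM magnitude correlation; correlation of
    the estimate's small-phase mask with the reference activation mask; TC
    magnitude/phase correlations after circular lag alignment; intensity
    magnitude correlation; lag-compensated delay accuracy; activation
    counts under the z-score threshold rule.
    """
    n_est, n_ref = est.rank, ref.S.shape[1]
    n = min(n_est, n_ref)
    J = est.B.shape[0]

    score = np.zeros((n_est, n_ref))
    for i in range(n_est):
        mag_i = np.abs(est.S[:, i])
        if mag_i.std() == 0.0:
            continue  # degenerate estimate component: excluded from matching
        for j in range(n_ref):
            rho = pearson_abs(mag_i, np.abs(ref.S[:, j]))
            score[i, j] = 0.0 if np.isnan(rho) else rho
    rows, cols = scipy.optimize.linear_sum_assignment(score, maximize=True)
    rows, cols = rows[:n], cols[:n]

    permutation = np.full(n_est, -1)
    res = MatchResult(
        permutation=permutation,
        sm_magnitude=np.full(n_est, np.nan),
        sm_phase=np.full(n_est, np.nan),
        tc_magnitude=np.full(n_est, np.nan),
        tc_phase=np.full(n_est, np.nan),
        intensity=np.full(n_est, np.nan),
        delay_rho=np.full(n_est, np.nan),
        n_correct_delays=np.zeros(n_est, dtype=int),
        alignment_lags=np.zeros(n_est, dtype=int),
        v_all=np.zeros(n_est, dtype=int),
        v_in=np.zeros(n_est, dtype=int),
        v_out=np.zeros(n_est, dtype=int),
        v_ratio=np.full(n_est, np.nan),
    )

    for i, j in zip(rows, cols):
        permutation[i] = j
        s_i = est.S[:, i]
        if np.abs(s_i).std() == 0.0:
            res.excluded.append(i)
            logger.warning("component %d degenerate; excluded from scoring", i)
            continue
        res.sm_magnitude[i] = pearson_abs(np.abs(s_i), np.abs(ref.S[:, j]))
        res.sm_phase[i] = pearson_abs(phase_mask(s_i), ref.masks[:, j].astype(float))

        lag = _align_lag(est.B[:, i], ref.B[:, j])
        res.alignment_lags[i] = lag
        b_al = cyclic_shift(est.B[:, i], lag)
        res.tc_magnitude[i] = pearson_abs(np.abs(b_al), np.abs(ref.B[:, j]))
        res.tc_phase[i] = pearson_abs(
            np.unwrap(np.angle(b_al)), np.unwrap(np.angle(ref.B[:, j]))
        )
        res.intensity[i] = pearson_abs(np.abs(est.C[:, i]), np.abs(ref.C[:, j]))

        if est.delays is not None:
            adj = _wrap_delay(est.delays[:, i] - lag, J)
            res.n_correct_delays[i] = int(np.sum(adj == ref.delays[:, j]))
            res.delay_rho[i] = pearson_abs(adj, ref.delays[:, j])

        counts = activation_counts(s_i, ref.masks[:, j], z_threshold)
        res.v_all[i], res.v_in[i], res.v_out[i], res.v_ratio[i] = counts
    return res


def activation_counts(
    est_sm: np.ndarray,
    ref_mask: np.ndarray,
    z_threshold: float = 2.0,
) -> tuple[int, int, int, float]:
    """Activated-voxel counts of an estimated SM against a reference mask.

    A voxel is activated when the z-score of the SM magnitude (scaled to
    zero mean, unit variance) exceeds ``z_threshold`` (default 2.0; the
    rule is a convention, not a reproduction of any published rule).
    Returns (V_all, V_in, V_out, V_in / V_all) with ratio 0 for V_all = 0.
    """
    mag = np.abs(np.asarray(est_sm))
    ref_mask = np.asarray(ref_mask, dtype=bool)
    sd = mag.std()
    if sd == 0.0:
        return 0, 0, 0, 0.0
    act = (mag - mag.mean()) / sd > z_threshold
    v_all = int(act.sum())
    v_in = int(np.sum(act & ref_mask))
    v_out = v_all - v_in
    ratio = v_in / v_all if v_all else 0.0
    return v_all, v_in, v_out, ratio
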