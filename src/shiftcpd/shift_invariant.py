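"""Cyclic time shifts, integer delay estimation, shift-invariant rank-1 LS.

The shift-invariant CPD model lets every subject delay each shared time
course by a small integer number of samples (hemodynamic delay
variability): component r of subject k uses ``shift(b_r, tau[k, r])``
instead of ``b_r``.  Delays are estimated by maximizing the real part of
the conjugate inner product between each subject's mixing-matrix column and
the delayed, intensity-scaled time course — a circular cross-correlation
evaluated for all shifts at once with one FFT and then restricted to the
physically meaningful window (|tau| <= max_delay, default 10 samples).
The time course itself is refit in the frequency domain, where a cyclic
shift is a per-frequency phase ramp and the rank-1 LS solution is closed
form at every Fourier index.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "cyclic_shift",
    "delay_candidates",
    "estimate_delay",
    "estimate_delays",
    "shift_rank1_update",
]


def cyclic_shift(b: np.ndarray, tau: int) -> np.ndarray:
    """Cyclic left shift by ``tau`` samples (right shift for negative tau).

    Element j of the output is ``b[(j + tau) mod J]``; a shift by 0 or by J
    is the identity and shifts compose additively mod J.
    """
    return np.roll(b, -int(tau), axis=0)


def delay_candidates(J: int, max_delay: int) -> np.ndarray:
    """Candidate delays in tie-break priority order.

    Smallest magnitude first, negative before positive at equal magnitude
    (0, -1, 1, -2, 2, ...); candidates aliasing an earlier one mod J are
    dropped, so the list is valid even when ``2 * max_delay + 1 > J``.
    """
    out: list[int] = [0]
    seen = {0}
    for d in range(1, int(max_delay) + 1):
        for t in (-d, d):
            if t % J not in seen:
                seen.add(t % J)
                out.append(t)
    return np.asarray(out, dtype=np.int64)


def _shift_scores_fft(Mr: np.ndarray, b: np.ndarray) -> np.ndarray:
    """g[tau, k] = sum_j conj(Mr[j, k]) * b[(j + tau) mod J] for all tau."""
    return np.fft.ifft(np.conj(np.fft.fft(Mr, axis=0)) * np.fft.fft(b)[:, None], axis=0)


def estimate_delay(
    m: np.ndarray,
    b: np.ndarray,
    c: complex,
    max_delay: int = 10,
    method: str = "fft",
    return_scores: bool = False,
):
    """Integer delay maximizing ``Re<m, c * shift(b, tau)>`` over |tau| <= max_delay.

    The inner product is conjugate-linear in the first argument.  With
    ``method="fft"`` all J shift scores come from one circular
    cross-correlation; ``method="exhaustive"`` evaluates each candidate
    shift in the time domain.  Both paths share the tie-break of
    :func:`delay_candidates` and must agree exactly.
    """
    m = np.asarray(m)
    b = np.asarray(b)
    J = b.shape[0]
    cands = delay_candidates(J, max_delay)
    if method == "fft":
        g = _shift_scores_fft(m[:, None], b)[:, 0]
        scores = np.real(c * g[cands % J])
    elif method == "exhaustive":
        scores = np.array(
            [np.real(np.vdot(m, c * cyclic_shift(b, int(t)))) for t in cands]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    tau = int(cands[int(np.argmax(scores))])
    if return_scores:
        return tau, cands, scores
    return tau


def estimate_delays(
    Mr: np.ndarray, b: np.ndarray, c: np.ndarray, max_delay: int = 10
) -> np.ndarray:
    """Vectorized :func:`estimate_delay` over the K columns of a J x K matrix."""
    J, K = Mr.shape
    cands = delay_candidates(J, max_delay)
    g = _shift_scores_fft(Mr, b)  # (J, K)
    scores = np.real(c[None, :] * g[cands % J, :])  # (n_cand, K)
    return cands[np.argmax(scores, axis=0)]


def shift_rank1_update(
    Mr: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    tau: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift-invariant rank-1 LS refit of (b, c) given integer delays.

    In the frequency domain the model column k reads
    ``Mr_hat[f, k] ~ b_hat[f] * e^{+i 2 pi f tau_k / J} * c_k`` (DFT shift
    theorem for the cyclic left shift), so the LS solution at each Fourier
    index f is

        b_hat[f] = sum_k Mr_hat[f, k] * conj(c_k) * e^{-i 2 pi f tau_k / J}
                   / sum_k |c_k|^2 .

    ``b`` is then normalized to unit norm, each ``c_k`` refit as the LS
    coefficient ``<shift(b, tau_k), m_k> / ||shift(b, tau_k)||^2`` and ``c``
    normalized to unit norm.  The residual ``sum_k ||m_k - shift(b, tau_k)
    c_k||^2`` is non-increasing before the final c normalization.
    """
    Mr = np.asarray(Mr, dtype=np.complex128)
    J, K = Mr.shape
    tau = np.asarray(tau, dtype=np.int64)
    c = np.asarray(c, dtype=np.complex128).copy()

    denom = float(np.sum(np.abs(c) ** 2))
    if denom == 0.0:
        logger.warning("degenerate component (||c|| = 0); reinitializing from Mr")
        b, c = _reinit(Mr)
        denom = float(np.sum(np.abs(c) ** 2))
        if denom == 0.0:
            return b, c

    f = np.arange(J)
    ramp = np.exp(-2j * np.pi * np.outer(f, tau) / J)  # (J, K)
    Mhat = np.fft.fft(Mr, axis=0)
    bhat = (Mhat * (np.conj(c)[None, :] * ramp)).sum(axis=1) / denom
    b = np.fft.ifft(bhat)
    nb = np.linalg.norm(b)
    if nb == 0.0:
        logger.warning("degenerate component (||b|| = 0); reinitializing from Mr")
        b, c = _reinit(Mr)
        nb = np.linalg.norm(b)
        if nb == 0.0:
            return b, c
    b = b / nb

    # shifted views of the (unit-norm) time course, one column per subject
    idx = (np.arange(J)[:, None] + tau[None, :]) % J
    Bk = b[idx]  # (J, K)
    c = np.sum(np.conj(Bk) * Mr, axis=0)  # ||shift(b, tau_k)||^2 = 1
    nc = np.linalg.norm(c)
    if nc == 0.0:
        logger.warning("degenerate component (||c|| = 0 after refit)")
        return b, c
    return b, c / nc


def _reinit(Mr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Mr, axis=0)
    if norms.max() == 0.0:
        return np.zeros(Mr.shape[0], complex), np.zeros(Mr.shape[1], complex)
    k = int(np.argmax(norms))
    b = Mr[:, k] / norms[k]
    c = np.zeros(Mr.shape[1], complex)
    c[k] = 1.0
    return b, c
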