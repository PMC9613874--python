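"""Synthetic complex-valued multi-subject fMRI tensor generator.

Emulates a SimTB-style task fMRI simulation: spatial sources are smooth
anisotropic Gaussian blobs on a square grid restricted to an elliptical
in-brain mask (7688 voxels on a 100 x 100 grid by default); the task time
course is a block design (40 s on / 30 s off) convolved with a canonical
double-gamma hemodynamic response, nuisance time courses are smooth random
signals.  Complex structure: activated voxels carry small phases drawn
uniformly from [-pi/18, pi/18] (task-induced phase changes are below pi/9),
background voxels carry phases uniform on [-pi, pi].

Inter-subject variability follows the stated ranges: per-subject SM
translation U(-3, 3) voxels in x and y, rotation U(-30, 30) degrees, spread
U(0.88, 1.12), plus integer time delays of the shared time courses.
Circular complex Gaussian noise is added at a requested SNR, defined as
``20 log10(sigma_s / sigma_n)`` with both sigmas temporal standard
deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .shift_invariant import cyclic_shift
from .tensor_core import FmriTensor

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_mask",
    "hrf",
    "generate_sm",
    "generate_tc",
    "add_noise",
    "generate_dataset",
]


@dataclass
class SimConfig:
    """Study-design parameters of the simulated dataset."""

    n_subjects: int = 10
    n_components: int = 30
    grid: tuple[int, int] = (100, 100)
    n_voxels: int = 7688
    n_timepoints: int = 160
    tr: float = 2.0
    block_on: float = 40.0
    block_off: float = 30.0
    snr_db: float = np.inf
    #: max |horizontal / vertical translation| of each subject's SM (voxels)
    translation: float = 3.0
    #: max |rotation| of each subject's SM (degrees)
    rotation: float = 30.0
    #: max relative contraction/expansion of each subject's SM
    spread: float = 0.12
    #: subject delays drawn uniformly from the integers [-max_delay, max_delay]
    max_delay: int = 10
    #: half-width of the activated-voxel phase range (radians)
    act_phase: float = np.pi / 18
    #: peak magnitude of the spatial sources.  With unit-norm time courses
    #: and intensities the decomposition's SM estimates carry the data
    #: scale, and the smoothed-l0 defaults (sigma0 = 2) expect activated
    #: magnitudes well above sigma0; 10 puts activation an order of
    #: magnitude above the annealing start, as in SimTB-style simulations.
    amplitude: float = 10.0
    seed: int | None = None
    store_subject_sms: bool = True


@dataclass
class GroundTruth:
    """Simulator-side truth used only by the evaluation module."""

    S: np.ndarray  # (V, R) variability-free reference SMs
    B: np.ndarray  # (J, R) shared TCs
    C: np.ndarray  # (K, R) subject intensities
    delays: np.ndarray  # (K, R) integer delays applied to the data
    masks: np.ndarray  # (V, R) boolean activation masks of the references
    task_index: int = 0
    #: per-subject SM variants (V, R, K), pre-aggregation, for reference
    subject_sms: np.ndarray | None = None
    component_meta: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry


def make_mask(grid: tuple[int, int] = (100, 100), n_voxels: int = 7688,
              axis_ratio: float = 0.92) -> np.ndarray:
    """Elliptical in-brain mask containing exactly ``n_voxels`` grid cells.

    The cells with the smallest elliptical radius around the grid center
    are selected (y semi-axis shrunk by ``axis_ratio``), which yields an
    exact count without tuning a radius.
    """
    nx, ny = grid
    if n_voxels > nx * ny:
        raise ValueError("n_voxels exceeds the grid size")
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r2 = (x - cx) ** 2 + ((y - cy) / axis_ratio) ** 2
    order = np.argsort(r2, axis=None, kind="stable")
    mask = np.zeros(nx * ny, dtype=bool)
    mask[order[:n_voxels]] = True
    return mask.reshape(nx, ny)


@dataclass
class _BlobSpec:
    """Canonical geometry of one spatial source."""

    center: tuple[float, float]
    sx: float
    sy: float
    angle: float  # radians
    amplitude: float = 1.0


def _blob_image(
    grid: tuple[int, int],
    center: tuple[float, float],
    sx: float,
    sy: float,
    angle: float,
) -> np.ndarray:
    """Anisotropic Gaussian blob evaluated analytically on the grid."""
    nx, ny = grid
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = x - center[0]
    dy = y - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    w = -sa * dx + ca * dy
    return np.exp(-0.5 * ((u / sx) ** 2 + (w / sy) ** 2))


def generate_sm(
    spec: _BlobSpec,
    grid: tuple[int, int],
    mask: np.ndarray,
    rng: np.random.Generator,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    spread: float = 1.0,
    act_phase: float = np.pi / 18,
    half_max: float = 0.5,
    background_phase: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One complex spatial map restricted to the in-brain mask.

    The canonical blob is translated, rotated (about its own center) and
    spread-scaled analytically, vectorized over the mask; activated voxels
    (magnitude above ``half_max`` of the in-mask maximum) get i.i.d. small
    phases in [-act_phase, act_phase], the rest phases uniform on
    [-pi, pi].  ``background_phase`` supplies a pre-drawn per-voxel
    background phase field (one per component, shared by all its subject
    variants — the non-activated phase pattern is a property of the
    source, not of the subject); when omitted it is drawn i.i.d.

    Returns (complex V-vector, boolean activation V-vector).
    """
    cx = spec.center[0] + translation[0]
    cy = spec.center[1] + translation[1]
    img = _blob_image(
        grid,
        (cx, cy),
        spec.sx * spread,
        spec.sy * spread,
        spec.angle + np.deg2rad(rotation_deg),
    )
    mag = spec.amplitude * img[mask]
    if mag.max() <= 0.0:
        raise ValueError("blob fell entirely outside the in-brain mask")
    act = mag > half_max * mag.max()
    V = mag.size
    if background_phase is None:
        phases = rng.uniform(-np.pi, np.pi, size=V)
    else:
        phases = np.array(background_phase, copy=True)
    phases[act] = rng.uniform(-act_phase, act_phase, size=int(act.sum()))
    return mag * np.exp(1j * phases), act


# ---------------------------------------------------------------------------
# time courses


def hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``tr`` s.

    Response peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6;
    scaled to unit peak.
    """
    t = np.arange(0.0, duration, tr)
    h = scipy.stats.gamma.pdf(t, 6) - scipy.stats.gamma.pdf(t, 16) / 6.0
    return h / np.max(np.abs(h))


def generate_tc(
    kind: str,
    n_timepoints: int,
    tr: float,
    rng: np.random.Generator,
    block_on: float = 40.0,
    block_off: float = 30.0,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """One unit-norm shared time course (returned complex with zero phase).

    ``kind="task"``: block-design boxcar (on first) convolved with the
    canonical HRF and truncated to ``n_timepoints``.  ``kind="nuisance"``:
    Gaussian white noise smoothed by a Gaussian kernel of width
    ``smooth_sigma`` samples.
    """
    J = n_timepoints
    if kind == "task":
        on = int(round(block_on / tr))
        off = int(round(block_off / tr))
        period = on + off
        if period > J:
            raise ValueError("block-design period exceeds the run length")
        boxcar = (np.arange(J) % period < on).astype(float)
        tc = np.convolve(boxcar, hrf(tr))[:J]
    elif kind == "nuisance":
        white = rng.standard_normal(J)
        half = min(int(4 * smooth_sigma), max((J - 1) // 2, 1))
        t = np.arange(-half, half + 1)
        kern = np.exp(-0.5 * (t / smooth_sigma) ** 2)
        tc = np.convolve(white, kern / kern.sum(), mode="same")
    else:
        raise ValueError(f"unknown TC kind {kind!r}")
    return (tc / np.linalg.norm(tc)).astype(np.complex128)


# ---------------------------------------------------------------------------
# noise


def add_noise(
    X_clean: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Add circular complex Gaussian noise at ``20 log10(sigma_s/sigma_n)`` dB.

    ``sigma_s`` is the temporal standard deviation of the clean signal,
    pooled over voxels and subjects (root-mean of per-series complex
    variances); ``sigma_n`` is the noise standard deviation
    (``E|n|^2 = sigma_n^2``).  An infinite SNR returns the input unchanged.
    """
    if np.isinf(snr_db):
        return np.array(X_clean, copy=True)
    centered = X_clean - X_clean.mean(axis=1, keepdims=True)
    sigma_s = float(np.sqrt(np.mean(np.abs(centered) ** 2)))
    sigma_n = sigma_s * 10.0 ** (-snr_db / 20.0)
    noise = (
        rng.standard_normal(X_clean.shape) + 1j * rng.standard_normal(X_clean.shape)
    ) * (sigma_n / math.sqrt(2.0))
    return X_clean + noise


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(cfg: SimConfig) -> tuple[FmriTensor, GroundTruth]:
    """Generate one simulated tensor and its ground truth.

    Per subject k the clean slab is
    ``sum_r s_r^(k) * (shift(b_r, tau[k, r]) * c[k, r]).T`` where
    ``s_r^(k)`` is the subject's transformed variant of component r's SM;
    noise is added last.  The ground truth stores the variability-free
    reference SMs (used for scoring) alongside the per-subject variants.
    """
    rng = np.random.default_rng(cfg.seed)
    V, J, K, R = cfg.n_voxels, cfg.n_timepoints, cfg.n_subjects, cfg.n_components
    mask = make_mask(cfg.grid, V)
    coords = np.argwhere(mask)

    specs = _draw_blob_specs(cfg, mask, rng)

    B = np.empty((J, R), dtype=np.complex128)
    B[:, 0] = generate_tc("task", J, cfg.tr, rng, cfg.block_on, cfg.block_off)
    for r in range(1, R):
        B[:, r] = generate_tc("nuisance", J, cfg.tr, rng)

    C = rng.uniform(0.5, 1.5, size=(K, R)).astype(np.complex128)
    delays = rng.integers(-cfg.max_delay, cfg.max_delay + 1, size=(K, R))

    # one background phase field per component, shared by all its subject
    # variants: the non-activated phase pattern belongs to the source
    phi_bg = rng.uniform(-np.pi, np.pi, size=(V, R))

    S_ref = np.empty((V, R), dtype=np.complex128)
    masks = np.empty((V, R), dtype=bool)
    for r in range(R):
        S_ref[:, r], masks[:, r] = generate_sm(
            specs[r], cfg.grid, mask, rng, act_phase=cfg.act_phase,
            background_phase=phi_bg[:, r],
        )

    subject_sms = (
        np.empty((V, R, K), dtype=np.complex128) if cfg.store_subject_sms else None
    )
    # with zero spatial variability every subject shares the canonical map
    # exactly (phases included), so the clean tensor conforms to the
    # shift-invariant CPD model with rank R
    no_variability = cfg.translation == 0 and cfg.rotation == 0 and cfg.spread == 0

    X = np.zeros((V, J, K), dtype=np.complex128)
    for k in range(K):
        for r in range(R):
            if no_variability:
                s_kr = S_ref[:, r]
            else:
                s_kr = _subject_variant(specs[r], cfg, mask, rng, phi_bg[:, r])
            if subject_sms is not None:
                subject_sms[:, r, k] = s_kr
            bk = cyclic_shift(B[:, r], int(delays[k, r]))
            X[:, :, k] += np.outer(s_kr, bk) * C[k, r]

    X = add_noise(X, cfg.snr_db, rng)
    truth = GroundTruth(
        S=S_ref,
        B=B,
        C=C,
        delays=delays,
        masks=masks,
        task_index=0,
        subject_sms=subject_sms,
        component_meta=specs,
    )
    return FmriTensor(X, tr=cfg.tr, voxel_coords=coords), truth


def _draw_blob_specs(
    cfg: SimConfig, mask: np.ndarray, rng: np.random.Generator
) -> list[_BlobSpec]:
    """Blob centers in the mask interior (safe margin for the variability)."""
    nx, ny = cfg.grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    interior = np.argwhere(mask)
    r2 = ((interior[:, 0] - cx) ** 2 + (interior[:, 1] - cy) ** 2)
    inner = interior[r2 <= (0.75 * min(nx, ny) / 2.0) ** 2]
    # compact, near-round sources whose width scales with the in-brain
    # area available per component (sqrt(V/R)), placed with a minimum
    # center separation: brain parcellations tile the volume with
    # moderately overlapping footprints rather than stacking sources on
    # top of each other, and the stated subject variability (translation
    # within 3 voxels, rotation within 30 degrees, spread within 12%)
    # then perturbs rather than replaces each footprint
    base = np.sqrt(cfg.n_voxels / cfg.n_components)
    lo = min(0.22 * base, 0.08 * min(nx, ny))
    hi = min(0.35 * base, 0.13 * min(nx, ny))
    d_min = 1.6 * hi
    centers: list[np.ndarray] = []
    for _ in range(200000):
        if len(centers) == cfg.n_components:
            break
        cand = inner[rng.integers(len(inner))]
        if all(
            (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= d_min**2
            for c in centers
        ):
            centers.append(cand)
        elif rng.random() < 0.01:
            d_min *= 0.95  # relax separation when the packing is tight
    if len(centers) < cfg.n_components:
        raise RuntimeError("could not place the requested number of sources")
    specs = []
    for center in centers:
        sx = float(rng.uniform(lo, hi))
        specs.append(
            _BlobSpec(
                center=(float(center[0]), float(center[1])),
                sx=sx,
                sy=sx * float(rng.uniform(0.8, 1.25)),
                angle=float(rng.uniform(0, np.pi)),
                amplitude=cfg.amplitude,
            )
        )
    return specs


def _subject_variant(
    spec: _BlobSpec,
    cfg: SimConfig,
    mask: np.ndarray,
    rng: np.random.Generator,
    background_phase: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one subject's transformed SM; redraw if it misses the mask."""
    for _ in range(10):
        try:
            s, _ = generate_sm(
                spec,
                cfg.grid,
                mask,
                rng,
                translation=tuple(rng.uniform(-cfg.translation, cfg.translation, 2)),
                rotation_deg=float(rng.uniform(-cfg.rotation, cfg.rotation)),
                spread=float(rng.uniform(1 - cfg.spread, 1 + cfg.spread)),
                act_phase=cfg.act_phase,
                background_phase=background_phase,
            )
            return s
        except ValueError:  # blob pushed fully outside the mask; redraw
            continue
    raise RuntimeError("could not place a subject SM variant inside the mask")
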