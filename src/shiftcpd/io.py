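"""Archives, NIfTI entry points and configuration files.

Internal archives are ``.npz`` containers of named arrays with a version
field, covering tensors (plus mask coordinates and a config echo), factor
sets and simulator ground truth.  Real data enter through a YAML subject
manifest listing per-subject NIfTI pairs — real+imaginary or
magnitude+phase 4-D volumes — plus one shared 3-D binary brain mask;
voxels are flattened row-major over the mask and the coordinates kept so
spatial maps can be written back as NIfTI volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .simulate import GroundTruth
from .tensor_core import FactorSet, FmriTensor

ARCHIVE_VERSION = "1"

__all__ = [
    "SubjectManifest",
    "load_manifest",
    "load_tensor",
    "save_tensor_archive",
    "load_tensor_archive",
    "save_factors",
    "load_factors",
    "save_truth",
    "load_truth",
    "save_maps",
    "load_solver_config",
    "write_run_manifest",
]


# ---------------------------------------------------------------------------
# npz archives


def save_tensor_archive(path, X: FmriTensor, config_echo: dict | None = None) -> None:
    np.savez_compressed(
        path,
        version=ARCHIVE_VERSION,
        data=X.data,
        tr=X.tr,
        voxel_coords=X.voxel_coords if X.voxel_coords is not None else np.zeros((0, 0)),
        config=json.dumps(config_echo or {}),
    )


def load_tensor_archive(path) -> FmriTensor:
    with np.load(path, allow_pickle=False) as z:
        coords = z["voxel_coords"]
        return FmriTensor(
            z["data"],
            tr=float(z["tr"]),
            voxel_coords=coords if coords.size else None,
        )


def save_factors(path, F: FactorSet) -> None:
    arrays = dict(version=ARCHIVE_VERSION, S=F.S, B=F.B, C=F.C)
    if F.delays is not None:
        arrays["delays"] = F.delays
    np.savez_compressed(path, **arrays)


def load_factors(path) -> FactorSet:
    with np.load(path, allow_pickle=False) as z:
        return FactorSet(
            z["S"], z["B"], z["C"], z["delays"] if "delays" in z.files else None
        )


def save_truth(path, truth: GroundTruth) -> None:
    arrays = dict(
        version=ARCHIVE_VERSION,
        S=truth.S,
        B=truth.B,
        C=truth.C,
        delays=truth.delays,
        masks=truth.masks,
        task_index=truth.task_index,
    )
    if truth.subject_sms is not None:
        arrays["subject_sms"] = truth.subject_sms
    np.savez_compressed(path, **arrays)


def load_truth(path) -> GroundTruth:
    with np.load(path, allow_pickle=False) as z:
        return GroundTruth(
            S=z["S"],
            B=z["B"],
            C=z["C"],
            delays=z["delays"],
            masks=z["masks"],
            task_index=int(z["task_index"]),
            subject_sms=z["subject_sms"] if "subject_sms" in z.files else None,
        )


# ---------------------------------------------------------------------------
# NIfTI entry points


@dataclass
class SubjectManifest:
    """Per-subject NIfTI file pairs plus the shared brain mask.

    ``subjects`` maps subject id -> dict with either keys
    ``real``/``imag`` or ``magnitude``/``phase`` (file paths).
    """

    mask: Path
    subjects: list[dict]


def load_manifest(path) -> SubjectManifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "mask" not in doc or "subjects" not in doc:
        raise ValueError(f"{path}: manifest needs 'mask' and 'subjects' keys")
    base = path.parent
    subjects = []
    for entry in doc["subjects"]:
        e = dict(entry)
        for key in ("real", "imag", "magnitude", "phase"):
            if key in e:
                e[key] = base / e[key]
        subjects.append(e)
    return SubjectManifest(mask=base / doc["mask"], subjects=subjects)


def _load_subject(entry: dict) -> np.ndarray:
    if "real" in entry and "imag" in entry:
        re = np.asarray(nib.load(entry["real"]).dataobj)
        im = np.asarray(nib.load(entry["imag"]).dataobj)
        if re.shape != im.shape:
            raise ValueError(
                f"{entry['real']} and {entry['imag']}: shapes differ "
                f"({re.shape} vs {im.shape})"
            )
        return re + 1j * im
    if "magnitude" in entry and "phase" in entry:
        mag = np.asarray(nib.load(entry["magnitude"]).dataobj)
        ph = np.asarray(nib.load(entry["phase"]).dataobj)
        if mag.shape != ph.shape:
            raise ValueError(
                f"{entry['magnitude']} and {entry['phase']}: shapes differ"
            )
        return mag * np.exp(1j * ph)
    raise ValueError(
        f"subject entry {entry.get('id', '?')} needs real+imag or magnitude+phase"
    )


def load_tensor(manifest: SubjectManifest, tr: float = 2.0) -> FmriTensor:
    """Assemble the (V, J, K) complex tensor from the manifest's volumes."""
    mask_img = nib.load(manifest.mask)
    mask = np.asarray(mask_img.dataobj)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{manifest.mask}: mask must be binary, found {uniq}")
    mask = mask.astype(bool)
    coords = np.argwhere(mask)

    slabs = []
    for entry in manifest.subjects:
        vol = _load_subject(entry)
        if vol.shape[:-1] != mask.shape:
            raise ValueError(
                f"subject {entry.get('id', '?')}: grid {vol.shape[:-1]} does "
                f"not match mask {mask.shape}"
            )
        slabs.append(vol[mask, :])  # (V, J), row-major over the mask
    J = {s.shape[1] for s in slabs}
    if len(J) != 1:
        raise ValueError(f"subjects disagree on time points: {sorted(J)}")
    return FmriTensor(np.stack(slabs, axis=2), tr=tr, voxel_coords=coords)


def save_maps(
    s: np.ndarray,
    voxel_coords: np.ndarray,
    grid_shape: tuple[int, ...],
    out_prefix,
    affine: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write magnitude and phase volumes of one spatial map column.

    Out-of-mask voxels are zero; phase values lie in [-pi, pi].  Returns
    the two written paths (``<prefix>_magnitude.nii.gz`` and
    ``<prefix>_phase.nii.gz``).
    """
    s = np.asarray(s)
    voxel_coords = np.asarray(voxel_coords, dtype=int)
    if voxel_coords.shape[0] != s.size:
        raise ValueError("voxel_coords must cover the map length")
    if affine is None:
        affine = np.eye(4)
    out_prefix = Path(out_prefix)
    paths = []
    for part, vals in (("magnitude", np.abs(s)), ("phase", np.angle(s))):
        vol = np.zeros(grid_shape)
        vol[tuple(voxel_coords.T)] = vals
        p = out_prefix.parent / f"{out_prefix.name}_{part}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths.append(p)
    return tuple(paths)


# ---------------------------------------------------------------------------
# configuration / provenance


def load_solver_config(path) -> dict:
    """Read a YAML key/value file of solver options (CLI overrides it)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of solver options")
    return doc


def write_run_manifest(path, **fields) -> None:
    """Persist a JSON record of a run (config, seed, package version)."""
    from . import __version__

    doc = {"package": "shiftcpd", "version": __version__, **fields}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")
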