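"""Readers and writers for the formats the pipeline exchanges.

NIfTI volumes through nibabel (data stored float32, affine preserved
bit-exactly), FSL-style bvals/bvecs text files, TCK/TRK tractograms with a
sidecar CSV of streamline bundle labels, and cohort/tractometry CSV tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import AcquisitionProtocol, DWISeries, ScalarVolume, Tractogram

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume", "write_volume", "read_dwi", "write_dwi",
    "read_tractogram", "write_tractogram", "validate_shared_grid",
]


def write_volume(volume: ScalarVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, name: str = "") -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    return ScalarVolume(np.asarray(img.get_fdata(), dtype=float), img.affine,
                        name=name or path.stem.split(".")[0])


def write_dwi(dwi: DWISeries, path: str | Path) -> Path:
    """4D NIfTI plus sidecar ``.bval``/``.bvec`` files (FSL convention)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine), str(path))
    stem = path.parent / path.name.split(".")[0]
    np.savetxt(f"{stem}.bval", dwi.protocol.bvals[None, :], fmt="%g")
    np.savetxt(f"{stem}.bvec", dwi.protocol.bvecs.T, fmt="%.8f")
    return path


def read_dwi(
    path: str | Path,
    bvals_path: str | Path | None = None,
    bvecs_path: str | Path | None = None,
    delta_ms: float = 7.0,
    Delta_ms: float = 24.0,
) -> DWISeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DWI series not found: {path}")
    stem = path.parent / path.name.split(".")[0]
    bvals_path = Path(bvals_path) if bvals_path else Path(f"{stem}.bval")
    bvecs_path = Path(bvecs_path) if bvecs_path else Path(f"{stem}.bvec")
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    if nz.any() and not np.allclose(norms, 1.0, atol=1e-3):
        logger.warning("read_dwi: normalizing non-unit gradient directions in %s", bvecs_path)
        bvecs = bvecs.copy()
        bvecs[nz] = bvecs[nz] / norms[:, None]
    img = nib.load(str(path))
    protocol = AcquisitionProtocol(bvals, bvecs, delta_ms=delta_ms, Delta_ms=Delta_ms)
    return DWISeries(np.asarray(img.get_fdata(), dtype=float), img.affine, protocol)


def write_tractogram(tractogram: Tractogram, path: str | Path,
                     labels_path: str | Path | None = None) -> Path:
    """TCK or TRK (by extension) with a streamline->bundle label CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tg = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix.lower() == ".trk":
        # TRK stores voxel-frame offsets; give the header the grid affine
        aff = tractogram.affine if tractogram.affine is not None else np.eye(4)
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: aff.astype(np.float32),
            nib.streamlines.trk.Field.VOXEL_SIZES: tuple(
                np.sqrt((aff[:3, :3] ** 2).sum(axis=0)).astype(np.float32)),
            nib.streamlines.trk.Field.DIMENSIONS: (1, 1, 1),
        }
        nib.streamlines.save(tg, str(path), header=header)
    else:
        nib.streamlines.save(tg, str(path))
    if tractogram.labels is not None:
        labels_path = labels_path or path.with_suffix(".labels.csv")
        pd.DataFrame({
            "streamline": np.arange(len(tractogram)),
            "bundle": tractogram.labels,
        }).to_csv(labels_path, index=False)
    return path


def read_tractogram(path: str | Path, labels_path: str | Path | None = None) -> Tractogram:
    """Load TCK/TRK; points are exposed in world mm in either case."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tractogram not found: {path}")
    tf = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if not streamlines:
        raise ValueError(f"empty tractogram: {path}")
    labels = None
    if labels_path is None:
        candidate = path.with_suffix(".labels.csv")
        labels_path = candidate if candidate.exists() else None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        if len(lab) != len(streamlines):
            raise ValueError(
                f"label count ({len(lab)}) does not match streamline count "
                f"({len(streamlines)}) for {path}"
            )
        labels = lab["bundle"].astype(str).to_numpy(dtype=object)
    return Tractogram(streamlines, labels=labels)


def validate_shared_grid(volumes: dict, paths: dict | None = None) -> None:
    """Reject cohorts whose volumes disagree on shape or affine, naming the
    offending subject/file."""
    ref_key = next(iter(volumes))
    ref = volumes[ref_key]
    for key, vol in volumes.items():
        if not vol.same_grid(ref):
            where = paths.get(key, key) if paths else key
            raise ValueError(f"grid mismatch: {where} differs from {ref_key}")
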