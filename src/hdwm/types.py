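"""Core in-memory containers shared by every pipeline stage.

Conventions: the world frame is RAS millimetres; voxel indices are 0-based
with voxel centers at integer continuous coordinates, so a voxel ``c`` owns
the half-open extent ``[c - 0.5, c + 0.5)`` along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalarVolume",
    "Tractogram",
    "AcquisitionProtocol",
    "DWISeries",
]


@dataclass
class ScalarVolume:
    """A 3D scalar map (e.g. MTR, FA, FR) on a regular grid.

    Parameters
    ----------
    data : (I, J, K) float array
    affine : (4, 4) array mapping voxel index to world mm.
    name : metric label, e.g. ``"MTR"``.
    """

    data: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarVolume data must be 3D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to continuous voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class Tractogram:
    """Streamlines in world mm with optional per-streamline bundle labels."""

    streamlines: list[np.ndarray]
    labels: np.ndarray | None = None
    affine: np.ndarray | None = None  # grid the tractogram was built against

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {i} must be (N, 3), got {s.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.streamlines):
                raise ValueError(
                    f"{len(self.labels)} labels for {len(self.streamlines)} streamlines"
                )

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, label) -> "Tractogram":
        """Streamlines carrying a given bundle label."""
        if self.labels is None:
            raise ValueError("tractogram has no labels")
        keep = [s for s, l in zip(self.streamlines, self.labels) if l == label]
        return Tractogram(keep, labels=np.asarray([label] * len(keep)), affine=self.affine)

    def bundle_labels(self) -> list:
        if self.labels is None:
            return []
        seen: list = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return seen


@dataclass
class AcquisitionProtocol:
    """Diffusion acquisition: b-values with unit gradient directions and
    pulsed-gradient timings (gradient duration delta, separation Delta)."""

    bvals: np.ndarray  # s/mm^2
    bvecs: np.ndarray  # (n, 3), unit norm for b > 0
    delta_ms: float = 7.0
    Delta_ms: float = 24.0

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("gradient directions must be unit vectors for b > 0")
        if not self.delta_ms < self.Delta_ms:
            raise ValueError("delta must be smaller than Delta")

    @property
    def n(self) -> int:
        return int(self.bvals.size)

    @property
    def diffusion_time_s(self) -> float:
        """Effective diffusion time (Delta - delta/3) in seconds."""
        return (self.Delta_ms - self.delta_ms / 3.0) / 1000.0

    def shell_mask(self, b_min: float, b_max: float, include_b0: bool = True):
        m = (self.bvals >= b_min) & (self.bvals <= b_max)
        if include_b0:
            m |= self.bvals == 0
        return m


@dataclass
class DWISeries:
    """4D diffusion-weighted data plus its acquisition protocol."""

    data: np.ndarray  # (I, J, K, n) or (V, n) for voxel lists
    affine: np.ndarray
    protocol: AcquisitionProtocol = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[-1] != self.protocol.n:
            raise ValueError(
                f"last data axis ({self.data.shape[-1]}) must match protocol "
                f"volume count ({self.protocol.n})"
            )
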