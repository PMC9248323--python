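"""Along-bundle sampling of quantitative maps.

Maps are sampled by trilinear interpolation at every streamline vertex; a
segment summary is the median over each streamline's vertex values followed
by the mean over streamlines (the aggregation order is switchable to a
pooled median across all vertices). The result is the long-format subject x
segment x metric table that feeds the PCA / ANCOVA stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .types import ScalarVolume, Tractogram

logger = logging.getLogger(__name__)

__all__ = ["sample_streamline", "segment_value", "build_table"]

TRACTOMETRY_METRICS = ("FA", "AD", "RD", "FR", "MTR")


def sample_streamline(volume: ScalarVolume, streamline: np.ndarray) -> np.ndarray:
    """Trilinear map values at each vertex of a world-mm streamline.

    Vertices outside the grid yield NaN. Raises if every vertex falls
    outside the grid.
    """
    vox = volume.world_to_voxel(streamline)
    vals = map_coordinates(volume.data, vox.T, order=1, mode="constant",
                           cval=np.nan)
    # trilinear interpolation is defined on the voxel-center hull [0, n-1];
    # vertices beyond it are reported missing rather than extrapolated
    outside = np.any((vox < 0) | (vox > np.asarray(volume.shape) - 1), axis=1)
    vals = np.where(outside, np.nan, vals)
    if np.all(np.isnan(vals)):
        raise ValueError("all streamline vertices fall outside the volume grid")
    n_out = int(outside.sum())
    if n_out:
        logger.info("sample_streamline: %d of %d vertices outside grid", n_out, len(vals))
    return vals


def segment_value(
    volume: ScalarVolume,
    bundle: Tractogram,
    aggregate: str = "vertex-median-streamline-mean",
) -> float:
    """Summarise one metric over one bundle.

    Default aggregation: per-streamline median over vertex samples, then the
    mean over streamlines. ``aggregate="pooled-median"`` instead takes a
    single median over all vertex samples pooled across streamlines.
    """
    if len(bundle) == 0:
        raise ValueError("empty bundle")
    per_streamline = []
    pooled = []
    n_dropped = 0
    for s in bundle.streamlines:
        vals = sample_streamline(volume, s)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            n_dropped += 1
            continue
        per_streamline.append(np.median(vals))
        pooled.append(vals)
    if n_dropped:
        logger.info("segment_value: dropped %d fully-missing streamlines", n_dropped)
    if not per_streamline:
        raise ValueError("no streamline with in-grid vertices")
    if aggregate == "vertex-median-streamline-mean":
        return float(np.mean(per_streamline))
    if aggregate == "pooled-median":
        return float(np.median(np.concatenate(pooled)))
    raise ValueError(f"unknown aggregation {aggregate!r}")


class _BundleSampler:
    """Precomputed continuous voxel coordinates for one bundle.

    Subject maps share a grid, so the world-to-voxel transform of every
    vertex can be computed once and reused across subjects and metrics;
    each map then needs a single interpolation call.
    """

    def __init__(self, bundle: Tractogram, ref: ScalarVolume) -> None:
        if len(bundle) == 0:
            raise ValueError("empty bundle")
        pts = np.concatenate(bundle.streamlines, axis=0)
        self.vox = ref.world_to_voxel(pts)
        self.splits = np.cumsum([len(s) for s in bundle.streamlines])[:-1]
        self.outside = np.any(
            (self.vox < 0) | (self.vox > np.asarray(ref.shape) - 1), axis=1
        )

    def value(self, volume: ScalarVolume, aggregate: str) -> float:
        vals = map_coordinates(volume.data, self.vox.T, order=1,
                               mode="constant", cval=np.nan)
        vals = np.where(self.outside, np.nan, vals)
        per_streamline = [v[np.isfinite(v)] for v in np.split(vals, self.splits)]
        per_streamline = [v for v in per_streamline if v.size]
        if not per_streamline:
            raise ValueError("no streamline with in-grid vertices")
        if aggregate == "vertex-median-streamline-mean":
            return float(np.mean([np.median(v) for v in per_streamline]))
        if aggregate == "pooled-median":
            return float(np.median(np.concatenate(per_streamline)))
        raise ValueError(f"unknown aggregation {aggregate!r}")


def build_table(
    cohort: pd.DataFrame,
    tractogram: Tractogram,
    maps: dict,
    metrics: tuple[str, ...] = TRACTOMETRY_METRICS,
    aggregate: str = "vertex-median-streamline-mean",
) -> pd.DataFrame:
    """Subject x callosal-segment x metric table (long format).

    Only the seven callosal segments (labels "1".."7") enter the table; the
    CST and any other bundle labels are excluded. Raises if any subject is
    missing any requested metric volume.
    """
    segments = [l for l in tractogram.bundle_labels() if str(l) in set("1234567")]
    first_sid = cohort["subject_id"].iloc[0]
    if first_sid not in maps:
        raise ValueError(f"no metric volumes for subject {first_sid}")
    ref = next(iter(maps[first_sid].values()))
    samplers = {l: _BundleSampler(tractogram.subset(l), ref) for l in segments}
    rows = []
    for sid in cohort["subject_id"]:
        if sid not in maps:
            raise ValueError(f"no metric volumes for subject {sid}")
        for metric in metrics:
            if metric not in maps[sid]:
                raise ValueError(f"subject {sid} is missing metric {metric}")
            vol = maps[sid][metric]
            if not vol.same_grid(ref):
                raise ValueError(f"grid mismatch for subject {sid}, metric {metric}")
            for label, sampler in samplers.items():
                rows.append({
                    "subject_id": sid,
                    "segment": int(label),
                    "metric": metric,
                    "value": sampler.value(vol, aggregate),
                })
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table["value"])):
        raise ValueError("non-finite tractometry values")
    return table
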