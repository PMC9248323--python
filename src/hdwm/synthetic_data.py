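"""Synthetic study generator.

Produces everything the downstream stages consume, without any real data:

* a phantom tractogram with seven callosal arc bundles ordered
  anterior-to-posterior (rostrum ... splenium, labels "1".."7") plus a
  vertical corticospinal-tract-like bundle ("CST"),
* per-subject quantitative maps (MTR, FA, AD, RD, FR, FWF) built as a smooth
  baseline plus bundle-localised planted effects plus Gaussian noise,
* a cohort table (group, age, sex, CAG, ICV, DBS, cognitive battery),
* noise-free or Rician-noised diffusion signals from the composite
  hindered/restricted forward model.

Planted effects mirror the qualitative findings the analysis stages are
meant to recover: a group-by-segment MTR pattern (patients higher anteriorly,
lower posteriorly), a positive CAG-MTR association, a group-by-age MTR
interaction, a posterior-high axon-density gradient, and a patient FR
increase in the CST. Effect magnitudes in native map units are free
parameters of the generator; the defaults are sized to give conventional
power at small-cohort sizes (see docs/methods.md).

Every random draw flows from a single root seed through named substreams,
so adding a new generator never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .micro_maps import CharmedParams, charmed_signal
from .types import AcquisitionProtocol, ScalarVolume, Tractogram

__all__ = [
    "PhantomConfig",
    "EffectSpec",
    "CALLOSAL_SEGMENTS",
    "COGNITIVE_OUTCOMES",
    "DEFAULT_COGNITIVE_LOADINGS",
    "METRICS",
    "substream",
    "make_phantom_tractogram",
    "bundle_masks",
    "make_cohort",
    "make_cognitive_scores",
    "simulate_charmed_signal",
    "make_protocol",
    "disease_burden_score",
]

CALLOSAL_SEGMENTS = {
    1: "rostrum",
    2: "genu",
    3: "rostral body",
    4: "anterior midbody",
    5: "posterior midbody",
    6: "isthmus",
    7: "splenium",
}

METRICS = ("MTR", "FA", "AD", "RD", "FR", "FWF")

#: 13-item cognitive battery (n-back, digit span, visual patterns, finger
#: tapping, Stroop, verbal fluency, trail making, symbol digit modality).
COGNITIVE_OUTCOMES = (
    "nback_1back", "nback_2back", "digit_span", "visual_patterns",
    "finger_tapping", "stroop_word", "stroop_color", "stroop_interference",
    "fluency_phonetic", "fluency_category", "trails_a", "trails_b",
    "symbol_digit",
)

#: One dominant executive factor: strong loadings (0.7) on ten outcomes,
#: weak (0.2) on digit span, visual patterns and phonetic fluency.
DEFAULT_COGNITIVE_LOADINGS = np.array(
    [0.7, 0.7, 0.2, 0.2, 0.7, 0.7, 0.7, 0.7, 0.2, 0.7, 0.7, 0.7, 0.7]
)

# in-bundle / background baseline values per metric (native units)
_BASELINES = {
    "MTR": (45.0, 25.0),   # percent units
    "FA": (0.65, 0.15),
    "AD": (1.6e-3, 0.8e-3),  # mm^2/s
    "RD": (0.45e-3, 0.7e-3),
    "FR": (0.32, 0.08),
    "FWF": (0.10, 0.25),
}

_DEFAULT_NOISE_SD = {
    "MTR": 0.5, "FA": 0.02, "AD": 6e-5, "RD": 6e-5, "FR": 0.015, "FWF": 0.02,
}

_DEFAULT_DENSITY_GRADIENT = {"FA": 0.06, "FR": 0.06, "AD": 1.2e-4, "RD": 1.2e-4}

#: loadings of the per-subject latent axon-density factor (RD opposes)
_DEFAULT_SUBJECT_DENSITY_SD = {"FA": 0.02, "FR": 0.015, "AD": 5e-5, "RD": -5e-5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator named off a root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class PhantomConfig:
    """Geometry, noise and sampling parameters of the synthetic study."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 2.0  # mm, isotropic
    n_streamlines_per_bundle: int = 2000
    n_points_per_streamline: int = 30
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    smoothing_fwhm_mm: float = 4.0
    #: between-subject biological variability: a global MTR offset and a
    #: latent axon-density factor moving FA/FR/AD up and RD down together
    subject_mtr_sd: float = 0.5
    subject_density_sd: dict = field(
        default_factory=lambda: dict(_DEFAULT_SUBJECT_DENSITY_SD))
    age_range: tuple[float, float] = (21.0, 71.0)
    age_mean: float = 42.0
    age_sd: float = 12.7
    cag_range: tuple[int, int] = (37, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_streamlines_per_bundle < 1:
            raise ValueError("need at least one streamline per bundle")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    @property
    def world_extent(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.voxel_size


@dataclass
class EffectSpec:
    """Planted group effects, in native map units.

    ``group_segment_mtr`` is the additive MTR offset for patients in each of
    the seven callosal segments (anterior positive, posterior negative by
    default). ``cag_mtr_slope`` is MTR units per CAG repeat about the
    mid-range repeat count; ``group_age_interaction`` is MTR units per year
    of age difference from the cohort mean (patients only);
    ``cst_fr_offset`` is the additive patient FR offset in the CST bundle;
    ``density_gradient`` maps metric name to the posterior-minus-anterior
    half-span of the baseline axon-density gradient (sign flipped for RD).
    """

    group_segment_mtr: tuple = (1.0, 0.6, 0.3, 0.0, -0.3, -0.6, -1.0)
    cag_mtr_slope: float = 0.15
    group_age_interaction: float = -0.05
    cst_fr_offset: float = 0.05
    density_gradient: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITY_GRADIENT))

    def __post_init__(self) -> None:
        vals = list(self.group_segment_mtr) + [
            self.cag_mtr_slope, self.group_age_interaction, self.cst_fr_offset,
        ] + list(self.density_gradient.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("effect offsets must be finite")
        if len(self.group_segment_mtr) != 7:
            raise ValueError("group_segment_mtr needs one offset per callosal segment")

    @classmethod
    def null(cls) -> "EffectSpec":
        """The global null: no group effects, no baseline gradient."""
        return cls(
            group_segment_mtr=(0.0,) * 7, cag_mtr_slope=0.0,
            group_age_interaction=0.0, cst_fr_offset=0.0, density_gradient={},
        )


# --------------------------------------------------------------------------
# Phantom tractogram
# --------------------------------------------------------------------------

# geometry in fractions of the world extent; x is the anterior->posterior axis
_CC_X_FIRST, _CC_X_LAST = 0.15, 0.66
_CC_SLAB_HALFWIDTH = 0.02
_ARC_Y_CENTER, _ARC_Y_RADIUS = 0.50, 0.25
_ARC_Z_BASE, _ARC_Z_RADIUS = 0.30, 0.33
_CST_X, _CST_Y, _CST_RADIUS = 0.90, 0.50, 0.03
_CST_Z_LO, _CST_Z_HI = 0.15, 0.85


def _check_in_grid(points: np.ndarray, config: PhantomConfig, bundle: str) -> None:
    vox = points / config.voxel_size
    lo_ok = np.all(vox >= -0.5)
    hi_ok = np.all(vox < np.asarray(config.grid_shape) - 0.5)
    if not (lo_ok and hi_ok):
        raise ValueError(
            f"bundle {bundle!r} geometry exceeds the phantom grid "
            f"{config.grid_shape} at voxel size {config.voxel_size}"
        )


def make_phantom_tractogram(config: PhantomConfig) -> Tractogram:
    """Labeled phantom streamlines: seven parasagittal callosal arcs ordered
    anterior-to-posterior along x, plus a straight vertical CST-like tube
    spatially disjoint from the arcs. Deterministic under ``config.seed``."""
    rng = substream(config.seed, "phantom")
    L = config.world_extent
    npts = config.n_points_per_streamline
    streamlines: list[np.ndarray] = []
    labels: list[str] = []

    t = np.linspace(0.0, np.pi, npts)
    for k in range(1, 8):
        fx = _CC_X_FIRST + (_CC_X_LAST - _CC_X_FIRST) * (k - 1) / 6.0
        for _ in range(config.n_streamlines_per_bundle):
            x = (fx + rng.uniform(-_CC_SLAB_HALFWIDTH, _CC_SLAB_HALFWIDTH)) * L[0]
            yc = (_ARC_Y_CENTER + rng.uniform(-0.01, 0.01)) * L[1]
            zc = (_ARC_Z_BASE + rng.uniform(-0.01, 0.01)) * L[2]
            ry = _ARC_Y_RADIUS * rng.uniform(0.92, 1.05) * L[1]
            rz = _ARC_Z_RADIUS * rng.uniform(0.92, 1.05) * L[2]
            pts = np.column_stack([
                np.full(npts, x),
                yc + ry * np.cos(t),
                zc + rz * np.sin(t),
            ])
            streamlines.append(pts)
            labels.append(str(k))
        _check_in_grid(np.concatenate(streamlines[-config.n_streamlines_per_bundle:]),
                       config, str(k))

    z = np.linspace(_CST_Z_LO, _CST_Z_HI, npts)
    for _ in range(config.n_streamlines_per_bundle):
        r = _CST_RADIUS * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        x = (_CST_X + r * np.cos(phi)) * L[0]
        y = (_CST_Y + r * np.sin(phi)) * L[1]
        pts = np.column_stack([np.full(npts, x), np.full(npts, y), z * L[2]])
        streamlines.append(pts)
        labels.append("CST")
    _check_in_grid(np.concatenate(streamlines[-config.n_streamlines_per_bundle:]),
                   config, "CST")

    return Tractogram(streamlines, labels=np.asarray(labels, dtype=object),
                      affine=config.affine)


def bundle_masks(tractogram: Tractogram, config: PhantomConfig) -> dict:
    """Boolean voxel mask per bundle label (voxels traversed by any
    streamline of the bundle, segment-stepped at half-voxel resolution)."""
    from .tbca import streamline_voxels  # local import avoids a cycle at import time

    masks: dict = {}
    for label in tractogram.bundle_labels():
        m = np.zeros(config.grid_shape, dtype=bool)
        for s, l in zip(tractogram.streamlines, tractogram.labels):
            if l != label:
                continue
            idx = streamline_voxels(s, config.affine, config.grid_shape)
            m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        masks[label] = m
    return masks


# --------------------------------------------------------------------------
# Cohort and metric maps
# --------------------------------------------------------------------------

def disease_burden_score(age, cag):
    """DBS = age x (CAG - 35.5)."""
    from .stats import dbs

    return dbs(age, cag)


def _paint_masks(masks: dict) -> dict:
    """Exclusive painting regions: each bundle mask dilated by one voxel.

    Painting on the dilated mask keeps the trilinear-interpolation support
    of every streamline vertex inside painted voxels, so sampled bundle
    values track the planted ones instead of mixing with the background at
    bundle edges. Where dilated regions of two bundles overlap (adjacent
    callosal slabs on coarse grids) the voxel is assigned to the bundle
    whose undilated mask is nearest, keeping the regions disjoint."""
    from scipy.ndimage import binary_dilation, distance_transform_edt

    struct = np.ones((3, 3, 3), dtype=bool)
    keys = list(masks)
    dilated = {k: binary_dilation(masks[k], structure=struct) for k in keys}
    overlap = np.sum([dilated[k] for k in keys], axis=0) > 1
    if not overlap.any():
        return dilated
    dist = np.stack([
        np.where(dilated[k], distance_transform_edt(~masks[k]), np.inf)
        for k in keys
    ])
    owner = np.argmin(dist, axis=0)
    out = {}
    for i, k in enumerate(keys):
        m = dilated[k].copy()
        m[overlap] = owner[overlap] == i
        out[k] = m
    return out


def _baseline_fields(config: PhantomConfig, paint: dict, effects: EffectSpec) -> dict:
    """Per-metric baseline volumes shared by all subjects: flat background
    with planted bundle values (including the anterior-to-posterior
    axon-density gradient) painted on the dilated bundle regions."""
    fields = {}
    for metric in METRICS:
        bundle_val, bg = _BASELINES[metric]
        f = np.full(config.grid_shape, bg)
        grad = effects.density_gradient.get(metric, 0.0)
        sign = -1.0 if metric == "RD" else 1.0
        for k in range(1, 8):
            f[paint[str(k)]] = bundle_val + sign * grad * (k - 4) / 3.0
        if "CST" in paint:
            f[paint["CST"]] = bundle_val
        fields[metric] = f
    return fields


def _correlated_noise(rng: np.random.Generator, shape, sd: float,
                      sigma_vox: float) -> np.ndarray:
    """Gaussian noise field, optionally spatially smoothed and rescaled so
    its standard deviation stays at ``sd`` (derived maps inherit spatial
    correlation from acquisition and fitting)."""
    eps = rng.standard_normal(shape)
    if sigma_vox > 0:
        eps = gaussian_filter(eps, sigma_vox)
        eps /= eps.std()
    return sd * eps


def make_cohort(
    n_patients: int,
    n_controls: int,
    effects: EffectSpec | None = None,
    config: PhantomConfig | None = None,
    tractogram: Tractogram | None = None,
    with_structural: bool = True,
    metrics: tuple[str, ...] = METRICS,
):
    """Generate the cohort table and per-subject metric volumes.

    Returns ``(cohort, maps)`` where ``cohort`` is a DataFrame (one row per
    subject) and ``maps`` maps subject id -> {metric: ScalarVolume}. When
    ``with_structural`` is true, synthetic S0/SMT magnetization-transfer
    image pairs consistent with each subject's MTR map are included, so the
    MTR computation can be exercised end to end.

    Ages are matched between groups by permuting the patients' ages with a
    small uniform perturbation; patient CAG repeats are uniform over the
    configured range; DBS = age x (CAG - 35.5) for patients only.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    config = config or PhantomConfig()
    effects = effects or EffectSpec()
    if tractogram is None:
        tractogram = make_phantom_tractogram(config)
    masks = bundle_masks(tractogram, config)
    paint = _paint_masks(masks)
    baselines = _baseline_fields(config, paint, effects)

    rng_demo = substream(config.seed, "cohort-demographics")
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    pat_ages = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                             size=n_patients, random_state=rng_demo)
    idx = rng_demo.permutation(n_patients)
    if n_controls > n_patients:
        idx = np.concatenate([idx, rng_demo.integers(0, n_patients, n_controls - n_patients)])
    ctl_ages = np.clip(pat_ages[idx[:n_controls]] + rng_demo.uniform(-2, 2, n_controls), lo, hi)

    rows = []
    for i in range(n_patients + n_controls):
        is_pat = i < n_patients
        cag = int(rng_demo.integers(config.cag_range[0], config.cag_range[1] + 1)) if is_pat else np.nan
        age = pat_ages[i] if is_pat else ctl_ages[i - n_patients]
        rows.append({
            "subject_id": f"{'pat' if is_pat else 'ctl'}{i if is_pat else i - n_patients:03d}",
            "group": "patient" if is_pat else "control",
            "age": float(age),
            "sex": "M" if rng_demo.uniform() < 0.58 else "F",
            "cag": cag,
            "icv": float(rng_demo.normal(1.5e6, 1.2e5)),
        })
    cohort = pd.DataFrame(rows)
    cohort["dbs"] = np.where(
        cohort["group"] == "patient",
        disease_burden_score(cohort["age"], cohort["cag"]),
        np.nan,
    )

    cag_mid = 0.5 * (config.cag_range[0] + config.cag_range[1])
    age_mid = config.age_mean
    sigma_vox = config.smoothing_fwhm_mm / (2.3548 * config.voxel_size)
    affine = config.affine
    maps: dict = {}
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        rng_subj = substream(config.seed, f"subject-factors/{sid}")
        mtr_offset = rng_subj.standard_normal() * config.subject_mtr_sd
        density_factor = rng_subj.standard_normal()
        vols: dict = {}
        for metric in metrics:
            rng_maps = substream(config.seed, f"maps/{sid}/{metric}")
            f = baselines[metric].copy()
            if metric == "MTR":
                f = f + mtr_offset
            elif metric in config.subject_density_sd:
                f = f + density_factor * config.subject_density_sd[metric]
            if row["group"] == "patient":
                if metric == "MTR":
                    mtr_shift = (
                        effects.cag_mtr_slope * (row["cag"] - cag_mid)
                        + effects.group_age_interaction * (row["age"] - age_mid)
                    )
                    for k in range(1, 8):
                        f[paint[str(k)]] += effects.group_segment_mtr[k - 1] + mtr_shift
                elif metric == "FR" and "CST" in paint:
                    f[paint["CST"]] += effects.cst_fr_offset
            sd = config.noise_sd.get(metric, 0.0)
            if sd > 0:
                f = f + _correlated_noise(rng_maps, f.shape, sd, sigma_vox)
            vols[metric] = ScalarVolume(f, affine, name=metric)
        if with_structural and "MTR" in metrics:
            s0 = np.full(config.grid_shape, 100.0)
            smt = s0 * (1.0 - vols["MTR"].data / 100.0)
            vols["S0"] = ScalarVolume(s0, affine, name="S0")
            vols["SMT"] = ScalarVolume(smt, affine, name="SMT")
        maps[sid] = vols

    cohort = make_cognitive_scores(cohort, DEFAULT_COGNITIVE_LOADINGS,
                                   noise_sd=0.5, seed=config.seed)
    return cohort, maps


def make_cognitive_scores(
    cohort: pd.DataFrame,
    loading: np.ndarray,
    noise_sd: float = 0.5,
    seed: int = 0,
    latent: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach the 13-outcome cognitive battery to a cohort table.

    Each outcome is ``loading_j * latent + noise``, with a standard-normal
    latent factor per subject unless one is supplied (e.g. to correlate
    cognition with a covariate)."""
    loading = np.asarray(loading, dtype=float)
    if loading.shape != (len(COGNITIVE_OUTCOMES),):
        raise ValueError(f"loading must have length {len(COGNITIVE_OUTCOMES)}")
    rng = substream(seed, "cognitive")
    n = len(cohort)
    if latent is None:
        latent = rng.standard_normal(n)
    latent = np.asarray(latent, dtype=float)
    out = cohort.copy()
    for j, name in enumerate(COGNITIVE_OUTCOMES):
        noise = rng.standard_normal(n) * noise_sd if noise_sd > 0 else 0.0
        out[name] = loading[j] * latent + noise
    return out


# --------------------------------------------------------------------------
# Diffusion signal simulation
# --------------------------------------------------------------------------

def make_protocol(
    shells: dict | None = None,
    delta_ms: float = 7.0,
    Delta_ms: float = 24.0,
) -> AcquisitionProtocol:
    """Multi-shell protocol with deterministic (Fibonacci-sphere) directions.

    Default shells mirror the study acquisition: b = 0 (14), 500 (30),
    1200 (30), 2400 (60), 4000 (60), 6000 (60) s/mm^2.
    """
    if shells is None:
        shells = {0: 14, 500: 30, 1200: 30, 2400: 60, 4000: 60, 6000: 60}
    bvals, bvecs = [], []
    for b, n in shells.items():
        if b == 0:
            bvals += [0.0] * n
            bvecs += [[0.0, 0.0, 0.0]] * n
        else:
            bvals += [float(b)] * n
            bvecs += list(_fibonacci_sphere(n))
    return AcquisitionProtocol(np.asarray(bvals), np.asarray(bvecs),
                               delta_ms=delta_ms, Delta_ms=Delta_ms)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def simulate_charmed_signal(
    params: CharmedParams,
    protocol: AcquisitionProtocol,
    snr: float = np.inf,
    seed: int = 0,
) -> np.ndarray:
    """Forward composite hindered/restricted signal, optionally Rician-noised.

    Finite ``snr`` adds two independent Gaussian channels of sd S0/snr and
    takes the magnitude, the standard Rician model for magnitude MRI data.
    """
    if snr <= 0:
        raise ValueError("snr must be positive (or infinite)")
    s = charmed_signal(params, protocol)
    if np.isinf(snr):
        return s
    rng = substream(seed, "charmed-noise")
    sd = params.s0 / snr
    real = s + rng.normal(0.0, sd, s.shape)
    imag = rng.normal(0.0, sd, s.shape)
    return np.sqrt(real**2 + imag**2)
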