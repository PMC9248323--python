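"""Quantitative microstructure maps.

Implements the five map types used throughout the pipeline:

* MTR — magnetization transfer ratio, ``(S0 - SMT) / S0 * 100``.
* FA / AD / RD / MD — from a diffusion tensor fitted with linearly weighted
  least squares to the b = 500–1200 s/mm^2 shells (plus b = 0), the low-b
  restriction reducing CSF partial-volume contamination.
* FR — restricted (intra-axonal) signal fraction from a two-compartment
  composite hindered-and-restricted model: a Gaussian "hindered" tensor
  compartment plus a cylindrically restricted compartment whose perpendicular
  attenuation follows the Gaussian-phase small-radius expansion.
* FWF — free-water signal fraction from a two-compartment fit with the free
  diffusivity fixed at 3.0e-3 mm^2/s, fitted on the b <= 1200 shells.

All diffusivities are in mm^2/s, b-values in s/mm^2, gradient timings in ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .types import AcquisitionProtocol, DWISeries, ScalarVolume

logger = logging.getLogger(__name__)

MISSING = np.nan
FREE_WATER_DIFFUSIVITY = 3.0e-3  # mm^2/s, body-temperature free water

__all__ = [
    "CharmedParams",
    "TensorFit",
    "FwfFit",
    "compute_mtr",
    "fit_dti",
    "fit_charmed",
    "fit_fwf",
    "charmed_signal",
    "hindered_attenuation",
    "restricted_attenuation",
    "tensor_from_eigen",
    "fa_from_eigenvalues",
]


# --------------------------------------------------------------------------
# MTR
# --------------------------------------------------------------------------

def compute_mtr(s0: ScalarVolume, s_mt: ScalarVolume, mask: np.ndarray | None = None) -> ScalarVolume:
    """MTR = (S0 - SMT) / S0 * 100, in percent units.

    Voxels outside ``mask`` or with non-positive S0 are set to NaN.
    """
    if not s0.same_grid(s_mt):
        raise ValueError("S0 and SMT volumes must share shape and affine")
    valid = s0.data > 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != s0.shape:
            raise ValueError("mask shape mismatch")
        valid &= mask
    out = np.full(s0.shape, MISSING)
    out[valid] = (s0.data[valid] - s_mt.data[valid]) / s0.data[valid] * 100.0
    return ScalarVolume(out, s0.affine, name="MTR")


# --------------------------------------------------------------------------
# Diffusion tensor
# --------------------------------------------------------------------------

@dataclass
class TensorFit:
    """Per-voxel symmetric diffusion tensors and derived scalar maps."""

    tensors: np.ndarray          # (..., 3, 3)
    eigenvalues: np.ndarray      # (..., 3) descending, clipped at 0
    eigenvectors: np.ndarray     # (..., 3, 3) columns matching eigenvalues
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    n_excluded_voxels: int = 0


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """log S = X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack([
        np.ones_like(bvals),
        -bvals * gx**2,
        -bvals * gy**2,
        -bvals * gz**2,
        -2 * bvals * gx * gy,
        -2 * bvals * gx * gz,
        -2 * bvals * gy * gz,
    ])


def tensor_from_eigen(eigenvalues, axis) -> np.ndarray:
    """Axially symmetric tensor with ``eigenvalues = (lam_par, lam_perp)``
    about unit vector ``axis``."""
    lam_par, lam_perp = eigenvalues
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(axis, axis)


def fa_from_eigenvalues(lams: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (possibly batched) eigenvalue triples."""
    lams = np.asarray(lams, dtype=float)
    md = lams.mean(axis=-1, keepdims=True)
    num = np.sum((lams - md) ** 2, axis=-1)
    den = np.sum(lams**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def _fit_tensor_wls(signals: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Weighted linear LS tensor fit on log signal; one reweighting pass
    with weights equal to the squared predicted signal.

    signals: (V, n) strictly positive. Returns (V, 7) coefficients.
    """
    logs = np.log(signals)
    beta = np.linalg.lstsq(X, logs.T, rcond=None)[0].T        # OLS pass
    w = np.exp(X @ beta.T).T ** 2                             # (V, n)
    A = np.einsum("ni,vn,nj->vij", X, w, X)
    b = np.einsum("ni,vn,vn->vi", X, w, logs)
    return np.linalg.solve(A, b[..., None])[..., 0]


def fit_dti(
    dwi: DWISeries,
    b_range: tuple[float, float] = (500.0, 1200.0),
    mask: np.ndarray | None = None,
) -> TensorFit:
    """Fit the diffusion tensor by linearly weighted least squares.

    Only volumes with b = 0 or ``b_range[0] <= b <= b_range[1]`` enter the
    fit (the b = 1200 boundary is included). Voxels with any non-positive
    signal in the selected volumes are excluded (eigenvalues and scalars set
    to NaN) and counted in ``n_excluded_voxels``.
    """
    prot = dwi.protocol
    sel = prot.shell_mask(*b_range, include_b0=True)
    bvals, bvecs = prot.bvals[sel], prot.bvecs[sel]
    n_dirs = len({tuple(np.round(v, 6)) for v, b in zip(bvecs, bvals) if b > 0})
    if n_dirs < 6:
        raise ValueError(
            f"tensor fit needs >= 6 unique gradient directions in b range "
            f"{b_range}, got {n_dirs}"
        )
    X = _design_matrix(bvals, bvecs)

    vol_shape = dwi.data.shape[:-1]
    Y = dwi.data[..., sel].reshape(-1, sel.sum())
    usable = np.all(Y > 0, axis=1)
    if mask is not None:
        usable &= np.asarray(mask, dtype=bool).ravel()
        n_excl = int(np.sum(~np.all(Y > 0, axis=1) & np.asarray(mask, bool).ravel()))
    else:
        n_excl = int(np.sum(~usable))
    if n_excl:
        logger.info("fit_dti: excluded %d voxels with non-positive signal", n_excl)

    coeffs = np.full((Y.shape[0], 7), np.nan)
    if usable.any():
        coeffs[usable] = _fit_tensor_wls(Y[usable], X)

    D = np.full((Y.shape[0], 3, 3), np.nan)
    xx, yy, zz, xy, xz, yz = (coeffs[:, i] for i in range(1, 7))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = xx, yy, zz
    D[:, 0, 1] = D[:, 1, 0] = xy
    D[:, 0, 2] = D[:, 2, 0] = xz
    D[:, 1, 2] = D[:, 2, 1] = yz

    lams = np.full((Y.shape[0], 3), np.nan)
    vecs = np.full((Y.shape[0], 3, 3), np.nan)
    if usable.any():
        w, v = np.linalg.eigh(D[usable])
        order = np.argsort(w, axis=1)[:, ::-1]
        w = np.take_along_axis(w, order, axis=1)
        v = np.take_along_axis(v, order[:, None, :], axis=2)
        lams[usable] = np.clip(w, 0.0, None)
        vecs[usable] = v

    fa = fa_from_eigenvalues(lams)
    fa[~usable] = np.nan
    md = lams.mean(axis=1)
    ad = lams[:, 0]
    rd = lams[:, 1:].mean(axis=1)

    rs = lambda a: a.reshape(vol_shape + a.shape[1:])
    return TensorFit(
        tensors=rs(D), eigenvalues=rs(lams), eigenvectors=rs(vecs),
        fa=rs(fa), md=rs(md), ad=rs(ad), rd=rs(rd),
        n_excluded_voxels=n_excl,
    )


# --------------------------------------------------------------------------
# CHARMED: composite hindered and restricted diffusion
# --------------------------------------------------------------------------

@dataclass
class CharmedParams:
    """Single-population composite hindered/restricted model parameters.

    ``fr`` is the restricted (intra-axonal) signal fraction. The hindered
    compartment is an axially symmetric Gaussian tensor about ``axis``;
    the restricted compartment is a cylinder of radius ``radius_um``
    (micrometres) aligned with the same axis, with axial diffusivity
    ``d_par_restricted`` and intracylinder diffusivity tied to it.
    """

    s0: float = 1.0
    fr: float = 0.3
    lam_par_hindered: float = 1.5e-3
    lam_perp_hindered: float = 0.5e-3
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    d_par_restricted: float = 1.7e-3
    radius_um: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fr <= 1.0:
            raise ValueError("fr must lie in [0, 1]")
        if self.d_par_restricted <= 0 or self.radius_um <= 0:
            raise ValueError("restricted diffusivity and radius must be positive")
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)


def hindered_attenuation(protocol: AcquisitionProtocol, tensor: np.ndarray) -> np.ndarray:
    """Gaussian tensor attenuation exp(-b g^T D g) for each volume."""
    quad = np.einsum("ni,ij,nj->n", protocol.bvecs, tensor, protocol.bvecs)
    return np.exp(-protocol.bvals * quad)


def restricted_attenuation(
    protocol: AcquisitionProtocol,
    axis: np.ndarray,
    d_par: float,
    radius_um: float,
    d_perp: float | None = None,
) -> np.ndarray:
    """Cylindrically restricted attenuation.

    Axial part is free Gaussian diffusion along the cylinder; the
    perpendicular part uses the Gaussian-phase expansion in the cylinder
    radius ``a`` (valid for a^2 << D_perp * Delta):

        E_perp = exp( -(7/96) * (4 pi^2 q_perp^2) * a^4 / (D_perp * Delta)
                       * (2 - (99/112) * a^2 / (D_perp * Delta)) )

    with 4 pi^2 q^2 = b / (Delta - delta/3).
    """
    if d_perp is None:
        d_perp = d_par  # intracylinder diffusivity tied to the axial one
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos2 = (protocol.bvecs @ axis) ** 2
    sin2 = np.clip(1.0 - cos2, 0.0, None)

    a_mm = radius_um * 1e-3
    tau = protocol.diffusion_time_s                  # Delta - delta/3, s
    Delta_s = protocol.Delta_ms / 1000.0
    four_pi2_q2 = protocol.bvals / tau               # 1/mm^2 scaled by b
    dperp_Delta = d_perp * Delta_s                   # mm^2
    perp_exponent = (
        (7.0 / 96.0)
        * four_pi2_q2 * sin2
        * (a_mm**4 / dperp_Delta)
        * (2.0 - (99.0 / 112.0) * a_mm**2 / dperp_Delta)
    )
    return np.exp(-protocol.bvals * cos2 * d_par) * np.exp(-perp_exponent)


def charmed_signal(params: CharmedParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """Noise-free composite signal S = S0 [(1 - FR) E_h + FR E_r]."""
    D_h = tensor_from_eigen(
        (params.lam_par_hindered, params.lam_perp_hindered), params.axis
    )
    e_h = hindered_attenuation(protocol, D_h)
    e_r = restricted_attenuation(
        protocol, params.axis, params.d_par_restricted, params.radius_um
    )
    return params.s0 * ((1.0 - params.fr) * e_h + params.fr * e_r)


def _fit_charmed_voxel(
    signal: np.ndarray,
    protocol: AcquisitionProtocol,
    axis: np.ndarray,
    d_par_restricted: float,
    radius_um: float,
    fr_inits: tuple[float, ...],
) -> tuple[np.ndarray, float]:
    e_r = restricted_attenuation(protocol, axis, d_par_restricted, radius_um)
    cos2 = (protocol.bvecs @ axis) ** 2
    sin2 = 1.0 - cos2

    def model(theta):
        s0, fr, lp, lt = theta
        e_h = np.exp(-protocol.bvals * (cos2 * lp + sin2 * lt))
        return s0 * ((1.0 - fr) * e_h + fr * e_r)

    def resid(theta):
        return model(theta) - signal

    s0_init = float(np.mean(signal[protocol.bvals == 0])) if np.any(protocol.bvals == 0) else float(signal.max())
    lo = [1e-12, 0.0, 1e-5, 1e-5]
    hi = [np.inf, 1.0, 4e-3, 4e-3]
    best: tuple[np.ndarray, float] | None = None
    for fr0 in fr_inits:
        x0 = np.array([s0_init, fr0, 1.5e-3, 0.5e-3])
        res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best[1]:
            best = (res.x, res.cost)
    assert best is not None
    return best


def fit_charmed(
    dwi: DWISeries,
    mask: np.ndarray | None = None,
    d_par_restricted: float = 1.7e-3,
    radius_um: float = 3.0,
    fr_inits: tuple[float, ...] = (0.3, 0.7),
) -> dict:
    """Per-voxel composite hindered/restricted fit, returning FR maps.

    The cylinder axis is fixed to the principal eigenvector of a tensor fit
    on the b <= 1200 shells; radius and restricted axial diffusivity are held
    at their defaults (only FR is of analytic interest downstream). Two FR
    starting points are tried and the lower-misfit solution kept, avoiding
    the boundary local minima at FR = 0 and 1.
    """
    prot = dwi.protocol
    if prot.bvals.max() < 4000:
        raise ValueError("composite hindered/restricted fit needs max b >= 4000 s/mm^2")
    vol_shape = dwi.data.shape[:-1]
    Y = dwi.data.reshape(-1, prot.n)

    dti = fit_dti(dwi, mask=mask)
    axes = dti.eigenvectors.reshape(-1, 3, 3)[:, :, 0]

    usable = np.all(Y > 0, axis=1) & np.isfinite(axes).all(axis=1)
    if mask is not None:
        usable &= np.asarray(mask, bool).ravel()

    fr = np.full(Y.shape[0], np.nan)
    s0 = np.full(Y.shape[0], np.nan)
    n_failed = 0
    for v in np.flatnonzero(usable):
        try:
            theta, _ = _fit_charmed_voxel(
                Y[v], prot, axes[v], d_par_restricted, radius_um, fr_inits
            )
            s0[v], fr[v] = theta[0], theta[1]
        except Exception:  # pragma: no cover - non-convergence is data driven
            n_failed += 1
    if n_failed:
        logger.warning("fit_charmed: %d voxels failed to converge", n_failed)

    return {
        "fr": fr.reshape(vol_shape),
        "s0": s0.reshape(vol_shape),
        "axis": axes.reshape(vol_shape + (3,)),
        "n_failed": n_failed,
    }


# --------------------------------------------------------------------------
# Free-water signal fraction
# --------------------------------------------------------------------------

@dataclass
class FwfFit:
    fwf: np.ndarray
    tissue_md: np.ndarray
    n_excluded_voxels: int = 0


MAX_TISSUE_MD = 2.0e-3  # mm^2/s; keeps the tissue tensor distinct from free water


def _fit_fwf_voxel(signal: np.ndarray, X: np.ndarray, bvals: np.ndarray) -> tuple[float, float]:
    """1D search over FWF with an inner linear tensor fit at each candidate.

    The tissue tensor's mean diffusivity is capped at ``MAX_TISSUE_MD`` so
    that free-water-like signal cannot be absorbed by the tissue compartment
    (without the cap the two compartments are unidentifiable when the tissue
    MD approaches the free diffusivity).
    """
    b0 = bvals == 0
    s0 = float(np.mean(signal[b0]))
    atten = signal / s0
    free = np.exp(-bvals * FREE_WATER_DIFFUSIVITY)

    def tissue_beta(f: float) -> np.ndarray | None:
        tissue = (atten - f * free) / (1.0 - f)
        if np.any(tissue <= 0):
            return None
        beta = np.linalg.lstsq(X, np.log(tissue), rcond=None)[0]
        md_t = (beta[1] + beta[2] + beta[3]) / 3.0
        if md_t > MAX_TISSUE_MD:
            beta = beta.copy()
            beta[1:] *= MAX_TISSUE_MD / md_t
        return beta

    def cost(f: float) -> float:
        beta = tissue_beta(f)
        if beta is None:
            return float(np.sum((f * free - atten) ** 2)) + 1e3
        model = f * free + (1.0 - f) * np.exp(X @ beta)
        return float(np.sum((model - atten) ** 2))

    res = minimize_scalar(cost, bounds=(0.0, 0.9999), method="bounded",
                          options={"xatol": 1e-7})
    f = float(np.clip(res.x, 0.0, 1.0))
    beta = tissue_beta(min(f, 0.9999))
    md = float((beta[1] + beta[2] + beta[3]) / 3.0) if beta is not None else np.nan
    return f, md


def fit_fwf(
    dwi: DWISeries,
    mask: np.ndarray | None = None,
    b_max: float = 1200.0,
) -> FwfFit:
    """Two-compartment free-water fit on the low-b shells.

    S / S0 = FWF exp(-b D_free) + (1 - FWF) exp(-b g^T D_t g), with D_free
    fixed at 3.0e-3 mm^2/s. FWF is found by bounded 1D minimisation with an
    exact inner log-linear tensor fit, so the procedure is deterministic.
    """
    prot = dwi.protocol
    sel = prot.shell_mask(0.0, b_max, include_b0=True)
    shells = {b for b in prot.bvals[sel] if b > 0}
    if len(shells) < 2:
        raise ValueError("free-water fit needs >= 2 nonzero shells <= b_max")
    bvals, bvecs = prot.bvals[sel], prot.bvecs[sel]
    X = _design_matrix(bvals, bvecs)

    vol_shape = dwi.data.shape[:-1]
    Y = dwi.data[..., sel].reshape(-1, sel.sum())
    usable = np.all(Y > 0, axis=1)
    if mask is not None:
        usable &= np.asarray(mask, bool).ravel()
    n_excl = int(np.sum(~usable)) if mask is None else int(
        np.sum(~np.all(Y > 0, axis=1) & np.asarray(mask, bool).ravel())
    )
    if n_excl:
        logger.info("fit_fwf: excluded %d voxels with non-positive signal", n_excl)

    fwf = np.full(Y.shape[0], np.nan)
    md = np.full(Y.shape[0], np.nan)
    for v in np.flatnonzero(usable):
        fwf[v], md[v] = _fit_fwf_voxel(Y[v], X, bvals)
    return FwfFit(
        fwf=fwf.reshape(vol_shape), tissue_md=md.reshape(vol_shape),
        n_excluded_voxels=n_excl,
    )
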