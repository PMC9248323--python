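"""Tract-based cluster analysis (TBCA).

Whole-brain voxel statistics with streamline-aware cluster inference:

1. a per-voxel GLM t-statistic for the group contrast, with nuisance
   covariates (age, sex) regressed;
2. nonparametric voxel p-values from Freedman-Lane permutation of the
   reduced-model residuals;
3. thresholding of the permutation p-map (default p = .01) and cluster
   formation on a hypervoxel template — two suprathreshold voxels belong to
   the same cluster when they are 26-adjacent **or** share a streamline;
4. cluster-mass inference (mass = sum of member t-scores) with family-wise
   error control from the permutation distribution of the maximum cluster
   mass, recomputed under the identical threshold rule for every
   permutation;
5. ROI extraction: union of significant clusters, binarized, mean per
   subject, feeding the cross-metric correlation analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ScalarVolume, Tractogram

logger = logging.getLogger(__name__)

__all__ = [
    "HypervoxelTemplate",
    "Design",
    "ClusterResult",
    "PermutationResult",
    "streamline_voxels",
    "build_template",
    "glm_tmap",
    "permutation_p",
    "form_clusters",
    "fwe_correct",
    "cluster_roi_means",
    "run_tbca",
    "stack_volumes",
]


# --------------------------------------------------------------------------
# Hypervoxel template
# --------------------------------------------------------------------------

def streamline_voxels(
    points: np.ndarray,
    affine: np.ndarray,
    shape: tuple[int, int, int],
    step_fraction: float = 0.5,
) -> np.ndarray:
    """Voxel indices entered by a streamline, by segment traversal.

    Each inter-vertex segment is stepped at ``step_fraction`` of a voxel
    edge so voxels crossed between sparse vertices are not missed. Returns
    unique in-grid indices, order of first visit.
    """
    points = np.asarray(points, dtype=float)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    samples = [vox[:1]]
    seg = np.diff(vox, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    for i, L in enumerate(seg_len):
        n_steps = max(int(np.ceil(L / step_fraction)), 1)
        t = np.arange(1, n_steps + 1) / n_steps
        samples.append(vox[i] + t[:, None] * seg[i])
    allpts = np.concatenate(samples, axis=0)
    idx = np.round(allpts).astype(int)
    shape_arr = np.asarray(shape)
    ok = np.all((idx >= 0) & (idx < shape_arr), axis=1)
    idx = idx[ok]
    if idx.size == 0:
        return idx.reshape(0, 3)
    _, first = np.unique(idx, axis=0, return_index=True)
    return idx[np.sort(first)]


@dataclass
class HypervoxelTemplate:
    """Bidirectional voxel <-> streamline incidence on a fixed grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_to_streamlines: dict = field(default_factory=dict)   # (i,j,k) -> set[int]
    streamline_to_voxels: dict = field(default_factory=dict)   # int -> set[(i,j,k)]

    def check_transpose(self) -> bool:
        """Exhaustively verify the two incidence maps are mutual transposes."""
        for v, sids in self.voxel_to_streamlines.items():
            for sid in sids:
                if v not in self.streamline_to_voxels.get(sid, ()):
                    return False
        for sid, voxels in self.streamline_to_voxels.items():
            for v in voxels:
                if sid not in self.voxel_to_streamlines.get(v, ()):
                    return False
        return True


def build_template(
    tractograms: Tractogram | list[Tractogram],
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> HypervoxelTemplate:
    """Hypervoxel template from one or more tractograms in the grid frame.

    A streamline is linked to every voxel any of its segments enters;
    revisited voxels are linked once.
    """
    if isinstance(tractograms, Tractogram):
        tractograms = [tractograms]
    if not any(len(t) for t in tractograms):
        raise ValueError("cannot build a template from empty tractograms")
    v2s: dict = {}
    s2v: dict = {}
    sid = 0
    for tg in tractograms:
        for s in tg.streamlines:
            idx = streamline_voxels(s, affine, shape)
            voxels = {tuple(v) for v in idx}
            if voxels:
                s2v[sid] = voxels
                for v in voxels:
                    v2s.setdefault(v, set()).add(sid)
            sid += 1
    return HypervoxelTemplate(shape=tuple(shape), affine=np.asarray(affine, float),
                              voxel_to_streamlines=v2s, streamline_to_voxels=s2v)


# --------------------------------------------------------------------------
# GLM and permutation inference
# --------------------------------------------------------------------------

@dataclass
class Design:
    """Per-subject explanatory variables plus the contrast of interest."""

    matrix: np.ndarray          # (n, p), includes the intercept
    contrast: np.ndarray        # (p,)
    direction: str = "greater"  # patient-greater or patient-lower effect
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (self.matrix.shape[1],):
            raise ValueError("contrast length must equal EV count")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("EV matrix is rank deficient")
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        covariates: tuple[str, ...] = ("age", "sex"),
        direction: str = "greater",
    ) -> "Design":
        """Intercept + patient indicator + nuisance covariates; the contrast
        selects the group effect while the other EVs are regressed."""
        n = len(cohort)
        cols = [np.ones(n), (cohort["group"] == "patient").to_numpy(float)]
        names = ["intercept", "group"]
        for cov in covariates:
            v = cohort[cov]
            col = (v == "M").to_numpy(float) if v.dtype == object else v.to_numpy(float)
            cols.append(col)
            names.append(cov)
        c = np.zeros(len(cols))
        c[1] = 1.0
        return cls(np.column_stack(cols), c, direction=direction, names=names)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def reduced_matrix(self) -> np.ndarray:
        """EVs with the contrast-bearing columns removed (nuisance only)."""
        keep = np.isclose(self.contrast, 0.0)
        return self.matrix[:, keep]


def _t_statistics(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorised OLS contrast t per column of Y. Returns (t, n_degenerate);
    degenerate (zero residual variance) voxels get t = 0."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    sigma2 = np.sum(resid**2, axis=0) / dof
    var_c = float(c @ np.linalg.inv(X.T @ X) @ c)
    se = np.sqrt(sigma2 * var_c)
    effect = c @ beta
    # treat numerically-zero residual variance as degenerate (constant maps)
    degenerate = sigma2 <= 1e-12 * (np.mean(Y**2, axis=0) + 1e-300)
    t = np.zeros_like(effect)
    np.divide(effect, se, out=t, where=~degenerate)
    return t, int(degenerate.sum())


def glm_tmap(Y: np.ndarray, design: Design) -> np.ndarray:
    """Observed per-voxel t for the design's contrast. Y is (n_subjects, V)."""
    groups = design.matrix[:, ~np.isclose(design.contrast, 0.0)]
    if design.n_subjects < 6 or min(
        int((groups != 0).sum()), int((groups == 0).sum())
    ) < 3:
        raise ValueError("need at least 3 subjects per group")
    t, n_deg = _t_statistics(np.asarray(Y, float), design.matrix, design.contrast)
    if n_deg:
        logger.info("glm_tmap: %d degenerate voxels set to t = 0", n_deg)
    return t


@dataclass
class PermutationResult:
    """Observed and permuted score maps (score = signed t in the direction
    of interest, so larger is always more extreme) plus voxel p-values."""

    score_obs: np.ndarray       # (V,)
    score_perm: np.ndarray      # (n_perm, V)
    p_voxel: np.ndarray         # (V,)
    n_perm: int
    seed: int
    direction: str
    capped: bool = False

    def row_pvalues(self) -> np.ndarray:
        """Per-voxel p of every row (observed first) against the joint
        permutation distribution — the thresholding surface reused for
        cluster inference under every permutation."""
        T = np.vstack([self.score_obs[None, :], self.score_perm])
        return rankdata(-T, method="max", axis=0) / T.shape[0]


def permutation_p(
    Y: np.ndarray,
    design: Design,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Freedman-Lane permutation test of the group contrast.

    The reduced (nuisance-only) model is fitted once; its residual rows are
    permuted, the nuisance fit added back, and the full model refitted per
    permutation. Voxel p = (1 + #{t_perm >= t_obs}) / (n_perm + 1), one-sided
    in the design's direction. If the requested permutation count meets or
    exceeds the number of distinct orderings, the non-identity orderings are
    enumerated exhaustively instead.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    Y = np.asarray(Y, dtype=float)
    n = design.n_subjects
    sign = 1.0 if design.direction == "greater" else -1.0
    t_obs, _ = _t_statistics(Y, design.matrix, design.contrast)
    score_obs = sign * t_obs

    Z = design.reduced_matrix()
    if Z.size:
        hatY = Z @ np.linalg.pinv(Z) @ Y
    else:
        hatY = np.zeros_like(Y)
    R = Y - hatY

    capped = False
    n_distinct = math.factorial(n)
    if n_perm >= n_distinct - 1:
        import itertools

        perms = [np.asarray(p) for p in itertools.permutations(range(n))
                 if p != tuple(range(n))]
        capped = True
        logger.warning(
            "permutation_p: requested %d permutations but only %d distinct "
            "non-identity orderings exist; enumerating exhaustively",
            n_perm, n_distinct - 1,
        )
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    score_perm = np.empty((len(perms), Y.shape[1]))
    for j, perm in enumerate(perms):
        Ystar = hatY + R[perm]
        t_perm, _ = _t_statistics(Ystar, design.matrix, design.contrast)
        score_perm[j] = sign * t_perm

    n_eff = len(perms)
    # count ties robustly: group-preserving permutations reproduce the
    # observed statistic up to floating error and must count as >=
    tol = 1e-9 * (1.0 + np.abs(score_obs))
    p_voxel = (1 + np.sum(score_perm >= (score_obs - tol)[None, :], axis=0)) / (n_eff + 1)
    return PermutationResult(
        score_obs=score_obs, score_perm=score_perm, p_voxel=p_voxel,
        n_perm=n_eff, seed=seed, direction=design.direction, capped=capped,
    )


# --------------------------------------------------------------------------
# Cluster formation and FWE
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """A suprathreshold cluster: member voxels, the streamlines that pass
    through them, the cluster mass (sum of member scores, positive in the
    tested direction) and its permutation p-values."""

    voxels: list                 # [(i, j, k), ...]
    streamlines: set
    mass: float
    p_uncorrected: float = float("nan")
    p_fwe: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.voxels)


_NEIGHBORS = [
    (di, dj, dk)
    for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_voxel_sets(
    supra_coords: list,
    template: HypervoxelTemplate | None,
) -> list[list[int]]:
    """Partition indices of ``supra_coords`` into clusters under the
    26-adjacency-or-shared-streamline rule."""
    pos = {tuple(v): i for i, v in enumerate(supra_coords)}
    uf = _UnionFind(len(supra_coords))
    for v, i in pos.items():
        for d in _NEIGHBORS:
            j = pos.get((v[0] + d[0], v[1] + d[1], v[2] + d[2]))
            if j is not None:
                uf.union(i, j)
    if template is not None:
        touched: dict = {}
        for v, i in pos.items():
            for sid in template.voxel_to_streamlines.get(v, ()):
                touched.setdefault(sid, []).append(i)
        for members in touched.values():
            for m in members[1:]:
                uf.union(members[0], m)
    groups: dict = {}
    for i in range(len(supra_coords)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def form_clusters(
    score: np.ndarray,
    p_voxel: np.ndarray,
    coords: np.ndarray,
    template: HypervoxelTemplate | None,
    p_thr: float = 0.01,
) -> list[ClusterResult]:
    """Clusters of voxels with permutation p <= ``p_thr``.

    ``score``/``p_voxel`` are flat per-voxel arrays over ``coords`` (the
    analysis voxel list, (V, 3) integer indices). Passing ``template=None``
    reduces the rule to plain 26-connectivity clustering.
    """
    supra = np.flatnonzero(p_voxel <= p_thr)
    supra_coords = [tuple(c) for c in coords[supra]]
    clusters = []
    for members in _cluster_voxel_sets(supra_coords, template):
        vox = [supra_coords[i] for i in members]
        sids: set = set()
        if template is not None:
            for v in vox:
                sids |= template.voxel_to_streamlines.get(v, set())
        mass = float(np.sum(score[supra[members]]))
        clusters.append(ClusterResult(voxels=vox, streamlines=sids, mass=mass))
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def _max_masses(
    perm: PermutationResult,
    coords: np.ndarray,
    template: HypervoxelTemplate | None,
    p_thr: float,
) -> tuple[np.ndarray, list[float]]:
    """Per-permutation maximum cluster mass (0 when no cluster forms), plus
    the pooled list of all permutation cluster masses."""
    P = perm.row_pvalues()
    maxes = np.zeros(perm.n_perm)
    pooled: list[float] = []
    for r in range(1, perm.n_perm + 1):
        cl = form_clusters(perm.score_perm[r - 1], P[r], coords, template, p_thr)
        if cl:
            masses = [c.mass for c in cl]
            maxes[r - 1] = max(masses)
            pooled.extend(masses)
    return maxes, pooled


def fwe_correct(
    clusters: list[ClusterResult],
    perm: PermutationResult,
    coords: np.ndarray,
    template: HypervoxelTemplate | None,
    p_thr: float = 0.01,
) -> list[ClusterResult]:
    """Attach permutation p-values to observed clusters.

    FWE: p = (1 + #{max permuted mass >= mass}) / (n_perm + 1), with the
    permuted maxima recomputed under the same threshold and clustering rule.
    Uncorrected: the cluster mass against the pooled distribution of all
    permutation cluster masses, capped at the FWE value so corrected never
    undercuts uncorrected.
    """
    maxes, pooled = _max_masses(perm, coords, template, p_thr)
    pooled_arr = np.asarray(pooled)
    for c in clusters:
        tol = 1e-9 * (1.0 + abs(c.mass))  # count floating-point ties as >=
        c.p_fwe = float((1 + np.sum(maxes >= c.mass - tol)) / (perm.n_perm + 1))
        if pooled_arr.size:
            p_unc = float(
                (1 + np.sum(pooled_arr >= c.mass - tol)) / (pooled_arr.size + 1))
        else:
            p_unc = c.p_fwe
        c.p_uncorrected = min(p_unc, c.p_fwe)
    return clusters


def cluster_roi_means(
    clusters: list[ClusterResult],
    subject_volumes: dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean metric value per subject inside the union of significant
    clusters (binarized ROI mask)."""
    sig = [c for c in clusters if c.p_fwe < alpha]
    vox = sorted({v for c in sig for v in c.voxels})
    if not vox:
        raise ValueError("no significant cluster voxels to form an ROI")
    idx = np.asarray(vox)
    rows = []
    for sid, vol in subject_volumes.items():
        vals = vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        rows.append({"subject_id": sid, "roi_mean": float(np.nanmean(vals))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def stack_volumes(
    volumes: list[ScalarVolume],
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject volumes to (n_subjects, V) over ``mask`` (or the
    whole grid), returning the data matrix and (V, 3) voxel coordinates."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not v.same_grid(ref):
            raise ValueError("subject volumes must share grid and affine")
    if mask is None:
        mask = np.ones(ref.shape, dtype=bool)
    coords = np.argwhere(mask)
    Y = np.stack([v.data[mask] for v in volumes], axis=0)
    return Y, coords


@dataclass
class TbcaResult:
    clusters: list[ClusterResult]
    permutation: PermutationResult
    coords: np.ndarray
    t_volume: ScalarVolume
    p_volume: ScalarVolume

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": i + 1,
                    "size": c.size,
                    "n_streamlines": len(c.streamlines),
                    "mass": c.mass,
                    "p_uncorrected": c.p_uncorrected,
                    "p_fwe": c.p_fwe,
                }
                for i, c in enumerate(self.clusters)
            ]
        )


def run_tbca(
    volumes: list[ScalarVolume],
    design: Design,
    template: HypervoxelTemplate | None,
    mask: np.ndarray | None = None,
    p_thr: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> TbcaResult:
    """Full TBCA for one metric and one direction."""
    Y, coords = stack_volumes(volumes, mask)
    perm = permutation_p(Y, design, n_perm=n_perm, seed=seed)
    clusters = form_clusters(perm.score_obs, perm.p_voxel, coords, template, p_thr)
    clusters = fwe_correct(clusters, perm, coords, template, p_thr)

    ref = volumes[0]
    tvol = np.zeros(ref.shape)
    pvol = np.ones(ref.shape)
    tvol[coords[:, 0], coords[:, 1], coords[:, 2]] = perm.score_obs
    pvol[coords[:, 0], coords[:, 1], coords[:, 2]] = perm.p_voxel
    return TbcaResult(
        clusters=clusters, permutation=perm, coords=coords,
        t_volume=ScalarVolume(tvol, ref.affine, name="t"),
        p_volume=ScalarVolume(pvol, ref.affine, name="p"),
    )
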