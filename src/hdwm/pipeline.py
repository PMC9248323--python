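"""End-to-end pipeline driver.

Runs the synthetic study from a single config: simulate (phantom + cohort +
maps) -> maps (MTR computation) -> tractometry -> group statistics (PCA,
ANCOVA, moderation, correlation families) -> TBCA. Every stage writes its
outputs plus a provenance record (config, seed, package versions) and can
be re-run from the previous stage's on-disk outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from . import stats as hstats
from . import tbca as htbca
from . import tractometry as htract
from .micro_maps import compute_mtr
from .synthetic_data import (
    COGNITIVE_OUTCOMES,
    METRICS,
    EffectSpec,
    PhantomConfig,
    bundle_masks,
    make_cohort,
    make_phantom_tractogram,
    substream,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "group_statistics"]

_CONFIG_FIELDS = {
    "out_dir", "seed", "n_patients", "n_controls", "grid_shape", "voxel_size",
    "n_streamlines_per_bundle", "smoothing_fwhm_mm", "n_perm", "p_thr",
    "alpha", "tbca_metrics", "aggregate", "effects",
}


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; unknown or missing keys are rejected."""

    out_dir: str
    seed: int = 0
    n_patients: int = 12
    n_controls: int = 12
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.0
    n_streamlines_per_bundle: int = 200
    smoothing_fwhm_mm: float = 4.0
    n_perm: int = 300
    p_thr: float = 0.01
    alpha: float = 0.05
    #: metric -> test direction for the whole-brain cluster analysis
    tbca_metrics: dict = field(default_factory=lambda: {"MTR": "less", "FR": "greater"})
    aggregate: str = "vertex-median-streamline-mean"
    effects: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in d:
            raise ValueError("config is missing required key: out_dir")
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            grid_shape=self.grid_shape, voxel_size=self.voxel_size,
            n_streamlines_per_bundle=self.n_streamlines_per_bundle,
            smoothing_fwhm_mm=self.smoothing_fwhm_mm, seed=self.seed,
        )

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(**self.effects) if self.effects else EffectSpec()


def _provenance(out: Path, config: PipelineConfig, stage: str) -> None:
    import nibabel
    import scipy
    import statsmodels

    record = {
        "stage": stage,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "nibabel": nibabel.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(record, indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> dict:
    out = Path(config.out_dir) / "simulate"
    phantom = config.phantom_config()
    tract = make_phantom_tractogram(phantom)
    cohort, maps = make_cohort(
        config.n_patients, config.n_controls, config.effect_spec(), phantom,
        tractogram=tract,
    )
    hio.write_tractogram(tract, out / "tractogram.tck")
    cohort.to_csv(out / "cohort.csv", index=False)
    for sid, vols in maps.items():
        for metric, vol in vols.items():
            hio.write_volume(vol, out / "maps" / f"{sid}_{metric}.nii.gz")
    _provenance(out, config, "simulate")
    return {"tractogram": tract, "cohort": cohort, "maps": maps, "phantom": phantom}


def stage_maps(config: PipelineConfig, sim: dict) -> dict:
    """Compute MTR from the structural S0/SMT pair and assemble the final
    per-subject metric volumes."""
    out = Path(config.out_dir) / "maps"
    maps_out: dict = {}
    for sid, vols in sim["maps"].items():
        subject: dict = {}
        if "S0" in vols and "SMT" in vols:
            subject["MTR"] = compute_mtr(vols["S0"], vols["SMT"])
        for metric in METRICS:
            if metric not in subject:
                subject[metric] = vols[metric]
        hio.validate_shared_grid(subject)
        maps_out[sid] = subject
        for metric, vol in subject.items():
            hio.write_volume(vol, out / f"{sid}_{metric}.nii.gz")
    _provenance(out, config, "maps")
    return maps_out


def stage_tractometry(config: PipelineConfig, sim: dict, maps: dict) -> pd.DataFrame:
    out = Path(config.out_dir) / "tractometry"
    metrics = tuple(list(htract.TRACTOMETRY_METRICS) + ["FWF"])
    table = htract.build_table(sim["cohort"], sim["tractogram"], maps,
                               metrics=metrics, aggregate=config.aggregate)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "tractometry.csv", index=False)
    _provenance(out, config, "tractometry")
    return table


def group_statistics(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    covariate_candidates: tuple[str, ...] = ("age", "icv"),
    include_fwf_reanalysis: bool = True,
) -> dict:
    """The full group-level statistical analysis on a tractometry table.

    Steps: microstructure PCA (FA/AD/RD/FR/MTR over subject x segment rows,
    Kaiser retention, varimax, regression scores); component-wise covariate
    screening at |r| > 0.3; ANCOVA per retained component with group,
    segment and group x segment (plus group x age for the
    magnetization-transfer component); simple-slopes moderation of the
    group effect per segment; cognitive PCA (patients, complete cases, one
    component); Spearman families of the MT component's per-segment scores
    against composite cognition, CAG and DBS, with partial (ICV + DBS)
    follow-up; optional re-analysis with FWF as covariate.
    """
    pca_metrics = [m for m in ("FA", "FR", "RD", "AD", "MTR") if m in set(table["metric"])]
    wide = table.pivot_table(index=["subject_id", "segment"], columns="metric",
                             values="value").reset_index()
    demo_cols = [c for c in ("group", "age", "sex", "icv", "cag", "dbs") if c in cohort]
    wide = wide.merge(cohort[["subject_id"] + demo_cols], on="subject_id")

    # two components by interpretability: the axon-density block
    # (FA/FR/AD/-RD) and the magnetization-transfer dimension
    pca = hstats.pca_varimax(wide[pca_metrics], retain=min(2, len(pca_metrics)))
    for j in range(pca.n_components):
        wide[f"PC{j + 1}"] = pca.scores[f"PC{j + 1}"].to_numpy()

    # identify the magnetization-transfer component by its MTR loading
    mtr_row = pca_metrics.index("MTR")
    mt_idx = int(np.argmax(np.abs(pca.loadings[mtr_row, :])))
    mt_comp = f"PC{mt_idx + 1}"

    ancovas: dict = {}
    slopes = None
    for j in range(pca.n_components):
        comp = f"PC{j + 1}"
        covs = hstats.screen_covariates(
            wide[comp], wide[list(covariate_candidates)])
        cov_inter = (("group", "age"),) if comp == mt_comp and "age" in covs else ()
        res = hstats.ancova(
            wide, dv=comp, factors=("group", "segment"), covariates=tuple(covs),
            factor_interactions=(("group", "segment"),),
            covariate_interactions=cov_inter,
        )
        ancovas[comp] = {"result": res, "covariates": covs,
                         "label": pca.component_labels[j]}
        if comp == mt_comp:
            slopes = hstats.simple_slopes(res, moderator="segment")

    # cognitive composite: one-component PCA on the patients' battery
    cognitive = None
    cog_cols = [c for c in COGNITIVE_OUTCOMES if c in cohort.columns]
    patients = cohort[cohort["group"] == "patient"]
    if cog_cols and len(patients) > 3:
        complete = patients.dropna(subset=cog_cols)
        cog_pca = hstats.pca_varimax(complete[cog_cols], retain=1,
                                     check_adequacy=len(complete) > len(cog_cols))
        cognitive = complete[["subject_id"]].copy()
        cognitive["composite"] = cog_pca.scores["PC1"].to_numpy()
        cognitive_pca = cog_pca
    else:
        cognitive_pca = None

    # per-segment MT scores for the patient correlation families
    mt_scores = wide.pivot_table(index="subject_id", columns="segment",
                                 values=mt_comp)
    mt_scores.columns = [f"segment_{s}" for s in mt_scores.columns]
    pat = cohort[cohort["group"] == "patient"].set_index("subject_id")
    mt_pat = mt_scores.loc[mt_scores.index.intersection(pat.index)]

    correlations: dict = {}
    if len(mt_pat) >= 5:
        correlations["cag"] = hstats.spearman_family(mt_pat, pat["cag"])
        correlations["cag_partial"] = hstats.spearman_family(
            mt_pat, pat["cag"], covariates=pat[["icv", "dbs"]])
        correlations["dbs"] = hstats.spearman_family(mt_pat, pat["dbs"])
        if cognitive is not None:
            comp = cognitive.set_index("subject_id")["composite"]
            shared = mt_pat.index.intersection(comp.index)
            if len(shared) >= 5:
                correlations["cognitive"] = hstats.spearman_family(
                    mt_pat.loc[shared], comp.loc[shared])

    fwf_reanalysis = None
    if include_fwf_reanalysis and "FWF" in set(table["metric"]):
        fwf = table[table["metric"] == "FWF"].rename(columns={"value": "fwf"})
        wide_fwf = wide.merge(fwf[["subject_id", "segment", "fwf"]],
                              on=["subject_id", "segment"])
        fwf_reanalysis = hstats.ancova(
            wide_fwf, dv=mt_comp, factors=("group", "segment"),
            covariates=("age", "icv", "fwf"),
            factor_interactions=(("group", "segment"),),
            covariate_interactions=(("group", "age"), ("group", "fwf")),
        )

    return {
        "pca": pca, "scores_table": wide, "mt_component": mt_comp,
        "ancovas": ancovas, "simple_slopes": slopes,
        "cognitive_pca": cognitive_pca, "cognitive_scores": cognitive,
        "correlations": correlations, "fwf_reanalysis": fwf_reanalysis,
    }


def stage_stats(config: PipelineConfig, table: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    out = Path(config.out_dir) / "stats"
    out.mkdir(parents=True, exist_ok=True)
    res = group_statistics(table, cohort)
    pca = res["pca"]
    pd.DataFrame(pca.loadings, index=pca.variable_names,
                 columns=[f"PC{i + 1}" for i in range(pca.n_components)]
                 ).to_csv(out / "pca_loadings.csv")
    res["scores_table"].to_csv(out / "scores.csv", index=False)
    frames = []
    for comp, a in res["ancovas"].items():
        t = a["result"].anova_table.copy()
        t.insert(0, "component", comp)
        frames.append(t.reset_index(names="term"))
    pd.concat(frames).to_csv(out / "ancova.csv", index=False)
    if res["simple_slopes"] is not None:
        res["simple_slopes"].to_csv(out / "simple_slopes.csv", index=False)
    if res["correlations"]:
        corr = pd.concat(
            [df.assign(family=name) for name, df in res["correlations"].items()])
        corr.to_csv(out / "correlations.csv", index=False)
    _provenance(out, config, "stats")
    return res


def stage_tbca(config: PipelineConfig, sim: dict, maps: dict) -> dict:
    out = Path(config.out_dir) / "tbca"
    out.mkdir(parents=True, exist_ok=True)
    phantom = sim["phantom"]
    template = htbca.build_template(sim["tractogram"], phantom.grid_shape,
                                    phantom.affine)
    mask = np.zeros(phantom.grid_shape, dtype=bool)
    for v in template.voxel_to_streamlines:
        mask[v] = True
    cohort = sim["cohort"]
    results: dict = {}
    for metric, direction in config.tbca_metrics.items():
        design = htbca.Design.from_cohort(cohort, covariates=("age", "sex"),
                                          direction=direction)
        vols = [maps[sid][metric] for sid in cohort["subject_id"]]
        seed = int(substream(config.seed, f"tbca/{metric}").integers(2**31))
        res = htbca.run_tbca(vols, design, template, mask=mask,
                             p_thr=config.p_thr, n_perm=config.n_perm, seed=seed)
        res.table().to_csv(out / f"clusters_{metric}.csv", index=False)
        sig = [c for c in res.clusters if c.p_fwe < config.alpha]
        if sig:
            roi = htbca.cluster_roi_means(
                res.clusters,
                {sid: maps[sid][metric] for sid in cohort["subject_id"]},
                alpha=config.alpha,
            )
            roi.to_csv(out / f"roi_means_{metric}.csv", index=False)
        results[metric] = res
    _provenance(out, config, "tbca")
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; each stage failure is re-raised with the
    stage name attached."""
    outputs: dict = {}
    stages = [
        ("simulate", lambda: stage_simulate(config)),
        ("maps", lambda: stage_maps(config, outputs["simulate"])),
        ("tractometry", lambda: stage_tractometry(config, outputs["simulate"],
                                                  outputs["maps"])),
        ("stats", lambda: stage_stats(config, outputs["tractometry"],
                                      outputs["simulate"]["cohort"])),
        ("tbca", lambda: stage_tbca(config, outputs["simulate"], outputs["maps"])),
    ]
    for name, fn in stages:
        logger.info("pipeline: running stage %s", name)
        try:
            outputs[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return outputs
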