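"""End-to-end orchestration: cohort -> surface maps -> statistics -> reports.

The group analysis follows the study design the package implements:

1. every subject's tract surfaces are matched from the atlas surfaces by
   currents-based LDDMM, giving a per-vertex log-Jacobian "surface
   deformation map" per tract;
2. the subject's FA volume is projected onto the matched surface (whose
   vertices correspond one-to-one with atlas vertices), giving a per-vertex
   FA map;
3. vertex-wise GLMs with a permutation omnibus, PCA + t-test component
   selection + LOOCV LDA classification, and a canonical-score correlation
   with MMSE are run on the stacked maps — the deformation-map GLM controls
   for intracranial volume, the FA-map GLM uses diagnosis only;
4. baseline analyses (per-tract volume and mean FA with an LDA classifier
   over significant ROIs) mirror the traditional ROI approach.

Group analyses consume the cohort's tract surfaces directly (one vertex
ordering shared with the atlas); the volumetric segmentation stage is
validated separately by Dice overlap against the generator's label truth.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_registration import (ElasticitySchedule, MultiChannelImage, dice,
                                 image_lddmm, propagate_labels)
from .lddmm_surface import KernelSpec, MatchOptions, MatchResult, match_surfaces
from .mesh_core import TriMesh, mesh_volume
from .stats_pipeline import (
    ClassifierResult, DesignMatrix, bonferroni_threshold, canonical_scores,
    classify_maps, lda_loocv, pearson_corr, permutation_omnibus, select_pcs,
    pca_reduce, vertexwise_glm,
)
from .surface_maps import deformation_map, project_fa, roi_summaries
from .synthetic_cohort import (AtlasBundle, SubjectRecord, generate_atlas,
                               generate_cohort)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; all seeds explicit.

    ``from_toml`` loads the same fields from a flat TOML file (unknown keys
    are rejected so typos cannot silently fall back to defaults).
    """

    seed: int = 0
    n_tracts: int = 3
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_con: int = 19
    n_ad: int = 13
    sigma_v: float = 10.0
    sigma_w: float = 5.0
    match_weight: float = 1.0
    n_steps: int = 10
    max_iter: int = 60
    max_control_points: int = 100
    elasticity_ratios: tuple[float, ...] = (0.01, 0.005, 0.0025)
    compression_scale: float = 0.8
    fa_delta: float = 0.08
    segment_subjects: int = 2
    alpha: float = 0.05
    n_perm: int = 10000
    classifier_mode: str = "paper"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effect(self) -> "EffectSpec":
        from .synthetic_cohort import EffectSpec

        return EffectSpec(compression_scale=self.compression_scale,
                          fa_delta=self.fa_delta)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "elasticity_ratios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def subject_maps(atlas: AtlasBundle, subject: SubjectRecord,
                 kernels: KernelSpec = KernelSpec(), weight: float = 1.0,
                 opts: MatchOptions | None = None
                 ) -> tuple[np.ndarray, np.ndarray, list[MatchResult]]:
    """Deformation and FA maps for one subject, concatenated over tracts.

    Returns ``(logjac_vector, fa_vector, match_results)`` where the vectors
    stack per-tract per-vertex values in atlas vertex order.
    """
    opts = opts or MatchOptions(max_iter=60, max_control_points=100, rel_tol=1e-5)
    lj_parts, fa_parts, results = [], [], []
    for k, (atlas_mesh, subj_mesh) in enumerate(
            zip(atlas.tract_meshes, subject.tract_meshes)):
        res = match_surfaces(atlas_mesh, subj_mesh, kernels, weight, opts)
        results.append(res)
        lj = deformation_map(res.diffeo, atlas_mesh, tract_id=k + 1)
        lj_parts.append(lj.values)
        fa = project_fa(subject.fa_volume, subject.label_volume == (k + 1),
                        subj_mesh, atlas.world_affine, tract_id=k + 1)
        fa_parts.append(fa.values)
    return np.concatenate(lj_parts), np.concatenate(fa_parts), results


def cohort_maps(atlas: AtlasBundle, subjects: list[SubjectRecord],
                kernels: KernelSpec = KernelSpec(), weight: float = 1.0,
                opts: MatchOptions | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (n_subjects x n_vertices_total) deformation and FA maps."""
    lj_rows, fa_rows = [], []
    for s in subjects:
        lj, fa, _ = subject_maps(atlas, s, kernels, weight, opts)
        lj_rows.append(lj)
        fa_rows.append(fa)
    return np.vstack(lj_rows), np.vstack(fa_rows)


def cohort_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "group": [s.group for s in subjects],
        "diagnosis": [1 if s.group == "AD" else 0 for s in subjects],
        "icv_mm3": [s.icv_mm3 for s in subjects],
        "mmse": [s.mmse for s in subjects],
        "severity": [s.severity for s in subjects],
    })


def roi_features(atlas: AtlasBundle, subjects: list[SubjectRecord]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject tract volumes (mesh-based, mm^3) and label mean FA."""
    volumes, mean_fa = [], []
    for s in subjects:
        volumes.append([mesh_volume(m) for m in s.tract_meshes])
        rois = roi_summaries(s.label_volume, s.fa_volume, atlas.voxel_size,
                             tract_ids=list(range(1, atlas.n_tracts + 1)))
        mean_fa.append([r.mean_fa for r in rois])
    return np.asarray(volumes), np.asarray(mean_fa)


@dataclass
class GroupAnalysis:
    """Full statistical battery on one cohort."""

    table: pd.DataFrame
    deformation_glm_p: np.ndarray
    deformation_perm_p: float
    fa_perm_p: float
    shape_classifier: ClassifierResult
    shape_selected_pcs: np.ndarray
    fa_classifier: ClassifierResult
    fa_selected_pcs: np.ndarray
    volume_classifier: ClassifierResult | None
    meanfa_classifier: ClassifierResult | None
    shape_canonical_r: float
    shape_canonical_p: float
    fa_canonical_r: float
    fa_canonical_p: float
    bonferroni: float


def analyze_cohort(atlas: AtlasBundle, subjects: list[SubjectRecord],
                   lj_maps: np.ndarray, fa_maps: np.ndarray,
                   alpha: float = 0.05, n_perm: int = 2000,
                   seed: int = 0, mode: str = "paper") -> GroupAnalysis:
    """Run the statistical battery on precomputed map stacks."""
    table = cohort_table(subjects)
    y = table["diagnosis"].to_numpy()
    icv = table["icv_mm3"].to_numpy()
    mmse = table["mmse"].to_numpy()

    design_shape = DesignMatrix(y, covariates=icv[:, None],
                                covariate_names=("icv",))
    design_fa = DesignMatrix(y)

    glm_shape = vertexwise_glm(lj_maps, design_shape)
    perm_shape = permutation_omnibus(lj_maps, design_shape, alpha=alpha,
                                     n_perm=n_perm, seed=seed)
    perm_fa = permutation_omnibus(fa_maps, design_fa, alpha=alpha,
                                  n_perm=n_perm, seed=seed + 1)

    shape_clf, shape_sel = classify_maps(lj_maps, y, alpha=alpha, mode=mode)
    fa_clf, fa_sel = classify_maps(fa_maps, y, alpha=alpha, mode=mode)

    volumes, mean_fa = roi_features(atlas, subjects)
    vol_clf = _roi_classifier(volumes, y, icv=icv, alpha=alpha)
    mfa_clf = _roi_classifier(mean_fa, y, icv=None, alpha=alpha)

    shape_canon = _canonical_vs_mmse(lj_maps, y, mmse, alpha, mode)
    fa_canon = _canonical_vs_mmse(fa_maps, y, mmse, alpha, mode)

    return GroupAnalysis(
        table=table,
        deformation_glm_p=glm_shape.p,
        deformation_perm_p=perm_shape.overall_p,
        fa_perm_p=perm_fa.overall_p,
        shape_classifier=shape_clf, shape_selected_pcs=shape_sel,
        fa_classifier=fa_clf, fa_selected_pcs=fa_sel,
        volume_classifier=vol_clf, meanfa_classifier=mfa_clf,
        shape_canonical_r=shape_canon[0], shape_canonical_p=shape_canon[1],
        fa_canonical_r=fa_canon[0], fa_canonical_p=fa_canon[1],
        bonferroni=bonferroni_threshold(alpha, atlas.n_tracts),
    )


def _roi_classifier(features: np.ndarray, y: np.ndarray,
                    icv: np.ndarray | None, alpha: float) -> ClassifierResult | None:
    """ROI baseline: keep tracts with significant group difference, LDA LOOCV.

    Falls back to the single most significant tract when none passes, so
    the baseline always reports a number (as a weakest-feature classifier).
    """
    from scipy import stats as sps

    feats = np.asarray(features, dtype=np.float64)
    pvals = []
    for j in range(feats.shape[1]):
        x = feats[:, j]
        if icv is not None:
            design = DesignMatrix(y, covariates=icv[:, None])
            pvals.append(float(vertexwise_glm(x[:, None], design).p[0]))
        else:
            pvals.append(sps.ttest_ind(x[y == 0], x[y == 1], equal_var=True).pvalue)
    pvals = np.asarray(pvals)
    sel = np.flatnonzero(pvals < alpha)
    if sel.size == 0:
        sel = np.array([int(np.argmin(pvals))])
    return lda_loocv(feats[:, sel], y)


def _canonical_vs_mmse(maps: np.ndarray, y: np.ndarray, mmse: np.ndarray,
                       alpha: float, mode: str) -> tuple[float, float]:
    pca = pca_reduce(maps)
    sel, pv = select_pcs(pca.scores, y, alpha=alpha)
    if sel.size == 0:
        sel = np.array([int(np.argmin(pv))])
    res = canonical_scores(pca.scores[:, sel], y, mmse=mmse)
    return res.pearson_r, res.p


def analysis_report(analysis: GroupAnalysis) -> dict:
    """JSON-serializable summary in the conventional reporting precision."""
    def clf(c: ClassifierResult | None) -> dict | None:
        if c is None:
            return None
        return {"accuracy_pct": c.accuracy_pct, "sensitivity_pct": c.sensitivity_pct,
                "specificity_pct": c.specificity_pct, "f_score": c.f_score,
                "confusion": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp}}

    return {
        "n_con": int((analysis.table["diagnosis"] == 0).sum()),
        "n_ad": int((analysis.table["diagnosis"] == 1).sum()),
        "deformation_permutation_p": analysis.deformation_perm_p,
        "fa_permutation_p": analysis.fa_perm_p,
        "shape_classifier": clf(analysis.shape_classifier),
        "shape_selected_pcs_1based": [int(i) + 1 for i in analysis.shape_selected_pcs],
        "fa_classifier": clf(analysis.fa_classifier),
        "fa_selected_pcs_1based": [int(i) + 1 for i in analysis.fa_selected_pcs],
        "volume_classifier": clf(analysis.volume_classifier),
        "meanfa_classifier": clf(analysis.meanfa_classifier),
        "shape_canonical_mmse_r": round(analysis.shape_canonical_r, 4),
        "shape_canonical_mmse_p": round(analysis.shape_canonical_p, 4),
        "fa_canonical_mmse_r": round(analysis.fa_canonical_r, 4),
        "fa_canonical_mmse_p": round(analysis.fa_canonical_p, 4),
        "bonferroni_threshold": round(analysis.bonferroni, 4),
    }


PIPELINE_STAGES = ("simulate", "segment", "maps", "stats", "classify", "report")

# file inputs / outputs per stage (inputs additionally include the config);
# the provenance manifest hashes both sides for every stage.
_STAGE_IO: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "simulate": ((), ("cohort.csv",)),
    "segment": (("cohort.csv",), ("segmentation_dice.csv",)),
    "maps": (("cohort.csv",), ("deformation_maps.csv", "fa_maps.csv")),
    "stats": (("cohort.csv", "deformation_maps.csv", "fa_maps.csv"),
              ("stats.json",)),
    "classify": (("cohort.csv", "deformation_maps.csv", "fa_maps.csv"),
                 ("classify.json",)),
    "report": (("stats.json", "classify.json"), ("report.json",)),
}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it.

    The run directory keeps ``stage_state.json`` listing the stages that
    completed before the failure, so ``run_pipeline(..., resume=True)`` with
    the identical config picks up from the failed stage.
    """

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _setup_run_logging(log_path: Path) -> logging.Logger:
    logger = logging.getLogger("tractsurf.pipeline")
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        h.close()
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    for handler in (logging.FileHandler(log_path), logging.StreamHandler()):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    logger.propagate = False
    return logger


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _maps_frame(arr: np.ndarray, subject_ids) -> pd.DataFrame:
    df = pd.DataFrame(arr, columns=[f"v{j}" for j in range(arr.shape[1])])
    df.insert(0, "subject_id", list(subject_ids))
    return df


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> dict:
    """Run the full study into ``out_dir`` and return the final report dict.

    Stages run in the fixed order simulate -> segment -> maps -> stats ->
    classify -> report.  Each stage writes its outputs before the next one
    starts and records completion in ``stage_state.json``; a failure raises
    :class:`StageError` naming the stage, and a rerun with ``resume=True``
    and the identical config skips completed stages by reloading their
    files.  Every output is deterministic given the config, so rerunning
    with the same config reproduces the artifacts bit for bit.

    ``provenance.json`` records the config, its hash, the seed, and the
    SHA-256 of every stage's input and output files.  ``run.log`` receives
    structured logs (also echoed to the console).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _setup_run_logging(out / "run.log")
    cfg_hash = config.config_hash()
    state_path = out / "stage_state.json"

    completed: list[str] = []
    if resume and state_path.exists():
        prior = json.loads(state_path.read_text())
        if prior.get("config_hash") == cfg_hash:
            completed = [s for s in prior.get("completed", [])
                         if s in PIPELINE_STAGES]
            log.info("resuming; completed stages: %s",
                     ", ".join(completed) or "none")
        else:
            log.warning("existing run used a different config; starting over")
    log.info("config hash %s, seed %d", cfg_hash, config.seed)

    def _run(stage: str, fn) -> None:
        if stage in completed:
            log.info("stage %s: already complete, skipping", stage)
            return
        log.info("stage %s: started", stage)
        try:
            fn()
        except Exception as exc:
            log.error("stage %s: failed: %s", stage, exc)
            raise StageError(stage, str(exc)) from exc
        completed.append(stage)
        state_path.write_text(json.dumps(
            {"config_hash": cfg_hash, "seed": config.seed,
             "completed": completed}, indent=2))
        log.info("stage %s: done", stage)

    # --- simulate -------------------------------------------------------
    atlas: AtlasBundle | None = None
    subjects: list[SubjectRecord] | None = None

    def _generate() -> None:
        nonlocal atlas, subjects
        atlas = generate_atlas(config.n_tracts, config.grid_shape,
                               seed=config.seed)
        subjects = generate_cohort(atlas, config.n_con, config.n_ad,
                                   config.effect(), seed=config.seed)

    def _simulate() -> None:
        _generate()
        cohort_table(subjects).to_csv(out / "cohort.csv", index=False)

    _run("simulate", _simulate)
    if atlas is None:
        # the stage was skipped on resume; later stages still need the
        # deterministic in-memory cohort (cheap next to surface matching)
        try:
            _generate()
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc

    # --- segment --------------------------------------------------------
    def _segment() -> None:
        n = min(config.segment_subjects, len(subjects))
        rows = []
        if n > 0:
            img_atlas = MultiChannelImage(
                {"FA": atlas.channels["FA"], "b0": atlas.channels["b0"]},
                voxel_size=atlas.voxel_size, world_affine=atlas.world_affine)
            schedule = ElasticitySchedule(config.elasticity_ratios)
            for s in subjects[:n]:
                img_s = MultiChannelImage(
                    {"FA": s.fa_volume, "b0": s.b0_volume},
                    voxel_size=atlas.voxel_size,
                    world_affine=atlas.world_affine)
                deform = image_lddmm(img_atlas, img_s, schedule,
                                     iters_per_stage=30)
                labels, _ = propagate_labels(deform, atlas.label_volume, [])
                for k in range(1, atlas.n_tracts + 1):
                    d = dice(labels == k, s.label_volume == k)
                    rows.append({"subject_id": s.subject_id, "tract": k,
                                 "dice": round(d, 4)})
                    log.info("segment %s tract %d: dice %.3f",
                             s.subject_id, k, d)
        pd.DataFrame(rows, columns=["subject_id", "tract", "dice"]).to_csv(
            out / "segmentation_dice.csv", index=False)

    _run("segment", _segment)

    # --- maps -----------------------------------------------------------
    lj: np.ndarray | None = None
    fa: np.ndarray | None = None

    def _maps() -> None:
        nonlocal lj, fa
        kernels = KernelSpec(config.sigma_v, config.sigma_w)
        opts = MatchOptions(n_steps=config.n_steps, max_iter=config.max_iter,
                            max_control_points=config.max_control_points,
                            rel_tol=1e-5)
        lj, fa = cohort_maps(atlas, subjects, kernels, config.match_weight,
                             opts)
        ids = [s.subject_id for s in subjects]
        _maps_frame(lj, ids).to_csv(out / "deformation_maps.csv", index=False)
        _maps_frame(fa, ids).to_csv(out / "fa_maps.csv", index=False)

    _run("maps", _maps)
    if lj is None:
        lj = pd.read_csv(out / "deformation_maps.csv").drop(
            columns="subject_id").to_numpy(np.float64)
        fa = pd.read_csv(out / "fa_maps.csv").drop(
            columns="subject_id").to_numpy(np.float64)

    table = cohort_table(subjects)
    y = table["diagnosis"].to_numpy()
    icv = table["icv_mm3"].to_numpy()
    mmse = table["mmse"].to_numpy()

    # --- stats ----------------------------------------------------------
    stats_out: dict = {}

    def _stats() -> None:
        nonlocal stats_out
        design_shape = DesignMatrix(y, covariates=icv[:, None],
                                    covariate_names=("icv",))
        design_fa = DesignMatrix(y)
        perm_shape = permutation_omnibus(lj, design_shape, alpha=config.alpha,
                                         n_perm=config.n_perm,
                                         seed=config.seed)
        perm_fa = permutation_omnibus(fa, design_fa, alpha=config.alpha,
                                      n_perm=config.n_perm,
                                      seed=config.seed + 1)
        stats_out = {
            "config_hash": cfg_hash, "seed": config.seed,
            "n_vertices": int(lj.shape[1]), "n_perm": config.n_perm,
            "deformation_suprathreshold_vertices": int(perm_shape.observed_count),
            "deformation_permutation_p": perm_shape.overall_p,
            "fa_suprathreshold_vertices": int(perm_fa.observed_count),
            "fa_permutation_p": perm_fa.overall_p,
            "bonferroni_threshold": round(
                bonferroni_threshold(config.alpha, atlas.n_tracts), 6),
        }
        (out / "stats.json").write_text(json.dumps(stats_out, indent=2))

    _run("stats", _stats)
    if not stats_out:
        stats_out = json.loads((out / "stats.json").read_text())

    # --- classify -------------------------------------------------------
    classify_out: dict = {}

    def _classify() -> None:
        nonlocal classify_out
        shape_clf, shape_sel = classify_maps(lj, y, alpha=config.alpha,
                                             mode=config.classifier_mode)
        fa_clf, fa_sel = classify_maps(fa, y, alpha=config.alpha,
                                       mode=config.classifier_mode)
        volumes, mean_fa = roi_features(atlas, subjects)
        vol_clf = _roi_classifier(volumes, y, icv=icv, alpha=config.alpha)
        mfa_clf = _roi_classifier(mean_fa, y, icv=None, alpha=config.alpha)
        shape_canon = _canonical_vs_mmse(lj, y, mmse, config.alpha,
                                         config.classifier_mode)
        fa_canon = _canonical_vs_mmse(fa, y, mmse, config.alpha,
                                      config.classifier_mode)

        def clf(c: ClassifierResult) -> dict:
            return {"accuracy_pct": c.accuracy_pct,
                    "sensitivity_pct": c.sensitivity_pct,
                    "specificity_pct": c.specificity_pct,
                    "f_score": c.f_score,
                    "confusion": {"tp": c.tp, "fn": c.fn,
                                  "tn": c.tn, "fp": c.fp}}

        classify_out = {
            "config_hash": cfg_hash, "seed": config.seed,
            "mode": config.classifier_mode,
            "shape_classifier": clf(shape_clf),
            "shape_selected_pcs_1based": [int(i) + 1 for i in shape_sel],
            "fa_classifier": clf(fa_clf),
            "fa_selected_pcs_1based": [int(i) + 1 for i in fa_sel],
            "volume_classifier": clf(vol_clf),
            "meanfa_classifier": clf(mfa_clf),
            "shape_canonical_mmse_r": round(shape_canon[0], 4),
            "shape_canonical_mmse_p": round(shape_canon[1], 4),
            "fa_canonical_mmse_r": round(fa_canon[0], 4),
            "fa_canonical_mmse_p": round(fa_canon[1], 4),
        }
        (out / "classify.json").write_text(json.dumps(classify_out, indent=2))

    _run("classify", _classify)
    if not classify_out:
        classify_out = json.loads((out / "classify.json").read_text())

    # --- report ---------------------------------------------------------
    report: dict = {}

    def _report() -> None:
        nonlocal report
        strip = ("config_hash", "seed")
        report = {
            "config_hash": cfg_hash,
            "seed": config.seed,
            "n_con": config.n_con,
            "n_ad": config.n_ad,
            "stats": {k: v for k, v in stats_out.items() if k not in strip},
            "classification": {k: v for k, v in classify_out.items()
                               if k not in strip},
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        manifest = {
            stage: {
                "inputs": {name: _sha256(out / name) for name in io[0]},
                "outputs": {name: _sha256(out / name) for name in io[1]},
            }
            for stage, io in _STAGE_IO.items()
        }
        provenance = {
            "config": asdict(config) | {
                "grid_shape": list(config.grid_shape),
                "elasticity_ratios": list(config.elasticity_ratios)},
            "config_hash": cfg_hash,
            "seed": config.seed,
            "stages": manifest,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    _run("report", _report)
    if not report:
        report = json.loads((out / "report.json").read_text())
    log.info("run complete: %s", out / "report.json")
    return report
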