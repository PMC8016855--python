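"""Config-driven end-to-end joint shape-modeling pipeline.

Orchestrates the full workflow on a cohort manifest: reflect left bones →
preprocess → ICP-align across subjects on a reference bone (preserving the
within-subject weightbearing pose) → common cutting plane → correspondence
particles → GPA → PCA with parallel analysis → mode warps and distance
maps → then, back in the original scanner pose, curvature → candidate
articular regions → coverage → joint-space distance → congruence →
per-particle population maps → paired-area statistics, emitting audit CSVs
and report tables at every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, articulation, correspondence, curvature, geometry, modes

DEFAULTS = {
    "seed": 0,
    "reference_bone": "talus",
    "particles": 1024,
    "refine_rounds": 1,
    "preprocess": {"smoothing_iterations": 10, "smoothing_factor": 0.5,
                   "target_face_count": None},
    "icp": {"max_iterations": 50, "sample_count": 500, "rms_tolerance": 1e-6},
    "pca": {"n_reps": 200, "percentile": 95.0},
    "cut_bones": [],
    "cut_axis": [0.0, 0.0, 1.0],
    "inclusion_rule": 0.5,
    "warp_k_sd": 2.0,
}


class PipelineError(RuntimeError):
    """Stage failure with the stage name and offending subject."""

    def __init__(self, stage: str, message: str, subject_id: str | None = None):
        self.stage = stage
        self.subject_id = subject_id
        where = f"stage {stage!r}" + (f", subject {subject_id!r}" if subject_id else "")
        super().__init__(f"{where}: {message}")


@dataclass
class JointConfig:
    name: str
    bone_a: str
    bone_b: str
    threshold_a: articulation.ThresholdSpec
    threshold_b: articulation.ThresholdSpec
    max_ray_length: float = 10.0
    particle_bone: str | None = None  # defaults to bone_a


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat YAML-compatible mapping)."""

    manifest: list            # rows: {subject_id, side, bone, path|mesh}
    joints: list
    output_dir: Path
    seed: int = 0
    reference_bone: str = "talus"
    particles: int = 1024
    refine_rounds: int = 1
    preprocess: dict = field(default_factory=lambda: dict(DEFAULTS["preprocess"]))
    icp: dict = field(default_factory=lambda: dict(DEFAULTS["icp"]))
    pca: dict = field(default_factory=lambda: dict(DEFAULTS["pca"]))
    cut_bones: list = field(default_factory=list)
    cut_axis: list = field(default_factory=lambda: [0.0, 0.0, 1.0])
    inclusion_rule: float = 0.5
    warp_k_sd: float = 2.0
    defaults_used: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        defaults_used = [k for k in DEFAULTS if k not in raw]
        joints = []
        for j in raw.get("joints", []):
            joints.append(JointConfig(
                name=j["name"], bone_a=j["bone_a"], bone_b=j["bone_b"],
                threshold_a=articulation.ThresholdSpec(**j["threshold_a"]),
                threshold_b=articulation.ThresholdSpec(**j["threshold_b"]),
                max_ray_length=j.get("max_ray_length", 10.0),
                particle_bone=j.get("particle_bone")))
        cfg = cls(
            manifest=raw["manifest"], joints=joints,
            output_dir=Path(raw["output_dir"]),
            seed=raw.get("seed", DEFAULTS["seed"]),
            reference_bone=raw.get("reference_bone", DEFAULTS["reference_bone"]),
            particles=raw.get("particles", DEFAULTS["particles"]),
            refine_rounds=raw.get("refine_rounds", DEFAULTS["refine_rounds"]),
            preprocess={**DEFAULTS["preprocess"], **raw.get("preprocess", {})},
            icp={**DEFAULTS["icp"], **raw.get("icp", {})},
            pca={**DEFAULTS["pca"], **raw.get("pca", {})},
            cut_bones=raw.get("cut_bones", []),
            cut_axis=raw.get("cut_axis", DEFAULTS["cut_axis"]),
            inclusion_rule=raw.get("inclusion_rule", DEFAULTS["inclusion_rule"]),
            warp_k_sd=raw.get("warp_k_sd", DEFAULTS["warp_k_sd"]),
            defaults_used=defaults_used)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        sides = {}
        for row in self.manifest:
            for key in ("subject_id", "bone"):
                if key not in row:
                    raise PipelineError("validate", f"manifest row missing {key!r}")
            if "mesh" not in row:
                p = Path(row.get("path", ""))
                if not p.exists():
                    raise PipelineError("validate", f"mesh path {p} not found",
                                        row["subject_id"])
            side = row.get("side", "n/a")
            prev = sides.setdefault(row["subject_id"], side)
            if prev != side:
                raise PipelineError(
                    "validate",
                    "one limb per subject: sides "
                    f"{prev!r} and {side!r} both present", row["subject_id"])
        bones = self.bones()
        if self.reference_bone not in bones:
            raise PipelineError(
                "validate", f"reference bone {self.reference_bone!r} absent "
                f"from manifest bones {sorted(bones)}")
        for j in self.joints:
            for b in (j.bone_a, j.bone_b):
                if b not in bones:
                    raise PipelineError("validate",
                                        f"joint {j.name!r} uses unknown bone {b!r}")

    def bones(self):
        return sorted({row["bone"] for row in self.manifest})

    def subjects(self):
        seen = []
        for row in self.manifest:
            if row["subject_id"] not in seen:
                seen.append(row["subject_id"])
        return seen


@dataclass
class PipelineResult:
    config: PipelineConfig
    models: dict            # bone → CorrespondenceModel
    modesets: dict          # bone → ShapeModeSet
    mean_surfaces: dict     # bone → SurfaceMesh
    joint_results: dict     # joint name → dict of per-joint outputs
    table1: pd.DataFrame
    table2: pd.DataFrame


def run(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; deterministic under the configured seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = config.subjects()
    bones = config.bones()

    # -- load, reflect, preprocess (original = weightbearing scanner pose) --
    original = {b: {} for b in bones}
    for row in config.manifest:
        sid, bone = row["subject_id"], row["bone"]
        try:
            mesh = row.get("mesh")
            if mesh is None:
                mesh = geometry.load_mesh(row["path"], bone_label=bone,
                                          side=row.get("side", "n/a"),
                                          subject_id=sid)
            else:
                mesh = mesh.copy()
                mesh.subject_id = sid
                if bone in geometry.BONE_LABELS:
                    mesh.bone_label = bone
                mesh.side = row.get("side", mesh.side)
            if mesh.side == "left":
                mesh = geometry.reflect_mesh(mesh)
            mesh = geometry.preprocess_mesh(mesh, **config.preprocess)
        except Exception as exc:
            raise PipelineError("preprocess", str(exc), sid) from exc
        original[bone][sid] = mesh

    # -- cross-subject alignment on the reference bone -----------------------
    ref_bone = config.reference_bone
    ref_subject = subjects[0]
    aligned = {b: {} for b in bones}
    transforms = {}
    for sid in subjects:
        try:
            if sid == ref_subject:
                t = geometry.RigidTransform.identity()
            else:
                res = alignment.icp_align(original[ref_bone][sid],
                                          original[ref_bone][ref_subject],
                                          seed=config.seed, **config.icp)
                t = res.transform
            transforms[sid] = t
            for b in bones:
                m = original[b][sid].copy()
                m.vertices = t.apply(m.vertices)
                aligned[b][sid] = m
        except Exception as exc:
            raise PipelineError("align", str(exc), sid) from exc
    (out / "transforms.json").write_text(json.dumps(
        {s: json.loads(t.to_json()) for s, t in transforms.items()}, indent=1))

    # -- cutting plane, correspondence, PCA per bone --------------------------
    planes = {}
    for b in config.cut_bones:
        planes[b] = alignment.common_cutting_plane(aligned[b].values(),
                                                   axis=config.cut_axis)
    model_by_bone, modeset_by_bone, mean_surface = {}, {}, {}
    mode_rows = []
    for b in bones:
        try:
            model = correspondence.build_correspondence_model(
                aligned[b], P=config.particles, cutting_plane=planes.get(b),
                seed=config.seed, refine_rounds=config.refine_rounds,
                icp_kwargs=config.icp)
            modeset = modes.fit_modes(model)
            data = model.particle_matrix(aligned=True).reshape(len(subjects), -1)
            modeset.n_significant = modes.parallel_analysis(
                data, seed=config.seed, **config.pca)
            _, msurf = correspondence.mean_shape(model)
        except Exception as exc:
            raise PipelineError("correspondence", str(exc), b) from exc
        model_by_bone[b] = model
        modeset_by_bone[b] = modeset
        mean_surface[b] = msurf
        model.save(out / f"correspondence_{b}")
        geometry.save_mesh(msurf, out / f"mean_{b}.ply")
        for row in modes.mode_summary_rows(modeset):
            mode_rows.append({"bone": b, **row})
        for mi in range(modeset.n_significant or 0):
            for k in (+config.warp_k_sd, -config.warp_k_sd):
                warped = modes.warp_mode(modeset, mi, k, msurf,
                                         model.mean_particles)
                dist = modes.mode_distance_map(msurf, warped)
                geometry.save_mesh(warped, out / f"{b}_mode{mi + 1}_{k:+g}sd.ply",
                                   scalars={"distance_mm": dist})
    pd.DataFrame(mode_rows).to_csv(out / "mode_summary.csv", index=False)

    # -- joint analyses in the original pose ----------------------------------
    curv_cache = {}

    def curv(bone, sid):
        key = (bone, sid)
        if key not in curv_cache:
            curv_cache[key] = curvature.curvature_field(original[bone][sid])
        return curv_cache[key]

    joint_results = {}
    t1_rows, t2_rows, particle_rows = [], [], []
    for jc in config.joints:
        pbone = jc.particle_bone or jc.bone_a
        if pbone != jc.bone_a:
            raise PipelineError(
                f"joint:{jc.name}",
                "particle maps are evaluated on bone_a; set bone_a to the "
                f"particle bone (got particle_bone={pbone!r})")
        model = model_by_bone[pbone]
        area_a, area_b = [], []
        dist_by_subject, ci_by_subject = {}, {}
        for sid in subjects:
            try:
                mesh_a = original[jc.bone_a][sid]
                mesh_b = original[jc.bone_b][sid]
                cand_a = articulation.candidate_region(
                    mesh_a, curv(jc.bone_a, sid), jc.threshold_a, jc.name)
                cand_b = articulation.candidate_region(
                    mesh_b, curv(jc.bone_b, sid), jc.threshold_b, jc.name)
                cov_a, cov_b = articulation.coverage(cand_a, cand_b,
                                                     jc.max_ray_length)
                area_a.append(cov_a.area)
                area_b.append(cov_b.area)

                dist = articulation.joint_space(cov_a, mesh_b)
                node_dist = np.full(mesh_a.n_vertices, np.nan)
                node_dist[cov_a.vertex_ids] = dist
                pairs = articulation.pair_opposing_vertices(cov_a, cov_b)
                recs = articulation.congruence_arrays(
                    curv(jc.bone_a, sid).H[pairs[:, 0]],
                    curv(jc.bone_a, sid).G[pairs[:, 0]],
                    curv(jc.bone_b, sid).H[pairs[:, 1]],
                    curv(jc.bone_b, sid).G[pairs[:, 1]])
                node_ci = np.full(mesh_a.n_vertices, np.nan)
                node_ci[pairs[:, 0]] = recs[5]

                assign, _, _ = correspondence.map_particles(
                    model.mean_particles, mesh_a,
                    mean_surface=mean_surface[pbone],
                    icp_kwargs={**config.icp, "seed": config.seed})
                dist_by_subject[sid] = articulation.particle_values_from_nodes(
                    assign, node_dist)
                ci_by_subject[sid] = articulation.particle_values_from_nodes(
                    assign, node_ci)
            except Exception as exc:
                raise PipelineError(f"joint:{jc.name}", str(exc), sid) from exc

        try:
            dist_map = articulation.particle_map(dist_by_subject, jc.name,
                                                 config.inclusion_rule)
            ci_map = articulation.particle_map(ci_by_subject, jc.name,
                                               config.inclusion_rule)
            stats = (articulation.paired_area_stats(area_a, area_b)
                     if len(area_a) >= 2 else None)
        except Exception as exc:
            raise PipelineError(f"joint:{jc.name}", str(exc)) from exc

        joint_results[jc.name] = {
            "areas_a": np.array(area_a), "areas_b": np.array(area_b),
            "distance_map": dist_map, "ci_map": ci_map, "area_stats": stats}
        t1_rows.append(_table1_row(jc, area_a, area_b, stats))
        t2_rows.append(_table2_row(jc.name, dist_map, ci_map))
        for pm, kind in ((dist_map, "distance_mm"), (ci_map, "congruence_mm-1")):
            for k, pid in enumerate(pm.particle_ids):
                particle_rows.append({
                    "joint": jc.name, "field": kind, "particle_id": int(pid),
                    "n_subjects": int((~np.isnan(pm.values[:, k])).sum()),
                    "mean": pm.per_particle_mean[k], "sd": pm.per_particle_sd[k]})

    table1 = pd.DataFrame(t1_rows)
    table2 = pd.DataFrame(t2_rows)
    table1.to_csv(out / "table1_coverage.csv", index=False)
    table2.to_csv(out / "table2_distance_congruence.csv", index=False)
    pd.DataFrame(particle_rows).to_csv(out / "particle_maps.csv", index=False)

    log = {"seed": config.seed, "defaults_not_overridden": config.defaults_used,
           "preprocess": config.preprocess, "icp": config.icp,
           "pca": config.pca, "particles": config.particles,
           "inclusion_rule": config.inclusion_rule,
           "subjects": subjects, "bones": bones}
    (out / "run_log.json").write_text(json.dumps(log, indent=1))

    return PipelineResult(config, model_by_bone, modeset_by_bone, mean_surface,
                          joint_results, table1, table2)


def _table1_row(jc: JointConfig, area_a, area_b, stats) -> dict:
    row = {"joint": jc.name, "bone_a": jc.bone_a, "bone_b": jc.bone_b,
           "n": len(area_a),
           "area_a_mean": float(np.mean(area_a)),
           "area_a_sd": float(np.std(area_a, ddof=1)) if len(area_a) > 1 else np.nan,
           "area_b_mean": float(np.mean(area_b)),
           "area_b_sd": float(np.std(area_b, ddof=1)) if len(area_b) > 1 else np.nan}
    if stats is None or stats.degenerate:
        row.update({"t": np.nan, "p": np.nan, "cohens_d": np.nan,
                    "effect": "", "power": np.nan})
    else:
        row.update({"t": stats.t, "p": stats.p_two_tailed,
                    "cohens_d": stats.cohens_d, "effect": stats.effect_label,
                    "power": stats.posthoc_power})
    return row


def _table2_row(name: str, dist_map, ci_map) -> dict:
    return {"joint": name,
            "distance_mean": dist_map.global_mean,
            "distance_sd": dist_map.global_sd,
            "distance_min": dist_map.global_min,
            "distance_max": dist_map.global_max,
            "distance_mean_of_particle_means": dist_map.mean_of_particle_means(),
            "ci_mean": ci_map.global_mean,
            "ci_sd": ci_map.global_sd,
            "ci_min": ci_map.global_min,
            "ci_max": ci_map.global_max,
            "ci_mean_of_particle_means": ci_map.mean_of_particle_means(),
            "n_particles_distance": len(dist_map.particle_ids),
            "n_particles_ci": len(ci_map.particle_ids)}


def report_tables(result: PipelineResult, directory=None):
    """Re-emit the Table-1/Table-2 style reports from a completed run."""
    directory = Path(directory or result.config.output_dir)
    directory.mkdir(parents=True, exist_ok=True)
    result.table1.to_csv(directory / "table1_coverage.csv", index=False)
    result.table2.to_csv(directory / "table2_distance_congruence.csv",
                         index=False)
    return (directory / "table1_coverage.csv",
            directory / "table2_distance_congruence.csv")
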