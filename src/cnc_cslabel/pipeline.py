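"""Configured end-to-end pipeline: build -> decorate -> simulate -> detect
-> analyze -> compare.

A single YAML/dict document (schema-validated, unknown keys rejected)
drives every stage; one global seed fans out to per-stage seeds through a
counter-based derivation so each stage is independently reproducible.
Every artifact is written with provenance and the run report records the
artifact hashes, so a rerun with the same config reproduces them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as _io
from .analysis import SpacingReport, compare_models, distinct_spacings, group_rows, rdf
from .decoration import LabelGeometry, OccupancyModel, decorate_model
from .detection import classify_pixels, match_to_truth, segment_and_centroid, smooth
from .lattice import build_cnc, build_unit_cell, face_on_rotation
from .substrate import CarbonSlab, generate_carbon
from .synthetic_data import SceneSpec, generate_scene

__all__ = ["PipelineConfig", "run_pipeline", "StageError", "stage_seed"]

log = logging.getLogger("cnc_cslabel")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and artifact dir."""

    def __init__(self, stage: str, out_dir: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed in {out_dir}: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    return int(np.random.SeedSequence((global_seed, stage_index)).generate_state(1)[0] % (2**31))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BuildStage(_Strict):
    habit: str = "diamond"
    n_chains: int = 24
    length_repeats: int = 4


class DecorateStage(_Strict):
    facet: str = "(110)"
    both_sides: bool = True
    coverage: float = 1.0
    f_cs: float = 1.0
    f_na: float = 0.0
    f_h: float = 0.0
    elevation: float = 45.0
    conformer: str | None = None


class SubstrateStage(_Strict):
    thickness_nm: float = 2.0
    area_nm: tuple[float, float] = (10.0, 10.0)
    density_g_cm3: float = 2.0
    min_separation: float = 1.2


class SynthStage(_Strict):
    n_cncs: int = 1
    habit: str = "diamond"
    n_chains: int = 24
    length_repeats: int = 5
    facet: str = "(110)"
    coverage: float = 1.0
    f_cs: float = 1.0
    jitter_sigma_pm: float = 30.0
    vacancy_rate: float = 0.05
    dose_scale: float = 1.0
    noise: bool = True
    field_nm: tuple[float, float] = (9.0, 9.0)
    in_plane_rotations: tuple[float, ...] | str = (20.0,)
    substrate: bool = True


class DetectStage(_Strict):
    # k_sigma 12: frames containing the crystal body need a threshold well
    # above the projected light-atom lattice texture, not just shot noise
    mode: str = "threshold"
    k_sigma: float = 12.0
    min_area: int = 4
    match_radius_nm: float = 0.1


class AnalyzeStage(_Strict):
    rdf_bin_width_nm: float = 0.02
    rdf_r_max_nm: float = 3.0


class CompareCandidate(_Strict):
    habit: str
    n_chains: int
    facet: str


class CompareStage(_Strict):
    candidates: list[CompareCandidate] = Field(
        default_factory=lambda: [
            CompareCandidate(habit="diamond", n_chains=24, facet="(110)"),
            CompareCandidate(habit="rectangular", n_chains=24, facet="(010)"),
        ]
    )
    length_repeats: int = 5


class PipelineConfig(_Strict):
    """One document holding every stage's spec plus seed and output dir."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    build: BuildStage | None = Field(default_factory=BuildStage)
    decorate: DecorateStage | None = Field(default_factory=DecorateStage)
    substrate: SubstrateStage | None = Field(default_factory=SubstrateStage)
    synth: SynthStage | None = Field(default_factory=SynthStage)
    detect: DetectStage | None = Field(default_factory=DetectStage)
    analyze: AnalyzeStage | None = Field(default_factory=AnalyzeStage)
    compare: CompareStage | None = Field(default_factory=CompareStage)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml

        return PipelineConfig.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; returns the report dict.

    The report lists every artifact with its content hash and, when both
    synthetic truth and detections exist, the detection metrics and model
    comparison table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    report: dict = {"artifacts": {}, "stages": []}
    cell = build_unit_cell()
    model = decorated = scene_res = detections = measured = None

    def record(name: str, path: Path):
        report["artifacts"][name] = {"path": str(path), "hash": _file_hash(path)}

    stages = [
        ("build", config.build), ("decorate", config.decorate),
        ("substrate", config.substrate), ("synth", config.synth),
        ("detect", config.detect), ("analyze", config.analyze),
        ("compare", config.compare),
    ]
    for idx, (name, stage) in enumerate(stages):
        if stage is None:
            continue
        seed = stage_seed(config.seed, idx)
        log.info("stage %s (seed %d)", name, seed)
        try:
            if name == "build":
                model = build_cnc(cell, stage.habit, stage.n_chains, stage.length_repeats)
                p = out / "model.xyz"
                _io.write_xyz(model.atoms, p)
                record("model", p)
            elif name == "decorate":
                if model is None:
                    raise ValueError("decorate requires the build stage")
                facets = [model.facet(stage.facet, True)]
                if stage.both_sides:
                    facets.append(model.facet(stage.facet, False))
                occ = OccupancyModel(
                    f_cs=stage.f_cs, f_na=stage.f_na, f_h=stage.f_h,
                    coverage=stage.coverage, seed=seed,
                )
                decorated = decorate_model(
                    model, facets, occ, LabelGeometry(elevation=stage.elevation),
                    conformer_override=stage.conformer,
                )
                p = out / "decorated.xyz"
                _io.write_xyz(decorated.atoms, p)
                record("decorated", p)
            elif name == "substrate":
                slab = CarbonSlab(
                    thickness_nm=stage.thickness_nm, area_nm=tuple(stage.area_nm),
                    density_g_cm3=stage.density_g_cm3,
                    min_separation=stage.min_separation, seed=seed,
                )
                sub = generate_carbon(slab)
                p = out / "substrate.xyz"
                _io.write_xyz(sub, p)
                record("substrate", p)
            elif name == "synth":
                spec = SceneSpec(
                    n_cncs=stage.n_cncs, habit=stage.habit, n_chains=stage.n_chains,
                    length_repeats=stage.length_repeats, facet=stage.facet,
                    occupancy=OccupancyModel(
                        f_cs=stage.f_cs, f_na=max(0.0, (1 - stage.f_cs) / 2),
                        f_h=max(0.0, 1 - stage.f_cs - max(0.0, (1 - stage.f_cs) / 2)),
                        coverage=stage.coverage,
                    ),
                    jitter_sigma_pm=stage.jitter_sigma_pm,
                    vacancy_rate=stage.vacancy_rate,
                    substrate=CarbonSlab() if stage.substrate else None,
                    dose_scale=stage.dose_scale, noise=stage.noise,
                    field_nm=tuple(stage.field_nm),
                    in_plane_rotations=(
                        stage.in_plane_rotations
                        if isinstance(stage.in_plane_rotations, str)
                        else tuple(stage.in_plane_rotations)
                    ),
                    seed=seed,
                )
                scene_res = generate_scene(spec)
                p = out / "scene.tiff"
                _io.write_tiff(scene_res.micrograph, p)
                scene_res.truth.to_csv(out / "truth.csv", index=False)
                record("scene", p)
                record("truth", out / "truth.csv")
            elif name == "detect":
                if scene_res is None:
                    raise ValueError("detect requires the synth stage")
                img = smooth(scene_res.micrograph)
                mask = classify_pixels(img, mode=stage.mode, k_sigma=stage.k_sigma)
                detections = segment_and_centroid(mask, img, min_area=stage.min_area)
                p = out / "detections.csv"
                detections.table.to_csv(p, index=False)
                record("detections", p)
                m = match_to_truth(
                    detections, scene_res.truth[["x_nm", "y_nm"]].to_numpy(),
                    radius_nm=stage.match_radius_nm,
                )
                report["detection_metrics"] = {
                    "recall": m.recall, "precision": m.precision, "rmse_pm": m.rmse_pm,
                }
            elif name == "analyze":
                if detections is None or len(detections) < 2:
                    raise ValueError("analyze requires detections (run synth + detect)")
                pos = detections.positions_nm
                r = rdf(pos, bin_width=stage.rdf_bin_width_nm, r_max=stage.rdf_r_max_nm)
                pd.DataFrame({"r_nm": r.bin_centers, "g": r.g}).to_csv(
                    out / "rdf.csv", index=False
                )
                record("rdf", out / "rdf.csv")
                # axis from config when the scene orientation is known;
                # PCA of the positions otherwise
                axis = None
                if config.synth is not None and not isinstance(
                    config.synth.in_plane_rotations, str
                ):
                    phi = np.radians(config.synth.in_plane_rotations[0])
                    axis = np.array([np.cos(phi), np.sin(phi)])
                rows = group_rows(pos, axis_direction=axis, units_per_A=0.1)
                from .analysis import _principal_axis

                if axis is None:
                    axis = _principal_axis(pos)
                perp = np.array([-axis[1], axis[0]])
                u = pos @ perp * 10.0
                centers = sorted(float(np.mean(u[rw])) for rw in rows)
                inter = np.diff(centers)
                along = []
                for rw in rows:
                    t = np.sort(pos[rw] @ axis * 10.0)
                    d = np.diff(t)
                    along.extend(d[d > 0.5])
                measured = SpacingReport(
                    along_axis_spacings=np.array(along),
                    along_axis_errors=np.zeros(len(along)),
                    inter_line_spacings=np.asarray(inter),
                    inter_line_errors=np.zeros(len(inter)),
                    axis_direction=axis, method="rows",
                )
                summary = {
                    "along_axis_A": [list(t) for t in distinct_spacings(measured.along_axis_spacings)],
                    "inter_line_A": [list(t) for t in distinct_spacings(measured.inter_line_spacings)],
                }
                (out / "spacings.json").write_text(json.dumps(summary, indent=1))
                record("spacings", out / "spacings.json")
            elif name == "compare":
                if measured is None:
                    raise ValueError("compare requires the analyze stage")
                cands = []
                for c in stage.candidates:
                    m = build_cnc(cell, c.habit, c.n_chains, stage.length_repeats)
                    occ = OccupancyModel(f_cs=1.0, f_na=0.0, f_h=0.0, coverage=1.0, seed=0)
                    m = decorate_model(
                        m, [m.facet(c.facet, True), m.facet(c.facet, False)], occ
                    )
                    cands.append((f"{c.habit}-{c.n_chains}", m, face_on_rotation(m, c.facet)))
                table = compare_models(measured, cands)
                table.to_json(out / "comparison.json", orient="records", indent=1)
                record("comparison", out / "comparison.json")
                report["comparison"] = table.to_dict(orient="records")
            report["stages"].append(name)
        except Exception as e:  # noqa: BLE001 - stage failures must carry context
            log.exception("stage %s failed", name)
            log.removeHandler(fh)
            raise StageError(name, str(out), e) from e
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    log.removeHandler(fh)
    return report
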