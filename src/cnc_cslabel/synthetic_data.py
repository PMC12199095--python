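"""Synthetic micrographs with ground truth.

Emulates the statistical structure of the experimental raw data: one or a
few parallel ~3 nm-wide nanocrystals lying face-on on a ~2 nm amorphous
carbon film at an arbitrary in-plane rotation, decorated with sulfate/Cs
labels at fractional occupancy, imaged with a ~100 pm probe and shot
noise.  Beam damage enters phenomenologically as Gaussian positional
jitter of the label atoms and random Cs vacancies.  Every frame carries a
complete ground-truth table of the rendered Cs positions, so detection
and spacing analysis can be validated quantitatively.

Default scenes are desk-scale (a 10x10 nm field with 1-3 crystals of a
few repeats), not the 50-200 nm experimental bundles; the crystal
cross-sections, label statistics (15 % coverage, 86 % Cs), probe and dose
defaults follow the experimental values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .decoration import LabelGeometry, OccupancyModel, decorate_model
from .imaging import Micrograph, ProbeParams, add_noise, render
from .lattice import CNCModel, build_cnc, build_unit_cell, face_on_rotation
from .substrate import CarbonSlab, generate_carbon

__all__ = ["SceneSpec", "SceneResult", "generate_scene", "fixture_suite"]


@dataclass(frozen=True)
class SceneSpec:
    """Complete specification of one synthetic micrograph."""

    n_cncs: int = 2
    habit: str = "diamond"
    n_chains: int = 24
    length_repeats: int = 6
    facet: str = "(110)"  # decorated / beam-facing family
    decorate_both_sides: bool = True
    in_plane_rotations: tuple[float, ...] | str = "random"  # degrees, or "random"
    tilt_about_axis: float = 0.0  # extra rotation about [001] away from face-on
    occupancy: OccupancyModel = field(default_factory=OccupancyModel)
    geom: LabelGeometry = field(default_factory=LabelGeometry)
    jitter_sigma_pm: float = 30.0
    vacancy_rate: float = 0.1
    substrate: CarbonSlab | None = field(default_factory=CarbonSlab)
    probe: ProbeParams = field(default_factory=ProbeParams)
    dose_scale: float = 1.0
    noise: bool = True
    field_nm: tuple[float, float] = (10.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_cncs < 1:
            raise ValueError("n_cncs must be >= 1")
        if not (0.0 <= self.vacancy_rate <= 1.0):
            raise ValueError("vacancy_rate must lie in [0, 1]")
        if self.jitter_sigma_pm < 0:
            raise ValueError("jitter_sigma_pm must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.substrate is None:
            d["substrate"] = None
        return d

    @staticmethod
    def from_dict(d: dict) -> "SceneSpec":
        d = dict(d)
        if d.get("occupancy") is not None:
            d["occupancy"] = OccupancyModel(**d["occupancy"])
        if d.get("geom") is not None:
            d["geom"] = LabelGeometry(**d["geom"])
        if d.get("substrate") is not None:
            sub = dict(d["substrate"])
            sub["area_nm"] = tuple(sub["area_nm"])
            d["substrate"] = CarbonSlab(**sub)
        if d.get("probe") is not None:
            p = dict(d["probe"])
            for k in ("haadf_range_mrad", "adf_range_mrad"):
                p[k] = tuple(p[k])
            d["probe"] = ProbeParams(**p)
        for k in ("field_nm",):
            d[k] = tuple(d[k])
        if isinstance(d.get("in_plane_rotations"), list):
            d["in_plane_rotations"] = tuple(d["in_plane_rotations"])
        return SceneSpec(**d)


@dataclass
class SceneResult:
    micrograph: Micrograph
    truth: pd.DataFrame  # x_nm, y_nm, cnc, chain, residue, facet
    scene: pd.DataFrame  # full atom table in scene coordinates
    models: list[CNCModel]


def _model_to_scene(atoms: pd.DataFrame, theta_deg: float, phi_deg: float, shift_A):
    """Model frame -> scene frame: face-on about [001], then lay the chain
    axis into the image plane, then rotate in-plane and translate.

    Scene basis: x = model z (chain axis), y = model x, z = beam = model y.
    """
    th, ph = np.radians(theta_deg), np.radians(phi_deg)
    x = atoms["x"].to_numpy() * np.cos(th) - atoms["y"].to_numpy() * np.sin(th)
    y = atoms["x"].to_numpy() * np.sin(th) + atoms["y"].to_numpy() * np.cos(th)
    z = atoms["z"].to_numpy()
    sx, sy, sz = z, x, y
    rx = sx * np.cos(ph) - sy * np.sin(ph) + shift_A[0]
    ry = sx * np.sin(ph) + sy * np.cos(ph) + shift_A[1]
    out = atoms.copy()
    out["x"], out["y"], out["z"] = rx, ry, sz + shift_A[2]
    return out


def generate_scene(spec: SceneSpec) -> SceneResult:
    """Build, decorate, damage, compose and render one synthetic frame."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(6 + 2 * spec.n_cncs) % (2**31)
    rng_place = np.random.default_rng(seeds[0])
    rng_rot = np.random.default_rng(seeds[1])
    rng_vac = np.random.default_rng(seeds[2])
    rng_jit = np.random.default_rng(seeds[3])

    cell = build_unit_cell()
    fx, fy = spec.field_nm[0] * 10.0, spec.field_nm[1] * 10.0
    length_A = spec.length_repeats * cell.c
    # projected footprint radius: half the chain length plus cross-section
    half_extent = length_A / 2.0 + 20.0

    if spec.in_plane_rotations == "random":
        phis = rng_rot.uniform(0.0, 360.0, size=spec.n_cncs)
    else:
        phis = list(spec.in_plane_rotations)
        if len(phis) < spec.n_cncs:
            raise ValueError("need one in-plane rotation per CNC")

    models, parts, truth_rows = [], [], []
    centers: list[np.ndarray] = []
    for i in range(spec.n_cncs):
        model = build_cnc(cell, spec.habit, spec.n_chains, spec.length_repeats)
        facets = [model.facet(spec.facet, True)]
        if spec.decorate_both_sides:
            facets.append(model.facet(spec.facet, False))
        occ = dataclasses.replace(spec.occupancy, seed=int(seeds[6 + 2 * i]))
        model = decorate_model(model, facets, occ, spec.geom)
        models.append(model)

        theta = face_on_rotation(model, spec.facet) + spec.tilt_about_axis
        # place with bounded retries; crystals must fit the field and must
        # not overlap in projection
        lo_x, hi_x = min(half_extent, fx / 2.0), max(fx - half_extent, fx / 2.0)
        lo_y, hi_y = min(half_extent, fy / 2.0), max(fy - half_extent, fy / 2.0)
        for attempt in range(200):
            cx = rng_place.uniform(lo_x, hi_x) if hi_x > lo_x else fx / 2.0
            cy = rng_place.uniform(lo_y, hi_y) if hi_y > lo_y else fy / 2.0
            c = np.array([cx, cy])
            if all(np.linalg.norm(c - o) > 35.0 for o in centers):
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_cncs} crystals of length {length_A:.0f} Å "
                f"without overlap in a {spec.field_nm} nm field"
            )
        centers.append(c)
        placed = _model_to_scene(model.atoms, theta, float(phis[i]), (cx, cy, 20.0))
        placed["cnc"] = i
        parts.append(placed)

    scene = pd.concat(parts, ignore_index=True)

    # beam damage: random Cs vacancies, then positional jitter of the labels
    is_cs = scene["role"] == "Cs"
    if spec.vacancy_rate > 0 and is_cs.sum() > 0:
        cs_idx = np.flatnonzero(is_cs)
        n_drop = int(round(spec.vacancy_rate * len(cs_idx)))
        drop = rng_vac.choice(cs_idx, size=n_drop, replace=False)
        scene = scene.drop(index=scene.index[drop]).reset_index(drop=True)
    lab = scene["role"].isin(["S", "Cs", "Na"]).to_numpy()
    if spec.jitter_sigma_pm > 0 and lab.any():
        jit = rng_jit.normal(0.0, spec.jitter_sigma_pm / 100.0, size=(int(lab.sum()), 2))
        scene.loc[lab, "x"] += jit[:, 0]
        scene.loc[lab, "y"] += jit[:, 1]

    if spec.substrate is not None:
        slab = dataclasses.replace(
            spec.substrate, area_nm=spec.field_nm, seed=int(seeds[4])
        )
        sub = generate_carbon(slab, z_top=0.0)
        sub["cnc"] = -1
        scene = pd.concat([scene, sub], ignore_index=True)

    img = render(scene, spec.probe, extent=(0.0, fx, 0.0, fy))
    if spec.noise:
        img = add_noise(img, spec.probe, spec.dose_scale, seed=int(seeds[5]))
    img.provenance.update({"spec_seed": spec.seed})

    cs = scene[scene["role"] == "Cs"]
    inside = (cs["x"] >= 0) & (cs["x"] <= fx) & (cs["y"] >= 0) & (cs["y"] <= fy)
    cs = cs[inside]  # the truth lists rendered Cs only
    truth = pd.DataFrame(
        {
            "x_nm": cs["x"].to_numpy() / 10.0,
            "y_nm": cs["y"].to_numpy() / 10.0,
            "cnc": cs["cnc"].to_numpy(int),
            "chain": cs["chain"].to_numpy(int),
            "residue": cs["residue"].to_numpy(int),
            "facet": cs["facet"].to_numpy() if "facet" in cs else "",
        }
    ).reset_index(drop=True)
    return SceneResult(micrograph=img, truth=truth, scene=scene, models=models)


_FIXTURES = [
    ("diamond24_faceon", {"habit": "diamond", "n_chains": 24, "seed": 11}),
    ("diamond18_faceon", {"habit": "diamond", "n_chains": 18, "seed": 12}),
    ("rect24_faceon", {"habit": "rectangular", "n_chains": 24, "facet": "(010)", "seed": 13}),
    ("rect18_faceon", {"habit": "rectangular", "n_chains": 18, "facet": "(010)", "seed": 14}),
    ("diamond24_tilt_p15", {"habit": "diamond", "n_chains": 24, "tilt_about_axis": 15.0, "seed": 15}),
    ("diamond24_tilt_m15", {"habit": "diamond", "n_chains": 24, "tilt_about_axis": -15.0, "seed": 16}),
    ("diamond24_lowdose", {"habit": "diamond", "n_chains": 24, "dose_scale": 0.2, "seed": 17}),
    ("diamond24_highdose", {"habit": "diamond", "n_chains": 24, "dose_scale": 10.0, "seed": 18}),
]


def fixture_suite(out_dir) -> dict:
    """Write a small canonical set of scenes with a reproducibility manifest.

    Each entry records the full SceneSpec and seed, so every image and
    truth table can be regenerated bit-identically from the manifest
    alone.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"scenes": []}
    for name, over in _FIXTURES:
        spec = SceneSpec(n_cncs=1, length_repeats=4, field_nm=(7.0, 7.0),
                         in_plane_rotations=(25.0,), **over)
        res = generate_scene(spec)
        _io.write_tiff(res.micrograph, out / f"{name}.tiff")
        res.truth.to_csv(out / f"{name}_truth.csv", index=False)
        _io.write_xyz(res.scene, out / f"{name}.xyz")
        manifest["scenes"].append(
            {
                "name": name,
                "spec": spec.to_dict(),
                "image_hash": _io.scene_hash(res.scene),
                "n_truth": int(len(res.truth)),
                "tags": sorted(set(over) - {"seed"}),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
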