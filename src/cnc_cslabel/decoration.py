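"""Sulfate/Cs surface labels on C6 sites.

Each sulfated site is approximated by a rigid two-atom arm anchored at the
surface O6: a sulfur placed 145 pm from O6 and a counterion (Cs or Na)
250 pm further, the two bonds forming a 120° angle and zig-zagging in the
plane spanned by the facet normal and the chain axis (tilted toward +c).
Keeping the arm in that plane means the label adds no transverse offset in
a face-on projection — measured Cs line positions then reflect the chain
and O6 geometry alone.  H counterions contribute no atom (hydrogens are
omitted globally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .lattice import CNCModel, Facet, enumerate_surface_c6, facet_belongs

__all__ = [
    "LabelGeometry",
    "OccupancyModel",
    "assign_conformer",
    "place_label",
    "decorate_model",
    "CONFORMER_BY_FACET",
]

# Facet-dependent hydroxymethyl rotamer: gg dominates at free surfaces, but
# interchain hydrogen bonding on (200) and steric constraints on (1-10)
# leave those faces in the bulk-like tg state.
CONFORMER_BY_FACET = {"(110)": "gg", "(010)": "gg", "(200)": "tg", "(1-10)": "tg"}

_MIN_SEPARATION = 0.8  # Å, hard-sphere floor for any atom pair


@dataclass(frozen=True)
class LabelGeometry:
    """Rigid geometry of the simplified sulfate/counterion arm."""

    o6_s_distance: float = 1.45  # Å (145 pm)
    s_cs_distance: float = 2.50  # Å (250 pm)
    azimuth: float = 120.0  # degrees between successive bonds
    elevation: float = 45.0  # degrees of the O6-S bond above the facet plane
    bridging_oxygen: bool = False  # optionally insert O between S and Cs

    def __post_init__(self):
        if self.o6_s_distance <= 0 or self.s_cs_distance <= 0:
            raise ValueError("bond distances must be positive")
        if not (0.0 <= self.elevation <= 90.0):
            raise ValueError("elevation must lie in [0, 90] degrees")


@dataclass(frozen=True)
class OccupancyModel:
    """Fractional sulfation coverage and counterion composition."""

    f_cs: float = 0.86
    f_na: float = 0.06
    f_h: float = 0.08
    coverage: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if abs(self.f_cs + self.f_na + self.f_h - 1.0) > 1e-9:
            raise ValueError("counterion fractions must sum to 1")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")


def assign_conformer(facet) -> str:
    """Facet-dependent C5-C6-O6 rotamer used for the label orientation."""
    label = facet.miller_label if isinstance(facet, Facet) else str(facet)
    try:
        return CONFORMER_BY_FACET[label]
    except KeyError:
        raise ValueError(f"unknown facet {label!r}") from None


def _arm_positions(o6: np.ndarray, normal: np.ndarray, geom: LabelGeometry) -> list[np.ndarray]:
    """S (and optional bridging O) and counterion positions for one site."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    # tilt toward -c: the +c side above each O6 is blocked by the screw
    # partner's outward hydroxyls
    c_hat = np.array([0.0, 0.0, -1.0])
    e1 = math.radians(geom.elevation)
    d1 = math.sin(e1) * n + math.cos(e1) * c_hat
    s = o6 + geom.o6_s_distance * d1
    # second bond: rotate by the bond-angle supplement within the same plane
    bend = math.radians(180.0 - geom.azimuth)
    e2 = e1 + bend
    d2 = math.sin(e2) * n + math.cos(e2) * c_hat
    out = [s]
    if geom.bridging_oxygen:
        out.append(s + 0.5 * geom.s_cs_distance * d2)
    out.append(s + geom.s_cs_distance * d2)
    return out


def place_label(
    site,
    conformer: str,
    geom: LabelGeometry,
    counterion: str,
    normal: np.ndarray,
    existing_tree: cKDTree | None = None,
) -> pd.DataFrame:
    """Atoms added by labeling one C6 site (possibly none, for H).

    ``site`` is a row of :func:`enumerate_surface_c6` output.  Raises if a
    placed atom falls within 0.8 Å of an existing atom (``existing_tree``).
    """
    if counterion not in ("Cs", "Na", "H"):
        raise ValueError(f"unsupported counterion {counterion!r}")
    if counterion == "H":
        return pd.DataFrame(columns=["element", "x", "y", "z", "chain", "residue", "role"])
    o6 = np.array([site["o6x"], site["o6y"], site["o6z"]], dtype=float)
    pos = _arm_positions(o6, normal, geom)
    elements = ["S"] + (["O"] if geom.bridging_oxygen else []) + [counterion]
    roles = ["S"] + (["backbone"] if geom.bridging_oxygen else []) + [counterion]
    if existing_tree is not None:
        for p in pos:
            d, _ = existing_tree.query(p)
            if d < _MIN_SEPARATION:
                raise ValueError(
                    f"label collision at chain {int(site['chain'])} residue "
                    f"{int(site['residue'])}: placed atom {d:.2f} Å from an existing atom"
                )
    rows = [
        (el, p[0], p[1], p[2], int(site["chain"]), int(site["residue"]), role)
        for el, role, p in zip(elements, roles, pos)
    ]
    return pd.DataFrame(rows, columns=["element", "x", "y", "z", "chain", "residue", "role"])


def decorate_model(
    model: CNCModel,
    facets: list[Facet],
    occupancy: OccupancyModel,
    geom: LabelGeometry | None = None,
    conformer_override: str | None = None,
) -> CNCModel:
    """Return a copy of the model with sulfate/counterion labels attached.

    With ``coverage=1`` and ``f_cs=1`` every accessible C6 site on the
    listed facets is occupied by S+Cs (the full-occupation simulation
    regime).  Fractional coverage selects round(coverage x n_sites) sites
    uniformly without replacement; counterions are drawn per site from
    (f_cs, f_na, f_h).  Deterministic under ``occupancy.seed``.
    """
    geom = geom or LabelGeometry()
    for f in facets:
        if not facet_belongs(model, f):
            raise ValueError(f"facet {f.miller_label} does not belong to the model")
    rng = np.random.default_rng(occupancy.seed)
    tree = cKDTree(model.atoms[["x", "y", "z"]].to_numpy())
    added = []
    for f in facets:
        sites = enumerate_surface_c6(model, f)
        n_dec = int(round(occupancy.coverage * len(sites)))
        idx = np.sort(rng.choice(len(sites), size=n_dec, replace=False)) if n_dec else []
        ions = rng.choice(
            ["Cs", "Na", "H"], size=n_dec, p=[occupancy.f_cs, occupancy.f_na, occupancy.f_h]
        )
        conf = conformer_override or assign_conformer(f)
        n2, _ = model.cell.facet_frame(f.miller_label)
        sign = "+" if float(np.dot(f.outward_normal[:2], n2)) > 0 else "-"
        for i, ion in zip(idx, ions):
            d = place_label(sites.iloc[int(i)], conf, geom, str(ion), f.outward_normal, tree)
            d["facet"] = f.miller_label + sign
            d["conformer"] = conf
            added.append(d)
    added = [d for d in added if len(d)]
    atoms = model.atoms if not added else pd.concat([model.atoms, *added], ignore_index=True)
    return CNCModel(
        atoms=atoms,
        habit=model.habit,
        n_chains=model.n_chains,
        length_repeats=model.length_repeats,
        facets=model.facets,
        chain_xy=model.chain_xy,
        cell=model.cell,
    )
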