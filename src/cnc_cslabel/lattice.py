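"""Cellulose Iβ lattice and nanocrystal cross-section builder.

The cellulose Iβ crystal is monoclinic (unique axis c, the chain axis):
two parallel glucan chains per cell — an "origin" chain on the cell corners
and a "center" chain at (1/2, 1/2) offset by c/4 along the axis — each with
a two-fold screw along c, so one c-repeat holds two anhydroglucose units
(AGUs) per chain.  All analytic spacings used downstream derive from the
four cell constants:

    a = 7.784 Å, b = 8.201 Å, c = 10.380 Å, γ = 96.5°

Cross-sections are built as explicit per-layer chain maps (config data,
overridable) for the two habits discussed for 18/24-chain elementary
fibrils: a diamond bounded by {110}/{1-10} facets and a near-rectangular
slab bounded by {010}/{200}.

Facet row-spacing convention: chains lying *within* a (110) bounding plane
are separated by (a−b)/2 (5.96 Å ≈ 6.0), within (1-10) by (a+b)/2 (5.33 Å ≈
5.3), within (200) by b (8.2 Å) and within (010) by a (7.8 Å).  This is the
assignment consistent with observed inter-line distances of 6–7 Å being
attributed to {110}-type faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "Facet",
    "CNCModel",
    "build_unit_cell",
    "plane_spacing",
    "interchain_row_spacing",
    "build_cnc",
    "enumerate_surface_c6",
    "face_on_rotation",
    "FACET_LABELS",
    "CHAIN_LAYOUTS",
]

# Iβ cell constants (monoclinic, chain axis c).
CELL_A = 7.784
CELL_B = 8.201
CELL_C = 10.380
CELL_GAMMA = 96.5

FACET_LABELS = ("(110)", "(1-10)", "(200)", "(010)")

# Idealized AGU heavy-atom template in a chain-local frame: z along the
# chain axis, y' along the exocyclic (C6/O6) direction, x' the transverse
# pucker direction.  Only the C6/O6 placement is structurally load-bearing:
# O6 sits 0.65 Å off the chain axis along y', which fixes where Cs lines
# fall relative to chain rows in projection.  Hydrogens are omitted.
_AGU_TEMPLATE_LOCAL = [
    # (element, role, x', y', z)
    ("C", "backbone", +0.25, 0.00, -1.45),  # C1
    ("C", "backbone", -0.25, -0.90, -0.73),  # C2
    ("C", "backbone", +0.25, -0.90, 0.73),  # C3
    ("C", "backbone", -0.25, 0.00, 1.45),  # C4
    ("C", "backbone", +0.25, 0.90, 0.73),  # C5
    ("O", "backbone", -0.25, 0.90, -0.73),  # O5 (ring)
    ("O", "backbone", -0.30, -1.95, -1.35),  # O2
    ("O", "backbone", +0.30, -1.95, 1.35),  # O3
    ("C", "C6", 0.00, 0.55, 2.10),
    ("O", "O6", 0.00, 0.65, 3.10),
]

# Direction of the exocyclic arm in the Cartesian (a-along-x) cell frame.
# The transverse O6 offset vector is |p| * P_HAT = (0.25, 0.60) Å.
_P_VEC = np.array([0.25, 0.60])
_P_NORM = float(np.linalg.norm(_P_VEC))
_P_HAT = _P_VEC / _P_NORM
_X_HAT = np.array([_P_HAT[1], -_P_HAT[0]])  # right-handed in-plane partner

# Explicit chain maps per (habit, n_chains): list of layers, each layer a
# dict with the layer index along the stacking normal and the integer
# k-window of chains within the layer.  Diamond layers stack along the
# (110) normal (one full `a` translation per layer, in-layer step
# (a-b)/2); rectangular layers stack along the (010) normal in half-b*
# steps ((a+b)/2 translation per layer, in-layer step a).  Windows were
# chosen to center each row and give the documented habit outline.
CHAIN_LAYOUTS: dict[tuple[str, int], dict] = {
    ("diamond", 24): {"row_sizes": [4, 5, 6, 5, 4]},
    ("diamond", 18): {"row_sizes": [3, 4, 4, 4, 3]},
    ("rectangular", 24): {"row_sizes": [4, 4, 4, 4, 4, 4]},
    ("rectangular", 18): {"row_sizes": [3, 3, 3, 3, 3, 3]},
}


@dataclass(frozen=True)
class UnitCell:
    """Cellulose Iβ unit cell (monoclinic, chain axis along c)."""

    a: float = CELL_A
    b: float = CELL_B
    c: float = CELL_C
    gamma: float = CELL_GAMMA
    agu_template: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not (90.0 < self.gamma < 180.0):
            raise ValueError("gamma must lie in (90, 180) degrees")

    @property
    def a_vec(self) -> np.ndarray:
        return np.array([self.a, 0.0, 0.0])

    @property
    def b_vec(self) -> np.ndarray:
        g = math.radians(self.gamma)
        return np.array([self.b * math.cos(g), self.b * math.sin(g), 0.0])

    @property
    def c_vec(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.c])

    def reciprocal_2d(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane reciprocal vectors a*, b* with a*.a = 1, a*.b = 0."""
        A = np.stack([self.a_vec[:2], self.b_vec[:2]])
        G = np.linalg.inv(A).T
        return G[0], G[1]

    def facet_frame(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(outward normal, in-plane row vector), both 2D, for a facet family.

        The row vector is the shortest chain-lattice translation lying in
        the facet plane; the normal is the unit outward direction of the
        positive-side facet.
        """
        astar, bstar = self.reciprocal_2d()
        a2, b2 = self.a_vec[:2], self.b_vec[:2]
        if label == "(110)":
            n, row = astar + bstar, (a2 - b2) / 2.0
        elif label == "(1-10)":
            n, row = astar - bstar, (a2 + b2) / 2.0
        elif label == "(200)":
            n, row = astar, b2
        elif label == "(010)":
            n, row = bstar, a2
        else:
            raise ValueError(f"unsupported facet label {label!r}; expected one of {FACET_LABELS}")
        n = n / np.linalg.norm(n)
        if np.dot(n, row) > 1e-9:  # pragma: no cover - orthogonal by construction
            raise AssertionError("facet frame not orthogonal")
        return n, row

    def screw_phase(self) -> float:
        """Axial offset between the two screw-related AGUs of one chain."""
        return self.c / 2.0


@dataclass(eq=False)
class Facet:
    """One bounding face of a nanocrystal cross-section."""

    miller_label: str
    outward_normal: np.ndarray  # 3D unit vector, z-component 0
    member_chain_ids: list[int]
    row_vector: np.ndarray  # 3D, in facet plane, perpendicular to normal

    def __post_init__(self):
        self.outward_normal = np.asarray(self.outward_normal, dtype=float)
        if abs(self.outward_normal[2]) > 1e-9:
            raise ValueError("facet normal must be perpendicular to the chain axis")


@dataclass
class CNCModel:
    """Atomistic nanocrystal model: a bundle of parallel chains along +z."""

    atoms: pd.DataFrame  # columns: element, x, y, z, chain, residue, role
    habit: str
    n_chains: int
    length_repeats: int
    facets: list[Facet]
    chain_xy: dict[int, np.ndarray]  # chain id -> axis position in the xy plane
    cell: UnitCell

    def facet(self, label: str, positive: bool = True) -> Facet:
        """Look up a facet by family label and normal sign."""
        want = None
        for f in self.facets:
            if f.miller_label != label:
                continue
            n, _ = self.cell.facet_frame(label)
            s = float(np.dot(f.outward_normal[:2], n))
            if (s > 0) == positive:
                want = f
        if want is None:
            raise ValueError(f"model has no facet {label!r} (positive={positive})")
        return want

    def positions(self, roles: list[str] | None = None) -> np.ndarray:
        df = self.atoms if roles is None else self.atoms[self.atoms.role.isin(roles)]
        return df[["x", "y", "z"]].to_numpy()


def build_unit_cell() -> UnitCell:
    """Return the cellulose Iβ cell with the idealized AGU template.

    The template is stored as fractional coordinates of one AGU of the
    origin chain and one of the center chain (offset (1/2, 1/2, 1/4)).
    """
    cell = UnitCell()
    M = np.stack([cell.a_vec, cell.b_vec, cell.c_vec]).T  # cart = M @ frac
    Minv = np.linalg.inv(M)
    template = {}
    for chain_kind, shift in (("origin", np.zeros(3)), ("center", np.array([0.5, 0.5, 0.25]))):
        rows = []
        for el, role, xp, yp, z in _AGU_TEMPLATE_LOCAL:
            lat = xp * _X_HAT + yp * _P_HAT
            cart = np.array([lat[0], lat[1], z])
            frac = Minv @ cart + shift
            rows.append((el, role, tuple(frac)))
        template[chain_kind] = rows
    return UnitCell(agu_template=template)


def plane_spacing(cell: UnitCell, miller: tuple[int, int, int]) -> float:
    """Monoclinic d-spacing (unique axis c) for Miller indices (h, k, l)."""
    h, k, l = miller
    if h == 0 and k == 0 and l == 0:
        raise ValueError("Miller indices (0,0,0) have no plane spacing")
    g = math.radians(cell.gamma)
    s2 = math.sin(g) ** 2
    inv_d2 = (
        h * h / cell.a**2 + k * k / cell.b**2 - 2 * h * k * math.cos(g) / (cell.a * cell.b)
    ) / s2 + l * l / cell.c**2
    return 1.0 / math.sqrt(inv_d2)


def interchain_row_spacing(cell: UnitCell, facet) -> float:
    """Center-to-center distance of adjacent parallel chains within a facet plane.

    (110) -> |a-b|/2 = 5.96, (1-10) -> |a+b|/2 = 5.33, (200) -> |b| = 8.2,
    (010) -> |a| = 7.78 Å.
    """
    label = facet.miller_label if isinstance(facet, Facet) else str(facet)
    _, row = cell.facet_frame(label)
    return float(np.linalg.norm(row))


def _chain_lattice(cell: UnitCell, habit: str, n_chains: int, row_sizes: list[int]):
    """Return (positions xy, axial offsets, per-chain sublattice parity).

    Diamond: layer p sits at p*a (stacking along the (110) normal), chains
    within a layer at integer multiples of (a-b)/2 — the in-layer step
    alternates origin/center sublattices.  Rectangular: layer q at
    q*(a+b)/2 (half-b* stacking, whole layers alternate sublattice),
    chains within a layer at integer multiples of a.
    """
    a2, b2 = cell.a_vec[:2], cell.b_vec[:2]
    if habit == "diamond":
        layer_vec, step = a2, (a2 - b2) / 2.0
        # in-layer step flips sublattice; layer translation preserves it
        parity = lambda p, k: k % 2
    elif habit == "rectangular":
        layer_vec, step = (a2 + b2) / 2.0, a2
        parity = lambda p, k: p % 2
    else:
        raise ValueError(f"unsupported habit {habit!r}")

    u_hat = step / np.linalg.norm(step)
    layer_u = float(np.dot(layer_vec, u_hat))
    step_u = float(np.linalg.norm(step))

    xy, zoff, subl = [], [], []
    c0 = (row_sizes[0] - 1) / 2.0
    for p, size in enumerate(row_sizes):
        # Center each row near the first row while re-centering by whole
        # in-layer lattice steps, so equal-size top and bottom rows stay
        # in registry (their chains differ by a pure stacking translation).
        k0 = int(round(c0 - (size - 1) / 2.0)) - int(round(p * layer_u / step_u))
        for k in range(k0, k0 + size):
            r = p * layer_vec + k * step
            xy.append(r)
            subl.append(parity(p, k))
    xy = np.array(xy)
    xy -= xy.mean(axis=0)  # centroid at origin
    zoff = np.array([cell.c / 4.0 if s else 0.0 for s in subl])
    return xy, zoff, np.array(subl)


# Membership tolerance (Å) along the outward normal for each facet family:
# a chain belongs to a facet if it lies within this distance of the
# bounding plane.  Values are ~half the stacking period of that family.
_FACET_MEMBER_TOL = {"(110)": 2.6, "(1-10)": 2.9, "(200)": 4.0, "(010)": 2.0}

_HABIT_FACETS = {"diamond": ("(110)", "(1-10)"), "rectangular": ("(010)", "(200)")}


def build_cnc(
    cell: UnitCell,
    habit: str,
    n_chains: int,
    length_repeats: int,
    row_sizes: list[int] | None = None,
) -> CNCModel:
    """Build an atomistic nanocrystal of the given habit and chain count.

    ``length_repeats`` is the number of crystallographic c-repeats, i.e.
    each chain carries ``2 * length_repeats`` AGUs.
    """
    if length_repeats < 1:
        raise ValueError("length_repeats must be >= 1")
    key = (habit, n_chains)
    if row_sizes is None:
        if key not in CHAIN_LAYOUTS:
            supported = sorted(CHAIN_LAYOUTS)
            raise ValueError(f"unsupported (habit, n_chains) {key}; supported layouts: {supported}")
        row_sizes = CHAIN_LAYOUTS[key]["row_sizes"]
    if sum(row_sizes) != n_chains:
        raise ValueError("row_sizes do not sum to n_chains")

    xy, zoff, _ = _chain_lattice(cell, habit, n_chains, row_sizes)

    # local template in Cartesian chain frame
    tmpl = []
    for el, role, xp, yp, z in _AGU_TEMPLATE_LOCAL:
        lat = xp * _X_HAT + yp * _P_HAT
        tmpl.append((el, role, np.array([lat[0], lat[1], z])))

    records = []
    n_res = 2 * length_repeats
    for cid in range(len(xy)):
        cx, cy = xy[cid]
        for i in range(n_res):
            sgn = -1.0 if i % 2 else 1.0  # two-fold screw: 180° about the axis
            zr = zoff[cid] + i * cell.c / 2.0
            for el, role, v in tmpl:
                records.append(
                    (el, cx + sgn * v[0], cy + sgn * v[1], zr + v[2], cid, i, role)
                )
    atoms = pd.DataFrame.from_records(
        records, columns=["element", "x", "y", "z", "chain", "residue", "role"]
    )

    facets = []
    for label in _HABIT_FACETS[habit]:
        n2, row2 = cell.facet_frame(label)
        tol = _FACET_MEMBER_TOL[label]
        proj = xy @ n2
        for sign in (+1.0, -1.0):
            s = proj * sign
            members = [int(i) for i in np.flatnonzero(s >= s.max() - tol)]
            facets.append(
                Facet(
                    miller_label=label,
                    outward_normal=np.array([sign * n2[0], sign * n2[1], 0.0]),
                    member_chain_ids=members,
                    row_vector=np.array([row2[0], row2[1], 0.0]),
                )
            )

    chain_xy = {int(i): xy[i].copy() for i in range(len(xy))}
    return CNCModel(
        atoms=atoms,
        habit=habit,
        n_chains=n_chains,
        length_repeats=length_repeats,
        facets=facets,
        chain_xy=chain_xy,
        cell=cell,
    )


# Minimum outward O6 offset (Å, along the facet normal) for a C6 site to
# count as surface-accessible.
_ACCESS_MIN_OUTWARD = 0.1


def facet_belongs(model: CNCModel, facet: Facet) -> bool:
    """A facet belongs to a model if its label and normal match one of the
    model's facets (the member list may differ, e.g. user-restricted)."""
    return any(
        f.miller_label == facet.miller_label
        and np.allclose(f.outward_normal, facet.outward_normal)
        for f in model.facets
    )


def enumerate_surface_c6(model: CNCModel, facet: Facet) -> pd.DataFrame:
    """Surface-accessible C6 sites on a facet.

    Returns a DataFrame (chain, residue, c6 x/y/z, o6 x/y/z).  A site is
    accessible when its O6 points into the outward half-space of its own
    chain *and* lies within the facet's surface shell of the whole crystal
    (so interior chains never contribute).  The two-fold screw alternates
    the exocyclic arm between opposite sides of a chain, hence each chain
    exposes every other AGU — an axial period of one c-repeat, 10.4 Å, per
    facet.
    """
    if not facet_belongs(model, facet):
        raise ValueError("facet does not belong to this model")
    n2 = facet.outward_normal[:2]
    shell = max(np.dot(model.chain_xy[i], n2) for i in model.chain_xy)
    tol = _FACET_MEMBER_TOL.get(facet.miller_label, 2.6)
    sel = model.atoms[model.atoms.chain.isin(facet.member_chain_ids)]
    c6 = sel[sel.role == "C6"].sort_values(["chain", "residue"], kind="mergesort")
    o6 = sel[sel.role == "O6"].sort_values(["chain", "residue"], kind="mergesort")
    assert (c6.chain.to_numpy() == o6.chain.to_numpy()).all()
    axes = np.array([model.chain_xy[int(c)] for c in c6.chain])
    o6_xy = o6[["x", "y"]].to_numpy()
    out = ((o6_xy - axes) @ n2) >= _ACCESS_MIN_OUTWARD
    surface = (o6_xy @ n2) >= shell - tol
    keep = out & surface
    df = pd.DataFrame(
        {
            "chain": c6.chain.to_numpy()[keep],
            "residue": c6.residue.to_numpy()[keep],
            "c6x": c6.x.to_numpy()[keep],
            "c6y": c6.y.to_numpy()[keep],
            "c6z": c6.z.to_numpy()[keep],
            "o6x": o6.x.to_numpy()[keep],
            "o6y": o6.y.to_numpy()[keep],
            "o6z": o6.z.to_numpy()[keep],
        }
    )
    return df.reset_index(drop=True)


def face_on_rotation(model: CNCModel, facet_label: str, positive: bool = True) -> float:
    """Rotation about [001] (degrees) that turns the facet normal to +y.

    With the convention that the beam direction is the model +y axis after
    rotation, this is the face-on orientation for that facet.
    """
    f = model.facet(facet_label, positive=positive)
    nx, ny = f.outward_normal[:2]
    return math.degrees(math.atan2(nx, ny))
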