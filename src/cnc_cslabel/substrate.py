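"""Random amorphous-carbon support slab.

The TEM support is modeled as carbon atoms placed uniformly at random in a
box of the requested area and thickness, subject to a minimum pairwise
separation (rejection sampling).  The atom count follows from the mass
density (default 2.0 g/cm³, typical of evaporated amorphous carbon — the
thin films used as supports are ~2 nm thick).  No attempt is made at a
realistic sp2/sp3 network topology; the slab only supplies the
thickness-dependent grey background in the rendered images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["CarbonSlab", "generate_carbon", "carbon_atom_count"]

_M_CARBON_G = 12.011 * 1.66053906660e-24  # g per atom


@dataclass(frozen=True)
class CarbonSlab:
    """Specification of an amorphous-carbon support slab."""

    thickness_nm: float = 2.0
    area_nm: tuple[float, float] = (10.0, 10.0)
    density_g_cm3: float = 2.0
    min_separation: float = 1.2  # Å
    seed: int = 0

    def __post_init__(self):
        if self.thickness_nm < 0 or min(self.area_nm) < 0:
            raise ValueError("slab dimensions must be non-negative")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")


def carbon_atom_count(slab: CarbonSlab) -> int:
    """N = round(density * volume / m_C)."""
    vol_cm3 = slab.area_nm[0] * slab.area_nm[1] * slab.thickness_nm * 1e-21
    return int(round(slab.density_g_cm3 * vol_cm3 / _M_CARBON_G))


def generate_carbon(slab: CarbonSlab, z_top: float = 0.0, max_tries: int = 200) -> pd.DataFrame:
    """Uniform random carbon positions honoring the minimum separation.

    The slab occupies ``z in [z_top - thickness, z_top]`` (Å) so that with
    the default ``z_top=0`` it sits below a specimen at z > 0.  Atoms are
    drawn in bulk and offending ones redrawn; raises if the requested
    density is unreachable at the given separation.
    """
    n = carbon_atom_count(slab)
    cols = ["element", "x", "y", "z", "chain", "residue", "role"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    lx, ly = slab.area_nm[0] * 10.0, slab.area_nm[1] * 10.0
    lz = slab.thickness_nm * 10.0
    rng = np.random.default_rng(slab.seed)

    def draw(m):
        p = rng.random((m, 3))
        p[:, 0] *= lx
        p[:, 1] *= ly
        p[:, 2] = z_top - lz + p[:, 2] * lz
        return p

    pos = draw(n)
    for _ in range(max_tries):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(slab.min_separation, output_type="ndarray")
        if len(pairs) == 0:
            break
        bad = np.unique(pairs[:, 1])  # redraw the later atom of each close pair
        pos[bad] = draw(len(bad))
    else:
        raise RuntimeError(
            f"could not pack {n} C atoms at min_separation={slab.min_separation} Å "
            f"in {slab.area_nm} nm² x {slab.thickness_nm} nm after {max_tries} passes"
        )
    df = pd.DataFrame(pos, columns=["x", "y", "z"])
    df.insert(0, "element", "C")
    df["chain"] = -1
    df["residue"] = -1
    df["role"] = "substrate-C"
    return df[cols]
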