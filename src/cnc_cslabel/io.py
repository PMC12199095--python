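"""Structure and image file I/O.

Structures: extended XYZ (element + Cartesian Å, with chain/residue/role
carried in trailing columns) and CIF (via gemmi, fractional coordinates in
a P1 bounding box with custom tags for the annotations).  Images: 16-bit
TIFF with a JSON sidecar holding the pixel calibration and provenance.
Atom order is deterministic: (chain, residue, role rank, element).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_cif",
    "read_cif",
    "write_structure",
    "read_structure",
    "write_tiff",
    "read_tiff",
    "scene_hash",
]

_ROLE_RANK = {
    "backbone": 0, "C6": 1, "O6": 2, "S": 3, "Cs": 4, "Na": 5, "substrate-C": 6,
}
_COLS = ["element", "x", "y", "z", "chain", "residue", "role"]


def _canonical_order(atoms: pd.DataFrame) -> pd.DataFrame:
    df = atoms.copy()
    df["_rank"] = df["role"].map(_ROLE_RANK).fillna(99)
    df = df.sort_values(
        ["chain", "residue", "_rank", "element", "z", "x", "y"], kind="mergesort"
    )
    return df.drop(columns="_rank").reset_index(drop=True)


def scene_hash(atoms: pd.DataFrame) -> str:
    """Stable hash of an atom table (positions rounded to 0.01 pm)."""
    df = _canonical_order(atoms)
    payload = df[_COLS].round({"x": 4, "y": 4, "z": 4}).to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_xyz(atoms: pd.DataFrame, path) -> None:
    df = _canonical_order(atoms)
    lines = [str(len(df)), "element x y z chain residue role (Angstrom)"]
    for t in df.itertuples(index=False):
        lines.append(
            f"{t.element} {t.x:.6f} {t.y:.6f} {t.z:.6f} {int(t.chain)} {int(t.residue)} {t.role}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].strip())
    rows = []
    for ln in lines[2 : 2 + n]:
        el, x, y, z, chain, residue, role = ln.split()
        rows.append((el, float(x), float(y), float(z), int(chain), int(residue), role))
    return pd.DataFrame(rows, columns=_COLS)


def _box(atoms: pd.DataFrame, margin: float = 10.0) -> np.ndarray:
    lo = atoms[["x", "y", "z"]].to_numpy().min(axis=0)
    hi = atoms[["x", "y", "z"]].to_numpy().max(axis=0)
    return np.maximum(hi - lo, 1.0) + 2 * margin, lo - margin


def write_cif(atoms: pd.DataFrame, path) -> None:
    import gemmi

    df = _canonical_order(atoms)
    span, origin = _box(df)
    doc = gemmi.cif.Document()
    block = doc.add_new_block("cnc_scene")
    block.set_pair("_cell_length_a", f"{span[0]:.4f}")
    block.set_pair("_cell_length_b", f"{span[1]:.4f}")
    block.set_pair("_cell_length_c", f"{span[2]:.4f}")
    for tag in ("_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        block.set_pair(tag, "90.0")
    block.set_pair("_symmetry_space_group_name_H-M", "'P 1'")
    loop = block.init_loop(
        "_atom_site_",
        ["type_symbol", "fract_x", "fract_y", "fract_z", "cnc_chain", "cnc_residue", "cnc_role"],
    )
    for t in df.itertuples(index=False):
        fx = (t.x - origin[0]) / span[0]
        fy = (t.y - origin[1]) / span[1]
        fz = (t.z - origin[2]) / span[2]
        loop.add_row(
            [t.element, f"{fx:.9f}", f"{fy:.9f}", f"{fz:.9f}",
             str(int(t.chain)), str(int(t.residue)), t.role]
        )
    # record the box origin so Cartesian coordinates round-trip
    block.set_pair("_cnc_origin_x", f"{origin[0]:.6f}")
    block.set_pair("_cnc_origin_y", f"{origin[1]:.6f}")
    block.set_pair("_cnc_origin_z", f"{origin[2]:.6f}")
    doc.write_file(str(path))


def read_cif(path) -> pd.DataFrame:
    import gemmi

    block = gemmi.cif.read(str(path)).sole_block()
    span = np.array([float(block.find_pair(f"_cell_length_{ax}")[1]) for ax in "abc"])
    origin = np.array([float(block.find_pair(f"_cnc_origin_{ax}")[1]) for ax in "xyz"])
    tab = block.find(
        "_atom_site_",
        ["type_symbol", "fract_x", "fract_y", "fract_z", "cnc_chain", "cnc_residue", "cnc_role"],
    )
    rows = []
    for r in tab:
        f = np.array([float(r[1]), float(r[2]), float(r[3])])
        xyz = f * span + origin
        rows.append((r[0], xyz[0], xyz[1], xyz[2], int(r[4]), int(r[5]), r[6]))
    return pd.DataFrame(rows, columns=_COLS)


def write_structure(atoms: pd.DataFrame, path, fmt: str | None = None) -> None:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        write_xyz(atoms, path)
    elif fmt == "cif":
        write_cif(atoms, path)
    else:
        raise ValueError(f"unknown structure format {fmt!r} (use 'xyz' or 'cif')")


def read_structure(path, fmt: str | None = None) -> pd.DataFrame:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "cif":
        return read_cif(path)
    raise ValueError(f"unknown structure format {fmt!r} (use 'xyz' or 'cif')")


def write_tiff(img, path) -> None:
    """16-bit TIFF plus JSON sidecar (pixel size, provenance, scale)."""
    import tifffile

    arr = np.asarray(img.intensity, dtype=float)
    peak = float(arr.max()) if arr.size and arr.max() > 0 else 1.0
    scaled = np.clip(arr / peak * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), scaled)
    sidecar = {
        "pixel_size_pm": img.pixel_size_pm,
        "origin": list(map(float, img.origin)),
        "intensity_peak": peak,
        "provenance": img.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tiff(path):
    import tifffile

    from .imaging import Micrograph

    sidecar = json.loads(Path(str(path) + ".json").read_text())
    arr = tifffile.imread(str(path)).astype(float)
    arr *= sidecar["intensity_peak"] / 65535.0
    return Micrograph(
        intensity=arr,
        pixel_size_pm=sidecar["pixel_size_pm"],
        origin=tuple(sidecar["origin"]),
        provenance=sidecar.get("provenance", {}),
    )
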