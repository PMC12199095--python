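"""Unit-cell geometry, habit construction and surface-site enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from cnc_cslabel import (
    build_cnc,
    enumerate_surface_c6,
    interchain_row_spacing,
    plane_spacing,
)
from cnc_cslabel.lattice import CHAIN_LAYOUTS, Facet


class TestUnitCell:
    def test_cell_constants(self, cell):
        assert (cell.a, cell.b, cell.c, cell.gamma) == (7.784, 8.201, 10.380, 96.5)

    def test_printed_spacings_recovered(self, cell):
        """The five printed distances follow from the cell alone, at 1 d.p."""
        assert round(plane_spacing(cell, (2, 0, 0)), 1) == 3.9
        assert round(cell.c, 1) == 10.4  # same-side C6 repeat along a chain
        rows = sorted(
            round(interchain_row_spacing(cell, lab), 1)
            for lab in ("(110)", "(1-10)", "(200)")
        )
        assert rows == [5.3, 6.0, 8.2]

    def test_screw_symmetry_squared_is_c_translation(self, diamond24, cell):
        """Applying the two-fold screw twice is a pure c translation."""
        a = diamond24.atoms
        r0 = a[(a.chain == 0) & (a.residue == 0)][["x", "y", "z"]].to_numpy()
        r2 = a[(a.chain == 0) & (a.residue == 2)][["x", "y", "z"]].to_numpy()
        np.testing.assert_allclose(r2 - r0, [[0, 0, cell.c]] * len(r0), atol=1e-9)

    def test_two_agus_per_repeat(self, diamond24):
        per_chain = diamond24.atoms[diamond24.atoms.chain == 0]
        assert per_chain.residue.nunique() == 2 * diamond24.length_repeats

    def test_invalid_cells_rejected(self):
        from cnc_cslabel.lattice import UnitCell

        with pytest.raises(ValueError):
            UnitCell(a=-1.0)
        with pytest.raises(ValueError):
            UnitCell(gamma=85.0)


class TestPlaneSpacing:
    def test_trivial_00l(self, cell):
        assert plane_spacing(cell, (0, 0, 2)) == pytest.approx(cell.c / 2)

    def test_zero_indices_error(self, cell):
        with pytest.raises(ValueError):
            plane_spacing(cell, (0, 0, 0))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        h=st.integers(-3, 3), k=st.integers(-3, 3), l=st.integers(-3, 3)
    )
    def test_matches_brute_force_lattice_planes(self, cell, h, k, l):
        """Closed form equals the minimal gap between generated lattice planes."""
        if (h, k, l) == (0, 0, 0):
            return
        d = plane_spacing(cell, (h, k, l))
        # brute force: project lattice points onto the plane normal
        basis = np.stack([cell.a_vec, cell.b_vec, cell.c_vec])
        rec = np.linalg.inv(basis).T  # rows: a*, b*, c*
        g = h * rec[0] + k * rec[1] + l * rec[2]
        g_hat = g / np.linalg.norm(g)
        m = np.arange(-3, 4)
        pts = (
            m[:, None, None, None] * basis[0]
            + m[None, :, None, None] * basis[1]
            + m[None, None, :, None] * basis[2]
        ).reshape(-1, 3)
        proj = np.unique(np.round(pts @ g_hat, 9))
        gaps = np.diff(proj)
        # lattice planes exist only at the coprime spacing: the closed form
        # for n*(h,k,l) is 1/n of that
        g_cd = np.gcd.reduce([abs(h), abs(k), abs(l)])
        assert abs(gaps[gaps > 1e-6].min() - g_cd * d) < 0.01


class TestRowSpacings:
    @pytest.mark.parametrize(
        "label,expected",
        [("(110)", 6.0), ("(1-10)", 5.3), ("(200)", 8.2), ("(010)", 7.8)],
    )
    def test_values(self, cell, label, expected):
        assert round(interchain_row_spacing(cell, label), 1) == expected

    def test_unknown_facet_error(self, cell):
        with pytest.raises(ValueError):
            interchain_row_spacing(cell, "(111)")

    def test_row_vector_lies_in_facet_plane(self, cell):
        for lab in ("(110)", "(1-10)", "(200)", "(010)"):
            n, row = cell.facet_frame(lab)
            assert abs(np.dot(n, row)) < 1e-9


class TestBuildCnc:
    def test_chain_counts_and_atom_count(self, cell):
        m = build_cnc(cell, "diamond", 18, 2)
        assert m.atoms.chain.nunique() == 18
        assert len(m.atoms) == 18 * 4 * 10  # chains x AGUs x heavy atoms/AGU

    def test_chains_recoverable_by_xy_clustering(self, diamond24):
        """Chain count and positions re-emerge from clustering atoms on (x, y)."""
        from scipy.cluster.hierarchy import fcluster, linkage

        xy = diamond24.atoms[["x", "y"]].to_numpy()
        sub = xy[:: max(len(xy) // 400, 1)]
        labels = fcluster(linkage(sub, method="single"), t=2.5, criterion="distance")
        assert len(np.unique(labels)) == diamond24.n_chains

    def test_diamond24_caliper(self, diamond24):
        """Cross-section size sits in the expected 18-24 chain envelope."""
        from scipy.spatial import ConvexHull

        xy = diamond24.atoms[["x", "y"]].to_numpy()
        h = ConvexHull(xy)
        v = xy[h.vertices]
        d = np.linalg.norm(v[:, None] - v[None, :], axis=2).max()
        assert 30.0 <= d <= 36.0  # 3.0-3.6 nm

    def test_rect_facet_families(self, rect24):
        labels = {f.miller_label for f in rect24.facets}
        assert labels == {"(200)", "(010)"}
        assert len(rect24.facets) == 4  # both facets and their opposites

    def test_min_separation(self, diamond24_cs):
        xyz = diamond24_cs.atoms[["x", "y", "z"]].to_numpy()
        pairs = cKDTree(xyz).query_pairs(0.8)
        assert pairs == set()

    def test_parallel_chains(self, diamond24):
        # every chain spans the same z range: axes are parallel to [001]
        g = diamond24.atoms.groupby("chain").z.agg(["min", "max"])
        assert g["min"].nunique() <= 2 and g["max"].nunique() <= 2

    def test_unsupported_layout_error(self, cell):
        with pytest.raises(ValueError, match="supported layouts"):
            build_cnc(cell, "diamond", 23, 2)
        with pytest.raises(ValueError):
            build_cnc(cell, "diamond", 24, 0)

    @pytest.mark.parametrize("habit,n", sorted(CHAIN_LAYOUTS))
    def test_every_surface_chain_on_a_facet_interior_on_none(self, cell, habit, n):
        m = build_cnc(cell, habit, n, 1)
        member = set()
        for f in m.facets:
            member.update(f.member_chain_ids)
            assert abs(f.outward_normal[2]) < 1e-12
        # interior chains: strictly inside the convex hull of chain axes
        from scipy.spatial import ConvexHull

        xy = np.array([m.chain_xy[i] for i in range(n)])
        hull = set(ConvexHull(xy).vertices.tolist())
        assert hull <= member


class TestSurfaceSites:
    def test_site_count_top_facet(self, diamond24):
        f = diamond24.facet("(110)", True)
        sites = enumerate_surface_c6(diamond24, f)
        assert len(sites) == len(f.member_chain_ids) * diamond24.length_repeats

    def test_axial_gap_is_one_repeat(self, diamond24, cell):
        f = diamond24.facet("(110)", True)
        sites = enumerate_surface_c6(diamond24, f)
        one = sites[sites.chain == sites.chain.iloc[0]].sort_values("c6z")
        gaps = np.diff(one.c6z.to_numpy())
        np.testing.assert_allclose(gaps, cell.c, atol=1e-9)
        assert round(float(gaps[0]), 1) == 10.4

    def test_forged_facet_with_interior_chain_yields_no_sites(self, diamond24, cell):
        """Interior chains never expose surface sites, even via a forged facet."""
        n2, row2 = cell.facet_frame("(110)")
        interior = [
            i for i in range(diamond24.n_chains)
            if not any(i in f.member_chain_ids for f in diamond24.facets)
        ]
        assert interior
        forged = Facet(
            miller_label="(110)",
            outward_normal=np.array([n2[0], n2[1], 0.0]),
            member_chain_ids=interior[:2],
            row_vector=np.array([row2[0], row2[1], 0.0]),
        )
        assert len(enumerate_surface_c6(diamond24, forged)) == 0

    def test_facet_not_in_model_error(self, diamond24, rect24):
        with pytest.raises(ValueError):
            enumerate_surface_c6(diamond24, rect24.facets[0])


class TestStructureRoundTrip:
    @pytest.mark.parametrize("fmt", ["xyz", "cif"])
    def test_positions_roundtrip_sub_0p1_pm(self, diamond24_cs, tmp_path, fmt):
        from cnc_cslabel.io import read_structure, write_structure

        path = tmp_path / f"model.{fmt}"
        write_structure(diamond24_cs.atoms, path)
        from cnc_cslabel.io import _canonical_order

        back = read_structure(path)
        assert len(back) == len(diamond24_cs.atoms)
        a = _canonical_order(back)
        b = _canonical_order(diamond24_cs.atoms)
        assert (a.element.to_numpy() == b.element.to_numpy()).all()
        for col in ("x", "y", "z"):
            np.testing.assert_allclose(
                a[col].to_numpy(), b[col].to_numpy(), atol=1e-3
            )  # 0.1 pm = 1e-3 A

    def test_deterministic_ordering(self, diamond24, tmp_path):
        from cnc_cslabel.io import write_xyz

        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        write_xyz(diamond24.atoms, p1)
        write_xyz(diamond24.atoms.sample(frac=1.0, random_state=3), p2)
        assert p1.read_text() == p2.read_text()
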