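"""RDF, profile spacings, row grouping and model projections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnc_cslabel import (
    build_cnc,
    compare_models,
    distinct_spacings,
    face_on_rotation,
    group_rows,
    interchain_row_spacing,
    line_profile_spacings,
    model_projected_spacings,
    rdf,
    render,
)
from conftest import FULL_CS, decorate_family


def brute_force_rdf(pos, bin_width, r_max):
    """O(N^2) pair histogram with the same normalization as rdf()."""
    pos = np.asarray(pos, float)
    n = len(pos)
    span = pos.max(axis=0) - pos.min(axis=0)
    area = float(np.prod(np.maximum(span, bin_width)))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < edges[-1]:
                counts[np.searchsorted(edges, d, side="right") - 1] += 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    return 2.0 * counts / (n * (n / area) * 2 * np.pi * centers * bin_width)


class TestRDF:
    def test_two_points_single_bin(self):
        r = rdf(np.array([[0.0, 0.0], [0.4, 0.0]]), bin_width=0.02, r_max=1.0)
        nz = np.flatnonzero(r.g > 0)
        assert len(nz) == 1
        assert r.bin_centers[nz[0]] == pytest.approx(0.4, abs=0.011)

    def test_square_lattice_peaks(self):
        """Peaks at s, s*sqrt(2), 2s; bin-for-bin equal to brute force."""
        s = 0.5
        xx, yy = np.meshgrid(np.arange(8), np.arange(8))
        pos = np.stack([xx.ravel() * s, yy.ravel() * s], axis=1)
        r = rdf(pos, bin_width=0.02, r_max=1.1)
        bf = brute_force_rdf(pos, 0.02, 1.1)
        np.testing.assert_allclose(r.g, bf, rtol=1e-12)
        for target in (s, s * np.sqrt(2), 2 * s):
            i = np.argmin(np.abs(r.bin_centers - target))
            window = r.g[max(i - 2, 0) : i + 3]
            assert window.max() > 0
            assert window.max() >= r.g.max() * 0.05

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 5, size=(rng.integers(10, 120), 2))
        r = rdf(pos, bin_width=0.05, r_max=2.0)
        bf = brute_force_rdf(pos, 0.05, 2.0)
        np.testing.assert_allclose(r.g, bf, rtol=1e-12)

    def test_poisson_process_g_near_one(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 30, size=(1500, 2))
        r = rdf(pos, bin_width=0.1, r_max=3.0)
        sel = (r.bin_centers > 1.0) & (r.bin_centers < 2.5)
        # 3 SE via Poisson bin counts
        counts = r.g[sel] * 1500 * (1500 / 900) * 2 * np.pi * r.bin_centers[sel] * 0.1 / 2
        se = 3.0 / np.sqrt(counts)
        assert (np.abs(r.g[sel] - 1.0) < np.maximum(3 * se, 0.15)).all()

    def test_too_few_positions(self):
        with pytest.raises(ValueError):
            rdf(np.array([[0.0, 0.0]]))


class TestLineProfiles:
    def test_planted_gaussians_spacing(self, probe):
        rows = [("Cs", x, 0.0, 0.0, 0, i, "Cs") for i, x in enumerate((0.0, 4.0, 8.0))]
        scene = pd.DataFrame(rows, columns=["element", "x", "y", "z", "chain", "residue", "role"])
        img = render(scene, probe, extent=(-3, 11, -2, 2))
        rep = line_profile_spacings(img, ((-2.0, 0.0), (10.0, 0.0)), width_px=5)
        np.testing.assert_allclose(rep.along_axis_spacings, [4.0, 4.0], atol=0.05)

    def test_rendered_diamond_rows_match_analytic(self, cell, probe):
        """Full-occupancy (110)-facing diamond: profile = facet row spacing."""
        from cnc_cslabel import decorate_model

        model = build_cnc(cell, "diamond", 24, 4)
        # top facet only: a single clean comb of Cs lines
        dec = decorate_model(model, [model.facet("(110)", True)], FULL_CS)
        th = np.radians(face_on_rotation(dec, "(110)"))
        cs = dec.atoms[dec.atoms.role == "Cs"]
        x = cs.x.to_numpy() * np.cos(th) - cs.y.to_numpy() * np.sin(th)
        scene = pd.DataFrame(
            {"element": "Cs", "x": x, "y": cs.z.to_numpy(), "z": 0.0,
             "chain": cs.chain.to_numpy(), "residue": cs.residue.to_numpy(), "role": "Cs"}
        )
        img = render(scene, probe)
        y_mid = (scene.y.min() + scene.y.max()) / 2
        rep = line_profile_spacings(
            img, ((scene.x.min() - 2, y_mid), (scene.x.max() + 2, y_mid)), width_px=40
        )
        expect = interchain_row_spacing(cell, "(110)")
        np.testing.assert_allclose(rep.along_axis_spacings, expect, atol=0.1)

    def test_noisy_profile_consistent_with_clean(self, probe):
        from cnc_cslabel import add_noise

        rows = [("Cs", x, 0.0, 0.0, 0, i, "Cs") for i, x in enumerate((0.0, 5.0, 10.0))]
        scene = pd.DataFrame(rows, columns=["element", "x", "y", "z", "chain", "residue", "role"])
        img = render(scene, probe, extent=(-3, 13, -2, 2))
        noisy = add_noise(img, probe, dose_scale=50.0, seed=4)
        clean = line_profile_spacings(img, ((-2.0, 0.0), (12.0, 0.0)))
        nz = line_profile_spacings(noisy, ((-2.0, 0.0), (12.0, 0.0)))
        err = np.maximum(np.hypot(clean.along_axis_errors, nz.along_axis_errors), 0.05)
        assert (np.abs(clean.along_axis_spacings - nz.along_axis_spacings) < 5 * err + 0.1).all()

    def test_flat_profile_error(self, probe):
        from cnc_cslabel.imaging import Micrograph

        img = Micrograph(np.ones((50, 50)), pixel_size_pm=20.0, origin=(0.0, 10.0))
        with pytest.raises(ValueError, match="peaks"):
            line_profile_spacings(img, ((1.0, 5.0), (9.0, 5.0)))

    def test_endpoints_outside_error(self, probe):
        from cnc_cslabel.imaging import Micrograph

        img = Micrograph(np.ones((50, 50)), pixel_size_pm=20.0, origin=(0.0, 10.0))
        with pytest.raises(ValueError, match="inside"):
            line_profile_spacings(img, ((-5.0, 5.0), (9.0, 5.0)))


class TestGroupRows:
    def test_planted_five_rows(self):
        rng = np.random.default_rng(0)
        pos = []
        for i in range(5):
            t = np.linspace(0, 40, 9)
            pos += [(ti, i * 6.5 + rng.normal(0, 0.05)) for ti in t]
        rows = group_rows(np.array(pos), axis_direction=np.array([1.0, 0.0]))
        assert len(rows) == 5

    def test_single_row(self):
        pos = np.array([[0.0, 0.0], [5.0, 0.1], [10.0, -0.1]])
        assert len(group_rows(pos, axis_direction=np.array([1.0, 0.0]))) == 1

    def test_rows_at_3A_still_separate(self):
        """3 A perpendicular gaps exceed the 2.6 A threshold: two rows."""
        pos = np.array([(t, u) for u in (0.0, 3.0) for t in np.linspace(0, 30, 7)])
        rows = group_rows(pos, axis_direction=np.array([1.0, 0.0]))
        assert len(rows) == 2
        # brute-force oracle: unique perpendicular values cluster to 2 groups
        assert len(np.unique(np.round(pos[:, 1], 6))) == 2

    def test_needs_two_positions(self):
        with pytest.raises(ValueError):
            group_rows(np.array([[0.0, 0.0]]))


class TestModelProjections:
    def test_rect_face_on_screw_arithmetic(self, rect24_cs):
        """Face-on rectangle: along-axis set {c/4, 3c/4} = {2.6, 7.8} A."""
        rep = model_projected_spacings(rect24_cs, face_on_rotation(rect24_cs, "(010)"))
        values = sorted(v for v, _ in distinct_spacings(rep.along_axis_spacings))
        assert [round(v, 1) for v in values] == [2.6, 7.8]
        # brute-force check of the screw arithmetic: 2.6 = 10.4 - 7.8
        assert values[0] + values[1] == pytest.approx(10.38, abs=0.01)

    def test_all_models_interline_within_printed_band(self, cell):
        for habit, n, facet in [
            ("diamond", 24, "(110)"), ("diamond", 18, "(110)"),
            ("rectangular", 24, "(010)"), ("rectangular", 18, "(010)"),
        ]:
            dec = decorate_family(build_cnc(cell, habit, n, 4), facet)
            rep = model_projected_spacings(dec, face_on_rotation(dec, facet))
            assert len(rep.inter_line_spacings) >= 2
            assert rep.inter_line_spacings.min() >= 5.8 - 1e-6
            assert rep.inter_line_spacings.max() <= 8.3 + 1e-6

    def test_rotation_full_turn_identical(self, diamond24_cs):
        r0 = model_projected_spacings(diamond24_cs, 0.0)
        r360 = model_projected_spacings(diamond24_cs, 360.0)
        np.testing.assert_allclose(
            r0.along_axis_spacings, r360.along_axis_spacings, atol=1e-9
        )
        np.testing.assert_allclose(
            r0.inter_line_spacings, r360.inter_line_spacings, atol=1e-9
        )

    def test_translation_invariance(self, diamond24_cs):
        import copy

        shifted = copy.copy(diamond24_cs)
        shifted.atoms = diamond24_cs.atoms.copy()
        shifted.atoms[["x", "y", "z"]] += [13.0, -7.0, 4.0]
        a = model_projected_spacings(diamond24_cs, 31.0)
        b = model_projected_spacings(shifted, 31.0)
        np.testing.assert_allclose(a.inter_line_spacings, b.inter_line_spacings, atol=1e-9)
        np.testing.assert_allclose(a.along_axis_spacings, b.along_axis_spacings, atol=1e-9)

    def test_half_turn_symmetric_habit(self, diamond24_cs):
        th = face_on_rotation(diamond24_cs, "(110)")
        a = model_projected_spacings(diamond24_cs, th)
        b = model_projected_spacings(diamond24_cs, th + 180.0)
        np.testing.assert_allclose(
            np.sort(a.inter_line_spacings), np.sort(b.inter_line_spacings), atol=1e-9
        )

    def test_undecorated_model_error(self, diamond24):
        with pytest.raises(ValueError, match="Cs"):
            model_projected_spacings(diamond24, 0.0)


class TestCompareModels:
    def _report(self, along, inter):
        from cnc_cslabel.analysis import SpacingReport

        return SpacingReport(
            along_axis_spacings=np.asarray(along, float),
            along_axis_errors=np.zeros(len(along)),
            inter_line_spacings=np.asarray(inter, float),
            inter_line_errors=np.zeros(len(inter)),
        )

    def test_self_match_scores_zero(self, diamond24_cs):
        th = face_on_rotation(diamond24_cs, "(110)")
        pred = model_projected_spacings(diamond24_cs, th)
        measured = self._report(
            [v for v, _ in distinct_spacings(pred.along_axis_spacings)],
            [v for v, _ in distinct_spacings(pred.inter_line_spacings)],
        )
        table = compare_models(measured, [("self", diamond24_cs, th)])
        assert table.score_A.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_experimental_envelope_prefers_diamond(self, diamond24_cs, rect24_cs):
        measured = self._report([4.0, 5.0, 6.5], [6.5])
        table = compare_models(
            measured,
            [
                ("diamond-24", diamond24_cs, face_on_rotation(diamond24_cs, "(110)")),
                ("rect-24", rect24_cs, face_on_rotation(rect24_cs, "(010)")),
            ],
        )
        assert table.model.iloc[0] == "diamond-24"
        assert table.score_A.iloc[0] < table.score_A.iloc[1]

    def test_single_candidate(self, rect24_cs):
        table = compare_models(
            self._report([7.8], []), [("rect", rect24_cs, face_on_rotation(rect24_cs, "(010)"))]
        )
        assert len(table) == 1 and np.isfinite(table.score_A.iloc[0])

    def test_empty_inputs_error(self, diamond24_cs):
        with pytest.raises(ValueError):
            compare_models(self._report([], []), [("d", diamond24_cs, 0.0)])
        with pytest.raises(ValueError):
            compare_models(self._report([5.0], []), [])
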