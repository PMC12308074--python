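"""Tests for registration, pairing, matching, chord strains and morphology."""

import numpy as np
import pandas as pd
import pytest

from strainpart import measure as me
from strainpart.measure import CellRecord, LabelFrame


def _frame(cell, nuc, intensity=None, ps=1.0):
    return LabelFrame(np.asarray(cell), np.asarray(nuc), intensity, ps)


def rect_frame(ps=1.0):
    """60x60 px frame: 30-px cell with a centred 10-px nucleus."""
    cell = np.zeros((60, 60), dtype=int)
    nuc = np.zeros((60, 60), dtype=int)
    cell[15:45, 15:45] = 1
    nuc[25:35, 25:35] = 1
    return _frame(cell, nuc, ps=ps)


class TestRegistration:
    def test_identity(self, hetero_monolayer):
        pre = hetero_monolayer["pre"]
        (dx, dy), shifted = me.register_frames(pre, pre)
        assert (dx, dy) == (0, 0)
        assert (shifted.cell_mask == pre.cell_mask).all()

    def test_pure_translation(self, hetero_monolayer):
        pre = hetero_monolayer["pre"]
        moved = LabelFrame(
            me.translate_image(pre.cell_mask, 5, -3),
            me.translate_image(pre.nucleus_mask, 5, -3),
            pixel_size=pre.pixel_size,
        )
        (dx, dy), shifted = me.register_frames(pre, moved)
        assert (dx, dy) == (5, -3)
        inner = np.s_[10:-10, 10:-10]
        assert (shifted.cell_mask[inner] == pre.cell_mask[inner]).all()

    def test_stretched_frame_offset_recovered(self, hetero_monolayer):
        # the generator applied a (8, 2) px rigid offset on top of the stretch;
        # under per-cell strain heterogeneity every boundary also carries its
        # own displacement, so the correlation peak can sit a couple of pixels
        # off (the uniform-stretch case recovers the offset exactly)
        (dx, dy), _ = me.register_frames(
            hetero_monolayer["pre"], hetero_monolayer["post"], strain_guess=0.25
        )
        assert abs(dx - 8) <= 3 and abs(dy - 2) <= 1

    def test_empty_mask_raises(self):
        empty = _frame(np.zeros((20, 20), int), np.zeros((20, 20), int))
        with pytest.raises(me.RegistrationError):
            me.register_frames(empty, empty)


class TestPairing:
    def test_synthetic_pairing_matches_construction(self, hetero_monolayer):
        pairing, diag = me.pair_nucleus_to_cell(hetero_monolayer["pre"])
        assert pairing and all(nuc == cell for nuc, cell in pairing.items())
        assert not diag["ambiguous_cells"]

    def test_orphan_nucleus_dropped(self):
        cell = np.zeros((40, 40), int)
        nuc = np.zeros((40, 40), int)
        cell[5:20, 5:20] = 1
        nuc[8:12, 8:12] = 1
        nuc[30:35, 30:35] = 2  # entirely on background
        pairing, diag = me.pair_nucleus_to_cell(_frame(cell, nuc))
        assert pairing == {1: 1}
        assert diag["dropped_nuclei"] == [2]

    def test_mitotic_doublet_excluded(self):
        cell = np.zeros((40, 40), int)
        nuc = np.zeros((40, 40), int)
        cell[5:35, 5:35] = 1
        nuc[10:15, 10:15] = 1
        nuc[25:30, 25:30] = 2
        pairing, diag = me.pair_nucleus_to_cell(_frame(cell, nuc))
        assert pairing == {}
        assert diag["ambiguous_cells"] == [1]


class TestMatching:
    def test_identity_on_identical_frames(self, hetero_monolayer):
        pre = hetero_monolayer["pre"]
        mapping = me.match_pre_post(pre, pre, strain_guess=0.0)
        assert mapping and all(a == b for a, b in mapping.items())

    def test_synthetic_stretch_pair(self, hetero_monolayer):
        _, post = me.register_frames(
            hetero_monolayer["pre"], hetero_monolayer["post"], strain_guess=0.25
        )
        mapping = me.match_pre_post(hetero_monolayer["pre"], post, strain_guess=0.25)
        agree = np.mean([a == b for a, b in mapping.items()])
        assert agree > 0.95

    def test_missing_cell_robustness(self, hetero_monolayer):
        pre = hetero_monolayer["pre"]
        gone = int(pre.cell_mask[pre.shape[0] // 2, pre.shape[1] // 2])
        cells = pre.cell_mask.copy()
        cells[cells == gone] = 0
        post = LabelFrame(cells, pre.nucleus_mask, pixel_size=pre.pixel_size)
        mapping = me.match_pre_post(pre, post, strain_guess=0.0)
        assert gone not in mapping
        others = [a == b for a, b in mapping.items()]
        assert np.mean(others) > 0.95


class TestChords:
    def test_rectangle(self):
        rec = me.measure_chords(rect_frame(), 1)
        assert rec.cell_chord == 30 and rec.nucleus_chord == 10
        assert rec.cytoplasm_chord == 20

    def test_rectangle_micron_units(self):
        rec = me.measure_chords(rect_frame(ps=0.5), 1)
        assert rec.cell_chord == 15.0 and rec.nucleus_chord == 5.0

    def test_concentric_discs(self):
        yy, xx = np.mgrid[:101, :101]
        r2 = (yy - 50) ** 2 + (xx - 50) ** 2
        cell = (r2 <= 40**2).astype(int)
        nuc = (r2 <= 20**2).astype(int)
        rec = me.measure_chords(_frame(cell, nuc), 1)
        assert rec.cell_chord == pytest.approx(2 * 40, abs=1.5)
        assert rec.nucleus_chord == pytest.approx(2 * 20, abs=1.5)

    def test_concave_cell_uses_run_containing_centroid(self):
        # C-shaped cell: the mid-line crosses the shape twice; the chord is
        # the run containing the nucleus, not the total occupancy of the row
        cell = np.zeros((40, 60), int)
        cell[5:35, 5:15] = 1          # left bar
        cell[5:12, 5:55] = 1          # top bar
        cell[28:35, 5:55] = 1         # bottom bar
        cell[15:25, 40:55] = 1        # detached-looking lobe on the same rows
        nuc = np.zeros_like(cell)
        nuc[17:23, 7:13] = 1          # nucleus inside the left bar
        rec = me.measure_chords(_frame(cell, nuc), 1)
        assert rec.cell_chord == 10  # not 10 + 15

    def test_centroid_row_without_cell_pixels_skipped(self):
        cell = np.zeros((30, 30), int)
        nuc = np.zeros((30, 30), int)
        cell[2:6, 2:6] = 1
        nuc[20:24, 20:24] = 1  # far from the cell; centroid lands on background
        assert me.measure_chords(_frame(cell, nuc), 1, pairing={1: 1}) is None


class TestStrains:
    def _rec(self, lcell, ln, area=100.0, cv=None):
        return CellRecord(1, (0.0, 0.0), lcell, ln, lcell - ln, area, cv)

    def test_simple_arithmetic(self):
        row = me.compute_strains(self._rec(30, 10), self._rec(36, 12))
        assert row["eps_n"] == pytest.approx(0.2)

    def test_uniform_affine_stretch(self):
        row = me.compute_strains(self._rec(30, 10), self._rec(37.5, 12.5))
        for key in ("eps_n", "eps_c", "eps_cell"):
            assert row[key] == pytest.approx(0.25)

    def test_weighted_sum_identity(self):
        row = me.compute_strains(self._rec(30, 10), self._rec(37.2, 11))
        assert row["eps_n"] == pytest.approx(0.10)
        assert row["eps_c"] == pytest.approx(0.31)
        assert row["eps_cell"] == pytest.approx(0.24)
        assert row["eps_cell"] == pytest.approx(
            (10 * row["eps_n"] + 20 * row["eps_c"]) / 30
        )

    def test_zero_chord_skipped(self):
        assert me.compute_strains(self._rec(30, 30), self._rec(36, 31)) is None

    def test_area_change_and_cv(self):
        row = me.compute_strains(
            self._rec(30, 10, area=100.0, cv=0.2), self._rec(36, 12, area=97.0, cv=0.15)
        )
        assert row["dA_A"] == pytest.approx(-0.03)
        assert row["dCV"] == pytest.approx(-0.05)
        assert row["size_class"] == "shrink"


class TestAreaChangeClassifier:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-0.015, "shrink"),
            (-0.01, "shrink"),
            (0.0, "no_change"),
            (0.0099, "no_change"),
            (0.01, "expand"),
            (0.4, "expand"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert me.classify_area_change(value) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            me.classify_area_change(float("nan"))


class TestMorphology:
    def disc_frame(self, radius=40, pad=10, shift=(0, 0)):
        size = 2 * (radius + pad)
        yy, xx = np.mgrid[:size, :size]
        cy, cx = size // 2 + shift[0], size // 2 + shift[1]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell = (r2 <= radius**2).astype(int)
        nuc = (r2 <= (radius // 2) ** 2).astype(int)
        return _frame(cell, nuc)

    def test_feature_count(self):
        row = me.compute_morphology(self.disc_frame(), 1)
        assert sum(1 for k in me.MORPHOLOGY_FEATURES if k in row) == 19

    def test_disc_closed_forms(self):
        # raster perimeter estimates carry a few percent bias, so the
        # closed-form checks use a ~10% band on perimeter-squared quantities
        row = me.compute_morphology(self.disc_frame(), 1)
        assert row["cell_circularity"] == pytest.approx(1 / (4 * np.pi), rel=0.11)
        assert row["cell_shape_index"] == pytest.approx(2 * np.sqrt(np.pi), rel=0.06)
        assert row["cell_roundness"] == pytest.approx(1.0, rel=0.05)

    def test_square_solidity_and_aspect(self):
        cell = np.zeros((60, 60), int)
        nuc = np.zeros((60, 60), int)
        cell[10:50, 10:50] = 1
        nuc[25:35, 25:35] = 1
        row = me.compute_morphology(_frame(cell, nuc), 1)
        assert row["cell_solidity"] == pytest.approx(1.0, abs=0.01)
        assert row["cell_aspect_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_rectangle_aspect_ratio(self):
        cell = np.zeros((60, 100), int)
        nuc = np.zeros((60, 100), int)
        cell[10:50, 10:90] = 1  # 2:1 rectangle
        nuc[25:35, 40:60] = 1
        row = me.compute_morphology(_frame(cell, nuc), 1)
        assert row["cell_aspect_ratio"] == pytest.approx(2.0, rel=0.05)

    def test_translation_invariance(self):
        a = me.compute_morphology(self.disc_frame(), 1)
        b = me.compute_morphology(self.disc_frame(shift=(6, -4)), 1)
        for key in me.MORPHOLOGY_FEATURES:
            assert a[key] == pytest.approx(b[key], rel=1e-6)

    def test_resolution_scaling(self):
        a = me.compute_morphology(self.disc_frame(radius=30), 1)
        b = me.compute_morphology(self.disc_frame(radius=60, pad=20), 1)
        area_like = ("cell_area", "nuc_area", "cell_convex_area", "nuc_convex_area")
        perim_like = (
            "cell_perimeter",
            "nuc_perimeter",
            "cell_convex_perimeter",
            "nuc_convex_perimeter",
        )
        for key in area_like:
            assert b[key] / a[key] == pytest.approx(4.0, rel=0.05)
        for key in perim_like:
            assert b[key] / a[key] == pytest.approx(2.0, rel=0.05)
        for key in set(me.MORPHOLOGY_FEATURES) - set(area_like) - set(perim_like):
            assert b[key] == pytest.approx(a[key], rel=0.06), key

    def test_border_cell_flagged(self):
        cell = np.zeros((30, 30), int)
        nuc = np.zeros((30, 30), int)
        cell[0:15, 5:20] = 1  # touches the top edge
        nuc[5:10, 9:14] = 1
        row = me.compute_morphology(_frame(cell, nuc), 1)
        assert row["touches_border"] is True


class TestMeasurePair:
    def test_round_trip_recovers_truth(self, hetero_monolayer):
        st = hetero_monolayer["strain_table"].set_index("cell_id")
        truth = hetero_monolayer["truth"]
        joined = st.join(truth, rsuffix="_t")
        for col in ("eps_cell", "eps_n", "eps_c"):
            mae = (joined[col] - joined[col + "_real"]).abs().mean()
            assert mae < 0.02, col

    def test_length_weighted_consistency(self, hetero_monolayer):
        st = hetero_monolayer["strain_table"]
        ln, lcell = st["L_n_pre"], st["L_cell_pre"]
        lc = lcell - ln
        pred = (ln * st["eps_n"] + lc * st["eps_c"]) / lcell
        assert (st["eps_cell"] - pred).abs().max() < 0.02

    def test_cell_strain_between_compartment_strains(self, hetero_monolayer):
        st = hetero_monolayer["strain_table"]
        lo = np.minimum(st["eps_n"], st["eps_c"]) - 1e-9
        hi = np.maximum(st["eps_n"], st["eps_c"]) + 1e-9
        assert ((st["eps_cell"] >= lo) & (st["eps_cell"] <= hi)).all()

    def test_border_cells_excluded(self, hetero_monolayer):
        st = hetero_monolayer["strain_table"]
        border = me._border_labels(hetero_monolayer["pre"].cell_mask)
        assert not (set(st["cell_id"]) & border)
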