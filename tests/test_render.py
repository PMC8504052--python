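"""Layout geometry, rendering determinism, joint-view data equality."""

import numpy as np
import pytest

from trackstack import (
    Frame,
    GenomeRange,
    JointViewSpec,
    arc_geometry,
    layout_gene_rows,
    make_track,
    matrix_panel_transform,
    parse_region,
    read_contact_matrix,
    frame_fetch_all,
    render_frame,
    render_joint_view,
)
from trackstack.io.records import PairedInterval
from trackstack.render import build_frame_figure, fetch_joint_center, plan_layout

VIEW = "chr1:1-200000"


@pytest.fixture
def demo_frame(dataset):
    return (
        make_track("XAxis", track_id="x")
        + make_track("BedGraph", dataset.files["bedgraph"], track_id="bg")
        + make_track("Spacer", track_id="sp")
        + make_track("GTF", dataset.files["gtf"], track_id="genes")
    )


class TestGeneRowLayout:
    def test_first_fit_by_hand(self):
        spans = [GenomeRange("chr1", 1, 10), GenomeRange("chr1", 5, 15),
                 GenomeRange("chr1", 20, 30)]
        rows = layout_gene_rows(spans, min_gap=0)
        assert [rows[s] for s in spans] == [0, 1, 0]

    def test_disjoint_genes_share_row_zero(self):
        spans = [GenomeRange("chr1", i * 100 + 1, i * 100 + 50) for i in range(5)]
        assert set(layout_gene_rows(spans, 0).values()) == {0}

    def test_mutually_overlapping_genes_get_distinct_rows(self):
        spans = [GenomeRange("chr1", 1, 1000) for _ in range(6)]
        spans = [GenomeRange("chr1", 1 + i, 1000 + i) for i in range(6)]
        rows = layout_gene_rows(spans, 0)
        assert sorted(rows.values()) == list(range(6))

    def test_min_gap_separates_rows(self):
        spans = [GenomeRange("chr1", 1, 100), GenomeRange("chr1", 150, 250)]
        assert set(layout_gene_rows(spans, min_gap=100).values()) == {0, 1}
        assert set(layout_gene_rows(spans, min_gap=10).values()) == {0}


class TestArcGeometry:
    def test_apex_at_midpoint_of_midpoints(self):
        pair = PairedInterval(GenomeRange("chr1", 50, 150), GenomeRange("chr1", 250, 350))
        spec = arc_geometry(pair)
        assert spec.x0 == 100 and spec.x1 == 300
        assert spec.apex_x == 200

    def test_heights_proportional_to_span(self):
        p1 = PairedInterval(GenomeRange("chr1", 1, 1), GenomeRange("chr1", 201, 201))
        p2 = PairedInterval(GenomeRange("chr1", 1, 1), GenomeRange("chr1", 401, 401))
        assert arc_geometry(p2).span == pytest.approx(2 * arc_geometry(p1).span)

    def test_score_carried_through(self):
        pair = PairedInterval(GenomeRange("chr1", 1, 10), GenomeRange("chr1", 90, 100), 7.5)
        assert arc_geometry(pair).score == 7.5


class TestMatrixPanelTransform:
    def square_cm(self, values):
        from trackstack import BinAxis, ContactMatrix

        values = np.asarray(values, dtype=float)
        axis = BinAxis(GenomeRange("chr1", 1, 100 * values.shape[0]), 100)
        return ContactMatrix(axis, axis, values, 100)

    def test_square_raster_dimensions(self):
        pt = matrix_panel_transform(self.square_cm(np.ones((4, 4))), style="square")
        assert pt.color_values.shape == (4, 4)
        assert pt.mesh_x.shape == (5, 5)

    def test_log1p_all_zero_is_uniform_minimum(self):
        pt = matrix_panel_transform(self.square_cm(np.zeros((3, 3))), style="square",
                                    scale="log1p")
        assert (pt.color_values == pt.color_values.flat[0]).all()
        assert pt.color_values.flat[0] == pt.vmin

    def test_clamp_caps_values_and_labels(self):
        vals = np.array([[0.0, 100.0], [100.0, 0.0]])
        pt = matrix_panel_transform(self.square_cm(vals), style="square",
                                    scale="linear", clamp=(0, 10))
        assert pt.color_values.max() == 10
        assert pt.clamp_data == (0, 10)

    def test_triangular_masks_lower_half(self):
        pt = matrix_panel_transform(self.square_cm(np.ones((4, 4))), style="triangular")
        assert np.isnan(pt.color_values[2, 0])
        assert np.isfinite(pt.color_values[0, 2])
        assert pt.depth == pytest.approx(0.5 * 400)

    def test_auto_clamp_uses_percentiles(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 50, size=(20, 20))
        vals = (vals + vals.T) / 2
        pt = matrix_panel_transform(self.square_cm(vals), style="square", scale="linear")
        lo, hi = np.percentile(vals, [2, 98])
        assert pt.clamp_data == (pytest.approx(lo), pytest.approx(hi))


class TestRenderFrame:
    def test_repeat_render_byte_identical_svg(self, demo_frame, tmp_path):
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_frame(demo_frame, VIEW, str(a))
        render_frame(demo_frame, VIEW, str(b))
        assert a.read_bytes() == b.read_bytes()

    @pytest.mark.parametrize("ext", ["png", "jpeg", "pdf", "svg"])
    def test_all_formats_written(self, demo_frame, tmp_path, ext):
        out = tmp_path / f"fig.{ext}"
        render_frame(demo_frame, VIEW, str(out))
        assert out.stat().st_size > 0

    def test_unsupported_format_rejected(self, demo_frame, tmp_path):
        with pytest.raises(ValueError, match="format"):
            render_frame(demo_frame, VIEW, str(tmp_path / "fig.tiff"))

    def test_panel_heights_proportional_to_height_prop(self, dataset):
        frame = (
            make_track("BedGraph", dataset.files["bedgraph"], track_id="a", height=1.0)
            + make_track("BedGraph", dataset.files["bedgraph"], track_id="b", height=3.0)
        )
        fig = build_frame_figure(frame, parse_region(VIEW))
        try:
            axes = fig.get_axes()
            h = [ax.get_position().height for ax in axes if not ax.get_label() == "<colorbar>"]
            assert h[1] / h[0] == pytest.approx(3.0, rel=0.005)
        finally:
            import matplotlib.pyplot as plt

            plt.close(fig)

    def test_layout_plan_mirrors_track_order_and_heights(self, demo_frame):
        plan = plan_layout(demo_frame, parse_region(VIEW))
        assert [p[0] for p in plan.panels] == ["x", "bg", "sp", "genes"]
        assert [p[1] for p in plan.panels] == [t.props.height for t in demo_frame.tracks]

    def test_error_placeholder_vs_strict(self, dataset, tmp_path):
        import os

        doomed_path = tmp_path / "gone.bedgraph"
        doomed_path.write_text("chr1\t0\t10\t1\n")
        frame = (make_track("XAxis")
                 + make_track("BedGraph", str(doomed_path), track_id="doomed"))
        os.remove(doomed_path)
        lenient = tmp_path / "lenient.svg"
        render_frame(frame, VIEW, str(lenient))
        assert lenient.stat().st_size > 0  # placeholder panel, figure produced
        strict_out = tmp_path / "strict.svg"
        with pytest.raises(FileNotFoundError):
            render_frame(frame, VIEW, str(strict_out), strict=True)
        assert not strict_out.exists()

    def test_spacer_draws_blank_gap(self, dataset, tmp_path):
        with_sp = (make_track("BedGraph", dataset.files["bedgraph"], track_id="bg")
                   + make_track("Spacer", track_id="sp", height=0.8)
                   + make_track("XAxis", track_id="x"))
        fig = build_frame_figure(with_sp, parse_region(VIEW))
        try:
            sp_ax = fig.get_axes()[1]
            assert not sp_ax.axison  # blank panel
            assert sp_ax.get_position().height > 0  # but consumes height
        finally:
            import matplotlib.pyplot as plt

            plt.close(fig)


class TestJointView:
    def test_center_payload_equals_direct_offdiagonal_read(self, dataset, matrix_source):
        spec = JointViewSpec(
            make_track("HiCMat", list(matrix_source)),
            "chr1:1-250000", "chr1:250001-500000",
        )
        center = fetch_joint_center(spec).payload
        direct = read_contact_matrix(matrix_source, parse_region("chr1:250001-500000"),
                                     parse_region("chr1:1-250000"))
        np.testing.assert_array_equal(center.values, direct.values)

    def test_on_diagonal_center_is_symmetric(self, dataset, matrix_source):
        spec = JointViewSpec(make_track("HiCMat", list(matrix_source)),
                             "chr1:1-250000", "chr1:1-250000")
        m = fetch_joint_center(spec).payload
        assert (m.values == m.values.T).all()

    def test_side_frame_payloads_equal_frame_fetch_all(self, dataset, matrix_source):
        side = Frame([make_track("BedGraph", dataset.files["bedgraph"], track_id="bg")])
        spec = JointViewSpec(make_track("HiCMat", list(matrix_source)),
                             "chr1:1-250000", "chr1:250001-500000",
                             side_frames={"top": side, "left": side})
        top_data = frame_fetch_all(spec.side_frames["top"], spec.range_h)
        left_data = frame_fetch_all(spec.side_frames["left"], spec.range_v)
        assert top_data["bg"].range == parse_region("chr1:1-250000")
        assert left_data["bg"].range == parse_region("chr1:250001-500000")
        assert top_data["bg"].payload != left_data["bg"].payload

    def test_render_is_deterministic(self, dataset, matrix_source, tmp_path):
        side = Frame([make_track("XAxis", track_id="x"),
                      make_track("BedGraph", dataset.files["bedgraph"], track_id="bg")])
        spec = JointViewSpec(make_track("HiCMat", list(matrix_source)),
                             "chr1:1-250000", "chr1:250001-500000",
                             side_frames={"top": side, "left": side, "bottom": side,
                                          "right": side})
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_joint_view(spec, str(a))
        render_joint_view(spec, str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_unknown_side_position_rejected(self, matrix_source):
        with pytest.raises(ValueError, match="side-frame"):
            JointViewSpec(make_track("HiCMat", list(matrix_source)),
                          "chr1:1-1000", "chr1:1-1000",
                          side_frames={"diagonal": Frame([])})
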