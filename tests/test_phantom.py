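import numpy as np
import pytest

from mgscaffold import phantom as ph
from mgscaffold.geometry import (
    DesignGraph,
    ScaffoldDesign,
    build_design,
    nominal_volume,
    straight_strut_graph,
)

from conftest import make_strut_volume


class TestVoxelize:
    def test_volume_matches_swept_oracle(self, small_design, small_graph, small_labels):
        """Voxel-union Mg volume vs analytic sum of swept segment volumes."""
        measured = ph.measured_volume(small_labels)
        analytic = nominal_volume(small_design, small_graph)
        assert measured == pytest.approx(analytic, rel=0.10)

    def test_empty_graph_zero_mg(self, small_design):
        empty = DesignGraph(design=small_design, nodes=np.zeros((0, 3)), segments=[])
        vol = ph.voxelize(empty, spacing=0.02)
        assert vol.mg_voxel_count() == 0
        assert vol.class_mask(ph.TISSUE).any()

    def test_spacing_convergence(self, small_graph, small_labels):
        """Halving the spacing changes the volume estimate by < 5%.

        Uses the full small scaffold: its limbs sample many grid phases, so
        the voxel-count estimate self-averages (a single grid-aligned strut
        is dominated by quantization of its one phase).
        """
        v_coarse = ph.measured_volume(small_labels)  # 0.02 mm
        fine = ph.voxelize(small_graph, spacing=0.01)
        v_fine = ph.measured_volume(fine)
        assert abs(v_coarse - v_fine) / v_fine < 0.05

    def test_too_coarse_spacing_rejected(self, small_graph):
        with pytest.raises(ph.PhantomError, match="spacing"):
            ph.voxelize(small_graph, spacing=0.05)

    def test_label_classes_and_segment_ids(self, small_graph, small_labels):
        codes = np.unique(small_labels.labels)
        assert set(codes) <= {ph.BACKGROUND, ph.TISSUE, ph.MG_ALLOY}
        ids = np.unique(small_labels.segment_ids)
        assert ids.min() == -1
        assert set(ids[ids >= 0]) == set(small_graph.segment_ids())

    def test_mg_voxels_have_segment_ids(self, small_labels):
        mg = small_labels.labels == ph.MG_ALLOY
        assert np.all(small_labels.segment_ids[mg] >= 0)


class TestDegradation:
    def test_identity_at_zero_depth(self, small_graph, small_labels):
        state = ph.DegradationState(erosion_depth=0.0, seed=1)
        out = ph.apply_degradation(small_labels, small_graph, state)
        np.testing.assert_array_equal(out.labels, small_labels.labels)

    def test_full_depth_removes_all_mg(self, small_graph, small_labels):
        state = ph.DegradationState(erosion_depth=0.056, seed=1)
        out = ph.apply_degradation(small_labels, small_graph, state)
        assert out.mg_voxel_count() == 0

    def test_closed_form_oracle_spacing_002(self, strut_design):
        """Remaining fraction vs (1-2d/w)(1-2d/h) at the default spacing,
        averaged over stratified sub-voxel grid phases."""
        spacing, depth = 0.02, 0.02
        tot0 = tot1 = 0
        for i in range(8):
            phase = ((i + 0.5) / 8 * spacing, (((i + 0.5) / 8 + 0.37) % 1) * spacing)
            graph, vol = make_strut_volume(strut_design, spacing, phase=phase)
            out = ph.apply_degradation(
                vol, graph, ph.DegradationState(erosion_depth=depth, seed=i)
            )
            tot0 += vol.mg_voxel_count()
            tot1 += out.mg_voxel_count()
        w = strut_design.strut_width
        closed = (1 - 2 * depth / w) ** 2
        assert tot1 / tot0 == pytest.approx(closed, rel=0.07)

    def test_monotone_nesting(self, strut_design):
        graph, vol = make_strut_volume(strut_design, 0.02, phase=(0.007, 0.013))
        masks = []
        for depth in (0.005, 0.015, 0.03):
            out = ph.apply_degradation(
                vol, graph, ph.DegradationState(erosion_depth=depth, seed=42)
            )
            masks.append(out.labels == ph.MG_ALLOY)
        assert np.all(masks[1] <= masks[0])
        assert np.all(masks[2] <= masks[1])

    def test_voxel_count_conserved(self, small_graph, small_labels):
        state = ph.DegradationState(erosion_depth=0.02, seed=3)
        out = ph.apply_degradation(small_labels, small_graph, state)
        assert out.labels.size == small_labels.labels.size
        assert out.labels.shape == small_labels.labels.shape

    def test_substitution_fractions(self, strut_design):
        graph, vol = make_strut_volume(strut_design, 0.02)
        n0 = vol.mg_voxel_count()
        state = ph.DegradationState(
            erosion_depth=0.02,
            substitution_fraction_dense=0.5,
            substitution_fraction_lucent=0.3,
            seed=11,
        )
        out = ph.apply_degradation(vol, graph, state)
        n_eroded = n0 - out.mg_voxel_count()
        n_dense = int(np.count_nonzero(out.labels == ph.PRODUCT_DENSE))
        n_lucent = int(np.count_nonzero(out.labels == ph.PRODUCT_LUCENT))
        assert n_dense / n_eroded == pytest.approx(0.5, abs=0.05)
        assert n_lucent / n_eroded == pytest.approx(0.3, abs=0.05)

    def test_cut_removes_segment(self, small_graph, small_labels):
        seg_id = small_graph.segments[0].id
        state = ph.DegradationState(cut_segment_ids={seg_id}, seed=1)
        out = ph.apply_degradation(small_labels, small_graph, state)
        was_cut = small_labels.segment_ids == seg_id
        assert np.all(out.labels[was_cut] == ph.TISSUE)
        assert np.all(out.segment_ids[was_cut] == -1)

    def test_unknown_cut_id_rejected(self, small_graph, small_labels):
        state = ph.DegradationState(cut_segment_ids={9999}, seed=1)
        with pytest.raises(ph.PhantomError, match="9999"):
            ph.apply_degradation(small_labels, small_graph, state)

    def test_invalid_state(self):
        with pytest.raises(ph.PhantomError):
            ph.DegradationState(erosion_depth=-0.1)
        with pytest.raises(ph.PhantomError):
            ph.DegradationState(
                substitution_fraction_dense=0.7, substitution_fraction_lucent=0.5
            )

    def test_edt_method_available(self, strut_design):
        graph, vol = make_strut_volume(strut_design, 0.02)
        out = ph.apply_degradation(
            vol, graph, ph.DegradationState(erosion_depth=0.02, seed=2),
            method="edt",
        )
        w = strut_design.strut_width
        frac = out.mg_voxel_count() / vol.mg_voxel_count()
        assert frac == pytest.approx((1 - 2 * 0.02 / w) ** 2, rel=0.15)
        with pytest.raises(ph.PhantomError):
            ph.apply_degradation(
                vol, graph, ph.DegradationState(erosion_depth=0.01), method="nope"
            )


class TestRender:
    def test_piecewise_constant_without_blur_or_noise(self, small_labels):
        gray = ph.render_grayscale(small_labels, psf_sigma=0.0, noise_sd=0.0)
        material = ph.MaterialModel()
        for cls in (ph.BACKGROUND, ph.TISSUE, ph.MG_ALLOY):
            sel = small_labels.labels == cls
            if sel.any():
                assert np.all(gray.values[sel] == material.means[cls])

    def test_seed_reproducibility(self, small_labels):
        a = ph.render_grayscale(small_labels, psf_sigma=0.5, noise_sd=5.0, seed=7)
        b = ph.render_grayscale(small_labels, psf_sigma=0.5, noise_sd=5.0, seed=7)
        c = ph.render_grayscale(small_labels, psf_sigma=0.5, noise_sd=5.0, seed=8)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_interior_mean_near_class_mean(self, strut_design):
        graph, vol = make_strut_volume(strut_design, 0.01)
        noise_sd = 5.0
        gray = ph.render_grayscale(vol, psf_sigma=0.0, noise_sd=noise_sd, seed=3)
        mg = vol.labels == ph.MG_ALLOY
        n = int(mg.sum())
        tol = 2 * noise_sd / np.sqrt(n)
        assert float(gray.values[mg].mean()) == pytest.approx(100.0, abs=tol * 3)

    def test_invalid_params(self, small_labels):
        with pytest.raises(ph.PhantomError):
            ph.render_grayscale(small_labels, psf_sigma=-1.0)

    def test_material_ordering_enforced(self):
        with pytest.raises(ph.PhantomError, match="increasing"):
            ph.MaterialModel(means=(0, 30, 100, 60, 140))
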