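import math

import numpy as np
import pytest

from mgscaffold import histogram as hv
from mgscaffold import integrity as ig
from mgscaffold import phantom as ph


def cut_state(graph, n_cut, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    cuts = frozenset(int(i) for i in rng.permutation(graph.n_segments)[:n_cut])
    return ph.DegradationState(cut_segment_ids=cuts, seed=seed, **kwargs)


class TestSegmentScaffold:
    def test_label_input_exact(self, small_labels):
        mask = ig.segment_scaffold(small_labels)
        expected = np.isin(small_labels.labels, [ph.MG_ALLOY, ph.PRODUCT_DENSE])
        np.testing.assert_array_equal(mask, expected)

    def test_all_tissue_empty(self):
        vol = ph.LabelVolume(
            labels=np.full((10, 10, 10), ph.TISSUE, dtype=np.uint8), spacing=0.02
        )
        assert not ig.segment_scaffold(vol).any()

    def test_grayscale_agrees_with_labels(self, small_design, small_labels):
        """Pristine, unblurred, unnoised rendering: posterior classification
        matches the label mask on >= 99% of voxels."""
        gray = ph.render_grayscale(small_labels, psf_sigma=0.0, noise_sd=1.0, seed=0)
        roi = hv.cylindrical_roi(gray, small_design.nominal_diameter / 2 + 0.3)
        fit = hv.fit_peaks(hv.compute_histogram(gray.values[roi], 128), k="auto")
        mask = ig.segment_scaffold(gray, fit)
        truth = ig.segment_scaffold(small_labels)
        agreement = float(np.mean(mask == truth))
        assert agreement >= 0.99

    def test_grayscale_requires_fit(self, small_labels):
        gray = ph.render_grayscale(small_labels)
        with pytest.raises(ig.IntegrityError, match="HistogramFit"):
            ig.segment_scaffold(gray)


class TestDiscontinuity:
    def test_pristine_zero(self, small_graph, small_labels):
        mask = ig.segment_scaffold(small_labels)
        res = ig.discontinuity_ratio(
            mask, small_graph, small_labels.spacing, origin=small_labels.origin
        )
        assert res.discontinuity_ratio == 0.0
        assert res.n_fragments == 1
        assert res.n_segments == small_graph.n_segments

    @pytest.mark.parametrize("n_cut", [1, 3])
    def test_cut_counts_exact(self, small_graph, small_labels, n_cut):
        state = cut_state(small_graph, n_cut, seed=n_cut)
        out = ph.apply_degradation(small_labels, small_graph, state)
        res = ig.discontinuity_ratio(
            ig.segment_scaffold(out), small_graph, out.spacing, origin=out.origin
        )
        assert res.n_discontinuous == n_cut
        assert res.discontinuity_ratio == pytest.approx(
            100.0 * n_cut / small_graph.n_segments
        )
        cut_ids = state.cut_segment_ids
        for sid, status in res.per_segment_continuity.items():
            expected = ig.DISCONTINUOUS if sid in cut_ids else ig.CONTINUOUS
            assert status == expected

    def test_all_cut(self, small_graph, small_labels):
        state = cut_state(small_graph, small_graph.n_segments)
        out = ph.apply_degradation(small_labels, small_graph, state)
        res = ig.discontinuity_ratio(
            ig.segment_scaffold(out), small_graph, out.spacing, origin=out.origin
        )
        assert res.discontinuity_ratio == 100.0
        assert res.empty_mask

    def test_monotone_under_added_cuts(self, small_graph, small_labels):
        ratios = []
        for n_cut in (0, 2, 5, 10):
            # same permutation seed -> nested cut sets
            state = cut_state(small_graph, n_cut, seed=99)
            out = ph.apply_degradation(small_labels, small_graph, state)
            res = ig.discontinuity_ratio(
                ig.segment_scaffold(out), small_graph, out.spacing, origin=out.origin
            )
            ratios.append(res.discontinuity_ratio)
        assert ratios == sorted(ratios)

    def test_fragments_bound(self, small_graph, small_labels):
        """Cutting links (graph bridges) must create >= that many extra
        mask fragments."""
        links = [s.id for s in small_graph.segments if s.kind == "link"]
        state = ph.DegradationState(cut_segment_ids=frozenset(links), seed=0)
        out = ph.apply_degradation(small_labels, small_graph, state)
        res = ig.discontinuity_ratio(
            ig.segment_scaffold(out), small_graph, out.spacing, origin=out.origin
        )
        assert res.n_fragments >= 2  # two rings fully separated

    def test_bad_registration_rejected(self, small_graph, small_labels):
        mask = ig.segment_scaffold(small_labels)
        with pytest.raises(ig.IntegrityError, match="registration"):
            ig.discontinuity_ratio(
                mask, small_graph, small_labels.spacing,
                origin=small_labels.origin, registration="rigid",
            )

    def test_identity_registration_matches_none(self, small_graph, small_labels):
        mask = ig.segment_scaffold(small_labels)
        res_none = ig.discontinuity_ratio(
            mask, small_graph, small_labels.spacing, origin=small_labels.origin
        )
        res_id = ig.discontinuity_ratio(
            mask, small_graph, small_labels.spacing, origin=small_labels.origin,
            registration=(np.eye(3), np.zeros(3)),
        )
        assert res_id.per_segment_continuity == res_none.per_segment_continuity


def tube_mask(r_in, r_out, spacing=0.02, nz=12, half=1.8):
    n = int(round(2 * half / spacing))
    x = (np.arange(n) - n / 2 + 0.5) * spacing
    rr = np.hypot(*np.meshgrid(x, x, indexing="ij"))
    ring = (rr >= r_in) & (rr <= r_out)
    return np.broadcast_to(ring, (nz, n, n)).copy()


class TestInnerArea:
    def test_ideal_tube_matches_pi_r_squared(self):
        r = 1.4
        mask = tube_mask(r, r + 0.06)
        prof = ig.inner_area_profile(mask, 0.02, interval=0.1)
        expected = math.pi * r**2
        assert prof.measurable().all()
        assert prof.mean_area == pytest.approx(expected, rel=0.05)

    def test_two_struts_unmeasurable(self):
        mask = np.zeros((6, 80, 80), dtype=bool)
        mask[:, 10:14, 10:14] = True
        mask[:, 60:64, 60:64] = True
        prof = ig.inner_area_profile(mask, 0.02, interval=0.02)
        assert not prof.measurable().any()
        assert math.isnan(prof.mean_area)

    def test_empty_mask(self):
        prof = ig.inner_area_profile(np.zeros((5, 5, 5), bool), 0.02)
        assert prof.areas.size == 0
        assert math.isnan(prof.mean_area)

    def test_positions_spacing(self, small_labels):
        mask = ig.segment_scaffold(small_labels)
        prof = ig.inner_area_profile(mask, small_labels.spacing, interval=1.0)
        assert np.all(np.diff(prof.slice_positions) > 0)
        steps = np.diff(prof.slice_positions)
        assert np.allclose(steps, 1.0, atol=small_labels.spacing)

    def test_scaffold_slices_near_lumen_area(self, small_design, small_labels):
        mask = ig.segment_scaffold(small_labels)
        prof = ig.inner_area_profile(mask, small_labels.spacing, interval=1.0)
        ok = prof.measurable()
        assert ok.any()
        r_inner = small_design.centerline_radius - small_design.strut_thickness / 2
        upper = math.pi * r_inner**2
        assert np.all(prof.areas[ok] <= upper * 1.05)
        assert np.all(prof.areas[ok] >= 0.5 * upper)

    def test_dilated_phantom_larger_areas(self, small_design, small_graph):
        from dataclasses import replace
        from mgscaffold.geometry import build_design

        base_mask = ig.segment_scaffold(ph.voxelize(small_graph, spacing=0.02))
        dilated_design = replace(
            small_design, nominal_diameter=small_design.nominal_diameter * 1.1
        )
        dilated = ig.segment_scaffold(
            ph.voxelize(build_design(dilated_design), spacing=0.02)
        )
        p0 = ig.inner_area_profile(base_mask, 0.02, interval=1.0)
        p1 = ig.inner_area_profile(dilated, 0.02, interval=1.0)
        m0 = p0.areas[p0.measurable()].mean()
        m1 = p1.areas[p1.measurable()].mean()
        assert m1 > m0

    def test_empty_mask_downstream_propagation(self, small_graph):
        mask = np.zeros((10, 10, 10), dtype=bool)
        res = ig.discontinuity_ratio(mask, small_graph, 0.02)
        assert res.discontinuity_ratio == 100.0
        assert res.empty_mask
        assert res.n_fragments == 0
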