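import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scquant.metrics import (
    QuantConfig,
    TFMetrics,
    assign_tf_sides,
    classify_pairings,
    compute_asymmetry,
    compute_ce_nn,
    compute_density,
    compute_le_nn,
    compute_tf_metrics,
    metrics_dataframe,
    quantify_model,
    summarize,
    width_samples_from_points,
)


class TestSideAssignment:
    def test_zero_noise_sides_match_truth(self, zero_noise):
        model, truth = zero_noise
        sides = [a.side for a in assign_tf_sides(model)]
        assert sides == truth.sides()

    def test_orientation_flags_le_end(self, zero_noise):
        model, _ = zero_noise
        asg = assign_tf_sides(model)
        for tf, a in zip(model.tfs, asg):
            le_end = tf.points[0] if a.le_end_first else tf.points[-1]
            assert abs(le_end[1]) > 50  # LE ends sit inside the lateral elements

    def test_default_cohort_side_recovery(self, default_cohort, default_cohort_results):
        ok = n = 0
        for (_, truth), result in zip(default_cohort, default_cohort_results):
            for tm, tt in zip(result.tf_metrics, truth.tfs):
                n += 1
                ok += tm.side == tt.side
        assert ok / n >= 0.99


class TestTFMetrics:
    def test_zero_noise_segments_exact(self, zero_noise):
        model, truth = zero_noise
        for tm, tt in zip(compute_tf_metrics(model), truth.tfs):
            assert tm.len_total_nm == pytest.approx(tt.len_total_nm, abs=1e-6)
            assert tm.len_le_indent_nm == pytest.approx(tt.len_le_indent_nm, abs=1e-6)
            assert tm.len_ce_indent_nm == pytest.approx(tt.len_ce_indent_nm, abs=1e-6)
            assert tm.len_midsection_nm == pytest.approx(tt.len_midsection_nm, abs=1e-6)

    def test_cloud_regions_agree_with_slab(self, zero_noise):
        model, _ = zero_noise
        spacing = model.scale and 3.0  # generator cloud spacing
        slab_metrics = compute_tf_metrics(model)
        cloud_metrics = compute_tf_metrics(model.with_region_kind("point_cloud"))
        tol = spacing + 0.01
        diffs = [
            abs(a.len_le_indent_nm - b.len_le_indent_nm)
            for a, b in zip(slab_metrics, cloud_metrics)
            if not (math.isnan(a.len_le_indent_nm) or math.isnan(b.len_le_indent_nm))
        ]
        assert len(diffs) > 0.9 * len(slab_metrics)
        assert np.mean(diffs) < tol
        assert np.max(diffs) < 2 * tol


class TestWidths:
    def test_lateral_offset_closed_form(self):
        xle_left = np.array([[0.0, -57.0, 0.0]])
        xle_right = np.array([[10.0, 57.0, 0.0]])
        ws = width_samples_from_points(xle_left, xle_right, np.empty((0, 3)), np.empty((0, 3)))
        expected = math.sqrt(114.0**2 + 10.0**2)
        assert ws.cr_width == pytest.approx([expected, expected])

    def test_cr_width_never_below_planted_gap(self, default_cohort, default_cohort_results):
        for (_, truth), result in zip(default_cohort, default_cohort_results):
            assert result.widths.cr_width.min() >= truth.cr_width_nm - 1e-9

    def test_empty_opposing_side_reported_empty(self):
        ws = width_samples_from_points(
            np.array([[0.0, -57.0, 0.0]]), np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3))
        )
        assert len(ws.cr_width) == 0


class TestNearestNeighbors:
    @staticmethod
    def fake_metrics(points_by_side):
        out = []
        for i, (side, p) in enumerate(points_by_side):
            out.append(
                TFMetrics(i, side, endpoint_le=np.asarray(p) + [0, 60, 0],
                          endpoint_ce=np.asarray(p, dtype=float))
            )
        return out

    def test_two_opposing_tfs(self):
        tfm = self.fake_metrics([("left", [0, -1, 0]), ("right", [0, 16, 0])])
        compute_ce_nn(tfm)
        assert tfm[0].nn_opposite_nm == pytest.approx(17.0)
        assert tfm[1].nn_opposite_nm == pytest.approx(17.0)
        assert math.isnan(tfm[0].nn_parallel_nm)  # no same-side partner

    def test_matches_brute_force(self, default_cohort_results):
        tfm = default_cohort_results[0].tf_metrics
        left = [m for m in tfm if m.side == "left"]
        pts = np.array([m.endpoint_ce for m in left])
        for m in left[:20]:
            d = np.linalg.norm(pts - m.endpoint_ce, axis=1)
            d[d == 0] = np.inf
            assert m.nn_parallel_nm == pytest.approx(d.min())

    def test_le_nn(self):
        tfm = self.fake_metrics([("left", [0, 0, 0]), ("left", [21, 0, 0]), ("right", [5, 0, 0])])
        compute_le_nn(tfm)
        assert tfm[0].nn_le_nm == pytest.approx(21.0)
        assert math.isnan(tfm[2].nn_le_nm)  # lone endpoint on its side


class TestPairing:
    def make(self, nn_opp, nn_par):
        m = TFMetrics(0, "left", np.zeros(3), np.zeros(3))
        m.nn_opposite_nm, m.nn_parallel_nm = nn_opp, nn_par
        return m

    def test_threshold_rules_and_precedence(self):
        records = [self.make(8.0, 3.0), self.make(30.0, 10.0), self.make(30.0, 30.0)]
        props = classify_pairings(records, threshold_nm=15.0)
        assert [m.pairing for m in records] == ["opposite", "parallel", "single"]
        assert props == {"opposite": 1 / 3, "parallel": 1 / 3, "single": 1 / 3}

    def test_planted_mixture_recovery(self, default_cohort, default_cohort_results):
        ok = n = 0
        for (_, truth), result in zip(default_cohort, default_cohort_results):
            for tm, tt in zip(result.tf_metrics, truth.tfs):
                n += 1
                ok += tm.pairing == tt.pairing
        assert ok / n >= 0.90


class TestAsymmetryDensity:
    def test_reported_maximum_case(self):
        assert compute_asymmetry(100, 79) == pytest.approx(21.0)
        assert compute_asymmetry(50, 50) == 0.0
        assert math.isnan(compute_asymmetry(0, 10))

    @given(st.integers(1, 500), st.integers(1, 500))
    def test_symmetric_in_sides(self, a, b):
        assert compute_asymmetry(a, b) == compute_asymmetry(b, a)
        assert 0 <= compute_asymmetry(a, b) < 100

    def test_density_arithmetic(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([
            np.linspace(0, 2000.0, 158), rng.uniform(-1, 1, 158), rng.uniform(-40, 40, 158)
        ])
        tfm = [TFMetrics(i, "left", None, None, x_ce=p) for i, p in enumerate(pts)]
        d = compute_density(tfm, site="CE")
        assert d.tfs_per_um == pytest.approx(158 / 2.0, rel=1e-3)
        d2 = compute_density(tfm, site="CE", n_tfs=316)
        assert d2.tfs_per_um == pytest.approx(158.0, rel=1e-3)
        assert d2.tfs_per_um == pytest.approx(2 * d.tfs_per_um)

    def test_degenerate_sites_reported_as_nan(self):
        tfm = [TFMetrics(i, "left", None, None, x_ce=np.zeros(3)) for i in range(5)]
        d = compute_density(tfm, site="CE")
        assert math.isnan(d.tfs_per_um)

    def test_rect_length_tracks_sc_length(self, zero_noise):
        model, truth = zero_noise
        result = quantify_model(model)
        spacing = truth.config.sc_length_nm / max(truth.n_tfs // 2, 1)
        assert result.density.rect.length_nm == pytest.approx(
            truth.config.sc_length_nm, abs=2 * spacing
        )


class TestSummaries:
    def test_single_tomogram_pooled_equals_per_tomogram(self, default_cohort_results):
        r = default_cohort_results[0]
        pooled = summarize([r])
        for field in ("tf_len_mean", "cr_width_mean", "nn_opposite_mean", "midsection_sd"):
            assert getattr(pooled, field) == pytest.approx(getattr(r.summary, field), nan_ok=True)

    def test_pooled_mean_is_sample_weighted(self, default_cohort_results):
        pooled = summarize(default_cohort_results)
        samples = np.concatenate(
            [
                [m.len_total_nm for m in r.tf_metrics if m.side != "unresolved"]
                for r in default_cohort_results
            ]
        )
        assert pooled.tf_len_mean == pytest.approx(np.mean(samples))
        assert pooled.tf_len_sd == pytest.approx(np.std(samples, ddof=1))

    def test_pooled_width_sd_matches_concatenation(self, default_cohort_results):
        pooled = summarize(default_cohort_results)
        cat = np.concatenate([r.widths.cr_width for r in default_cohort_results])
        assert pooled.cr_width_sd == pytest.approx(np.std(cat, ddof=1))

    def test_metrics_dataframe_shape(self, default_cohort_results):
        df = metrics_dataframe(default_cohort_results[0].tf_metrics)
        assert len(df) == len(default_cohort_results[0].tf_metrics)
        assert {"side", "len_total_nm", "nn_opposite_nm", "x_le_x"} <= set(df.columns)
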