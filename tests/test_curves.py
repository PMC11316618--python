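"""Principal-curve fitters and projection."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import archdiag as ad
from archdiag.errors import DimensionError, FitFailureError, ParameterError


def _arch(n=80, noise=0.03, seed=0):
    rng = np.random.default_rng(seed)
    th = np.linspace(0.0, np.pi, n)
    pts = np.column_stack([np.cos(th), np.sin(th)])
    return pts + rng.normal(0.0, noise, pts.shape), th


class TestLocalCurve:
    def test_collinear_points_give_zero_projection_distance(self):
        t = np.linspace(0.0, 1.0, 40)
        pts = np.column_stack([t, 2.0 * t])
        curve = ad.fit_local_curve(pts)
        _, resid = ad.project_onto_curve(curve, pts)
        assert resid.max() < 1e-9

    def test_band_a_ordering_recovery(self, band_a, band_a_embedding):
        curve = ad.fit_local_curve(band_a_embedding)
        rep = ad.curve_fit_report(curve, band_a_embedding.scores[:, :2],
                                  reference_order=band_a.true_order)
        assert abs(rep.ordering_correlation) >= 0.95
        assert rep.coverage > 0.8

    def test_tight_circle_angle_constraint_blocks_the_turn(self):
        # following this circle needs ~0.4 rad of turn per step; with the
        # cone capped well below that the greedy constraint rejects the
        # very first continuation, while an unconstrained fit walks the
        # whole circumference (without ever closing into a polygon)
        th = np.linspace(0.0, 2 * np.pi, 120, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        unconstrained = ad.fit_local_curve(pts, step=0.15, radius=0.25,
                                           angle_max=np.pi / 2)
        assert unconstrained.length > 0.9 * 2 * np.pi
        assert np.linalg.norm(unconstrained.vertices[0]
                              - unconstrained.vertices[-1]) > 0.1
        with pytest.raises(FitFailureError):
            ad.fit_local_curve(pts, step=0.15, radius=0.25, angle_max=0.2)

    def test_first_step_failure_reported_with_diagnostics(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        pts[0] = [100.0, 100.0]  # isolated start, empty first neighborhood
        with pytest.raises(FitFailureError) as exc:
            ad.fit_local_curve(pts, step=0.1, radius=0.2)
        assert "radius" in exc.value.diagnostics

    def test_needs_ten_cells(self):
        with pytest.raises(ParameterError):
            ad.fit_local_curve(np.random.default_rng(0).normal(size=(9, 2)))

    def test_step_must_not_exceed_radius(self):
        pts, _ = _arch()
        with pytest.raises(ParameterError):
            ad.fit_local_curve(pts, step=0.5, radius=0.1)


class TestGlobalCurve:
    def test_collinear_points_give_straight_curve_and_zero_loss(self):
        t = np.linspace(0.0, 1.0, 30)
        pts = np.column_stack([t, -t])
        curve = ad.fit_global_curve(pts, n_nodes=8)
        _, resid = ad.project_onto_curve(curve, pts)
        assert resid.max() < 1e-6
        assert curve.total_curvature < 1e-3

    def test_global_beats_stalled_local_on_sparsely_sampled_arch(self):
        # an arch with a sparse stretch at its crest: the greedy local
        # fitter stalls in the gap and strands one arm; the global
        # fitter bridges it and attains a far lower projection error
        rng = np.random.default_rng(3)
        th = np.concatenate([np.linspace(0.0, 1.2, 30),
                             np.linspace(1.9, np.pi, 30)])
        pts = np.column_stack([np.cos(th), np.sin(th)])
        pts = pts + rng.normal(0.0, 0.01, pts.shape)
        local = ad.fit_local_curve(pts, step=0.1, radius=0.2)
        glob = ad.fit_global_curve(pts, n_nodes=12, smoothness=0.5)
        _, resid_local = ad.project_onto_curve(local, pts)
        _, resid_glob = ad.project_onto_curve(glob, pts)
        assert resid_glob.mean() < resid_local.mean()

    def test_curvature_non_increasing_in_smoothness(self):
        pts, _ = _arch(n=80, noise=0.05)
        curvatures = [ad.fit_global_curve(pts, n_nodes=15, smoothness=s).total_curvature
                      for s in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert np.all(np.diff(curvatures) <= 1e-9)

    def test_deterministic(self, band_a_embedding):
        c1 = ad.fit_global_curve(band_a_embedding.scores[:, :2])
        c2 = ad.fit_global_curve(band_a_embedding.scores[:, :2])
        np.testing.assert_array_equal(c1.vertices, c2.vertices)

    def test_parameter_validation(self):
        pts, _ = _arch()
        with pytest.raises(ParameterError):
            ad.fit_global_curve(pts, n_nodes=3)
        with pytest.raises(ParameterError):
            ad.fit_global_curve(pts[:5], n_nodes=10)
        with pytest.raises(ParameterError):
            ad.fit_global_curve(pts, smoothness=-1.0)


class TestProjection:
    def test_curve_vertex_projects_to_itself(self):
        curve = ad.PrincipalCurve(
            vertices=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]),
            arc_lengths=np.array([0.0, 1.0, 2.0]))
        arc, resid = ad.project_onto_curve(curve, np.array([[1.0, 0.0]]))
        assert resid[0] == 0.0
        assert arc[0] == 1.0

    def test_equidistant_point_assigned_to_lower_arc_segment(self):
        # a right-angle polyline; (1,1) is equidistant from both segments
        curve = ad.PrincipalCurve(
            vertices=np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0]]),
            arc_lengths=np.array([0.0, 2.0, 4.0]))
        arc, resid = ad.project_onto_curve(curve, np.array([[1.0, 1.0]]))
        assert resid[0] == pytest.approx(1.0)
        assert arc[0] == pytest.approx(1.0)  # on the first segment

    def test_dimension_mismatch_rejected(self):
        curve = ad.PrincipalCurve(vertices=np.zeros((2, 3)),
                                  arc_lengths=np.array([0.0, 0.0]))
        with pytest.raises(DimensionError):
            ad.project_onto_curve(curve, np.zeros((4, 2)))

    def test_band_a_arc_positions_rank_correlate_with_truth(
            self, band_a, band_a_embedding):
        curve = ad.fit_local_curve(band_a_embedding)
        arc, _ = ad.project_onto_curve(curve, band_a_embedding.scores[:, :2])
        rho = spearmanr(arc, band_a.true_order).statistic
        assert abs(rho) >= 0.95


class TestEquivariance:
    @pytest.mark.parametrize("fitter", ["local", "global"])
    def test_rotation_translation_leave_fit_quality_unchanged(self, fitter):
        pts, th = _arch(n=60, noise=0.02)
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + np.array([5.0, -3.0])

        def fit(p):
            if fitter == "local":
                return ad.fit_local_curve(p)
            return ad.fit_global_curve(p, n_nodes=12)

        r1 = ad.curve_fit_report(fit(pts), pts, reference_order=np.arange(60))
        r2 = ad.curve_fit_report(fit(moved), moved, reference_order=np.arange(60))
        assert r1.mean_projection_distance == pytest.approx(
            r2.mean_projection_distance, rel=1e-4, abs=1e-8)
        assert abs(r1.ordering_correlation) == pytest.approx(
            abs(r2.ordering_correlation), abs=1e-6)

    def test_uniform_scaling_scales_curve_and_preserves_correlation(self):
        pts, _ = _arch(n=60, noise=0.02)
        c1 = ad.fit_global_curve(pts, n_nodes=12)
        c2 = ad.fit_global_curve(pts * 4.0, n_nodes=12)
        np.testing.assert_allclose(c2.vertices, 4.0 * c1.vertices, atol=1e-6)

    def test_reversed_reference_negates_correlation(self):
        pts, _ = _arch(n=60, noise=0.02)
        c = ad.fit_global_curve(pts, n_nodes=12)
        fwd = ad.curve_fit_report(c, pts, reference_order=np.arange(60))
        rev = ad.curve_fit_report(c, pts, reference_order=np.arange(60)[::-1])
        assert fwd.ordering_correlation == pytest.approx(
            -rev.ordering_correlation, abs=1e-9)

    def test_noise_increases_projection_distance(self):
        mpds = []
        for noise in (0.0, 0.05, 0.15):
            pts, _ = _arch(n=80, noise=noise, seed=7)
            c = ad.fit_global_curve(pts, n_nodes=12, smoothness=1.0)
            _, resid = ad.project_onto_curve(c, pts)
            mpds.append(resid.mean())
        assert mpds[0] < mpds[1] < mpds[2]
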