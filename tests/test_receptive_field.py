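"""Receptive-field mapping, contour metrics, exclusion and classification."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon
from sklearn.metrics import calinski_harabasz_score

from ofsdn.circstats import circ_distance
from ofsdn.receptive_field import (
    RFGrid,
    analyse_neuron,
    apply_exclusion,
    classify_neuron,
    cluster_features,
    half_max_contour,
    interpolate_map,
    local_tuning,
    map_receptive_field,
    polygon_metrics,
    rf_preferred_direction,
    transform_coordinates,
)
from ofsdn.synthetic import class_template, simulate_rf_protocol

DIRS8 = np.arange(0.0, 360.0, 45.0)


class TestLocalTuning:
    def test_noiseless_model(self):
        rates = 10 + 5 * np.cos(np.deg2rad(DIRS8 - 90.0))
        t = local_tuning(DIRS8, rates, spontaneous=10.0)
        assert t.local_max == pytest.approx(5.0)
        assert t.lpd == pytest.approx(90.0, abs=1e-9)
        assert t.lms == pytest.approx(5.0)

    def test_flat_at_spontaneous(self):
        t = local_tuning(DIRS8, np.full(8, 10.0), spontaneous=10.0)
        assert t.local_max == pytest.approx(0.0)
        assert t.lms == pytest.approx(0.0)

    def test_poisson_recovery_of_lpd(self):
        # Poisson sampling around a known tuning recovers the LPD closely.
        # Rectification at 0 (baseline 10, amplitude 40) biases the
        # estimand slightly off 150 deg, so recovery is judged against the
        # noiseless rectified-tuning phase (the quantity the fit estimates).
        rng = np.random.default_rng(0)
        lam = np.maximum(0, 10 + 40 * np.cos(np.deg2rad(DIRS8 - 150.0)))
        from ofsdn.circstats import fit_cosine

        estimand = fit_cosine(DIRS8, lam).preferred_phase
        assert circ_distance(estimand, 150.0) < 3.0  # small rectification bias
        hits = 0
        for _ in range(100):
            rates = rng.poisson(lam * 0.36 * 20) / (0.36 * 20)
            t = local_tuning(DIRS8, rates, spontaneous=10.0)
            if circ_distance(t.lpd, estimand) <= 5.0:
                hits += 1
        assert hits >= 99


class TestInterpolateMap:
    def setup_method(self):
        self.az = np.arange(-30.0, 31.0, 20.0)
        self.el = np.arange(-20.0, 21.0, 20.0)

    def test_constant_map(self):
        vals = np.full((3, 4), 2.5)
        _, _, dense = interpolate_map(self.az, self.el, vals)
        assert np.allclose(dense, 2.5)

    def test_node_preservation(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 50, (3, 4))
        az_d, el_d, dense = interpolate_map(self.az, self.el, vals)
        assert np.allclose(dense[::10, ::10], vals)

    def test_bilinear_midpoint(self):
        vals = np.zeros((3, 4))
        vals[1, 1] = 10.0  # midpoint between this node and its 0-valued neighbour
        _, _, dense = interpolate_map(self.az, self.el, vals)
        assert dense[10, 15] == pytest.approx(5.0)

    def test_irregular_lattice_rejected(self):
        with pytest.raises(ValueError):
            interpolate_map([0.0, 10.0, 50.0], self.el, np.zeros((3, 3)))


class TestHalfMaxContour:
    def test_gaussian_bump_area_matches_analytic(self):
        # half-max contour of a Gaussian is a circle of radius sigma*sqrt(2 ln 2)
        az = np.linspace(-60, 60, 241)
        el = np.linspace(-60, 60, 241)
        aa, ee = np.meshgrid(az, el)
        sigma = 15.0
        dense = 40.0 * np.exp(-(aa**2 + ee**2) / (2 * sigma**2))
        contour, clipped = half_max_contour(az, el, dense)
        assert not clipped
        r_expected = sigma * np.sqrt(2 * np.log(2))
        area = Polygon(contour).area
        assert area == pytest.approx(np.pi * r_expected**2, rel=0.02)

    def test_two_bumps_selects_the_maximum(self):
        az = np.linspace(-50, 50, 201)
        el = np.linspace(-20, 20, 81)
        aa, ee = np.meshgrid(az, el)
        big = 50 * np.exp(-((aa - 30) ** 2 + ee**2) / 50.0)
        small = 40 * np.exp(-((aa + 30) ** 2 + ee**2) / 50.0)
        contour, _ = half_max_contour(az, el, big + small)
        poly = Polygon(contour)
        assert poly.contains(Point(30, 0))
        assert not poly.contains(Point(-30, 0))

    def test_border_touching_field_closed_and_flagged(self):
        az = np.linspace(0, 40, 81)
        el = np.linspace(0, 40, 81)
        aa, ee = np.meshgrid(az, el)
        dense = 30 * np.exp(-(aa**2 + ee**2) / (2 * 15.0**2))  # peak at the corner
        contour, clipped = half_max_contour(az, el, dense)
        assert clipped
        assert np.allclose(contour[0], contour[-1])  # closed

    def test_nonpositive_map_rejected(self):
        with pytest.raises(ValueError):
            half_max_contour(np.arange(3.0), np.arange(3.0), np.zeros((3, 3)))


class TestPolygonMetrics:
    def test_unit_square(self):
        w, h, c = polygon_metrics([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert (w, h) == (1.0, 1.0)
        assert c == pytest.approx((0.5, 0.5))

    def test_triangle_centroid(self):
        _, _, c = polygon_metrics([(0, 0), (1, 0), (0, 1)])
        assert c == pytest.approx((1 / 3, 1 / 3))

    def test_random_convex_polygons_against_monte_carlo(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 10, (20, 2))
            hull = Polygon(pts).convex_hull
            w, h, c = polygon_metrics(hull)
            minx, miny, maxx, maxy = hull.bounds
            samples = rng.uniform([minx, miny], [maxx, maxy], (200000, 2))
            inside = np.array([hull.contains(Point(p)) for p in samples[:20000]])
            mc = samples[:20000][inside].mean(axis=0)
            assert np.allclose(c, mc, atol=0.05)

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError):
            polygon_metrics([(0, 0), (1, 1), (1, 0), (0, 1)])


class TestPreferredDirection:
    def _tune(self, lpd, lms, loc=(0.0, 0.0)):
        from ofsdn.receptive_field import LocalTuning

        return LocalTuning(local_max=lms, lpd=lpd, lms=lms, location=loc)

    def test_uniform_lpds(self):
        tunings = [self._tune(270.0, lms) for lms in (10, 20, 30)]
        pd_, disp, n = rf_preferred_direction(tunings)
        assert pd_ == pytest.approx(270.0)
        assert disp == pytest.approx(0.0, abs=1e-6)
        assert n == 2  # only strictly-above-half locations counted

    def test_symmetric_median(self):
        tunings = [self._tune(d, 30.0) for d in (260.0, 270.0, 280.0)]
        pd_, _, n = rf_preferred_direction(tunings)
        assert pd_ == pytest.approx(270.0)
        assert n == 3

    def test_rotational_template_recovery(self):
        tpl = class_template("DN2_RHS", lpd_field=("rotational", (35.0, 0.0)),
                             spontaneous=120.0)
        grid = simulate_rf_protocol(tpl, noiseless=True)
        res = map_receptive_field(grid)
        # near the flow centre the tangent field at high-LMS locations is
        # orthogonal-symmetric; the median sits on the tangent circle family
        assert res.n_over_half >= 2
        assert np.isfinite(res.preferred_direction)


class TestExclusion:
    @pytest.mark.parametrize(
        "lms,n,disp,excluded,reason",
        [
            (19.0, 10, 10.0, True, "low_lms"),
            (50.0, 4, 10.0, True, "few_positions"),
            (50.0, 10, 35.0, True, "high_lpd_dispersion"),
            (50.0, 10, 10.0, False, None),
            (20.0, 5, 30.0, False, None),  # boundaries are inclusive-keep
        ],
    )
    def test_rule(self, lms, n, disp, excluded, reason):
        exc, reasons = apply_exclusion(lms, n, disp)
        assert exc is excluded
        if reason:
            assert reason in reasons

    def test_multiple_reasons_enumerated(self):
        _, reasons = apply_exclusion(5.0, 2, 60.0)
        assert set(reasons) == {"low_lms", "few_positions", "high_lpd_dispersion"}

    def test_monotonicity_under_tightening(self, rng):
        for _ in range(100):
            lms = rng.uniform(0, 60)
            n = int(rng.integers(0, 12))
            disp = rng.uniform(0, 60)
            exc_loose, _ = apply_exclusion(lms, n, disp)
            exc_tight, _ = apply_exclusion(lms, n, disp, min_lms=30.0,
                                           max_dispersion=20.0)
            assert exc_tight or not exc_loose


class TestClassification:
    @pytest.mark.parametrize(
        "direction,azimuth,expected",
        [
            (150.0, -40.0, "DN1_LHS"),
            (270.0, 20.0, "DN2_RHS"),
            (270.0, -20.0, "DN2_LHS"),
            (350.0, 30.0, "DN1_RHS"),
            (30.0, 30.0, "DN1_RHS"),
            (90.0, 0.0, "UNCLASSIFIED"),
            (120.0, 0.0, "DN1_LHS"),   # inclusive boundary
            (200.0, 0.0, "DN1_LHS"),
            (340.0, 0.0, "DN1_RHS"),
            (60.0, 0.0, "DN1_RHS"),
            (220.0, 1.0, "DN2_RHS"),
            (320.0, -1.0, "DN2_LHS"),
        ],
    )
    def test_examples(self, direction, azimuth, expected):
        assert classify_neuron(direction, azimuth) == expected

    def test_partition_of_the_circle(self):
        # every direction maps to exactly one class outcome
        for d in np.arange(0.0, 360.0, 0.25):
            for az in (-10.0, 10.0):
                assert classify_neuron(d, az) in (
                    "DN1_LHS", "DN1_RHS", "DN2_LHS", "DN2_RHS", "UNCLASSIFIED"
                )

    def test_undefined_direction(self):
        assert classify_neuron(float("nan"), 0.0) == "UNCLASSIFIED"


class TestTransforms:
    def setup_method(self):
        grid = simulate_rf_protocol(class_template("DN1_LHS"), seed=11)
        self.rf = map_receptive_field(grid)

    @pytest.mark.parametrize("kwargs", [{"ventral_up": True}, {"mirror_to_rhs": True}])
    def test_involution(self, kwargs):
        twice = transform_coordinates(transform_coordinates(self.rf, **kwargs), **kwargs)
        assert np.allclose(twice.dense_map, self.rf.dense_map)
        assert np.allclose(twice.dense_azimuths, self.rf.dense_azimuths)
        assert circ_distance(twice.preferred_direction,
                             self.rf.preferred_direction) < 1e-9
        assert np.allclose(twice.contour, self.rf.contour)

    def test_ventral_up_rotates_directions(self):
        out = transform_coordinates(self.rf, ventral_up=True)
        assert circ_distance(out.preferred_direction,
                             (self.rf.preferred_direction + 180) % 360) < 1e-9

    def test_mirror_reflects_directions(self):
        out = transform_coordinates(self.rf, mirror_to_rhs=True)
        assert circ_distance(out.preferred_direction,
                             (180 - self.rf.preferred_direction) % 360) < 1e-9
        assert out.centre[0] == pytest.approx(-self.rf.centre[0])

    def test_lms_and_count_preserved(self):
        out = transform_coordinates(self.rf, ventral_up=True, mirror_to_rhs=True)
        assert out.n_over_half == self.rf.n_over_half
        assert [t.lms for t in out.tunings] == [t.lms for t in self.rf.tunings]


class TestClustering:
    def test_separated_blobs(self, rng):
        x = np.vstack([rng.normal(0, 0.01, (20, 2)), rng.normal(100, 0.01, (20, 2))])
        labels, ch = cluster_features(x, k=2, seed=0)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]
        assert ch > 1000

    def test_ch_matches_hand_formula_and_sklearn(self):
        x = np.array([[0.0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]])
        labels, ch = cluster_features(x, k=2, seed=0)
        # independent cross-check on the same z-scored data
        mu, sd = x.mean(0), x.std(0)
        z = (x - mu) / sd
        assert ch == pytest.approx(calinski_harabasz_score(z, labels), rel=1e-9)

    def test_duplication_leaves_partition(self, rng):
        x = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(8, 1, (10, 3))])
        l1, _ = cluster_features(x, k=2, seed=0)
        l2, _ = cluster_features(np.vstack([x, x]), k=2, seed=0)
        same = np.mean(l1 == l2[:20])
        assert same in (0.0, 1.0)  # identical up to label permutation

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_features(np.zeros((3, 2)), k=5)


class TestEndToEnd:
    def test_noiseless_template_recovered_exactly(self):
        # spontaneous high enough that rate rectification never clips
        tpl = class_template("DN1_LHS", spontaneous=150.0)
        grid = simulate_rf_protocol(tpl, noiseless=True)
        res = map_receptive_field(grid)
        assert circ_distance(res.preferred_direction, 150.0) < 1e-9
        assert res.lpd_dispersion == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("cls", ["DN1_LHS", "DN1_RHS", "DN2_LHS", "DN2_RHS"])
    def test_noisy_recovery_per_class(self, cls):
        hits = 0
        for seed in range(20):
            rec = analyse_neuron(simulate_rf_protocol(class_template(cls), seed=seed), "n")
            hits += (not rec.excluded) and rec.neuron_class == cls
        assert hits >= 19

    def test_flat_neuron_excluded_for_low_lms(self):
        tpl = class_template("DN1_LHS", max_lms=0.0)
        rec = analyse_neuron(simulate_rf_protocol(tpl, seed=0), "flat")
        assert rec.excluded
        assert "low_lms" in rec.exclusion_reasons
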