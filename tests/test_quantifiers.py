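"""Order quantifiers: density, alignment indicator, projection, fits."""
import numpy as np
import pytest

import fibrenet as fn
from fibrenet.quantifiers import AL_THRESHOLD, AMAX_THRESHOLD


class TestDensity:
    @pytest.mark.parametrize("n, expected", [(3000, 0.58), (1500, 0.29), (0, 0.0)])
    def test_reference_volume_fractions(self, geom, box, n, expected):
        assert round(fn.fibre_density(n, geom, box), 2) == expected

    def test_regimes(self):
        assert fn.density_regime(0.29) == "sparse"
        assert fn.density_regime(0.58) == "dense"
        assert fn.density_regime(0.95) == "hyperdense"


class TestLinksPerFibre:
    def test_perfect_matching_is_half(self, box, geom):
        state = fn.make_orientation_field("uniform", 3000, seed=1, box=box)
        links = fn.make_link_topology(state, "perfect_matching", geom=geom, box=box)
        assert fn.links_per_fibre(links, 3000) == 0.5

    def test_counts(self):
        assert fn.links_per_fibre(fn.LinkTable(), 10) == 0.0
        links = fn.LinkTable(
            np.arange(2100), np.arange(2100) + 3000, np.zeros(2100),
            np.zeros(2100), np.zeros(2100),
        )
        assert fn.links_per_fibre(links, 3000) == pytest.approx(0.7)


class TestLocalAlignment:
    def test_parallel_neighbours_give_one(self, rng):
        w = np.array([0.0, 0.0, 1.0])
        signs = rng.choice([-1.0, 1.0], size=50)
        assert fn.local_alignment(w, np.outer(signs, w)) == pytest.approx(1.0)

    def test_uniform_neighbours_near_zero(self):
        st = fn.make_orientation_field("uniform", 10_000, seed=2)
        al = fn.local_alignment(st.omega[0], st.omega[1:])
        assert al < 0.5  # randomly oriented environment
        # eigenvalue-gap bias of the score scales like (n)**-0.25 via the sqrt
        assert al < 0.2

    def test_planar_neighbours_near_sqrt_half(self):
        st = fn.make_orientation_field("planar", 10_000, seed=3)
        al = fn.local_alignment(st.omega[0], st.omega[1:])
        assert al == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_concentrated_above_unidirectional_band(self):
        st = fn.make_orientation_field("concentration", 10_000, seed=4, kappa=20.0)
        al = fn.local_alignment(st.omega[0], st.omega[1:])
        assert al > 0.8

    def test_no_neighbours_undefined(self):
        assert np.isnan(fn.local_alignment([0, 0, 1], np.empty((0, 3))))

    def test_invariance_rotation_and_sign(self, rng):
        st = fn.make_orientation_field("concentration", 500, seed=5, kappa=3.0)
        w, nb = st.omega[0], st.omega[1:]
        base = fn.local_alignment(w, nb)
        # random rotation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert fn.local_alignment(w @ q.T, nb @ q.T) == pytest.approx(base, abs=1e-9)
        # per-fibre sign flips
        signs = rng.choice([-1.0, 1.0], size=(nb.shape[0], 1))
        assert fn.local_alignment(-w, nb * signs) == pytest.approx(base, abs=1e-12)

    def test_monotone_uniform_planar_unidirectional(self):
        """Al increases along the disorder -> planar -> unidirectional ladder."""
        vals = []
        for kind, kw in [
            ("uniform", {}),
            ("planar", {}),
            ("concentration", {"kappa": 30.0}),
            ("unidirectional", {}),
        ]:
            st = fn.make_orientation_field(kind, 5000, seed=6, **kw)
            vals.append(fn.local_alignment(st.omega[0], st.omega[1:]))
        assert vals == sorted(vals)

    def test_mean_alignment_is_unweighted_mean(self):
        al = np.array([0.2, np.nan, 0.8, 0.5])
        assert fn.mean_alignment(al) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            fn.mean_alignment(np.array([np.nan]))

    def test_alignment_field_perfectly_aligned_system(self, geom, box):
        st = fn.make_orientation_field("unidirectional", 400, seed=7, box=fn.DomainBox.cube(15))
        al = fn.alignment_field(st, geom, 1.0, fn.DomainBox.cube(15))
        assert fn.mean_alignment(al) == pytest.approx(1.0, abs=1e-9)


class TestStereographicProjection:
    def test_pole_maps_to_centre(self):
        pts = fn.stereographic_projection(np.array([[0.0, 0, 1]]), axis=[0, 0, 1])
        np.testing.assert_allclose(pts, [[0.0, 0.0]], atol=1e-12)

    def test_equator_maps_to_rim(self):
        pts = fn.stereographic_projection(np.array([[1.0, 0, 0]]), axis=[0, 0, 1])
        assert np.hypot(*pts[0]) == pytest.approx(1.0)

    def test_aligned_system_concentrates_at_centre(self):
        st = fn.make_orientation_field("concentration", 2000, seed=8, kappa=200.0)
        pts = fn.stereographic_projection(st.omega)  # data-driven axis
        assert np.hypot(pts[:, 0], pts[:, 1]).mean() < 0.2

    def test_uniform_directions_fill_disk_uniformly(self):
        """Equal-area projection: uniform directions -> uniform disk density."""
        st = fn.make_orientation_field("uniform", 50_000, seed=9)
        pts = fn.stereographic_projection(st.omega, axis=[0, 0, 1])
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        # r^2 of uniform disk points is uniform on [0, 1]
        assert abs(r2.mean() - 0.5) < 0.01
        assert np.all(r2 <= 1.0 + 1e-12)

    def test_amax_invariant_under_rotation_about_axis(self):
        st = fn.make_orientation_field("planar", 3000, seed=10)
        pts = fn.stereographic_projection(st.omega, axis=[0, 0, 1])
        a0 = fn.covariance_ellipse_semi_major(pts)
        th = 1.1
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        a1 = fn.covariance_ellipse_semi_major(
            fn.stereographic_projection(st.omega @ R.T, axis=[0, 0, 1])
        )
        assert a1 == pytest.approx(a0, abs=1e-9)


class TestCovarianceEllipse:
    def test_identical_points_give_zero(self):
        pts = np.tile([0.3, -0.2], (10, 1))
        assert fn.covariance_ellipse_semi_major(pts) == 0.0

    def test_uniform_disk_baseline_is_one(self, rng):
        n = 100_000
        r = np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        assert fn.covariance_ellipse_semi_major(pts) == pytest.approx(1.0, abs=0.01)

    def test_isotropic_gaussian_sigma(self, rng):
        pts = rng.normal(scale=0.2, size=(100_000, 2))
        assert fn.covariance_ellipse_semi_major(pts) == pytest.approx(0.4, abs=0.01)
        assert fn.covariance_ellipse_semi_major(pts) < AMAX_THRESHOLD


class TestClassification:
    @pytest.mark.parametrize(
        "al, amax, label",
        [
            (0.9, 0.3, "aligned"),
            (0.8, 0.6, "curved"),
            (0.4, 0.8, "unorganized"),
            (0.4, 0.3, "unnamed"),
        ],
    )
    def test_table_cells(self, al, amax, label):
        assert fn.classify_state(al, amax) == label

    def test_totality(self, rng):
        for al, amax in rng.uniform(0, 1.5, size=(200, 2)):
            assert fn.classify_state(al, amax) in {
                "aligned", "curved", "unorganized", "unnamed"
            }

    def test_thresholds_are_the_published_ones(self):
        assert AL_THRESHOLD == 0.7 and AMAX_THRESHOLD == 0.45


class TestTauFit:
    def test_recovers_known_time_constant(self):
        t = np.linspace(0, 800, 60)
        al = 0.9 * (1 - np.exp(-t / 100.0))
        fit = fn.fit_tau_al(t, al)
        assert fit.tau_al == pytest.approx(100.0, rel=0.05)

    def test_constant_series_gives_zero(self):
        t = np.linspace(0, 10, 10)
        assert fn.fit_tau_al(t, np.full(10, 0.5)).tau_al == 0.0

    def test_robust_to_noise(self, rng):
        t = np.linspace(0, 800, 120)
        al = 0.9 * (1 - np.exp(-t / 100.0)) + rng.normal(0, 0.009, t.size)
        fit = fn.fit_tau_al(t, al)
        assert fit.tau_al == pytest.approx(100.0, rel=0.10)

    def test_non_saturating_series_raises(self):
        t = np.linspace(0, 50, 30)
        al = 0.9 * (1 - np.exp(-t / 1000.0))
        with pytest.raises(ValueError):
            fn.fit_tau_al(t, al)


class TestLogLawFit:
    def test_exact_recovery_without_drop(self):
        x = np.linspace(0.1, 0.6, 8)
        y = 0.037 * np.log(x) + 1.006
        fit = fn.fit_log_law(x, y)
        assert fit.alpha == pytest.approx(0.037, abs=1e-10)
        assert fit.beta == pytest.approx(1.006, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert np.isnan(fit.n_critic)

    def test_drop_detection(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.5])
        y = 0.037 * np.log(x) + 1.006
        y[x > 0.7] -= 0.3  # abrupt fall above the critical link count
        fit = fn.fit_log_law(x, y)
        assert 0.7 < fit.n_critic <= 1.0
        assert fit.alpha == pytest.approx(0.037, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fn.fit_log_law([0.1, 0.2, 0.3], [0.9, 0.95, 1.0])


class TestEnsemble:
    def test_population_statistics(self):
        summaries = [
            fn.OrderSummary(0, al, nl, 0.5, "curved")
            for al, nl in [(0.8, 0.4), (0.9, 0.6)]
        ]
        es = fn.ensemble_summary(summaries)
        assert es.al_mean == pytest.approx(0.85)
        assert es.al_std == pytest.approx(0.05)
        assert es.nlinkperfib_mean == pytest.approx(0.5)
        assert es.n_replicates == 2
        with pytest.raises(ValueError):
            fn.ensemble_summary(summaries[:1])
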