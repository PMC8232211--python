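"""Classical hopping model: closed forms vs the rate-equation oracle."""

import numpy as np
import pytest

from b850sim.master_eq import (
    HoppingModel,
    LaserProfile,
    diffusion_length,
    dynamics_1d,
    dynamics_2d,
    hex_positions,
    laser_fwhm,
    ode_oracle_1d,
    ode_oracle_2d,
    stationary_1d,
    stationary_2d,
)


class TestStationary1D:
    def test_center_normalized_to_one(self):
        model = HoppingModel(K=0.02, k=0.1)
        laser = LaserProfile(sigma=100.0, center=50)
        _, ptilde = stationary_1d(model, laser, 101)
        assert ptilde[50] == 1.0

    def test_depends_only_on_rate_ratio(self):
        laser = LaserProfile(sigma=169.86, center=100)
        _, p1 = stationary_1d(HoppingModel(K=0.01, k=0.1), laser, 201)
        _, p2 = stationary_1d(HoppingModel(K=1.0, k=10.0), laser, 201)
        assert np.max(np.abs(p1 - p2)) < 1e-10

    def test_matches_ode_relaxation_on_101_rings(self):
        """The closed form equals the long-time limit of the directly
        integrated rate equations."""
        model = HoppingModel(K=0.05, k=0.1)
        laser = LaserProfile(sigma=80.0, center=50)
        field, _ = stationary_1d(model, laser, 101)
        y = ode_oracle_1d(model, np.array([0.0, 1500.0]), laser=laser, n_rings=101)
        assert np.max(np.abs(y[-1] - field.p)) / np.max(field.p) < 1e-8

    def test_no_dissipation_rejected(self):
        with pytest.raises(ValueError, match="K > 0"):
            stationary_1d(HoppingModel(K=0.0, k=0.1), LaserProfile(sigma=50.0, center=5), 11)


class TestStationary2D:
    def test_strong_dissipation_decouples_rings(self):
        """K >> k: p ~ r_a A / (K + 6k) at interior rings."""
        model = HoppingModel(K=50.0, k=0.1, layout="hexagonal")
        laser = LaserProfile(sigma=40.0)
        field = stationary_2d(model, laser, extent=8)
        x, y = hex_positions(8, model.a)
        A = np.exp(-(x**2 + y**2) / (2 * laser.sigma**2))
        approx = A / (model.K + 6 * model.k)
        center = slice(4, 13)
        rel = np.abs(field.p - approx)[center, center] / approx[center, center]
        assert np.max(rel) < 6 * model.k / model.K

    def test_sixty_degree_rotation_symmetry(self):
        """Rotating an off-center drive by 60 deg rotates the solution."""
        model = HoppingModel(K=0.6, k=0.1, layout="hexagonal")
        laser = LaserProfile(sigma=10.0)
        extent = 10
        n = 2 * extent + 1

        def drive(center_ij):
            A = np.zeros((n, n))
            ci, cj = center_ij
            A[extent + ci, extent + cj] = 1.0
            return A

        # axial rotation by 60 deg: (i, j) -> (-j, i + j)
        src = (2, 1)
        rot = (-src[1], src[0] + src[1])
        f1 = stationary_2d(model, laser, extent, A=drive(src))
        f2 = stationary_2d(model, laser, extent, A=drive(rot))
        # compare p1 at (i,j) with p2 at the rotated site for interior probes
        probes = [(0, 0), (1, 0), (0, 1), (3, 2), (-2, 1), (2, -1)]
        for i, j in probes:
            ri, rj = -j, i + j
            v1 = f1.p[extent + i, extent + j]
            v2 = f2.p[extent + ri, extent + rj]
            assert v1 == pytest.approx(v2, rel=1e-6)

    def test_linear_system_residual(self):
        from b850sim.master_eq import _hex_operator

        model = HoppingModel(K=0.05, k=0.1, layout="hexagonal")
        laser = LaserProfile(sigma=30.0)
        extent = 10
        field = stationary_2d(model, laser, extent)
        L = _hex_operator(extent, model)
        x, y = hex_positions(extent, model.a)
        A = np.exp(-(x**2 + y**2) / (2 * laser.sigma**2))
        resid = L @ field.p.reshape(-1) + A.reshape(-1)
        assert np.max(np.abs(resid)) < 1e-10


class TestDynamics1D:
    def test_time_zero_identity(self, rng):
        p0 = rng.random(21)
        out = dynamics_1d(p0, HoppingModel(K=0.1, k=0.2), 0.0)
        assert np.array_equal(out.p, p0)

    def test_conservation_without_dissipation(self, rng):
        p0 = np.zeros(301)
        p0[145:156] = rng.random(11)
        out = dynamics_1d(p0, HoppingModel(K=0.0, k=0.1), 200.0)
        assert out.total == pytest.approx(p0.sum(), abs=1e-10)

    @pytest.mark.parametrize("t", [1.0, 10.0, 100.0])
    def test_matches_ode_oracle_501_rings(self, t, rng):
        p0 = np.zeros(501)
        p0[245:256] = rng.random(11)
        model = HoppingModel(K=0.001, k=0.1)
        out = dynamics_1d(p0, model, t)
        y = ode_oracle_1d(model, np.array([0.0, t]), p0=p0)
        assert np.max(np.abs(out.p - y[-1])) < 1e-8

    def test_single_ring_pure_decay(self):
        model = HoppingModel(K=0.3, k=1e-9)
        y = ode_oracle_1d(model, np.array([0.0, 5.0]), p0=np.array([2.0]))
        assert y[-1, 0] == pytest.approx(2.0 * np.exp(-0.3 * 5.0 - 2e-9 * 5.0), rel=1e-8)


class TestDynamics2D:
    def test_time_zero_identity(self, rng):
        p0 = rng.random((9, 9))
        out = dynamics_2d(p0, HoppingModel(K=0.1, k=0.2, layout="hexagonal"), 0.0)
        assert np.array_equal(out.p, p0)

    def test_conservation_without_dissipation(self, rng):
        """Patch sized so that no probability reaches the boundary."""
        p0 = np.zeros((41, 41))
        p0[19:22, 19:22] = rng.random((3, 3))
        out = dynamics_2d(p0, HoppingModel(K=0.0, k=0.1, layout="hexagonal"), 8.0)
        assert abs(out.total - p0.sum()) < 1e-8

    def test_matches_ode_oracle_51x51(self, rng):
        p0 = np.zeros((51, 51))
        p0[24:27, 24:27] = rng.random((3, 3))
        model = HoppingModel(K=0.001, k=0.1, layout="hexagonal")
        t = 20.0
        out = dynamics_2d(p0, model, t)
        y = ode_oracle_2d(model, np.array([0.0, t]), p0)
        assert np.max(np.abs(out.p - y[-1])) < 1e-7


class TestDiffusionLength:
    def test_no_transport_limit(self):
        """K/k -> infinity: stationary profile ~ laser profile, L_d -> 0."""
        model = HoppingModel(K=100.0, k=0.1)
        laser = LaserProfile(sigma=169.86, center=200)
        field, _ = stationary_1d(model, laser, 401)
        pos = (np.arange(401) - 200) * model.a
        assert abs(diffusion_length(field, laser, pos)) < 0.5

    def test_monotonic_in_rate_ratio(self):
        """L_d strictly decreases as K/k grows over a log grid."""
        laser = LaserProfile(sigma=169.86, center=500)
        pos = (np.arange(1001) - 500) * 8.0
        lds = []
        for ratio in np.logspace(-3, 0, 7):
            field, _ = stationary_1d(HoppingModel(K=ratio * 0.1, k=0.1), laser, 1001)
            lds.append(diffusion_length(field, laser, pos))
        assert all(a > b for a, b in zip(lds, lds[1:]))

    def test_fwhm_closed_form(self):
        assert laser_fwhm(169.86) == pytest.approx(400.0, abs=0.05)

    def test_zero_field_rejected(self):
        from b850sim.master_eq import ProbabilityField

        f = ProbabilityField(p=np.zeros(5), stationary=True)
        with pytest.raises(ValueError):
            diffusion_length(f, LaserProfile(sigma=1.0), np.arange(5.0))


class TestDimensionalityComparison:
    def test_2d_maxima_lower_and_earlier_than_1d(self):
        """At matched distance from a switched-off Gaussian excitation
        (sigma = 33.97 nm, K = 0.001, k = 0.1), a distant ring's transient
        maximum is lower and peaks earlier on the hexagonal lattice than on
        the chain (more escape channels)."""
        m1 = HoppingModel(K=0.001, k=0.1)
        m2 = HoppingModel(K=0.001, k=0.1, layout="hexagonal")
        sig = 33.97
        n1, ext = 301, 30
        c1 = n1 // 2
        pos = (np.arange(n1) - c1) * 8.0
        p01 = np.exp(-(pos**2) / (2 * sig**2))
        p01 /= p01.sum()
        x, y = hex_positions(ext, 8.0)
        p02 = np.exp(-(x**2 + y**2) / (2 * sig**2))
        p02 /= p02.sum()
        m = 8  # ring eight spacings from the center
        ts = np.linspace(0.0, 250.0, 51)
        tr1 = np.array([dynamics_1d(p01, m1, t).p[c1 + m] for t in ts])
        scale = p01[c1 + m] / p02[ext + m, ext]
        tr2 = np.array(
            [dynamics_2d(p02, m2, t).p[ext + m, ext] * scale for t in ts]
        )
        assert tr2.max() < tr1.max()
        assert ts[np.argmax(tr2)] < ts[np.argmax(tr1)]


class TestOracleConvergence:
    def test_tolerance_tightening_is_converged(self):
        model = HoppingModel(K=0.01, k=0.1)
        laser = LaserProfile(sigma=50.0, center=25)
        y1 = ode_oracle_1d(model, [0.0, 300.0], laser=laser, n_rings=51, rtol=1e-8)
        y2 = ode_oracle_1d(model, [0.0, 300.0], laser=laser, n_rings=51, rtol=1e-11)
        assert np.max(np.abs(y1[-1] - y2[-1])) < 1e-6
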