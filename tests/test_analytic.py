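"""Semi-analytic machinery: substitution rate, waiting times, conditional and
unconditional step distributions, and slow-regime first-step moments."""

import math

import numpy as np
import pytest
from scipy import integrate

import fgmwalk as fw
from fgmwalk import analytic as an
from fgmwalk.model import ModelSpec, ModelSpecError


Y0 = np.zeros(2)


@pytest.fixture(scope="module")
def fig1_wt(fig1_model):
    """Waiting-time distribution of the reference scenario (Gaussian p)."""
    return an.WaitingTime(Y0, fig1_model)


class TestBeneficialSet:
    def test_empty_at_time_zero(self, fig1_model, rng):
        for _ in range(20):
            x = rng.standard_normal(2)
            assert not an.beneficial_set_indicator(x, Y0, 0.0, fig1_model)

    def test_ball_center_is_beneficial(self, fig1_model):
        t = 3e4
        assert an.beneficial_set_indicator(fig1_model.v * t, Y0, t, fig1_model)

    def test_boundary_point_excluded(self, fig1_model):
        t = 3e4
        assert not an.beneficial_set_indicator(2 * fig1_model.v * t, Y0, t,
                                               fig1_model)


class TestSubstitutionRate:
    def test_zero_at_time_zero(self, fig1_model):
        assert an.substitution_rate(0.0, Y0, fig1_model) == 0.0

    def test_uniform_closed_form_one_trait_vs_quadrature_oracle(self):
        # independent oracle: 1-D adaptive quadrature of the rate integrand
        # Theta p0 s_lin(alpha, t) over the beneficial interval (0, 2 v1 t)
        m = ModelSpec.from_params(1, sigma_sq=10.0, v1=1e-5)
        p0 = an.mutation_density_at_zero(m)
        for t in [1e4, 3e4]:
            r = m.v[0] * t

            def integrand(a):
                return p0 * (r * a - 0.5 * a * a) / 10.0

            oracle, _ = integrate.quad(integrand, 0.0, 2 * r, epsrel=1e-12)
            cf = an.substitution_rate(t, [0.0], m, method="uniform_closed_form")
            assert cf == pytest.approx(2 * p0 * r ** 3 / (3 * 10.0), rel=1e-12)
            assert cf == pytest.approx(oracle, rel=1e-6)

    def test_quadrature_matches_closed_form_uniform(self, fig1_model):
        for t in [1e4, 4e4]:
            q = an.substitution_rate(t, Y0, fig1_model, method="quadrature",
                                     density="uniform")
            cf = an.substitution_rate(t, Y0, fig1_model,
                                      method="uniform_closed_form")
            assert q == pytest.approx(cf, rel=1e-10)

    def test_monte_carlo_agrees_with_quadrature(self, fig1_model):
        t = 3e4
        q = an.substitution_rate(t, Y0, fig1_model, method="quadrature")
        mc = an.substitution_rate(t, Y0, fig1_model, method="monte_carlo",
                                  rng=0, n_mc=400_000)
        assert mc == pytest.approx(q, rel=0.01)

    def test_nondecreasing_in_time_from_optimum(self, fig1_model):
        ts = [1e4, 2e4, 3e4, 4e4]
        gs = [an.substitution_rate(t, Y0, fig1_model) for t in ts]
        assert all(a <= b for a, b in zip(gs, gs[1:]))

    def test_closed_form_requires_canonical(self, antagonistic_model):
        with pytest.raises(ModelSpecError):
            an.substitution_rate(1e4, Y0, antagonistic_model,
                                 method="uniform_closed_form")


class TestWaitingTime:
    def test_survival_starts_at_one_and_decreases(self, fig1_wt):
        assert fig1_wt.survival(0.0) == 1.0
        ts = np.linspace(0, fig1_wt.t_max, 50)
        F = fig1_wt.survival(ts)
        assert np.all(np.diff(F) <= 1e-15)
        assert np.all((0 <= F) & (F <= 1))

    def test_density_nonnegative(self, fig1_wt):
        ts = np.linspace(0, fig1_wt.t_max, 50)
        assert np.all(fig1_wt.density(ts) >= 0)

    def test_uniform_survival_closed_form(self, fig1_model):
        # F(t) = exp(-c t^(n+3)) in the slow regime from the optimum
        wt = an.WaitingTime(Y0, fig1_model, density="uniform")
        n, sigma_sq, v1 = 2, 10.0, 1e-5
        p0 = an.mutation_density_at_zero(fig1_model)
        c = p0 * an.unit_ball_volume(n) * v1 ** (n + 2) / (sigma_sq * (n + 2) * (n + 3))
        for t in [1e4, 3e4, 5e4]:
            assert wt.survival(t) == pytest.approx(math.exp(-c * t ** (n + 3)),
                                                   rel=1e-4)

    def test_static_optimum_never_steps(self):
        m = ModelSpec.from_params(2, sigma_sq=10.0, v1=0.0)
        wt = an.WaitingTime(Y0, m)
        assert wt.survival(1e9) == 1.0

    def test_median_matches_simulated_walks(self, fig1_model, fig1_wt):
        # the walk simulator is the oracle for the first-substitution time
        ens = fw.walk_ensemble(fig1_model, 2000, max_steps=1, seed=99)
        emp_med = np.median(ens.first_times)
        med = fig1_wt.median()
        # Monte-Carlo standard error of the median ~ 1/(2 f(med) sqrt(N))
        se = 1.0 / (2.0 * fig1_wt.density(med) * math.sqrt(len(ens.first_times)))
        assert abs(emp_med - med) < 3.0 * se


class TestConditionalStepDensity:
    def test_zero_outside_beneficial_set(self, fig1_model):
        t = 3e4
        assert an.conditional_step_density([-0.5, 0.0], t, Y0, fig1_model) == 0.0

    def test_reflection_symmetry(self, fig1_model):
        t = 3e4
        a = an.conditional_step_density([0.3, 0.1], t, Y0, fig1_model)
        b = an.conditional_step_density([0.3, -0.1], t, Y0, fig1_model)
        assert a == pytest.approx(b, rel=1e-12)
        assert a > 0

    def test_normalizes_to_one(self, fig1_model, fig1_wt):
        t = fig1_wt.median()
        g = an.substitution_rate(t, Y0, fig1_model)
        val, err = integrate.dblquad(
            lambda a2, a1: an.conditional_step_density([a1, a2], t, Y0,
                                                       fig1_model, g=g),
            -1.5, 1.5, -1.5, 1.5, epsabs=1e-6)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_undefined_when_rate_zero(self, fig1_model):
        with pytest.raises(ModelSpecError):
            an.conditional_step_density([0.1, 0.0], 0.0, Y0, fig1_model)


class TestStepDistribution:
    def test_dual_routes_agree_pointwise(self, fig1_model, fig1_wt):
        ax = np.linspace(-1.0, 1.0, 21)
        mesh = np.meshgrid(ax, ax, indexing="ij")
        pts = np.stack([a.ravel() for a in mesh], axis=-1)
        pa = an.phi_pointwise(pts, Y0, fig1_model, fig1_wt, route="psi_f")
        pb = an.phi_pointwise(pts, Y0, fig1_model, fig1_wt, route="lagtime")
        mask = pb > pb.max() * 1e-8
        assert np.max(np.abs(pa[mask] - pb[mask]) / pb[mask]) < 1e-3

    def test_normalizes_to_one(self, fig1_model):
        dist = an.step_distribution(Y0, fig1_model, grid_half_width=1.5,
                                    grid_points=121)
        assert dist.total_mass() == pytest.approx(1.0, abs=1e-3)

    def test_pleiotropic_marginal_centered_at_zero(self, fig1_model):
        dist = an.step_distribution(Y0, fig1_model, grid_half_width=1.5,
                                    grid_points=81)
        assert dist.mean()[1] == pytest.approx(0.0, abs=1e-10)
        assert dist.mean()[0] > 0

    def test_integrate_matches_simulated_first_steps(self, fig1_model):
        from scipy import stats

        dist = an.step_distribution(Y0, fig1_model, grid_half_width=1.5,
                                    grid_points=81)
        ens = fw.walk_ensemble(fig1_model, 2000, max_steps=1, seed=31)
        fs = ens.first_steps
        for axis in range(2):
            se = fs[:, axis].std(ddof=1) / math.sqrt(len(fs))
            assert abs(fs[:, axis].mean() - dist.mean()[axis]) < 3 * se
        # two-sample check on alpha_1: draw from the grid density
        rng = np.random.default_rng(5)
        w = dist.weights / dist.weights.sum()
        idx = rng.choice(len(w), size=2000, p=w)
        jitter = (rng.random(2000) - 0.5) * (dist.points[1, 1] - dist.points[0, 1])
        grid_sample = dist.points[idx, 0] + jitter
        _, pval = stats.ks_2samp(fs[:, 0], grid_sample)
        assert pval > 0.01

    def test_degenerate_static_optimum_rejected(self):
        m = ModelSpec.from_params(2, sigma_sq=10.0, v1=0.0)
        with pytest.raises(ModelSpecError):
            an.step_distribution(Y0, m)


class TestFirstStepMomentsUniform:
    def test_against_brute_force_integration_oracle(self, fig1_model):
        # dense numeric integration of the unconditional step distribution
        # under the flat mutational density, on a (t, alpha) product grid
        mom = an.first_step_moments_uniform(fig1_model)
        wt = an.WaitingTime(Y0, fig1_model, density="uniform")
        t_grid = np.linspace(0.0, wt.t_max, 400)
        F = wt.survival(t_grid)
        p0 = an.mutation_density_at_zero(fig1_model)
        ax = np.linspace(-1.6, 1.6, 161)
        A1, A2 = np.meshgrid(ax, ax, indexing="ij")
        cell = (ax[1] - ax[0]) ** 2
        Si = fig1_model.Sigma_inv
        quad_term = (A1 ** 2 * Si[0, 0] + A2 ** 2 * Si[1, 1])
        m0 = m1 = m2 = mperp = tw = 0.0
        v1 = fig1_model.v[0]
        for t, Ft in zip(t_grid, F):
            s = v1 * t * A1 * Si[0, 0] - 0.5 * quad_term
            s = np.maximum(s, 0.0)
            w = p0 * s * Ft * cell
            tot = w.sum()
            m0 += tot
            m1 += (w * A1).sum()
            m2 += (w * A1 ** 2).sum()
            mperp += (w * A2 ** 2).sum()
            tw += tot * t
        dt = t_grid[1] - t_grid[0]
        m0, m1, m2, mperp, tw = [x * dt for x in (m0, m1, m2, mperp, tw)]
        mean_a1 = m1 / m0
        var_a1 = m2 / m0 - mean_a1 ** 2
        var_perp = mperp / m0
        assert m0 == pytest.approx(1.0, abs=5e-3)
        assert mom.mean_a1 == pytest.approx(mean_a1, rel=5e-3)
        assert mom.var_a1 == pytest.approx(var_a1, rel=2e-2)
        assert mom.var_perp == pytest.approx(var_perp, rel=2e-2)
        assert mom.mean_waiting_time == pytest.approx(tw / m0, rel=5e-3)

    def test_cv_invariant_across_speed(self):
        cvs = [an.first_step_moments_uniform(
            ModelSpec.from_params(2, sigma_sq=10.0, v1=v1)).cv_a1
            for v1 in [1e-6, 1e-5, 1e-4]]
        assert max(cvs) - min(cvs) < 1e-3 * cvs[0]

    def test_cv_differs_across_dimension(self):
        cvs = [an.first_step_moments_uniform(an.canonical_model(n, 1e-4)).cv_a1
               for n in [1, 2, 4]]
        assert cvs[0] > cvs[1] > cvs[2]

    def test_mean_step_increases_with_rate(self):
        means = [an.first_step_moments_uniform(an.canonical_model(2, g)).mean_a1
                 for g in [1e-5, 1e-4, 1e-3]]
        assert means[0] < means[1] < means[2]

    def test_mean_step_increases_with_dimension(self):
        means = [an.first_step_moments_uniform(an.canonical_model(n, 1e-5)).mean_a1
                 for n in [1, 2, 4, 8]]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_perpendicular_mean_is_zero_by_symmetry(self, fig1_model):
        # symmetry of the beneficial ball about the axis of movement
        dist = an.step_distribution(Y0, fig1_model, density="uniform",
                                    grid_half_width=1.5, grid_points=81)
        assert dist.mean()[1] == pytest.approx(0.0, abs=1e-12)

    def test_warns_when_uniform_approximation_degrades(self):
        with pytest.warns(RuntimeWarning):
            an.first_step_moments_uniform(an.canonical_model(2, 0.5))

    def test_requires_canonical_model(self, antagonistic_model):
        with pytest.raises(ModelSpecError):
            an.first_step_moments_uniform(antagonistic_model)

    def test_uniform_approximation_accurate_in_slow_regime(self, fig1_model):
        # Gaussian-p grid mean vs flat-p closed machinery at gamma = 1e-4
        mom = an.first_step_moments_uniform(fig1_model)
        dist = an.step_distribution(Y0, fig1_model, grid_half_width=1.5,
                                    grid_points=81)
        assert dist.mean()[0] == pytest.approx(mom.mean_a1, rel=0.05)
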