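"""Exact and Monte Carlo solutions of the three-endmember mixing model."""

import numpy as np
import pytest

from isoresp.isotopes import CO2Fraction, IsotopeMeasurement
from isoresp.mixing import (
    CarbonSourceMixingModel,
    Endmember,
    EndmemberSet,
    MixingGeometryError,
    NoiseModel,
    monte_carlo_apportion,
    solve_exact,
    total_contributions,
)

NO_NOISE = NoiseModel(sigma_delta13C=0.0, sigma_Delta14C=0.0, perturb_endmembers=False)


def simplex_grid_oracle(measurement, endmembers, step=1e-3):
    """Brute-force grid search over the simplex minimizing the squared
    residual of the two tracer equations — independent of the linear solver."""
    f1 = np.arange(0.0, 1.0 + step / 2, step)
    g1, g2 = np.meshgrid(f1, f1, indexing="ij")
    mask = g1 + g2 <= 1.0 + 1e-12
    g1, g2 = g1[mask], g2[mask]
    g3 = 1.0 - g1 - g2
    sig = endmembers.signatures  # (2, 3)
    pred13 = sig[0, 0] * g1 + sig[0, 1] * g2 + sig[0, 2] * g3
    pred14 = sig[1, 0] * g1 + sig[1, 1] * g2 + sig[1, 2] * g3
    err = (pred13 - measurement.delta13C) ** 2 + (
        (pred14 - measurement.Delta14C) / 50.0
    ) ** 2
    i = int(np.argmin(err))
    return np.array([g1[i], g2[i], g3[i]])


class TestSolveExact:
    def test_vertex(self, exact_endmembers):
        """A measurement on an endmember's signature is pure that endmember."""
        m = IsotopeMeasurement(-20.0, 50.0)
        sol = solve_exact(m, exact_endmembers)
        assert sol.f == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)
        assert sol.in_simplex

    def test_centroid(self, exact_endmembers):
        sig = exact_endmembers.signatures
        m = IsotopeMeasurement(sig[0].mean(), sig[1].mean())
        sol = solve_exact(m, exact_endmembers)
        assert sol.f == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_sum_exactly_one(self, exact_endmembers, rng):
        for _ in range(100):
            m = IsotopeMeasurement(rng.uniform(-45, -10), rng.uniform(-950, 100))
            sol = solve_exact(m, exact_endmembers)
            assert float(np.sum(sol.f)) == 1.0  # exact, by construction

    def test_matches_grid_search_oracle(self, exact_endmembers, rng):
        """100 random in-simplex measurements vs a 1e-3-step simplex grid."""
        sig = exact_endmembers.signatures
        worst = 0.0
        for _ in range(100):
            w = rng.dirichlet([1.0, 1.0, 1.0])
            m = IsotopeMeasurement(float(sig[0] @ w), float(sig[1] @ w))
            sol = solve_exact(m, exact_endmembers)
            oracle = simplex_grid_oracle(m, exact_endmembers)
            worst = max(worst, float(np.max(np.abs(sol.f - oracle))))
            assert sol.f == pytest.approx(w, abs=1e-9)
        assert worst <= 2e-3

    def test_out_of_simplex_unclipped(self, exact_endmembers):
        m = IsotopeMeasurement(-10.0, 300.0)  # outside the triangle
        sol = solve_exact(m, exact_endmembers)
        assert not sol.in_simplex
        assert np.sum(sol.f) == pytest.approx(1.0)
        assert np.any(sol.f < 0) or np.any(sol.f > 1)

    def test_affine_translation_invariance(self, exact_endmembers, rng):
        """Shifting measurement and all signatures by the same offset leaves f unchanged."""
        m = IsotopeMeasurement(-28.0, -300.0)
        base = solve_exact(m, exact_endmembers).f
        for _ in range(10):
            off13, off14 = rng.uniform(-5, 5), rng.uniform(-100, 100)
            shifted_set = EndmemberSet(
                [
                    Endmember(
                        e.name,
                        IsotopeMeasurement(
                            e.signature.delta13C + off13, e.signature.Delta14C + off14
                        ),
                    )
                    for e in exact_endmembers
                ]
            )
            m2 = IsotopeMeasurement(m.delta13C + off13, m.Delta14C + off14)
            assert solve_exact(m2, shifted_set).f == pytest.approx(base, abs=1e-9)

    def test_collinear_endmembers_rejected(self):
        with pytest.raises(MixingGeometryError, match="collinear"):
            EndmemberSet(
                [
                    Endmember("a", IsotopeMeasurement(-20.0, 0.0)),
                    Endmember("b", IsotopeMeasurement(-25.0, -100.0)),
                    Endmember("c", IsotopeMeasurement(-30.0, -200.0)),
                ]
            )


class TestMonteCarloApportion:
    def test_zero_noise_degenerates_to_exact(self, exact_endmembers):
        m = IsotopeMeasurement(-28.0, -300.0)
        exact = solve_exact(m, exact_endmembers)
        app = monte_carlo_apportion(
            m, exact_endmembers, n_draws=500, noise=NO_NOISE, seed=0
        )
        assert app.mean == pytest.approx(exact.f, abs=1e-14)
        assert app.sd == pytest.approx([0.0] * 3, abs=1e-14)
        assert app.simplex_share == 1.0

    def test_every_draw_sums_to_one(self, endmembers):
        from isoresp.mixing import _mc_draws

        m = IsotopeMeasurement(-28.0, -300.0)
        draws, _ = _mc_draws(
            m, endmembers, 2000, NoiseModel(), np.random.default_rng(3)
        )
        assert np.all(draws.sum(axis=1) == 1.0)

    def test_reproducible_with_seed(self, endmembers):
        m = IsotopeMeasurement(-28.0, -300.0)
        a = monte_carlo_apportion(m, endmembers, n_draws=2000, seed=42)
        b = monte_carlo_apportion(m, endmembers, n_draws=2000, seed=42)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.sd, b.sd)
        assert a.simplex_share == b.simplex_share

    def test_unbiased_under_measurement_noise(self, exact_endmembers):
        """Measurement→fraction map is affine, so symmetric noise keeps the mean
        on the exact solution (within Monte Carlo standard error)."""
        m = IsotopeMeasurement(-28.0, -300.0)
        exact = solve_exact(m, exact_endmembers).f
        app = monte_carlo_apportion(
            m,
            exact_endmembers,
            n_draws=100_000,
            noise=NoiseModel(perturb_endmembers=False),
            seed=7,
        )
        se = app.sd / np.sqrt(app.n_draws)
        assert np.all(np.abs(app.mean - exact) < 3 * se + 1e-12)

    def test_sd_scales_linearly_with_measurement_sigma(self, exact_endmembers):
        m = IsotopeMeasurement(-28.0, -300.0)
        sds = []
        for scale in (0.5, 1.0, 2.0):
            app = monte_carlo_apportion(
                m,
                exact_endmembers,
                n_draws=40_000,
                noise=NoiseModel(
                    sigma_delta13C=2.0 * scale,
                    sigma_Delta14C=50.0 * scale,
                    perturb_endmembers=False,
                ),
                seed=11,
            )
            sds.append(app.sd.copy())
        assert sds[1] == pytest.approx(2.0 * sds[0], rel=0.1)
        assert sds[2] == pytest.approx(4.0 * sds[0], rel=0.1)

    def test_simplex_only_mode(self, endmembers):
        m = IsotopeMeasurement(-21.0, 40.0)  # near a vertex: many draws exit
        app = monte_carlo_apportion(m, endmembers, n_draws=5000, seed=1)
        strict = monte_carlo_apportion(
            m, endmembers, n_draws=5000, seed=1, simplex_only=True
        )
        assert 0.0 < app.simplex_share < 1.0
        assert np.sum(strict.mean) == pytest.approx(1.0, abs=1e-9)

    def test_geometry_error_on_huge_endmember_noise(self):
        wide = EndmemberSet(
            [
                Endmember("a", IsotopeMeasurement(-20.0, 50.0, 500.0, 5000.0)),
                Endmember("b", IsotopeMeasurement(-38.0, -250.0, 500.0, 5000.0)),
                Endmember("c", IsotopeMeasurement(-27.0, -900.0, 500.0, 5000.0)),
            ]
        )
        m = IsotopeMeasurement(-28.0, -300.0)
        # enormous endmember scatter makes many perturbed triangles flip/collapse;
        # the rejection guard is not expected to trip at 50% here, but rejections
        # must be counted
        app = monte_carlo_apportion(m, wide, n_draws=2000, seed=5)
        assert app.n_rejected >= 0


def _fractions_from_solutions(endmembers, fs, masses):
    sig = endmembers.signatures
    out = []
    t = 0.0
    for i, (f, mass) in enumerate(zip(fs, masses), start=1):
        f = np.asarray(f)
        out.append(
            CO2Fraction(
                index=i,
                t_start=t,
                t_end=t + 10.0,
                mass_ugC=mass,
                isotopes=IsotopeMeasurement(float(sig[0] @ f), float(sig[1] @ f)),
            )
        )
        t += 10.0
    return out


class TestTotalContributions:
    def test_single_fraction_matches_apportionment(self, exact_endmembers):
        fr = _fractions_from_solutions(exact_endmembers, [(0.5, 0.3, 0.2)], [100.0])
        summ = total_contributions(
            fr, exact_endmembers, n_replicates=200, noise=NO_NOISE, seed=0
        )
        assert summ.percent == pytest.approx([50.0, 30.0, 20.0], abs=1e-9)
        assert summ.percent_sd == pytest.approx([0.0] * 3, abs=1e-12)

    def test_identical_isotopes_weight_invariance(self, exact_endmembers):
        f = (0.4, 0.35, 0.25)
        fr = _fractions_from_solutions(
            exact_endmembers, [f, f, f], [10.0, 500.0, 90.0]
        )
        summ = total_contributions(
            fr, exact_endmembers, n_replicates=100, noise=NO_NOISE, seed=0
        )
        assert summ.percent == pytest.approx([40.0, 35.0, 25.0], abs=1e-9)

    def test_percents_sum_to_100(self, endmembers, rng):
        fs = rng.dirichlet([1, 1, 1], size=4)
        fr = _fractions_from_solutions(endmembers, fs, [100.0, 300.0, 50.0, 80.0])
        summ = total_contributions(fr, endmembers, n_replicates=3000, seed=9)
        assert float(np.sum(summ.percent)) == pytest.approx(100.0, abs=1e-9)

    def test_known_mix_recovered_within_2sd(self, endmembers, rng):
        """Noise-free composite masses: truth within mean ± 2 sd per pool."""
        fs = np.array([[0.6, 0.3, 0.1], [0.3, 0.4, 0.3], [0.1, 0.2, 0.7]])
        masses = [200.0, 300.0, 150.0]
        truth = 100.0 * (np.array(masses) @ fs) / np.sum(masses)
        fr = _fractions_from_solutions(endmembers, fs, masses)
        summ = total_contributions(fr, endmembers, n_replicates=10_000, seed=21)
        assert np.all(np.abs(summ.percent - truth) <= 2.0 * summ.percent_sd)

    def test_empty_list_errors(self, endmembers):
        with pytest.raises(ValueError, match="empty"):
            total_contributions([], endmembers)

    def test_shared_vs_independent_endmember_draws(self, endmembers, rng):
        fs = rng.dirichlet([1, 1, 1], size=3)
        fr = _fractions_from_solutions(endmembers, fs, [100.0, 100.0, 100.0])
        shared = total_contributions(
            fr, endmembers, n_replicates=8000, seed=2, shared_endmember_draws=True
        )
        indep = total_contributions(
            fr, endmembers, n_replicates=8000, seed=2, shared_endmember_draws=False
        )
        # systematic (shared) endmember error cannot average out across fractions,
        # so its aggregate spread is at least as large as the independent scheme's
        assert np.all(shared.percent_sd >= 0.8 * indep.percent_sd)


class TestModelResults:
    def test_fit_summary_and_frames(self, endmembers, rng):
        fs = rng.dirichlet([1, 1, 1], size=3)
        fr = _fractions_from_solutions(endmembers, fs, [120.0, 340.0, 75.0])
        model = CarbonSourceMixingModel(fr, endmembers)
        res = model.fit(n_draws=2000, seed=3)
        assert res.params.shape == (3, 3)
        assert np.allclose(res.params.sum(axis=1), 1.0, atol=1e-9)
        assert (res.bse.to_numpy() >= 0).all()
        text = res.summary()
        assert "share of total respired carbon" in text
        assert "phytoplankton" in text

    def test_fit_reproducible(self, endmembers, rng):
        fs = rng.dirichlet([1, 1, 1], size=2)
        fr = _fractions_from_solutions(endmembers, fs, [100.0, 60.0])
        model = CarbonSourceMixingModel(fr, endmembers)
        a = model.fit(n_draws=1500, seed=8)
        b = model.fit(n_draws=1500, seed=8)
        assert a.params.equals(b.params)
        assert np.array_equal(a.contributions.percent, b.contributions.percent)
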