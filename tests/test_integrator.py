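"""Euler--Maruyama stepping: diffusion machinery, determinism, clamping."""

import dataclasses
import math

import numpy as np
import pytest

from cbvsim import (
    FullState,
    JState,
    RunConfig,
    SpeciesState,
    XState,
    default_params,
    diffusion_terms,
    em_step,
    initial_state,
    reaction_partial,
    reaction_rate,
    run_simulation,
    sample_mutations,
    variance_terms,
    xvar_partials,
)
from cbvsim.biology import MutationDraw
from cbvsim.x_cycle import (
    byproduct_derivatives,
    feedback_flux,
    reservoir_step,
    suppression_alpha,
    x_derivative,
    xvar_flux,
)
from cbvsim.j_cycle import j_derivatives
from cbvsim.biology import fitnesses, growth_rate, performer_count, round_half_away
from cbvsim.params import SPECIES


def central_diff(f, x, h=1e-4):
    return (f(x + h) - f(x - h)) / (2 * h)


class TestReactionPartial:
    def test_matches_finite_difference_in_interior(self, params):
        for J, n in ((0.8, 120.0), (2.0, 500.0), (0.3, 40.0)):
            fd = central_diff(lambda x: reaction_rate(J, x, params), n)
            exact = reaction_partial(J, n, params)
            assert exact == pytest.approx(fd, rel=1e-6)

    def test_zero_above_enhancement_cap(self, params):
        assert reaction_partial(1.0, 1200.0, params) == 0.0

    def test_zero_without_substrate(self, params):
        assert reaction_partial(0.0, 100.0, params) == 0.0


class TestVarianceTerms:
    def test_binomial_arithmetic(self):
        VAR_p, _, _ = variance_terms(0.5, 1000.0, 1.0, 1.0, 1, 1, 0.1, 0.01)
        assert VAR_p == pytest.approx(0.09)

    def test_zero_at_fixation_without_mutation(self):
        for p in (0.0, 1.0):
            VAR_p, VAR_S, VAR_np = variance_terms(p, 1000.0, 1.0, 1.0, 0, 0, 0.0, 0.0)
            assert VAR_p == VAR_S == VAR_np == 0.0

    def test_matches_monte_carlo_variance_of_mutation_draws(self, rng):
        # The analytic binomial variance of the realized mutation fraction
        # must agree with its empirical variance over many draws.
        m0_p, W_p, p = 0.1, 10.0, 0.5   # RE_p = round(10*0.5) = 5 events
        draws = np.array(
            [sample_mutations(W_p, 1.0, p, 0.5, m0_p, 0.0, rng).m_p
             for _ in range(100_000)]
        )
        VAR_p, _, _ = variance_terms(p, 1000.0, W_p, 1.0, 5, 1, m0_p, 0.0)
        assert VAR_p == pytest.approx(draws.var(), rel=0.05)


class TestXvarPartials:
    def test_match_finite_differences(self, params):
        XA, XB = 0.7, 1.3
        dA, dB = xvar_partials(XA, XB, params)
        assert dA == pytest.approx(
            central_diff(lambda x: xvar_flux(x, XB, params), XA), rel=1e-6
        )
        assert dB == pytest.approx(
            central_diff(lambda x: xvar_flux(XA, x, params), XB), rel=1e-6
        )

    def test_scale_with_efficiency(self, params):
        half = dataclasses.replace(params, Xvar0=0.5)
        assert xvar_partials(1.0, 2.0, half)[0] == pytest.approx(
            0.5 * xvar_partials(1.0, 2.0, params)[0]
        )


def _fits_draws(state, params):
    """Fitnesses and zero-mutation draws for a diffusion-terms call."""
    subs = {"A": 0, "B": 1, "C": 0, "D": 2}
    J = (state.J.J1, state.J.J2, state.J.J3)
    fits, draws, n_ps = [], [], []
    for i, sid in enumerate(SPECIES):
        sp = state.species[i]
        fits.append(fitnesses(sp.p, sp.M, J[subs[sid]], params))
        draws.append(MutationDraw(0, 0, 0, 0, 0.0, 0.0))
        n_ps.append(performer_count(sp.p, sp.M))
    return fits, draws, n_ps


class TestDiffusionTerms:
    def test_all_zero_at_fixation_without_mutation(self, params):
        params.m0 = 0.0
        state = initial_state(params, RunConfig(p_init=1.0))
        fits, draws, n_ps = _fits_draws(state, params)
        g = diffusion_terms(state, draws, fits, n_ps, params)
        assert g.g_S == (0.0,) * 4
        assert g.g_J == (0.0,) * 3
        assert g.g_XA == g.g_XB == g.g_Xmain == 0.0

    def test_J3_noise_involves_only_C_and_D(self, params):
        # Give only species A a nonzero performer-count variance: J1 and J2
        # (fed by reaction A) pick up noise, J3 (reactions C, D only) none.
        state = initial_state(params, RunConfig(p_init=1.0))
        state.species[0].p = 0.5
        fits, draws, n_ps = _fits_draws(state, params)
        draws[0] = MutationDraw(1, 1, 1, 1, 0.0, 0.0)  # RE > 0 for A only
        g = diffusion_terms(state, draws, fits, n_ps, params)
        assert g.g_J[0] > 0 and g.g_J[1] > 0
        assert g.g_J[2] == 0.0
        assert g.g_XB == 0.0 and g.g_XA > 0


def reference_single_clock_step(state, params):
    """Independent plain Euler step of the full coupled system (dt = 1,
    deterministic, single shared clock) assembled directly from the
    published derivative forms."""
    J = (state.J.J1, state.J.J2, state.J.J3)
    subs = {"A": 0, "B": 1, "C": 0, "D": 2}
    n_p, R, dM, dp = {}, {}, {}, {}
    for i, sid in enumerate(SPECIES):
        sp = state.species[i]
        n_p[sid] = performer_count(sp.p, sp.M)
        R[sid] = reaction_rate(J[subs[sid]], n_p[sid], params)
        W_p, W_q, W_mean = fitnesses(sp.p, sp.M, J[subs[sid]], params)
        m_p = params.m0 if round_half_away(W_p * sp.p) >= 1 else 0.0
        m_q = params.m0 ** 2 if round_half_away(W_q * sp.q) >= 1 else 0.0
        dp[sid] = (W_p - W_mean) / W_mean - m_p + m_q
        dM[sid] = growth_rate(
            sp.M, params.g0, params.K, alpha=state.alpha, is_C=(sid == "C"),
            square_outside=params.growth_square_outside,
        )
    dJ = j_derivatives(state.J, R["A"], R["B"], R["C"], R["D"], params)
    Xvar = xvar_flux(state.X.XA, state.X.XB, params)
    dXA, dXB = byproduct_derivatives(state.X.XA, state.X.XB, R["A"], R["B"], Xvar, params)
    dXres, dXres2, Xrel = reservoir_step(state.X.Xres, state.X.Xres2, Xvar, params)
    dX = x_derivative(state.X.X, Xrel, feedback_flux(state.X.X, params), params)

    species = [
        SpeciesState(sid, max(state.species[i].M + dM[sid], 0.0),
                     min(max(state.species[i].p + dp[sid], 0.0), 1.0))
        for i, sid in enumerate(SPECIES)
    ]
    Jn = JState(*(max(J[k] + dJ[k], 0.0) for k in range(3)))
    Xn = XState(
        max(state.X.X + dX, 0.0), max(state.X.XA + dXA, 0.0),
        max(state.X.XB + dXB, 0.0), state.X.Xres + dXres,
        max(state.X.Xres2 + dXres2, 0.0),
    )
    return FullState(species, Jn, Xn, suppression_alpha(Xn.X, params), state.t + 1.0)


class TestEmStep:
    def test_deterministic_mode_ignores_seed(self, params):
        params.sigma_bar = 0.0
        state = initial_state(params, RunConfig())
        out1 = em_step(state.copy(), params, np.random.default_rng(1))
        out2 = em_step(state.copy(), params, np.random.default_rng(999))
        out3 = em_step(state.copy(), params, None)
        assert out1 == out2 == out3

    def test_same_seed_same_successor(self, params):
        state = initial_state(params, RunConfig())
        out1 = em_step(state.copy(), params, np.random.default_rng(5))
        out2 = em_step(state.copy(), params, np.random.default_rng(5))
        assert out1 == out2

    def test_unit_timescales_match_single_clock_euler(self, params):
        # With tau_J = tau_X = 1 and no noise the multi-rate stepper must
        # coincide with a plain single-clock Euler step of the full system.
        p = dataclasses.replace(params, tau_J=1.0, tau_X=1.0, sigma_bar=0.0)
        state = initial_state(p, RunConfig(p_init=0.4))
        state.X.XA, state.X.XB = 0.3, 0.2
        for _ in range(20):
            ref = reference_single_clock_step(state, p)
            got = em_step(state, p, None)
            for i in range(4):
                assert got.species[i].M == pytest.approx(ref.species[i].M, abs=1e-12)
                assert got.species[i].p == pytest.approx(ref.species[i].p, abs=1e-12)
            for name in ("J1", "J2", "J3"):
                assert getattr(got.J, name) == pytest.approx(getattr(ref.J, name), abs=1e-12)
            for name in ("X", "XA", "XB", "Xres", "Xres2"):
                assert getattr(got.X, name) == pytest.approx(getattr(ref.X, name), abs=1e-12)
            state = got

    def test_deterministic_drift_scales_linearly_in_dt(self, params):
        params.sigma_bar = 0.0
        state = initial_state(params, RunConfig(p_init=0.4))
        state.X.XA, state.X.XB = 0.3, 0.2
        full = em_step(state.copy(), params, None, dt_bio=1.0)
        half = em_step(state.copy(), params, None, dt_bio=0.5)
        assert half.J.J1 - state.J.J1 == pytest.approx(
            (full.J.J1 - state.J.J1) / 2, rel=1e-12
        )
        assert half.X.X - state.X.X == pytest.approx(
            (full.X.X - state.X.X) / 2, rel=1e-12
        )
        assert half.species[0].M - state.species[0].M == pytest.approx(
            (full.species[0].M - state.species[0].M) / 2, rel=1e-9
        )

    def test_noise_variance_scales_linearly_in_dt(self, params):
        # Euler--Maruyama consistency: halving the step halves the variance
        # of the stochastic increment about the deterministic drift.
        state = initial_state(params, RunConfig(p_init=0.4))
        state.X.XA, state.X.XB = 0.3, 0.2
        det = dataclasses.replace(params, sigma_bar=0.0)
        n = 4000
        var = {}
        for dt in (1.0, 0.5):
            drift = em_step(state.copy(), det, None, dt_bio=dt).J.J1
            rng = np.random.default_rng(42)
            incs = np.array(
                [em_step(state.copy(), params, rng, dt_bio=dt).J.J1 - drift
                 for _ in range(n)]
            )
            var[dt] = incs.var()
        assert var[1.0] / var[0.5] == pytest.approx(2.0, rel=0.1)

    def test_extinction_is_absorbing_and_zeroes_frequencies(self, params):
        # At carrying capacity the growth term vanishes, so a full-strength
        # kill term takes species C to zero in one deterministic step.
        params.sigma_bar = 0.0
        state = initial_state(params, RunConfig())
        state.alpha = 1.0
        out = em_step(state, params, None)
        assert out.species[2].M == 0.0
        assert out.species[2].p == 0.0
        assert out.species[0].M > 0  # other species unaffected
        again = em_step(out, params, None)
        assert again.species[2].M == 0.0 and again.species[2].p == 0.0

    def test_suppression_only_touches_species_C(self, params):
        params.sigma_bar = 0.0
        base = initial_state(params, RunConfig(M_init=500.0))
        no_sup = em_step(base.copy(), params, None)
        sup = base.copy()
        sup.alpha = 0.7
        with_sup = em_step(sup, params, None)
        for i, sid in enumerate(SPECIES):
            if sid == "C":
                assert with_sup.species[i].M < no_sup.species[i].M
            else:
                assert with_sup.species[i].M == no_sup.species[i].M


class TestRunSimulation:
    def test_abiotic_relaxation_to_closed_form(self, params):
        # Genuinely abiotic configuration (no performers, no mutation to
        # create them, no selection excess to re-seed them, no noise): each
        # J-variant relaxes to Fin0/Fout0 = 1 and X to Xin0/Xout0 = 1.
        p = dataclasses.replace(params, sigma_bar=0.0, m0=0.0, s=0.0)
        r = RunConfig(n_bio_steps=400, p_init=0.0, J_init=0.3, X_init=0.2)
        final = run_simulation(p, r).final
        for name in ("J1", "J2", "J3"):
            assert final[name] == pytest.approx(1.0, abs=1e-6)
        assert final["X"] == pytest.approx(1.0, abs=1e-6)
        assert final["alpha"] == 0.0

    def test_record_cadence(self, params):
        r = RunConfig(n_bio_steps=100, record_every=10, seed=1)
        result = run_simulation(params, r)
        assert len(result.data) == 11
        assert list(result.data["t"][:3]) == [0.0, 10.0, 20.0]

    def test_no_byproduct_flux_keeps_suppression_off(self, params):
        p = dataclasses.replace(params, sigma_bar=0.0, Xvar0=0.0)
        result = run_simulation(p, RunConfig(n_bio_steps=500))
        assert (result.data["alpha"] == 0.0).all()
        assert result.data["X"].max() < p.Xsuppress

    def test_state_invariants_along_stochastic_trajectory(self, params):
        data = run_simulation(params, RunConfig(n_bio_steps=1500, seed=11)).data
        for col in ("M_A", "M_B", "M_C", "M_D", "J1", "J2", "J3",
                    "X", "XA", "XB", "Xres", "Xres2"):
            assert (data[col] >= 0).all(), col
        for col in ("p_A", "p_B", "p_C", "p_D"):
            assert data[col].between(0, 1).all(), col
        # The solid reservoir only ever shrinks.
        assert (np.diff(data["Xres"]) <= 1e-12).all()
        # Release stays gated until the reservoir is exhausted.
        before = data[data["Xres"] > 0]
        assert (before["Xres2"].diff().dropna() >= -1e-12).all()

    def test_total_J_conserved_in_closed_configuration(self, params):
        p = dataclasses.replace(
            params, sigma_bar=0.0, eps_X=0.0, Fin0=0.0, Fout0=0.0
        )
        r = RunConfig(n_bio_steps=10_000, J_init=1.0, record_every=100)
        data = run_simulation(p, r).data
        total = data[["J1", "J2", "J3"]].sum(axis=1)
        assert abs(total.iloc[-1] - total.iloc[0]) / total.iloc[0] <= 1e-6

    def test_instability_error_names_step_and_variable(self, params):
        p = dataclasses.replace(params, sigma_bar=0.0, g0=1e308)
        with pytest.raises(FloatingPointError, match="step"):
            run_simulation(p, RunConfig(n_bio_steps=10, M_init=500.0))
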