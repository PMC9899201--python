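"""History construction, delay integration, density and branch scans."""

import math

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.optimize import brentq

from tickdae.behaviours import ModelParams, make_scenario
from tickdae.equilibria import critical_case_limit, solve_reactive
from tickdae.simulator import (
    PositivityError,
    bifurcation_scan,
    density_profile,
    make_history,
    simulate,
)


def _const_params():
    """Small constant-scenario system (tau + T = 22 days) for fast runs."""
    return ModelParams(delta=0.05, tau=20.0, T=2.0, eta=2.0,
                       p=0.05 * math.exp(0.2) / 2.0, mu0=0.1)


class TestMakeHistory:
    def test_zero_engorged_matches_to_zero_feeding(self, quadri):
        hist = make_history(0.0, "matched", quadri.params, quadri.scenario)
        assert np.all(hist.F_hist == 0.0)
        assert hist.matching_residual == 0.0

    def test_equilibrium_history_is_matched(self, quadri):
        eq = [e for e in solve_reactive(quadri.params) if e.branch == "plus_minus"][0]
        hist = make_history(eq.E_star, eq.F_star, quadri.params, quadri.scenario,
                            h=quadri.params.T / 350)
        assert hist.matching_residual < 1e-10

    def test_constant_scenario_closed_form(self):
        """With constant rates the matched feeding level has the closed form
        p eta E0 (1 - e^{-mu0 T}) / mu0."""
        p = _const_params()
        sc = make_scenario("constant", p)
        E0 = 40.0
        hist = make_history(E0, "matched", p, sc, h=p.T / 20)
        expect = p.p * p.eta * E0 * (1.0 - math.exp(-p.mu0 * p.T)) / p.mu0
        assert hist.F_hist[-1] == pytest.approx(expect, rel=1e-7)

    def test_matched_engorged_level(self, quadri):
        """E0 = F0 / (eta rho(F0) Phi(nu(F0), T)) puts the constant pair on
        the matching manifold with the feeding load exactly F0."""
        params, sc = quadri.params, quadri.scenario
        hist = make_history("matched", 10.0, params, sc)
        assert hist.F_hist[-1] == 10.0
        nu = float(sc.nu(10.0))
        phi = (1.0 - math.exp(-nu * params.T)) / nu
        assert hist.E_hist[-1] == pytest.approx(
            10.0 / (params.eta * float(sc.rho(10.0)) * phi), rel=1e-12
        )
        assert hist.matching_residual < 1e-7

    def test_negative_history_rejected(self, quadri):
        with pytest.raises(ValueError):
            make_history(-1.0, 5.0, quadri.params, quadri.scenario)

    def test_step_must_divide_delays(self, quadri):
        with pytest.raises(ValueError, match="divide"):
            make_history(1.0, 1.0, quadri.params, quadri.scenario, h=0.3)


class TestIntegration:
    def test_equilibrium_is_a_fixed_point(self, quadri):
        params, sc = quadri.params, quadri.scenario
        eq = [e for e in solve_reactive(params) if e.branch == "plus_minus"][0]
        hist = make_history(eq.E_star, eq.F_star, params, sc, h=params.T / 10)
        traj = simulate(hist, params, sc, t_end=2 * (params.tau + params.T),
                        h=params.T / 10, equilibria=[])
        assert abs(traj.F[-1] - eq.F_star) / eq.F_star < 1e-9
        assert abs(traj.E[-1] - eq.E_star) / eq.E_star < 1e-9

    def test_zero_history_stays_zero(self, quadri):
        params, sc = quadri.params, quadri.scenario
        hist = make_history(0.0, "matched", params, sc, h=params.T / 10)
        traj = simulate(hist, params, sc, t_end=1500.0, h=params.T / 10)
        assert np.all(traj.E == 0.0) and np.all(traj.F == 0.0)

    @pytest.mark.parametrize("preset_name, F_hi", [("bi", 300.0), ("quadri", 2000.0)])
    def test_positivity_from_random_histories(self, preset_name, F_hi, rng, request):
        """Nonnegative matched histories never leave the positive cone.

        Loads are drawn up to the scenario's plausible range: beyond it the
        matched engorged level explodes (the Ricker attachment rate decays
        exponentially) and the induced growth rate exceeds what an explicit
        scheme can stably resolve at this step — stiff integration is out of
        scope and such runs abort with positivity diagnostics by design.
        """
        preset = request.getfixturevalue(preset_name)
        params, sc = preset.params, preset.scenario
        h = params.T / 10
        for _ in range(50):
            F0 = 10 ** rng.uniform(-1, math.log10(F_hi))
            hist = make_history("matched", F0, params, sc, h=h)
            traj = simulate(hist, params, sc,
                            t_end=2 * (params.tau + params.T), h=h,
                            equilibria=[], residual_every=10 ** 9)
            assert np.all(traj.E >= 0) and np.all(traj.F >= 0)

    def test_subcritical_constant_scenario_decays_to_extinction(self):
        p = _const_params().replace(p=0.01)  # R0 < 1
        sc = make_scenario("constant", p)
        hist = make_history(30.0, "matched", p, sc, h=p.T / 20)
        traj = simulate(hist, p, sc, t_end=100 * (p.tau + p.T), h=p.T / 20)
        assert traj.terminal_state == "converged"
        assert traj.equilibrium.branch == "trivial"
        # envelope decreases over whole life-cycle windows
        w = round((p.tau + p.T) / (p.T / 20))
        peaks = [traj.E[i:i + w].max() for i in range(0, len(traj.E) - w, w)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_subcritical_decay_rate_matches_characteristic_root(self):
        """Terminal exponential decay of E matches the rightmost root of
        lambda = -delta + p eta e^{-mu0 T} e^{-lambda (tau+T)} to 1%."""
        p = _const_params().replace(p=0.01)
        sc = make_scenario("constant", p)
        K = p.p * p.eta * math.exp(-p.mu0 * p.T)
        lam = brentq(lambda x: x + p.delta - K * math.exp(-x * (p.tau + p.T)),
                     -p.delta, 0.0)
        hist = make_history(30.0, "matched", p, sc, h=p.T / 20)
        traj = simulate(hist, p, sc, t_end=40 * (p.tau + p.T), h=p.T / 20,
                        equilibria=[], residual_every=10 ** 9)
        n = len(traj.t)
        i0, i1 = int(0.7 * n), n - 1
        fitted = (math.log(traj.E[i1]) - math.log(traj.E[i0])) / (
            traj.t[i1] - traj.t[i0]
        )
        assert fitted == pytest.approx(lam, rel=0.01)

    def test_critical_constant_scenario_converges_to_Ec(self):
        """At R0 = 1 the engorged series converges to the asymptotic
        constant E_c predicted from the initial history alone."""
        p = _const_params()
        sc = make_scenario("constant", p)
        L = p.tau + p.T
        profile = lambda s: 20.0 + 15.0 * math.sin(math.pi * s / L) ** 2
        h = p.T / 20
        hist = make_history(profile, "matched", p, sc, h=h)
        Ec = critical_case_limit(profile, p)
        traj = simulate(hist, p, sc, t_end=50 * L, h=h, equilibria=[],
                        residual_every=10 ** 9)
        assert traj.E[-1] == pytest.approx(Ec, rel=1e-3)

    def test_constraint_residual_small_and_fourth_order(self, quadri):
        params, sc = quadri.params, quadri.scenario
        res = {}
        for div in (10, 20):
            h = params.T / div
            hist = make_history("matched", 300.0, params, sc, h=h)
            traj = simulate(hist, params, sc, t_end=3 * (params.tau + params.T),
                            h=h, equilibria=[], residual_every=100)
            res[div] = max(traj.constraint_residual)
        assert res[10] < 1e-3
        assert res[10] / res[20] > 8.0

    def test_grid_refinement_convergence(self, request):
        for name in ("bi", "quadri"):
            preset = request.getfixturevalue(name)
            params, sc = preset.params, preset.scenario
            ends = {}
            for div in (10, 20):
                h = params.T / div
                hist = make_history("matched", 120.0, params, sc, h=h)
                traj = simulate(hist, params, sc,
                                t_end=3 * (params.tau + params.T), h=h,
                                equilibria=[], residual_every=10 ** 9)
                ends[div] = traj.F[-1]
            assert abs(ends[10] - ends[20]) / max(abs(ends[20]), 1.0) < 1e-4

    def test_mismatched_step_rejected(self, quadri):
        params, sc = quadri.params, quadri.scenario
        hist = make_history(1.0, 1.0, params, sc, h=params.T / 10)
        with pytest.raises(ValueError, match="match the history"):
            simulate(hist, params, sc, t_end=100.0, h=params.T / 70)


class TestDensityProfile:
    def test_integral_recovers_feeding_total(self, quadri):
        params, sc = quadri.params, quadri.scenario
        hist = make_history("matched", 300.0, params, sc, h=params.T / 70)
        traj = simulate(hist, params, sc, t_end=2 * (params.tau + params.T),
                        h=params.T / 70, equilibria=[], residual_every=10 ** 9)
        for t in (0.0, 700.0, float(traj.t[-1])):
            a, n = density_profile(traj, t)
            i = round(t / traj.h)
            assert simpson(n, x=a) == pytest.approx(traj.F[i], rel=1e-6)

    def test_boundary_value_is_attachment_flux(self, quadri):
        params, sc = quadri.params, quadri.scenario
        hist = make_history("matched", 300.0, params, sc, h=params.T / 70)
        traj = simulate(hist, params, sc, t_end=1000.0, h=params.T / 70,
                        equilibria=[], residual_every=10 ** 9)
        t = 700.0
        i = round(t / traj.h)
        a, n = density_profile(traj, t)
        assert n[0] == pytest.approx(
            float(sc.rho(traj.F[i])) * traj.Q[i], rel=1e-12
        )

    def test_constant_scenario_exponential_profile(self):
        """At the critical constant-rate steady state the density is
        n(a) = p eta E* e^{-mu0 a}."""
        p = _const_params()
        sc = make_scenario("constant", p)
        E0 = 25.0
        hist = make_history(E0, "matched", p, sc, h=p.T / 40)
        traj = simulate(hist, p, sc, t_end=3 * (p.tau + p.T), h=p.T / 40,
                        equilibria=[], residual_every=10 ** 9)
        a, n = density_profile(traj, float(traj.t[-1]))
        expect = p.p * p.eta * E0 * np.exp(-p.mu0 * a)
        assert np.allclose(n, expect, rtol=1e-6)

    def test_time_outside_range_rejected(self, quadri):
        params, sc = quadri.params, quadri.scenario
        hist = make_history("matched", 10.0, params, sc, h=params.T / 10)
        traj = simulate(hist, params, sc, t_end=100.0, h=params.T / 10,
                        equilibria=[], residual_every=10 ** 9)
        with pytest.raises(ValueError, match="outside"):
            density_profile(traj, 1e6)


class TestBifurcationScan:
    def test_bi_fold_in_feeding_duration(self, bi):
        df = bifurcation_scan(bi.params, "ricker_linear", "T",
                              np.linspace(6.0, 12.0, 13))
        fold = df.attrs["fold"]
        # independent tangency root: delta (eta p)^-1 e^{mu0 T} = (e (1/c + mu T))^-1
        p = bi.params
        gap = lambda T: 1.0 / (math.e * (1.0 / p.c + p.mu * T)) - p.delta / (
            p.eta * p.p
        ) * math.exp(p.mu0 * T)
        assert fold == pytest.approx(brentq(gap, 6.0, 12.0, rtol=1e-13), rel=1e-10)
        below = df[df["T"] < fold].groupby("T").size()
        above = df[df["T"] > fold].groupby("T").size()
        assert set(below) == {3} and set(above) == {1}

    def test_branch_counts_change_only_at_fold(self, quadri):
        df = bifurcation_scan(quadri.params, "holling3_reactive", "delta",
                              np.linspace(0.05, 0.4, 15))
        fold = df.attrs["fold"]
        counts = df.groupby("delta").size()
        for value, cnt in counts.items():
            # below the fold 2 or 4 positive equilibria (the upper attachment
            # root may exceed the Holling maximum r j/2); above it, none
            assert (cnt == 1) == (value > fold)
            assert cnt in (1, 3, 5)
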