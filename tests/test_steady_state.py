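"""Closed-form equilibria, characteristic roots and recovery times."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import thermniche as tn
from thermniche.responses import ArrheniusParams, GaussianParams, SchoolfieldParams
from thermniche.steady_state import characteristic_roots, count_characteristic_roots


def dd_model(traits, comp, t_kelvin):
    return tn.ModelSpec(traits, tn.TemperatureForcing.constant(t_kelvin), comp)


class TestEquilibrium:
    def test_nonviable_below_replacement(self, harlequin, harlequin_niche):
        comp = tn.monotonic_mortality_competition(harlequin)
        eq = tn.equilibrium(dd_model(harlequin, comp, harlequin_niche.t_min - 0.5))
        assert not eq.viable
        assert eq.adults_star == 0.0
        assert eq.juveniles_star == 0.0

    def test_continuity_at_replacement_boundary(self, harlequin, harlequin_niche):
        # A* -> 0 as T approaches the niche edge from inside, for both forms
        for comp in (
            tn.monotonic_mortality_competition(harlequin),
            tn.unimodal_fecundity_competition(harlequin),
        ):
            eq = tn.equilibrium(dd_model(harlequin, comp, harlequin_niche.t_max - 1e-4))
            assert eq.viable
            assert eq.adults_star < 0.1

    def test_juvenile_dd_not_implemented(self, harlequin):
        comp = tn.CompetitionSpec(
            "juvenile_mortality", "monotonic",
            monotonic_params=ArrheniusParams(0.1, 6000.0, 297.0),
        )
        with pytest.raises(NotImplementedError):
            tn.equilibrium(dd_model(harlequin, comp, 297.0))

    def test_di_model_has_no_equilibrium(self, harlequin):
        with pytest.raises(ValueError):
            tn.equilibrium(tn.ModelSpec(harlequin, tn.TemperatureForcing.constant(297.0)))


class TestCharacteristicRoots:
    def test_no_delayed_term_gives_minus_a(self):
        roots = characteristic_roots(0.3, 0.0, 20.0)
        assert roots == [complex(-0.3, 0.0)]

    @given(
        a=st.floats(0.01, 1.0),
        c=st.floats(-1.0, 1.0),
        tau=st.floats(1.0, 100.0),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_residuals_below_tolerance(self, a, c, tau):
        scale = abs(a) + abs(c)
        for lam in characteristic_roots(a, c, tau):
            assert abs(lam + a - c * cmath.exp(-lam * tau)) < 1e-10 * scale

    @pytest.mark.parametrize(
        "a, c, tau", [(0.3, -0.1, 20.0), (0.05, 0.04, 50.0), (0.4, -0.35, 15.0)]
    )
    def test_argument_principle_agrees_with_branch_scan(self, a, c, tau):
        roots = characteristic_roots(a, c, tau, n_branches=12)
        re0, re1 = -a - 0.5, 5 * a + abs(c) + 1.0
        im = 8 * math.pi / tau
        inside = [
            z for z in roots if re0 < z.real < re1 and -im < z.imag < im
        ]
        count = count_characteristic_roots(a, c, tau, (re0, re1), (-im, im), n=8000)
        assert count == len(inside)

    def test_vanishing_delay_coupling_boundary(self, harlequin, harlequin_niche):
        # DD fecundity: c = d_A (1 - ln(b S_J / d_A)) crosses 0 where the
        # log replacement ratio equals 1; there lambda = -d_A exactly and
        # the recovery time is 1/d_A
        comp = tn.unimodal_fecundity_competition(harlequin)

        def log_replacement_minus_one(t):
            tau = harlequin.stage_duration(t)
            s = harlequin.juvenile_survivorship(t)
            return (
                math.log(harlequin.birth_rate(t) * s / harlequin.adult_mortality_rate(t))
                - 1.0
            )

        t_c = brentq(
            log_replacement_minus_one,
            harlequin_niche.t_min + 0.01,
            harlequin_niche.t_opt_r,
            xtol=1e-12,
        )
        model = dd_model(harlequin, comp, t_c)
        st_res = tn.dominant_eigenvalue(model, tn.equilibrium(model))
        d_a = harlequin.adult_mortality_rate(t_c)
        assert st_res.dominant_eigenvalue == pytest.approx(-d_a, rel=1e-6)
        assert st_res.recovery_time == pytest.approx(1.0 / d_a, rel=1e-6)


class TestStability:
    @pytest.mark.parametrize("species_name", ["bagrada", "harlequin"])
    def test_stable_at_envelope_optimum(self, species_name, request):
        traits = request.getfixturevalue(species_name)
        met = tn.niche_metrics(traits)
        comp = tn.monotonic_mortality_competition(traits)
        model = dd_model(traits, comp, met.t_opt_r)
        grid = np.arange(met.t_min + 0.1, met.t_max, 0.2)
        env = tn.dd_envelope(model, grid)
        eq = tn.equilibrium(model, env.t_best)
        st_res = tn.dominant_eigenvalue(model, eq)
        assert st_res.stable
        assert st_res.recovery_time > 0
        assert st_res.residual < 1e-10 * 1.0

    def test_perturbation_decay_matches_eigenvalue(self, harlequin):
        # simulation oracle: a 10% perturbation decays at rate -Re(lambda)
        comp = tn.monotonic_mortality_competition(harlequin)
        t = 296.7
        model = dd_model(harlequin, comp, t)
        eq = tn.equilibrium(model)
        st_res = tn.dominant_eigenvalue(model, eq)
        lam = st_res.dominant_eigenvalue
        traj = tn.simulate(
            model,
            initial_adults=1.1 * eq.adults_star,
            initial_juveniles=eq.juveniles_star,
            horizon=700.0,
            record_every=20,
        )
        dev = np.abs(traj.adults - eq.adults_star)
        mask = (traj.times > 250.0) & (dev > 0)
        rate = np.polyfit(traj.times[mask], np.log(dev[mask]), 1)[0]
        assert rate == pytest.approx(lam.real, rel=0.05)


class TestRecoveryCurve:
    def test_time_unit_rescaling_leaves_argmin_in_place(self, harlequin, harlequin_niche):
        # measuring rates per half-day doubles every rate and lambda and
        # halves every recovery time, but cannot move the argmin
        k = 2.0
        scaled = tn.SpeciesTraits(
            name="harlequin_halfday",
            birth=GaussianParams(
                k * harlequin.birth.peak, harlequin.birth.t_opt, harlequin.birth.breadth
            ),
            maturation=SchoolfieldParams(
                k * harlequin.maturation.value_at_ref,
                harlequin.maturation.arrhenius,
                harlequin.maturation.t_ref,
                harlequin.maturation.a_low,
                harlequin.maturation.t_half_low,
                harlequin.maturation.a_high,
                harlequin.maturation.t_half_high,
            ),
            juvenile_mortality=ArrheniusParams(
                k * harlequin.juvenile_mortality.value_at_ref,
                harlequin.juvenile_mortality.arrhenius,
                297.0,
            ),
            adult_mortality=ArrheniusParams(
                k * harlequin.adult_mortality.value_at_ref,
                harlequin.adult_mortality.arrhenius,
                297.0,
            ),
        )
        grid = np.arange(harlequin_niche.t_min + 0.2, harlequin_niche.t_max - 0.1, 0.2)
        rec = tn.recovery_curve(
            dd_model(harlequin, tn.monotonic_mortality_competition(harlequin), 297.0), grid
        )
        rec_scaled = tn.recovery_curve(
            dd_model(scaled, tn.monotonic_mortality_competition(scaled), 297.0), grid
        )
        assert rec_scaled.t_best == pytest.approx(rec.t_best, abs=0.02)
        assert rec_scaled.value_best == pytest.approx(rec.value_best / k, rel=1e-6)

    @pytest.mark.parametrize("species_name", ["bagrada", "harlequin", "generic"])
    def test_ordering_chain_under_dd_mortality(self, species_name, request):
        # steady-state abundance peaks at the cool end of the niche, the
        # fastest perturbation response at the warm end, straddling Topt_r
        traits = request.getfixturevalue(species_name)
        met = tn.niche_metrics(traits)
        comp = tn.monotonic_mortality_competition(traits)
        model = dd_model(traits, comp, met.t_opt_r)
        grid = np.arange(met.t_min + 0.1, met.t_max - 0.05, 0.2)
        env = tn.dd_envelope(model, grid)
        rec = tn.recovery_curve(model, grid)
        assert env.t_best < met.t_opt_r < rec.t_best

    def test_fecundity_dd_abundance_also_peaks_below_growth_optimum(
        self, bagrada, harlequin
    ):
        for traits in (bagrada, harlequin):
            met = tn.niche_metrics(traits)
            comp = tn.unimodal_fecundity_competition(traits)
            model = dd_model(traits, comp, met.t_opt_r)
            grid = np.arange(met.t_min + 0.1, met.t_max - 0.05, 0.2)
            env = tn.dd_envelope(model, grid)
            assert env.t_best < met.t_opt_r
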