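"""ODE assembly, steady-state solver and transient-simulation tests."""

import numpy as np
import pytest

from nvulnaa.forcing import PlasmaForcing, preset_case
from nvulnaa.params import Compartment, Species
from nvulnaa.simulate import (
    MINUTES_PER_DAY,
    NVUState,
    brain_average,
    membrane_fluxes,
    physiologic_baseline,
    reference_initial_state,
    residual,
    simulate,
    solve_steady_state,
    state_derivative,
)

MBEC, ISF, AST, NEU = (
    Compartment.MBEC,
    Compartment.ISF,
    Compartment.AST,
    Compartment.NEU,
)
PHE, CL = Species.PHE, Species.CL


class TestStateDerivative:
    def test_zero_at_solved_steady_state(self, baseline, physiologic_forcing, params):
        assert residual(baseline, physiologic_forcing, params) < 1e-6

    def test_zero_state_is_fixed_point(self, physiologic_forcing, params):
        """Empty brain: obligatory antiport has no counter-substrate and the
        symporter has no substrate, so nothing moves despite full plasma."""
        x = NVUState(np.zeros((4, 2)))
        dx = state_derivative(0.0, x, physiologic_forcing, params)
        assert np.all(dx == 0.0)

    def test_volume_doubling_halves_derivatives(self, physiologic_forcing, params):
        x = reference_initial_state()
        doubled = params.perturbed({k: 2.0 for k in ("V_MBEC", "V_ISF", "V_Ast", "V_Neu")})
        dx = state_derivative(0.0, x, physiologic_forcing, params)
        dx2 = state_derivative(0.0, x, physiologic_forcing, doubled)
        np.testing.assert_allclose(dx2, dx / 2.0, rtol=1e-12)

    def test_negative_state_rejected(self, physiologic_forcing, params):
        x = NVUState(np.full((4, 2), -1.0))
        with pytest.raises(ValueError, match="non-negative"):
            state_derivative(0.0, x, physiologic_forcing, params)

    def test_antiport_conserves_compartment_totals(self, params):
        """1:1 exchange: MBEC and Ast Phe+CL rates each sum to zero, and the
        ISF/Neu amounts change only through the two coupled carriers."""
        x = NVUState(np.array([[100.0, 150.0], [2.0, 1.0], [9.0, 40.0], [6.0, 50.0]]))
        f = PlasmaForcing(phe_ss=1600.0, cf=0.0)
        dx = state_derivative(0.0, x, f, params)
        assert dx[0].sum() == pytest.approx(0.0, abs=1e-12)
        amounts = dx * np.array([[3.5], [352.6], [742.0], [441.7]])
        # ISF + Ast + Neu totals only change via the abluminal LAT1 exchange,
        # which itself sums to zero across species
        assert amounts[1:].sum() == pytest.approx(0.0, abs=1e-9)


class TestSteadyState:
    def test_physiologic_steady_state_near_reference(self, baseline):
        """Relaxation from the literature initial state: the endothelial and
        astrocytic compartments barely move, while the neuron redistributes
        some Phe to the ISF within its conserved ISF+Neu amount."""
        ref = reference_initial_state().as_array()
        got = baseline.as_array()
        for i in (0, 2):
            np.testing.assert_allclose(got[i], ref[i], rtol=0.01)
        assert 4.0 < got[3, 0] < ref[3, 0]  # neuronal Phe settles lower
        np.testing.assert_allclose(got[3, 1], ref[3, 1], rtol=0.01)
        # the exchange stoichiometry conserves the summed ISF+Neu amount
        amt = lambda arr: 352.6 * arr[1].sum() + 441.7 * arr[3].sum()
        assert amt(got) == pytest.approx(amt(ref), rel=1e-4)

    def test_flux_balance_at_steady_state(self, baseline, physiologic_forcing, params):
        fl = membrane_fluxes(baseline, physiologic_forcing, params)
        lum, abl = fl["lat1_luminal"], fl["lat1_abluminal"]
        j2, jb = fl["lat2"], fl["b0at2"]
        tol = 1e-9  # umol/min, consistent with the 1e-6 uM/min residual
        assert lum.phe == pytest.approx(abl.phe, abs=tol)
        assert abl.phe == pytest.approx(j2.phe + jb.phe, abs=tol)
        assert j2.phe == pytest.approx(0.0, abs=tol)
        assert jb.phe == pytest.approx(0.0, abs=tol)

    def test_requires_constant_forcing(self, params):
        with pytest.raises(ValueError, match="cf"):
            solve_steady_state(preset_case("c2"), params)

    def test_rejects_explicit_method(self, physiologic_forcing, params):
        with pytest.raises(ValueError, match="stiff"):
            solve_steady_state(physiologic_forcing, params, method="RK45")

    def test_monotone_in_plasma_phe(self, steady_states_vs_plasma_phe):
        """Raising plasma Phe raises tissue Phe and depresses tissue CL."""
        levels = sorted(steady_states_vs_plasma_phe)
        for comp in (MBEC, AST, NEU):
            phe = [steady_states_vs_plasma_phe[l][comp, PHE] for l in levels]
            cl = [steady_states_vs_plasma_phe[l][comp, CL] for l in levels]
            assert phe == sorted(phe)
            assert cl == sorted(cl, reverse=True)

    def test_compartment_ordering(self, steady_states_vs_plasma_phe):
        """Endothelium accumulates far more Phe than parenchyma; ISF is lowest."""
        for ss in steady_states_vs_plasma_phe.values():
            assert ss[MBEC, PHE] > 4 * ss[AST, PHE]
            assert ss[AST, PHE] > ss[ISF, PHE]
            assert ss[NEU, PHE] > ss[ISF, PHE]

    def test_physiologic_baseline_helper(self, baseline, params):
        np.testing.assert_allclose(
            physiologic_baseline(params).as_array(), baseline.as_array(), rtol=1e-8
        )


class TestBrainAverage:
    def test_volume_weighted_oracle(self, params):
        x = reference_initial_state()
        vols = np.array([3.5, 352.6, 742.0, 441.7])
        oracle = vols @ x.as_array() / vols.sum()
        got = brain_average(x, params)
        assert got[PHE] == pytest.approx(oracle[0], rel=1e-12)
        assert got[CL] == pytest.approx(oracle[1], rel=1e-12)
        # parenchyma dominates the volume: average tracks Ast/Neu, not MBEC
        assert 4.0 < got[PHE] < 7.0

    def test_homogeneity(self, params):
        x = reference_initial_state()
        x3 = NVUState(3.0 * x.as_array())
        assert brain_average(x3, params)[PHE] == pytest.approx(
            3.0 * brain_average(x, params)[PHE], rel=1e-12
        )


class TestSimulate:
    def test_constant_forcing_stays_at_steady_state(
        self, baseline, physiologic_forcing, params
    ):
        traj = simulate(physiologic_forcing, params, span_days=2.0,
                        output_step_days=0.05, x0=baseline)
        dev = np.abs(traj.conc - baseline.as_array()[None])
        assert dev.max() < 1e-4  # uM

    def test_output_grid(self, baseline, physiologic_forcing, params):
        traj = simulate(physiologic_forcing, params, span_days=0.35,
                        output_step_days=0.1, x0=baseline)
        np.testing.assert_allclose(traj.times_days, [0.0, 0.1, 0.2, 0.3])
        assert traj.conc.shape == (4, 4, 2)

    def test_rejects_explicit_method(self, params):
        with pytest.raises(ValueError, match="stiff"):
            simulate(preset_case("c2"), params, span_days=1.0, method="RK45")

    def test_periodic_attractor(self, params):
        """After the transition, the response repeats with the forcing period."""
        f = preset_case("c2")  # period 1/3 day
        step = 1.0 / 300.0
        traj = simulate(f, params, span_days=3.0, output_step_days=step)
        last = traj.conc[-101:-1]
        prev = traj.conc[-201:-101]
        scale = np.maximum(np.abs(traj.conc).max(axis=0), 1e-3)
        assert np.max(np.abs(last - prev) / scale) < 1e-4

    def test_amplitude_linearity_for_small_cf(self, params):
        """Doubling a small fluctuation amplitude doubles the response."""
        base = preset_case("c2")
        ss = solve_steady_state(PlasmaForcing(phe_ss=base.phe_ss, cf=0.0), params)
        devs = {}
        for cf in (0.01, 0.02):
            f = PlasmaForcing(phe_ss=base.phe_ss, cf=cf, shape=base.shape)
            traj = simulate(f, params, span_days=1.0, output_step_days=0.005, x0=ss)
            mask = traj.post_transition
            devs[cf] = traj.conc[mask] - ss.as_array()[None]
        num = float(np.abs(devs[0.02]).max())
        den = float(np.abs(devs[0.01]).max())
        assert num / den == pytest.approx(2.0, rel=0.03)

    def test_solver_independence(self, params):
        f = preset_case("c2")
        kw = dict(span_days=1.0, output_step_days=0.01)
        a = simulate(f, params, method="LSODA", **kw)
        b = simulate(f, params, method="Radau", **kw)
        np.testing.assert_allclose(a.conc, b.conc, rtol=1e-3, atol=1e-4)

    def test_transition_default_is_one_period(self, params):
        f = preset_case("c2")
        traj = simulate(f, params, span_days=1.0, output_step_days=0.01)
        assert traj.transition_days == pytest.approx(f.period_days)

    def test_percent_of_baseline_and_frame(self, baseline, physiologic_forcing, params):
        traj = simulate(physiologic_forcing, params, span_days=0.2,
                        output_step_days=0.1, x0=baseline, baseline=baseline)
        pct = traj.percent_of_baseline()
        np.testing.assert_allclose(pct, 100.0, rtol=1e-4)
        df = traj.to_frame()
        assert list(df.columns) == [
            "time_day", "compartment", "species", "conc_uM", "pct_baseline"
        ]
        assert len(df) == 3 * 8

    def test_missing_baseline_raises(self, baseline, physiologic_forcing, params):
        traj = simulate(physiologic_forcing, params, span_days=0.2,
                        output_step_days=0.1, x0=baseline)
        with pytest.raises(ValueError, match="baseline"):
            traj.percent_of_baseline()


class TestExchangeConservation:
    def test_totals_conserved_along_trajectory(self, params):
        """Phe+CL totals of MBEC and Ast, and the summed ISF+Neu amount, are
        invariants of the carrier stoichiometry and survive integration."""
        f = preset_case("c2")
        traj = simulate(f, params, span_days=1.0, output_step_days=0.01)
        totals_mbec = traj.conc[:, 0].sum(axis=1)
        totals_ast = traj.conc[:, 2].sum(axis=1)
        amounts = (traj.conc * np.array([[3.5], [352.6], [742.0], [441.7]])).sum(
            axis=(1, 2)
        ) - (traj.conc[:, 0].sum(axis=1) * 3.5 + traj.conc[:, 2].sum(axis=1) * 742.0)
        for series in (totals_mbec, totals_ast, amounts):
            assert np.ptp(series) / series[0] < 1e-5
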