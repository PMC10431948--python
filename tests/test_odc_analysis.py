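"""ODC construction, Adair/Hill analysis, crossovers and cooperativity gain."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbodc.kinetic_schemes import ConfigurationError, MWCParams, RateParams, build_minimalist
from hbodc.odc_analysis import (
    DEFAULT_O2_GRID,
    AdairConstants,
    ODCCurve,
    allosteric_ladder,
    cooperativity_gain,
    crossover_kd,
    equilibrium_odc,
    equilibrium_saturation,
    fit_adair,
    fractional_saturation,
    half_saturation,
    hill_slope_at_half,
    hill_transform,
)
from hbodc.protocol_sim import Protocol, SpeciesTrajectory, simulate
from hbodc.synthetic_data import NOMINAL_CONSTANTS, nominal_protocol, nominal_scheme

MIN_K = NOMINAL_CONSTANTS["minimalist"]["K"]


def hyperbola_odc(kd=10.0, grid=None):
    g = DEFAULT_O2_GRID if grid is None else grid
    return ODCCurve(g, g / (g + kd), np.full(len(g), "deox"))


class TestFractionalSaturation:
    def _traj(self, conc_by_name, scheme=None):
        scheme = scheme or nominal_scheme("minimalist", with_ensemble=False)
        t = np.arange(3.0)
        conc = np.zeros((3, len(scheme.species)))
        for nm, v in conc_by_name.items():
            conc[:, scheme.index(nm)] = v
        proto = Protocol(t_grid=t, t_respiration_on=0.0, t_open=2.0)
        return SpeciesTrajectory(t, conc, scheme, proto)

    def test_fully_liganded_gives_unit_saturation(self):
        traj = self._traj({"HbO2_4": 5.0, "O": 100.0})
        assert np.allclose(fractional_saturation(traj).saturation, 1.0)

    def test_equimolar_deoxy_and_fully_liganded_gives_half(self):
        traj = self._traj({"Hb": 5.0, "HbO2_4": 5.0, "O": 50.0})
        assert np.allclose(fractional_saturation(traj).saturation, 0.5)

    def test_zero_hemoglobin_rejected(self):
        traj = self._traj({"O": 50.0})
        with pytest.raises(ConfigurationError):
            fractional_saturation(traj)

    def test_mwc_pooled_equals_per_state_sum(self, traj_mwc):
        odc = fractional_saturation(traj_mwc)
        lig = {s.name: s.ligation for s in traj_mwc.scheme.hemoglobin_species}
        bound = sum(n * traj_mwc.conc(nm) for nm, n in lig.items())
        total = sum(traj_mwc.conc(nm) for nm in lig)
        assert np.allclose(odc.saturation, bound / (4 * total), atol=1e-12)


class TestEquilibriumSaturation:
    def test_zero_oxygen_gives_zero(self):
        assert equilibrium_saturation(AdairConstants.equal(MIN_K), 0.0) == 0.0
        assert equilibrium_saturation(MWCParams(L=500, KT=0.02, KR=0.2), 0.0) == 0.0

    def test_equal_constant_curve_half_saturated_at_inverse_K(self):
        s = equilibrium_saturation(AdairConstants.equal(MIN_K), 1.0 / MIN_K)
        assert s == pytest.approx(0.5, abs=1e-12)  # (1+2+3+4)/(4*5)

    def test_mwc_c_equal_one_reduces_to_single_chain(self):
        x = np.linspace(0.1, 400, 50)
        mwc = MWCParams(L=504.6, KT=MIN_K, KR=MIN_K)
        assert np.allclose(
            equilibrium_saturation(mwc, x),
            equilibrium_saturation(AdairConstants.equal(MIN_K), x),
            atol=1e-12,
        )


class TestHalfSaturation:
    def test_hyperbola(self):
        f = lambda x: x / (x + 26.0)
        x50, p50 = half_saturation(f)
        assert x50 == pytest.approx(26.0, abs=1e-5)
        assert p50 == pytest.approx(26.0 / 1.223, rel=1e-6)

    def test_minimalist_equal_K(self):
        x50, _ = half_saturation(AdairConstants.equal(MIN_K).saturation)
        assert x50 == pytest.approx(1.0 / MIN_K, rel=1e-6)

    def test_mwc_against_grid_scan_oracle(self):
        mwc = MWCParams(L=504.6, KT=0.0191, KR=0.1787)
        x50, _ = half_saturation(lambda x: equilibrium_saturation(mwc, x))
        grid = np.arange(0.01, 200.0, 0.01)
        s = equilibrium_saturation(mwc, grid)
        x50_scan = grid[np.argmin(np.abs(s - 0.5))]
        assert x50 == pytest.approx(x50_scan, abs=0.01)

    def test_unbracketed_curve_rejected(self):
        with pytest.raises(ConfigurationError):
            half_saturation(lambda x: 0.1 * np.tanh(x / 1e5))


class TestFitAdair:
    def test_known_constants_recovered(self):
        truth = AdairConstants(0.0368, 0.0002, 2.2237, 0.1730)
        grid = np.concatenate([np.linspace(0.2, 30, 60), np.linspace(31, 183, 60)])
        odc = ODCCurve(grid, equilibrium_saturation(truth, grid), np.full(len(grid), "deox"))
        est = fit_adair(odc)
        assert np.allclose(est.as_array, truth.as_array, rtol=0.01)

    def test_equal_constant_collapse(self):
        odc = equilibrium_odc(AdairConstants.equal(MIN_K))
        est = fit_adair(odc)
        spread = est.as_array.max() / est.as_array.min() - 1
        assert spread < 0.01
        assert est.K1 == pytest.approx(MIN_K, rel=0.01)

    def test_hyperbolic_input_yields_statistical_ratios(self):
        kd = 10.0
        est = fit_adair(hyperbola_odc(kd))
        ratios = est.as_array * kd  # per-site K = 1/kd
        assert np.allclose(ratios, [4.0, 1.5, 2.0 / 3.0, 0.25], rtol=1e-3)

    def test_round_trip_identity_on_constants(self):
        truth = AdairConstants(0.02, 0.05, 0.4, 4.0)
        odc = equilibrium_odc(truth)
        est = fit_adair(odc)
        assert np.allclose(est.as_array, truth.as_array, rtol=0.01)

    def test_non_spanning_data_rejected(self):
        grid = np.linspace(0.1, 5.0, 30)  # saturation never approaches 1
        odc = ODCCurve(grid, equilibrium_saturation(AdairConstants.equal(0.01), grid),
                       np.full(len(grid), "deox"))
        with pytest.raises(ConfigurationError):
            fit_adair(odc)


class TestHill:
    def test_hyperbola_slope_is_one(self):
        assert hill_slope_at_half(hill_transform(hyperbola_odc())) == pytest.approx(1.0, abs=1e-9)

    def test_minimalist_curve_is_cooperative(self):
        odc = equilibrium_odc(AdairConstants.equal(MIN_K))
        n_h = hill_slope_at_half(hill_transform(odc))
        assert n_h > 1.5

    def test_mask_excludes_saturation_bounds(self):
        grid = np.array([0.0, 1.0, 10.0, 1e5])
        s = np.array([0.0, 0.3, 0.7, 1.0])
        hp = hill_transform(ODCCurve(grid, s, np.full(4, "deox")))
        assert list(hp.mask) == [False, True, True, False]
        assert np.all(np.isfinite(hp.y[hp.mask]))

    def test_too_few_points_near_half_rejected(self):
        grid = np.array([0.1, 1e4])
        s = np.array([0.01, 0.99])
        with pytest.raises(ConfigurationError):
            hill_slope_at_half(hill_transform(ODCCurve(grid, s, np.full(2, "deox"))))


class TestCrossover:
    def test_constructed_crossing_recovered_exactly(self):
        scheme = nominal_scheme("minimalist", with_ensemble=False)
        t = np.arange(0.0, 11.0)
        conc = np.zeros((len(t), len(scheme.species)))
        conc[:, scheme.index("Hb")] = 10.0 - t  # falls
        conc[:, scheme.index("HbO2_1")] = t  # rises; cross at t=5
        conc[:, scheme.index("O")] = 100.0 - 2.0 * t
        proto = Protocol(t_grid=t, t_respiration_on=0.0, t_open=10.0)
        traj = SpeciesTrajectory(t, conc, scheme, proto)
        res = crossover_kd(traj, "all")
        (c,) = res.crossings["deox"]
        assert c.time == pytest.approx(5.0)
        assert c.o2 == pytest.approx(90.0)

    def test_minimalist_crossover_near_inverse_K(self, traj_minimalist):
        res = crossover_kd(traj_minimalist, "all")
        x50, _ = half_saturation(AdairConstants.equal(MIN_K).saturation)
        for phase in ("deox", "reox"):
            assert res.kd[phase] == pytest.approx(x50, rel=0.02)

    def test_deox_and_reox_crossovers_agree_without_hysteresis(self, traj_minimalist):
        res = crossover_kd(traj_minimalist, "all")
        assert res.kd["deox"] == pytest.approx(res.kd["reox"], rel=0.01)

    def test_conformation_groups_match_state_affinities(self, traj_perutz, traj_mwc):
        per = NOMINAL_CONSTANTS["perutz"]
        res_t = crossover_kd(traj_perutz, "T")
        res_r = crossover_kd(traj_perutz, "R")
        assert res_t.kd["deox"] == pytest.approx(1 / per["KT"], rel=0.02)
        assert res_r.kd["deox"] == pytest.approx(1 / per["KR"], rel=0.02)
        mwc = NOMINAL_CONSTANTS["mwc"]
        assert crossover_kd(traj_mwc, "T").kd["deox"] == pytest.approx(1 / mwc["KT"], rel=0.02)
        assert crossover_kd(traj_mwc, "R").kd["deox"] == pytest.approx(1 / mwc["KR"], rel=0.05)

    def test_absent_crossing_reported_as_none(self):
        scheme = nominal_scheme("minimalist", with_ensemble=False)
        t = np.arange(0.0, 5.0)
        conc = np.zeros((len(t), len(scheme.species)))
        conc[:, scheme.index("Hb")] = 10.0
        conc[:, scheme.index("HbO2_1")] = 1.0
        conc[:, scheme.index("O")] = 50.0
        proto = Protocol(t_grid=t, t_respiration_on=0.0, t_open=4.0)
        res = crossover_kd(SpeciesTrajectory(t, conc, scheme, proto), "all")
        assert res.kd["deox"] is None


class TestAllostericLadder:
    def test_level_zero_is_L(self):
        assert allosteric_ladder(504.6, 0.1069, 0) == 504.6

    def test_reference_ladder_values(self):
        c = 0.0191 / 0.1787
        assert allosteric_ladder(504.6, c, 1) == pytest.approx(53.9, abs=0.05)
        assert allosteric_ladder(504.6, c, 4) == pytest.approx(0.066, abs=5e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            allosteric_ladder(-1.0, 0.1, 1)
        with pytest.raises(ConfigurationError):
            allosteric_ladder(1.0, 0.1, 7)


class TestCgain:
    def test_hyperbola_has_zero_gain(self):
        assert cooperativity_gain(hyperbola_odc()).cgain <= 1e-6

    def test_invariant_under_o2_rescaling(self):
        odc = equilibrium_odc(AdairConstants.equal(MIN_K))
        x50 = half_saturation(AdairConstants.equal(MIN_K).saturation)[0]
        g1 = cooperativity_gain(odc, x50=x50)
        scale = 7.3
        odc2 = ODCCurve(odc.o2 * scale, odc.saturation, odc.phase)
        g2 = cooperativity_gain(odc2, x50=x50 * scale)
        assert g2.cgain == pytest.approx(g1.cgain, rel=1e-12)

    def test_minimalist_gain_strictly_positive(self):
        odc = equilibrium_odc(AdairConstants.equal(MIN_K))
        assert cooperativity_gain(odc).cgain > 0.05

    def test_non_spanning_curve_rejected(self):
        grid = np.linspace(0.0, 20.0, 50)
        with pytest.raises(ConfigurationError):
            cooperativity_gain(hyperbola_odc(kd=26.0, grid=grid))


class TestNonEquilibriumProperties:
    def test_slow_protocol_converges_to_equilibrium_curve(self):
        """Quasi-static driving reproduces the closed-form ODC (equilibrium limit)."""
        slow = nominal_protocol(t_end=140000.0, dt=100.0)
        slow = Protocol(
            t_grid=slow.t_grid, t_respiration_on=5000.0, t_open=100000.0,
            o2_initial=183.0, o2_air=183.0, hb_heme_total=50.0, oxidase_total=0.05,
        )
        from hbodc.synthetic_data import NOMINAL_ENSEMBLE, nominal_rate_values, build_model
        from hbodc.kinetic_schemes import add_cell_ensemble

        sch = build_model("minimalist", nominal_rate_values("minimalist"))
        sch = add_cell_ensemble(sch, 0.05, NOMINAL_ENSEMBLE["kcat"] / 100.0,
                                NOMINAL_ENSEMBLE["k_air"] / 100.0, 183.0)
        traj = simulate(sch, slow)
        odc = fractional_saturation(traj)
        sel = (odc.o2 > 0.5) & (odc.o2 < 182.0)
        s_eq = sch.equilibrium_saturation(odc.o2[sel])
        assert np.max(np.abs(odc.saturation[sel] - s_eq)) <= 0.01

    @staticmethod
    def _branch_gap(traj):
        odc = fractional_saturation(traj)
        deox = odc.phase == "deox"
        x = np.linspace(10, 120, 30)
        s_d = np.interp(x, odc.o2[deox][::-1], odc.saturation[deox][::-1])
        s_r = np.interp(x, odc.o2[~deox], odc.saturation[~deox])
        return np.max(np.abs(s_d - s_r))

    def test_diffusion_limited_binding_shows_no_hysteresis(self, traj_minimalist):
        """At k_on = 100 µM⁻¹s⁻¹ binding equilibrates in milliseconds, so the
        deox and reox branches of the ODC coincide — consistent with both
        phases plotting on a single curve in real oxygraph experiments."""
        assert self._branch_gap(traj_minimalist) < 1e-3

    def test_slow_binding_hysteresis_shrinks_in_quasi_static_limit(self):
        """With per-site binding slowed 1000-fold the branches separate, and
        the separation collapses again when the protocol is driven slower."""
        from hbodc.kinetic_schemes import add_cell_ensemble
        from hbodc.synthetic_data import build_model, nominal_rate_values

        values = nominal_rate_values("minimalist", k_on=0.1)
        sch = add_cell_ensemble(build_model("minimalist", values), 0.05, 5.0, 0.015, 183.0)
        gap_fast = self._branch_gap(simulate(sch, nominal_protocol()))

        slow_proto = Protocol(
            t_grid=np.arange(0.0, 28000.0 + 5, 20.0), t_respiration_on=1000.0,
            t_open=20000.0, o2_initial=183.0, o2_air=183.0,
            hb_heme_total=50.0, oxidase_total=0.05,
        )
        sch_slow = sch.with_params({"k_cat": 0.25, "k_air": 0.00075})
        gap_slow = self._branch_gap(simulate(sch_slow, slow_proto))
        assert gap_fast > 0.01
        assert gap_slow < gap_fast / 2


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    logK=st.lists(st.floats(-3.0, 1.0), min_size=4, max_size=4),
    x=st.floats(0.0, 1e3),
)
def test_adair_saturation_bounded_and_monotone(logK, x):
    consts = AdairConstants(*(10.0**np.array(logK)))
    s = equilibrium_saturation(consts, x)
    assert 0.0 <= s <= 1.0
    assert equilibrium_saturation(consts, x + 1.0) >= s - 1e-12
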