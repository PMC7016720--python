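"""Equilibrium layer: sensor equilibria, couplings, open probability, landscapes."""

import math

import numpy as np
import pytest

from thermogate.constants import R_KCAL, celsius_to_kelvin
from thermogate.gating import (
    coupling_C,
    landscape,
    log_state_weights,
    open_probability,
    sensor_J,
    sensor_K,
    state_weights,
)
from thermogate.parameters import (
    CouplingParams,
    GatingParameters,
    ParameterError,
    ThermoSensorParams,
    VoltageSensorParams,
)

from conftest import random_params


TS = ThermoSensorParams(dH=91.0, dS=0.317)
VS = VoltageSensorParams(K0=0.003, z=0.74)


class TestSensorEquilibria:
    def test_thermo_sensor_unity_at_half_activation(self):
        # exponent vanishes exactly at T = dH/dS
        assert sensor_J(91.0 / 0.317, TS) == pytest.approx(1.0, abs=1e-12)

    def test_thermo_sensor_closed_form(self):
        # frozen oracle: exp[-(91 - 298.15*0.317)/(R*298.15)]
        expected = math.exp(-(91.0 - 298.15 * 0.317) / (R_KCAL * 298.15))
        assert sensor_J(298.15, TS) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(376.3, rel=2e-3)

    def test_thermo_sensor_identity_with_zero_energetics(self):
        p = ThermoSensorParams(dH=0.0, dS=0.0)
        for t in (250.0, 298.15, 340.0):
            assert sensor_J(t, p) == 1.0

    def test_thermo_sensor_increasing_for_positive_dh(self):
        t = np.linspace(270, 340, 50)
        assert np.all(np.diff(sensor_J(t, TS)) > 0)

    def test_voltage_sensor_k0_at_zero_mv(self):
        assert sensor_K(0.0, 298.15, VS) == pytest.approx(0.003, rel=1e-14)

    def test_voltage_sensor_closed_form(self):
        # RT/F = 25.693 mV at 298.15 K -> K = 0.003*e^(0.74*80/25.693)
        assert sensor_K(80.0, 298.15, VS) == pytest.approx(0.0300, abs=2e-4)

    def test_voltage_insensitive_limit(self):
        p = VoltageSensorParams(K0=0.42, z=0.0)
        for v in (-150.0, 0.0, 200.0):
            assert sensor_K(v, 298.15, p) == pytest.approx(0.42, rel=1e-14)

    def test_coupling_unity_at_compensation_temperature(self):
        p = CouplingParams(D=1, E=1, dHc=6.1, dSc=0.02)
        assert coupling_C(6.1 / 0.02, p) == pytest.approx(1.0, abs=1e-12)

    def test_coupling_closed_form(self):
        p = CouplingParams(D=1, E=1, dHc=6.1, dSc=0.020)
        assert coupling_C(298.15, p) == pytest.approx(0.794, abs=1e-3)

    def test_coupling_off(self):
        p = CouplingParams(D=1, E=1, dHc=0.0, dSc=0.0)
        for t in (260.0, 298.15, 333.15):
            assert coupling_C(t, p) == 1.0

    @pytest.mark.parametrize("fn,args", [
        (sensor_J, (TS,)),
        (sensor_K, (VS,)),
        (coupling_C, (CouplingParams(D=1, E=1, dHc=1, dSc=0.01),)),
    ])
    def test_nonpositive_temperature_rejected(self, fn, args):
        with pytest.raises(ValueError):
            if fn is sensor_K:
                fn(0.0, -1.0, *args)
            else:
                fn(-1.0, *args)


def _po_brute_force(v, t_k, p):
    """Independent enumeration oracle: explicit Boltzmann-weight sums.

    Returns None when plain float arithmetic over/underflows — those draws
    are still checked for saturation behaviour, just not for equality.
    """
    try:
        J = math.exp(-(p.tsensor.dH - t_k * p.tsensor.dS) / (R_KCAL * t_k))
        K = p.vsensor.K0 * math.exp(
            p.vsensor.z * 96485.33212331001 * (v / 1000.0) / (8.31446261815324 * t_k)
        )
        C = math.exp(-(p.coupling.dHc - t_k * p.coupling.dSc) / (R_KCAL * t_k))
        D, E, L = p.coupling.D, p.coupling.E, p.L
        closed = 1 + K + J + J * K * E
        opn = L * (1 + K * D + J * C + J * K * C * D * E)
        ratio = opn / (closed + opn)
    except OverflowError:
        return None
    return ratio if math.isfinite(ratio) else None


class TestOpenProbability:
    def test_two_state_reduction_exact(self):
        # C = D = E = 1 cancels both sensors: P_o = L/(1+L) at every (V, T)
        p = GatingParameters(
            L=0.37, tsensor=TS, vsensor=VS,
            coupling=CouplingParams(D=1.0, E=1.0, dHc=0.0, dSc=0.0),
        )
        for v, tc in [(-150, 5), (0, 25), (80, 60), (200, 40)]:
            assert open_probability(v, celsius_to_kelvin(tc), p) == pytest.approx(
                0.37 / 1.37, rel=1e-14
            )

    def test_fixed_point_example(self):
        # weights {1, K, J, JKE} closed and {L, LKD, LJC, LJKCDE} open with
        # L=0.01, J=5, K=2, C=3, D=4, E=2  ->  2.64/30.64
        t_k = 298.15
        p = GatingParameters(
            L=0.01,
            tsensor=ThermoSensorParams(dH=-R_KCAL * t_k * math.log(5), dS=0.0),
            vsensor=VoltageSensorParams(K0=2.0, z=1.0),
            coupling=CouplingParams(
                D=4.0, E=2.0, dHc=-R_KCAL * t_k * math.log(3), dSc=0.0
            ),
        )
        assert open_probability(0.0, t_k, p) == pytest.approx(2.64 / 30.64, rel=1e-12)

    def test_saturation_in_l(self):
        p = random_params(np.random.default_rng(7)).replace(L=1e12)
        assert open_probability(0.0, 298.15, p) > 1.0 - 1e-9

    def test_matches_enumeration_oracle(self, rng):
        # >= 1000 random draws including extreme exponents, <= 1e-12
        for i in range(1200):
            p = random_params(rng, extreme=(i % 3 == 0))
            v = rng.uniform(-200, 250)
            t_k = rng.uniform(250, 350)
            expected = _po_brute_force(v, t_k, p)
            got = float(open_probability(v, t_k, p))
            if expected is not None and 1e-300 < expected < 1 - 1e-13:
                assert got == pytest.approx(expected, abs=1e-12, rel=1e-9)
            assert 0.0 <= got <= 1.0
            assert math.isfinite(got)

    def test_monotone_in_l_and_v(self, rng):
        # Monotone in L always. Monotone in V (z > 0) under favorable
        # coupling, i.e. D >= 1 and (C-1)(E-1) >= 0 — with D < 1 the
        # voltage dependence legitimately inverts (the cold-sensitized
        # regime exploits exactly that), so the V check is restricted.
        def check_increasing(po):
            po = np.asarray(po)
            assert np.all(np.diff(po) >= -1e-12)  # float jitter at saturation
            # strict increase where the slope is float-resolvable
            interior = (po > 0.01) & (po < 0.99)
            if interior.sum() >= 2:
                assert np.all(np.diff(po[interior]) > 0)

        for _ in range(25):
            p = random_params(rng)
            t_k = rng.uniform(260, 340)
            ls = np.logspace(-3, 3, 25)
            check_increasing(
                [float(open_probability(0.0, t_k, p.replace(L=l))) for l in ls]
            )
            p = p.replace(
                z=abs(p.vsensor.z) + 0.1,
                D=1.0 + p.coupling.D,
                E=1.0 + p.coupling.E,
                dHc=-abs(p.coupling.dHc),
                dSc=abs(p.coupling.dSc),  # C(T) >= 1 at all T > 0
            )
            v = np.linspace(-150, 200, 30)
            check_increasing(open_probability(v, t_k, p))

    def test_numerical_robustness_extreme_exponents(self):
        # exponents to ~±700 in the underlying terms: saturate, never NaN
        p = GatingParameters(
            L=1e-300,
            tsensor=ThermoSensorParams(dH=400.0, dS=1.5),
            vsensor=VoltageSensorParams(K0=1e-6, z=4.0),
            coupling=CouplingParams(D=1e300, E=1e-300, dHc=-60.0, dSc=-0.1),
        )
        v = np.array([-300.0, 0.0, 300.0])
        t = np.array([[250.0], [300.0], [350.0]])
        po = open_probability(v, t, p)
        assert np.all(np.isfinite(po))
        assert np.all((po >= 0) & (po <= 1))

    def test_sensor_interchange_symmetry(self, rng):
        # With E=1 the two sensors enter the partition function identically:
        # swapping (J-parameters, C) with (K-parameters, D) preserves P_o.
        t_k = 298.15
        for _ in range(50):
            j = 10.0 ** rng.uniform(-3, 3)
            k = 10.0 ** rng.uniform(-3, 3)
            c = 10.0 ** rng.uniform(-2, 2)
            d = 10.0 ** rng.uniform(-2, 2)
            L = 10.0 ** rng.uniform(-2, 2)

            def build(jv, kv, cv, dv):
                return GatingParameters(
                    L=L,
                    tsensor=ThermoSensorParams(dH=-R_KCAL * t_k * math.log(jv), dS=0.0),
                    vsensor=VoltageSensorParams(K0=kv, z=0.0),
                    coupling=CouplingParams(
                        D=dv, E=1.0, dHc=-R_KCAL * t_k * math.log(cv), dSc=0.0
                    ),
                )

            a = open_probability(0.0, t_k, build(j, k, c, d))
            b = open_probability(0.0, t_k, build(k, j, d, c))
            assert a == pytest.approx(b, rel=1e-11)


class TestStateWeights:
    def test_symmetric_case_uniform(self):
        t_k = 298.15
        p = GatingParameters(
            L=1.0,
            tsensor=ThermoSensorParams(dH=0.0, dS=0.0),
            vsensor=VoltageSensorParams(K0=1.0, z=0.5),
            coupling=CouplingParams(D=1.0, E=1.0, dHc=0.0, dSc=0.0),
        )
        w = state_weights(0.0, t_k, p)
        assert w == pytest.approx(np.full(8, 0.125), abs=1e-14)

    def test_normalization_and_open_mass(self, rng):
        for _ in range(300):
            p = random_params(rng)
            v, t_k = rng.uniform(-200, 200), rng.uniform(255, 345)
            w = state_weights(v, t_k, p)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)
            assert w[4:].sum() == pytest.approx(
                float(open_probability(v, t_k, p)), abs=1e-12
            )


class TestLandscape:
    def test_single_cell_matches_scalar(self, simple_params):
        ls = landscape(simple_params, [80.0], [25.0])
        assert ls.po.shape == (1, 1)
        assert ls.po[0, 0] == pytest.approx(
            float(open_probability(80.0, celsius_to_kelvin(25.0), simple_params)),
            rel=1e-14,
        )

    def test_uncoupled_landscape_flat(self):
        p = GatingParameters(
            L=0.5, tsensor=TS, vsensor=VS,
            coupling=CouplingParams(D=1.0, E=1.0, dHc=0.0, dSc=0.0),
        )
        ls = landscape(p, np.arange(-150, 201, 25.0), np.arange(5, 61, 5.0))
        assert np.ptp(ls.po) < 1e-12

    def test_grid_validation(self, simple_params):
        with pytest.raises(ValueError):
            landscape(simple_params, [0.0, 10.0, 5.0], [5.0, 25.0])
        with pytest.raises(ValueError):
            landscape(simple_params, [], [25.0])

    def test_probabilities_in_unit_interval(self, rng):
        for _ in range(10):
            p = random_params(rng, extreme=True)
            ls = landscape(p, np.linspace(-200, 250, 12), np.linspace(5, 60, 9))
            assert np.all((ls.po >= 0) & (ls.po <= 1))
            assert np.all(np.isfinite(ls.po))


class TestParameterSerialization:
    def test_round_trip_lossless(self, rng):
        for _ in range(20):
            p = random_params(rng)
            q = GatingParameters.from_dict(p.to_dict(), normalize_z=False)
            assert q == p

    def test_negative_z_normalized_with_flag(self):
        d = dict(L=1.0, K0=0.003, z=-0.74, dH=91.0, dS=0.317,
                 dHc=6.1, dSc=0.02, D=2.0, E=3.0, label="blue")
        p = GatingParameters.from_dict(d)
        assert p.vsensor.z == 0.74
        assert p.z_sign_normalized
        q = GatingParameters.from_dict(d, normalize_z=False)
        assert q.vsensor.z == -0.74

    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            VoltageSensorParams(K0=-1.0, z=0.5)
        with pytest.raises(ParameterError):
            VoltageSensorParams(K0=0.01, z=5.0)
        with pytest.raises(ParameterError):
            CouplingParams(D=0.0, E=1.0, dHc=0.0, dSc=0.0)
        with pytest.raises(ParameterError):
            GatingParameters(
                L=-0.1, tsensor=TS, vsensor=VS,
                coupling=CouplingParams(D=1, E=1, dHc=0, dSc=0),
            )
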