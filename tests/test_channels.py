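import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from purkinje import channels as ch
from purkinje.morphology import RegionTag


class TestQ10:
    def test_identity_at_equal_temperature(self):
        assert ch.q10_scale(1.0, 37, 37) == 1.0

    def test_closed_form_up(self):
        assert ch.q10_scale(1.0, 23, 37) == pytest.approx(3 ** 1.4)
        assert ch.q10_scale(1.0, 23, 37) == pytest.approx(4.6555, abs=1e-3)

    def test_closed_form_down(self):
        assert ch.q10_scale(2.0, 37, 23) == pytest.approx(2 * 3 ** -1.4)
        assert ch.q10_scale(2.0, 37, 23) == pytest.approx(0.4296, abs=1e-3)

    def test_preserves_steady_state_of_alpha_beta_gates(self, channelome):
        """Scaling both rates by the same factor leaves x_inf unchanged and
        divides tau."""
        v = np.linspace(-100, 40, 57)
        for spec in channelome:
            for g in spec.gates:
                if g.form != "alpha_beta":
                    continue
                i1, t1 = g.inf_tau(v, ch.CA_REST, qt=1.0)
                i2, t2 = g.inf_tau(v, ch.CA_REST, qt=3.7)
                assert np.allclose(i1, i2)
                assert np.allclose(t1 / 3.7, t2)


class TestGhk:
    def test_zero_at_equal_concentrations(self):
        assert ch.ghk_ca_reversal(1.0, cao=1.0) == pytest.approx(0.0)

    def test_initial_reversal_at_rest(self):
        assert float(ch.ghk_ca_reversal(ch.CA_REST)) == pytest.approx(137.5)

    def test_physiological_cao_value(self):
        # at 2 mM external the rest reversal sits near 143 mV
        assert float(ch.ghk_ca_reversal(4.5e-5, cao=2.0, T=310.0)) \
            == pytest.approx(143.0, abs=1.0)

    def test_decreasing_in_cai(self):
        cai = np.logspace(-5, -2, 30)
        e = ch.ghk_ca_reversal(cai)
        assert np.all(np.diff(e) < 0)

    def test_nonpositive_concentration_raises(self):
        with pytest.raises(ValueError):
            ch.ghk_ca_reversal(0.0)


class TestSteadyStates:
    def test_alpha_beta_symmetry_half(self, channelome):
        """Where alpha(V) == beta(V), x_inf is exactly 0.5 (checked on the
        symmetric delayed-rectifier gates at their half-activation)."""
        kv33 = ch.get_channel(channelome, "Kv3.3")
        assert kv33.gate_steady_state(-16.0)["n"] == pytest.approx(0.5)
        kv11 = ch.get_channel(channelome, "Kv1.1")
        assert kv11.gate_steady_state(-45.0)["n"] == pytest.approx(0.5)

    def test_p_type_half_activation(self, channelome):
        cav = ch.get_channel(channelome, "Cav2.1")
        m = cav.gate_steady_state(-29.5)["m"]
        assert m == pytest.approx(0.5, abs=1e-9)
        # 8.5 mV slope: e-fold asymmetry point
        m2 = cav.gate_steady_state(-29.5 + 8.5)["m"]
        assert m2 == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)

    @pytest.mark.parametrize("name", ["KCa1.1", "KCa2.2", "KCa3.1"])
    def test_kca_open_probability_increases_with_calcium(self, channelome,
                                                         name):
        spec = ch.get_channel(channelome, name)
        p_lo = spec.open_fraction_steady(-30.0, 4.5e-5)
        p_mid = spec.open_fraction_steady(-30.0, 1.6e-3)
        p_hi = spec.open_fraction_steady(-30.0, 1e-2)
        assert p_lo < p_mid < p_hi

    def test_nav_closed_at_hyperpolarized_hold(self, channelome):
        nav = ch.get_channel(channelome, "Nav1.6")
        p = ch.markov_steady_state(nav.markov, -80.0)
        open_blocked = p[5] + p[6]
        assert open_blocked < 1e-5
        assert p[:5].sum() > 0.9


class TestMarkovSteadyState:
    def test_two_state_symmetric(self):
        def rates(V, Cai):
            R = np.zeros((V.shape[0], 2, 2))
            R[:, 0, 1] = 1.0
            R[:, 1, 0] = 1.0
            return R
        scheme = ch.MarkovScheme(("C", "O"), ("O",), rates)
        p = ch.markov_steady_state(scheme, -60.0)
        assert p == pytest.approx([0.5, 0.5])

    def test_three_state_detailed_balance(self):
        # linear chain with forward (1, 2) and backward (2, 1): occupancies
        # proportional to (1, 1/2, 1) by detailed balance
        def rates(V, Cai):
            R = np.zeros((V.shape[0], 3, 3))
            R[:, 0, 1] = 1.0
            R[:, 1, 0] = 2.0
            R[:, 1, 2] = 2.0
            R[:, 2, 1] = 1.0
            return R
        scheme = ch.MarkovScheme(("A", "B", "C"), ("C",), rates)
        p = ch.markov_steady_state(scheme, 0.0)
        expect = np.array([1.0, 0.5, 1.0])
        assert p == pytest.approx(expect / expect.sum(), abs=1e-12)
        # brute-force master-equation integration agrees
        G = scheme.generator(0.0, 0.0)[0]
        p0 = np.array([1.0, 0.0, 0.0])
        sol = solve_ivp(lambda t, y: G @ y, [0, 200], p0,
                        rtol=1e-10, atol=1e-12)
        assert sol.y[:, -1] == pytest.approx(p, abs=1e-7)

    @pytest.mark.parametrize("name,V,cai", [
        ("Nav1.6", -80.0, 4.5e-5),
        ("Nav1.6", -40.0, 4.5e-5),
        ("KCa1.1", -30.0, 1.6e-3),
        ("KCa2.2", -60.0, 3e-4),
    ])
    def test_against_master_equation_oracle(self, channelome, name, V, cai):
        spec = ch.get_channel(channelome, name)
        p = ch.markov_steady_state(spec.markov, V, cai)
        G = spec.markov.generator(V, cai)[0]
        p0 = np.zeros(spec.markov.n)
        p0[0] = 1.0
        sol = solve_ivp(lambda t, y: G @ y, [0, 5e4], p0,
                        rtol=1e-11, atol=1e-13, method="LSODA")
        assert np.abs(sol.y[:, -1] - p).max() < 1e-6

    def test_occupancies_sum_to_one(self, channelome):
        for spec in channelome:
            if spec.markov is None:
                continue
            for V in (-90.0, -55.0, 0.0, 40.0):
                p = ch.markov_steady_state(spec.markov, V, 1e-3)
                assert p.sum() == pytest.approx(1.0)
                assert np.all(p >= 0)


class TestChannelCurrent:
    def test_zero_at_reversal(self, channelome):
        kv = ch.get_channel(channelome, "Kv3.4")
        i = ch.channel_current(kv, ch.E_K, 0.7, 1e-6,
                               region=RegionTag.SOMA)
        assert i == pytest.approx(0.0)

    def test_zero_gmax_region(self, channelome):
        kv = ch.get_channel(channelome, "Kv3.3")  # absent from the soma
        assert ch.channel_current(kv, 0.0, 1.0, 1e-6,
                                  region=RegionTag.SOMA) == 0.0

    def test_unit_arithmetic(self):
        spec = ch.ChannelSpec("unit", gates=[], erev=-100.0,
                              gmax_by_region={RegionTag.SOMA: 0.01})
        i = ch.channel_current(spec, 0.0, 1.0, 1e-6, region=RegionTag.SOMA)
        assert i == pytest.approx(1.0)  # 0.01 S/cm2 * 1e-6 cm2 * 100 mV = 1 nA


class TestDefaultChannelome:
    def test_fifteen_channels(self, channelome):
        assert len(channelome) == 15
        names = {c.name for c in channelome}
        assert names == {"Nav1.6", "Kv1.1", "Kv1.5", "Kv3.3", "Kv3.4",
                         "Kv4.3", "Kir2.x", "KCa1.1", "KCa2.2", "KCa3.1",
                         "Cav2.1", "Cav3.1", "Cav3.2", "Cav3.3", "HCN1"}

    @pytest.mark.parametrize("name,region,gmax", [
        ("Nav1.6", RegionTag.AIS, 0.5),
        ("Nav1.6", RegionTag.SOMA, 0.214),
        ("Nav1.6", RegionTag.NODE, 0.03),
        ("Kv1.1", RegionTag.PARA_AIS, 0.01),
        ("Kv3.4", RegionTag.SOMA, 0.05),
        ("Kv3.4", RegionTag.COLLATERAL, 0.02),
        ("Kv1.5", RegionTag.TERMINAL, 1.3e-4),
        ("KCa1.1", RegionTag.PRINCIPAL, 3.5e-2),
        ("KCa3.1", RegionTag.SOMA, 0.01),
        ("Cav2.1", RegionTag.TERMINAL, 1e-3),
        ("Cav2.1", RegionTag.NODE, 2.2e-4),
        ("Cav3.1", RegionTag.AIS, 1e-5),
        ("Cav3.2", RegionTag.SOMA, 0.0008),
        ("HCN1", RegionTag.SOMA, 4e-4),
        ("Kir2.x", RegionTag.SOMA, 3e-5),
    ])
    def test_placement_table(self, channelome, name, region, gmax):
        assert ch.get_channel(channelome, name).gmax_in(region) == gmax

    def test_myelin_carries_nothing(self, channelome):
        for spec in channelome:
            assert spec.gmax_in(RegionTag.MYELIN) == 0.0

    def test_para_ais_carries_only_kv11(self, channelome):
        for spec in channelome:
            g = spec.gmax_in(RegionTag.PARA_AIS)
            if spec.name == "Kv1.1":
                assert g == 0.01
            else:
                assert g == 0.0

    def test_reversal_policies(self, channelome):
        for spec in channelome:
            if spec.name.startswith("Cav"):
                assert spec.erev == "ca_ghk"
            elif spec.name.startswith("K"):
                assert spec.erev == ch.E_K
        assert ch.get_channel(channelome, "Nav1.6").erev == 60.0
        assert ch.get_channel(channelome, "HCN1").erev == -34.4


class TestGateBounds:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-120, max_value=60),
                    min_size=3, max_size=12))
    def test_gates_stay_in_unit_interval_under_arbitrary_clamp(self, vs):
        """Exponential-Euler gate updates remain in [0, 1] for any clamp
        waveform in the supported voltage range."""
        chans = ch.build_default_channelome()
        dt = 0.025
        for spec in chans:
            if spec.markov is not None:
                continue
            qt = spec.qt()
            for g in spec.gates:
                x = 0.5
                for v in vs:
                    inf, tau = g.inf_tau(np.array([v]), 1e-3, qt)
                    x = float(inf[0] + (x - inf[0]) * np.exp(-dt / tau[0]))
                    assert 0.0 <= x <= 1.0

    def test_tau_positive_over_range(self, channelome):
        v = np.linspace(-120, 60, 361)
        for spec in channelome:
            for g in spec.gates:
                inf, tau = g.inf_tau(v, 1e-3, spec.qt())
                assert np.all(tau > 0)
                assert np.all((inf >= 0) & (inf <= 1))


class TestResurgentSodium:
    def test_resurgent_component_on_repolarization(self, channelome):
        """Depolarize to +30 (driving open channels into the blocked state),
        then step to -30: the reopening of blocked channels produces a
        transient open-probability peak exceeding the steady state."""
        nav = ch.get_channel(channelome, "Nav1.6")
        qt = nav.qt()
        dt = 0.01

        def evolve(p, V, T):
            G = nav.markov.generator(V, 4.5e-5, qt)[0]
            M = np.linalg.inv(np.eye(13) - dt * G)
            for _ in range(int(T / dt)):
                p = M @ p
            return p

        p = ch.markov_steady_state(nav.markov, -90.0)
        p = evolve(p, 30.0, 5.0)
        blocked_after_step = p[6]
        assert blocked_after_step > 0.2  # block accumulated at +30
        # repolarize and track open occupancy
        G = nav.markov.generator(-30.0, 4.5e-5, qt)[0]
        M = np.linalg.inv(np.eye(13) - dt * G)
        open_t = []
        for _ in range(int(10.0 / dt)):
            p = M @ p
            open_t.append(p[5])
        open_t = np.array(open_t)
        pss = ch.markov_steady_state(nav.markov, -30.0)[5]
        assert open_t.max() > 3 * pss          # transient resurgent peak
        assert np.argmax(open_t) > 0           # peaks after the step
        assert open_t[-1] < 0.5 * open_t.max()  # and decays again
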