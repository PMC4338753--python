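import math

import numpy as np
import pytest

from purkinje import channels as ch
from purkinje import solver as slv
from purkinje.morphology import (Morphology, PassiveParams, RegionTag,
                                 SectionGeometry, ROOT)


def single_compartment(d=10.0, L=10.0, g_leak=1e-4, cm=1.0, e_leak=-61.0):
    sec = SectionGeometry(0, ROOT, RegionTag.SOMA, d, L)
    p = PassiveParams(g_leak_default=g_leak, g_leak={}, cm_specific={},
                      cm_default=cm, e_leak=e_leak)
    return slv.Model(Morphology([sec]), p, [])


class TestCoupling:
    def test_two_compartment_closed_form(self):
        # two identical compartments d=1 um, L=100 um, Ra=122 Ohm*cm
        root = SectionGeometry(0, ROOT, RegionTag.TERMINAL, 1.0, 100.0, 1)
        child = SectionGeometry(1, 0, RegionTag.TERMINAL, 1.0, 100.0, 1)
        p = PassiveParams(ra=122.0)
        mat, grid = slv.assemble_coupling(Morphology([root, child]), p)
        r_half = 122.0 * 100.0 / (2 * math.pi * 0.25) * 1e4  # Ohm
        expect = 1e6 / (2 * r_half)  # uS
        assert mat[0, 1] == pytest.approx(expect, rel=1e-12)

    def test_symmetry_and_tree_sparsity(self, desk_model):
        mat, grid = slv.assemble_coupling(desk_model.morphology,
                                          desk_model.passive)
        dense = mat.toarray()
        assert np.allclose(dense, dense.T)
        # a tree with N nodes has N-1 edges -> 2(N-1) nonzeros
        assert mat.nnz == 2 * (grid.n - 1)

    def test_doubling_ra_halves_conductances(self, desk_model):
        p1 = desk_model.passive
        p2 = PassiveParams(ra=2 * p1.ra)
        m1, _ = slv.assemble_coupling(desk_model.morphology, p1)
        m2, _ = slv.assemble_coupling(desk_model.morphology, p2)
        assert np.allclose(m1.toarray(), 2 * m2.toarray())


class TestPassiveDynamics:
    def test_rc_charging_matches_analytic(self):
        model = single_compartment()
        g_uS = 1e-4 * math.pi * 10 * 10 * 1e-2
        cm_nF = 1.0 * math.pi * 10 * 10 * 1e-5
        tau = cm_nF / g_uS
        cfg = slv.SimConfig(dt=0.025, duration=60.0, record=[("soma", "v")],
                            decim=1, v_init=-61.0)
        sim = slv.Simulation(model, cfg, passive_only=True)
        tr = sim.run(stimuli=[slv.StimulusSource.step("soma", 0.01, 0.0, 1e9)])
        vinf = -61.0 + 0.01 / g_uS
        ana = vinf + (-61.0 - vinf) * np.exp(-tr.t / tau)
        assert np.abs(tr["soma.v"] - ana).max() / abs(vinf + 61.0) < 1e-3

    def test_relaxes_to_leak_reversal(self):
        model = single_compartment(e_leak=-61.0)
        cfg = slv.SimConfig(dt=0.025, duration=120.0, record=[("soma", "v")],
                            v_init=-100.0, decim=1)
        sim = slv.Simulation(model, cfg, passive_only=True)
        tr = sim.run()
        assert tr["soma.v"][-1] == pytest.approx(-61.0, abs=1e-3)

    def test_finite_cable_input_resistance(self):
        """Sealed-end cable: Rin at one end equals Rinf * coth(L/lambda)
        to 1%."""
        d_um, L_um = 2.0, 1500.0
        g_leak, ra = 1e-4, 122.0
        sec = SectionGeometry(0, ROOT, RegionTag.TERMINAL, d_um, L_um, 150)
        p = PassiveParams(ra=ra, g_leak_default=g_leak, g_leak={},
                          cm_specific={}, cm_default=1.0)
        model = slv.Model(Morphology([sec]), p, [])
        grid = model.grid
        # steady solve with current at the first (end) compartment
        d = grid.g_leak + slv._laplacian_diag(grid)
        rhs = np.zeros(grid.n)
        rhs[0] = 1.0  # 1 nA
        v = slv._hines(grid.parent.copy(), grid.g_parent, d.copy(), rhs)
        rin = v[0]  # MOhm per nA
        d_cm = d_um * 1e-4
        rm = 1.0 / g_leak                      # Ohm*cm^2
        r_m = rm / (math.pi * d_cm)            # Ohm*cm
        r_a = 4.0 * ra / (math.pi * d_cm ** 2)  # Ohm/cm
        lam = math.sqrt(r_m / r_a)
        rinf = math.sqrt(r_m * r_a)
        expect = rinf / math.tanh(L_um * 1e-4 / lam) / 1e6  # MOhm
        assert rin == pytest.approx(expect, rel=0.01)

    def test_charge_balance(self):
        """Injected charge equals capacitive plus leak charge under the
        backward-Euler discretization, to 1e-6 relative."""
        model = single_compartment()
        grid = model.grid
        cfg = slv.SimConfig(dt=0.025, duration=1.0, decim=1, v_init=-61.0)
        sim = slv.Simulation(model, cfg, passive_only=True)
        i_inj = np.zeros(grid.n)
        i_inj[0] = 0.02
        q_inj = q_cap = q_leak = 0.0
        for _ in range(2000):
            v_old = sim.v.copy()
            sim.step(i_inj)
            q_inj += i_inj[0] * cfg.dt
            q_cap += float(np.sum(grid.cm * (sim.v - v_old)))
            q_leak += float(np.sum(grid.g_leak * (sim.v - grid.e_leak))
                            * cfg.dt)
        assert q_inj == pytest.approx(q_cap + q_leak, rel=1e-6)


class TestImpedance:
    def test_single_compartment_gigaohm(self):
        # 1 nS total leak -> 1 GOhm input resistance
        d = L = 10.0
        area_cm2 = math.pi * d * L * 1e-8
        g_leak = 1e-9 / area_cm2
        model = single_compartment(g_leak=g_leak)
        rin, cin = slv.impedance_from_soma(model, i_test=-0.001)
        assert rin == pytest.approx(1000.0, rel=1e-6)  # MOhm

    def test_canonical_model_aggregates(self, desk_model):
        rin, cin = slv.impedance_from_soma(desk_model)
        assert rin == pytest.approx(14.0, rel=0.10)
        assert cin == pytest.approx(1090.0, rel=0.10)


class TestActiveIntegration:
    def test_determinism(self, desk_model):
        cfg = slv.SimConfig(dt=0.025, duration=200.0, record=[("soma", "v")],
                            decim=1)
        t1 = slv.Simulation(desk_model, cfg).run()
        t2 = slv.Simulation(desk_model, cfg).run()
        assert np.array_equal(t1["soma.v"], t2["soma.v"])

    def test_zero_duration_empty_traces(self, desk_model):
        cfg = slv.SimConfig(dt=0.025, duration=0.0, record=[("soma", "v")])
        tr = slv.Simulation(desk_model, cfg).run()
        assert tr.t.size == 0

    def test_divergence_guard(self):
        model = single_compartment(g_leak=1e-6)
        cfg = slv.SimConfig(dt=0.025, duration=500.0, decim=1)
        sim = slv.Simulation(model, cfg, passive_only=True)
        i_inj = np.zeros(1)
        i_inj[0] = 10.0  # drives far past the +-200 mV guard
        with pytest.raises(slv.SimulationDiverged):
            for _ in range(20000):
                sim.step(i_inj)

    def test_gate_and_markov_states_converge_under_clamp(self, desk_model):
        """Holding the voltage fixed, the dynamic gate and Markov states
        converge to the analytic steady state (1e-5)."""
        cfg = slv.SimConfig(dt=0.025, duration=1.0)
        sim = slv.Simulation(desk_model, cfg)
        v_clamp = -45.0
        T = 3000.0
        sim.v[:] = v_clamp
        cai = sim.calcium.cai.copy()
        x0 = sim.hh.x.copy()
        for _ in range(int(T / 0.025)):
            sim.hh.advance(sim.v, cai)
            for mk in sim.markov:
                mk.advance(sim.v, cai)
        # HH gates: compare against x_inf at the clamp; very slow gates
        # (tau of hundreds of ms) are granted their analytic residual
        n_ent = 0
        for spec, idx in sim.hh.specs:
            qt = spec.qt()
            for g in spec.gates:
                inf, tau = g.inf_tau(np.full(idx.size, v_clamp), cai[idx], qt)
                got = sim.hh.x[n_ent:n_ent + idx.size]
                resid = np.abs(x0[n_ent:n_ent + idx.size] - inf) \
                    * np.exp(-T / tau)
                tol = 1e-5 + 1.05 * resid.max()
                assert np.abs(got - inf).max() < tol, (spec.name, g.name)
                n_ent += idx.size
        for mk in sim.markov:
            for k in (0, mk.idx.size - 1):
                expect = ch.markov_steady_state(
                    mk.spec.markov, v_clamp, float(cai[mk.idx[k]]))
                assert np.abs(mk.occupancy()[k] - expect).max() < 1e-5

    def test_occupancies_bounded_under_arbitrary_clamp(self, desk_model):
        rng = np.random.default_rng(7)
        cfg = slv.SimConfig(dt=0.025, duration=1.0)
        sim = slv.Simulation(desk_model, cfg)
        cai = sim.calcium.cai.copy()
        for _ in range(300):
            sim.v[:] = rng.uniform(-120.0, 60.0)
            sim.hh.advance(sim.v, cai)
            for mk in sim.markov:
                mk.advance(sim.v, cai)
        assert np.all((sim.hh.x >= 0.0) & (sim.hh.x <= 1.0))
        for mk in sim.markov:
            assert np.all(mk.p >= 0.0)
            assert np.allclose(mk.p.sum(axis=1), 1.0)

    def test_spike_initiation_in_ais(self, desk_model):
        """On every spontaneous spike the AIS crosses the -20 mV detection
        level no later than the soma."""
        cfg = slv.SimConfig(dt=0.025, duration=600.0, decim=1,
                            record=[("soma", "v"), ("AIS", "v")])
        sim = slv.Simulation(desk_model, cfg)
        sim.run(duration=600.0, record=[("soma", "v")])
        tr = sim.run(duration=400.0)
        vs, va, t = tr["soma.v"], tr["AIS.v"], tr.t
        up_s = np.nonzero((vs[1:] > -20) & (vs[:-1] <= -20))[0]
        assert up_s.size >= 5
        for i in up_s:
            j0 = max(0, i - 40)
            assert np.any(va[j0:i + 1] > -20.0), "soma crossed before AIS"


class TestTraceSet:
    def test_csv_round_trip(self, desk_model, tmp_path):
        cfg = slv.SimConfig(dt=0.025, duration=10.0, decim=4,
                            record=[("soma", "v"), ("AIS", "v")])
        tr = slv.Simulation(desk_model, cfg).run()
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        assert arr.shape == (tr.t.size, 3)
        assert np.allclose(arr[:, 1], tr["soma.v"])

    def test_hdf5_round_trip(self, desk_model, tmp_path):
        import h5py
        cfg = slv.SimConfig(dt=0.025, duration=5.0, decim=4,
                            record=[("soma", "v")])
        tr = slv.Simulation(desk_model, cfg).run()
        path = tmp_path / "trace.h5"
        tr.to_hdf5(path)
        with h5py.File(path) as f:
            assert np.allclose(f["soma.v"][...], tr["soma.v"])


class TestDtConvergence:
    def test_spike_times_converge_first_order_in_dt(self, desk_model):
        """The implicit integrator's spike-time error shrinks when the time
        step is halved (first-order convergence of the limit-cycle phase),
        and the first spike is already placed to within 0.1 ms at the
        default step."""
        from purkinje import analysis as an
        times = {}
        for dt in (0.05, 0.025, 0.0125):
            cfg = slv.SimConfig(dt=dt, duration=300.0, decim=1,
                                record=[("soma", "v")])
            tr = slv.Simulation(desk_model, cfg).run()
            times[dt] = an.detect_spikes(tr["soma.v"], tr.t).times
        n = min(len(v) for v in times.values())
        assert n >= 4
        coarse = np.abs(times[0.05][:n] - times[0.0125][:n]).max()
        fine = np.abs(times[0.025][:n] - times[0.0125][:n]).max()
        assert fine < 0.75 * coarse
        assert abs(times[0.025][0] - times[0.0125][0]) < 0.1
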