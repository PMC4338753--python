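"""Ionic channel models of the Purkinje cell.

Fifteen voltage- and calcium-dependent conductances under one kinetics
framework:

* Hodgkin-Huxley gates (``alpha_beta`` or ``inf_tau`` form), integrated by
  exponential Euler;
* Markov chains (the 13-state resurgent Nav1.6, a 10-state
  Monod-Wyman-Changeux BK scheme and the 6-state SK2 scheme), integrated by
  backward Euler on the master equation.

All kinetics are expressed at the temperature of the source data and
rescaled to the simulation temperature with a Q10 of 3.  Reversal
potentials are fixed Nernst values except for calcium, whose reversal is
updated during simulation from the Goldman-Hodgkin-Katz relation using the
outermost-shell free calcium.

Kinetic constants follow the published source model of each channel
(resurgent-sodium scheme of Raman & Bean / Khaliq et al. for Nav1.6;
Akemann & Knopfel Kv1.1 and Kv3.3; the TEA-sensitive Purkinje current for
Kv3.4; the atrial ultrarapid delayed rectifier for Kv1.5; cerebellar
granule-cell A-type and inward rectifier for Kv4.3 and Kir2.x; thalamic,
CA3 and Purkinje T-type variants for Cav3.2, Cav3.3 and Cav3.1; the
Purkinje P-type for Cav2.1; the Hirschberg SK scheme for KCa2.2; a mitral
cell intermediate-conductance model for KCa3.1; a layer-5 HCN1).  Where a
constant could not be recovered from the sources (notably the BK Markov
parameters) values were calibrated once against the documented operating
ranges and pinned as regression fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .morphology import RegionTag, DENDRITE_TAGS

FARADAY = 96485.33212  # C/mol
R_GAS = 8.31446261815324  # J/(mol K)
T_SIM_DEFAULT = 37.0  # degC
Q10 = 3.0

# fixed reversal potentials (mV)
E_NA = 60.0
E_K = -88.0
E_HCN = -34.4
E_TRP = 0.0
E_CA_INIT = 137.5

#: resting free calcium, mM (45 nM)
CA_REST = 4.5e-5
#: extracellular calcium (mM), back-solved so that the GHK reversal at the
#: resting 45 nM free calcium equals the initial 137.5 mV
CA_OUT = CA_REST * math.exp(137.5e-3 * 2 * FARADAY / (R_GAS * 310.15))


class KineticsDomainError(ValueError):
    """A rate function returned a non-finite value."""


def q10_scale(rate, t_exp: float, t_sim: float, q10: float = Q10):
    """Rescale a kinetic rate from ``t_exp`` to ``t_sim`` (degC):
    rate * q10**((t_sim - t_exp)/10)."""
    return rate * q10 ** ((t_sim - t_exp) / 10.0)


def ghk_ca_reversal(cai, cao=CA_OUT, T: float = 310.15):
    """Calcium reversal potential (mV) from the single-ion GHK relation,
    (RT/2F) ln(cao/cai); concentrations in mM, T in kelvin."""
    cai = np.asarray(cai, dtype=float)
    if np.any(cai <= 0) or cao <= 0:
        raise ValueError("concentrations must be positive")
    return (R_GAS * T / (2 * FARADAY)) * np.log(cao / cai) * 1e3


# ---------------------------------------------------------------------------
# gating primitives
# ---------------------------------------------------------------------------

@dataclass
class HHGate:
    """A Hodgkin-Huxley gate.

    ``fn(V, Cai)`` returns ``(alpha, beta)`` in 1/ms for the ``alpha_beta``
    form or ``(x_inf, tau_ms)`` for the ``inf_tau`` form, both expressed at
    the channel's source temperature.  Q10 rescaling multiplies both rates
    (leaving x_inf untouched) or divides tau.
    """

    name: str
    exponent: int
    form: str  # "alpha_beta" | "inf_tau"
    fn: Callable

    def inf_tau(self, V, Cai, qt: float = 1.0):
        a, b = self.fn(np.asarray(V, dtype=float), Cai)
        if self.form == "alpha_beta":
            inf = a / (a + b)
            tau = 1.0 / (qt * (a + b))
        else:
            inf, tau = a, b / qt
        if not (np.all(np.isfinite(inf)) and np.all(np.isfinite(tau))):
            raise KineticsDomainError(f"gate {self.name}: nonfinite kinetics")
        return inf, tau


@dataclass
class MarkovScheme:
    """A Markov chain: named states, conducting subset and a rate builder
    ``rates(V, Cai)`` -> (batch, n_states, n_states) array of transition
    rates (entry [i, j] is the rate from state i to state j, 1/ms, at the
    source temperature)."""

    states: tuple
    conducting: tuple
    rates: Callable

    @property
    def n(self) -> int:
        return len(self.states)

    def generator(self, V, Cai, qt: float = 1.0):
        """Column-convention generator G (dp/dt = G @ p), batched over the
        leading axis of V."""
        R = self.rates(np.atleast_1d(np.asarray(V, dtype=float)),
                       np.atleast_1d(np.asarray(Cai, dtype=float))) * qt
        G = np.swapaxes(R, -1, -2).copy()
        diag = np.einsum("...ij->...i", R)  # total exit rate per state
        idx = np.arange(self.n)
        G[..., idx, idx] -= diag
        return G

    def conducting_index(self):
        return np.array([self.states.index(s) for s in self.conducting])


def markov_steady_state(scheme: MarkovScheme, V: float, Cai: float = CA_REST,
                        qt: float = 1.0):
    """Stationary occupancy of a Markov scheme at fixed (V, Cai).

    Solves G p = 0 with sum(p) = 1 (least squares on the bordered system);
    raises when the chain is numerically reducible at this operating point.
    """
    G = scheme.generator(V, Cai, qt)[0]
    n = scheme.n
    A = np.vstack([G, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(p < -1e-8):
        raise ValueError("reducible or ill-conditioned chain at this (V, Ca)")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


# ---------------------------------------------------------------------------
# channel specification
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """A channel: kinetics + placement + maximum conductance + reversal.

    ``erev`` is either a fixed potential in mV or the policy string
    ``"ca_ghk"`` (reversal updated from the GHK relation each step).
    ``gmax_by_region`` maps region tags to S/cm^2; unlisted regions carry
    none of the channel.
    """

    name: str
    gates: list = field(default_factory=list)
    markov: MarkovScheme | None = None
    gmax_by_region: dict = field(default_factory=dict)
    erev: float | str = E_K
    t_exp: float = 22.0
    ca_dependent: bool = False

    def qt(self, t_sim: float = T_SIM_DEFAULT) -> float:
        return Q10 ** ((t_sim - self.t_exp) / 10.0)

    def gmax_in(self, tag: RegionTag) -> float:
        return self.gmax_by_region.get(tag, 0.0)

    # -- steady state -----------------------------------------------------
    def gate_steady_state(self, V, Cai=CA_REST) -> dict:
        """Per-gate x_inf values (HH channels)."""
        return {g.name: g.inf_tau(V, Cai)[0] for g in self.gates}

    def open_fraction_steady(self, V, Cai=CA_REST):
        """Steady-state open fraction at (V, Cai)."""
        if self.markov is not None:
            p = markov_steady_state(self.markov, V, Cai)
            return float(p[self.markov.conducting_index()].sum())
        out = 1.0
        for g in self.gates:
            inf, _ = g.inf_tau(V, Cai)
            out = out * inf ** g.exponent
        return out


def gate_steady_state(spec: ChannelSpec, V, Cai=CA_REST) -> dict:
    """Module-level mirror of ``spec.gate_steady_state``."""
    return spec.gate_steady_state(V, Cai)


def channel_current(spec: ChannelSpec, V, open_fraction, area_cm2: float,
                    Cai=CA_REST, region: RegionTag = RegionTag.SOMA,
                    erev: float | None = None):
    """Ohmic channel current in nA (outward positive).

    I = gmax * area * open_fraction * (V - Erev); for the ``ca_ghk`` policy
    the reversal is evaluated from ``Cai`` unless ``erev`` overrides it.
    """
    if erev is None:
        erev = ghk_ca_reversal(Cai) if spec.erev == "ca_ghk" else spec.erev
    g = spec.gmax_in(region) * area_cm2 * np.asarray(open_fraction)
    return g * (np.asarray(V) - erev) * 1e6  # S*mV -> nA


# ---------------------------------------------------------------------------
# individual channels
# ---------------------------------------------------------------------------

def _dend(g):
    return {t: g for t in DENDRITE_TAGS}


def nav16() -> ChannelSpec:
    """Resurgent sodium channel: 13-state Markov scheme (5 closed, 6
    inactivated, open, open-blocked).  Unbinding of the open-blocked state
    on repolarization produces the resurgent current component; the
    closed-open pathway carries the transient and persistent components.
    Placed in AIS, nodes, collateral, soma and the main dendritic trunk.
    """
    states = ("C1", "C2", "C3", "C4", "C5", "O", "B",
              "I1", "I2", "I3", "I4", "I5", "I6")
    Con, Coff = 0.005, 0.5
    Oon, Ooff = 0.75, 0.005
    alfac = (Oon / Con) ** 0.25
    btfac = (Ooff / Coff) ** 0.25

    def rates(V, Cai):
        n = V.shape[0]
        a = 150.0 * np.exp(V / 20.0)
        b = 3.0 * np.exp(-V / 20.0)
        zeta = 0.03 * np.exp(-V / 25.0)
        R = np.zeros((n, 13, 13))
        ci = [0, 1, 2, 3, 4]      # C1..C5
        ii = [7, 8, 9, 10, 11]    # I1..I5  (I6 at 12)
        for k in range(4):
            R[:, ci[k], ci[k + 1]] = (4 - k) * a
            R[:, ci[k + 1], ci[k]] = (k + 1) * b
            R[:, ii[k], ii[k + 1]] = (4 - k) * a * alfac
            R[:, ii[k + 1], ii[k]] = (k + 1) * b * btfac
        for k in range(5):
            R[:, ci[k], ii[k]] = Con * alfac ** k
            R[:, ii[k], ci[k]] = Coff * btfac ** k
        R[:, 4, 5] = 150.0   # C5 -> O  (gamma)
        R[:, 5, 4] = 40.0    # O  -> C5 (delta)
        R[:, 5, 6] = 1.75    # O  -> B  (epsilon)
        R[:, 6, 5] = zeta    # B  -> O
        R[:, 5, 12] = 0.75   # O  -> I6 (Oon)
        R[:, 12, 5] = 0.005  # I6 -> O  (Ooff)
        R[:, 11, 12] = a * alfac  # I5 -> I6
        R[:, 12, 11] = b * btfac
        return R

    scheme = MarkovScheme(states, ("O",), rates)
    return ChannelSpec(
        "Nav1.6", markov=scheme, erev=E_NA, t_exp=22.0,
        gmax_by_region={RegionTag.TRUNK: 0.016, RegionTag.SOMA: 0.214,
                        RegionTag.AIS: 0.5, RegionTag.NODE: 0.03,
                        RegionTag.COLLATERAL: 0.03})


def kv11() -> ChannelSpec:
    def n_rates(V, Cai):
        a = 0.12889 * np.exp((V + 45.0) / 33.90877)
        b = 0.12889 * np.exp(-(V + 45.0) / 12.42101)
        return a, b

    return ChannelSpec(
        "Kv1.1", gates=[HHGate("n", 4, "alpha_beta", n_rates)],
        erev=E_K, t_exp=22.0,
        gmax_by_region={**_dend(0.0012), RegionTag.SOMA: 0.002,
                        RegionTag.PARA_AIS: 0.01})


def kv15() -> ChannelSpec:
    """Ultrarapid delayed rectifier with fast and slow inactivation."""

    def n_gate(V, Cai):
        a = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
        b = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
        inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
        tau = 1.0 / (3.0 * (a + b))
        return inf, tau

    def uf_gate(V, Cai):
        a = 0.001 / (2.4 + 10.9 * np.exp(-(V + 90.0) / 78.0))
        b = 0.001 * np.exp((V - 168.0) / 16.0)
        inf = 0.25 + 1.0 / (1.35 + np.exp((V + 7.0) / 14.0))
        tau = 1.0 / (3.0 * (a + b))
        return inf, tau

    def us_gate(V, Cai):
        inf = np.minimum(0.1 + 1.0 / (1.1 + np.exp((V + 7.0) / 14.0)), 1.0)
        return inf, np.full_like(np.asarray(V, dtype=float), 6800.0)

    return ChannelSpec(
        "Kv1.5",
        gates=[HHGate("n", 3, "inf_tau", n_gate),
               HHGate("uf", 1, "inf_tau", uf_gate),
               HHGate("us", 1, "inf_tau", us_gate)],
        erev=E_K, t_exp=22.0, gmax_by_region=_dend(1.3e-4))


def kv33() -> ChannelSpec:
    def n_rates(V, Cai):
        a = 0.22 * np.exp((V + 16.0) / 26.5)
        b = 0.22 * np.exp(-(V + 16.0) / 26.5)
        return a, b

    return ChannelSpec(
        "Kv3.3", gates=[HHGate("n", 4, "alpha_beta", n_rates)],
        erev=E_K, t_exp=22.0, gmax_by_region=_dend(0.01))


def kv34() -> ChannelSpec:
    """Fast-activating, partially inactivating axo-somatic K current; the
    main spike-repolarizing and axonal frequency-filtering conductance."""

    def m_gate(V, Cai):
        V = np.asarray(V, dtype=float)
        inf = 1.0 / (1.0 + np.exp(-(V + 24.0) / 15.4))
        tau_s = np.where(
            V < -35.0,
            (3.4225e-5 + 4.98e-3 * np.exp(V / 28.29)) * 3.0,
            1.2851e-4 + 1.0 / (np.exp((V + 100.7) / 12.9)
                               + np.exp(-(V - 56.0) / 23.1)))
        return inf, tau_s * 1e3

    def h_gate(V, Cai):
        V = np.asarray(V, dtype=float)
        inf = 0.31 + 0.69 / (1.0 + np.exp((V + 5.802) / 11.2))
        tau_s = np.where(
            V > 0.0,
            1.2e-3 + 2.3e-3 * np.exp(-0.141 * V),
            1.2202e-5 + 0.012 * np.exp(-((V + 56.3) / 49.62) ** 2))
        return inf, tau_s * 1e3

    return ChannelSpec(
        "Kv3.4",
        gates=[HHGate("m", 3, "inf_tau", m_gate),
               HHGate("h", 1, "inf_tau", h_gate)],
        erev=E_K, t_exp=22.0,
        gmax_by_region={RegionTag.SOMA: 0.05, RegionTag.AIS: 0.01,
                        RegionTag.NODE: 0.01, RegionTag.COLLATERAL: 0.02})


def kv43() -> ChannelSpec:
    """Dendritic A-type current (granule-cell kinetics)."""

    def a_rates(V, Cai):
        a = 0.8147 / (1.0 + np.exp((V + 9.17203) / -23.32708))
        b = 0.1655 * np.exp(-(V + 18.27914) / 19.47175)
        return a, b

    def b_rates(V, Cai):
        a = 0.0368 / (1.0 + np.exp((V + 111.33209) / 12.8433))
        b = 0.0345 / (1.0 + np.exp((V + 49.9537) / -8.90123))
        return a, b

    return ChannelSpec(
        "Kv4.3",
        gates=[HHGate("a", 2, "alpha_beta", a_rates),
               HHGate("b", 1, "alpha_beta", b_rates)],
        erev=E_K, t_exp=25.5, gmax_by_region=_dend(0.001))


def kir2x() -> ChannelSpec:
    def d_rates(V, Cai):
        a = 0.13289 * np.exp(-(V + 83.94) / 24.3902)
        b = 0.16994 * np.exp((V + 83.94) / 35.714)
        return a, b

    return ChannelSpec(
        "Kir2.x", gates=[HHGate("d", 1, "alpha_beta", d_rates)],
        erev=E_K, t_exp=20.0,
        gmax_by_region={**_dend(1e-5), RegionTag.SOMA: 3e-5})


def kca11() -> ChannelSpec:
    """Large-conductance Ca- and voltage-dependent K channel (BK).

    10-state Monod-Wyman-Changeux Markov scheme: five closed and five open
    states indexed by the number of bound Ca ions (0-4).  Binding is ten
    times tighter in the open tier, and the closed-open equilibrium is
    voltage dependent (~19 mV per e-fold).  Parameters are calibrated so
    the channel is silent at the 45 nM resting point and activates during
    spikes once submembrane Ca reaches the micromolar range.
    """
    kon = 100.0                # 1/(mM*ms)
    kd_c, kd_o = 0.003, 0.0003  # mM
    kv = 19.0                  # mV per e-fold of the open-close equilibrium
    a0, b0 = 6.0, 300.0        # opening/closing base rates at 0 mV
    states = tuple(f"C{i}" for i in range(5)) + tuple(f"O{i}" for i in range(5))

    def rates(V, Cai):
        n = V.shape[0]
        ca = np.broadcast_to(np.asarray(Cai, dtype=float), (n,))
        R = np.zeros((n, 10, 10))
        for i in range(4):
            R[:, i, i + 1] = (4 - i) * kon * ca
            R[:, i + 1, i] = (i + 1) * kon * kd_c
            R[:, 5 + i, 5 + i + 1] = (4 - i) * kon * ca
            R[:, 5 + i + 1, 5 + i] = (i + 1) * kon * kd_o
        ratio = kd_c / kd_o
        ev = np.exp(V / (2.0 * kv))
        for i in range(5):
            R[:, i, 5 + i] = a0 * ratio ** (i / 2.0) * ev
            R[:, 5 + i, i] = b0 * ratio ** (-i / 2.0) / ev
        return R

    scheme = MarkovScheme(states, tuple(f"O{i}" for i in range(5)), rates)
    return ChannelSpec(
        "KCa1.1", markov=scheme, erev=E_K, t_exp=37.0, ca_dependent=True,
        gmax_by_region={**_dend(3.5e-2), RegionTag.SOMA: 0.01})


def kca22() -> ChannelSpec:
    """Small-conductance Ca-activated K channel (SK2): 6-state Markov chain
    (4 closed, 2 open) with Ca-dependent forward binding."""
    states = ("C1", "C2", "C3", "C4", "O1", "O2")
    dirc2, dirc3, dirc4 = 200.0, 160.0, 80.0     # 1/(mM*ms)
    invc1, invc2, invc3 = 0.08, 0.08, 0.2        # 1/ms
    diro1, diro2 = 0.16, 1.2
    invo1, invo2 = 1.0, 0.1

    def rates(V, Cai):
        n = V.shape[0]
        ca = np.broadcast_to(np.asarray(Cai, dtype=float), (n,))
        R = np.zeros((n, 6, 6))
        R[:, 0, 1] = dirc2 * ca
        R[:, 1, 0] = invc1
        R[:, 1, 2] = dirc3 * ca
        R[:, 2, 1] = invc2
        R[:, 2, 3] = dirc4 * ca
        R[:, 3, 2] = invc3
        R[:, 2, 4] = diro1
        R[:, 4, 2] = invo1
        R[:, 3, 5] = diro2
        R[:, 5, 3] = invo2
        return R

    scheme = MarkovScheme(states, ("O1", "O2"), rates)
    return ChannelSpec(
        "KCa2.2", markov=scheme, erev=E_K, t_exp=23.0, ca_dependent=True,
        gmax_by_region={**_dend(1e-3), RegionTag.SOMA: 1e-3})


def kca31() -> ChannelSpec:
    """Intermediate-conductance Ca-activated K channel; a single gate whose
    opening rate carries both the voltage and the Ca dependence (saturating
    above 10 uM)."""

    def y_gate(V, Cai):
        ca = np.asarray(Cai, dtype=float)
        x = np.clip(0.015 - ca, 0.005, None)  # mM
        concdep = 500.0 * x / (np.exp(x / 0.0013) - 1.0)
        a = concdep * np.exp((V + 70.0) / 27.0)
        b = 0.05
        return a / (a + b), 1.0 / (a + b)

    return ChannelSpec(
        "KCa3.1", gates=[HHGate("y", 1, "inf_tau", y_gate)],
        erev=E_K, t_exp=37.0, ca_dependent=True,
        gmax_by_region={**_dend(0.002), RegionTag.SOMA: 0.01})


def cav21() -> ChannelSpec:
    """High-voltage-activated P-type Ca channel (half-activation -29.5 mV,
    slope 8.5 mV); the dominant dendritic Ca source."""

    def m_gate(V, Cai):
        V = np.asarray(V, dtype=float)
        inf = 1.0 / (1.0 + np.exp(-(V + 29.5) / 8.5))
        tau = np.where(
            V >= -40.0,
            0.2702 + 1.1622 * np.exp(-(V + 26.798) ** 2 / 164.19),
            0.6923 * np.exp(V / 1089.372))
        return inf, tau

    return ChannelSpec(
        "Cav2.1", gates=[HHGate("m", 1, "inf_tau", m_gate)],
        erev="ca_ghk", t_exp=37.0,
        gmax_by_region={**_dend(1e-3), RegionTag.SOMA: 2.2e-4,
                        RegionTag.AIS: 2.2e-4, RegionTag.NODE: 2.2e-4,
                        RegionTag.COLLATERAL: 2.2e-4})


def cav31() -> ChannelSpec:
    """T-type (low-voltage-activated) Ca channel, Purkinje variant."""

    def m_gate(V, Cai):
        inf = 1.0 / (1.0 + np.exp(-(V + 52.0) / 5.0))
        tau = 1.0 + 1.0 / (np.exp((V + 40.0) / 9.0)
                           + np.exp(-(V + 102.0) / 18.0))
        return inf, tau

    def h_gate(V, Cai):
        inf = 1.0 / (1.0 + np.exp((V + 72.0) / 7.0))
        tau = 15.0 + np.exp(-(V + 32.0) / 7.0)
        return inf, tau

    return ChannelSpec(
        "Cav3.1",
        gates=[HHGate("m", 2, "inf_tau", m_gate),
               HHGate("h", 1, "inf_tau", h_gate)],
        erev="ca_ghk", t_exp=37.0,
        gmax_by_region={**_dend(5e-6), RegionTag.SOMA: 7e-6,
                        RegionTag.AIS: 1e-5, RegionTag.NODE: 1e-5,
                        RegionTag.COLLATERAL: 1e-5})


def cav32() -> ChannelSpec:
    """T-type Ca channel, thalamic kinetics (the earliest-activating of the
    three LVA variants)."""

    def m_gate(V, Cai):
        inf = 1.0 / (1.0 + np.exp(-(V + 54.8) / 7.4))
        tau = 1.9 + 1.0 / (np.exp((V + 37.0) / 11.9)
                           + np.exp(-(V + 131.6) / 21.0))
        return inf, tau

    def h_gate(V, Cai):
        V = np.asarray(V, dtype=float)
        inf = 1.0 / (1.0 + np.exp((V + 85.5) / 7.18))
        # canonical thalamic-relay recovery: slow e-fold below -80 mV,
        # fast saturating branch above
        tau = np.where(V < -80.0,
                       np.exp((V + 467.0) / 66.6),
                       28.0 + np.exp(-(V + 22.0) / 10.5))
        return inf, tau

    return ChannelSpec(
        "Cav3.2",
        gates=[HHGate("m", 2, "inf_tau", m_gate),
               HHGate("h", 1, "inf_tau", h_gate)],
        erev="ca_ghk", t_exp=24.0,
        gmax_by_region={**_dend(0.0012), RegionTag.SOMA: 0.0008})


def cav33() -> ChannelSpec:
    """T-type Ca channel, slow (CA3-pyramidal kinetics); the latest-
    activating LVA variant."""

    def n_gate(V, Cai):
        V = np.asarray(V, dtype=float)
        inf = 1.0 / (1.0 + np.exp(-(V + 41.5) / 6.2))
        tau = np.where(V > -60.0,
                       7.2 + 0.02 * np.exp(-V / 14.7),
                       0.875 * np.exp((V + 120.0) / 41.0))
        return inf, tau

    def l_gate(V, Cai):
        V = np.asarray(V, dtype=float)
        inf = 1.0 / (1.0 + np.exp((V + 69.8) / 6.1))
        tau = np.where(V > -60.0,
                       79.5 + 2.0 * np.exp(-V / 9.3),
                       260.0)
        return inf, tau

    return ChannelSpec(
        "Cav3.3",
        gates=[HHGate("n", 2, "inf_tau", n_gate),
               HHGate("l", 1, "inf_tau", l_gate)],
        erev="ca_ghk", t_exp=21.0,
        gmax_by_region={**_dend(1e-4), RegionTag.SOMA: 1e-4})


def hcn1() -> ChannelSpec:
    """Hyperpolarization-activated cationic current (layer-5 kinetics)."""

    def h_rates(V, Cai):
        a = 0.0018 * np.exp(-(V + 58.7) / 22.0)
        b = 0.0018 * np.exp((V + 58.7) / 7.14)
        return a, b

    return ChannelSpec(
        "HCN1", gates=[HHGate("h", 1, "alpha_beta", h_rates)],
        erev=E_HCN, t_exp=35.0,
        gmax_by_region={**_dend(4e-6), RegionTag.SOMA: 4e-4})


def trp(gmax_dend: float = 0.0) -> ChannelSpec:
    """TRP-like background cationic leak (0 mV reversal); placed in the
    dendrites to emulate the high-rate (Z-) firing phenotype."""
    return ChannelSpec("TRP", gates=[], erev=E_TRP, t_exp=37.0,
                       gmax_by_region=_dend(gmax_dend))


_FACTORIES = (nav16, kv11, kv15, kv33, kv34, kv43, kir2x,
              kca11, kca22, kca31, cav21, cav31, cav32, cav33, hcn1)


def build_default_channelome() -> list:
    """The 15 canonical channel specifications with their default placements
    and maximum conductances.  ParaAIS carries only Kv1.1; myelinated
    internodes carry no channels at all."""
    return [f() for f in _FACTORIES]


def get_channel(chans: list, name: str) -> ChannelSpec:
    for c in chans:
        if c.name.lower() == name.lower():
            return c
    raise KeyError(name)
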