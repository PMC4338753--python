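"""Implicit integration of the coupled compartmental system.

Membrane voltage obeys, per compartment,

    Cm dV/dt = -[ sum_i g_i (V - E_i) + g_leak (V - E_leak) ] + I_axial + I_inj

with axial coupling through cylindrical axoplasm resistances over the
branched tree.  One time step performs, in order: (1) channel state update
(exponential Euler for Hodgkin-Huxley gates, backward Euler on the master
equation for Markov chains), (2) a backward-Euler voltage solve over the
tree by leaf-to-root elimination and root-to-leaf back-substitution (Hines
ordering) with conductances frozen at their post-gate-update values,
(3) the calcium shell update driven by the new Ca currents and (4) the GHK
refresh of the calcium reversal potential.

For speed, voltage-dependent gate kinetics and Markov rate entries are
tabulated on a fine voltage grid at initialization (the rate tables are
probed from the channel specifications themselves, so the tables cannot
drift from the reference kinetics), and all gates of all channels advance
in a single fused array operation.  The tree solve is JIT-compiled when
numba is importable and falls back to pure Python otherwise.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import channels as ch
from .calcium import CalciumField, CA_REST_DEFAULT
from .morphology import (Morphology, PassiveParams, RegionTag, DENDRITE_TAGS,
                         build_cell, _topo_order)

try:  # optional JIT for the tree solve
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

V_GUARD = 200.0  # mV; divergence guard
_VGRID = np.arange(-130.0, 80.0 + 1e-9, 0.05)


class SimulationDiverged(RuntimeError):
    """Voltage exceeded the divergence guard."""


# ---------------------------------------------------------------------------
# compartment grid and axial coupling
# ---------------------------------------------------------------------------

@dataclass
class CompartmentGrid:
    """Flat arrays describing the discretized cell (one row per
    compartment, parents-first ordering so parent index < child index)."""

    sec_id: np.ndarray
    tag: list
    diam: np.ndarray
    length: np.ndarray
    area: np.ndarray        # um^2
    parent: np.ndarray      # compartment index, -1 for root
    g_parent: np.ndarray    # uS to parent (0 for root)
    cm: np.ndarray          # nF
    g_leak: np.ndarray      # uS
    e_leak: float

    @property
    def n(self) -> int:
        return self.diam.size

    def comp_of(self, sec_id: int, pos: float = 0.5) -> int:
        idx = np.nonzero(self.sec_id == sec_id)[0]
        if idx.size == 0:
            raise KeyError(f"section {sec_id} not in grid")
        k = min(int(pos * idx.size), idx.size - 1)
        return int(idx[k])


def build_grid(m: Morphology, p: PassiveParams) -> CompartmentGrid:
    """Discretize a morphology into compartments with passive properties
    and axial coupling conductances."""
    order = _topo_order(m)
    secs, tags, diam, length, parent = [], [], [], [], []
    last_comp_of_sec = {}
    for s in order:
        for k in range(s.n_compartments):
            if k == 0:
                par = last_comp_of_sec.get(s.parent_id, -1)
            else:
                par = len(diam) - 1
            secs.append(s.id)
            tags.append(s.tag)
            diam.append(s.diameter)
            length.append(s.length / s.n_compartments)
            parent.append(par)
        last_comp_of_sec[s.id] = len(diam) - 1
    diam = np.array(diam)
    length = np.array(length)
    parent = np.array(parent, dtype=np.int64)
    area = np.pi * diam * length
    # half-compartment axial resistance in Ohm
    r_half = p.ra * length / (2.0 * np.pi * (diam / 2.0) ** 2) * 1e4
    g_parent = np.zeros(diam.size)
    for i in range(diam.size):
        if parent[i] >= 0:
            g_parent[i] = 1e6 / (r_half[i] + r_half[parent[i]])
    cm = np.array([p.cm_of(t) for t in tags]) * area * 1e-5           # nF
    g_leak = np.array([p.g_leak_of(t) for t in tags]) * area * 1e-2   # uS
    return CompartmentGrid(np.array(secs), tags, diam, length, area,
                           parent, g_parent, cm, g_leak, p.e_leak)


def assemble_coupling(m: Morphology, p: PassiveParams):
    """Axial coupling as a symmetric sparse matrix (uS) over compartments.

    Off-diagonal entry (i, j) is the conductance between adjacent
    compartments; the sparsity pattern is the tree of the morphology.
    """
    from scipy.sparse import coo_matrix
    grid = build_grid(m, p)
    rows, cols, vals = [], [], []
    for i in range(grid.n):
        j = grid.parent[i]
        if j >= 0:
            rows += [i, j]
            cols += [j, i]
            vals += [grid.g_parent[i], grid.g_parent[i]]
    return coo_matrix((vals, (rows, cols)), shape=(grid.n, grid.n)).tocsr(), grid


# ---------------------------------------------------------------------------
# tree solve
# ---------------------------------------------------------------------------

def _hines_py(parent, gpar, d, rhs):
    n = d.size
    for i in range(n - 1, 0, -1):
        p = parent[i]
        g = gpar[i]
        f = g * g / d[i]
        d[p] -= f
        rhs[p] += g * rhs[i] / d[i]
    v = np.empty(n)
    v[0] = rhs[0] / d[0]
    for i in range(1, n):
        v[i] = (rhs[i] + gpar[i] * v[parent[i]]) / d[i]
    return v


def _markov_be_py(vals, ei, ej, p, dt):
    n = p.shape[1]
    m = vals.shape[0]
    R = np.zeros((m, n, n))
    R[:, ei, ej] = vals
    G = np.swapaxes(R, 1, 2).copy()
    ii = np.arange(n)
    G[:, ii, ii] -= np.einsum("cij->ci", R)
    M = np.eye(n)[None] - dt * G
    p[:] = np.linalg.solve(M, p[..., None])[..., 0]
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _markov_be_nb(vals, ei, ej, p, dt):  # pragma: no cover - numba path
    m, nent = vals.shape
    n = p.shape[1]
    M = np.empty((n, n))
    rhs = np.empty(n)
    for c in range(m):
        for i in range(n):
            for j in range(n):
                M[i, j] = 0.0
            M[i, i] = 1.0
        for e in range(nent):
            r = vals[c, e] * dt
            i = ei[e]
            j = ej[e]
            M[j, i] -= r
            M[i, i] += r
        for i in range(n):
            rhs[i] = p[c, i]
        for k in range(n - 1):
            piv = M[k, k]
            for i in range(k + 1, n):
                f = M[i, k] / piv
                if f != 0.0:
                    for j in range(k + 1, n):
                        M[i, j] -= f * M[k, j]
                    rhs[i] -= f * rhs[k]
        for i in range(n - 1, -1, -1):
            ssum = rhs[i]
            for j in range(i + 1, n):
                ssum -= M[i, j] * p[c, j]
            p[c, i] = ssum / M[i, i]
        tot = 0.0
        for i in range(n):
            if p[c, i] < 0.0:
                p[c, i] = 0.0
            tot += p[c, i]
        for i in range(n):
            p[c, i] /= tot
    return p


if _HAVE_NUMBA:
    _hines = njit(cache=True)(_hines_py)
    _markov_be = njit(cache=True)(_markov_be_nb)
else:  # pragma: no cover
    _hines = _hines_py
    _markov_be = _markov_be_py


# ---------------------------------------------------------------------------
# stimulation
# ---------------------------------------------------------------------------

@dataclass
class StimulusSource:
    """A located current source: ``waveform(t_ms) -> nA`` injected at
    (section, pos)."""

    section: int | str
    pos: float
    waveform: object

    @classmethod
    def step(cls, section, amplitude: float, onset: float, offset: float,
             pos: float = 0.5) -> "StimulusSource":
        def wf(t):
            t = np.asarray(t, dtype=float)
            return np.where((t >= onset) & (t < offset), amplitude, 0.0)
        return cls(section, pos, wf)

    @classmethod
    def ramp(cls, section, start_amp: float, peak_amp: float, end_amp: float,
             t_start: float, t_peak: float, t_end: float,
             pos: float = 0.5) -> "StimulusSource":
        """Piecewise-linear double ramp (rise then fall); zero outside."""
        def wf(t):
            t = np.asarray(t, dtype=float)
            up = start_amp + (peak_amp - start_amp) * (t - t_start) \
                / max(t_peak - t_start, 1e-9)
            down = peak_amp + (end_amp - peak_amp) * (t - t_peak) \
                / max(t_end - t_peak, 1e-9)
            out = np.where(t < t_peak, up, down)
            return np.where((t >= t_start) & (t < t_end), out, 0.0)
        return cls(section, pos, wf)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

class TraceSet:
    """Recorded quantities at chosen sites, uniformly sampled."""

    def __init__(self, t: np.ndarray, data: dict, meta: dict | None = None):
        self.t = t
        self.data = data
        self.meta = meta or {}

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    def keys(self):
        return self.data.keys()

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    def to_csv(self, path) -> None:
        names = list(self.data.keys())
        arr = np.column_stack([self.t] + [self.data[k] for k in names])
        np.savetxt(path, arr, delimiter=",",
                   header=",".join(["t_ms"] + names), comments="")

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("t_ms", data=self.t)
            for k, v in self.data.items():
                f.create_dataset(k, data=v)
            for k, v in self.meta.items():
                f.attrs[k] = json.dumps(v) if isinstance(v, (dict, list)) else v


# ---------------------------------------------------------------------------
# the model: morphology + passive + channel table
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation controls: fixed time step (ms), temperature (degC),
    duration (ms), record sites (site name or (section, pos) with a
    quantity 'v' | 'cai'), initial voltage and recording decimation."""

    dt: float = 0.025
    temperature: float = 37.0
    duration: float = 1000.0
    record: list = field(default_factory=lambda: [("soma", "v")])
    v_init: float = -65.0
    decim: int = 1
    pump_on: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class Model:
    """A concrete cell: morphology + passive parameters + channel table.

    Edits (conductance scalings, knockouts, structural removals) always
    return a *new* model; the original is never mutated, which makes every
    protocol's edits trivially reversible.
    """

    def __init__(self, morphology: Morphology, passive: PassiveParams,
                 channel_specs: list, t_sim: float = 37.0):
        self.morphology = morphology
        self.passive = passive
        self.channels = channel_specs
        self.t_sim = t_sim
        self.grid = build_grid(morphology, passive)

    # -- construction -----------------------------------------------------
    @classmethod
    def canonical(cls, n_dend: int = 48, seed: int = 1,
                  passive: PassiveParams | None = None,
                  t_sim: float = 37.0) -> "Model":
        """The default cell: Table-specified axon + soma, surrogate
        dendrites (desk scale by default; pass ``n_dend=1599`` for the
        full-scale tree), canonical channel placements."""
        p = passive or PassiveParams()
        m = build_cell(n_dend=n_dend, seed=seed, passive=p)
        return cls(m, p, ch.build_default_channelome(), t_sim=t_sim)

    # -- edits ------------------------------------------------------------
    def with_edits(self, edits: list) -> "Model":
        """Return a copy with (channel, region-or-None, scale) applied;
        scale 0 is a knockout.  ``region=None`` scales everywhere."""
        specs = copy.deepcopy(self.channels)
        for name, region, scale in edits:
            spec = ch.get_channel(specs, name)
            if region is None:
                for r in list(spec.gmax_by_region):
                    spec.gmax_by_region[r] *= scale
            else:
                regions = DENDRITE_TAGS if region == "dendrites" \
                    else [RegionTag(region) if not isinstance(region, RegionTag)
                          else region]
                for r in regions:
                    if r in spec.gmax_by_region:
                        spec.gmax_by_region[r] = spec.gmax_by_region[r] * scale
        return Model(self.morphology, self.passive, specs, self.t_sim)

    def with_channel(self, spec) -> "Model":
        """Return a copy with an extra channel specification appended."""
        return Model(self.morphology, self.passive,
                     copy.deepcopy(self.channels) + [spec], self.t_sim)

    def without_dendrites(self) -> "Model":
        """Return a copy with the dendritic tree removed (soma + axon)."""
        keep = [s for s in self.morphology.sections
                if s.tag not in DENDRITE_TAGS]
        m = Morphology(copy.deepcopy(keep),
                       {**self.morphology.metadata, "dendrites": "removed"})
        return Model(m, self.passive, copy.deepcopy(self.channels), self.t_sim)

    def table_hash(self) -> str:
        """Digest of the (channel, region, gmax, erev) table plus the
        morphology; protocols assert it unchanged after a run."""
        rows = []
        for c in self.channels:
            for r, g in sorted(c.gmax_by_region.items(), key=lambda kv: kv[0].value):
                rows.append((c.name, r.value, repr(g), repr(c.erev)))
        blob = json.dumps(rows) + self.morphology.to_json()
        return hashlib.sha256(blob.encode()).hexdigest()

    # -- site resolution --------------------------------------------------
    def resolve_site(self, site) -> int:
        """Map a site spec to a compartment index.  Site names: 'soma',
        'AIS', 'paraAIS', 'node1'..'node3', 'collateral', 'trunk',
        'principal', 'terminal' (most distal by path length); or a tuple
        (section_id, pos)."""
        if isinstance(site, tuple):
            return self.grid.comp_of(site[0], site[1])
        name = str(site)
        m = self.morphology
        if name == "soma":
            return self.grid.comp_of(m.with_tag(RegionTag.SOMA)[0].id)
        if name == "AIS":
            return self.grid.comp_of(m.with_tag(RegionTag.AIS)[0].id)
        if name == "paraAIS":
            return self.grid.comp_of(m.with_tag(RegionTag.PARA_AIS)[0].id)
        if name.startswith("node"):
            k = int(name[4:]) - 1
            return self.grid.comp_of(m.with_tag(RegionTag.NODE)[k].id)
        if name == "collateral":
            return self.grid.comp_of(m.with_tag(RegionTag.COLLATERAL)[-1].id)
        tagmap = {"trunk": RegionTag.TRUNK, "principal": RegionTag.PRINCIPAL,
                  "terminal": RegionTag.TERMINAL}
        if name in tagmap:
            secs = m.with_tag(tagmap[name])
            soma_id = m.with_tag(RegionTag.SOMA)[0].id
            far = max(secs, key=lambda s: m.path_length(soma_id, s.id))
            return self.grid.comp_of(far.id)
        raise KeyError(f"unknown site {site!r}")


# ---------------------------------------------------------------------------
# runtime kernels (JIT-compiled when numba is available)
# ---------------------------------------------------------------------------

def _gates_update_py(x, ent_tab, ent_comp, v, tab_inf, tab_efac, v0, dv):
    """Fused exponential-Euler update of all table-driven gates."""
    hi = tab_inf.shape[1] - 1.001
    for e in range(x.size):
        pos = (v[ent_comp[e]] - v0) / dv
        if pos < 0.0:
            pos = 0.0
        elif pos > hi:
            pos = hi
        i0 = int(pos)
        w = pos - i0
        k = ent_tab[e]
        inf = tab_inf[k, i0] * (1.0 - w) + tab_inf[k, i0 + 1] * w
        ef = tab_efac[k, i0] * (1.0 - w) + tab_efac[k, i0 + 1] * w
        x[e] = inf + (x[e] - inf) * ef


def _hh_conduct_py(x, ent0, nc, ng, exps, cstart, ccomp, cgbar, erev, isca,
                   erev_ca, gtot, ge, gca, gece):
    """Per-channel open fractions -> conductance scatter into the
    accumulators (gca/gece collect the Ca-channel terms separately so the
    post-solve Ca current is sum(gca*V - gece))."""
    for c in range(ent0.size):
        n = nc[c]
        for i in range(n):
            o = 1.0
            for g in range(ng[c]):
                xv = x[ent0[c] + g * n + i]
                for _r in range(exps[c, g]):
                    o *= xv
            gcond = cgbar[cstart[c] + i] * o
            comp = ccomp[cstart[c] + i]
            gtot[comp] += gcond
            if isca[c] == 1:
                e = erev_ca[comp]
                ge[comp] += gcond * e
                gca[comp] += gcond
                gece[comp] += gcond * e
            else:
                ge[comp] += gcond * erev[c]


def _markov_step_py(A_tab, B_tab, ei, ej, p, v, ca, comp, gbar, dtqt, dt,
                    v0, dv, cond, isca, erevval, erev_ca, gtot, ge, gca,
                    gece, bw):
    """Backward-Euler master-equation step for one Markov channel on all of
    its compartments, with fused rate-table interpolation and conductance
    scatter.  Rates are R = (A(V) + B(V)*Ca) * qt.  States are pre-permuted
    (reverse Cuthill-McKee) so the system is banded with half bandwidth
    ``bw``; the elimination works on the band only."""
    m = comp.size
    n = p.shape[1]
    nent = ei.size
    hi = A_tab.shape[0] - 1.001
    width = 2 * bw + 1
    Mb = np.empty((n, width))
    rhs = np.empty(n)
    for c in range(m):
        cc = comp[c]
        pos = (v[cc] - v0) / dv
        if pos < 0.0:
            pos = 0.0
        elif pos > hi:
            pos = hi
        i0 = int(pos)
        w = pos - i0
        for i in range(n):
            for j in range(width):
                Mb[i, j] = 0.0
            Mb[i, bw] = 1.0
        cai = ca[cc]
        for e in range(nent):
            val = (A_tab[i0, e] * (1.0 - w) + A_tab[i0 + 1, e] * w
                   + (B_tab[i0, e] * (1.0 - w) + B_tab[i0 + 1, e] * w)
                   * cai) * dtqt
            i = ei[e]
            j = ej[e]
            Mb[j, i - j + bw] -= val      # -dt*G[j, i]
            Mb[i, bw] += val              # exit rate on the diagonal
        for i in range(n):
            rhs[i] = p[c, i]
        for k in range(n - 1):
            piv = Mb[k, bw]
            imax = k + bw
            if imax > n - 1:
                imax = n - 1
            for i in range(k + 1, imax + 1):
                f = Mb[i, k - i + bw] / piv
                if f != 0.0:
                    jmax = k + bw
                    if jmax > n - 1:
                        jmax = n - 1
                    for j in range(k, jmax + 1):
                        Mb[i, j - i + bw] -= f * Mb[k, j - k + bw]
                    rhs[i] -= f * rhs[k]
        for i in range(n - 1, -1, -1):
            ssum = rhs[i]
            jmax = i + bw
            if jmax > n - 1:
                jmax = n - 1
            for j in range(i + 1, jmax + 1):
                ssum -= Mb[i, j - i + bw] * p[c, j]
            p[c, i] = ssum / Mb[i, bw]
        tot = 0.0
        for i in range(n):
            if p[c, i] < 0.0:
                p[c, i] = 0.0
            tot += p[c, i]
        po = 0.0
        for i in range(n):
            p[c, i] /= tot
        for k in range(cond.size):
            po += p[c, cond[k]]
        g = gbar[c] * po
        gtot[cc] += g
        if isca == 1:
            e = erev_ca[cc]
            ge[cc] += g * e
            gca[cc] += g
            gece[cc] += g * e
        else:
            ge[cc] += g * erevval


if _HAVE_NUMBA:
    _gates_update = njit(cache=True)(_gates_update_py)
    _hh_conduct = njit(cache=True)(_hh_conduct_py)
    _markov_step = njit(cache=True)(_markov_step_py)
else:  # pragma: no cover
    _gates_update = _gates_update_py
    _hh_conduct = _hh_conduct_py
    _markov_step = _markov_step_py


# ---------------------------------------------------------------------------
# runtime channel structures
# ---------------------------------------------------------------------------

class _HHRuntime:
    """Fused table-driven runtime for all Hodgkin-Huxley channels."""

    def __init__(self, model: Model, dt: float):
        grid = model.grid
        tab_inf, tab_efac = [], []
        ent_tab, ent_comp = [], []
        meta_ent0, meta_nc, meta_ng, meta_exps = [], [], [], []
        meta_cstart, meta_erev, meta_isca = [], [], []
        ccomp, cgbar = [], []
        self.specs = []
        self.ca_gates = []  # (gate, entry slice, comp idx, qt)
        n_ent = 0
        n_comp_tot = 0
        for spec in model.channels:
            if spec.markov is not None:
                continue
            gmax = np.array([spec.gmax_in(t) for t in grid.tag])
            idx = np.nonzero(gmax > 0)[0]
            if idx.size == 0:
                continue
            qt = spec.qt(model.t_sim)
            self.specs.append((spec, idx))
            meta_ent0.append(n_ent)
            meta_nc.append(idx.size)
            meta_ng.append(len(spec.gates))
            meta_cstart.append(n_comp_tot)
            meta_erev.append(0.0 if spec.erev == "ca_ghk" else float(spec.erev))
            meta_isca.append(1 if spec.erev == "ca_ghk" else 0)
            exps = [g.exponent for g in spec.gates] + [0] * (4 - len(spec.gates))
            meta_exps.append(exps[:4])
            ccomp.append(idx)
            cgbar.append(gmax[idx] * grid.area[idx] * 1e-2)  # uS
            n_comp_tot += idx.size
            for g in spec.gates:
                sl = slice(n_ent, n_ent + idx.size)
                krow = len(tab_inf)
                inf, tau = g.inf_tau(_VGRID, CA_REST_DEFAULT, qt)
                tab_inf.append(inf * np.ones_like(_VGRID))
                tab_efac.append(np.exp(-dt / tau) * np.ones_like(_VGRID))
                if spec.ca_dependent and _gate_is_ca_dependent(g):
                    self.ca_gates.append((g, sl, idx, qt))
                ent_tab.append(np.full(idx.size, krow))
                ent_comp.append(idx)
                n_ent += idx.size
        z = np.zeros(0, dtype=np.int64)
        self.tab_inf = np.array(tab_inf) if tab_inf else np.zeros((1, _VGRID.size))
        self.tab_efac = np.array(tab_efac) if tab_efac else np.zeros((1, _VGRID.size))
        self.ent_tab = np.concatenate(ent_tab).astype(np.int64) if ent_tab else z
        self.ent_comp = np.concatenate(ent_comp).astype(np.int64) if ent_comp else z
        self.ent0 = np.array(meta_ent0, dtype=np.int64)
        self.nc = np.array(meta_nc, dtype=np.int64)
        self.ng = np.array(meta_ng, dtype=np.int64)
        self.exps = np.array(meta_exps, dtype=np.int64).reshape(-1, 4)
        self.cstart = np.array(meta_cstart, dtype=np.int64)
        self.erev = np.array(meta_erev)
        self.isca = np.array(meta_isca, dtype=np.uint8)
        self.ccomp = np.concatenate(ccomp).astype(np.int64) if ccomp else z
        self.cgbar = np.concatenate(cgbar) if cgbar else np.zeros(0)
        self.x = np.zeros(n_ent)
        self.dt = dt

    def set_steady(self, v: np.ndarray, cai: np.ndarray) -> None:
        n_ent = 0
        for spec, idx in self.specs:
            for g in spec.gates:
                inf, _ = g.inf_tau(v[idx], cai[idx], 1.0)
                self.x[n_ent:n_ent + idx.size] = inf
                n_ent += idx.size

    def advance(self, v: np.ndarray, cai: np.ndarray) -> None:
        if self.x.size == 0:
            return
        # Ca-dependent gates need their pre-update state for the override
        saves = [(sl, self.x[sl].copy()) for _g, sl, _i, _q in self.ca_gates]
        _gates_update(self.x, self.ent_tab, self.ent_comp, v,
                      self.tab_inf, self.tab_efac, _VGRID[0], 0.05)
        for (g, sl, idx, qt), (sl2, xold) in zip(self.ca_gates, saves):
            inf, tau = g.inf_tau(v[idx], cai[idx], qt)
            self.x[sl] = inf + (xold - inf) * np.exp(-self.dt / tau)

    def accumulate(self, erev_ca, gtot, ge, gca, gece) -> None:
        if self.x.size == 0:
            return
        _hh_conduct(self.x, self.ent0, self.nc, self.ng, self.exps,
                    self.cstart, self.ccomp, self.cgbar, self.erev,
                    self.isca, erev_ca, gtot, ge, gca, gece)


def _gate_is_ca_dependent(gate) -> bool:
    a1 = gate.fn(np.array([-60.0]), 1e-4)
    a2 = gate.fn(np.array([-60.0]), 1e-2)
    return not (np.allclose(a1[0], a2[0]) and np.allclose(a1[1], a2[1]))


class _MarkovRuntime:
    """Table-driven backward-Euler runtime for one Markov channel.

    Rate entries are decomposed as R(V, Ca) = A(V) + B(V) * Ca by probing
    the specification's rate builder at Ca = 0 and Ca = 1; the decomposition
    is verified at construction, so the fast path cannot drift from the
    reference kinetics.
    """

    def __init__(self, spec, model: Model, dt: float):
        grid = model.grid
        self.spec = spec
        self.n = spec.markov.n
        gmax = np.array([spec.gmax_in(t) for t in grid.tag])
        self.idx = np.nonzero(gmax > 0)[0].astype(np.int64)
        self.gbar = gmax[self.idx] * grid.area[self.idx] * 1e-2
        self.qt = spec.qt(model.t_sim)
        self.dt = dt
        A = spec.markov.rates(_VGRID, np.zeros_like(_VGRID))
        R1 = spec.markov.rates(_VGRID, np.ones_like(_VGRID))
        B = R1 - A
        R2 = spec.markov.rates(_VGRID, np.full_like(_VGRID, 2.0))
        if not np.allclose(R2, A + 2 * B, rtol=1e-10, atol=1e-12):
            raise ValueError(f"{spec.name}: rates not affine in Ca")
        ei, ej = np.nonzero(np.any(A != 0, axis=0) | np.any(B != 0, axis=0))
        self.A_tab = np.ascontiguousarray(A[:, ei, ej])  # (nv, nent)
        self.B_tab = np.ascontiguousarray(B[:, ei, ej])
        # permute states (reverse Cuthill-McKee) to minimize bandwidth
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import reverse_cuthill_mckee
        adj = coo_matrix((np.ones(ei.size), (ei, ej)),
                         shape=(self.n, self.n)).tocsr()
        perm = reverse_cuthill_mckee(adj + adj.T, symmetric_mode=True)
        inv = np.empty(self.n, dtype=np.int64)
        inv[perm] = np.arange(self.n)
        self.perm = np.asarray(perm, dtype=np.int64)
        self.inv_perm = inv
        self.ei = inv[ei]
        self.ej = inv[ej]
        self.bw = int(np.max(np.abs(self.ei - self.ej)))
        self.cond = inv[spec.markov.conducting_index()].astype(np.int64)
        self.isca = 1 if spec.erev == "ca_ghk" else 0
        self.erevval = 0.0 if self.isca else float(spec.erev)
        self.p = np.zeros((self.idx.size, self.n))

    def set_steady(self, v: np.ndarray, cai: np.ndarray) -> None:
        for k, i in enumerate(self.idx):
            self.p[k] = ch.markov_steady_state(
                self.spec.markov, float(v[i]), float(cai[i]))[self.perm]

    def advance_and_accumulate(self, v, cai, erev_ca, gtot, ge, gca,
                               gece) -> None:
        if self.idx.size == 0:
            return
        _markov_step(self.A_tab, self.B_tab, self.ei, self.ej, self.p, v,
                     cai, self.idx, self.gbar, self.dt * self.qt, self.dt,
                     _VGRID[0], 0.05, self.cond, self.isca, self.erevval,
                     erev_ca, gtot, ge, gca, gece, self.bw)

    def advance(self, v, cai) -> None:
        """State update alone (scratch accumulators); used by clamp-style
        experiments and tests."""
        n = v.size
        z = np.zeros(n)
        self.advance_and_accumulate(v, cai, z, np.zeros(n), np.zeros(n),
                                    np.zeros(n), np.zeros(n))

    def open_fraction(self) -> np.ndarray:
        return self.p[:, self.cond].sum(axis=1)

    def occupancy(self) -> np.ndarray:
        """Occupancies in the original state order of the scheme."""
        return self.p[:, self.inv_perm]


# ---------------------------------------------------------------------------
# the simulation engine
# ---------------------------------------------------------------------------

class Simulation:
    """Stateful integrator for one model + config."""

    def __init__(self, model: Model, config: SimConfig,
                 passive_only: bool = False):
        self.model = model
        self.config = config
        self.grid = model.grid
        self.passive_only = passive_only
        n = self.grid.n
        self.v = np.full(n, config.v_init)
        self.t = 0.0
        self.calcium = CalciumField.for_compartments(
            self.grid.diam, self.grid.length, self.grid.area, self.grid.tag)
        self.erev_ca = ch.ghk_ca_reversal(self.calcium.cai)
        if not passive_only:
            self.hh = _HHRuntime(model, config.dt)
            self.hh.set_steady(self.v, self.calcium.cai)
            self.markov = [
                _MarkovRuntime(spec, model, config.dt)
                for spec in model.channels
                if spec.markov is not None and any(
                    spec.gmax_in(t) > 0 for t in self.grid.tag)]
            for mk in self.markov:
                mk.set_steady(self.v, self.calcium.cai)
        else:
            self.hh = None
            self.markov = []
        self._lap = _laplacian_diag(self.grid)
        self._cm_dt = self.grid.cm / config.dt
        self._gca = np.zeros(n)
        self._gece = np.zeros(n)

    # -- single step ------------------------------------------------------
    def step(self, i_inj: np.ndarray | None = None) -> None:
        """One backward-Euler step; ``i_inj`` is nA per compartment."""
        grid = self.grid
        dt = self.config.dt
        cai = self.calcium.cai
        gtot = grid.g_leak.copy()
        ge = grid.g_leak * grid.e_leak
        gca = self._gca
        gece = self._gece
        gca[:] = 0.0
        gece[:] = 0.0
        if not self.passive_only:
            self.hh.advance(self.v, cai)
            self.hh.accumulate(self.erev_ca, gtot, ge, gca, gece)
            for mk in self.markov:
                mk.advance_and_accumulate(self.v, cai, self.erev_ca,
                                          gtot, ge, gca, gece)
        # backward-Euler voltage solve over the tree
        d = self._cm_dt + gtot + self._lap
        rhs = self._cm_dt * self.v + ge
        if i_inj is not None:
            rhs = rhs + i_inj
        v_new = _hines(grid.parent, grid.g_parent, d, rhs)
        if np.max(np.abs(v_new)) >= V_GUARD:
            k = int(np.argmax(np.abs(v_new)))
            raise SimulationDiverged(
                f"|V| >= {V_GUARD} mV at t={self.t:.3f} ms in section "
                f"{grid.sec_id[k]} ({grid.tag[k].value}); dt too large or "
                f"conductances inconsistent")
        self.v = v_new
        if not self.passive_only:
            # calcium update from the new voltage, then GHK refresh
            i_ca = gca * v_new - gece
            self.calcium.step(i_ca, dt, pump_on=self.config.pump_on)
            self.erev_ca = ch.ghk_ca_reversal(self.calcium.cai)
        self.t += dt

    # -- full run ---------------------------------------------------------
    def run(self, stimuli: list | None = None,
            duration: float | None = None,
            record: list | None = None) -> TraceSet:
        """Integrate for ``duration`` ms recording the configured sites."""
        cfg = self.config
        duration = cfg.duration if duration is None else duration
        record = cfg.record if record is None else record
        nsteps = int(round(duration / cfg.dt))
        sites = []
        for item in record:
            if len(item) == 2:
                site, qty = item
            else:
                site, qty = (item[0], item[1]), item[2]
            comp = self.model.resolve_site(site)
            name = site if isinstance(site, str) else f"sec{site[0]}"
            sites.append((f"{name}.{qty}", comp, qty))
        stim_arrays = []
        if stimuli:
            tgrid = self.t + np.arange(nsteps) * cfg.dt
            for s in stimuli:
                comp = self.model.resolve_site(
                    s.section if isinstance(s.section, str)
                    else (s.section, s.pos))
                stim_arrays.append((comp, np.asarray(s.waveform(tgrid),
                                                     dtype=float)))
        nrec = nsteps // cfg.decim
        out = {name: np.empty(nrec) for name, _, _ in sites}
        tout = np.empty(nrec)
        i_inj = np.zeros(self.grid.n)
        r = 0
        for k in range(nsteps):
            if stim_arrays:
                i_inj[:] = 0.0
                for comp, amps in stim_arrays:
                    i_inj[comp] += amps[k]
                self.step(i_inj)
            else:
                self.step(None)
            if (k + 1) % cfg.decim == 0 and r < nrec:
                tout[r] = self.t
                for name, comp, qty in sites:
                    out[name][r] = self.v[comp] if qty == "v" \
                        else self.calcium.cai[comp]
                r += 1
        return TraceSet(tout, out, meta={"dt": cfg.dt, "decim": cfg.decim})


def _laplacian_diag(grid: CompartmentGrid) -> np.ndarray:
    d = np.zeros(grid.n)
    for i in range(grid.n):
        p = grid.parent[i]
        if p >= 0:
            d[i] += grid.g_parent[i]
            d[p] += grid.g_parent[i]
    return d


# ---------------------------------------------------------------------------
# convenience drivers
# ---------------------------------------------------------------------------

def run(model: Model, config: SimConfig,
        stimuli: list | None = None) -> TraceSet:
    """Build a simulation at steady initial state and integrate."""
    sim = Simulation(model, config)
    return sim.run(stimuli=stimuli)


def impedance_from_soma(model: Model, i_test: float = -0.01,
                        dt: float = 0.025) -> tuple:
    """Passive input resistance (MOhm) and capacitance (pF) seen from the
    soma.

    Rin is the exact steady solution of the passive system for a small
    somatic test current (steady dV/dI).  Cin is the integral of the
    capacitive charging current over the transient divided by the somatic
    voltage step; because sum_i C_i dV_i/dt integrates to sum_i C_i dV_i,
    it is evaluated exactly from the two steady states.
    """
    grid = model.grid
    soma = model.resolve_site("soma")
    d = grid.g_leak + _laplacian_diag(grid)
    rhs = grid.g_leak * grid.e_leak
    v0 = _hines(grid.parent.copy(), grid.g_parent, d.copy(), rhs.copy())
    rhs2 = grid.g_leak * grid.e_leak
    rhs2[soma] += i_test
    d2 = grid.g_leak + _laplacian_diag(grid)
    v1 = _hines(grid.parent.copy(), grid.g_parent, d2, rhs2)
    dv_soma = v1[soma] - v0[soma]
    rin = dv_soma / i_test  # mV/nA = MOhm
    q_cap = np.sum(grid.cm * (v1 - v0))  # nF*mV = pC
    cin = q_cap / dv_soma * 1e3          # nF -> pF
    return float(rin), float(cin)
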