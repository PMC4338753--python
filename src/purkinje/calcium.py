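"""Intracellular calcium dynamics.

Each compartment carries a stack of concentric cytoplasmic shells under the
membrane.  Calcium enters the outermost shell from the compartment's Ca
currents, diffuses radially between shells, binds to passive diffusible
buffers (calbindin and parvalbumin; calmodulin is deliberately absent) and
is extruded by a generic membrane pump whose density varies by region.

The number of shells adapts to the compartment diameter: the outermost
shell has a fixed depth (default 0.1 um) and the remaining radius is split
evenly, with the shell count capped for speed.  Thin axonal compartments
therefore collapse to one or two well-mixed pools while the soma carries
the full stack.

All updates are constructed to conserve mass exactly in a closed system
(no influx, pump off): radial diffusion is a flux-form backward-Euler
tridiagonal solve, and buffer binding uses the closed-form backward-Euler
root of the binding ODE, exchanging matching amounts of free and bound
calcium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import RegionTag

try:
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

#: mM * um^3 produced per nA * ms of Ca current (1/(2F) in these units)
CA_INFLUX_CONV = 1e3 * 1e-12 / (2 * 96485.33212) / 1e-15

#: resting free calcium, mM (45 nM)
CA_REST_DEFAULT = 4.5e-5

#: free-calcium diffusion coefficient, um^2/ms
D_CA = 0.233

#: region-wise pump density scale (dimensionless, soma = 1); encodes the
#: region column of the pump-density table
PUMP_SCALE = {
    RegionTag.SOMA: 1.0,
    RegionTag.TRUNK: 0.4, RegionTag.PRINCIPAL: 0.4, RegionTag.TERMINAL: 0.4,
    RegionTag.AIS: 1.0,
    RegionTag.NODE: 10.0,
    RegionTag.COLLATERAL: 1.0,
    RegionTag.PARA_AIS: 1.0,
    RegionTag.MYELIN: 1.0,
}

#: generic saturable extrusion pump: maximum flux density (mM*um/ms per
#: unit regional scale) and half-saturation (mM).  The pump clears the
#: standing window-current influx near rest but saturates during spikes,
#: letting submembrane calcium rise into the micromolar range.
PUMP_VMAX_DEFAULT = 3e-3
PUMP_KM_DEFAULT = 2e-4


def resting_calcium() -> float:
    """Default initial free calcium in every shell, mM (45 nM)."""
    return CA_REST_DEFAULT


@dataclass
class BufferSpecies:
    """A passive diffusible calcium buffer.

    ``total`` is the total site concentration (mM), ``kf``/``kb`` the
    binding/unbinding rates (1/(mM*ms), 1/ms) and ``D`` the diffusion
    coefficient of the buffer (bound and free forms move together).
    """

    name: str
    total: float
    kf: float
    kb: float
    D: float

    @property
    def kd(self) -> float:
        return self.kb / self.kf

    def equilibrium_bound(self, ca: float) -> float:
        """Bound concentration in equilibrium with free ``ca`` (mM)."""
        return self.total * ca / (ca + self.kd)


def default_buffers() -> list:
    """Calbindin and parvalbumin with binding parameters adopted from the
    Purkinje calcium-dynamics literature (single effective site each)."""
    return [
        BufferSpecies("calbindin", total=0.16, kf=43.5, kb=8.7e-2, D=0.028),
        BufferSpecies("parvalbumin", total=0.08, kf=10.0, kb=1.0e-3, D=0.043),
    ]


def shell_boundaries(diameter: float, depth: float = 0.1,
                     max_shells: int = 4) -> np.ndarray:
    """Radial shell boundaries (um), outermost first.

    The outer shell has thickness ``depth``; the remaining radius is split
    evenly among at most ``max_shells - 1`` inner shells.  Compartments
    thinner than two depths collapse to a single well-mixed pool.
    """
    r = diameter / 2.0
    if r <= 2 * depth:
        return np.array([r, 0.0])
    n = min(max_shells, max(1, int(np.floor(r / depth))))
    if n == 1:
        return np.array([r, 0.0])
    inner = np.linspace(r - depth, 0.0, n)
    return np.concatenate([[r], inner])


def _ca_kernel_py(free, bound, i_ca, inflx, kpump, km, ca_rest, pump_on,
                  afac, cpfac, invfac, voldt, kf, kb, btot, dt, diffon):
    """Full per-step calcium update (influx, pump, radial diffusion with
    precomputed tridiagonal factors, buffer binding) as scalar loops."""
    n, ns = free.shape
    nspec = bound.shape[0]
    for c in range(n):
        free[c, 0] += i_ca[c] * inflx[c]
        if pump_on == 1:
            kv = kpump[c]          # max removal rate, mM/ms
            qrest = ca_rest / (ca_rest + km)
            rhsq = free[c, 0] + dt * kv * qrest
            bq = km + dt * kv - rhsq
            free[c, 0] = 0.5 * (-bq + np.sqrt(bq * bq + 4.0 * km * rhsq))
    for s in range(nspec + 1):
        if diffon[s] == 0:
            continue
        for c in range(n):
            # Thomas solve with cached factors; padded shells are decoupled
            if s == 0:
                d0 = (voldt[c, 0] * free[c, 0]) * invfac[s, c, 0]
            else:
                d0 = (voldt[c, 0] * bound[s - 1, c, 0]) * invfac[s, c, 0]
            dp0 = d0
            dps = np.empty(ns)
            dps[0] = dp0
            for k in range(1, ns):
                if s == 0:
                    rhs = voldt[c, k] * free[c, k]
                else:
                    rhs = voldt[c, k] * bound[s - 1, c, k]
                dps[k] = (rhs - afac[s, c, k] * dps[k - 1]) * invfac[s, c, k]
            if s == 0:
                free[c, ns - 1] = dps[ns - 1]
                for k in range(ns - 2, -1, -1):
                    free[c, k] = dps[k] - cpfac[s, c, k] * free[c, k + 1]
            else:
                bound[s - 1, c, ns - 1] = dps[ns - 1]
                for k in range(ns - 2, -1, -1):
                    bound[s - 1, c, k] = dps[k] \
                        - cpfac[s, c, k] * bound[s - 1, c, k + 1]
    for s in range(nspec):
        for c in range(n):
            for k in range(ns):
                a = free[c, k]
                T = a + bound[s, c, k]
                B = 1.0 + dt * kf[s] * (btot[s] - T) + dt * kb[s]
                disc = B * B + 4.0 * dt * kf[s] * (a + dt * kb[s] * T)
                x = (-B + np.sqrt(disc)) / (2.0 * dt * kf[s])
                free[c, k] = x
                bound[s, c, k] = T - x


if _HAVE_NUMBA:
    _ca_kernel = njit(cache=True)(_ca_kernel_py)
else:  # pragma: no cover
    _ca_kernel = _ca_kernel_py


@dataclass
class CalciumField:
    """Vectorized shell stacks for a set of compartments.

    Arrays are padded to the maximum shell count; ``mask`` flags real
    shells.  ``free`` has shape (n_comp, n_shell) in mM; ``bound`` has shape
    (n_species, n_comp, n_shell).
    """

    vol: np.ndarray          # um^3, padded with 1.0
    iface: np.ndarray        # um^2 interface area between shell k and k+1
    dist: np.ndarray         # um center-to-center distance across interfaces
    mask: np.ndarray         # bool, real shells
    out_area: np.ndarray     # um^2 membrane area per compartment
    pump_scale: np.ndarray   # per compartment
    buffers: list = field(default_factory=default_buffers)
    pump_vmax: float = PUMP_VMAX_DEFAULT
    pump_km: float = PUMP_KM_DEFAULT
    ca_rest: float = CA_REST_DEFAULT
    free: np.ndarray = None
    bound: np.ndarray = None

    def __post_init__(self):
        self._thomas = {}
        if self.free is None:
            self.free = np.full(self.vol.shape, self.ca_rest)
        if self.bound is None:
            self.bound = np.stack([
                np.full(self.vol.shape, b.equilibrium_bound(self.ca_rest))
                for b in self.buffers])

    # -- construction -----------------------------------------------------
    @classmethod
    def for_compartments(cls, diam, length, area, tags, depth: float = 0.1,
                         max_shells: int = 4, buffers=None,
                         pump_vmax: float = PUMP_VMAX_DEFAULT,
                         pump_km: float = PUMP_KM_DEFAULT,
                         ca_rest: float = CA_REST_DEFAULT) -> "CalciumField":
        """Build stacks for compartments given per-compartment diameter,
        length (um), membrane area (um^2) and region tags."""
        diam = np.asarray(diam, dtype=float)
        length = np.asarray(length, dtype=float)
        n = diam.size
        bounds = [shell_boundaries(d, depth, max_shells) for d in diam]
        ns = max(len(b) - 1 for b in bounds)
        vol = np.ones((n, ns))
        iface = np.zeros((n, ns))   # iface[:, k]: between shell k and k+1
        dist = np.ones((n, ns))
        mask = np.zeros((n, ns), dtype=bool)
        for i, b in enumerate(bounds):
            k = len(b) - 1
            vol[i, :k] = np.pi * (b[:-1] ** 2 - b[1:] ** 2) * length[i]
            mask[i, :k] = True
            thick = b[:-1] - b[1:]
            for j in range(k - 1):
                iface[i, j] = 2 * np.pi * b[j + 1] * length[i]
                dist[i, j] = 0.5 * (thick[j] + thick[j + 1])
        return cls(vol=vol, iface=iface, dist=dist, mask=mask,
                   out_area=np.asarray(area, dtype=float),
                   pump_scale=np.array([PUMP_SCALE.get(t, 1.0) for t in tags]),
                   buffers=default_buffers() if buffers is None else buffers,
                   pump_vmax=pump_vmax, pump_km=pump_km, ca_rest=ca_rest)

    @property
    def n_comp(self) -> int:
        return self.vol.shape[0]

    @property
    def cai(self) -> np.ndarray:
        """Outermost-shell free calcium per compartment (mM) -- the value
        seen by Ca-dependent channels and the GHK reversal update."""
        return self.free[:, 0]

    def total_calcium(self) -> np.ndarray:
        """Volume-weighted total (free + bound) calcium per compartment,
        in mM*um^3."""
        tot = self.free.copy()
        for s in range(len(self.buffers)):
            tot = tot + self.bound[s]
        return np.sum(np.where(self.mask, tot * self.vol, 0.0), axis=1)

    # -- one time step ----------------------------------------------------
    def step(self, i_ca, dt: float, pump_on: bool = True) -> None:
        """Advance the calcium subsystem by ``dt`` ms.

        ``i_ca`` is the per-compartment calcium current in nA (outward
        positive, so an inward Ca current is negative and raises the
        outer-shell concentration).
        """
        i_ca = np.asarray(i_ca, dtype=float)
        fac = self._kernel_factors(dt)
        if fac is not None:
            afac, cpfac, invfac, voldt, inflx, kpump, kf, kb, btot, diffon = fac
            _ca_kernel(self.free, self.bound, i_ca, inflx, kpump,
                       self.pump_km, self.ca_rest, 1 if pump_on else 0,
                       afac, cpfac, invfac, voldt, kf, kb, btot, dt, diffon)
            if np.any(self.free[self.mask] < -1e-12):
                raise FloatingPointError(
                    "negative calcium concentration: time step too large")
            np.clip(self.free, 0.0, None, out=self.free)
            return
        # influx into the outermost shell
        self.free[:, 0] += -i_ca * dt * CA_INFLUX_CONV / self.vol[:, 0]
        # saturable pump extrusion, semi-implicit (closed-form root)
        if pump_on:
            kv = (self.pump_vmax * self.pump_scale * self.out_area
                  / self.vol[:, 0])
            km = self.pump_km
            qrest = self.ca_rest / (self.ca_rest + km)
            rhsq = self.free[:, 0] + dt * kv * qrest
            bq = km + dt * kv - rhsq
            self.free[:, 0] = 0.5 * (-bq + np.sqrt(bq * bq + 4 * km * rhsq))
        # radial diffusion (free Ca and each buffer species)
        self._diffuse(self.free, D_CA, dt)
        for s, b in enumerate(self.buffers):
            self._diffuse(self.bound[s], b.D, dt)
        # buffer binding, closed-form backward Euler per species
        for s, b in enumerate(self.buffers):
            self._bind(s, b, dt)
        if np.any(self.free[self.mask] < -1e-12):
            raise FloatingPointError(
                "negative calcium concentration: time step too large")
        np.clip(self.free, 0.0, None, out=self.free)

    def _kernel_factors(self, dt: float):
        """Stacked tridiagonal factors and rate vectors for the fused
        kernel; cached per dt.  Species index 0 is free calcium."""
        cached = self._thomas.get(("kernel", dt))
        if cached is not None:
            return cached
        ns = self.vol.shape[1]
        Ds = [D_CA] + [b.D for b in self.buffers]
        nspec1 = len(Ds)
        n = self.vol.shape[0]
        afac = np.zeros((nspec1, n, ns))
        cpfac = np.zeros((nspec1, n, ns))
        invfac = np.zeros((nspec1, n, ns))
        diffon = np.zeros(nspec1, dtype=np.uint8)
        voldt = self.vol / dt
        for s, D in enumerate(Ds):
            if D == 0.0 or ns == 1:
                continue
            diffon[s] = 1
            g = D * self.iface / self.dist
            a = np.zeros((n, ns))
            c = np.zeros((n, ns))
            c[:, :-1] = -g[:, :-1]
            a[:, 1:] = -g[:, :-1]
            b = voldt - a - c
            invfac[s, :, 0] = 1.0 / b[:, 0]
            cpfac[s, :, 0] = c[:, 0] * invfac[s, :, 0]
            for k in range(1, ns):
                invfac[s, :, k] = 1.0 / (b[:, k] - a[:, k] * cpfac[s, :, k - 1])
                cpfac[s, :, k] = c[:, k] * invfac[s, :, k]
            afac[s] = a
        inflx = -dt * CA_INFLUX_CONV / self.vol[:, 0]
        kpump = (self.pump_vmax * self.pump_scale * self.out_area
                 / self.vol[:, 0])
        kf = np.array([b.kf for b in self.buffers])
        kb = np.array([b.kb for b in self.buffers])
        btot = np.array([b.total for b in self.buffers])
        out = (afac, cpfac, invfac, voldt, inflx, kpump, kf, kb, btot, diffon)
        self._thomas[("kernel", dt)] = out
        return out

    def _diffuse(self, conc, D: float, dt: float) -> None:
        """Backward-Euler flux-form radial diffusion; conserves
        sum(vol * conc) exactly.  The tridiagonal factorization is static
        per (D, dt) and cached."""
        if D == 0.0 or conc.shape[1] == 1:
            return
        n, ns = conc.shape
        fac = self._thomas.get((D, dt))
        if fac is None:
            g = D * self.iface / self.dist        # um^3/ms per interface
            a = np.zeros((n, ns))   # sub-diagonal (coupling to shell k-1)
            c = np.zeros((n, ns))   # super-diagonal (coupling to shell k+1)
            c[:, :-1] = -g[:, :-1]
            a[:, 1:] = -g[:, :-1]
            b = self.vol / dt - a - c
            cp = np.zeros((n, ns))
            inv = np.zeros((n, ns))
            inv[:, 0] = 1.0 / b[:, 0]
            cp[:, 0] = c[:, 0] * inv[:, 0]
            for k in range(1, ns):
                inv[:, k] = 1.0 / (b[:, k] - a[:, k] * cp[:, k - 1])
                cp[:, k] = c[:, k] * inv[:, k]
            fac = (a, cp, inv, self.vol / dt)
            self._thomas[(D, dt)] = fac
        a, cp, inv, voldt = fac
        rhs = voldt * conc
        dp = np.empty((n, ns))
        dp[:, 0] = rhs[:, 0] * inv[:, 0]
        for k in range(1, ns):
            dp[:, k] = (rhs[:, k] - a[:, k] * dp[:, k - 1]) * inv[:, k]
        conc[:, -1] = dp[:, -1]
        for k in range(ns - 2, -1, -1):
            conc[:, k] = dp[:, k] - cp[:, k] * conc[:, k + 1]

    def _bind(self, s: int, b: BufferSpecies, dt: float) -> None:
        """Backward-Euler update of one buffer's binding step; the implicit
        equation is quadratic with a closed-form positive root, and bound
        calcium is updated as the exact complement (mass conserved)."""
        a = self.free
        T = a + self.bound[s]
        B = 1.0 + dt * b.kf * (b.total - T) + dt * b.kb
        disc = B * B + 4.0 * dt * b.kf * (a + dt * b.kb * T)
        x = (-B + np.sqrt(disc)) / (2.0 * dt * b.kf)
        self.free = x
        self.bound[s] = T - x


# ---------------------------------------------------------------------------
# single-compartment convenience (the shell-stack object)
# ---------------------------------------------------------------------------

class CaShellStack:
    """Shell stack of a single cylindrical compartment.

    A thin wrapper over :class:`CalciumField` with one compartment; useful
    for inspecting shell geometry and for closed-system experiments.
    """

    def __init__(self, diameter: float, length: float = 1.0,
                 depth: float = 0.1, max_shells: int = 4,
                 tag: RegionTag = RegionTag.SOMA, buffers=None,
                 pump_vmax: float = PUMP_VMAX_DEFAULT,
                 pump_km: float = PUMP_KM_DEFAULT,
                 ca_rest: float = CA_REST_DEFAULT):
        self.diameter = diameter
        self.length = length
        area = np.pi * diameter * length
        self.field = CalciumField.for_compartments(
            [diameter], [length], [area], [tag], depth=depth,
            max_shells=max_shells, buffers=buffers, pump_vmax=pump_vmax,
            pump_km=pump_km, ca_rest=ca_rest)

    @property
    def n_shells(self) -> int:
        return int(self.field.mask[0].sum())

    @property
    def shell_volumes(self) -> np.ndarray:
        m = self.field.mask[0]
        return self.field.vol[0][m]

    @property
    def free(self) -> np.ndarray:
        return self.field.free[0][self.field.mask[0]]

    @property
    def cai(self) -> float:
        return float(self.field.cai[0])

    def total_calcium(self) -> float:
        return float(self.field.total_calcium()[0])

    def step(self, i_ca: float, dt: float, pump_on: bool = True) -> None:
        self.field.step(np.array([i_ca]), dt, pump_on=pump_on)


def make_shells(diameter: float, depth: float = 0.1, length: float = 1.0,
                max_shells: int = 4, **kw) -> CaShellStack:
    """Build the shell stack for one compartment (see
    :func:`shell_boundaries` for the adaptation rule)."""
    return CaShellStack(diameter, length=length, depth=depth,
                        max_shells=max_shells, **kw)


def step_ca(stack: CaShellStack, i_ca: float, dt: float,
            pump_on: bool = True) -> CaShellStack:
    """Advance a single shell stack by ``dt`` ms (in place; returned for
    convenience)."""
    stack.step(i_ca, dt, pump_on=pump_on)
    return stack
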