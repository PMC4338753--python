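"""Electrophysiological metrics from recorded traces.

Spike detection, spike-shape statistics (half width, afterhyperpolarization
depth, trough-to-peak amplitude), burst segmentation, axonal transmission
reliability, conduction velocity and frequency-current (F/I) summaries.
All functions operate on uniformly sampled voltage traces (mV, ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default detection threshold for full axo-somatic spikes (mV)
SPIKE_THRESHOLD = -20.0
#: nominal action potential threshold used for reporting (mV)
NOMINAL_THRESHOLD = -50.0


class NoSpikeError(ValueError):
    """The operation needs spikes that the trace does not contain."""


class NoBurstError(ValueError):
    """Burst segmentation found fewer than two bursts."""


class NoPropagationError(ValueError):
    """Too few propagated spikes (or zero delay) for a velocity estimate."""


@dataclass
class SpikeTrain:
    """Detected spikes at one site: times (ms, strictly increasing) and the
    peak voltage of each spike."""

    site: str
    times: np.ndarray
    peaks: np.ndarray

    def __len__(self) -> int:
        return self.times.size

    def rate(self, t_start: float | None = None,
             t_end: float | None = None) -> float:
        """Mean firing rate (Hz) over [t_start, t_end] (defaults to the
        recorded span)."""
        if self.times.size == 0:
            return 0.0
        t0 = self.times[0] if t_start is None else t_start
        t1 = self.times[-1] if t_end is None else t_end
        n = int(np.sum((self.times >= t0) & (self.times <= t1)))
        span = (t1 - t0) / 1000.0
        return n / span if span > 0 else 0.0

    def filter_peaks(self, min_peak: float) -> "SpikeTrain":
        """Keep only full-blown spikes whose peak exceeds ``min_peak`` mV
        (drops fading spikelets at depolarization block onset)."""
        m = self.peaks >= min_peak
        return SpikeTrain(self.site, self.times[m], self.peaks[m])

    def instantaneous_rate(self):
        """(times, rates): reciprocal inter-spike intervals in Hz assigned
        at the second spike of each pair."""
        if self.times.size < 2:
            return np.zeros(0), np.zeros(0)
        isi = np.diff(self.times)
        return self.times[1:], 1000.0 / isi


@dataclass
class SpikeShape:
    """Average somatic spike geometry.

    ``height`` is the mean peak voltage above the nominal -50 mV threshold;
    ``amplitude`` the mean trough-to-peak (AHP-to-peak) excursion;
    ``half_width`` the mean width at half of that excursion; ``ahp_depth``
    the mean inter-spike voltage minimum.
    """

    height: float
    amplitude: float
    half_width: float
    ahp_depth: float


@dataclass
class BurstMetrics:
    bursts_per_second: float
    spikes_per_burst: float
    intra_burst_frequency: float
    fast_spikes_at_onset: float
    n_bursts: int = 0


def detect_spikes(v, t, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = 1.0, site: str = "soma") -> SpikeTrain:
    """Detect spikes as local maxima following upward threshold crossings.

    One spike is kept per ``refractory`` window (ms).  The trace must be
    uniformly sampled.
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if v.size != t.size:
        raise ValueError("trace and time base differ in length")
    if v.size < 3:
        return SpikeTrain(site, np.zeros(0), np.zeros(0))
    dt = t[1] - t[0]
    up = np.nonzero((v[1:] > threshold) & (v[:-1] <= threshold))[0] + 1
    times, peaks = [], []
    win = max(2, int(round(2.0 / dt)))  # search 2 ms forward for the peak
    last = -np.inf
    for i in up:
        j = min(i + win, v.size)
        k = i + int(np.argmax(v[i:j]))
        tk = t[k]
        if 0 < k < v.size - 1:
            # parabolic refinement of the peak time (sub-sample accuracy)
            y0, y1, y2 = v[k - 1], v[k], v[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                tk = t[k] + 0.5 * dt * (y0 - y2) / denom
        if tk - last < refractory:
            continue
        times.append(tk)
        peaks.append(v[k])
        last = tk
    return SpikeTrain(site, np.array(times), np.array(peaks))


def spike_shape(v, t, train: SpikeTrain | None = None) -> SpikeShape:
    """Spike-shape statistics averaged over all complete inter-spike
    intervals.

    The half width of each spike is measured at half of its AHP-to-peak
    amplitude (trough of the following interval to peak); the AHP depth is
    the voltage minimum of the interval following the spike.
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if train is None:
        train = detect_spikes(v, t)
    if len(train) < 2:
        raise NoSpikeError("need at least two spikes for shape statistics")
    dt = t[1] - t[0]
    idx = np.searchsorted(t, train.times)
    heights, amps, widths, ahps = [], [], [], []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = v[a:b]
        peak = seg[0:max(1, int(2.0 / dt))].max()
        trough = seg.min()
        amp = peak - trough
        half = trough + amp / 2.0
        # width at the half level, scanning out from the peak in both
        # directions (the rising limb lies just before the peak sample)
        p = a + int(np.argmax(v[a:a + max(1, int(2.0 / dt))]))
        left = p
        while left > 0 and v[left - 1] > half:
            left -= 1
        right = p
        while right < b - 1 and v[right + 1] > half:
            right += 1
        widths.append((right - left + 1) * dt)
        amps.append(amp)
        ahps.append(trough)
        heights.append(peak - NOMINAL_THRESHOLD)
    return SpikeShape(float(np.mean(heights)), float(np.mean(amps)),
                      float(np.mean(widths)), float(np.mean(ahps)))


def transmission_reliability(train_a: SpikeTrain, train_b: SpikeTrain,
                             window: float = 1.0) -> float:
    """Fraction of spikes in ``train_a`` matched by a spike in ``train_b``
    within ``window`` ms (greedy nearest-neighbour, each b-spike used
    once)."""
    if len(train_a) == 0:
        return 1.0
    used = np.zeros(len(train_b), dtype=bool)
    hits = 0
    tb = train_b.times
    for ta in train_a.times:
        if tb.size == 0:
            break
        order = np.argsort(np.abs(tb - ta))
        for j in order[:4]:
            if not used[j] and abs(tb[j] - ta) <= window:
                used[j] = True
                hits += 1
                break
    return hits / len(train_a)


def conduction_velocity(train_a: SpikeTrain, train_b: SpikeTrain,
                        path_length_um: float, window: float = 2.0,
                        min_spikes: int = 5) -> float:
    """Conduction velocity (m/s) from the median per-spike peak-time delay
    between two co-registered spike trains separated by
    ``path_length_um``."""
    delays = []
    tb = train_b.times
    for ta in train_a.times:
        if tb.size == 0:
            break
        j = int(np.argmin(np.abs(tb - ta)))
        d = tb[j] - ta
        if 0.0 <= d <= window:
            delays.append(d)
    if len(delays) < min_spikes:
        raise NoPropagationError(
            f"only {len(delays)} propagated spikes (need {min_spikes})")
    med = float(np.median(delays))
    if med <= 0:
        raise NoPropagationError("zero or negative median delay")
    return path_length_um * 1e-6 / (med * 1e-3)


def burst_metrics(train: SpikeTrain, gap_factor: float = 3.0) -> BurstMetrics:
    """Segment a spike train into bursts at inter-spike intervals exceeding
    ``gap_factor`` times the intra-burst median ISI, and summarize them.

    Raises :class:`NoBurstError` for tonic trains (fewer than two bursts).
    """
    if len(train) < 4:
        raise NoBurstError("too few spikes")
    isi = np.diff(train.times)
    med = np.median(isi)
    gaps = np.nonzero(isi > gap_factor * med)[0]
    if gaps.size == 0:
        raise NoBurstError("no inter-burst gaps found (tonic firing)")
    bounds = np.concatenate([[-1], gaps, [len(train) - 1]])
    bursts = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
    bursts = [(a, b) for a, b in bursts if b > a]  # >= 2 spikes
    if len(bursts) < 2:
        raise NoBurstError("fewer than two bursts")
    span_s = (train.times[-1] - train.times[0]) / 1000.0
    nspk = [b - a + 1 for a, b in bursts]
    intra = []
    fast = []
    for a, b in bursts:
        bt = train.times[a:b + 1]
        if bt.size > 1:
            intra.append(1000.0 / np.median(np.diff(bt)))
        bp = train.peaks[a:b + 1]
        # leading run of full-size spikes (>= 90% of the burst's max peak,
        # measured from the burst trough baseline)
        ref = bp.max()
        k = 0
        for p in bp:
            if p >= ref - 0.1 * (ref - bp.min() + 1e-9):
                k += 1
            else:
                break
        fast.append(max(k, 1))
    return BurstMetrics(
        bursts_per_second=len(bursts) / span_s,
        spikes_per_burst=float(np.mean(nspk)),
        intra_burst_frequency=float(np.mean(intra)) if intra else 0.0,
        fast_spikes_at_onset=float(np.mean(fast)),
        n_bursts=len(bursts))


def is_bursting(train: SpikeTrain, gap_factor: float = 3.0) -> bool:
    """True when burst segmentation succeeds (>= 2 bursts)."""
    try:
        burst_metrics(train, gap_factor)
        return True
    except NoBurstError:
        return False


@dataclass
class FICurve:
    currents: np.ndarray
    rates: np.ndarray
    slope: float = 0.0           # Hz/nA over the linear range
    intercept: float = 0.0
    linear_top_rate: float = 0.0  # highest rate still on the linear branch
    max_residual: float = 0.0

    @classmethod
    def fit(cls, currents, rates, tol_hz: float = 20.0) -> "FICurve":
        """Least-squares line over the longest leading stretch whose
        residuals stay within ``tol_hz``; reports where linearity ends."""
        currents = np.asarray(currents, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if currents.size < 5:
            raise ValueError("need at least 5 current levels")
        order = np.argsort(currents)
        c, r = currents[order], rates[order]
        best = None
        for top in range(4, c.size + 1):
            A = np.vstack([c[:top], np.ones(top)]).T
            coef, *_ = np.linalg.lstsq(A, r[:top], rcond=None)
            resid = np.abs(A @ coef - r[:top]).max()
            if resid <= tol_hz:
                best = (coef, top, resid)
            else:
                break
        if best is None:
            A = np.vstack([c[:4], np.ones(4)]).T
            coef, *_ = np.linalg.lstsq(A, r[:4], rcond=None)
            best = (coef, 4, np.abs(A @ coef - r[:4]).max())
        coef, top, resid = best
        return cls(c, r, slope=float(coef[0]), intercept=float(coef[1]),
                   linear_top_rate=float(r[top - 1]),
                   max_residual=float(resid))


def fi_curve(currents, rates, tol_hz: float = 20.0) -> FICurve:
    """Module-level convenience wrapper for :meth:`FICurve.fit`."""
    return FICurve.fit(currents, rates, tol_hz)
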