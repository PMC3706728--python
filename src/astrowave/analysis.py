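"""Post-processing of simulated trajectories.

Covers the model's standard readouts: calcium-spike detection and
interspike-interval (ISI) statistics for single cells, the σ_ISI vs. T_av
regression across stimulus levels, spatiotemporal clustering of network
activations into intercellular calcium waves (ICW), wavefront radius–time
fits yielding propagation speeds, and wave-probability parameter sweeps
with a logistic transition fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace as dc_replace

import numpy as np
from scipy import optimize, stats

from .geometry import CellField
from .simulate import SimulationConfig, Trajectory, run_simulation

__all__ = [
    "SpikeRaster",
    "WaveEvent",
    "detect_spikes",
    "spike_raster",
    "isi_stats",
    "sigma_vs_tav_fit",
    "detect_waves",
    "wave_speed",
    "fit_logistic",
    "probability_sweep",
    "isi_poisson_tail_test",
]

# defaults chosen for this model's scales: resting calcium ~0.01 μM and
# spike amplitudes of order 0.3-1 μM make baseline+0.1 μM an unambiguous
# threshold; 10 s refractory matches the h-gate recovery time.
SPIKE_THRESHOLD = 0.1     # μM above baseline
SPIKE_REFRACTORY = 10.0   # s

# linking scales for wave clustering: a 2-5 μm/s front crossing a network
# with ~20-40 μm cell spacing recruits a neighbor within ~20 s.  At the
# working model's spontaneous transient rates, chance spatiotemporal chains
# of up to ~7 activations occur in subthreshold 1000-s runs; requiring 8
# member cells separates recruited waves from coincidence.
WAVE_LINK_DIST = 40.0     # μm
WAVE_LINK_TIME = 20.0     # s
WAVE_MIN_CELLS = 8


@dataclass
class SpikeRaster:
    """Ordered spike times per cell."""

    spikes: list                      # list of arrays, one per cell
    duration: float

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    def events(self) -> np.ndarray:
        """All (time, cell) activation events, sorted by time."""
        if not any(len(s) for s in self.spikes):
            return np.empty((0, 2))
        ev = np.concatenate(
            [np.stack([s, np.full(len(s), i)], axis=1)
             for i, s in enumerate(self.spikes) if len(s)]
        )
        return ev[np.argsort(ev[:, 0], kind="stable")]

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))


@dataclass
class WaveEvent:
    """A detected intercellular calcium wave."""

    cells: np.ndarray            # member cell ids
    times: np.ndarray            # activation time of each member, s
    positions: np.ndarray        # (m, 2) member positions, μm
    origin: np.ndarray           # position of the earliest member, μm
    t0: float                    # activation time of the earliest member
    radius_time: np.ndarray      # (m, 2): (radius μm, t - t0 s), time-sorted
    speed: float                 # μm/s from the radius-time OLS fit
    r_squared: float
    extent: float                # max radius, μm

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def detect_spikes(trace, times, baseline: float,
                  threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY) -> np.ndarray:
    """Upward crossings of baseline+threshold separated by >= refractory."""
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    above = trace > baseline + threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    out = []
    last = -np.inf
    for k in onsets:
        t = times[k]
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.array(out)


def spike_raster(traj: Trajectory, threshold: float = SPIKE_THRESHOLD,
                 refractory: float = SPIKE_REFRACTORY,
                 baseline=None) -> SpikeRaster:
    """Detect spikes in every cell of a trajectory.

    The per-cell baseline defaults to the median of the trace, which is
    insensitive to sparse spikes riding on a flat resting level.
    """
    spikes = []
    for i in range(traj.n_cells):
        b = float(np.median(traj.C[:, i])) if baseline is None else baseline
        spikes.append(detect_spikes(traj.C[:, i], traj.times, b, threshold,
                                    refractory))
    return SpikeRaster(spikes=spikes, duration=float(traj.times[-1]))


def isi_stats(spikes, bins=20):
    """Mean and sample standard deviation of interspike intervals.

    Returns ``(T_av, sigma_ISI, (counts, edges))``.  Requires at least
    three spikes (two intervals).
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 3:
        raise ValueError("need >= 3 spikes for ISI statistics")
    isi = np.diff(spikes)
    counts, edges = np.histogram(isi, bins=bins)
    return float(isi.mean()), float(isi.std(ddof=1)), (counts, edges)


def sigma_vs_tav_fit(pairs):
    """OLS line through (T_av, σ_ISI) pairs: returns (slope, intercept, R²)."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape[0] < 3:
        raise ValueError("need >= 3 (T_av, sigma_ISI) pairs")
    if np.ptp(pairs[:, 0]) == 0:
        raise ValueError("degenerate fit: all T_av equal")
    res = stats.linregress(pairs[:, 0], pairs[:, 1])
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def detect_waves(raster: SpikeRaster, cells: CellField,
                 link_dist: float = WAVE_LINK_DIST,
                 link_time: float = WAVE_LINK_TIME,
                 min_cells: int = WAVE_MIN_CELLS) -> list:
    """Single-linkage spatiotemporal clustering of activations into ICW.

    An activation joins a cluster if it lies within ``link_dist`` (μm) and
    ``link_time`` (s) of any activation already in it; clusters reaching
    ``min_cells`` distinct cells become :class:`WaveEvent` objects.  Only a
    cell's first activation within a cluster counts for membership.
    """
    ev = raster.events()
    if len(ev) == 0:
        return []
    pos = cells.positions
    t = ev[:, 0]
    cid = ev[:, 1].astype(int)
    n = len(ev)
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ld2 = link_dist ** 2
    start = 0
    for j in range(1, n):
        while t[j] - t[start] > link_time:
            start += 1
        pj = pos[cid[j]]
        for k in range(start, j):
            d2 = (pj[0] - pos[cid[k], 0]) ** 2 + (pj[1] - pos[cid[k], 1]) ** 2
            if d2 <= ld2:
                ra, rb = find(j), find(k)
                if ra != rb:
                    parent[ra] = rb
    roots = np.array([find(i) for i in range(n)])
    waves = []
    for root in np.unique(roots):
        members = np.flatnonzero(roots == root)
        seen = {}
        for m in members:  # time-ordered: keep first activation per cell
            if cid[m] not in seen:
                seen[cid[m]] = t[m]
        if len(seen) < min_cells:
            continue
        wcells = np.array(sorted(seen, key=lambda c: seen[c]))
        wtimes = np.array([seen[c] for c in wcells])
        wpos = pos[wcells]
        origin = wpos[0]
        radii = np.hypot(wpos[:, 0] - origin[0], wpos[:, 1] - origin[1])
        rt = np.stack([radii, wtimes - wtimes[0]], axis=1)
        if len(wcells) >= 4 and np.ptp(radii) > 0 and np.ptp(wtimes) > 0:
            res = stats.linregress(rt[:, 1], rt[:, 0])
            speed, r2 = float(res.slope), float(res.rvalue ** 2)
        else:
            speed, r2 = np.nan, np.nan
        waves.append(WaveEvent(
            cells=wcells, times=wtimes, positions=wpos, origin=origin,
            t0=float(wtimes[0]), radius_time=rt, speed=speed,
            r_squared=r2, extent=float(radii.max()),
        ))
    waves.sort(key=lambda w: w.t0)
    return waves


def wave_speed(wave: WaveEvent):
    """Radial propagation speed (μm/s) and R² of the radius-time OLS fit."""
    if wave.n_cells < 4:
        raise ValueError("need >= 4 wave members to fit a speed")
    radii, times = wave.radius_time[:, 0], wave.radius_time[:, 1]
    if np.ptp(radii) == 0:
        raise ValueError("degenerate geometry: all members collocated")
    if np.ptp(times) == 0:
        raise ValueError("degenerate timing: all activations simultaneous")
    res = stats.linregress(times, radii)
    return float(res.slope), float(res.rvalue ** 2)


def fit_logistic(x, successes, trials):
    """Maximum-likelihood logistic fit of Bernoulli fractions.

    p(x) = 1/(1 + exp(-(x - midpoint)/width)).  Returns (midpoint, width).
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(successes, dtype=float)
    nt = np.asarray(trials, dtype=float)
    if np.all(s == 0) or np.all(s == nt):
        raise ValueError("degenerate sweep: all outcomes identical")

    def nll(theta):
        x0, logw = theta
        w = np.exp(logw)
        p = 1.0 / (1.0 + np.exp(-np.clip((x - x0) / w, -30, 30)))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(s * np.log(p) + (nt - s) * np.log1p(-p))

    span = max(np.ptp(x), 1e-6)
    best = None
    for x0 in np.linspace(x.min(), x.max(), 9):
        for logw in np.log([span / 20, span / 5, span]):
            res = optimize.minimize(nll, [x0, logw], method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
    return float(best.x[0]), float(np.exp(best.x[1]))


@dataclass
class SweepResult:
    param: str
    values: np.ndarray
    n_reps: int
    n_waves: np.ndarray       # runs with >= 1 wave, per value
    fractions: np.ndarray
    midpoint: float           # logistic transition midpoint (nan if flat)
    width: float
    monotone_nondecreasing: bool
    wave_counts: list = dc_field(default_factory=list)


def probability_sweep(param: str, values, n_reps: int, duration: float,
                      cfg: SimulationConfig, seed=None,
                      link_dist: float = WAVE_LINK_DIST,
                      link_time: float = WAVE_LINK_TIME,
                      min_cells: int = WAVE_MIN_CELLS) -> SweepResult:
    """Empirical wave probability across a stimulus sweep.

    For each value of ``param`` (a :class:`SimulationConfig` field such as
    ``glu_ext`` or ``abeta_leak_increase``) runs ``n_reps`` independent
    simulations of length ``duration`` and records the fraction containing
    at least one detected wave, plus a logistic fit of the transition.
    """
    values = np.asarray(values, dtype=float)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(values) * n_reps)
    n_waves = np.zeros(len(values), dtype=int)
    counts = []
    k = 0
    for iv, v in enumerate(values):
        per_rep = []
        for rep in range(n_reps):
            run_cfg = dc_replace(cfg, duration=duration,
                                 seed=int(child[k].generate_state(1)[0]
                                          % (2 ** 31)))
            setattr(run_cfg, param, float(v))
            k += 1
            traj = run_simulation(run_cfg)
            raster = spike_raster(traj)
            waves = detect_waves(raster, CellField(traj.positions),
                                 link_dist, link_time, min_cells)
            per_rep.append(len(waves))
            if waves:
                n_waves[iv] += 1
        counts.append(per_rep)
    fractions = n_waves / n_reps
    try:
        midpoint, width = fit_logistic(values, n_waves,
                                       np.full(len(values), n_reps))
    except ValueError:
        midpoint, width = float("nan"), float("nan")
    monotone = bool(np.all(np.diff(fractions) >= -1.0 / n_reps))
    return SweepResult(param=param, values=values, n_reps=n_reps,
                       n_waves=n_waves, fractions=fractions,
                       midpoint=midpoint, width=width,
                       monotone_nondecreasing=monotone, wave_counts=counts)


def isi_poisson_tail_test(isis, floor=None):
    """Kolmogorov–Smirnov check of an exponential ISI tail.

    Nucleation is (approximately) a Poisson process once the refractory
    period has elapsed, so ISIs beyond the refractory mode should be
    exponential.  ``floor`` defaults to the histogram mode of the ISIs.
    The exponential scale is estimated from the tail itself, which makes
    the test mildly conservative toward non-rejection; it is used as a
    qualitative consistency check.

    Returns the KS p-value.
    """
    isis = np.asarray(isis, dtype=float)
    if floor is None:
        counts, edges = np.histogram(isis, bins="auto")
        floor = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    tail = isis[isis >= floor] - floor
    if tail.size < 10:
        raise ValueError("too few tail ISIs for a KS test")
    return float(stats.kstest(tail, "expon", args=(0.0, tail.mean())).pvalue)
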