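"""Coupled network simulation: initialization, stimulus protocols and the
forward-Euler / Euler–Maruyama time loop over all cells plus the ATP field.

A run proceeds as: relax a single isolated, noise-free cell to its resting
state (ER store initialized at 400 μM), replicate that state across the
network, then switch on the stimulus — a bath glutamate step and/or a
fractional increase of the extracellular calcium leak (the amyloid-β pore
protocol) — at t = 0 and integrate the stochastic system, recording
decimated trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernels
from .diffusion import (ATPField, NetworkGeometry, build_weights,
                        ftcs_stable_dt, make_field_for_positions, sample)
from .geometry import CellField, random_field
from .model_core import CellState, cell_derivs
from .params import ModelParams

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "find_steady_state",
    "euler_maruyama_step",
    "run_simulation",
]


@dataclass
class SimulationConfig:
    params: ModelParams = dc_field(default_factory=ModelParams)
    cells: Optional[CellField] = None      # explicit geometry, or use the
    n_cells: int = 100                     # random-field spec below
    extent: tuple = (400.0, 400.0)         # μm
    min_dist: float = 20.0                 # μm
    duration: float = 1000.0               # s
    dt: float = 0.005                      # s, shared ODE/PDE step
    record_interval: float = 1.0           # s
    seed: Optional[int] = None
    glu_ext: float = 0.0                   # μM bath glutamate from t = 0
    abeta_leak_increase: float = 0.0       # fractional k_l_ext increase
    C_ER_init: float = 400.0               # μM
    spacing: float = 2.0                   # μm ATP grid spacing
    pad: float = 50.0                      # μm grid margin around the cells
    relax_time: float = 2000.0             # s, resting-state relaxation

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.record_interval < self.dt:
            raise ValueError("record_interval must be >= dt")
        bound = ftcs_stable_dt(self.spacing, self.params.D)
        if self.dt > bound * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} violates the FTCS stability bound "
                f"spacing^2/(4D) = {bound:.6g} s"
            )
        if self.abeta_leak_increase < 0:
            raise ValueError("abeta_leak_increase must be >= 0")
        if self.glu_ext < 0:
            raise ValueError("glu_ext must be >= 0")


@dataclass
class Trajectory:
    """Recorded time series for every cell plus its sampled local ATP."""

    times: np.ndarray        # (T,)
    C: np.ndarray            # (T, N)
    I: np.ndarray
    h: np.ndarray
    C_ER: np.ndarray
    A_local: np.ndarray
    positions: np.ndarray    # (N, 2)
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.C.shape[1]

    def to_dataframe(self):
        import pandas as pd

        T, N = self.C.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, N),
                "cell": np.tile(np.arange(N), T),
                "C": self.C.ravel(),
                "I": self.I.ravel(),
                "h": self.h.ravel(),
                "C_ER": self.C_ER.ravel(),
                "A_local": self.A_local.ravel(),
            }
        )


_STEADY_CACHE: dict = {}


def find_steady_state(p: ModelParams, glu_ext: float = 0.0,
                      horizon: float = 2000.0, dt: float = 0.005,
                      C_ER_init: float = 400.0) -> CellState:
    """Resting state of a single isolated cell with the noise switched off.

    The cell is relaxed for ``horizon`` seconds with no extracellular ATP.
    If the deterministic dynamics oscillate instead of settling, the state
    at the time of minimal calcium over the final quarter of the run (a
    quiescent phase of the cycle) is returned and a warning is issued.
    The relaxation is deterministic, so results are memoized on the
    parameter set.
    """
    key = (_kernels.pack_kernel_params(p).tobytes(), float(glu_ext),
           float(horizon), float(dt), float(C_ER_init))
    hit = _STEADY_CACHE.get(key)
    if hit is not None:
        return CellState(*hit)
    n_steps = int(round(horizon / dt))
    rec_every = max(1, int(round(0.5 / dt)))
    p_relax = p.with_updates(j_atp_max=0.0, sigma=0.0, delta=p.delta)
    pv = _kernels.pack_kernel_params(p_relax)
    C = np.array([1e-3]); h = np.array([0.99])
    CER = np.array([float(C_ER_init)]); I = np.array([p.I0])
    A = np.zeros((5, 5))
    idx = np.array([[2 * 5 + 2] * 4], dtype=np.int64)
    w = np.array([[1.0, 0.0, 0.0, 0.0]])
    from .model_core import gprotein_glu

    G_glu = float(gprotein_glu(glu_ext, p)) if glu_ext > 0 else 0.0
    n_rec = n_steps // rec_every
    hist = np.empty((n_rec, 4))
    noise = np.zeros((rec_every, 1))
    done = 0
    for r in range(n_rec):
        _kernels.advance_chunk(C, h, CER, I, A, idx, w, noise, dt, 2.0,
                               G_glu, pv)
        done += rec_every
        hist[r] = (C[0], h[0], CER[0], I[0])
    rem = n_steps - done
    if rem > 0:
        _kernels.advance_chunk(C, h, CER, I, A, idx, w, noise[:rem], dt,
                               2.0, G_glu, pv)
    tail = hist[int(0.75 * n_rec):]
    oscillating = np.ptp(tail[:, 0]) > 1e-3
    if oscillating:
        warnings.warn(
            "no steady state: deterministic dynamics oscillate; returning "
            "the minimum-calcium (quiescent) state of the final quarter",
            RuntimeWarning,
        )
        k = int(np.argmin(tail[:, 0]))
        state = CellState(*tail[k])
    else:
        state = CellState(C=float(C[0]), h=float(h[0]), C_ER=float(CER[0]),
                          I=float(I[0]))
        derivs = cell_derivs(state, 0.0, glu_ext, p_relax)
        if max(abs(float(d)) for d in derivs) > 1e-5:
            warnings.warn("steady-state derivatives not small at return",
                          RuntimeWarning)
    _STEADY_CACHE[key] = (float(state.C), float(state.h),
                          float(state.C_ER), float(state.I))
    return state


def euler_maruyama_step(state: CellState, field: ATPField,
                        geom: NetworkGeometry, glu_ext: float, dt: float,
                        rng: np.random.Generator, p: ModelParams,
                        n_steps: int = 1) -> CellState:
    """Advance cells and field by ``n_steps`` coupled steps, in place.

    ``state`` holds per-cell arrays; the field is modified in place and the
    updated state is returned.  Noise is drawn from ``rng`` in fixed cell
    order, one row per step.
    """
    bound = ftcs_stable_dt(field.spacing, p.D)
    if dt > bound * (1 + 1e-12):
        raise ValueError(f"dt={dt} violates FTCS stability bound {bound:.6g}")
    C = np.atleast_1d(np.asarray(state.C, dtype=float)).copy()
    h = np.atleast_1d(np.asarray(state.h, dtype=float)).copy()
    CER = np.atleast_1d(np.asarray(state.C_ER, dtype=float)).copy()
    I = np.atleast_1d(np.asarray(state.I, dtype=float)).copy()
    noise = rng.standard_normal((n_steps, C.shape[0]))
    from .model_core import gprotein_glu

    G_glu = float(gprotein_glu(glu_ext, p)) if glu_ext > 0 else 0.0
    _kernels.advance_chunk(C, h, CER, I, field.values, geom.node_index,
                           geom.weights, noise, dt, field.spacing, G_glu,
                           _kernels.pack_kernel_params(p))
    return CellState(C=C, h=h, C_ER=CER, I=I)


def run_simulation(cfg: SimulationConfig) -> Trajectory:
    """Run the full stochastic network simulation described by ``cfg``."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    geom_seed, noise_seed = ss.spawn(2)
    if cfg.cells is not None:
        cells = cfg.cells
    else:
        cells = random_field(cfg.n_cells, cfg.extent, cfg.min_dist,
                             seed=geom_seed)
    N = cells.n

    # resting state under baseline parameters, before any stimulus
    rest = find_steady_state(cfg.params, glu_ext=0.0,
                             horizon=cfg.relax_time, dt=cfg.dt,
                             C_ER_init=cfg.C_ER_init)

    p_run = cfg.params
    if cfg.abeta_leak_increase:
        p_run = p_run.with_updates(
            k_l_ext=cfg.params.k_l_ext * (1.0 + cfg.abeta_leak_increase)
        )

    field = make_field_for_positions(cells.positions, cfg.spacing, cfg.pad)
    geom = build_weights(cells.positions, field)

    C = np.full(N, float(rest.C))
    h = np.full(N, float(rest.h))
    CER = np.full(N, float(cfg.C_ER_init))
    I = np.full(N, float(rest.I))

    from .model_core import gprotein_glu

    G_glu = float(gprotein_glu(cfg.glu_ext, p_run)) if cfg.glu_ext > 0 else 0.0
    pv = _kernels.pack_kernel_params(p_run)
    rng = np.random.default_rng(noise_seed)

    rec_every = int(round(cfg.record_interval / cfg.dt))
    n_rec = int(np.floor(cfg.duration / (rec_every * cfg.dt)))
    T = n_rec + 1
    out = {k: np.empty((T, N)) for k in ("C", "I", "h", "C_ER", "A_local")}
    times = np.arange(T) * rec_every * cfg.dt

    def record(r):
        out["C"][r] = C
        out["I"][r] = I
        out["h"][r] = h
        out["C_ER"][r] = CER
        out["A_local"][r] = sample(field, geom)

    record(0)
    for r in range(1, T):
        noise = rng.standard_normal((rec_every, N))
        _kernels.advance_chunk(C, h, CER, I, field.values, geom.node_index,
                               geom.weights, noise, cfg.dt, cfg.spacing,
                               G_glu, pv)
        record(r)

    meta = {
        "seed": cfg.seed,
        "glu_ext": cfg.glu_ext,
        "abeta_leak_increase": cfg.abeta_leak_increase,
        "k_l_ext_effective": p_run.k_l_ext,
        "dt": cfg.dt,
        "spacing": cfg.spacing,
        "duration": cfg.duration,
        "backend": _kernels.BACKEND,
        "resting_state": {
            "C": float(rest.C), "h": float(rest.h),
            "C_ER": float(rest.C_ER), "I": float(rest.I),
        },
    }
    return Trajectory(times=times, C=out["C"], I=out["I"], h=out["h"],
                      C_ER=out["C_ER"], A_local=out["A_local"],
                      positions=cells.positions, meta=meta)
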