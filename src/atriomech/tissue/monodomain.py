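"""Deformation-aware monodomain solver on regular lattices.

  Cm dV/dt = -(I_ion + I_stim) + div( D C^-1 grad V )

solved with Strang splitting: half a step of the cell reaction (the fast
Rush-Larsen kernel), one Crank-Nicolson step of the anisotropic diffusion,
half a step of reaction — second-order in dt, unconditionally stable in the
diffusion.  Space is discretised with conservative finite-difference face
fluxes (no-flux boundaries by dropped boundary faces); the mixed-derivative
terms of rotated fibre fields use face-averaged cross differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from numba import njit

from ..ionic import build_cell_parameters
from ..myofilament.rice import RiceParameters
from ..cell.state import initial_state
from ..cell.kernel import build_lut, pack_params, pace_beats, cell_step
from .grid import TissueGrid

__all__ = [
    "StimulusEvent",
    "TissueTrace",
    "MonodomainSolver",
    "prepaced_state",
    "measure_cv",
]


@dataclass(frozen=True)
class StimulusEvent:
    """Rectangular current injection into a set of nodes."""

    mask: np.ndarray      # bool, grid shape
    onset: float          # ms
    duration: float       # ms
    amplitude: float      # pA per cell (positive depolarises)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


_prepace_cache: dict = {}


def prepaced_state(
    region: str,
    remodeling: str,
    beats: int = 200,
    rice: RiceParameters | None = None,
    dt: float = 0.01,
    period: float = 1000.0,
    stim_amp: float = 4000.0,
) -> np.ndarray:
    """Steady-state single-cell state used to initialise tissue nodes
    (cached per variant)."""
    rice = rice or RiceParameters()
    key = (region, remodeling, beats, dt, period, stim_amp, rice)
    if key not in _prepace_cache:
        p = build_cell_parameters(region, remodeling)
        pv = pack_params(p, rice, "cell")
        lut, aux = build_lut(dt)
        y = initial_state(rice)
        if beats > 0:
            pace_beats(y, pv, lut, aux, dt, beats, period, 2.0, stim_amp)
        _prepace_cache[key] = y
    return _prepace_cache[key].copy()


@njit(cache=True, fastmath=True)
def _reaction_sweep(Y, pv_all, vidx, lut, aux, dt, istim):
    for n in range(Y.shape[0]):
        cell_step(Y[n], pv_all[vidx[n]], lut, aux, dt, istim[n])


def assemble_operator(grid: TissueGrid) -> sp.csc_matrix:
    """Sparse discretisation of div(M grad .) with no-flux boundaries,
    M = D C^-1 (1/ms units after division by dx^2)."""
    M = grid.effective_tensor()
    dx = grid.dx
    if grid.ndim == 1:
        n = grid.n_nodes
        face = 0.5 * (M[:-1] + M[1:]) / dx**2  # (n-1,)
        main = np.zeros(n)
        main[:-1] -= face
        main[1:] -= face
        return sp.diags([face, main, face], [-1, 0, 1], format="csc")

    ny, nx = grid.shape
    n = ny * nx

    def gid(j, i):
        return j * nx + i

    rows: list = []
    cols: list = []
    vals: list = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    Mxx, Mxy, Myy = M[..., 0, 0], M[..., 0, 1], M[..., 1, 1]

    # d/dy V as a per-node stencil (central interior, one-sided at walls),
    # returned as (offsets in j, weights)
    def dy_stencil(j):
        if 0 < j < ny - 1:
            return ((j + 1, 0.5 / dx), (j - 1, -0.5 / dx))
        if j == 0:
            return ((1, 1.0 / dx), (0, -1.0 / dx))
        return ((ny - 1, 1.0 / dx), (ny - 2, -1.0 / dx))

    def dx_stencil(i):
        if 0 < i < nx - 1:
            return ((i + 1, 0.5 / dx), (i - 1, -0.5 / dx))
        if i == 0:
            return ((1, 1.0 / dx), (0, -1.0 / dx))
        return ((nx - 1, 1.0 / dx), (nx - 2, -1.0 / dx))

    inv_dx2 = 1.0 / dx**2
    # x-faces: between (j,i) and (j,i+1)
    for j in range(ny):
        for i in range(nx - 1):
            p, q = gid(j, i), gid(j, i + 1)
            a = 0.5 * (Mxx[j, i] + Mxx[j, i + 1]) * inv_dx2
            add(p, q, a); add(p, p, -a)
            add(q, p, a); add(q, q, -a)
            b = 0.5 * (Mxy[j, i] + Mxy[j, i + 1])
            if b != 0.0:
                # flux_x = b * dV/dy at the face (average of the two nodes)
                for ii in (i, i + 1):
                    for jj, w in dy_stencil(j):
                        c = 0.5 * b * w / dx
                        add(p, gid(jj, ii), c)
                        add(q, gid(jj, ii), -c)
    # y-faces: between (j,i) and (j+1,i)
    for j in range(ny - 1):
        for i in range(nx):
            p, q = gid(j, i), gid(j + 1, i)
            a = 0.5 * (Myy[j, i] + Myy[j + 1, i]) * inv_dx2
            add(p, q, a); add(p, p, -a)
            add(q, p, a); add(q, q, -a)
            b = 0.5 * (Mxy[j, i] + Mxy[j + 1, i])
            if b != 0.0:
                for jj in (j, j + 1):
                    for ii, w in dx_stencil(i):
                        c = 0.5 * b * w / dx
                        add(p, gid(jj, ii), c)
                        add(q, gid(jj, ii), -c)

    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return L.tocsc()


@dataclass
class TissueTrace:
    """Recorded fields and activation bookkeeping of one tissue run."""

    t: np.ndarray                 # frame times, ms
    V: np.ndarray                 # (n_frames, n_nodes)
    gamma: np.ndarray | None      # (n_frames, n_nodes) active strain
    activation_time: np.ndarray   # (n_nodes,) first -40 mV upcross, nan if none
    activation_count: np.ndarray  # (n_nodes,)
    last_activity: float          # time of the last upcross anywhere
    probe_t: np.ndarray | None = None
    probe_V: np.ndarray | None = None   # (n_steps, n_probes)


class MonodomainSolver:
    """Strang-split reaction-diffusion integrator over a TissueGrid."""

    def __init__(
        self,
        grid: TissueGrid,
        dt: float = 0.01,
        rice: RiceParameters | None = None,
        pre_beats: int = 200,
        states: np.ndarray | None = None,
        dt_cap: float = 0.01,
    ):
        # the default cap is the 0.01 ms electrophysiology step; callers may
        # raise it explicitly (to at most 0.02 ms) for qualitative desk-scale
        # runs, at the cost of some upstroke accuracy
        if dt_cap > 0.02 + 1e-12:
            raise ValueError("dt_cap above 0.02 ms is not supported")
        if dt > dt_cap + 1e-12:
            raise ValueError(f"dt={dt} exceeds the {dt_cap} ms electrophysiology cap")
        self.grid = grid
        self.dt = dt
        self.rice = rice or RiceParameters()
        self.t = 0.0
        self.pv_all = np.stack(
            [
                pack_params(build_cell_parameters(reg, rem), self.rice, "cell")
                for reg, rem in grid.variants
            ]
        )
        self.vidx = grid.variant_idx.ravel().astype(np.int64)
        self.lut_h, self.aux_h = build_lut(dt / 2.0)
        self.lut_f, self.aux_f = build_lut(dt)
        if states is None:
            states = np.empty((grid.n_nodes, 30))
            for k, (reg, rem) in enumerate(grid.variants):
                y = prepaced_state(reg, rem, beats=pre_beats, rice=self.rice, dt=dt)
                states[self.vidx == k] = y
        self.Y = np.ascontiguousarray(states, dtype=float)
        self._istim = np.zeros(grid.n_nodes)
        self.refresh_operator()

    # -- operator ---------------------------------------------------------
    def refresh_operator(self):
        L = assemble_operator(self.grid)
        n = L.shape[0]
        I = sp.identity(n, format="csc")
        th = 0.5 * self.dt
        self._A = splu((I - th * L).tocsc())
        self._B = (I + th * L).tocsr()

    # -- stepping ---------------------------------------------------------
    def _stim_field(self, t: float, stimuli) -> np.ndarray:
        self._istim[:] = 0.0
        for s in stimuli:
            if s.onset <= t < s.onset + s.duration:
                self._istim[s.mask.ravel()] += s.amplitude
        return self._istim

    def step(self, stimuli=()):
        """One exact Strang step: R(dt/2) - CN diffusion(dt) - R(dt/2)."""
        istim = self._stim_field(self.t, stimuli)
        _reaction_sweep(self.Y, self.pv_all, self.vidx, self.lut_h, self.aux_h,
                        self.dt / 2.0, istim)
        self.Y[:, 0] = self._A.solve(self._B @ self.Y[:, 0])
        istim = self._stim_field(self.t + self.dt / 2.0, stimuli)
        _reaction_sweep(self.Y, self.pv_all, self.vidx, self.lut_h, self.aux_h,
                        self.dt / 2.0, istim)
        self.t += self.dt

    def run(
        self,
        t_end: float,
        stimuli=(),
        record_dt: float = 1.0,
        record_gamma: bool = False,
        merged: bool = True,
        activation_threshold: float = -40.0,
        quiet_stop: float | None = None,
        probes=None,
        probe_every: int = 10,
    ) -> TissueTrace:
        """Integrate to t_end (absolute), recording V (and gamma) frames.

        ``merged=True`` fuses the trailing/leading reaction half-steps of
        consecutive Strang steps into full steps (same order of accuracy).
        ``quiet_stop``: stop early once every node has been below the
        activation threshold for that many ms (re-entry died out).
        ``probes``: flat node indices whose V is recorded every step.
        """
        nsteps = int(round((t_end - self.t) / self.dt))
        every = max(1, int(round(record_dt / self.dt)))
        last_stim_end = max((s.onset + s.duration for s in stimuli), default=-np.inf)
        SL0 = self.rice.SLset
        frames_t, frames_V, frames_g = [], [], []
        n = self.grid.n_nodes
        act_time = np.full(n, np.nan)
        act_count = np.zeros(n, dtype=np.int64)
        last_activity = -np.inf
        Vprev = self.Y[:, 0].copy()
        tprev = self.t
        probe_rows = [] if probes is not None else None
        probe_ts = [] if probes is not None else None

        def snapshot():
            frames_t.append(self.t)
            frames_V.append(self.Y[:, 0].copy())
            if record_gamma:
                frames_g.append((self.Y[:, 28] - SL0) / SL0)

        snapshot()
        pending_half = False  # a trailing reaction half-step is owed
        for k in range(nsteps):
            istim = self._stim_field(self.t, stimuli)
            if merged:
                # leading half (or fused full) reaction, then diffusion
                if pending_half:
                    _reaction_sweep(self.Y, self.pv_all, self.vidx,
                                    self.lut_f, self.aux_f, self.dt, istim)
                else:
                    _reaction_sweep(self.Y, self.pv_all, self.vidx,
                                    self.lut_h, self.aux_h, self.dt / 2.0, istim)
                self.Y[:, 0] = self._A.solve(self._B @ self.Y[:, 0])
                pending_half = True
                self.t += self.dt
                closing = (k + 1) % every == 0 or k == nsteps - 1
                if closing:
                    _reaction_sweep(self.Y, self.pv_all, self.vidx,
                                    self.lut_h, self.aux_h, self.dt / 2.0,
                                    self._stim_field(self.t, stimuli))
                    pending_half = False
            else:
                self.step(stimuli)
                closing = (k + 1) % every == 0 or k == nsteps - 1

            if probe_rows is not None and (k + 1) % probe_every == 0:
                probe_rows.append(self.Y[probes, 0].copy())
                probe_ts.append(self.t)

            if closing:
                V = self.Y[:, 0]
                up = (Vprev < activation_threshold) & (V >= activation_threshold)
                if np.any(up):
                    last_activity = self.t
                    act_count[up] += 1
                    newly = up & np.isnan(act_time)
                    if np.any(newly):
                        # linear interpolation of the threshold crossing
                        frac = (activation_threshold - Vprev[newly]) / (
                            V[newly] - Vprev[newly]
                        )
                        act_time[newly] = tprev + frac * (self.t - tprev)
                Vprev = V.copy()
                tprev = self.t
                snapshot()
                if (
                    quiet_stop is not None
                    and self.t > last_stim_end
                    and self.t - max(last_activity, 0.0) > quiet_stop
                    and V.max() < activation_threshold
                ):
                    break

        return TissueTrace(
            t=np.array(frames_t),
            V=np.array(frames_V),
            gamma=np.array(frames_g) if record_gamma else None,
            activation_time=act_time,
            activation_count=act_count,
            last_activity=last_activity,
            probe_t=None if probes is None else np.array(probe_ts),
            probe_V=None if probes is None else np.array(probe_rows),
        )


def measure_cv(grid: TissueGrid, trace: TissueTrace, probe_a, probe_b) -> float:
    """Conduction velocity (mm/ms) from activation-time difference between two
    probe nodes (flat indices for 1D, (j, i) pairs for 2D)."""
    if grid.ndim == 1:
        ia, ib = int(probe_a), int(probe_b)
        dist = abs(ib - ia) * grid.dx
        ta, tb = trace.activation_time[ia], trace.activation_time[ib]
    else:
        ny, nx = grid.shape
        (ja, ia), (jb, ib) = probe_a, probe_b
        dist = np.hypot((jb - ja), (ib - ia)) * grid.dx
        ta = trace.activation_time[ja * nx + ia]
        tb = trace.activation_time[jb * nx + ib]
    if np.isnan(ta) or np.isnan(tb):
        raise RuntimeError("a probe node was never activated; no wave to measure")
    if tb == ta:
        raise RuntimeError("zero activation-time difference between probes")
    return dist / abs(tb - ta)
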