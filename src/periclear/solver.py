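"""Explicit finite-difference integration of the two-compartment model.

Two concentration fields live on every interior (gray/white) cell of a
rasterized slice:

* ``c`` -- solute in the extracellular space (ECS). It diffuses with the
  tortuosity-scaled (possibly anisotropic) tensor, is advected by the slow
  white-matter bulk flow, and loses mass to the membrane compartment at the
  first-order take-up rate ``k_b`` (plus optional degradation ``k_d``).
* ``c_b`` -- solute inside vascular basement membranes, co-located with the
  tissue ("every point carries both layers"). It is advected by the constant
  drainage velocity ``u_b`` along the slice's drainage direction, receives
  the take-up source ``k_b * c``, and does not diffuse.

Discretization: second-order central differences in flux form for the
diffusion tensor, first-order upwind fluxes for both advection terms, and
forward Euler in time under a combined CFL/diffusive stability bound. All
fluxes are face-based and vanish on faces touching exterior or needle cells,
which realises the zero-normal-flux brain boundary (tracer carried by the
drainage field accumulates in the last interior cell upstream of the
boundary) and makes the scheme exactly conservative; for the piecewise-
constant velocity fields used in this model the upwind flux divergence is
identical to the advective form of the governing equations away from
boundaries.

During the injection window the ECS value of the needle-tip (inflow) cells
is prescribed at ``c0`` (Dirichlet); afterwards the tip either becomes a
``c = 0`` sink (the literal injection schedule, default) or reverts to
no-flux, selectable per run. The membrane field is never prescribed at the
tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import metrics
from .errors import GeometryError, SolverDivergenceError
from .geometry import GeometryGrid, RegionFields, region_fields
from .params import CaseSpec, Parameters, courant_timestep

__all__ = [
    "FieldState", "SimulationResult", "TransportOperator",
    "stable_dt", "apply_injection", "step", "run_simulation",
]

InjectionMode = Literal["dirichlet_zero", "no_flux"]

#: instability guard: any concentration beyond this multiple of c0 aborts
DIVERGENCE_FACTOR = 10.0


@dataclass
class FieldState:
    """The two concentration fields (mol m^-3) at simulation time ``t`` (s)."""

    c: np.ndarray
    c_b: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.c.copy(), self.c_b.copy(), self.t)

    @classmethod
    def zeros(cls, grid: GeometryGrid) -> "FieldState":
        shape = (grid.nx, grid.ny)
        return cls(np.zeros(shape), np.zeros(shape), 0.0)


@dataclass
class Snapshot:
    t: float
    c: np.ndarray
    c_b: np.ndarray


@dataclass
class SimulationResult:
    """Time series and snapshots recorded during one case run.

    ``times`` is the record grid (s); the three ``dist_*`` arrays hold the
    maximum detection distance (m) per compartment at those times, the
    ``moles_*`` arrays the compartment mass ledger (mol, assuming unit
    out-of-plane depth) and ``injected_net`` the cumulative net moles
    supplied through the prescribed needle-tip cells.
    """

    times: np.ndarray
    dist_ecs: np.ndarray
    dist_membrane: np.ndarray
    dist_combined: np.ndarray
    moles_ecs: np.ndarray
    moles_membrane: np.ndarray
    injected_net: np.ndarray
    snapshots: list[Snapshot]
    case: CaseSpec
    params: Parameters
    grid: GeometryGrid
    injection_mode: InjectionMode
    dt: float
    geometry_checksum: str = ""

    def __post_init__(self) -> None:
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if not self.geometry_checksum:
            self.geometry_checksum = self.grid.checksum()

    def distance_series(self, compartment: str = "combined") -> tuple[np.ndarray, np.ndarray]:
        arr = {"ecs": self.dist_ecs, "membrane": self.dist_membrane,
               "combined": self.dist_combined}[compartment]
        return self.times, arr

    def state_at(self, t: float) -> FieldState:
        """Snapshot nearest to time ``t`` (exact match expected)."""
        if not self.snapshots:
            raise ValueError("no snapshots were recorded")
        best = min(self.snapshots, key=lambda s: abs(s.t - t))
        if abs(best.t - t) > 1e-6 + 1e-9 * abs(t):
            raise KeyError(f"no snapshot at t={t} (nearest: {best.t})")
        return FieldState(best.c, best.c_b, best.t)


class TransportOperator:
    """Pre-assembled update operator for one (grid, params, case) triple.

    Face transmissibilities and masks are computed once; :meth:`step`
    advances a :class:`FieldState` by one explicit Euler step.
    """

    def __init__(self, grid: GeometryGrid, params: Parameters, case: CaseSpec,
                 injection_mode: InjectionMode = "dirichlet_zero",
                 fields: RegionFields | None = None):
        if injection_mode not in ("dirichlet_zero", "no_flux"):
            raise ValueError(f"unknown injection mode {injection_mode!r}")
        self.grid = grid
        self.params = params
        self.case = case
        self.injection_mode: InjectionMode = injection_mode
        self.fields = fields if fields is not None else region_fields(grid, params, case)
        self.injected_net = 0.0

        dx = grid.dx
        self.dx = dx
        interior = grid.interior_mask
        self.interior = interior
        inflow_mask = grid.inflow_mask
        self.inflow = grid.inflow
        self.has_inflow = inflow_mask.any()
        # cells participating in ECS diffusion: tissue plus the prescribed
        # needle-tip cells (so injected mass enters by diffusive exchange)
        active = interior | inflow_mask
        self.active = active

        # diffusion coefficients for face averaging; inflow cells borrow the
        # gray-matter value so the tip face carries a sensible conductance
        D_gray = case.diffusion_multiplier * params.D_star
        Dxx = self.fields.Dxx.copy()
        Dyy = self.fields.Dyy.copy()
        Dxy = self.fields.Dxy.copy()
        for arr, iso in ((Dxx, D_gray), (Dyy, D_gray), (Dxy, 0.0)):
            arr[inflow_mask] = iso

        pair_x = active[:-1, :] & active[1:, :]
        pair_y = active[:, :-1] & active[:, 1:]
        self._Dxx_fx = np.where(pair_x, 0.5 * (Dxx[:-1, :] + Dxx[1:, :]), 0.0)
        self._Dyy_fy = np.where(pair_y, 0.5 * (Dyy[:, :-1] + Dyy[:, 1:]), 0.0)
        self.has_cross = bool(np.any(Dxy))
        if self.has_cross:
            self._Dxy_fx = np.where(pair_x, 0.5 * (Dxy[:-1, :] + Dxy[1:, :]), 0.0)
            self._Dxy_fy = np.where(pair_y, 0.5 * (Dxy[:, :-1] + Dxy[:, 1:]), 0.0)

        # ECS advection: face-averaged bulk-flow velocity between tissue cells
        ipair_x = interior[:-1, :] & interior[1:, :]
        ipair_y = interior[:, :-1] & interior[:, 1:]
        ux_f = np.where(ipair_x, 0.5 * (self.fields.ux[:-1, :] + self.fields.ux[1:, :]), 0.0)
        uy_f = np.where(ipair_y, 0.5 * (self.fields.uy[:, :-1] + self.fields.uy[:, 1:]), 0.0)
        self._ux_f = ux_f
        self._uy_f = uy_f
        self.has_bulkflow = bool(np.any(ux_f) or np.any(uy_f))

        # membrane drainage velocity: constant direction and magnitude
        ub_speed = case.drainage_multiplier * params.u_b
        ddir = grid.drainage_direction
        self.ub_vec = (ub_speed * ddir[0], ub_speed * ddir[1])
        self._ubx_f = np.where(ipair_x, self.ub_vec[0], 0.0)
        self._uby_f = np.where(ipair_y, self.ub_vec[1], 0.0)
        self.has_drainage = ub_speed > 0.0

        # optional injection-driven radial flow, active only while injecting
        self.has_inject_flow = params.u_inject > 0 and grid.needle_tip is not None
        if self.has_inject_flow:
            tip_x, tip_y = grid.needle_tip
            X, Y = grid.cell_centers()
            r = np.hypot(X - tip_x, Y - tip_y)
            r = np.where(r > 0, r, np.inf)
            vx = params.u_inject * (X - tip_x) / r
            vy = params.u_inject * (Y - tip_y) / r
            self._inj_ux_f = np.where(ipair_x, 0.5 * (vx[:-1, :] + vx[1:, :]), 0.0)
            self._inj_uy_f = np.where(ipair_y, 0.5 * (vy[:, :-1] + vy[:, 1:]), 0.0)

        self.k_up = case.uptake_multiplier * params.k_b
        self.k_d = params.k_d
        self._cell_volume = dx * dx  # unit out-of-plane depth

    # -- stability ---------------------------------------------------------
    def stable_dt(self) -> float:
        """Largest stable Euler step: min of advective CFL and diffusive cap."""
        if self.dx <= 0:
            raise GeometryError("grid spacing must be positive")
        speeds = [self.fields.max_speed_l1,
                  abs(self.ub_vec[0]) + abs(self.ub_vec[1])]
        if self.has_inject_flow:
            speeds.append(2.0 * self.params.u_inject)  # |vx|+|vy| <= sqrt(2) u
        adv = courant_timestep(self.dx, max(speeds), self.params.C_max)
        max_eig = self.fields.max_eigenvalue
        diff = math.inf if max_eig == 0 else 0.9 * self.dx**2 / (4.0 * max_eig)
        return min(adv, diff)

    # -- injection ---------------------------------------------------------
    def apply_injection(self, state: FieldState) -> None:
        """Prescribe the needle-tip ECS value appropriate for ``state.t``.

        Mass added or removed by the prescription is accumulated into
        ``injected_net`` so the ledger stays auditable. ``c_b`` is never
        prescribed (the tip is a no-flux obstacle for the membrane field).
        """
        if not self.has_inflow:
            return
        t = state.t
        p = self.params
        if t <= p.t_inject + 1e-12 and p.t_inject > 0:
            target = p.c0
        elif self.injection_mode == "dirichlet_zero":
            target = 0.0
        else:  # no_flux: tip cells evolve freely after the injection
            return
        before = state.c[self.inflow].sum()
        state.c[self.inflow] = target
        self.injected_net += (target * self.inflow[0].size - before) * self._cell_volume

    # -- single step -------------------------------------------------------
    def step(self, state: FieldState, dt: float) -> FieldState:
        """Advance by one forward-Euler step of size ``dt`` (s)."""
        c, cb = state.c, state.c_b
        dx = self.dx

        # ECS diffusion: conservative face fluxes of the full tensor
        Fx = self._Dxx_fx * (c[1:, :] - c[:-1, :])
        Fy = self._Dyy_fy * (c[:, 1:] - c[:, :-1])
        if self.has_cross:
            gx, gy = self._masked_gradients(c)
            Fx += self._Dxy_fx * 0.5 * (gy[:-1, :] + gy[1:, :]) * dx
            Fy += self._Dxy_fy * 0.5 * (gx[:, :-1] + gx[:, 1:]) * dx
        dc = np.zeros_like(c)
        dc[:-1, :] += Fx
        dc[1:, :] -= Fx
        dc[:, :-1] += Fy
        dc[:, 1:] -= Fy
        dc /= dx * dx

        # ECS advection (upwind fluxes), only with bulk flow switched on
        if self.has_bulkflow:
            dc -= self._upwind_divergence(c, self._ux_f, self._uy_f)
        if self.has_inject_flow and state.t < self.params.t_inject:
            dc -= self._upwind_divergence(c, self._inj_ux_f, self._inj_uy_f)

        # compartment exchange and degradation
        if self.k_up or self.k_d:
            uptake = np.where(self.interior, self.k_up * c, 0.0)
            dcb = uptake - (self._upwind_divergence(cb, self._ubx_f, self._uby_f)
                            if self.has_drainage else 0.0)
            dc -= uptake
            if self.k_d:
                dc -= np.where(self.interior, self.k_d * c, 0.0)
        elif self.has_drainage:
            dcb = -self._upwind_divergence(cb, self._ubx_f, self._uby_f)
        else:
            dcb = None

        new_c = c + dt * dc
        new_cb = cb + dt * dcb if dcb is not None else cb.copy()
        out = FieldState(new_c, new_cb, state.t + dt)
        self.apply_injection(out)
        self._check_finite(out)
        return out

    def _masked_gradients(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # cell-centred first derivatives as the average of the valid one-sided
        # differences (central in the interior, one-sided at region edges);
        # used only for the tensor cross terms of rotated fibre axes
        fwd = np.zeros_like(c)
        bwd = np.zeros_like(c)
        vf = np.zeros_like(c)
        vb = np.zeros_like(c)
        fwd[:-1, :] = (c[1:, :] - c[:-1, :]) * (self.active[1:, :] & self.active[:-1, :])
        vf[:-1, :] = (self.active[1:, :] & self.active[:-1, :])
        bwd[1:, :] = fwd[:-1, :]
        vb[1:, :] = vf[:-1, :]
        gx = np.divide(fwd + bwd, np.maximum(vf + vb, 1.0)) / self.dx
        fwd[:] = 0.0
        vf[:] = 0.0
        fwd[:, :-1] = (c[:, 1:] - c[:, :-1]) * (self.active[:, 1:] & self.active[:, :-1])
        vf[:, :-1] = (self.active[:, 1:] & self.active[:, :-1])
        bwd[:] = 0.0
        vb[:] = 0.0
        bwd[:, 1:] = fwd[:, :-1]
        vb[:, 1:] = vf[:, :-1]
        gy = np.divide(fwd + bwd, np.maximum(vf + vb, 1.0)) / self.dx
        return gx, gy

    def _upwind_divergence(self, c: np.ndarray, ux_f: np.ndarray,
                           uy_f: np.ndarray) -> np.ndarray:
        """div(u c) with first-order upwind face fluxes, zero at boundaries."""
        Fx = np.where(ux_f > 0, c[:-1, :], c[1:, :]) * ux_f
        Fy = np.where(uy_f > 0, c[:, :-1], c[:, 1:]) * uy_f
        # face f sits between cells f and f+1: outflow through the right/top
        # face of a cell minus inflow through its left/bottom face
        div = np.zeros_like(c)
        div[:-1, :] += Fx
        div[1:, :] -= Fx
        div[:, :-1] += Fy
        div[:, 1:] -= Fy
        return div / self.dx

    def _check_finite(self, state: FieldState) -> None:
        cap = DIVERGENCE_FACTOR * max(self.params.c0, 1e-300)
        for name, arr in (("c", state.c), ("c_b", state.c_b)):
            m = float(np.abs(arr).max(initial=0.0))
            if not math.isfinite(m) or m > cap:
                raise SolverDivergenceError(
                    f"solver diverged in field {name} at t={state.t:.3f} s "
                    f"(max |{name}| = {m:.3e}, cap = {cap:.3e})", t=state.t)

    # -- mass ledger -------------------------------------------------------
    def moles(self, state: FieldState) -> tuple[float, float]:
        v = self._cell_volume
        return (float(state.c[self.active].sum()) * v,
                float(state.c_b[self.interior].sum()) * v)


def stable_dt(grid: GeometryGrid, fields: RegionFields, params: Parameters,
              case: CaseSpec | None = None) -> float:
    """Stable Euler step for the given grid and transport coefficients."""
    from .params import build_case
    case = case if case is not None else build_case("C1")
    return TransportOperator(grid, params, case, fields=fields).stable_dt()


def apply_injection(state: FieldState, t: float, params: Parameters,
                    grid: GeometryGrid,
                    mode: InjectionMode = "dirichlet_zero") -> FieldState:
    """Functional wrapper: return a copy with the injection BC applied at ``t``."""
    from .params import build_case
    out = state.copy()
    out.t = t
    op = TransportOperator(grid, params, build_case("A1"), injection_mode=mode)
    op.apply_injection(out)
    return out


def step(state: FieldState, grid: GeometryGrid, fields: RegionFields | None,
         params: Parameters, case: CaseSpec, dt: float,
         injection_mode: InjectionMode = "dirichlet_zero") -> FieldState:
    """Single-step convenience wrapper around :class:`TransportOperator`.

    Builds the operator on every call; for time loops use the operator (or
    :func:`run_simulation`) directly.
    """
    op = TransportOperator(grid, params, case, injection_mode=injection_mode,
                           fields=fields)
    return op.step(state, dt)


def run_simulation(case: CaseSpec, grid: GeometryGrid, params: Parameters,
                   *, record_dt: float = 10.0, snapshot_dt: float = 120.0,
                   injection_mode: InjectionMode = "dirichlet_zero",
                   initial_state: FieldState | None = None,
                   t_total: float | None = None,
                   progress=None) -> SimulationResult:
    """Integrate one case from t = 0 to ``t_total`` and record the outcome.

    The run is deterministic: the step size is the largest stable Euler step
    rounded down so an integer number of steps lands exactly on every record
    time. Detection distances (threshold ``params.detection_threshold``,
    origin ``grid.needle_tip``) and the compartment mass ledger are recorded
    every ``record_dt`` seconds; full field snapshots every ``snapshot_dt``
    seconds (and at the final time).

    Parameters
    ----------
    initial_state:
        Optional starting fields (e.g. an instantaneous point release for
        analytic validation); defaults to all-zero fields.
    progress:
        Optional callback ``f(t, state)`` invoked at every record time.
    """
    t_end = params.t_total if t_total is None else float(t_total)
    if t_end <= 0:
        raise ValueError(f"t_total must be > 0, got {t_end!r}")
    if record_dt <= 0:
        raise ValueError(f"record_dt must be > 0, got {record_dt!r}")

    op = TransportOperator(grid, params, case, injection_mode=injection_mode)
    dt_cap = op.stable_dt()
    n_sub = max(1, math.ceil(record_dt / min(dt_cap, record_dt)))
    dt = record_dt / n_sub

    state = initial_state.copy() if initial_state is not None else FieldState.zeros(grid)
    state.t = 0.0
    op.apply_injection(state)

    origin = grid.needle_tip if grid.needle_tip is not None else (
        grid.origin[0] + (grid.nx - 1) * grid.dx / 2,
        grid.origin[1] + (grid.ny - 1) * grid.dx / 2)
    thr = params.detection_threshold

    times, d_e, d_m, d_c, m_e, m_m, inj = [], [], [], [], [], [], []
    snapshots: list[Snapshot] = []
    n_rec = math.ceil(t_end / record_dt - 1e-9)
    snap_every = max(1, round(snapshot_dt / record_dt))

    def record(k: int) -> None:
        t = k * record_dt
        times.append(min(t, t_end))
        d_e.append(metrics._max_distance(state.c, grid, origin, thr))
        d_m.append(metrics._max_distance(state.c_b, grid, origin, thr))
        d_c.append(metrics._max_distance(np.maximum(state.c, state.c_b), grid, origin, thr))
        me, mm = op.moles(state)
        m_e.append(me)
        m_m.append(mm)
        inj.append(op.injected_net)
        if k % snap_every == 0 or k == n_rec:
            snapshots.append(Snapshot(times[-1], state.c.copy(), state.c_b.copy()))
        if progress is not None:
            progress(times[-1], state)

    record(0)
    for k in range(1, n_rec + 1):
        block_end = min(k * record_dt, t_end)
        steps = n_sub if k * record_dt <= t_end + 1e-9 else \
            max(1, math.ceil((block_end - (k - 1) * record_dt) / dt))
        for _ in range(steps):
            state = op.step(state, dt)
        state.t = block_end  # suppress floating-point drift
        record(k)

    return SimulationResult(
        times=np.asarray(times), dist_ecs=np.asarray(d_e),
        dist_membrane=np.asarray(d_m), dist_combined=np.asarray(d_c),
        moles_ecs=np.asarray(m_e), moles_membrane=np.asarray(m_m),
        injected_net=np.asarray(inj), snapshots=snapshots, case=case,
        params=params, grid=grid, injection_mode=injection_mode, dt=dt)
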