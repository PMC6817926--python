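"""Numerical cross-examination of the closed-form families.

A method-of-lines integrator for the dimensionless system (prey without
diffusion, predator with unit diffusivity, zero-flux walls), plus
manufactured-solution convergence machinery, a level-crossing wave-speed
estimator, and a verification report that measures -- layer by layer -- what
a closed-form family actually solves: the combined scalar ODE (which the
construction annihilates), the prey/predator system ODEs separately (which
it need not), positivity, far-field limits, and drift against a PDE run
initialized from the closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from typing import Callable

import numpy as np

from .model import ScaledParams, equilibria, kinetics
from .travelling_wave import ClosedFormProfile, WaveFrame, residual_combined, residual_system

__all__ = [
    "SimGrid",
    "SimResult",
    "VerificationReport",
    "NoFrontError",
    "pde_simulate",
    "wave_speed_estimate",
    "manufactured_problem",
    "mms_convergence_orders",
    "verify_family",
]


class NoFrontError(RuntimeError):
    """The requested level is not crossed exactly once per snapshot."""


@dataclass(frozen=True)
class SimGrid:
    """Spatial grid and time-stepping contract.

    ``dt=None`` selects the explicit-diffusion stability bound
    ``safety * dx**2 / 2``.  Boundary condition is zero-flux (reflecting).
    """

    x0: float
    x1: float
    nx: int
    T: float
    dt: float | None = None
    bc: str = "zero-flux"
    safety: float = 0.4

    def __post_init__(self) -> None:
        if self.nx < 16:
            raise ValueError("nx must be >= 16")
        if not self.x1 > self.x0:
            raise ValueError("x1 must exceed x0")
        if self.bc != "zero-flux":
            raise ValueError("only zero-flux boundaries are implemented")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x0, self.x1, self.nx)

    @property
    def dx(self) -> float:
        return (self.x1 - self.x0) / (self.nx - 1)

    def stable_dt(self) -> float:
        limit = self.safety * self.dx**2 / 2.0
        return min(self.dt, limit) if self.dt is not None else limit


@dataclass
class SimResult:
    """Space-time fields at snapshot times; diagnostics recomputed on demand."""

    x: np.ndarray
    times: np.ndarray
    U: list
    V: list
    aborted: bool = False
    meta: dict = field(default_factory=dict)

    def diagnostics(self) -> dict:
        d = {
            "aborted": self.aborted,
            "times": [float(t) for t in self.times],
            "U_min": [float(np.nanmin(u)) for u in self.U],
            "U_max": [float(np.nanmax(u)) for u in self.U],
            "V_min": [float(np.nanmin(v)) for v in self.V],
            "V_max": [float(np.nanmax(v)) for v in self.V],
        }
        d["positivity_violations"] = int(
            sum(int(np.sum(np.asarray(u) < 0) + np.sum(np.asarray(v) < 0)) for u, v in zip(self.U, self.V))
        )
        return d


def _laplacian_zero_flux(V: np.ndarray, dx: float) -> np.ndarray:
    lap = np.empty_like(V)
    lap[1:-1] = (V[2:] - 2.0 * V[1:-1] + V[:-2]) / dx**2
    lap[0] = 2.0 * (V[1] - V[0]) / dx**2       # mirror ghost node
    lap[-1] = 2.0 * (V[-2] - V[-1]) / dx**2
    return lap


def _solve_tridiag(sub, diag, sup, d):
    from scipy.linalg import solve_banded

    ab = np.zeros((3, len(d)))
    ab[0, 1:] = sup[:-1]
    ab[1, :] = diag
    ab[2, :-1] = sub[1:]
    return solve_banded((1, 1), ab, d)


def pde_simulate(
    p: ScaledParams,
    U0,
    V0,
    grid: SimGrid,
    snapshot_times=None,
    source_u: Callable | None = None,
    source_v: Callable | None = None,
    method: str = "explicit",
) -> SimResult:
    """Integrate U_t = f_U (+ s_U), V_t = V_xx + f_V (+ s_V) on the grid.

    ``method='explicit'`` is forward Euler under the diffusion stability
    bound; ``method='imex'`` treats diffusion backward-Euler (tridiagonal
    solve) and the reaction explicitly, for stiff runs.  Runs whose fields
    exceed 1e6 in magnitude are aborted and flagged, not raised.
    """
    x = grid.x
    U = np.array(U0(x) if callable(U0) else U0, dtype=float).copy()
    V = np.array(V0(x) if callable(V0) else V0, dtype=float).copy()
    if U.shape != x.shape or V.shape != x.shape:
        raise ValueError("initial profiles must match the grid")
    snaps = np.asarray(sorted(snapshot_times) if snapshot_times is not None else [grid.T], dtype=float)
    if snaps[-1] > grid.T + 1e-12:
        raise ValueError("snapshot times must not exceed T")

    dt_target = grid.stable_dt() if method == "explicit" else (grid.dt or grid.T / 200.0)
    dx = grid.dx
    times_out, Us, Vs = [], [], []
    aborted = False
    t = 0.0
    if snaps[0] == 0.0:
        times_out.append(0.0)
        Us.append(U.copy())
        Vs.append(V.copy())
        snaps = snaps[1:]

    for target in snaps:
        seg = target - t
        nsteps = max(1, ceil(seg / dt_target - 1e-12))
        dt = seg / nsteps
        if method == "imex":
            rr = dt / dx**2
            sub = np.full(grid.nx, -rr)
            sup = np.full(grid.nx, -rr)
            diag = np.full(grid.nx, 1.0 + 2.0 * rr)
            sup[0] = -2.0 * rr
            sub[-1] = -2.0 * rr
        for _ in range(nsteps):
            fU, fV = kinetics(U, V, p)
            if source_u is not None:
                fU = fU + source_u(x, t)
            if source_v is not None:
                fV = fV + source_v(x, t)
            if method == "explicit":
                V = V + dt * (_laplacian_zero_flux(V, dx) + fV)
                U = U + dt * fU
            else:
                U = U + dt * fU
                V = _solve_tridiag(sub, diag, sup, V + dt * fV)
            t += dt
            if not np.isfinite(U).all() or not np.isfinite(V).all() or max(np.max(np.abs(U)), np.max(np.abs(V))) > 1e6:
                aborted = True
                break
        times_out.append(t)
        Us.append(U.copy())
        Vs.append(V.copy())
        if aborted:
            break
    return SimResult(x=x, times=np.asarray(times_out), U=Us, V=Vs, aborted=aborted,
                     meta={"method": method, "dt_target": dt_target, "nx": grid.nx})


def wave_speed_estimate(res: SimResult, level: float, which: str = "U"):
    """Front speed from a linear fit of level-crossing position vs. time.

    Each snapshot must cross ``level`` exactly once (linear interpolation
    between grid points).  Returns ``(speed, fit_rmse)``.
    """
    if len(res.times) < 3:
        raise NoFrontError("need at least 3 snapshots for a speed fit")
    fields = res.U if which == "U" else res.V
    xs = []
    for f in fields:
        g = np.asarray(f) - level
        crossings = [float(res.x[i]) for i in np.nonzero(g == 0.0)[0]]
        idx = np.nonzero(g[:-1] * g[1:] < 0)[0]
        idx = idx[np.isfinite(g[idx]) & np.isfinite(g[idx + 1])]
        for i in idx:
            x0, x1 = res.x[i], res.x[i + 1]
            crossings.append(float(x0 - g[i] * (x1 - x0) / (g[i + 1] - g[i])))
        if len(crossings) != 1:
            raise NoFrontError(f"level {level} crossed {len(crossings)} times; need exactly one")
        xs.append(crossings[0])
    coef = np.polyfit(res.times, xs, 1)
    fit = np.polyval(coef, res.times)
    rmse = float(np.sqrt(np.mean((fit - np.asarray(xs)) ** 2)))
    return float(coef[0]), rmse


def manufactured_problem(p: ScaledParams):
    """Manufactured solution U* = exp(-t)sin(x)+2, V* = exp(-t)cos(x)+2 on [0, pi].

    Returns callables ``(U*, V*, s_U, s_V)`` where the sources make (U*, V*)
    an exact solution of the forced system; V* satisfies zero-flux at 0 and
    pi (U carries no diffusion, so it needs no boundary condition).
    """
    import sympy as sp

    x, t = sp.symbols("x t", real=True)
    Us = sp.exp(-t) * sp.sin(x) + 2
    Vs = sp.exp(-t) * sp.cos(x) + 2
    fU = Us - Us**2 - Us * Vs - Us * Vs**2
    fV = p.k1 * (-p.k2 * Vs - Vs**2 + Us * Vs + Us * Vs**2)
    sU = sp.simplify(sp.diff(Us, t) - fU)
    sV = sp.simplify(sp.diff(Vs, t) - sp.diff(Vs, x, 2) - fV)
    L = lambda e: sp.lambdify((x, t), e, "numpy")
    return L(Us), L(Vs), L(sU), L(sV)


def mms_convergence_orders(p: ScaledParams, nxs=(64, 128, 256), T: float = 0.25) -> list[float]:
    """Observed spatial convergence orders from successive grid refinements."""
    Ue, Ve, sU, sV = manufactured_problem(p)
    errs = []
    for nx in nxs:
        grid = SimGrid(0.0, float(np.pi), nx, T)
        res = pde_simulate(p, lambda x: Ue(x, 0.0), lambda x: Ve(x, 0.0), grid,
                           source_u=sU, source_v=sV)
        x, tT = res.x, res.times[-1]
        err = max(np.max(np.abs(res.U[-1] - Ue(x, tT))), np.max(np.abs(res.V[-1] - Ve(x, tT))))
        errs.append(err)
    return [float(np.log2(errs[i] / errs[i + 1])) for i in range(len(errs) - 1)]


@dataclass
class VerificationReport:
    """What a closed-form family actually solves, measured."""

    family: dict
    max_combined_residual: float
    max_prey_residual: float
    max_predator_residual: float
    sum_identity_max_gap: float
    masked_points: int
    min_U: float
    min_V: float
    positivity_ok: bool
    edge_values: dict
    nearest_equilibrium: dict
    pde_divergence: list

    def to_json(self, **kw) -> str:
        def conv(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(o)

        from dataclasses import asdict

        return json.dumps(asdict(self), default=conv, **kw)


def verify_family(
    profile: ClosedFormProfile,
    p: ScaledParams,
    window=(-4.0, 4.0),
    n: int = 801,
    pde_T: float = 1.0,
    pde_pad: float = 6.0,
    pde_dx: float = 0.05,
) -> VerificationReport:
    """Measure the residual layers and PDE drift of a closed-form profile.

    The combined-ODE residual is expected at round-off level by
    construction; the prey/predator system residuals are reported without
    any smallness claim.  The PDE comparison initializes the simulator from
    the profile at t = 0 on a padded domain and records the max divergence
    at a few snapshot times (a measurement, not a pass/fail check).
    """
    grid = np.linspace(window[0], window[1], n)
    frame = WaveFrame(profile.c, grid)
    pp = profile.profile_pair()
    ra, rb = residual_system(pp, frame, p)
    rc = residual_combined(pp, frame, p)
    gap = np.abs(rc - (ra + rb))
    masked = int(np.sum(~np.isfinite(rc)))
    u = pp.eval(grid)[0]
    v = pp.eval(grid)[2]

    eqs = equilibria(p)
    edge = {"left": (float(u[0]), float(v[0])), "right": (float(u[-1]), float(v[-1]))}
    nearest = {}
    for side in ("left", "right"):
        pu, pv = edge[side]
        dists = [(np.hypot(e.U_star - pu, e.V_star - pv), e) for e in eqs]
        d, e = min(dists, key=lambda t: t[0])
        nearest[side] = {"U_star": e.U_star, "V_star": e.V_star, "tag": e.stability_tag, "distance": float(d)}

    x0, x1 = window[0] - pde_pad, window[1] + pde_pad
    nx = max(16, int(round((x1 - x0) / pde_dx)) + 1)
    sgrid = SimGrid(x0, x1, nx, pde_T)
    U0, V0 = profile.evaluate(sgrid.x, 0.0)
    U0 = np.nan_to_num(U0)
    V0 = np.nan_to_num(V0)
    snaps = list(np.linspace(0.0, pde_T, 5))
    res = pde_simulate(p, U0, V0, sgrid, snapshot_times=snaps)
    div = []
    for t, Ut, Vt in zip(res.times, res.U, res.V):
        Ue, Ve = profile.evaluate(res.x, float(t))
        m = np.isfinite(Ue) & np.isfinite(Ve)
        div.append(
            {
                "t": float(t),
                "max_dU": float(np.max(np.abs(Ut[m] - Ue[m]))) if m.any() else float("nan"),
                "max_dV": float(np.max(np.abs(Vt[m] - Ve[m]))) if m.any() else float("nan"),
            }
        )

    def nmax(a):
        return float(np.nanmax(np.abs(a))) if np.any(np.isfinite(a)) else float("nan")

    minU, minV = float(np.nanmin(u)), float(np.nanmin(v))
    return VerificationReport(
        family=dict(profile.meta),
        max_combined_residual=nmax(rc),
        max_prey_residual=nmax(ra),
        max_predator_residual=nmax(rb),
        sum_identity_max_gap=float(np.nanmax(gap)) if np.any(np.isfinite(gap)) else float("nan"),
        masked_points=masked,
        min_U=minU,
        min_V=minV,
        positivity_ok=bool(minU >= 0 and minV >= 0),
        edge_values=edge,
        nearest_equilibrium=nearest,
        pde_divergence=div,
    )
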