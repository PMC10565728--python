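"""Coupled population/strategy dynamics and singular-point analysis.

The state of a community of n lineages is (x_1..x_n, u_1..u_n) with

    dx_i/dt = x_i * G(v = u_i)
    du_i/dt = k_i * dG/dv | v = u_i

integrated piecewise between environmental discontinuities.  Extinction is
checked at every recorded sample: a lineage whose density has fallen below
the extinction threshold is removed from all competition sums, its density
set to zero and its strategy frozen.  An optional speciation rule (used by
the adaptive-radiation scenario) may insert daughter lineages whenever a
parent's strategy sits close enough to a convergent-stable minimum of the
adaptive landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from .model import (
    Environment,
    ModelParams,
    Species,
    _community_arrays,
    _landscape_terms,
    equilibrium_single_species,
    fitness,
    landscape_curvature,
    selection_gradient,
)

__all__ = [
    "Event",
    "Trajectory",
    "SingularPoint",
    "SpeciationRule",
    "IntegrationError",
    "rhs",
    "simulate",
    "find_singular_points",
    "verify_ess",
]

RTOL = 1e-8
ATOL = 1e-10
NEG_CLIP = 1e-9  # integration overshoot below zero tolerated up to here


class IntegrationError(RuntimeError):
    """The ODE solver failed to meet its tolerances."""


@dataclass(frozen=True)
class Event:
    time: float
    kind: Literal["extinction", "speciation", "env_change"]
    species_id: str | None = None
    info: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Densely sampled record of a simulation.

    ``density``/``strategy`` are (T, N) arrays; entries are NaN before a
    lineage's birth sample and density is 0 from its extinction sample on.
    """

    times: np.ndarray
    species_ids: list[str]
    density: np.ndarray
    strategy: np.ndarray
    gamma: np.ndarray
    events: list[Event]
    species: list[Species]
    config: dict = field(default_factory=dict)

    def index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def extinction_time(self, species_id: str) -> float | None:
        for ev in self.events:
            if ev.kind == "extinction" and ev.species_id == species_id:
                return ev.time
        return None

    def extant_ids(self) -> list[str]:
        return [s.id for s in self.species if s.extant]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (rows before a lineage's birth dropped)."""
        frames = []
        for j, sid in enumerate(self.species_ids):
            born = ~np.isnan(self.strategy[:, j])
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times[born],
                        "species_id": sid,
                        "density": self.density[born, j],
                        "strategy": self.strategy[born, j],
                        "gamma": self.gamma[born],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SingularPoint:
    """A root of the selection gradient with its local classification."""

    v_star: float
    curvature: float
    kind: Literal["ess_peak", "convergent_minimum", "other"]


@dataclass(frozen=True)
class SpeciationRule:
    """Adaptive-speciation trigger used by the radiation scenario.

    When an extant lineage's strategy comes within ``trigger_distance`` of a
    convergent-stable minimum of the landscape, a daughter is inserted with
    the parent's evolvability, a strategy offset drawn on
    [-offset, +offset] (``offset_mode="uniform"``) or from {-offset, +offset}
    (``"two_point"``), and density ``daughter_density``.

    The trigger is edge-sensitive with hysteresis: a lineage fires when it
    *enters* the ``trigger_distance`` neighborhood of a minimum, and must
    retreat beyond ``rearm_distance`` from every minimum before it can
    fire again — so a parent parked on a (numerically jittering) minimum
    does not re-speciate every sample.  A lineage is also barred for
    ``refractory`` time units after its birth or last speciation, giving
    the landscape time to re-equilibrate.
    """

    trigger_distance: float = 0.02
    offset: float = 0.02
    offset_mode: Literal["uniform", "two_point"] = "uniform"
    daughter_density: float = 1.0
    refractory: float = 5.0
    rearm_distance: float = 0.04
    max_species: int = 64
    search_interval: tuple[float, float] = (-20.0, 20.0)
    grid_step: float = 0.01


def rhs(
    t: float,
    state: np.ndarray,
    k: np.ndarray,
    extant: np.ndarray,
    gamma,
    params: ModelParams,
) -> np.ndarray:
    """Time derivative of the packed state (x_1..x_n, u_1..u_n).

    ``gamma`` may be a number or a callable of time (smooth schedules).
    Extinct lineages contribute nothing to competition and have zero
    derivatives, so their density stays 0 and their strategy frozen.
    """
    n = k.size
    x = np.clip(state[:n], 0.0, None) * extant
    u = state[n:]
    g = gamma(t) if callable(gamma) else gamma
    dx = np.zeros(n)
    du = np.zeros(n)
    if extant.any():
        idx = np.flatnonzero(extant)
        base, g1 = _landscape_terms(u[idx], u[idx], x[idx], g, params, order=1)
        dx[idx] = x[idx] * (base - params.d * k[idx])
        du[idx] = k[idx] * g1
    return np.concatenate([dx, du])


def _daughter_id(parent_id: str, existing: Sequence[str]) -> str:
    prefix = parent_id.rsplit("_", 1)[0]
    n = sum(1 for s in existing if s.rsplit("_", 1)[0] == prefix)
    return f"{prefix}_{n}"


def simulate(
    community: Sequence[Species],
    env: Environment,
    params: ModelParams,
    t_end: float,
    record_dt: float = 1.0,
    rng_seed: int | np.random.SeedSequence | None = None,
    speciation: SpeciationRule | None = None,
    config: dict | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the community forward to ``t_end``.

    The integrator (LSODA, rtol=1e-8, atol=1e-10) is restarted at every
    environmental discontinuity so no step straddles a jump in gamma, and
    at every extinction or speciation event.  Events are detected at the
    recorded samples (spacing ``record_dt``): extinction when density drops
    strictly below ``params.extinction_threshold``.

    ``rng_seed`` is the master seed; environmental redraws and speciation
    offsets consume separate child streams, so e.g. adding lineages does
    not shift the gamma sequence.
    """
    if t_end <= 0 or record_dt <= 0:
        raise ValueError("t_end and record_dt must be positive")
    species = [replace(s) for s in community]
    if not species:
        raise ValueError("community must contain at least one species")
    if len({s.id for s in species}) != len(species):
        raise ValueError("species ids must be unique")

    master = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(0 if rng_seed is None else rng_seed)
    )
    env_ss, spec_ss = master.spawn(2)
    env_rng = np.random.default_rng(
        env.seed if env.seed is not None else env_ss
    )
    spec_rng = np.random.default_rng(spec_ss)
    realized = env.realize(t_end, env_rng)

    ids = [s.id for s in species]
    x = np.array([s.x for s in species], dtype=float)
    u = np.array([s.u for s in species], dtype=float)
    karr = np.array([s.k for s in species], dtype=float)
    extant = np.array([s.extant for s in species], dtype=bool)
    last_speciation = np.array([s.birth_time for s in species], dtype=float)
    armed = np.ones(len(species), dtype=bool)  # outside any minimum's neighborhood

    times: list[float] = []
    gammas: list[float] = []
    rows_x: list[np.ndarray] = []
    rows_u: list[np.ndarray] = []
    events: list[Event] = []

    def add_species(parent_j: int, t: float) -> None:
        nonlocal x, u, karr, extant, last_speciation, armed
        parent = species[parent_j]
        if speciation.offset_mode == "two_point":
            off = float(spec_rng.choice([-speciation.offset, speciation.offset]))
        else:
            off = float(spec_rng.uniform(-speciation.offset, speciation.offset))
        sid = _daughter_id(parent.id, ids)
        child = Species(
            id=sid,
            k=parent.k,
            u=float(u[parent_j]) + off,
            x=speciation.daughter_density,
            parent_id=parent.id,
            birth_time=t,
        )
        species.append(child)
        ids.append(sid)
        x = np.append(x, child.x)
        u = np.append(u, child.u)
        karr = np.append(karr, child.k)
        extant = np.append(extant, True)
        last_speciation = np.append(last_speciation, t)
        armed = np.append(armed, False)  # born inside the neighborhood
        last_speciation[parent_j] = t
        armed[parent_j] = False
        events.append(
            Event(t, "speciation", sid, {"parent_id": parent.id, "u": child.u})
        )

    def snapshot() -> list[Species]:
        return [
            Species(id=ids[j], k=karr[j], u=float(u[j]), x=float(x[j]))
            for j in range(len(ids))
            if extant[j]
        ]

    def process_sample(t: float, g: float) -> bool:
        """Extinction/speciation bookkeeping at a recorded sample."""
        t = float(t)
        changed = False
        if params.extinction_threshold > 0:
            for j in np.flatnonzero(extant):
                if x[j] < params.extinction_threshold:
                    extant[j] = False
                    x[j] = 0.0
                    species[j].u = float(u[j])
                    species[j].mark_extinct(t)
                    events.append(Event(t, "extinction", ids[j]))
                    changed = True
        if speciation is not None and extant.any():
            minima = [
                sp.v_star
                for sp in find_singular_points(
                    karr[0],
                    snapshot(),
                    g,
                    params,
                    search_interval=speciation.search_interval,
                    grid_step=speciation.grid_step,
                )
                if sp.kind == "convergent_minimum"
            ]
            for j in sorted(np.flatnonzero(extant), key=lambda j: ids[j]):
                dist = (
                    min(abs(u[j] - m) for m in minima) if minima else np.inf
                )
                if dist > speciation.rearm_distance:
                    armed[j] = True
                elif (
                    dist < speciation.trigger_distance
                    and armed[j]
                    and len(ids) < speciation.max_species
                    and t - last_speciation[j]
                    >= speciation.refractory - 1e-9
                ):
                    add_species(j, t)
                    changed = True
        times.append(t)
        gammas.append(float(g))
        rows_x.append(x.copy())
        rows_u.append(u.copy())
        return changed

    samples = np.arange(0.0, t_end + record_dt * 0.5, record_dt)
    bps = [float(b) for b in realized.breakpoints if b < t_end - 1e-9]
    bounds = [0.0] + bps + [float(t_end)]

    gamma0 = realized.gamma(0.0)
    process_sample(0.0, float(gamma0))
    next_sample = 1  # index into `samples`

    for a, b in zip(bounds, bounds[1:]):
        if a > 0.0:
            events.append(
                Event(a, "env_change", None, {"gamma": float(realized.gamma(a))})
            )
        gamma_seg = realized.func if realized.func is not None else float(
            realized.gamma(a)
        )
        t_cur = a
        while t_cur < b - 1e-9:
            t_pts = list(samples[next_sample:][samples[next_sample:] <= b + 1e-9])
            flags = [True] * len(t_pts)
            if not t_pts or t_pts[-1] < b - 1e-9:
                t_pts.append(b)
                flags.append(False)
            y0 = np.concatenate([x, u])
            sol = solve_ivp(
                rhs,
                (t_cur, t_pts[-1]),
                y0,
                t_eval=t_pts,
                args=(karr, extant.copy(), gamma_seg, params),
                method="LSODA",
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"integration failed on [{t_cur}, {t_pts[-1]}]: {sol.message}"
                )
            interrupted = False
            for jcol, (tj, is_sample) in enumerate(zip(t_pts, flags)):
                n = karr.size
                xj = sol.y[:n, jcol]
                if np.any(xj < -NEG_CLIP):
                    raise IntegrationError(
                        f"negative density overshoot beyond {NEG_CLIP} at t={tj}"
                    )
                x[:] = np.clip(xj, 0.0, None) * extant
                u[:] = np.where(extant, sol.y[n:, jcol], u)
                t_cur = tj
                if is_sample:
                    next_sample += 1
                    g_here = (
                        gamma_seg(tj) if callable(gamma_seg) else gamma_seg
                    )
                    changed = process_sample(tj, float(g_here))
                    if changed and tj < b - 1e-9:
                        interrupted = True
                        break
            if not interrupted:
                t_cur = b

    # finalize per-species state and matrices
    T, N = len(times), len(ids)
    density = np.full((T, N), np.nan)
    strategy = np.full((T, N), np.nan)
    for i, (rx, ru) in enumerate(zip(rows_x, rows_u)):
        density[i, : rx.size] = rx
        strategy[i, : ru.size] = ru
    for j, s in enumerate(species):
        if s.extant:
            s.x = float(x[j])
            s.u = float(u[j])

    cfg = dict(config or {})
    cfg.setdefault("t_end", float(t_end))
    cfg.setdefault("record_dt", float(record_dt))
    return Trajectory(
        times=np.array(times),
        species_ids=list(ids),
        density=density,
        strategy=strategy,
        gamma=np.array(gammas),
        events=events,
        species=species,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# singular-point analysis


def _gradient_arrays(v, u, x, gamma, params):
    _, g1 = _landscape_terms(np.asarray(v, float), u, x, gamma, params, order=1)
    return g1


def find_singular_points(
    k_focal: float,
    community: Sequence[Species],
    gamma: float,
    params: ModelParams,
    search_interval: tuple[float, float] = (-20.0, 20.0),
    grid_step: float = 0.01,
    root_tol: float = 1e-8,
) -> list[SingularPoint]:
    """Locate and classify all roots of the selection gradient in an interval.

    Every sign change of dG/dv over a regular grid is bracketed and refined
    by bisection.  Classification: curvature < 0 is an ESS peak; curvature
    > 0 is a convergent-stable minimum (branching point) if the convergence
    test passes, i.e. the gradient experienced by a resident placed at
    v* + h points back toward v*.

    An empty community is treated as the vanishing-density limit of a
    monomorphic lineage: the landscape is evaluated with a pseudo-resident
    sitting at its closed-form equilibrium on the carrying-capacity peak,
    which yields the single singular point v* = gamma.
    """
    u, x = _community_arrays(community)
    if u.size == 0:
        u_star, x_star = equilibrium_single_species(k_focal, gamma, params)
        u = np.array([u_star])
        x = np.array([x_star])
    lo, hi = search_interval
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("search_interval must be finite with lo < hi")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")

    grid = np.arange(lo, hi + grid_step * 0.5, grid_step)
    g = _gradient_arrays(grid, u, x, gamma, params)

    def gradient(v: float) -> float:
        return float(_gradient_arrays(v, u, x, gamma, params))

    roots: list[float] = []
    for i in range(len(grid) - 1):
        gi, gj = g[i], g[i + 1]
        if gi == 0.0:
            roots.append(float(grid[i]))
        elif gi * gj < 0.0:
            roots.append(bisect(gradient, grid[i], grid[i + 1], xtol=root_tol))
    if len(g) and g[-1] == 0.0:
        roots.append(float(grid[-1]))

    out: list[SingularPoint] = []
    for v_star in roots:
        if out and abs(v_star - out[-1].v_star) < 10 * root_tol:
            continue
        _, _, curv = _landscape_terms(
            np.asarray(v_star), u, x, gamma, params, order=2
        )
        curv = float(curv)
        if curv < 0:
            kind = "ess_peak"
        elif curv > 0 and _convergent_stable(v_star, u, x, gamma, params):
            kind = "convergent_minimum"
        else:
            kind = "other"
        out.append(SingularPoint(v_star=v_star, curvature=curv, kind=kind))
    return out


def _convergent_stable(v_star, u, x, gamma, params, h: float = 1e-4) -> bool:
    """Convergence test: move the nearest resident to v*±h; the gradient it
    then experiences must point back toward v* (negative slope in u)."""
    j = int(np.argmin(np.abs(u - v_star)))

    def resident_gradient(uv: float) -> float:
        uu = u.copy()
        uu[j] = uv
        return float(_gradient_arrays(uv, uu, x, gamma, params))

    slope = (resident_gradient(v_star + h) - resident_gradient(v_star - h)) / (
        2.0 * h
    )
    return slope < 0


def verify_ess(
    community: Sequence[Species],
    gamma: float,
    params: ModelParams,
    tol: float = 1e-6,
) -> list[dict]:
    """Check the maximum-principle conditions at a candidate equilibrium.

    For every extant lineage reports |G(u_i)| < tol (ecological
    equilibrium), |dG/dv| < tol (evolutionary equilibrium), and the sign of
    the curvature (negative: on a peak, a true ESS; positive: on a
    convergent-stable minimum, a branching point).
    """
    report = []
    for s in community:
        if not s.extant:
            continue
        fit = fitness(s.u, s.k, community, gamma, params)
        grad = selection_gradient(s.u, s.k, community, gamma, params)
        curv = landscape_curvature(s.u, s.k, community, gamma, params)
        report.append(
            {
                "species_id": s.id,
                "fitness": fit,
                "gradient": grad,
                "curvature": curv,
                "fitness_zero": abs(fit) < tol,
                "gradient_zero": abs(grad) < tol,
                "is_peak": curv < 0,
            }
        )
    return report
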