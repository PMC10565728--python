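"""Fitness-generating (G-) function for competing species on a shared niche axis.

The model is Lotka–Volterra competition with Gaussian kernels.  A focal
individual with strategy ``v`` living in a community of resident species
with strategies ``u_j`` and densities ``x_j`` has per-capita growth rate

    G(v, u, x) = (r / K(v)) * (K(v) - sum_j a(v, u_j) x_j) - d * k

where

    K(v) = Km * exp(-(v - gamma)^2 / (2 sigma_k^2))        carrying capacity
    a(v, u) = exp(-(v - u)^2 / (2 sigma_a^2))              competition kernel

``gamma`` is the environmental optimum (the position of the carrying-capacity
peak), which may move with time.  ``k`` is the focal lineage's evolvability:
the coefficient that converts the selection gradient dG/dv into a rate of
strategy change.  Evolvability carries a linear fitness cost ``d * k``.

When the competition kernel is narrower than the resource kernel
(sigma_a^2 < sigma_k^2), a pure Gaussian kernel produces artifacts such as
infinite niche packing; for that regime a bounded kernel

    a(v, u) = floor + (1 - floor) * exp(-(v - u)^2 / (2 sigma_a^2))

is used instead, which keeps a baseline level of competition between
arbitrarily distant strategies.

All functions here are pure and accept scalar or array ``v``; the dynamics
module consumes them to build the coupled population/strategy ODE system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "Species",
    "Environment",
    "RealizedEnvironment",
    "NoViableEquilibriumError",
    "carrying_capacity",
    "competition_coeff",
    "fitness",
    "selection_gradient",
    "landscape_curvature",
    "equilibrium_single_species",
]

KernelName = Literal["gaussian", "bounded"]


class NoViableEquilibriumError(ValueError):
    """The evolvability cost exceeds the intrinsic growth rate (d*k >= r)."""


@dataclass(frozen=True)
class ModelParams:
    """Constants of the G-function.

    Defaults are the baseline parameter set used throughout the simulation
    scenarios: r=0.25, Km=100, d=0.05, sigma_k2=12.5, sigma_a2=100 with a
    plain Gaussian competition kernel.

    Parameters
    ----------
    r : intrinsic growth rate (per unit time).
    Km : maximum carrying capacity (density), attained at v = gamma.
    d : cost of evolvability (fitness penalty per unit k).
    sigma_k2 : environmental niche size, the variance of the
        carrying-capacity kernel (strategy units squared).
    sigma_a2 : species niche width, the variance of the competition kernel
        (strategy units squared).
    kernel : "gaussian" or "bounded".  The bounded variant keeps a baseline
        ``kernel_floor`` of competition at any strategy distance and is
        meant for the niche-packing regime sigma_a2 < sigma_k2.
    kernel_floor : baseline of the bounded kernel (unitless).
    extinction_threshold : density below which a lineage is declared
        extinct (the ODE itself never reaches zero).  Zero disables the
        rule; the adaptive-radiation scenario uses that, since its
        incipient species are seeded exactly at the threshold.
    """

    r: float = 0.25
    Km: float = 100.0
    d: float = 0.05
    sigma_k2: float = 12.5
    sigma_a2: float = 100.0
    kernel: KernelName = "gaussian"
    kernel_floor: float = 0.05
    extinction_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.Km <= 0:
            raise ValueError("Km must be positive")
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if self.sigma_k2 <= 0 or self.sigma_a2 <= 0:
            raise ValueError("kernel variances must be positive")
        if self.kernel not in ("gaussian", "bounded"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0 <= self.kernel_floor < 1:
            raise ValueError("kernel_floor must lie in [0, 1)")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be non-negative")


@dataclass
class Species:
    """One evolving lineage: evolvability, current strategy and density."""

    id: str
    k: float
    u: float
    x: float
    extant: bool = True
    parent_id: str | None = None
    birth_time: float = 0.0
    extinction_time: float | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("evolvability k must be non-negative")
        if self.x < 0:
            raise ValueError("density must be non-negative")
        if self.extant and self.extinction_time is not None:
            raise ValueError("extant species cannot carry an extinction time")

    def mark_extinct(self, time: float) -> None:
        """Freeze the lineage: density to zero, strategy as-is."""
        self.extant = False
        self.extinction_time = time
        self.x = 0.0


@dataclass(frozen=True)
class Environment:
    """Schedule of the environmental optimum gamma(t).

    Modes
    -----
    constant : gamma(t) = gamma0.
    stochastic : gamma redrawn uniformly from ``redraw_bounds`` every
        ``redraw_interval`` time units, starting at t = redraw_interval
        (gamma(0) = gamma0 until the first redraw).
    sinusoidal : gamma(t) = amplitude * sin(t / period).
    step : explicit ordered list of (time, new gamma) jumps.
    """

    mode: Literal["constant", "stochastic", "sinusoidal", "step"] = "constant"
    gamma0: float = 0.0
    redraw_interval: float = 5.0
    redraw_bounds: tuple[float, float] = (-2.0, 2.0)
    amplitude: float = 1.0
    period: float = 50.0
    steps: tuple[tuple[float, float], ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "stochastic", "sinusoidal", "step"):
            raise ValueError(f"unknown environment mode {self.mode!r}")
        if self.mode == "stochastic":
            lo, hi = self.redraw_bounds
            if not lo < hi:
                raise ValueError("redraw_bounds must satisfy low < high")
            if self.redraw_interval <= 0:
                raise ValueError("redraw_interval must be positive")
        if self.mode == "sinusoidal" and self.period <= 0:
            raise ValueError("period must be positive")
        if self.mode == "step":
            times = [t for t, _ in self.steps]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("step times must be strictly increasing")
            if times and times[0] <= 0:
                raise ValueError("step times must be positive")

    def realize(
        self, t_end: float, rng: np.random.Generator | None = None
    ) -> "RealizedEnvironment":
        """Materialize gamma(t) on [0, t_end].

        Stochastic redraws are consumed from ``rng`` (or from a generator
        seeded with ``self.seed``), so the gamma sequence is reproducible
        and independent of everything else in a simulation.
        """
        if self.mode == "sinusoidal":
            amp, per = self.amplitude, self.period
            return RealizedEnvironment(
                times=np.array([0.0]),
                values=None,
                func=lambda t, a=amp, p=per: a * np.sin(t / p),
            )
        if self.mode == "constant":
            return RealizedEnvironment(
                times=np.array([0.0]), values=np.array([self.gamma0])
            )
        if self.mode == "step":
            times = np.array([0.0] + [t for t, _ in self.steps if t < t_end])
            vals = np.array(
                [self.gamma0] + [g for t, g in self.steps if t < t_end]
            )
            return RealizedEnvironment(times=times, values=vals)
        # stochastic
        if rng is None:
            rng = np.random.default_rng(self.seed)
        n = int(np.floor((t_end - 1e-9) / self.redraw_interval))
        times = np.concatenate(
            [[0.0], self.redraw_interval * np.arange(1, n + 1)]
        )
        lo, hi = self.redraw_bounds
        vals = np.concatenate([[self.gamma0], rng.uniform(lo, hi, size=n)])
        return RealizedEnvironment(times=times, values=vals)


@dataclass
class RealizedEnvironment:
    """gamma(t) as either a piecewise-constant table or a smooth function."""

    times: np.ndarray
    values: np.ndarray | None
    func: Callable[[float], float] | None = None

    @property
    def breakpoints(self) -> np.ndarray:
        """Discontinuity times (integration restarts here)."""
        return self.times[1:]

    def gamma(self, t):
        if self.func is not None:
            return self.func(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.values[np.maximum(idx, 0)]


# ---------------------------------------------------------------------------
# core evaluations


def _community_arrays(community: Sequence[Species]) -> tuple[np.ndarray, np.ndarray]:
    us = np.array([s.u for s in community if s.extant], dtype=float)
    xs = np.array([s.x for s in community if s.extant], dtype=float)
    return us, xs


def _landscape_terms(v, u, x, gamma, p: ModelParams, order: int = 2):
    """Cost-free fitness r*(1 - S/K) and its first ``order`` v-derivatives.

    ``u``/``x`` are the resident strategy/density arrays.  Everything is in
    closed form: with S(v) = sum_j a(v,u_j) x_j and Q = S/K,

        G_base = r (1 - Q),   G_base' = -r Q',   G_base'' = -r Q''.
    """
    v = np.asarray(v, dtype=float)
    w = v - gamma
    K = p.Km * np.exp(-w * w / (2.0 * p.sigma_k2))
    K1 = -(w / p.sigma_k2) * K
    K2 = (w * w / p.sigma_k2**2 - 1.0 / p.sigma_k2) * K
    if u.size:
        W = v[..., None] - u
        E = np.exp(-W * W / (2.0 * p.sigma_a2))
        scale = 1.0 - p.kernel_floor if p.kernel == "bounded" else 1.0
        A = p.kernel_floor + scale * E if p.kernel == "bounded" else E
        S = A @ x
        S1 = (-scale * W / p.sigma_a2 * E) @ x
        S2 = (scale * (W * W / p.sigma_a2**2 - 1.0 / p.sigma_a2) * E) @ x
    else:
        S = S1 = S2 = np.zeros_like(v)
    Q = S / K
    base = p.r * (1.0 - Q)
    if order == 0:
        return (base,)
    Q1 = (S1 - Q * K1) / K
    if order == 1:
        return base, -p.r * Q1
    Q2 = (S2 - 2.0 * Q1 * K1 - Q * K2) / K
    return base, -p.r * Q1, -p.r * Q2


def _maybe_scalar(v, out):
    return float(out) if np.asarray(v).ndim == 0 else out


def carrying_capacity(v, gamma: float, params: ModelParams):
    """K(v): Gaussian resource kernel, maximized at v = gamma with value Km."""
    v = np.asarray(v, dtype=float)
    w = v - gamma
    return _maybe_scalar(v, params.Km * np.exp(-w * w / (2.0 * params.sigma_k2)))


def competition_coeff(v, u, params: ModelParams):
    """a(v, u): unity at v = u, decaying with strategy distance.

    The bounded kernel decays to ``kernel_floor`` instead of zero.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(v, dtype=float) - np.asarray(u, dtype=float)
    e = np.exp(-w * w / (2.0 * params.sigma_a2))
    if params.kernel == "bounded":
        e = params.kernel_floor + (1.0 - params.kernel_floor) * e
    return _maybe_scalar(w, e)


def fitness(v, k_focal: float, community: Sequence[Species], gamma: float,
            params: ModelParams):
    """G(v): per-capita growth rate of a rare focal with strategy v.

    The competition sum runs over all *extant* members of ``community``
    (including the focal lineage itself, if present).  The evolvability
    cost is ``d * k_focal``, i.e. each lineage pays for its own k.
    """
    u, x = _community_arrays(community)
    (base,) = _landscape_terms(v, u, x, gamma, params, order=0)
    return _maybe_scalar(v, base - params.d * k_focal)


def selection_gradient(v, k_focal: float, community: Sequence[Species],
                       gamma: float, params: ModelParams):
    """dG/dv at v, residents held fixed.  Analytic (closed-form kernels).

    Independent of ``k_focal`` because the cost term is linear in k; the
    argument is kept for interface symmetry with :func:`fitness`.
    """
    u, x = _community_arrays(community)
    _, g1 = _landscape_terms(v, u, x, gamma, params, order=1)
    return _maybe_scalar(v, g1)


def landscape_curvature(v, k_focal: float, community: Sequence[Species],
                        gamma: float, params: ModelParams):
    """d2G/dv2 at v.  Negative at an ESS peak, positive at a branching point."""
    u, x = _community_arrays(community)
    _, _, g2 = _landscape_terms(v, u, x, gamma, params, order=2)
    return _maybe_scalar(v, g2)


def equilibrium_single_species(
    k: float, gamma: float, params: ModelParams
) -> tuple[float, float]:
    """Closed-form eco-evolutionary equilibrium of a lone lineage.

    Setting the selection gradient and fitness to zero for one resident
    gives u* = gamma and, since a(u*, u*) = 1 for both kernels,
    x* = K(u*) * (1 - d k / r).

    Raises
    ------
    NoViableEquilibriumError
        If d*k >= r, where the cost of evolvability leaves no positive
        equilibrium density.
    """
    if params.d * k >= params.r:
        raise NoViableEquilibriumError(
            f"no viable equilibrium: d*k = {params.d * k} >= r = {params.r}"
        )
    u_star = float(gamma)
    x_star = carrying_capacity(u_star, gamma, params) * (
        1.0 - params.d * k / params.r
    )
    return u_star, float(x_star)
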