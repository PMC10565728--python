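"""The experimental protocols: clade initiation, evolutionary tracking,
evolutionary rescue, disturbance regimes, and adaptive radiation.

Every scenario competes a fast evolver (k=0.5) against a slow evolver
(k=0.2), founded at a shared initial strategy u0 and density x0, under a
scenario-specific environment schedule for the carrying-capacity optimum
gamma(t):

* clade initiation — constant gamma=0; the founders race toward the
  eco-evolutionary equilibrium at u*=0.
* tracking (stochastic) — gamma redrawn uniformly on [-2, 2] every 5 time
  units; run as a batch of independent replicates.
* tracking (deterministic) — gamma(t) = sin(t/50).
* rescue — constant gamma=0 until an abrupt step to a hostile optimum.
* disturbance regime — an explicit step schedule probing how the timing of
  repeated catastrophes selects between the two evolvabilities
  (storage-effect style transient coexistence at intermediate timing).
* adaptive radiation — bounded competition kernel with sigma_a2=2 <
  sigma_k2, where the landscape develops convergent-stable minima and
  lineages sitting on them speciate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import SpeciationRule, Trajectory, simulate
from .model import Environment, ModelParams, Species

__all__ = [
    "ScenarioConfig",
    "Phylogeny",
    "PhyloNode",
    "REGIME_PRESETS",
    "periodic_steps",
    "make_founders",
    "run_clade_initiation",
    "run_tracking",
    "run_rescue",
    "run_disturbance_regime",
    "run_adaptive_radiation",
    "run_scenario",
    "extinction_summary",
]

ScenarioName = Literal[
    "clade_initiation",
    "tracking_stochastic",
    "tracking_deterministic",
    "rescue",
    "disturbance_regime",
    "adaptive_radiation",
]

_T_END_DEFAULTS: dict[str, float] = {
    "clade_initiation": 1200.0,
    "tracking_stochastic": 600.0,
    "tracking_deterministic": 600.0,
    "rescue": 1500.0,
    "disturbance_regime": 2500.0,
    "adaptive_radiation": 10000.0,
}

#: Named step schedules for the disturbance-regime experiments.  The
#: "collapse" family shifts gamma 0 -> -4 at t=900 and then to -8 at a
#: second time whose value (1800 rare / 1700 intermediate / 1600 frequent)
#: decides which evolvability survives.  The "transient" family shifts to
#: -4.4 at t=900 and reverts to 0 at the listed time.
REGIME_PRESETS: dict[str, tuple[tuple[float, float], ...]] = {
    "collapse_rare": ((900.0, -4.0), (1800.0, -8.0)),
    "collapse_intermediate": ((900.0, -4.0), (1700.0, -8.0)),
    "collapse_frequent": ((900.0, -4.0), (1600.0, -8.0)),
    "transient_rare": ((900.0, -4.4), (2000.0, 0.0)),
    "transient_intermediate": ((900.0, -4.4), (1800.0, 0.0)),
    "transient_frequent": ((900.0, -4.4), (1400.0, 0.0)),
}


def periodic_steps(
    t_start: float,
    period: float,
    gamma_disturbed: float,
    gamma_calm: float = 0.0,
    duty: float = 0.5,
    t_end: float = 5000.0,
) -> tuple[tuple[float, float], ...]:
    """A repeating disturbance/stasis step train (qualitative fixture).

    From ``t_start`` onward, gamma alternates between ``gamma_disturbed``
    (for ``duty``*period) and ``gamma_calm``.  Useful for exploring
    prolonged cyclical coexistence under regular disturbances; the exact
    schedule behind that phenomenon is a free experimental choice.
    """
    steps: list[tuple[float, float]] = []
    t = t_start
    while t < t_end:
        steps.append((t, gamma_disturbed))
        if t + duty * period < t_end:
            steps.append((t + duty * period, gamma_calm))
        t += period
    return tuple(steps)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, serializable description of one scenario run."""

    scenario: ScenarioName
    u0: float = 4.0
    x0: float = 10.0
    k_fast: float = 0.5
    k_slow: float = 0.2
    params: ModelParams | None = None
    env: Environment | None = None
    n_trials: int = 100
    t_end: float | None = None
    record_dt: float = 1.0
    seed: int = 0
    max_species: int = 16
    speciation: SpeciationRule = field(default_factory=SpeciationRule)

    def __post_init__(self) -> None:
        if self.scenario not in _T_END_DEFAULTS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if self.scenario in ("rescue", "disturbance_regime"):
            env = self.resolved_env()
            if env.mode != "step" or not env.steps:
                raise ValueError(
                    f"{self.scenario} requires a step environment schedule"
                )

    def resolved_params(self) -> ModelParams:
        if self.params is not None:
            return self.params
        if self.scenario == "adaptive_radiation":
            # Incipient species are seeded at density 1, exactly the usual
            # extinction threshold; a strict density rule would cull every
            # daughter during its insertion transient, so the radiation
            # protocol runs with the rule disabled.
            return ModelParams(
                kernel="bounded", sigma_a2=2.0, extinction_threshold=0.0
            )
        return ModelParams()

    def resolved_env(self) -> Environment:
        if self.env is not None:
            return self.env
        if self.scenario == "tracking_stochastic":
            return Environment(mode="stochastic")
        if self.scenario == "tracking_deterministic":
            return Environment(mode="sinusoidal")
        if self.scenario == "rescue":
            return Environment(mode="step", steps=((600.0, -4.0),))
        if self.scenario == "disturbance_regime":
            return Environment(
                mode="step", steps=REGIME_PRESETS["collapse_intermediate"]
            )
        return Environment(mode="constant", gamma0=0.0)

    def resolved_t_end(self) -> float:
        return (
            self.t_end
            if self.t_end is not None
            else _T_END_DEFAULTS[self.scenario]
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.resolved_params())
        d["env"] = asdict(self.resolved_env())
        d["t_end"] = self.resolved_t_end()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if isinstance(d.get("params"), dict):
            d["params"] = ModelParams(**d["params"])
        if isinstance(d.get("env"), dict):
            env = dict(d["env"])
            if "steps" in env:
                env["steps"] = tuple(tuple(s) for s in env["steps"])
            if "redraw_bounds" in env:
                env["redraw_bounds"] = tuple(env["redraw_bounds"])
            d["env"] = Environment(**env)
        if isinstance(d.get("speciation"), dict):
            spec = dict(d["speciation"])
            if "search_interval" in spec:
                spec["search_interval"] = tuple(spec["search_interval"])
            d["speciation"] = SpeciationRule(**spec)
        return cls(**d)


def make_founders(config: ScenarioConfig) -> list[Species]:
    """The two founding lineages, named by their evolvability class."""
    return [
        Species(id="fast_0", k=config.k_fast, u=config.u0, x=config.x0),
        Species(id="slow_0", k=config.k_slow, u=config.u0, x=config.x0),
    ]


def _run_single(
    config: ScenarioConfig,
    rng_seed=None,
    speciation: SpeciationRule | None = None,
) -> Trajectory:
    return simulate(
        make_founders(config),
        config.resolved_env(),
        config.resolved_params(),
        t_end=config.resolved_t_end(),
        record_dt=config.record_dt,
        rng_seed=config.seed if rng_seed is None else rng_seed,
        speciation=speciation,
        config=config.to_dict(),
    )


def run_clade_initiation(config: ScenarioConfig) -> Trajectory:
    """Two founders dropped into a constant environment far from u*=0.

    Starting close to the equilibrium favors the slow evolver (the fast
    one pays the evolvability cost for nothing); starting far favors the
    fast evolver, which climbs the landscape first and competitively
    excludes the laggard.
    """
    return _run_single(config)


def run_tracking(
    config: ScenarioConfig,
) -> tuple[list[Trajectory], pd.DataFrame | None]:
    """Evolutionary tracking of a moving carrying-capacity peak.

    Stochastic mode runs ``n_trials`` independent replicates (child seeds
    spawned from the master seed) and returns them with an extinction
    summary table; sinusoidal mode returns a single trajectory and None.
    """
    if config.scenario == "tracking_stochastic":
        children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
        trajectories = [_run_single(config, rng_seed=ss) for ss in children]
        return trajectories, extinction_summary(trajectories)
    return [_run_single(config)], None


def run_rescue(config: ScenarioConfig) -> Trajectory:
    """Abrupt environmental catastrophe after an equilibration phase.

    Identical to clade initiation until the step in gamma; survival then
    hinges on evolving a viable strategy before density crosses the
    extinction threshold.
    """
    return _run_single(config)


def run_disturbance_regime(
    config: ScenarioConfig,
) -> tuple[Trajectory, str]:
    """Run an explicit disturbance schedule and classify the outcome.

    Returns the trajectory and one of "coexistence", "fast_survives",
    "slow_survives" or "both_extinct", judged on extant lineages at t_end.
    """
    traj = _run_single(config)
    fast = any(s.extant and s.id.startswith("fast") for s in traj.species)
    slow = any(s.extant and s.id.startswith("slow") for s in traj.species)
    if fast and slow:
        outcome = "coexistence"
    elif fast:
        outcome = "fast_survives"
    elif slow:
        outcome = "slow_survives"
    else:
        outcome = "both_extinct"
    return traj, outcome


def run_adaptive_radiation(
    config: ScenarioConfig,
) -> tuple[Trajectory, "Phylogeny"]:
    """Iterated speciation in the niche-packing regime (sigma_a2 < sigma_k2).

    Uses the bounded competition kernel.  Whenever an extant lineage's
    strategy comes within the trigger distance of a convergent-stable
    minimum of the landscape, a daughter lineage is inserted (same
    evolvability, strategy offset drawn on +/-offset, density 1).  Returns
    the trajectory and the lineage tree.
    """
    rule = replace(config.speciation, max_species=config.max_species)
    traj = _run_single(config, speciation=rule)
    return traj, Phylogeny.from_trajectory(traj)


def run_scenario(config: ScenarioConfig):
    """Dispatch on ``config.scenario``; returns whatever the runner does."""
    runner = {
        "clade_initiation": run_clade_initiation,
        "tracking_stochastic": run_tracking,
        "tracking_deterministic": run_tracking,
        "rescue": run_rescue,
        "disturbance_regime": run_disturbance_regime,
        "adaptive_radiation": run_adaptive_radiation,
    }[config.scenario]
    return runner(config)


def extinction_summary(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Per-species extinction statistics over replicate runs.

    Counts replicates containing an extinction event for each species id;
    mean and sample standard deviation are taken over those replicates
    only (NaN when undefined: no extinctions, or a single one for the sd).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ids: list[str] = []
    for traj in trajectories:
        for sid in traj.species_ids:
            if sid not in ids:
                ids.append(sid)
    rows = []
    for sid in ids:
        times = [
            t
            for traj in trajectories
            if (t := traj.extinction_time(sid)) is not None
        ]
        n = len(times)
        rows.append(
            {
                "species_id": sid,
                "n_trials": len(trajectories),
                "n_extinct": n,
                "mean_time": float(np.mean(times)) if n else np.nan,
                "sd_time": float(np.std(times, ddof=1)) if n > 1 else
                (0.0 if n == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


# ---------------------------------------------------------------------------
# phylogeny


@dataclass(frozen=True)
class PhyloNode:
    id: str
    parent_id: str | None
    birth_time: float
    extinction_time: float | None
    k: float
    final_u: float


@dataclass
class Phylogeny:
    """Lineage tree of a radiation run (founders are separate roots)."""

    nodes: list[PhyloNode]
    t_end: float

    def __post_init__(self) -> None:
        by_id = {n.id: n for n in self.nodes}
        if len(by_id) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for n in self.nodes:
            if n.parent_id is None:
                continue
            parent = by_id.get(n.parent_id)
            if parent is None:
                raise ValueError(f"{n.id}: unknown parent {n.parent_id}")
            if parent.birth_time > n.birth_time:
                raise ValueError(f"{n.id} born before its parent")

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "Phylogeny":
        nodes = [
            PhyloNode(
                id=s.id,
                parent_id=s.parent_id,
                birth_time=s.birth_time,
                extinction_time=s.extinction_time,
                k=s.k,
                final_u=s.u,
            )
            for s in traj.species
        ]
        return cls(nodes=nodes, t_end=float(traj.times[-1]))

    @property
    def roots(self) -> list[PhyloNode]:
        return [n for n in self.nodes if n.parent_id is None]

    def children_of(self, node_id: str) -> list[PhyloNode]:
        kids = [n for n in self.nodes if n.parent_id == node_id]
        return sorted(kids, key=lambda n: (n.birth_time, n.id))

    def to_newick(self) -> str:
        """Single-line Newick; branch lengths in simulation time units.

        A lineage's branch is split at each of its speciation times, with
        the internal node labeled by the parent lineage id.  Multiple
        roots are joined under a zero-length node labeled "root".
        """

        def end_time(n: PhyloNode) -> float:
            return n.extinction_time if n.extinction_time is not None else self.t_end

        def render(n: PhyloNode, from_time: float) -> str:
            kids = [c for c in self.children_of(n.id) if c.birth_time > from_time]
            if not kids:
                return f"{n.id}:{end_time(n) - from_time!r}"
            c = kids[0]
            cont = render(n, c.birth_time)
            sub = render(c, c.birth_time)
            return f"({cont},{sub}){n.id}:{c.birth_time - from_time!r}"

        parts = [render(r, r.birth_time) for r in self.roots]
        if len(parts) == 1:
            return parts[0] + ";"
        return "(" + ",".join(parts) + ")root:0.0;"
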