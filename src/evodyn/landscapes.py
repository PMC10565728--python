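"""Adaptive-landscape grids over the course of a simulation.

A landscape frame is G(v) evaluated on a strategy grid at one recorded
time, for each distinct evolvability in the extant community (the cost
term d*k shifts the whole curve down by a constant, so each k class sees
its own copy of the landscape).  Species positions are marked as
(u_i, G(u_i)) using each lineage's own k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .model import ModelParams, Species, fitness

__all__ = ["LandscapeFrame", "landscape_series", "default_v_grid"]


@dataclass(frozen=True)
class Marker:
    species_id: str
    k: float
    u: float
    G: float


@dataclass
class LandscapeFrame:
    time: float
    v_grid: np.ndarray
    fitness: dict[float, np.ndarray]  # k_focal -> G(v) on the grid
    markers: list[Marker]


def default_v_grid(
    traj: Trajectory, lo: float = -12.0, hi: float = 12.0, step: float = 0.05
) -> np.ndarray:
    """[-12, 12] at step 0.05, widened to cover all strategies +/- 2."""
    u = traj.strategy[~np.isnan(traj.strategy)]
    if u.size:
        lo = min(lo, float(u.min()) - 2.0)
        hi = max(hi, float(u.max()) + 2.0)
    return np.arange(lo, hi + step * 0.5, step)


def landscape_series(
    traj: Trajectory,
    params: ModelParams,
    v_grid: np.ndarray | None = None,
    stride: int = 50,
) -> list[LandscapeFrame]:
    """Evaluate the adaptive landscape at every ``stride``-th sample.

    Community state (extant strategies and densities) and gamma are taken
    from the trajectory; extinct lineages do not shape the landscape.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if v_grid is None:
        v_grid = default_v_grid(traj)
    frames: list[LandscapeFrame] = []
    birth = {s.id: s.birth_time for s in traj.species}
    kmap = {s.id: s.k for s in traj.species}
    ext = {s.id: s.extinction_time for s in traj.species}
    for i in range(0, len(traj.times), stride):
        t = float(traj.times[i])
        gamma = float(traj.gamma[i])
        community = []
        for j, sid in enumerate(traj.species_ids):
            u = traj.strategy[i, j]
            if np.isnan(u):
                continue
            e = ext[sid]
            if e is not None and t >= e:
                continue
            community.append(
                Species(
                    id=sid,
                    k=kmap[sid],
                    u=float(u),
                    x=float(traj.density[i, j]),
                    birth_time=birth[sid],
                )
            )
        ks = sorted({s.k for s in community})
        fit = {
            k: fitness(v_grid, k, community, gamma, params) for k in ks
        }
        markers = [
            Marker(
                species_id=s.id,
                k=s.k,
                u=s.u,
                G=fitness(s.u, s.k, community, gamma, params),
            )
            for s in community
        ]
        frames.append(
            LandscapeFrame(time=t, v_grid=v_grid, fitness=fit, markers=markers)
        )
    return frames
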