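"""Writers and readers for trajectories, landscapes, phylogenies, configs.

All outputs are plain text: tab-separated tables with "#"-prefixed header
comments embedding the resolved run configuration (for reproducibility),
JSON event sidecars, single-line Newick trees, and YAML scenario configs.
Writers are deterministic byte-for-byte given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import Event, Trajectory
from .landscapes import LandscapeFrame
from .scenarios import Phylogeny, ScenarioConfig

__all__ = [
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_events_json",
    "read_events_json",
    "write_landscape_tsv",
    "write_summary_tsv",
    "write_newick",
    "load_config",
    "save_config",
]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_header(config: dict) -> str:
    payload = json.dumps(config, default=_json_default, sort_keys=True)
    return f"# config: {payload}\n"


def write_trajectory_tsv(
    traj: Trajectory, path: str | Path, events_path: str | Path | None = None
) -> Path:
    """Tidy TSV (time, species_id, density, strategy, gamma) plus a JSON
    events sidecar (default: ``<path>.events.json``)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_config_header(traj.config))
        traj.to_frame().to_csv(fh, sep="\t", index=False)
    if events_path is None:
        events_path = path.with_name(path.name + ".events.json")
    write_events_json(traj.events, events_path)
    return path


def read_trajectory_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back a trajectory table; returns (tidy frame, config dict)."""
    path = Path(path)
    config: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# config: "):
            config = json.loads(first[len("# config: "):])
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return df, config


def write_events_json(events: list[Event], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "time": ev.time,
            "kind": ev.kind,
            "species_id": ev.species_id,
            "info": ev.info,
        }
        for ev in events
    ]
    path.write_text(
        json.dumps(payload, default=_json_default, indent=1, sort_keys=True)
        + "\n"
    )
    return path


def read_events_json(path: str | Path) -> list[Event]:
    payload = json.loads(Path(path).read_text())
    return [
        Event(
            time=d["time"],
            kind=d["kind"],
            species_id=d["species_id"],
            info=d.get("info", {}),
        )
        for d in payload
    ]


def write_landscape_tsv(
    frames: list[LandscapeFrame], path: str | Path, config: dict | None = None
) -> Path:
    """Long-format frames: (time, k_focal, v, G) plus species markers
    flagged by a non-empty species_id column."""
    path = Path(path)
    rows = []
    for fr in frames:
        for k, g in sorted(fr.fitness.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "time": fr.time,
                        "k_focal": k,
                        "v": fr.v_grid,
                        "G": g,
                        "species_id": "",
                    }
                )
            )
        for m in fr.markers:
            rows.append(
                pd.DataFrame(
                    {
                        "time": [fr.time],
                        "k_focal": [m.k],
                        "v": [m.u],
                        "G": [m.G],
                        "species_id": [m.species_id],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_config_header(config or {}))
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_summary_tsv(
    summary: pd.DataFrame, path: str | Path, config: dict | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_config_header(config or {}))
        summary.to_csv(fh, sep="\t")
    return path


def write_newick(phylo: Phylogeny, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(phylo.to_newick() + "\n")
    return path


def load_config(path: str | Path) -> ScenarioConfig:
    """Scenario config from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    data = json.loads(
        json.dumps(config.to_dict(), default=_json_default, sort_keys=True)
    )
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path
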