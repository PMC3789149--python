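"""Configuration files, output writers and the run manifest.

All tabular outputs are CSV; lattice snapshots are written both as integer
CSV (one row per lattice row) and as binary PGM (P5), which any image
viewer renders without an imaging dependency.  Writers are deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .birth import (B0_DEFAULT, MORTALITY_GLOBAL, MORTALITY_LOCAL,
                    PIVOT_B_DEFAULT, PIVOT_P_DEFAULT, Community,
                    default_community)
from .errors import ConfigurationError
from .experiments import SweepResult
from .lattice import LatticeState, SimConfig, TimeSeries

_SIM_KEYS = {"mode", "p", "l", "steps", "seed", "initial_occupancy",
             "record_every"}
_COMM_KEYS = {"n", "pivot_p", "pivot_b", "b0", "mortality", "file"}


def load_config(path) -> tuple[SimConfig, Community]:
    """Parse an INI-style run configuration.

    Two sections: ``[simulation]`` (requires ``mode`` and ``p``; other keys
    default) and an optional ``[community]`` (either generator parameters or
    ``file = <csv>`` pointing at a serialized community).  Unknown keys are
    rejected.  Mortality defaults to 0.3 for local and 0.5 for global
    interaction when not given.
    """
    parser = configparser.ConfigParser(inline_comment_prefixes=("#",))
    read = parser.read(path)
    if not read:
        raise ConfigurationError(f"cannot read config file {path}")
    if "simulation" not in parser:
        raise ConfigurationError("missing required [simulation] section")
    sim = parser["simulation"]
    unknown = set(sim) - _SIM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown [simulation] keys: {sorted(unknown)}")
    for key in ("mode", "p"):
        if key not in sim:
            raise ConfigurationError(f"missing required [simulation] key: {key}")
    try:
        cfg = SimConfig(
            P=sim.getfloat("p"),
            mode=sim.get("mode"),
            L=sim.getint("l", fallback=1000),
            steps=sim.getint("steps", fallback=20000),
            seed=sim.getint("seed", fallback=0),
            initial_occupancy=sim.getfloat("initial_occupancy", fallback=0.3),
            record_every=sim.getint("record_every", fallback=10),
        )
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc

    comm = parser["community"] if "community" in parser else {}
    if comm:
        unknown = set(comm) - _COMM_KEYS
        if unknown:
            raise ConfigurationError(f"unknown [community] keys: {sorted(unknown)}")
    if "file" in comm:
        community = Community.from_csv(
            Path(path).parent / parser["community"].get("file"))
    else:
        get = parser["community"] if comm else None
        default_m = MORTALITY_LOCAL if cfg.mode == "local" else MORTALITY_GLOBAL
        community = default_community(
            N=get.getint("n", fallback=10) if get else 10,
            pivot_P=get.getfloat("pivot_p", fallback=PIVOT_P_DEFAULT) if get else PIVOT_P_DEFAULT,
            pivot_b=get.getfloat("pivot_b", fallback=PIVOT_B_DEFAULT) if get else PIVOT_B_DEFAULT,
            b0=get.getfloat("b0", fallback=B0_DEFAULT) if get else B0_DEFAULT,
            mortality=get.getfloat("mortality", fallback=default_m) if get else default_m,
        )
    return cfg, community


def write_config(path, cfg: SimConfig, community_file: str | None = None) -> None:
    """Write a config file that :func:`load_config` reads back identically."""
    parser = configparser.ConfigParser()
    parser["simulation"] = {
        "mode": cfg.mode,
        "p": repr(cfg.P),
        "l": str(cfg.L),
        "steps": str(cfg.steps),
        "seed": str(cfg.seed),
        "initial_occupancy": repr(cfg.initial_occupancy),
        "record_every": str(cfg.record_every),
    }
    if community_file is not None:
        parser["community"] = {"file": community_file}
    with open(path, "w") as fh:
        parser.write(fh)


# ---------------------------------------------------------------------------
# snapshot writers

def write_snapshot_csv(state: LatticeState, path) -> None:
    """Integer CSV, one line per lattice row."""
    np.savetxt(path, state.grid, fmt="%d", delimiter=",")


def write_snapshot_pgm(state: LatticeState, path, n_species: int | None = None) -> None:
    """Binary PGM (P5): empty cells white (255), species scaled over 0..200."""
    g = state.grid
    if n_species is None:
        n_species = int(g.max())
    img = np.full(g.shape, 255, dtype=np.uint8)
    occ = g > 0
    if n_species > 1:
        img[occ] = ((g[occ].astype(np.int32) - 1) * 200) // (n_species - 1)
    else:
        img[occ] = 0
    with open(path, "wb") as fh:
        fh.write(f"P5\n{g.shape[1]} {g.shape[0]}\n255\n".encode())
        fh.write(img.tobytes())


# ---------------------------------------------------------------------------
# run manifest

@dataclass
class RunManifest:
    """Record of one completed run: config echo, outputs, provenance."""

    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    community_file: str | None = None
    version: str = ""
    wall_time_s: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_outputs(out_prefix, cfg: SimConfig | None = None,
                  series: TimeSeries | None = None,
                  state: LatticeState | None = None,
                  sweep: SweepResult | None = None,
                  community: Community | None = None,
                  wall_time_s: float = 0.0) -> RunManifest:
    """Write whichever artifacts are given; return the manifest (also written).

    Produces ``<prefix>_timeseries.csv``, ``<prefix>_snapshot.csv`` /
    ``.pgm``, ``<prefix>_sweep.csv``, ``<prefix>_community.csv`` and
    ``<prefix>_manifest.json``.
    """
    from . import __version__

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def _mark(p: Path) -> Path:
        outputs.append(str(p))
        return p

    if series is not None:
        series.to_csv(_mark(prefix.parent / f"{prefix.name}_timeseries.csv"))
    if state is not None:
        n_sp = series.n_species if series is not None else None
        write_snapshot_csv(state, _mark(prefix.parent / f"{prefix.name}_snapshot.csv"))
        write_snapshot_pgm(state, _mark(prefix.parent / f"{prefix.name}_snapshot.pgm"),
                           n_species=n_sp)
    if sweep is not None:
        sweep.to_csv(_mark(prefix.parent / f"{prefix.name}_sweep.csv"))
    community_file = None
    if community is not None:
        p = _mark(prefix.parent / f"{prefix.name}_community.csv")
        community.to_csv(p)
        community_file = str(p)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg) if cfg is not None else {},
        seed=cfg.seed if cfg is not None else 0,
        outputs=outputs,
        community_file=community_file,
        version=__version__,
        wall_time_s=wall_time_s,
    )
    manifest.to_json(prefix.parent / f"{prefix.name}_manifest.json")
    return manifest
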