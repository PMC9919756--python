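"""Trajectory persistence and run-configuration parsing.

Snapshots are stored in a plain-text extended-XYZ dialect chosen for
inspectability:

    <N_at>
    step=<int> box=<L> phi=<float> theta0=<deg> k_theta=<float>
    HS x y z chain_id mono_idx sx sy sz
    ...

Positions are written wrapped into the box together with integer unwrap
shifts ``(sx, sy, sz)``, so exact periodic-boundary semantics round-trip:
unwrapped = wrapped + shift * L.  Positions carry 17 significant digits
(full double precision).

Run configurations are flat YAML documents mirroring ``SystemParams``,
``MoveSchedule`` and ``CBSettings`` plus budget/cadence/seed keys;
unknown keys are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .chain_model import Configuration, SystemParams, Trajectory
from .mc_engine import CBSettings, MoveSchedule

__all__ = [
    "RunConfig",
    "write_trajectory",
    "read_trajectory",
    "iter_frames",
    "write_frame",
    "parse_config",
]


# ---------------------------------------------------------------------------
# extended-XYZ dialect
# ---------------------------------------------------------------------------

def write_frame(fh, step: int, config: Configuration,
                theta0_deg: float = 0.0, k_theta: float = 9.0) -> None:
    L = config.box_edge
    wrapped = config.positions_wrapped()
    shifts = config.unwrap_shifts()
    cids = config.chain_ids()
    midx = config.mono_indices()
    phi = config.packing_fraction()
    fh.write(f"{config.n_atoms}\n")
    fh.write(f"step={step} box={float(L)!r} phi={float(phi)!r} "
             f"theta0={float(theta0_deg)!r} k_theta={float(k_theta)!r}\n")
    for p, s, c, m in zip(wrapped, shifts, cids, midx):
        fh.write(f"HS {float(p[0])!r} {float(p[1])!r} {float(p[2])!r} "
                 f"{c} {m} {s[0]} {s[1]} {s[2]}\n")


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write all frames to one extended-XYZ file."""
    params = trajectory.metadata.get("params")
    theta0 = math.degrees(params.theta0) if params else 0.0
    k_theta = params.k_theta if params else 9.0
    with open(path, "w") as fh:
        for step, config in trajectory:
            write_frame(fh, step, config, theta0, k_theta)


def _parse_comment(line: str, lineno: int) -> dict:
    out = {}
    for tok in line.split():
        if "=" not in tok:
            raise ValueError(f"line {lineno}: malformed comment token {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    for key in ("step", "box"):
        if key not in out:
            raise ValueError(f"line {lineno}: comment line missing {key!r}")
    return out


def iter_frames(path) -> Iterator[tuple[int, Configuration, dict]]:
    """Lazily yield (step, configuration, header) from an extended-XYZ file.

    Frames are parsed one at a time so arbitrarily long trajectories can
    be streamed with bounded memory.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                if not header:
                    return
                continue
            try:
                n_at = int(header)
            except ValueError:
                raise ValueError(f"line {lineno}: expected atom count, "
                                 f"got {header.strip()!r}") from None
            meta = _parse_comment(fh.readline(), lineno + 1)
            lineno += 1
            L = float(meta["box"])
            step = int(meta["step"])
            rows = []
            for _ in range(n_at):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) != 9:
                    raise ValueError(f"line {lineno}: expected 9 columns, "
                                     f"got {len(parts)}")
                rows.append(parts)
            if len(rows) != n_at:
                raise ValueError(f"frame at line {lineno}: atom count mismatch")
            arr = np.array(rows, dtype=object)
            pos = arr[:, 1:4].astype(float)
            cid = arr[:, 4].astype(int)
            midx = arr[:, 5].astype(int)
            shift = arr[:, 6:9].astype(int)
            unwrapped = pos + shift * L
            chains = []
            for c in np.unique(cid):
                sel = cid == c
                order = np.argsort(midx[sel])
                chains.append(unwrapped[sel][order])
            yield step, Configuration(L, chains), meta


def read_trajectory(path) -> Trajectory:
    """Read a whole trajectory file into memory."""
    traj = Trajectory()
    meta0 = None
    for step, config, meta in iter_frames(path):
        if meta0 is None:
            meta0 = meta
            traj.metadata.update(meta)
        traj.append(step, config)
    return traj


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_PARAM_KEYS = {"sigma", "dl", "k_theta", "theta0_deg", "n_chains", "n_av",
               "length_min", "length_max"}
_SCHEDULE_KEYS = {"reptation", "rotation", "flip", "intermolecular_reptation",
                  "end_segment_regrowth", "sEB", "sIEB"}
_CB_KEYS = {"max_regrow"}
_RUN_KEYS = {"n_steps", "snapshot_interval", "seed", "phi", "phi_init",
             "shrink_factor", "relax_moves", "output"}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved state-point run description."""

    params: SystemParams
    schedule: MoveSchedule
    cb: CBSettings
    phi: float = 0.30
    phi_init: float = 0.001
    n_steps: int = 10**5
    snapshot_interval: int = 10**4
    seed: int = 0
    shrink_factor: float = 0.999
    relax_moves: int = 500
    output: str = "trajectory.xyz"


def parse_config(path) -> RunConfig:
    """Parse a YAML run configuration, applying the default preset.

    An empty file yields the reference study conditions (100 chains of
    mean length 12, dl = 6.5e-4, k_theta = 9, the standard move mix).
    Unknown keys, out-of-range values and a move schedule that does not
    sum to 1 are rejected with descriptive errors.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError("run configuration must be a YAML mapping")
    known = _PARAM_KEYS | _SCHEDULE_KEYS | _CB_KEYS | _RUN_KEYS
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    pkw = {}
    if "theta0_deg" in doc:
        pkw["theta0"] = math.radians(float(doc["theta0_deg"]))
    for key in ("sigma", "dl", "k_theta"):
        if key in doc:
            pkw[key] = float(doc[key])
    for key in ("n_chains", "n_av"):
        if key in doc:
            pkw[key] = int(doc[key])
    if "length_min" in doc or "length_max" in doc:
        pkw["length_bounds"] = (int(doc.get("length_min", 6)),
                                int(doc.get("length_max", 18)))
    params = SystemParams(**pkw)

    skw = {k: float(doc[k]) for k in _SCHEDULE_KEYS if k in doc}
    schedule = MoveSchedule(**skw) if skw else MoveSchedule()
    cb = CBSettings(max_regrow=int(doc["max_regrow"])) if "max_regrow" in doc \
        else CBSettings()

    rkw = {}
    for key, cast in (("n_steps", int), ("snapshot_interval", int),
                      ("seed", int), ("phi", float), ("phi_init", float),
                      ("shrink_factor", float), ("relax_moves", int),
                      ("output", str)):
        if key in doc:
            rkw[key] = cast(doc[key])
    if "phi" in rkw and not (0.0 < rkw["phi"] < 0.7405):
        raise ValueError("phi must lie in (0, 0.7405)")
    return RunConfig(params=params, schedule=schedule, cb=cb, **rkw)
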