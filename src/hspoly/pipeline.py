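"""State-point orchestration and phase classification.

A state point is a (packing density phi, equilibrium bending angle
theta0) pair.  The pipeline generates the system at dilute conditions,
compresses it isotropically to the target density, equilibrates at
constant volume, and records the global (nematic q) and local (CCE
order parameters S^X, crystallinity tau_c) descriptors along the run.
Steady-state averages over the detected stationary tail feed the joint
phase label: AMO/CRY at the monomer level (crystallinity cutoff) times
ISO/PRO/OBL at the chain level (nematic cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cce import DEFAULT_THRESHOLD, label_sites
from .chain_model import Configuration, SystemParams, Trajectory, bond_geometry
from .mc_engine import CBSettings, MCEngine, MoveSchedule, compress, generate_dilute
from .nematic import classify_mesophase, nematic_order

__all__ = [
    "PhasePoint",
    "run_state_point",
    "steady_state_average",
    "classify_phase",
    "bending_distribution",
    "build_phase_diagram",
]

#: a state point is crystalline when its steady-state crystallinity
#: reaches this fraction (amorphous packings sit near 0, crystals at
#: 0.65-0.85, so the cutoff has a wide margin on both sides)
CRY_CUTOFF = 0.3


@dataclass
class PhasePoint:
    """Steady-state summary of one (phi, theta0) state point."""

    phi: float
    theta0_deg: float
    q_mean: float
    S_hcp: float
    S_fcc: float
    S_fiv: float
    tau_c: float
    local_label: str       # AMO | CRY
    global_label: str      # ISO | PRO | OBL
    equilibrated: bool
    provenance: dict = field(default_factory=dict)


def run_state_point(phi: float, theta0_deg: float,
                    params: SystemParams | None = None,
                    schedule: MoveSchedule | None = None,
                    cb: CBSettings | None = None,
                    budget: int = 2 * 10**5, seed: int = 0,
                    snapshot_interval: int = 10**4,
                    shrink_factor: float = 0.99, relax_moves: int = 300,
                    compute_cce: bool = True) -> pd.DataFrame:
    """Simulate one state point and return the descriptor time series.

    Protocol: dilute generation (phi = 0.001) -> isotropic compression
    with MC relaxation -> constant-volume equilibration of ``budget``
    attempted moves, recording (step, q, S^HCP, S^FCC, S^FIV, tau_c)
    every ``snapshot_interval`` attempts.  Deterministic given the seed.
    """
    base = params or SystemParams()
    p = base.replace(theta0=math.radians(theta0_deg))
    config = generate_dilute(p, seed=seed)
    engine = MCEngine(config, p, schedule, cb, seed=seed + 1)
    if phi > engine.phi + 1e-9:
        compress(config, p, phi, seed=seed + 1, shrink_factor=shrink_factor,
                 relax_moves=relax_moves, engine=engine)
    rows = []
    n_snap = max(1, budget // snapshot_interval)
    for i in range(n_snap):
        engine.run(snapshot_interval)
        snap = engine.config()
        q = nematic_order(snap).q
        row = {"step": (i + 1) * snapshot_interval, "q": q}
        if compute_cce:
            res = label_sites(snap)
            row.update({"S_hcp": res.S["HCP"], "S_fcc": res.S["FCC"],
                        "S_fiv": res.S["FIV"], "tau_c": res.tau_c})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["params"] = p
    df.attrs["phi"] = phi
    df.attrs["theta0_deg"] = theta0_deg
    df.attrs["seed"] = seed
    df.attrs["budget"] = budget
    df.attrs["acceptance_ratios"] = engine.acceptance_ratios()
    return df


def run_ordered_branch(phi: float, params: SystemParams | None = None,
                       schedule: MoveSchedule | None = None,
                       cb: CBSettings | None = None,
                       budget: int = 5 * 10**5, seed: int = 0,
                       snapshot_interval: int = 2 * 10**4) -> pd.DataFrame:
    """Nematic stability run started from a perfectly aligned state.

    Locating the isotropic-nematic transition from a disordered start
    requires orientational equilibration budgets far beyond desk scale
    (small boxes additionally trap interlocked multi-director states).
    The ordered branch is cheap in both directions: below the
    transition an aligned start melts quickly to the isotropic
    equilibrium, above it the nematic persists.  Rods longer than the
    box edge are laid as periodic spanning columns; otherwise as an
    in-box aligned bundle.  Chain-length dispersity develops
    dynamically through the connectivity-altering moves.
    """
    from .synthetic import make_aligned_rods, make_nematic_columns

    p = (params or SystemParams()).replace(theta0=0.0)
    from .chain_model import box_edge_for_phi
    n_at = p.n_chains * p.n_av
    if box_edge_for_phi(n_at, p.sigma, phi) >= (p.n_av + 1) * p.sigma:
        config = make_aligned_rods(p.n_chains, p.n_av, phi=phi,
                                   jitter_angle=0.0, sigma=p.sigma, seed=seed)
    else:
        config = make_nematic_columns(p.n_chains, p.n_av, phi=phi,
                                      sigma=p.sigma, seed=seed)
    engine = MCEngine(config, p, schedule, cb, seed=seed + 1)
    rows = []
    for i in range(max(1, budget // snapshot_interval)):
        engine.run(snapshot_interval)
        rows.append({"step": (i + 1) * snapshot_interval,
                     "q": nematic_order(engine.config()).q})
    df = pd.DataFrame(rows)
    df.attrs.update({"phi": phi, "theta0_deg": 0.0, "seed": seed,
                     "budget": budget, "branch": "ordered"})
    return df


def steady_state_average(series, window_fraction: float = 0.5,
                         n_blocks: int = 4) -> tuple[float, float, bool]:
    """Average over the stationary tail with a block-error estimate.

    The averaging window is the trailing ``window_fraction`` of the
    series.  Equilibration test: the least-squares drift over the
    window (slope x span) must be consistent with zero within twice the
    block-averaging error; otherwise the series is flagged
    unequilibrated.  Returns (mean, block standard error, equilibrated).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    tail = x[int(len(x) * (1.0 - window_fraction)):]
    mean = float(tail.mean())
    if len(tail) < n_blocks:
        return mean, float("nan"), True
    blocks = np.array_split(tail, n_blocks)
    bmeans = np.array([b.mean() for b in blocks])
    sem = float(bmeans.std(ddof=1) / math.sqrt(n_blocks))
    t = np.arange(len(tail), dtype=float)
    slope, intercept = np.polyfit(t, tail, 1)
    resid = tail - (slope * t + intercept)
    denom = float(((t - t.mean()) ** 2).sum())
    se_slope = math.sqrt(max(resid.var(ddof=2), 0.0) / denom) if denom else 0.0
    drift = abs(slope) * (len(tail) - 1)
    # consistent with zero drift against either error scale: the block
    # error of the mean, or the regression slope's own standard error
    equilibrated = (drift <= 2.0 * sem + 1e-12
                    or abs(slope) <= 2.0 * se_slope + 1e-12)
    return mean, sem, equilibrated


def classify_phase(q_mean: float, tau_c_mean: float,
                   cry_cutoff: float = CRY_CUTOFF) -> tuple[str, str]:
    """Joint (local, global) phase label from steady-state averages."""
    local = "CRY" if tau_c_mean >= cry_cutoff else "AMO"
    return local, classify_mesophase(q_mean)


def bending_distribution(trajectory: Trajectory, n_bins: int = 60):
    """Normalized density of bending angles pooled over all frames.

    Returns (bin_centers, density) with unit integral over [0, pi].
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    angles = []
    for _, config in trajectory:
        for chain in config.chains:
            if len(chain) >= 3:
                _, th, _ = bond_geometry(chain)
                angles.append(th)
    if not angles:
        raise ValueError("no bending angles in trajectory (chains too short)")
    pooled = np.concatenate(angles)
    density, edges = np.histogram(pooled, bins=n_bins, range=(0.0, math.pi),
                                  density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def summarize_state_point(df: pd.DataFrame) -> PhasePoint:
    """Collapse a descriptor time series into a classified PhasePoint."""
    q_mean, q_sem, q_eq = steady_state_average(df["q"].to_numpy())
    has_cce = "tau_c" in df.columns
    if has_cce:
        tau_mean, _, tau_eq = steady_state_average(df["tau_c"].to_numpy())
        s_hcp, _, _ = steady_state_average(df["S_hcp"].to_numpy())
        s_fcc, _, _ = steady_state_average(df["S_fcc"].to_numpy())
        s_fiv, _, _ = steady_state_average(df["S_fiv"].to_numpy())
    else:
        tau_mean = s_hcp = s_fcc = s_fiv = float("nan")
        tau_eq = True
    local, glob = classify_phase(q_mean, tau_mean if has_cce else 0.0)
    return PhasePoint(
        phi=df.attrs.get("phi", float("nan")),
        theta0_deg=df.attrs.get("theta0_deg", float("nan")),
        q_mean=q_mean, S_hcp=s_hcp, S_fcc=s_fcc, S_fiv=s_fiv,
        tau_c=tau_mean, local_label=local, global_label=glob,
        equilibrated=bool(q_eq and tau_eq),
        provenance={"seed": df.attrs.get("seed"),
                    "budget": df.attrs.get("budget"),
                    "q_sem": q_sem})


def build_phase_diagram(points: list[PhasePoint]) -> pd.DataFrame:
    """Long-format machine-readable phase diagram.

    One row per submitted state point, deterministically ordered by
    (theta0, phi); unequilibrated points are flagged, never dropped.
    """
    if not points:
        raise ValueError("need at least one state point")
    rows = [{
        "theta0_deg": p.theta0_deg, "phi": p.phi, "q_mean": p.q_mean,
        "S_hcp": p.S_hcp, "S_fcc": p.S_fcc, "S_fiv": p.S_fiv,
        "tau_c": p.tau_c, "local": p.local_label, "global": p.global_label,
        "phase": f"{p.local_label}-{p.global_label}",
        "equilibrated": p.equilibrated,
    } for p in points]
    df = pd.DataFrame(rows)
    return df.sort_values(["theta0_deg", "phi"], kind="mergesort",
                          ignore_index=True)
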