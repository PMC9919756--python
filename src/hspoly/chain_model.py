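"""Domain types, geometry and energetics of tangent hard-sphere chains.

The molecular model is a linear chain of hard spherical monomers of
collision diameter ``sigma`` (the length unit).  Bonded neighbors sit at
(near) contact: bond lengths fluctuate uniformly in ``[sigma, sigma + dl]``
with ``dl`` a very small gap that practically enforces tangency.  Chain
stiffness enters through a harmonic potential on the bending angle
``theta`` between successive bond vectors,

    U_bend(theta) = k_theta * (theta - theta0)**2      (in units of kBT)

with ``theta = 0`` a straight continuation and ``theta = 2*pi/3`` (120 deg)
a fully compact touching trimer.  Non-bonded pairs interact through the
hard-sphere potential: zero for center distance ``>= sigma``, infeasible
below.  All simulations are athermal (kBT = 1) in a cubic periodic box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SystemParams",
    "Configuration",
    "Trajectory",
    "Violation",
    "hard_sphere_energy",
    "bending_energy",
    "packing_fraction",
    "box_edge_for_phi",
    "bond_geometry",
    "validate_configuration",
    "minimum_image",
]

#: geometric tolerance used when checking hard constraints
GEOM_TOL = 1e-9


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemParams:
    """All model constants of a semi-flexible tangent hard-sphere system.

    Defaults correspond to the reference study conditions: 100 chains of
    mean length 12 (1200 monomers), uniform length dispersity on [6, 18],
    bond gap ``dl = 6.5e-4 sigma`` and bending constant ``k_theta = 9``
    (kBT / rad^2).
    """

    sigma: float = 1.0
    dl: float = 6.5e-4
    k_theta: float = 9.0
    theta0: float = 0.0                      # radians
    n_chains: int = 100
    n_av: int = 12
    length_bounds: tuple[int, int] = (6, 18)
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dl < 0:
            raise ValueError("dl must be non-negative")
        if self.k_theta < 0:
            raise ValueError("k_theta must be non-negative")
        if not (0.0 <= self.theta0 <= 2.0 * math.pi / 3.0 + 1e-12):
            raise ValueError("theta0 must lie in [0, 2*pi/3]")
        lo, hi = self.length_bounds
        if not (lo <= self.n_av <= hi):
            raise ValueError("length_bounds must contain n_av")
        if lo < 1:
            raise ValueError("chains need at least 1 monomer")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.kBT != 1.0:
            raise ValueError("the model is athermal: kBT is fixed to 1")

    @classmethod
    def with_theta0_deg(cls, theta0_deg: float, **kwargs) -> "SystemParams":
        """Build params with the equilibrium bending angle given in degrees."""
        return cls(theta0=math.radians(theta0_deg), **kwargs)

    @property
    def theta0_deg(self) -> float:
        return math.degrees(self.theta0)

    def replace(self, **kwargs) -> "SystemParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# configuration container
# ---------------------------------------------------------------------------

class Configuration:
    """A snapshot of the system: cubic periodic box + chain coordinates.

    Coordinates are held *unwrapped* per chain (chains may span several
    periodic images); wrapped positions and integer unwrap shifts are
    derived on demand.  ``chains[c]`` is an ``(n_c, 3)`` float array whose
    rows follow the chain contour.
    """

    def __init__(self, box_edge: float, chains: list[np.ndarray]):
        if box_edge <= 0:
            raise ValueError("box_edge must be positive")
        self.box_edge = float(box_edge)
        self.chains = [np.asarray(c, dtype=float).reshape(-1, 3) for c in chains]

    # -- derived views ------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def chain_lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.chains], dtype=int)

    def positions_unwrapped(self) -> np.ndarray:
        """Flat ``(N, 3)`` unwrapped coordinates, chains concatenated."""
        return np.concatenate(self.chains, axis=0) if self.chains else np.empty((0, 3))

    def positions_wrapped(self) -> np.ndarray:
        return np.mod(self.positions_unwrapped(), self.box_edge)

    def unwrap_shifts(self) -> np.ndarray:
        """Integer image offsets such that unwrapped = wrapped + shift * L."""
        return np.floor(self.positions_unwrapped() / self.box_edge).astype(int)

    def chain_ids(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.chain_lengths)

    def mono_indices(self) -> np.ndarray:
        if not self.chains:
            return np.empty(0, dtype=int)
        return np.concatenate([np.arange(len(c)) for c in self.chains])

    def packing_fraction(self, sigma: float = 1.0) -> float:
        return packing_fraction(self.n_atoms, sigma, self.box_edge)

    def copy(self) -> "Configuration":
        return Configuration(self.box_edge, [c.copy() for c in self.chains])


@dataclass
class Trajectory:
    """Ordered sequence of (MC step, Configuration) snapshots."""

    steps: list[int] = field(default_factory=list)
    configurations: list[Configuration] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def append(self, step: int, config: Configuration) -> None:
        if self.steps and step <= self.steps[-1]:
            raise ValueError("mc_step must be strictly increasing")
        self.steps.append(int(step))
        self.configurations.append(config)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(zip(self.steps, self.configurations))


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------

def hard_sphere_energy(r: float, sigma: float = 1.0) -> tuple[float, bool]:
    """Hard-sphere pair energy.

    Returns ``(energy, feasible)``: energy is always 0; ``feasible`` is
    False for overlapping pairs (``r < sigma``), in which place the
    configuration carries infinite energy (no finite value is ever
    returned for an overlap).
    """
    if r < 0:
        raise ValueError("distance must be non-negative")
    return 0.0, bool(r >= sigma)


def bending_energy(theta, k_theta: float, theta0: float):
    """Harmonic bending energy ``k_theta * (theta - theta0)**2`` in kBT.

    ``theta`` may be a scalar or array of angles in radians on [0, pi].
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < -1e-12) or np.any(th > math.pi + 1e-12):
        raise ValueError("bending angle must lie in [0, pi]")
    out = k_theta * (th - theta0) ** 2
    return float(out) if np.isscalar(theta) else out


def packing_fraction(n_at: int, sigma: float, box_edge: float) -> float:
    """Volume fraction phi = (pi/6) N_at sigma^3 / L^3 of a cubic cell."""
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    return math.pi / 6.0 * n_at * sigma**3 / box_edge**3


def box_edge_for_phi(n_at: int, sigma: float, phi: float) -> float:
    """Invert the packing-fraction relation: the L giving the target phi."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    return (math.pi / 6.0 * n_at * sigma**3 / phi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def minimum_image(dx: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image displacement(s) for a cubic periodic box."""
    return dx - box_edge * np.round(dx / box_edge)


def bond_angles_from_bonds(bonds: np.ndarray) -> np.ndarray:
    """Angles between successive bond vectors (0 = straight continuation)."""
    b1 = bonds[:-1]
    b2 = bonds[1:]
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-length bond")
    cosang = np.einsum("ij,ij->i", b1, b2) / (n1 * n2)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def bond_geometry(coords: np.ndarray):
    """Per-bond lengths, per-triplet bending angles, per-quadruplet torsions.

    ``coords`` are the *unwrapped* coordinates of one chain, rows along the
    contour.  The bending angle is measured between successive bond
    vectors ``b_i = x_{i+1} - x_i``, so a straight chain has theta = 0 and
    a compact touching trimer has theta = 2*pi/3.  Torsions are the
    dihedral angles of three successive bonds (returned in [0, pi]).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) < 2:
        raise ValueError("need at least 2 monomers for bond geometry")
    bonds = np.diff(coords, axis=0)
    lengths = np.linalg.norm(bonds, axis=1)
    if np.any(lengths == 0):
        raise ValueError("zero-length bond")
    angles = bond_angles_from_bonds(bonds) if len(coords) >= 3 else np.empty(0)
    torsions = np.empty(0)
    if len(coords) >= 4:
        b1, b2, b3 = bonds[:-2], bonds[1:-1], bonds[2:]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.linalg.norm(n1, axis=1)
        m2 = np.linalg.norm(n2, axis=1)
        ok = (m1 > 0) & (m2 > 0)
        cosphi = np.full(len(b2), np.nan)
        cosphi[ok] = np.einsum("ij,ij->i", n1[ok], n2[ok]) / (m1[ok] * m2[ok])
        torsions = np.arccos(np.clip(cosphi, -1.0, 1.0))
    return lengths, angles, torsions


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    kind: str          # "overlap" | "bond_window" | "chain_length"
    detail: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}{self.detail}"


def _overlap_pairs(config: Configuration, sigma: float) -> list[tuple[int, int]]:
    """Non-bonded pairs with minimum-image distance < sigma (tolerance GEOM_TOL)."""
    from scipy.spatial import cKDTree

    pos = config.positions_wrapped()
    n = len(pos)
    if n < 2:
        return []
    L = config.box_edge
    cutoff = sigma * (1.0 - 1e-12)
    if L > 2.0 * sigma:
        # guard against coordinates == L after the modulo
        tree = cKDTree(np.mod(pos, L), boxsize=L)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    else:
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(minimum_image(pos[ii] - pos[jj], L), axis=1)
        pairs = np.stack([ii, jj], axis=1)[d < cutoff]
    cid = config.chain_ids()
    mono = config.mono_indices()
    out = []
    for i, j in pairs:
        bonded = cid[i] == cid[j] and abs(int(mono[i]) - int(mono[j])) == 1
        if not bonded:
            out.append((int(i), int(j)))
    return out


def validate_configuration(config: Configuration, params: SystemParams) -> list[Violation]:
    """Check all hard constraints; an empty report means a valid configuration.

    Checks, in order: (i) every non-bonded pair (including 1-3 and farther
    intra-chain pairs) at minimum-image distance >= sigma; (ii) every bond,
    on unwrapped coordinates, inside the hard window [sigma, sigma + dl];
    (iii) every chain length inside ``length_bounds``.
    """
    violations: list[Violation] = []
    sigma = params.sigma
    for i, j in _overlap_pairs(config, sigma):
        violations.append(Violation("overlap", (i, j)))
    lo = sigma * (1.0 - GEOM_TOL)
    hi = (sigma + params.dl) * (1.0 + GEOM_TOL)
    for c, coords in enumerate(config.chains):
        if len(coords) >= 2:
            lengths = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            for b in np.nonzero((lengths < lo) | (lengths > hi))[0]:
                violations.append(Violation("bond_window", (c, int(b), float(lengths[b]))))
        nlo, nhi = params.length_bounds
        if not (nlo <= len(coords) <= nhi):
            violations.append(Violation("chain_length", (c, len(coords))))
    return violations
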