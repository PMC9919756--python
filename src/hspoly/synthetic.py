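"""Synthetic reference structures for descriptor and pipeline tests.

Generators for every idealized configuration the order descriptors must
recognize without running long Monte Carlo: close-packed stacks (FCC /
HCP / RHCP), icosahedral clusters, aligned rod bundles (prolate
mesogen), planar layered chain systems (oblate mesogen), and dilute
random gases.  Close-packed and gas fixtures use single-monomer dummy
chains: the local descriptor operates on sites irrespective of
connectivity, which decouples crystallinity tests from chain-geometry
feasibility.  Chain fixtures (rods, layers) are used for the nematic
descriptor.  All generators are deterministic given their parameters
and seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .chain_model import (Configuration, SystemParams, box_edge_for_phi,
                          minimum_image, validate_configuration)

__all__ = [
    "validate_stacking",
    "stacking_labels",
    "make_close_packed",
    "make_bulk_fcc",
    "make_icosahedral_cluster",
    "make_random_gas",
    "make_aligned_rods",
    "make_planar_layers",
    "perturb",
]

_OFFSETS = {"A": 0.0, "B": 1.0 / 3.0, "C": 2.0 / 3.0}


def validate_stacking(stacking: str) -> str:
    """A stacking string is valid if over {A,B,C} with no repeats."""
    s = stacking.upper()
    if len(s) < 1 or any(ch not in "ABC" for ch in s):
        raise ValueError(f"invalid stacking string {stacking!r}")
    if any(a == b for a, b in zip(s, s[1:])):
        raise ValueError("stacking string has two consecutive equal layers")
    return s


def stacking_labels(stacking: str) -> list[str | None]:
    """Expected environment per layer: the flanking-layer rule.

    Interior layers whose two flanking layers carry the same letter
    (...X Y X...) have HCP environments; differing flanks (...X Y Z...)
    give FCC.  Boundary layers have no complete shell (None).
    """
    s = validate_stacking(stacking)
    out: list[str | None] = [None] * len(s)
    for i in range(1, len(s) - 1):
        out[i] = "HCP" if s[i - 1] == s[i + 1] else "FCC"
    return out


def make_close_packed(stacking: str, layer_dims: tuple[int, int] = (6, 6),
                      spacing: float = 1.0, margin: float = 4.0) -> Configuration:
    """Finite close-packed stack of triangular-lattice layers.

    Layer letters select the in-plane offset (A/B/C thirds of a1+a2);
    successive layers sit ``spacing * sqrt(2/3)`` apart so all nearest
    neighbors are at ``spacing``.  The slab floats isolated inside a
    cubic box (no wrap contact), as single-monomer dummy chains.
    """
    s = validate_stacking(stacking)
    nx, ny = layer_dims
    a1 = np.array([1.0, 0.0, 0.0]) * spacing
    a2 = np.array([0.5, math.sqrt(3.0) / 2.0, 0.0]) * spacing
    dz = spacing * math.sqrt(2.0 / 3.0)
    pts = []
    for k, letter in enumerate(s):
        off = _OFFSETS[letter] * (a1 + a2)
        for i in range(nx):
            for j in range(ny):
                p = i * a1 + j * a2 + off
                pts.append([p[0], p[1], k * dz])
    pts = np.array(pts)
    pts -= pts.min(axis=0) - margin / 2.0
    L = float(pts.max() + margin / 2.0)
    return Configuration(L, [p.reshape(1, 3) for p in pts])


def layer_of_sites(config: Configuration, spacing: float = 1.0) -> np.ndarray:
    """Recover the stacking-layer index of each close-packed site from z."""
    z = config.positions_unwrapped()[:, 2]
    dz = spacing * math.sqrt(2.0 / 3.0)
    return np.rint((z - z.min()) / dz).astype(int)


def interior_mask(config: Configuration, spacing: float = 1.0) -> np.ndarray:
    """Sites with a complete first shell: 12th neighbor within 1.1 spacing."""
    pos = np.mod(config.positions_wrapped(), config.box_edge)
    tree = cKDTree(pos, boxsize=config.box_edge)
    d, _ = tree.query(pos, k=13)
    return d[:, 12] < 1.1 * spacing


def make_bulk_fcc(n_cells: int = 3, spacing: float = 1.0) -> Configuration:
    """Periodic bulk FCC crystal (cubic cell, 4 sites/cell, all shells full)."""
    a = spacing * math.sqrt(2.0)
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]) * a
    cells = np.arange(n_cells)
    grid = np.array(np.meshgrid(cells, cells, cells, indexing="ij")).reshape(3, -1).T * a
    pts = (grid[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    L = n_cells * a
    return Configuration(L, [p.reshape(1, 3) for p in pts])


def make_icosahedral_cluster(distance: float = 1.1, sigma: float = 1.0,
                             margin: float = 4.0) -> Configuration:
    """13-sphere icosahedral (fivefold) cluster: center + 12 vertices.

    ``distance`` is the center-to-vertex distance; vertex-vertex spacing
    is ~1.0515 * distance, so ``distance >= sigma / 0.951`` keeps the
    vertex spheres from overlapping.
    """
    g = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            verts += [(0, s1, s2 * g), (s1, s2 * g, 0), (s2 * g, 0, s1)]
    v = np.array(verts, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * distance
    edge = distance * math.sqrt(2.0 - 2.0 / math.sqrt(5.0))
    if edge < sigma * (1.0 - 1e-12):
        raise ValueError("vertex spheres overlap: increase distance")
    pts = np.vstack([[0.0, 0.0, 0.0], v])
    pts -= pts.min(axis=0) - margin / 2.0
    L = float(pts.max() + margin / 2.0)
    return Configuration(L, [p.reshape(1, 3) for p in pts])


def make_random_gas(n_sites: int, phi: float = 0.01, sigma: float = 1.0,
                    seed: int = 0, max_tries: int = 10000) -> Configuration:
    """Dilute random gas of non-overlapping spheres (single-monomer chains)."""
    rng = np.random.default_rng(seed)
    L = box_edge_for_phi(n_sites, sigma, phi)
    placed: list[np.ndarray] = []
    for _ in range(n_sites):
        for _ in range(max_tries):
            p = rng.uniform(0.0, L, size=3)
            if not placed:
                placed.append(p)
                break
            d = np.linalg.norm(minimum_image(np.array(placed) - p, L), axis=1)
            if np.all(d >= sigma):
                placed.append(p)
                break
        else:
            raise RuntimeError("placement failed; lower phi")
    return Configuration(L, [p.reshape(1, 3) for p in placed])


def _cap_direction(rng: np.random.Generator, jitter_angle: float) -> np.ndarray:
    """Uniform direction on the spherical cap of half-angle jitter about +z."""
    cos_min = math.cos(min(jitter_angle, math.pi))
    c = rng.uniform(cos_min, 1.0)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    psi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([s * math.cos(psi), s * math.sin(psi), c])


def _place_chains(protos: list[np.ndarray], L: float, sigma: float,
                  rng: np.random.Generator, max_tries: int = 2000) -> list[np.ndarray]:
    """Place chain prototypes without overlap: lattice site first, then
    random translations (orientations are never resampled, so the
    prototypes' axis statistics are preserved)."""
    n = len(protos)
    n_side = math.ceil(math.sqrt(n))
    pitch = L / n_side
    chains: list[np.ndarray] = []
    occ: np.ndarray | None = None
    for c, proto in enumerate(protos):
        i, j = divmod(c, n_side)
        base = np.array([(i + 0.5) * pitch, (j + 0.5) * pitch, L / 2.0])
        for t in range(max_tries):
            shift = base if t == 0 else rng.uniform(0.0, L, size=3)
            cand = proto + shift
            if occ is not None:
                d = np.linalg.norm(
                    minimum_image(occ[:, None, :] - cand[None, :, :], L), axis=2)
                if d.min() < sigma:
                    continue
            chains.append(cand)
            occ = cand if occ is None else np.vstack([occ, cand])
            break
        else:
            raise ValueError("infeasible phi: chain placement failed")
    return chains


def make_aligned_rods(n_chains: int, n_av: int = 12, phi: float = 0.03,
                      jitter_angle: float = 0.0, sigma: float = 1.0,
                      seed: int = 0) -> Configuration:
    """Bundle of straight tangent rods with a common (jittered) axis.

    Rods of ``n_av`` tangent spheres point along +z, each tilted by a
    random angle <= ``jitter_angle`` (pi gives isotropic axes), centers
    on a square lattice in the xy plane.  Feasibility requires the box
    edge from phi to exceed the rod extent; the generator raises for
    infeasible requests rather than wrapping rods onto themselves.
    """
    rng = np.random.default_rng(seed)
    n_at = n_chains * n_av
    L = box_edge_for_phi(n_at, sigma, phi)
    if (n_av - 1) * sigma + sigma > L:
        raise ValueError("infeasible phi: rod extent exceeds the box edge")
    protos = []
    for _ in range(n_chains):
        u = _cap_direction(rng, jitter_angle)
        k = np.arange(n_av) - (n_av - 1) / 2.0
        protos.append(k[:, None] * sigma * u[None, :])
    return Configuration(L, _place_chains(protos, L, sigma, rng))


def make_nematic_columns(n_chains: int, n_av: int = 12, phi: float = 0.30,
                         sigma: float = 1.0, seed: int = 0) -> Configuration:
    """Aligned rods spanning the periodic box as tangent columns.

    At densities where a straight ``n_av``-mer is longer than the box
    edge, an aligned phase can only be built with rods running through
    the periodic boundary.  Each chain occupies one site of a square
    lateral lattice and runs along z with bonds exactly at contact; the
    chain's own periodic image continues the column, so feasibility
    requires the wrap gap ``L - (n_av - 1) sigma >= sigma``.  Column
    phases (z offsets) are randomized per chain.  This is the
    ordered-branch starting state for nematic stability runs.
    """
    rng = np.random.default_rng(seed)
    n_at = n_chains * n_av
    L = box_edge_for_phi(n_at, sigma, phi)
    if L < n_av * sigma:
        raise ValueError("infeasible phi: wrap gap below contact; "
                         "use fewer/shorter chains or lower phi")
    n_side = math.ceil(math.sqrt(n_chains))
    pitch = L / n_side
    if pitch < sigma * (1 + 1e-9):
        raise ValueError("infeasible phi: lateral column pitch below sigma")
    chains = []
    for c in range(n_chains):
        i, j = divmod(c, n_side)
        z0 = rng.uniform(0.0, L)
        pts = np.array([[(i + 0.5) * pitch, (j + 0.5) * pitch,
                         z0 + k * sigma] for k in range(n_av)])
        chains.append(pts)
    return Configuration(L, chains)


def make_planar_layers(n_chains: int, n_av: int = 12, phi: float = 0.03,
                       n_directions: int = 3, sigma: float = 1.0,
                       seed: int = 0) -> Configuration:
    """Planar layered chain system: right-angle staircase paths in xy planes.

    Each chain is a staircase of tangent spheres alternating between two
    perpendicular in-plane step directions, so every bending angle is 90
    degrees and the chain's long axis lies in the plane along the step
    diagonal.  Axis directions are assigned round-robin over
    ``n_directions`` equally spaced in-plane angles: three or more
    balanced directions realize the ideal oblate mesogen (q = -1/2);
    ``n_directions=1`` degenerates to a prolate bundle (q = 1).
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    n_at = n_chains * n_av
    L = box_edge_for_phi(n_at, sigma, phi)
    diag_extent = (n_av - 1) * sigma / math.sqrt(2.0) + sigma
    pitch_xy = diag_extent + 0.2 * sigma       # disjoint in-plane footprints
    pitch_z = 1.02 * sigma
    per_plane = max(1, int(L // pitch_xy)) ** 2
    n_planes = max(1, int(L // pitch_z))
    if per_plane * n_planes < n_chains or diag_extent > L:
        raise ValueError("infeasible phi: too many chains for the plane lattice")
    chains = []
    for c in range(n_chains):
        theta = (c % n_directions) * math.pi / n_directions
        d1 = np.array([math.cos(theta - math.pi / 4),
                       math.sin(theta - math.pi / 4), 0.0])
        d2 = np.array([math.cos(theta + math.pi / 4),
                       math.sin(theta + math.pi / 4), 0.0])
        steps = [d1 if k % 2 == 0 else d2 for k in range(n_av - 1)]
        pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0) * sigma])
        pts -= pts.mean(axis=0)
        plane, cell = divmod(c, per_plane)
        gi, gj = divmod(cell, max(1, int(L // pitch_xy)))
        center = np.array([(gi + 0.5) * pitch_xy, (gj + 0.5) * pitch_xy,
                           (plane + 0.5) * pitch_z])
        chains.append(pts + center)
    return Configuration(L, chains)


def perturb(config: Configuration, amplitude: float, seed: int = 0,
            params: SystemParams | None = None) -> Configuration:
    """Gaussian-jitter every monomer, rejecting per-monomer violations.

    Each monomer in turn receives an isotropic Gaussian displacement of
    standard deviation ``amplitude``; the displacement is discarded if
    it would overlap any other sphere or push a bond out of the hard
    window.  The output is therefore always a valid configuration.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    out = config.copy()
    if amplitude == 0:
        return out
    p = params or SystemParams(n_chains=out.n_chains, n_av=1, length_bounds=(1, 10**9))
    rng = np.random.default_rng(seed)
    L = out.box_edge
    flat = out.positions_unwrapped()
    counts = out.chain_lengths
    starts = np.concatenate([[0], np.cumsum(counts)])
    lo, hi = p.sigma, p.sigma + p.dl
    for c, coords in enumerate(out.chains):
        for i in range(len(coords)):
            disp = rng.normal(0.0, amplitude, size=3)
            new = coords[i] + disp
            gi = starts[c] + i
            d = np.linalg.norm(minimum_image(flat - new, L), axis=1)
            d[gi] = np.inf
            for nb in (i - 1, i + 1):           # bonded neighbors: window, not HS
                if 0 <= nb < len(coords):
                    d[starts[c] + nb] = np.inf
            if d.min() < p.sigma * (1 - 1e-12):
                continue
            ok = True
            for nb in (i - 1, i + 1):
                if 0 <= nb < len(coords):
                    bl = np.linalg.norm(new - coords[nb])
                    if not (lo * (1 - 1e-12) <= bl <= hi * (1 + 1e-12)):
                        ok = False
                        break
            if ok:
                coords[i] = new
                flat[gi] = new
    return out
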