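"""Metropolis / configurational-bias Monte Carlo for hard-sphere chains.

The move mix follows the reference protocol for dense athermal polymer
packings: local configurational-bias (CB) moves — reptation (10%),
end rotation (10%), internal flip (34.8%), intermolecular reptation
(25%), end-segment regrowth (20%) — plus rare connectivity-altering
bridging moves, simplified end-bridging (sEB, 0.1%) and simplified
intramolecular end-bridging (sIEB, 0.1%), which reapportion monomers
among chains and equilibrate dense melts.

All local moves regrow monomers trial-by-trial: ``n_trials`` candidate
positions are sampled in the hard bond shell ``[sigma, sigma+dl]``,
weighted by the Boltzmann factor of every bending angle the move
alters, and the move is accepted with the standard CB rule
``min(1, W_new / W_old)``.  Bridging moves change no positions, only
connectivity; their acceptance carries the forward/reverse
eligible-target count ratio to preserve detailed balance.

One MC step is one attempted move.  A single seeded generator drives
the whole run, so trajectories are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .chain_model import (Configuration, SystemParams, Trajectory,
                          box_edge_for_phi, minimum_image,
                          validate_configuration)

__all__ = [
    "MoveSchedule",
    "CBSettings",
    "CellList",
    "build_cell_list",
    "cb_accept",
    "MCEngine",
    "run_mc",
    "generate_dilute",
    "compress",
]

MOVE_TYPES = ("reptation", "rotation", "flip", "intermolecular_reptation",
              "end_segment_regrowth", "sEB", "sIEB")


@dataclass(frozen=True)
class MoveSchedule:
    """Attempt probability per move type (defaults: the reference mix)."""

    reptation: float = 0.10
    rotation: float = 0.10
    flip: float = 0.348
    intermolecular_reptation: float = 0.25
    end_segment_regrowth: float = 0.20
    sEB: float = 0.001
    sIEB: float = 0.001

    def __post_init__(self):
        probs = self.probabilities()
        if np.any(probs < 0):
            raise ValueError("move probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"move probabilities must sum to 1, got {probs.sum()!r}")

    def probabilities(self) -> np.ndarray:
        return np.array([getattr(self, t) for t in MOVE_TYPES])


@dataclass(frozen=True)
class CBSettings:
    """Configurational-bias parameters.

    ``n_trials_table`` maps packing-fraction upper bounds to trial
    counts; trial numbers grow with density (they affect efficiency
    only — CB weights enter the acceptance exactly).
    """

    n_trials_table: tuple[tuple[float, int], ...] = ((0.45, 10), (0.55, 20), (2.0, 40))
    max_regrow: int = 3

    def __post_init__(self):
        if any(n < 1 for _, n in self.n_trials_table):
            raise ValueError("n_trials must be >= 1")
        if self.max_regrow < 1:
            raise ValueError("max_regrow must be >= 1")

    def n_trials(self, phi: float) -> int:
        for bound, n in self.n_trials_table:
            if phi < bound:
                return n
        return self.n_trials_table[-1][1]


# ---------------------------------------------------------------------------
# cell list
# ---------------------------------------------------------------------------

class CellList:
    """Linked cells over wrapped positions for fixed-radius neighbor queries.

    Cells are at least ``cutoff`` wide, so a 27-cell stencil around a
    query point finds every particle within ``cutoff``.  Storage is the
    classic array-based linked list (``head`` per cell, ``next`` per
    particle) so the hot overlap kernel can run compiled.  Falls back to
    an all-particles scan when the box fits fewer than 3 cells per edge.
    """

    def __init__(self, positions: np.ndarray, box_edge: float, cutoff: float):
        self.L = float(box_edge)
        self.cutoff = float(cutoff)
        n = max(1, int(math.floor(self.L / cutoff)))
        if n < 3:
            n = 1                      # brute-force: a single cell
        self.n_cells = n
        self.positions = np.mod(np.asarray(positions, float), self.L)
        N = len(self.positions)
        self.head = np.full(n * n * n, -1, dtype=np.int64)
        self.next = np.full(N, -1, dtype=np.int64)
        self.id_cell = np.empty(N, dtype=np.int64)
        for i in range(N):
            c = self._cell_of(self.positions[i])
            self.id_cell[i] = c
            self.next[i] = self.head[c]
            self.head[c] = i

    def _cell_of(self, p: np.ndarray) -> int:
        n = self.n_cells
        inv = n / self.L
        cx = min(n - 1, int(p[0] * inv))
        cy = min(n - 1, int(p[1] * inv))
        cz = min(n - 1, int(p[2] * inv))
        return cx + n * (cy + n * cz)

    def _unlink(self, i: int) -> None:
        c = self.id_cell[i]
        j = self.head[c]
        if j == i:
            self.head[c] = self.next[i]
            return
        while self.next[j] != i:
            j = self.next[j]
        self.next[j] = self.next[i]

    def move(self, i: int, new_p: np.ndarray) -> None:
        new_p = np.mod(new_p, self.L)
        self.positions[i] = new_p
        c = self._cell_of(new_p)
        if c != self.id_cell[i]:
            self._unlink(i)
            self.id_cell[i] = c
            self.next[i] = self.head[c]
            self.head[c] = i

    def query_point(self, p: np.ndarray) -> np.ndarray:
        """Candidate ids: all particles possibly within ``cutoff`` of p."""
        N = len(self.positions)
        if self.n_cells == 1:
            return np.arange(N)
        out = np.empty(N, dtype=np.int64)
        cnt = _gather_candidates(np.mod(p, self.L), self.head, self.next,
                                 self.n_cells, self.L, out)
        return out[:cnt]

    def neighbor_pairs(self, r: float) -> set[tuple[int, int]]:
        """All pairs within r (<= cutoff), for oracle checks."""
        if r > self.cutoff * (1 + 1e-12):
            raise ValueError("r exceeds the cell-list cutoff")
        pairs = set()
        for i, p in enumerate(self.positions):
            cand = self.query_point(p)
            cand = cand[cand > i]
            if len(cand) == 0:
                continue
            d = np.linalg.norm(
                minimum_image(self.positions[cand] - p, self.L), axis=1)
            for j in cand[d <= r]:
                pairs.add((i, int(j)))
        return pairs


@njit(cache=True)
def _gather_candidates(p, head, nxt, n, L, out):  # pragma: no cover - compiled
    inv = n / L
    cx = min(n - 1, int(p[0] * inv))
    cy = min(n - 1, int(p[1] * inv))
    cz = min(n - 1, int(p[2] * inv))
    cnt = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                c = ((cx + dx) % n) + n * (((cy + dy) % n) + n * ((cz + dz) % n))
                j = head[c]
                while j != -1:
                    out[cnt] = j
                    cnt += 1
                    j = nxt[j]
    return cnt


@njit(cache=True, inline="always")
def _point_ok(px, py, pz, positions, head, nxt, n, L, sig2, exempt,
              extra):  # pragma: no cover - compiled
    """Hard-sphere feasibility of one wrapped point against the cell list
    (27-cell stencil; all particles when n == 1) plus explicit extras."""
    if n == 1:
        for j in range(positions.shape[0]):
            skip = False
            for e in exempt:
                if j == e:
                    skip = True
                    break
            if skip:
                continue
            dx = px - positions[j, 0]
            dx -= L * round(dx / L)
            dy = py - positions[j, 1]
            dy -= L * round(dy / L)
            dz = pz - positions[j, 2]
            dz -= L * round(dz / L)
            if dx * dx + dy * dy + dz * dz < sig2:
                return False
    else:
        inv = n / L
        cx = min(n - 1, int(px * inv))
        cy = min(n - 1, int(py * inv))
        cz = min(n - 1, int(pz * inv))
        for ddx in range(-1, 2):
            for ddy in range(-1, 2):
                for ddz in range(-1, 2):
                    c = ((cx + ddx) % n) + n * (((cy + ddy) % n)
                                                + n * ((cz + ddz) % n))
                    j = head[c]
                    while j != -1:
                        skip = False
                        for e in exempt:
                            if j == e:
                                skip = True
                                break
                        if not skip:
                            dx = px - positions[j, 0]
                            dx -= L * round(dx / L)
                            dy = py - positions[j, 1]
                            dy -= L * round(dy / L)
                            dz = pz - positions[j, 2]
                            dz -= L * round(dz / L)
                            if dx * dx + dy * dy + dz * dz < sig2:
                                return False
                        j = nxt[j]
    for m in range(extra.shape[0]):
        dx = px - extra[m, 0]
        dx -= L * round(dx / L)
        dy = py - extra[m, 1]
        dy -= L * round(dy / L)
        dz = pz - extra[m, 2]
        dz -= L * round(dz / L)
        if dx * dx + dy * dy + dz * dz < sig2:
            return False
    return True


@njit(cache=True)
def _trial_feasible(tw, positions, head, nxt, n, L, sig2, exempt,
                    extra):  # pragma: no cover - compiled
    T = tw.shape[0]
    ok = np.empty(T, np.bool_)
    for t in range(T):
        ok[t] = _point_ok(tw[t, 0], tw[t, 1], tw[t, 2], positions, head,
                          nxt, n, L, sig2, exempt, extra)
    return ok


@njit(cache=True)
def _grow_kernel(anchor, prev, has_prev, randn, randu, positions, head, nxt,
                 n, L, sig2, sigma, dl, k_theta, theta0, exempt, extra, real,
                 has_real):  # pragma: no cover - compiled
    """Rosenbluth trial set for regrowing one bonded monomer.

    Trial bond vectors: uniform direction x uniform length in the hard
    window.  Weight = Boltzmann factor of the altered bending angle
    (1 if no inner bond), zeroed for hard-sphere-infeasible trials.
    When ``has_real``, slot 0 holds the current (retrace) position,
    feasible by construction.  Returns (weights, bonds).
    """
    T = randu.shape[0]
    bonds = np.empty((T, 3))
    start = 0
    if has_real:
        for k in range(3):
            bonds[0, k] = real[k] - anchor[k]
        start = 1
    for t in range(start, T):
        bx, by, bz = randn[t, 0], randn[t, 1], randn[t, 2]
        nrm = math.sqrt(bx * bx + by * by + bz * bz)
        ln = (sigma + randu[t] * dl) / nrm
        bonds[t, 0] = bx * ln
        bonds[t, 1] = by * ln
        bonds[t, 2] = bz * ln
    pnorm = 0.0
    if has_prev:
        pnorm = math.sqrt(prev[0] ** 2 + prev[1] ** 2 + prev[2] ** 2)
    w = np.zeros(T)
    for t in range(T):
        px = anchor[0] + bonds[t, 0]
        py = anchor[1] + bonds[t, 1]
        pz = anchor[2] + bonds[t, 2]
        px -= L * math.floor(px / L)
        py -= L * math.floor(py / L)
        pz -= L * math.floor(pz / L)
        if (has_real and t == 0) or _point_ok(px, py, pz, positions, head,
                                              nxt, n, L, sig2, exempt, extra):
            if has_prev:
                bl = math.sqrt(bonds[t, 0] ** 2 + bonds[t, 1] ** 2
                               + bonds[t, 2] ** 2)
                ca = (prev[0] * bonds[t, 0] + prev[1] * bonds[t, 1]
                      + prev[2] * bonds[t, 2]) / (pnorm * bl)
                ca = min(1.0, max(-1.0, ca))
                th = math.acos(ca)
                w[t] = math.exp(-k_theta * (th - theta0) ** 2)
            else:
                w[t] = 1.0
    return w, bonds


@njit(cache=True)
def _flip_kernel(p0, p2, center, e1, e2, rho, psis, cur, use_cur, pm, pp,
                 has_m, has_p, positions, head, nxt, n, L, sig2, k_theta,
                 theta0, exempt):  # pragma: no cover - compiled
    """Trial set for rotating an interior monomer about its neighbor axis.

    Candidate positions lie on the circle ``center + rho (cos psi e1 +
    sin psi e2)``; slot 0 holds the current position when ``use_cur``.
    Weight = Boltzmann factor of the bending angles at the two flanking
    monomers (where they exist), zeroed for infeasible trials.
    ``pm``/``pp`` are the i-2 / i+2 monomer positions; ``p0``/``p2`` the
    bonded neighbors i-1 / i+1.  Returns (weights, positions).
    """
    T = psis.shape[0]
    pos = np.empty((T, 3))
    start = 0
    if use_cur:
        for k in range(3):
            pos[0, k] = cur[k]
        start = 1
    for t in range(start, T):
        cp = math.cos(psis[t])
        sp = math.sin(psis[t])
        for k in range(3):
            pos[t, k] = center[k] + rho * (cp * e1[k] + sp * e2[k])
    extra = np.empty((0, 3))
    w = np.zeros(T)
    for t in range(T):
        px = pos[t, 0] - L * math.floor(pos[t, 0] / L)
        py = pos[t, 1] - L * math.floor(pos[t, 1] / L)
        pz = pos[t, 2] - L * math.floor(pos[t, 2] / L)
        if (use_cur and t == 0) or _point_ok(px, py, pz, positions, head,
                                             nxt, n, L, sig2, exempt, extra):
            U = 0.0
            if has_m:
                ax = p0[0] - pm[0]
                ay = p0[1] - pm[1]
                az = p0[2] - pm[2]
                bx = pos[t, 0] - p0[0]
                by = pos[t, 1] - p0[1]
                bz = pos[t, 2] - p0[2]
                ca = (ax * bx + ay * by + az * bz) / math.sqrt(
                    (ax * ax + ay * ay + az * az)
                    * (bx * bx + by * by + bz * bz))
                th = math.acos(min(1.0, max(-1.0, ca)))
                U += k_theta * (th - theta0) ** 2
            if has_p:
                ax = pp[0] - p2[0]
                ay = pp[1] - p2[1]
                az = pp[2] - p2[2]
                bx = p2[0] - pos[t, 0]
                by = p2[1] - pos[t, 1]
                bz = p2[2] - pos[t, 2]
                ca = (ax * bx + ay * by + az * bz) / math.sqrt(
                    (ax * ax + ay * ay + az * az)
                    * (bx * bx + by * by + bz * bz))
                th = math.acos(min(1.0, max(-1.0, ca)))
                U += k_theta * (th - theta0) ** 2
            w[t] = math.exp(-U)
    return w, pos


def build_cell_list(config: Configuration, cutoff: float) -> CellList:
    """Cell list over a configuration's wrapped positions."""
    return CellList(config.positions_wrapped(), config.box_edge, cutoff)


# ---------------------------------------------------------------------------
# CB acceptance rule
# ---------------------------------------------------------------------------

def cb_accept(W_new: float, W_old: float, delta_U_extra: float,
              rng: np.random.Generator) -> bool:
    """Accept with probability min(1, (W_new/W_old) * exp(-delta_U_extra)).

    ``delta_U_extra`` covers energy terms not already folded into the
    Rosenbluth weights (for bridging moves it carries the bending
    difference and the log of the eligible-count ratio).
    """
    if W_new < 0:
        raise ValueError("W_new must be non-negative")
    if W_old <= 0:
        raise ValueError("W_old must be positive")
    if W_new == 0.0:
        return False
    ratio = (W_new / W_old) * math.exp(-delta_U_extra)
    return bool(ratio >= 1.0 or rng.random() < ratio)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.acos(max(-1.0, min(1.0, c)))


class MCEngine:
    """Mutable simulation state + move kernels.

    Coordinates are kept unwrapped per chain (``self.chains``); a
    wrapped copy lives inside the cell list for overlap queries.
    ``members[c]`` maps chain rows to stable flat particle ids.
    """

    def __init__(self, config: Configuration, params: SystemParams,
                 schedule: MoveSchedule | None = None,
                 cb: CBSettings | None = None, seed: int = 0):
        report = validate_configuration(config, params)
        if report:
            raise ValueError(f"invalid starting configuration: {report[:5]}")
        self.params = params
        self.schedule = schedule or MoveSchedule()
        self.cb = cb or CBSettings()
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.L = config.box_edge
        self.chains = [c.copy() for c in config.chains]
        self.members: list[list[int]] = []
        nxt = 0
        for c in self.chains:
            self.members.append(list(range(nxt, nxt + len(c))))
            nxt += len(c)
        self.n_at = nxt
        self._rebuild_cells()
        self._cum_probs = np.cumsum(self.schedule.probabilities())
        self.attempts = dict.fromkeys(MOVE_TYPES, 0)
        self.accepts = dict.fromkeys(MOVE_TYPES, 0)
        self.step_count = 0

    # -- infrastructure -----------------------------------------------------

    def _rebuild_cells(self) -> None:
        pos = np.empty((self.n_at, 3))
        for c, coords in enumerate(self.chains):
            pos[self.members[c]] = coords
        cutoff = 2.0 * (self.params.sigma + self.params.dl) * 1.001
        self.cells = CellList(np.mod(pos, self.L), self.L, cutoff)

    @property
    def phi(self) -> float:
        return math.pi / 6.0 * self.n_at * self.params.sigma**3 / self.L**3

    def config(self) -> Configuration:
        return Configuration(self.L, [c.copy() for c in self.chains])

    def _feasible(self, trials: np.ndarray, anchor: np.ndarray,
                  exempt: set[int], extra: np.ndarray | None = None) -> np.ndarray:
        """Per-trial hard-sphere feasibility near ``anchor``.

        ``exempt`` ids are skipped (the moving particle and its bonded
        partners); ``extra`` unwrapped points (already regrown monomers)
        are always checked.
        """
        p = self.params
        sig2 = (p.sigma * p.sigma) * (1 - 1e-12)
        cl = self.cells
        tw = np.mod(trials, self.L)
        ex = np.array(sorted(exempt), dtype=np.int64) if exempt else \
            np.empty(0, dtype=np.int64)
        xt = np.mod(np.asarray(extra, float), self.L) if extra is not None \
            and len(extra) else np.empty((0, 3))
        return _trial_feasible(tw, cl.positions, cl.head, cl.next,
                               cl.n_cells, cl.L, sig2, ex, xt)

    def _bend(self, theta: float) -> float:
        p = self.params
        return p.k_theta * (theta - p.theta0) ** 2

    # -- CB regrowth of a single end monomer --------------------------------

    def _grow_weights(self, anchor: np.ndarray, prev: np.ndarray | None,
                      exempt: set[int], extra: np.ndarray | None,
                      real: np.ndarray | None, n_trials: int):
        """Rosenbluth weight of regrowing one monomer bonded to ``anchor``.

        ``prev`` is the inner bond vector forming the altered bending
        angle (None for a 1-monomer anchor chain).  With ``real`` given,
        the real position joins the trial set (retrace) and only the
        weight is returned; otherwise a new position is selected and
        returned alongside the weight.
        """
        p = self.params
        cl = self.cells
        T = n_trials
        randn = self.rng.standard_normal((T, 3))
        randu = self.rng.random(T)
        ex = np.array(sorted(exempt), dtype=np.int64) if exempt else \
            np.empty(0, dtype=np.int64)
        xt = np.mod(np.asarray(extra, float), self.L) \
            if extra is not None and len(extra) else np.empty((0, 3))
        has_prev = prev is not None
        has_real = real is not None
        w, bonds = _grow_kernel(
            np.asarray(anchor, float),
            np.asarray(prev, float) if has_prev else np.zeros(3), has_prev,
            randn, randu, cl.positions, cl.head, cl.next, cl.n_cells, cl.L,
            p.sigma * p.sigma * (1 - 1e-12), p.sigma, p.dl, p.k_theta,
            p.theta0, ex, xt,
            np.asarray(real, float) if has_real else np.zeros(3), has_real)
        W = float(w.sum())
        if has_real:
            return W, None
        if W <= 0.0:
            return 0.0, None
        pick = int(np.searchsorted(np.cumsum(w), self.rng.random() * W))
        return W, anchor + bonds[min(pick, T - 1)]

    # -- local moves ---------------------------------------------------------

    def _move_reptation(self, intermolecular: bool) -> bool:
        rng = self.rng
        nch = len(self.chains)
        a = int(rng.integers(nch))
        del_head = bool(rng.integers(2))
        if intermolecular:
            if nch < 2:
                return False
            b = int(rng.integers(nch - 1))
            b = b + 1 if b >= a else b
            grow_head = bool(rng.integers(2))
            lo, hi = self.params.length_bounds
            if len(self.chains[a]) - 1 < lo or len(self.chains[b]) + 1 > hi:
                return False
        else:
            b = a
            grow_head = not del_head
        ca, cb_ = self.chains[a], self.chains[b]
        if len(ca) < 3 or len(cb_) < 2:
            return False
        moved_id = self.members[a][0 if del_head else -1]
        old_pos = ca[0 if del_head else -1].copy()

        # forward: grow at chain b's end
        if grow_head:
            anchor_new, inner_new = cb_[0], cb_[1]
        else:
            anchor_new, inner_new = cb_[-1], cb_[-2]
        prev_new = anchor_new - inner_new          # inner bond pointing outward
        T = self.cb.n_trials(self.phi)
        exempt = {moved_id,
                  self.members[b][0 if grow_head else -1]}
        W_new, new_pos = self._grow_weights(anchor_new, prev_new, exempt,
                                            None, None, T)
        if new_pos is None:
            return False

        # retrace: regrow the removed monomer at chain a's old end,
        # with the new monomer present
        if del_head:
            anchor_old, inner_old = ca[1], ca[2]
        else:
            anchor_old, inner_old = ca[-2], ca[-3]
        prev_old = anchor_old - inner_old
        exempt_old = {moved_id,
                      self.members[a][1 if del_head else -2]}
        W_old, _ = self._grow_weights(anchor_old, prev_old, exempt_old,
                                      new_pos[None, :], old_pos, T)
        if not cb_accept(W_new, W_old, 0.0, rng):
            return False

        # commit
        ma = self.members[a]
        if del_head:
            ma.pop(0)
            self.chains[a] = ca[1:].copy()
        else:
            ma.pop()
            self.chains[a] = ca[:-1].copy()
        mb = self.members[b]
        cb_new = self.chains[b]
        if grow_head:
            mb.insert(0, moved_id)
            self.chains[b] = np.vstack([new_pos, cb_new])
        else:
            mb.append(moved_id)
            self.chains[b] = np.vstack([cb_new, new_pos])
        self.cells.move(moved_id, new_pos)
        return True

    def _move_rotation(self) -> bool:
        """CB resample of a terminal monomer about its bonded neighbor."""
        rng = self.rng
        a = int(rng.integers(len(self.chains)))
        ca = self.chains[a]
        n = len(ca)
        if n < 2:
            return False
        head = bool(rng.integers(2))
        i = 0 if head else n - 1
        nb = 1 if head else n - 2
        moved_id = self.members[a][i]
        anchor = ca[nb]
        prev = None
        if n >= 3:
            inner = ca[2] if head else ca[-3]
            prev = anchor - inner
        T = self.cb.n_trials(self.phi)
        exempt = {moved_id, self.members[a][nb]}
        W_new, new_pos = self._grow_weights(anchor, prev, exempt, None, None, T)
        if new_pos is None:
            return False
        # retrace: the monomer itself is absent from the reverse state
        W_old, _ = self._grow_weights(anchor, prev, exempt, None,
                                      ca[i].copy(), T)
        if not cb_accept(W_new, W_old, 0.0, rng):
            return False
        self.chains[a][i] = new_pos
        self.cells.move(moved_id, new_pos)
        return True

    def _move_flip(self) -> bool:
        """Rotate an interior monomer about the axis of its two neighbors.

        The rotation preserves both adjacent bond lengths and the
        bending angle at the monomer itself; only the angles at the two
        flanking monomers change, and they weight the CB trial set.
        """
        rng = self.rng
        a = int(rng.integers(len(self.chains)))
        ca = self.chains[a]
        n = len(ca)
        if n < 3:
            return False
        i = int(rng.integers(1, n - 1))
        moved_id = self.members[a][i]
        T = self.cb.n_trials(self.phi)
        p0, p1, p2 = ca[i - 1], ca[i], ca[i + 1]
        axis = p2 - p0
        nrm = math.sqrt(axis @ axis)
        if nrm < 1e-12:
            return False
        ah = axis / nrm
        rel = p1 - p0
        center = p0 + (rel @ ah) * ah
        radial = p1 - center
        rho = math.sqrt(radial @ radial)
        if rho < 1e-14:
            return False               # collinear: the rotation is a no-op
        e1 = radial / rho
        e2 = np.array([ah[1] * e1[2] - ah[2] * e1[1],
                       ah[2] * e1[0] - ah[0] * e1[2],
                       ah[0] * e1[1] - ah[1] * e1[0]])
        has_m = i - 2 >= 0
        has_p = i + 2 <= n - 1
        pm = ca[i - 2] if has_m else np.zeros(3)
        pp = ca[i + 2] if has_p else np.zeros(3)
        ex = np.array(sorted({moved_id, self.members[a][i - 1],
                              self.members[a][i + 1]}), dtype=np.int64)
        p = self.params
        cl = self.cells
        sig2 = p.sigma * p.sigma * (1 - 1e-12)
        w_new, pos_new = _flip_kernel(
            p0, p2, center, e1, e2, rho, rng.uniform(0, 2 * math.pi, T),
            np.zeros(3), False, pm, pp, has_m, has_p, cl.positions, cl.head,
            cl.next, cl.n_cells, cl.L, sig2, p.k_theta, p.theta0, ex)
        W_new = float(w_new.sum())
        if W_new <= 0.0:
            return False
        pick = int(np.searchsorted(np.cumsum(w_new), rng.random() * W_new))
        new_pos = pos_new[min(pick, T - 1)]
        w_old, _ = _flip_kernel(
            p0, p2, center, e1, e2, rho, rng.uniform(0, 2 * math.pi, T),
            p1, True, pm, pp, has_m, has_p, cl.positions, cl.head,
            cl.next, cl.n_cells, cl.L, sig2, p.k_theta, p.theta0, ex)
        W_old = float(w_old.sum())
        if not cb_accept(W_new, W_old, 0.0, rng):
            return False
        self.chains[a][i] = new_pos
        self.cells.move(moved_id, new_pos)
        return True

    def _move_end_regrowth(self) -> bool:
        """Delete 1..max_regrow end monomers and regrow them trial-by-trial."""
        rng = self.rng
        a = int(rng.integers(len(self.chains)))
        ca = self.chains[a]
        n = len(ca)
        max_k = min(self.cb.max_regrow, n - 2)
        if max_k < 1:
            return False
        k = int(rng.integers(1, max_k + 1))
        head = bool(rng.integers(2))
        view = ca[::-1].copy() if head else ca.copy()
        ids = self.members[a][::-1] if head else list(self.members[a])
        moving = set(ids[n - k:])
        T = self.cb.n_trials(self.phi)

        retained = view[:n - k]
        old_segment = view[n - k:]
        W_new_total, W_old_total = 1.0, 1.0
        grown: list[np.ndarray] = []
        # forward growth
        for j in range(k):
            anchor = grown[-1] if grown else retained[-1]
            below = (grown[-2] if len(grown) >= 2
                     else retained[-1] if len(grown) == 1 else retained[-2])
            prev = anchor - below
            extra = np.array(grown) if grown else None
            W, pos = self._grow_weights(anchor, prev, moving, extra, None, T)
            if pos is None:
                return False
            W_new_total *= W
            grown.append(pos)
        # retrace of the old segment, with the new one present
        placed_old: list[np.ndarray] = []
        for j in range(k):
            anchor = placed_old[-1] if placed_old else retained[-1]
            below = (placed_old[-2] if len(placed_old) >= 2
                     else retained[-1] if len(placed_old) == 1 else retained[-2])
            prev = anchor - below
            extra = np.array(placed_old + grown)
            W, _ = self._grow_weights(anchor, prev, moving, extra,
                                      old_segment[j].copy(), T)
            W_old_total *= W
            placed_old.append(old_segment[j])
        if not cb_accept(W_new_total, W_old_total, 0.0, rng):
            return False
        new_view = np.vstack([retained, np.array(grown)])
        self.chains[a] = new_view[::-1].copy() if head else new_view
        for mid, pos in zip(ids[n - k:], grown):
            self.cells.move(mid, pos)
        return True

    # -- bridging moves -------------------------------------------------------

    def _window_targets(self, point: np.ndarray, exclude: set[int]) -> np.ndarray:
        """Flat ids whose minimum-image distance to ``point`` is in the bond window."""
        p = self.params
        cand = self.cells.query_point(np.mod(point, self.L))
        if len(cand) == 0:
            return cand
        d = np.linalg.norm(minimum_image(
            self.cells.positions[cand] - np.mod(point, self.L), self.L), axis=1)
        lo = p.sigma * (1 - 1e-12)
        hi = (p.sigma + p.dl) * (1 + 1e-12)
        hits = cand[(d >= lo) & (d <= hi)]
        return hits[~np.isin(hits, list(exclude))] if exclude else hits

    def _locate(self, flat_id: int) -> tuple[int, int]:
        for c, ids in enumerate(self.members):
            try:
                return c, ids.index(flat_id)
            except ValueError:
                continue
        raise KeyError(flat_id)

    def _seb_candidates(self, a: int, head: bool):
        """Eligible (chain b, index j, cut_side) targets for an sEB attack."""
        ca = self.chains[a]
        end_pos = ca[0] if head else ca[-1]
        lo, hi = self.params.length_bounds
        na = len(ca)
        exclude = set(self.members[a])
        out = []
        for fid in self._window_targets(end_pos, exclude):
            b, j = self._locate(int(fid))
            nb = len(self.chains[b])
            if not (1 <= j <= nb - 2):
                continue
            # cut bond (j, j+1): gain segment j..0, remainder j+1..nb-1
            if lo <= na + j + 1 <= hi and lo <= nb - 1 - j <= hi:
                out.append((b, j, +1))
            # cut bond (j-1, j): gain segment j..nb-1, remainder 0..j-1
            if lo <= na + nb - j <= hi and lo <= j <= hi:
                out.append((b, j, -1))
        return out

    def _chain_angles_energy(self, coords: np.ndarray) -> float:
        if len(coords) < 3:
            return 0.0
        b = np.diff(coords, axis=0)
        n1 = np.linalg.norm(b[:-1], axis=1)
        n2 = np.linalg.norm(b[1:], axis=1)
        cosang = np.einsum("ij,ij->i", b[:-1], b[1:]) / (n1 * n2)
        th = np.arccos(np.clip(cosang, -1, 1))
        p = self.params
        return float(np.sum(p.k_theta * (th - p.theta0) ** 2))

    def _unwrap_join(self, base_end: np.ndarray, coords: np.ndarray) -> np.ndarray:
        """Shift a chain segment by whole boxes so it bonds to base_end."""
        gap = minimum_image(coords[0] - base_end, self.L)
        return coords - (coords[0] - base_end) + gap

    def _move_seb(self) -> bool:
        rng = self.rng
        nch = len(self.chains)
        if nch < 2:
            return False
        a = int(rng.integers(nch))
        head = bool(rng.integers(2))
        cands = self._seb_candidates(a, head)
        n_fwd = len(cands)
        if n_fwd == 0:
            return False
        b, j, side = cands[int(rng.integers(n_fwd))]
        ca = self.chains[a] if not head else self.chains[a][::-1]
        ids_a = list(self.members[a]) if not head else self.members[a][::-1]
        cb_ = self.chains[b]
        ids_b = list(self.members[b])

        if side == +1:
            seg = cb_[j::-1]
            seg_ids = ids_b[j::-1]
            rem = cb_[j + 1:]
            rem_ids = ids_b[j + 1:]
        else:
            seg = cb_[j:]
            seg_ids = ids_b[j:]
            rem = cb_[:j]
            rem_ids = ids_b[:j]
        seg = self._unwrap_join(ca[-1], seg)
        new_a = np.vstack([ca, seg])
        dU = (self._chain_angles_energy(new_a) + self._chain_angles_energy(rem)
              - self._chain_angles_energy(ca) - self._chain_angles_energy(cb_))
        # count reverse targets in the trial state: the severed remainder's
        # end (old j+1 for side=+1, old j-1 for side=-1) re-attacks the
        # bridged monomer, so the reverse proposal is always eligible
        saved = (self.chains[a], self.members[a], self.chains[b], self.members[b])
        self.chains[a] = new_a
        self.members[a] = ids_a + seg_ids
        self.chains[b] = rem.copy()
        self.members[b] = rem_ids
        n_rev = len(self._seb_candidates(b, head=(side == +1)))
        ok = n_rev > 0 and cb_accept(float(n_fwd), float(n_rev), dU, rng)
        if not ok:
            self.chains[a], self.members[a], self.chains[b], self.members[b] = saved
            return False
        return True

    def _move_sieb(self) -> bool:
        rng = self.rng
        a = int(rng.integers(len(self.chains)))
        head = bool(rng.integers(2))
        ca = self.chains[a] if not head else self.chains[a][::-1]
        ids = list(self.members[a]) if not head else self.members[a][::-1]
        n = len(ca)
        if n < 4:
            return False
        end_pos = ca[-1]
        targets = []
        for fid in self._window_targets(end_pos, set()):
            if fid not in ids:
                continue
            j = ids.index(int(fid))
            if j <= n - 3:          # j = n-2 is the existing bond: no-op
                targets.append(j)
        n_fwd = len(targets)
        if n_fwd == 0:
            return False
        j = targets[int(rng.integers(n_fwd))]
        # new contour: 0..j then n-1 down to j+1 (end re-bridged, segment reversed)
        new_ca = np.vstack([ca[:j + 1],
                            self._unwrap_join(ca[j], ca[j + 1:][::-1])])
        new_ids = ids[:j + 1] + ids[j + 1:][::-1]
        dU = self._chain_angles_energy(new_ca) - self._chain_angles_energy(ca)
        saved = (self.chains[a], self.members[a])
        self.chains[a] = new_ca if not head else new_ca[::-1].copy()
        self.members[a] = new_ids if not head else new_ids[::-1]
        # reverse: the new end (old j+1) re-attacks monomer j
        rev_ca = self.chains[a] if not head else self.chains[a][::-1]
        rev_ids = list(self.members[a]) if not head else self.members[a][::-1]
        rev_end = rev_ca[-1]
        n_rev = 0
        for fid in self._window_targets(rev_end, set()):
            if fid in rev_ids:
                jj = rev_ids.index(int(fid))
                if jj <= n - 3:
                    n_rev += 1
        ok = n_rev > 0 and cb_accept(float(n_fwd), float(n_rev), dU, rng)
        if not ok:
            self.chains[a], self.members[a] = saved
            return False
        return True

    # -- driver ---------------------------------------------------------------

    def step(self) -> bool:
        """Attempt one move drawn from the schedule; True if accepted."""
        k = int(np.searchsorted(self._cum_probs, self.rng.random()))
        kind = MOVE_TYPES[min(k, len(MOVE_TYPES) - 1)]
        self.attempts[kind] += 1
        self.step_count += 1
        if kind == "reptation":
            ok = self._move_reptation(intermolecular=False)
        elif kind == "rotation":
            ok = self._move_rotation()
        elif kind == "flip":
            ok = self._move_flip()
        elif kind == "intermolecular_reptation":
            ok = self._move_reptation(intermolecular=True)
        elif kind == "end_segment_regrowth":
            ok = self._move_end_regrowth()
        elif kind == "sEB":
            ok = self._move_seb()
        else:
            ok = self._move_sieb()
        if ok:
            self.accepts[kind] += 1
        return ok

    def run(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self.step()

    def attempt_rescale(self, new_L: float) -> bool:
        """Isotropic box rescale moving chain centers of mass affinely.

        Internal chain geometry is kept rigid (bond lengths and angles
        untouched); the attempt is rejected if any non-bonded pair
        overlaps at the new volume.
        """
        scale = new_L / self.L
        new_chains = []
        for coords in self.chains:
            com = coords.mean(axis=0)
            new_chains.append(coords - com + com * scale)
        trial = Configuration(new_L, new_chains)
        from .chain_model import _overlap_pairs
        if _overlap_pairs(trial, self.params.sigma):
            return False
        self.L = new_L
        self.chains = new_chains
        self._rebuild_cells()
        return True

    def acceptance_ratios(self) -> dict[str, float]:
        return {t: (self.accepts[t] / self.attempts[t] if self.attempts[t] else
                    math.nan) for t in MOVE_TYPES}


# ---------------------------------------------------------------------------
# high-level operations
# ---------------------------------------------------------------------------

def run_mc(config: Configuration, params: SystemParams,
           schedule: MoveSchedule | None = None, cb: CBSettings | None = None,
           n_steps: int = 10**5, seed: int = 0,
           snapshot_interval: int = 10**4) -> Trajectory:
    """Run a constant-volume MC simulation, recording periodic snapshots.

    One step is one attempted move.  Snapshots are recorded every
    ``snapshot_interval`` attempts (and at the final step); each
    snapshot satisfies every hard constraint by construction.
    """
    engine = MCEngine(config, params, schedule, cb, seed)
    traj = Trajectory(metadata={
        "params": params, "seed": seed,
        "schedule": schedule or MoveSchedule(),
        "n_steps": n_steps, "snapshot_interval": snapshot_interval,
    })
    for step in range(1, n_steps + 1):
        engine.step()
        if step % snapshot_interval == 0 or step == n_steps:
            traj.append(step, engine.config())
    traj.metadata["acceptance_ratios"] = engine.acceptance_ratios()
    return traj


def generate_dilute(params: SystemParams, phi_init: float = 0.001,
                    seed: int = 0, max_retries: int = 200) -> Configuration:
    """Build a dilute random-walk configuration of non-overlapping chains.

    Chain lengths are drawn uniformly from ``length_bounds`` (their mean
    is ``n_av`` for the default symmetric bounds); bonds are sampled in
    the hard window; every monomer placement is overlap-checked.
    """
    if phi_init > 0.05:
        raise ValueError("phi_init must be dilute (<= 0.05)")
    rng = np.random.default_rng(seed)
    lo, hi = params.length_bounds
    lengths = rng.integers(lo, hi + 1, params.n_chains)
    n_at = int(lengths.sum())
    L = box_edge_for_phi(n_at, params.sigma, phi_init)
    placed: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    sigma = params.sigma
    for n in lengths:
        for attempt in range(max_retries):
            coords = _random_walk(n, L, params, rng, all_pos)
            if coords is not None:
                placed.append(coords)
                all_pos.extend(np.mod(coords, L))
                break
        else:
            raise RuntimeError("chain placement failed; phi_init too high?")
    return Configuration(L, placed)


def _random_walk(n: int, L: float, params: SystemParams,
                 rng: np.random.Generator, existing: list[np.ndarray],
                 max_step_tries: int = 60):
    sigma = params.sigma
    occ = np.array(existing) if existing else np.empty((0, 3))
    coords = [rng.uniform(0, L, 3)]
    def clashes(p):
        pw = np.mod(p, L)
        if len(occ) and np.any(np.linalg.norm(
                minimum_image(occ - pw, L), axis=1) < sigma):
            return True
        own = np.array(coords[:-1]) if len(coords) > 1 else None
        if own is not None and len(own):
            d = np.linalg.norm(minimum_image(np.mod(own, L) - pw, L), axis=1)
            if np.any(d < sigma):
                return True
        return False
    if clashes(coords[0]):
        return None
    for _ in range(n - 1):
        for _ in range(max_step_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            step = (sigma + rng.uniform(0, 1) * params.dl) * u
            p = coords[-1] + step
            if not clashes(p):
                coords.append(p)
                break
        else:
            return None
    return np.array(coords)


def compress(config: Configuration, params: SystemParams,
             target_phi: float, schedule: MoveSchedule | None = None,
             cb: CBSettings | None = None, seed: int = 0,
             shrink_factor: float = 0.999, relax_moves: int = 500,
             max_failures: int = 2000,
             engine: MCEngine | None = None) -> Configuration:
    """Shrink the box isotropically until the target packing fraction.

    Volume compressions move chain centers of mass affinely (internal
    chain geometry rigid) and are attempted at regular intervals of
    ``relax_moves`` MC relaxation moves; an attempt that creates any
    overlap is rejected and the box restored.  On repeated rejection the
    shrink decrement is halved, so the phi sequence is monotone
    non-decreasing and terminates at |phi - target| <= 1e-6.
    """
    eng = engine or MCEngine(config, params, schedule, cb, seed)
    if eng.phi > target_phi + 1e-9:
        raise ValueError("target_phi must exceed the current packing fraction")
    L_target = box_edge_for_phi(eng.n_at, params.sigma, target_phi)
    factor = shrink_factor
    failures = 0
    while abs(eng.phi - target_phi) > 1e-6:
        new_L = max(L_target, eng.L * factor)
        if eng.attempt_rescale(new_L):
            failures = 0
            factor = shrink_factor           # restore the full decrement
        else:
            failures += 1
            factor = math.sqrt(factor)       # gentler decrement near jamming
            if failures >= max_failures:
                raise RuntimeError(
                    f"compression stalled at phi={eng.phi:.4f} "
                    f"(target {target_phi})")
        eng.run(relax_moves)
    return eng.config()
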