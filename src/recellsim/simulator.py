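"""Agent-based stepping engine for scaffold recellularization.

The scaffold is seeded at t = 0 with ``n_cells`` (default 30,000) randomly
placed agents, each of which engrafts immediately with probability
``engraft_prob`` (default 0.95, i.e. a uniform draw on [0, 100] exceeding
``N_crit = 5``).  The model then runs for ``n_steps`` (default 80) time
steps.  Within each step every cell executes its rules once — move, attach,
death check, proliferation check — with agents visited in a freshly
randomized order, mirroring NetLogo-style sequential agent iteration:

* motile cells re-randomize their heading, weigh the substrate signal of the
  three patches ahead of them (straight / ahead-left / ahead-right) and move
  toward the strongest signal when ``S > 1``, otherwise to a random free
  neighbor; they then attempt to attach (uniform draw N on [0, 100] with
  engraftment when ``N > N_crit``);
* engrafted cells age (``N_life``), die when the counter reaches their drawn
  lifespan ``T_life`` (freeing the patch and withdrawing their substrate
  deposit), and otherwise advance their proliferation counter ``N_prol``,
  placing one offspring on a random free neighbor patch that itself has at
  most ``max_target_neighbors`` occupied neighbors once ``N_prol`` reaches
  ``T_prol``.  If no eligible neighbor exists the attempt is retried on
  subsequent steps.

Two engines produce statistically identical dynamics: ``engine="fast"``
vectorizes the order-independent counter updates and serializes only the
actions that touch shared state (deaths, proliferations, motile turns) in a
random order; ``engine="reference"`` is a plain per-agent loop kept as an
internal cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rulesets import RuleSet, draw_engraftment_params, hypothesis1, hypothesis2
from .scaffold import EMPTY, NEIGHBOR_OFFSETS, ScaffoldState

__all__ = [
    "SimConfig",
    "MotileCell",
    "EngraftedCell",
    "Trajectory",
    "Simulation",
    "seed",
    "movement_step",
    "attachment_step",
    "death_step",
    "proliferation_step",
    "run",
    "run_replicates",
    "extract_slice",
    "calibrate_time_scale",
]

_AXES = {"x": 0, "y": 1, "z": 2}

# unit vectors of the 26 lattice directions, used for heading quantization
_OFFSET_UNITS = NEIGHBOR_OFFSETS / np.linalg.norm(NEIGHBOR_OFFSETS, axis=1, keepdims=True)


@dataclass
class SimConfig:
    """Engine parameters (the behavioral parameters live on the RuleSet)."""

    grid_size: int = 32
    n_cells: int = 30_000
    engraft_prob: float | None = None  # None -> (100 - N_crit) / 100
    n_steps: int = 80
    record_every: int = 10
    seeding_mode: str = "instant_cull"  # or "one_step_grace"
    substrate_deposit_mode: str = "once"  # or "per_step"
    slice_axis: str = "z"
    n_slices: int = 30  # fixed interior slice indices, identical across runs
    record_cvhv: bool = True
    engine: str = "fast"  # or "reference"
    c_formula_scale: float = 20.0
    c_formula_divisor: float = 21.2

    def __post_init__(self) -> None:
        if self.seeding_mode not in ("instant_cull", "one_step_grace"):
            raise ValueError(f"unknown seeding_mode {self.seeding_mode!r}")
        if self.substrate_deposit_mode not in ("once", "per_step"):
            raise ValueError(
                f"unknown substrate_deposit_mode {self.substrate_deposit_mode!r}"
            )
        if self.slice_axis not in _AXES:
            raise ValueError(f"slice_axis must be one of {sorted(_AXES)}")
        if self.engine not in ("fast", "reference"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class MotileCell:
    """Read-only snapshot of a motile agent."""

    cell_id: int
    position: tuple[int, int, int]
    heading: tuple[float, float, float]


@dataclass
class EngraftedCell:
    """Read-only snapshot of an engrafted agent."""

    cell_id: int
    position: tuple[int, int, int]
    T_life: int
    T_prol: int
    N_life: int
    N_prol: int


@dataclass
class Trajectory:
    """Per-time-point, per-slice cell counts and CVHV for one run."""

    time_points: list[int]
    slice_indices: list[int]
    counts: np.ndarray  # shape (n_time_points, n_slices)
    cvhv: np.ndarray | None  # same shape, or None if not recorded
    normalized: bool = False

    def mean_counts(self) -> np.ndarray:
        """Mean engrafted-cell count per slice at each recorded time point."""
        return self.counts.mean(axis=1)

    def mean_cvhv(self) -> np.ndarray:
        if self.cvhv is None:
            raise ValueError("CVHV was not recorded for this trajectory")
        return self.cvhv.mean(axis=1)

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.time_points):
            for j, s in enumerate(self.slice_indices):
                rows.append(
                    {
                        "replicate": replicate,
                        "time_step": t,
                        "slice_index": s,
                        "n_cells": int(self.counts[i, j]),
                        "cvhv": float(self.cvhv[i, j]) if self.cvhv is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


class Simulation:
    """Mutable simulation state: scaffold, agents, and the step loop."""

    def __init__(
        self,
        rules: RuleSet,
        config: SimConfig | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.rules = rules
        self.config = config or SimConfig()
        self.rng = np.random.default_rng(rng)
        self.state = ScaffoldState(
            grid_size=self.config.grid_size,
            c_formula_scale=self.config.c_formula_scale,
            c_formula_divisor=self.config.c_formula_divisor,
            c_amount=rules.c_amount,
        )
        self.t = 0
        # structure-of-arrays agent storage
        cap = max(16, self.config.n_cells)
        self._cap = cap
        self.n_agents = 0
        self.pos = np.zeros((cap, 3), dtype=np.int64)
        self.T_life = np.zeros(cap, dtype=np.int64)
        self.T_prol = np.zeros(cap, dtype=np.int64)
        self.N_life = np.zeros(cap, dtype=np.int64)
        self.N_prol = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.engrafted = np.zeros(cap, dtype=bool)
        self.has_proliferated = np.zeros(cap, dtype=bool)
        self.heading = np.zeros((cap, 3), dtype=np.float64)
        # incrementally maintained count of occupied neighbors per patch
        g = self.config.grid_size
        self._occ_nbr = np.zeros((g, g, g), dtype=np.int32)
        # per-step bookkeeping (conservation accounting)
        self.last_step_stats: dict[str, int] = {}

    # -- storage ------------------------------------------------------------

    def _grow(self) -> None:
        new_cap = self._cap * 2
        for name in ("pos", "T_life", "T_prol", "N_life", "N_prol", "alive",
                     "engrafted", "has_proliferated", "heading"):
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            new[: self._cap] = arr
            setattr(self, name, new)
        self._cap = new_cap

    def _new_agent(self) -> int:
        if self.n_agents >= self._cap:
            self._grow()
        cid = self.n_agents
        self.n_agents += 1
        return cid

    # -- occupancy with neighbor-count maintenance --------------------------

    def _occupy(self, coords, cid: int) -> None:
        self.state.occupy(coords, cid)
        self._bump_neighbors(coords, +1)

    def _vacate(self, coords) -> None:
        self.state.vacate(coords)
        self._bump_neighbors(coords, -1)

    def _bump_neighbors(self, coords, delta: int) -> None:
        g = self.config.grid_size
        ix, iy, iz = self.state._index(coords)
        x0, x1 = max(0, ix - 1), min(g, ix + 2)
        y0, y1 = max(0, iy - 1), min(g, iy + 2)
        z0, z1 = max(0, iz - 1), min(g, iz + 2)
        self._occ_nbr[x0:x1, y0:y1, z0:z1] += delta
        self._occ_nbr[ix, iy, iz] -= delta  # a patch is not its own neighbor

    # -- seeding ------------------------------------------------------------

    def seed(self, n_cells: int | None = None, engraft_prob: float | None = None) -> None:
        """Place ``n_cells`` agents on distinct random patches at t = 0.

        Each agent engrafts immediately with probability ``engraft_prob``
        (drawing initial-mode T_life / T_prol and depositing substrate).
        Non-engrafters are eliminated at once (``instant_cull``) or seeded as
        motile cells that get one full step to attach before elimination
        (``one_step_grace``).
        """
        cfg = self.config
        n = cfg.n_cells if n_cells is None else int(n_cells)
        if n > self.state.n_patches:
            raise ValueError(
                f"cannot place {n} cells on {self.state.n_patches} patches"
            )
        p = engraft_prob if engraft_prob is not None else cfg.engraft_prob
        if p is None:
            p = (100.0 - self.rules.N_crit) / 100.0
        if not 0.0 <= p <= 1.0:
            raise ValueError("engraft_prob must lie in [0, 1]")
        if n == 0:
            return
        g = cfg.grid_size
        flat = self.rng.choice(self.state.n_patches, size=n, replace=False)
        coords = np.stack(np.unravel_index(flat, (g, g, g)), axis=1) + self.state.lo
        engraft = self.rng.uniform(0.0, 100.0, size=n) > (100.0 * (1.0 - p))
        n_eng = int(engraft.sum())

        # engrafters: vectorized initial-mode draws
        eng_coords = coords[engraft]
        ids = np.arange(self.n_agents, self.n_agents + n_eng)
        while self.n_agents + n_eng > self._cap:
            self._grow()
        self.n_agents += n_eng
        self.pos[ids] = eng_coords
        r = self.rules
        self.T_life[ids] = self.rng.integers(
            int(math.ceil(r.initial_T_life.lo)), int(math.floor(r.initial_T_life.hi)) + 1,
            size=n_eng)
        self.T_prol[ids] = self.rng.integers(
            int(math.ceil(r.initial_T_prol.lo)), int(math.floor(r.initial_T_prol.hi)) + 1,
            size=n_eng)
        self.N_life[ids] = 0
        self.N_prol[ids] = 0
        self.alive[ids] = True
        self.engrafted[ids] = True
        idx = tuple((eng_coords - self.state.lo).T)
        self.state.occupancy[idx] = ids
        if cfg.substrate_deposit_mode == "once":
            self.state.substrate[idx] += r.c_amount
        # neighbor counts, rebuilt in one pass (cheaper than 28k slice adds)
        self._rebuild_occ_nbr()

        if cfg.seeding_mode == "one_step_grace":
            for c in coords[~engraft]:
                cid = self._new_agent()
                self.pos[cid] = c
                self.alive[cid] = True
                self.engrafted[cid] = False
                self.heading[cid] = self._random_unit()
                self._occupy(tuple(c), cid)
        # instant_cull: non-engrafters are eliminated immediately and never
        # enter the agent list

    def _rebuild_occ_nbr(self) -> None:
        occ = (self.state.occupancy != EMPTY).astype(np.int32)
        g = self.config.grid_size
        pad = np.zeros((g + 2, g + 2, g + 2), dtype=np.int32)
        pad[1:-1, 1:-1, 1:-1] = occ
        total = np.zeros_like(occ)
        for dx in (0, 1, 2):
            for dy in (0, 1, 2):
                for dz in (0, 1, 2):
                    total += pad[dx : dx + g, dy : dy + g, dz : dz + g]
        self._occ_nbr = total - occ

    # -- randomness helpers --------------------------------------------------

    def _random_unit(self) -> np.ndarray:
        v = self.rng.normal(size=3)
        n = np.linalg.norm(v)
        while n < 1e-12:
            v = self.rng.normal(size=3)
            n = np.linalg.norm(v)
        return v / n

    # -- per-cell rule implementations --------------------------------------

    def ahead_directions(self, heading: np.ndarray) -> list[np.ndarray]:
        """Quantize a forward vector to lattice directions: straight ahead and
        the two ±45°-rotated "ahead-left"/"ahead-right" companions."""
        ahead_idx = int(np.argmax(_OFFSET_UNITS @ heading))
        ahead_u = _OFFSET_UNITS[ahead_idx]
        up = np.array([0.0, 0.0, 1.0])
        if abs(float(ahead_u @ up)) > 0.9:
            up = np.array([1.0, 0.0, 0.0])
        # rotation axis: the part of `up` orthogonal to the heading
        w = up - (up @ ahead_u) * ahead_u
        w /= np.linalg.norm(w)
        dirs = [NEIGHBOR_OFFSETS[ahead_idx]]
        for angle in (math.pi / 4, -math.pi / 4):
            rot = _rodrigues(ahead_u, w, angle)
            dirs.append(NEIGHBOR_OFFSETS[int(np.argmax(_OFFSET_UNITS @ rot))])
        return dirs

    def _motile_move(self, cid: int) -> None:
        """Rule 1: re-randomize heading, then chemotactic or random move."""
        self.heading[cid] = self._random_unit()
        pos = self.pos[cid]
        dirs = self.ahead_directions(self.heading[cid])
        ahead = [tuple(pos + d) for d in dirs]
        conc = np.array(
            [self.state.concentration_at(a) if self.state.in_bounds(a) else 0.0
             for a in ahead]
        )
        x = self.rng.uniform(0.0, 1.0, size=3)
        S = float(x @ conc)
        target = None
        if S > 1.0:
            best_c = -1.0
            for a, c in zip(ahead, conc):
                if self.state.in_bounds(a) and not self.state.is_occupied(a) and c > best_c:
                    best_c, target = c, a
        else:
            free = [n for n in self.state.neighbors(tuple(pos))
                    if not self.state.is_occupied(n)]
            if free:
                target = free[int(self.rng.integers(len(free)))]
        if target is not None:
            self._vacate(tuple(pos))
            self._occupy(target, cid)
            self.pos[cid] = target
        # if every candidate is occupied or out of bounds the cell stays put

    def _attach(self, cid: int) -> bool:
        """Rule 2: uniform draw N on [0, 100]; engraft when N > N_crit."""
        N = self.rng.uniform(0.0, 100.0)
        if N > self.rules.N_crit:
            self._engraft(cid, is_offspring=False)
            return True
        return False

    def _engraft(self, cid: int, is_offspring: bool) -> None:
        coords = tuple(self.pos[cid])
        c_patch = self.state.concentration_at(coords)
        t_life, t_prol = draw_engraftment_params(
            self.rules, c_patch, is_offspring, self.rng
        )
        self.T_life[cid] = t_life
        self.T_prol[cid] = t_prol
        self.N_life[cid] = 0
        self.N_prol[cid] = 0
        self.engrafted[cid] = True
        if self.config.substrate_deposit_mode == "once":
            self.state.deposit_substrate(coords, self.rules.c_amount)

    def _die(self, cid: int) -> None:
        """Rule 3 consequence: remove the cell, free its patch, decay substrate."""
        coords = tuple(self.pos[cid])
        self._vacate(coords)
        self.alive[cid] = False
        if self.engrafted[cid]:
            self.state.decay_substrate(coords, self.rules.c_amount)

    def _eligible_targets(self, cid: int) -> list[tuple[int, int, int]]:
        """Unoccupied neighbor patches with at most ``max_target_neighbors``
        occupied neighbors of their own."""
        out = []
        x, y, z = (int(v) for v in self.pos[cid])
        lo, hi = self.state.lo, self.state.hi
        occ = self.state.occupancy
        for dx, dy, dz in NEIGHBOR_OFFSETS:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (lo <= nx <= hi and lo <= ny <= hi and lo <= nz <= hi):
                continue
            ix, iy, iz = nx - lo, ny - lo, nz - lo
            if occ[ix, iy, iz] != EMPTY:
                continue
            if self._occ_nbr[ix, iy, iz] <= self.rules.max_target_neighbors:
                out.append((nx, ny, nz))
        return out

    def _try_proliferate(self, cid: int) -> int | None:
        """Rule 4 consequence: place one offspring on an eligible neighbor.

        Returns the offspring id, or None when no eligible target exists (the
        attempt is then retried on later steps, the counter held at T_prol).
        """
        targets = self._eligible_targets(cid)
        if not targets:
            return None
        target = targets[int(self.rng.integers(len(targets)))]
        new_id = self._new_agent()
        self.pos[new_id] = target
        self.alive[new_id] = True
        self.engrafted[new_id] = False  # set by _engraft
        self._occupy(target, new_id)
        self._engraft(new_id, is_offspring=True)
        # one proliferation opportunity per cell: the equality-style trigger
        # fires once per lifetime (deferred attempts keep retrying until one
        # succeeds, after which the cell is done dividing)
        self.has_proliferated[cid] = True
        return new_id

    def _motile_turn(self, cid: int) -> None:
        """One full step for a motile cell: move, then attempt attachment;
        a cell that engrafts mid-step immediately runs its engrafted rules."""
        self._motile_move(cid)
        if self._attach(cid):
            # same-turn death / proliferation checks (rules 3-4)
            self.N_life[cid] += 1
            if self.N_life[cid] >= self.T_life[cid]:
                self._die(cid)
                return
            self.N_prol[cid] = min(int(self.N_prol[cid]) + 1, int(self.T_prol[cid]))
            if self.N_prol[cid] >= self.T_prol[cid] and not self.has_proliferated[cid]:
                self._try_proliferate(cid)

    # -- stepping -----------------------------------------------------------

    def step(self) -> None:
        self.t += 1
        n_before = int((self.alive & self.engrafted).sum())
        if self.config.engine == "fast":
            births, attachments, deaths = self._step_fast()
        else:
            births, attachments, deaths = self._step_reference()
        if self.config.seeding_mode == "one_step_grace" and self.t == 1:
            self._cull_motile()
        n_after = int((self.alive & self.engrafted).sum())
        self.last_step_stats = {
            "t": self.t,
            "engrafted_before": n_before,
            "engrafted_after": n_after,
            "attachments": attachments,
            "births": births,
            "deaths": deaths,
        }

    def _per_step_deposit(self, eng_ids: np.ndarray) -> None:
        if self.config.substrate_deposit_mode == "per_step" and eng_ids.size:
            idx = tuple((self.pos[eng_ids] - self.state.lo).T)
            np.add.at(self.state.substrate, idx, self.rules.c_amount)

    def _step_fast(self) -> tuple[int, int, int]:
        live = self.alive[: self.n_agents]
        eng = live & self.engrafted[: self.n_agents]
        eng_ids = np.nonzero(eng)[0]
        motile_ids = np.nonzero(live & ~self.engrafted[: self.n_agents])[0]
        self._per_step_deposit(eng_ids)

        # order-independent counter advances (rules 3-4 preamble)
        self.N_life[eng_ids] += 1
        dying_mask = self.N_life[eng_ids] >= self.T_life[eng_ids]
        # deferred attempts hold the counter at T_prol
        self.N_prol[eng_ids] = np.minimum(
            self.N_prol[eng_ids] + 1, self.T_prol[eng_ids]
        )
        prol_mask = (
            ~dying_mask
            & (self.N_prol[eng_ids] >= self.T_prol[eng_ids])
            & ~self.has_proliferated[eng_ids]
        )
        dying_ids = eng_ids[dying_mask]
        prol_ids = eng_ids[prol_mask]

        # serialize the actions that touch shared state, in random order
        events = np.concatenate(
            [
                np.stack([dying_ids, np.zeros_like(dying_ids)], axis=1),
                np.stack([prol_ids, np.ones_like(prol_ids)], axis=1),
                np.stack([motile_ids, np.full_like(motile_ids, 2)], axis=1),
            ]
        )
        births = attachments = 0
        deaths = dying_ids.size
        if events.shape[0]:
            events = events[self.rng.permutation(events.shape[0])]
            for cid, kind in events:
                if kind == 0:
                    self._die(int(cid))
                elif kind == 1:
                    if self._try_proliferate(int(cid)) is not None:
                        births += 1
                else:
                    was = self.engrafted[cid]
                    self._motile_turn(int(cid))
                    if self.engrafted[cid] and not was:
                        attachments += 1
                        if not self.alive[cid]:
                            deaths += 1
        return births, attachments, deaths

    def _step_reference(self) -> tuple[int, int, int]:
        live_ids = np.nonzero(self.alive[: self.n_agents])[0]
        eng_ids = live_ids[self.engrafted[live_ids]]
        self._per_step_deposit(eng_ids)
        order = self.rng.permutation(live_ids)
        births = attachments = deaths = 0
        for cid in order:
            cid = int(cid)
            if not self.alive[cid]:
                continue
            if not self.engrafted[cid]:
                self._motile_turn(cid)
                if self.engrafted[cid]:
                    attachments += 1
                    if not self.alive[cid]:
                        deaths += 1
                continue
            # rule 3: age and possibly die
            self.N_life[cid] += 1
            if self.N_life[cid] >= self.T_life[cid]:
                self._die(cid)
                deaths += 1
                continue
            # rule 4: proliferation counter (held at T_prol while deferred)
            self.N_prol[cid] = min(self.N_prol[cid] + 1, int(self.T_prol[cid]))
            if self.N_prol[cid] >= self.T_prol[cid] and not self.has_proliferated[cid]:
                if self._try_proliferate(cid) is not None:
                    births += 1
        return births, attachments, deaths

    def _cull_motile(self) -> None:
        live = self.alive[: self.n_agents]
        motile_ids = np.nonzero(live & ~self.engrafted[: self.n_agents])[0]
        for cid in motile_ids:
            coords = tuple(self.pos[cid])
            self._vacate(coords)
            self.alive[cid] = False

    # -- observation ---------------------------------------------------------

    @property
    def n_engrafted(self) -> int:
        return int((self.alive[: self.n_agents] & self.engrafted[: self.n_agents]).sum())

    @property
    def n_motile(self) -> int:
        return int((self.alive[: self.n_agents] & ~self.engrafted[: self.n_agents]).sum())

    def engrafted_positions(self) -> np.ndarray:
        live = self.alive[: self.n_agents] & self.engrafted[: self.n_agents]
        return self.pos[: self.n_agents][live]

    def cell(self, cid: int) -> MotileCell | EngraftedCell:
        if not self.alive[cid]:
            raise ValueError(f"cell {cid} is not alive")
        pos = tuple(int(v) for v in self.pos[cid])
        if self.engrafted[cid]:
            return EngraftedCell(cid, pos, int(self.T_life[cid]), int(self.T_prol[cid]),
                                 int(self.N_life[cid]), int(self.N_prol[cid]))
        return MotileCell(cid, pos, tuple(float(v) for v in self.heading[cid]))

    def default_slice_indices(self) -> list[int]:
        """``n_slices`` fixed interior indices, centered on the lattice."""
        g = self.config.grid_size
        k = min(self.config.n_slices, g)
        start = self.state.lo + (g - k) // 2
        return list(range(start, start + k))

    def slice_counts(self, indices: Sequence[int]) -> np.ndarray:
        ax = _AXES[self.config.slice_axis]
        pos = self.engrafted_positions()
        vals = pos[:, ax]
        return np.array([(vals == s).sum() for s in indices], dtype=np.int64)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``v`` by ``angle`` about the unit vector ``axis``."""
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * float(axis @ v) * (1.0 - math.cos(angle))
    )


# -- spec-level operation wrappers (per-cell API) ----------------------------


def seed(
    sim: Simulation,
    n_cells: int,
    engraft_prob: float,
    rules: RuleSet | None = None,
    rng: np.random.Generator | None = None,
) -> Simulation:
    """Seed ``n_cells`` agents onto the scaffold of ``sim`` (t = 0)."""
    if rules is not None:
        sim.rules = rules
    if rng is not None:
        sim.rng = rng
    sim.seed(n_cells=n_cells, engraft_prob=engraft_prob)
    return sim


def movement_step(sim: Simulation, cell_id: int) -> MotileCell:
    """Execute one movement rule for a motile cell; returns its new snapshot."""
    if sim.engrafted[cell_id] or not sim.alive[cell_id]:
        raise ValueError("movement_step requires a live motile cell")
    sim._motile_move(cell_id)
    return sim.cell(cell_id)  # type: ignore[return-value]


def attachment_step(sim: Simulation, cell_id: int) -> MotileCell | EngraftedCell:
    """Execute the attachment rule for a motile cell."""
    if sim.engrafted[cell_id] or not sim.alive[cell_id]:
        raise ValueError("attachment_step requires a live motile cell")
    sim._attach(cell_id)
    return sim.cell(cell_id)


def death_step(sim: Simulation, cell_id: int) -> bool:
    """Advance the lifespan counter; returns whether the cell survived."""
    if not (sim.alive[cell_id] and sim.engrafted[cell_id]):
        raise ValueError("death_step requires a live engrafted cell")
    sim.N_life[cell_id] += 1
    if sim.N_life[cell_id] >= sim.T_life[cell_id]:
        sim._die(cell_id)
        return False
    return True


def proliferation_step(sim: Simulation, cell_id: int) -> EngraftedCell | None:
    """Advance the proliferation counter; returns the offspring, if any."""
    if not (sim.alive[cell_id] and sim.engrafted[cell_id]):
        raise ValueError("proliferation_step requires a live engrafted cell")
    sim.N_prol[cell_id] = min(int(sim.N_prol[cell_id]) + 1, int(sim.T_prol[cell_id]))
    if sim.N_prol[cell_id] >= sim.T_prol[cell_id] and not sim.has_proliferated[cell_id]:
        new_id = sim._try_proliferate(cell_id)
        if new_id is not None:
            return sim.cell(new_id)  # type: ignore[return-value]
    return None


def extract_slice(sim: Simulation, axis: str, index: int) -> np.ndarray:
    """In-plane coordinates of engrafted cells in a one-patch-thick plane."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    if not (sim.state.lo <= index <= sim.state.hi):
        raise IndexError(f"slice index {index} out of bounds")
    ax = _AXES[axis]
    pos = sim.engrafted_positions()
    keep = [i for i in range(3) if i != ax]
    return pos[pos[:, ax] == index][:, keep]


def run(
    rules: RuleSet | str,
    n_steps: int | None = None,
    seed: int | np.random.Generator | None = 0,
    record_every: int | None = None,
    config: SimConfig | None = None,
) -> Trajectory:
    """Run one full simulation and record per-slice counts (and CVHV).

    ``rules`` may be a :class:`RuleSet` or ``"hypothesis1"`` / ``"hypothesis2"``.
    Identical ``seed`` (with identical configuration) gives an identical
    trajectory.
    """
    from .images import analyze_slice_points  # local import: no cycle at module load

    if isinstance(rules, str):
        rules = {"hypothesis1": hypothesis1, "hypothesis2": hypothesis2}[rules]()
    cfg = config or SimConfig()
    if n_steps is not None:
        cfg = dataclass_replace(cfg, n_steps=int(n_steps))
    if record_every is not None:
        cfg = dataclass_replace(cfg, record_every=int(record_every))
    if cfg.n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    sim = Simulation(rules, cfg, rng=seed)
    sim.seed()
    slices = sim.default_slice_indices()
    half = 0.5
    bounds = (sim.state.lo - half, sim.state.hi + half,
              sim.state.lo - half, sim.state.hi + half)
    time_points: list[int] = []
    counts: list[np.ndarray] = []
    cvhvs: list[np.ndarray] = []
    ax = _AXES[cfg.slice_axis]
    keep = [i for i in range(3) if i != ax]
    for _ in range(cfg.n_steps):
        sim.step()
        if sim.t % cfg.record_every == 0:
            time_points.append(sim.t)
            pos = sim.engrafted_positions()
            vals = pos[:, ax]
            counts.append(np.array([(vals == s).sum() for s in slices], dtype=np.int64))
            if cfg.record_cvhv:
                row = np.zeros(len(slices))
                for j, s in enumerate(slices):
                    pts = pos[vals == s][:, keep]
                    if len(pts) >= 2:
                        # fewer than 2 cells: no measurable area heterogeneity
                        _, row[j] = analyze_slice_points(pts, bounds)
                cvhvs.append(row)
    return Trajectory(
        time_points=time_points,
        slice_indices=slices,
        counts=np.array(counts),
        cvhv=np.array(cvhvs) if cfg.record_cvhv else None,
    )


def run_replicates(
    rules: RuleSet | str,
    n_replicates: int,
    seed: int = 0,
    config: SimConfig | None = None,
    **run_kwargs,
) -> pd.DataFrame:
    """Run independent replicates; returns a long-format DataFrame with
    columns replicate, time_step, slice_index, n_cells, cvhv."""
    ss = np.random.SeedSequence(seed)
    frames = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        traj = run(rules, seed=np.random.default_rng(child), config=config, **run_kwargs)
        frames.append(traj.to_frame(replicate=rep))
    return pd.concat(frames, ignore_index=True)


def calibrate_time_scale(
    grid_size: int,
    scaffold_width_um: float,
    n_steps: int,
    duration_days: float,
) -> tuple[float, float, float]:
    """Map model units onto physical units.

    Returns ``(patch_size_um, step_rate_per_min, velocity_um_per_min)``: the
    physical edge length of one patch, the number of time steps elapsing per
    minute of real time, and the speed of a cell moving one patch per step.
    With the defaults (32 patches across a 1,000 μm slice, 80 steps over 28
    days) this gives ≈0.002 steps/min and ≈0.06 μm/min.
    """
    if grid_size <= 0 or scaffold_width_um <= 0 or n_steps <= 0 or duration_days <= 0:
        raise ValueError("all calibration inputs must be positive")
    patch_size = scaffold_width_um / grid_size
    step_rate = n_steps / (duration_days * 24.0 * 60.0)
    return patch_size, step_rate, patch_size * step_rate


def dataclass_replace(cfg: SimConfig, **kwargs) -> SimConfig:
    import dataclasses

    return dataclasses.replace(cfg, **kwargs)
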