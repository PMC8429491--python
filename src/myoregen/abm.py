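"""Hourly-tick agent-based model of muscle damage response and regeneration.

One tick is one hour.  Within a tick the update order is fixed: cytokine
pools, neutrophils, macrophages, satellite cells and myoblasts, fibroblasts,
then border re-formation and hypertrophy, and finally the census/logging.

The emergent timeline the rules are built to produce mirrors the canonical
four-phase regeneration cascade: damage at hour 1; a neutrophil burst that
peaks within the first day (recruitment wanes linearly over ~24 h while
individual cells expire with a ~12 h mean lifespan); macrophage invasion
over the first three days, ending when every damaged object has been
phagocytosed, at which point M1 macrophages switch to the anti-inflammatory
M2 phenotype; an IGF-1-gated satellite-cell proliferation window that stays
open while M2 macrophages persist (~3 more days); myoblast-mediated fibril
repair racing fibroblast collagen deposition; and, once the pre-injury
fibril count is restored, ghost-fiber border re-formation with modest
hypertrophy while active satellite cells remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .cytokines import (
    CellCensus,
    CytokineState,
    deposit_local,
    diffuse_local,
    gradient_positive,
    update_cytokines,
)
from .geometry import TissueGrid

_N4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # + center
_STEPS5 = np.array([(0, 0), (0, -1), (1, 0), (0, 1), (-1, 0)])  # stay + N,E,S,W
_MOORE9 = np.array(
    [(0, 0), (0, -1), (1, 0), (0, 1), (-1, 0), (1, -1), (1, 1), (-1, 1), (-1, -1)]
)


@dataclass
class SimConfig:
    """Run configuration.  Counts follow the density formula
    ``round(density_per_fiber_per_10µm × n_fibers × slice_thickness/10)``
    with stochastic rounding of fractional remainders.

    The TD milieu uses ``sc_per_fiber_per_10um=0.10`` (10 satellite cells on
    the 20-fiber, 50 µm bundle); the CP milieu uses 0.04 (4 cells).  Agent
    parameters the source physiology does not pin down (lifespans,
    recruitment tapers, division and hypertrophy rates, caps) are exposed
    here; defaults are calibrated so the emergent time course matches the
    documented cascade (see docs/methods.md).
    """

    sc_per_fiber_per_10um: float = 0.10
    sc_count_override: int | None = None
    damage_fraction: float = 0.10
    ticks: int = 672
    replicates: int = 150
    seed: int = 0

    # inflammatory and stromal seeding (literature gives no explicit counts)
    initial_neutrophils: int = 5
    initial_macrophages: int = 5
    fb_per_fiber_per_10um: float = 0.09

    # chemotaxis speeds (pixels per hour, ~2.54 µm per pixel)
    inflammatory_speed_px_h: int = 4
    stromal_speed_px_h: int = 3

    # neutrophil kinetics
    neutrophil_lifespan_mean_h: float = 17.0
    neutrophil_recruit_window_h: float = 27.0
    neutrophil_spawn_p: float = 0.2
    neutrophil_influx_per_h: float = 10.0  # systemic recruitment while damaged
    neutrophil_clear_per_h: float = 0.38  # damaged px broken down per cell-hour
    neutrophil_capacity_px: float = 6.0  # lifetime phagocytic capacity
    max_neutrophils: int = 250

    # macrophage kinetics
    macrophage_recruit_window_h: float = 33.0
    macrophage_wane_window_h: float = 12.0  # invasion wanes after the build-up
    macrophage_spawn_p: float = 0.2
    macrophage_influx_per_h: float = 4.2  # systemic recruitment while damaged
    m1_death_hazard: float = 0.005
    m2_lifespan_range_h: tuple = (0.0, 64.0)
    m2_lifespan_skew: float = 3.0  # most M2 die early; a few persist
    macrophage_clear_per_h: float = 1.6  # phagocytosed pixels per cell-hour
    macrophage_capacity_px: float = 24.0  # lifetime phagocytic capacity
    max_macrophages: int = 300

    # satellite cells / myoblasts
    sc_division_base_p: float = 0.5
    sc_division_min_age_h: int = 18
    p_division_sym_sc: float = 0.40
    p_division_sym_mb: float = 0.27  # remainder is asymmetric
    sc_activation: str = "hgf_rising"  # or "hgf_above_baseline"
    hgf_activation_threshold: float = 0.0
    sc_repairs_per_tick: int = 8
    sc_exit_hazard: float = 1.0 / 36.0
    repair_requires_myoblast: bool = True
    mb_placement_p: float = 0.75  # per active SC per hour, proliferative window
    mb_placement_niche_cap: float = 1.0  # max placements/h per seeded SC
    mb_fusion_yield: int = 6  # grid pixels regrown per fused myoblast
    myoblast_lifespan_h: int = 96
    hypertrophy_p: float = 0.04
    hypertrophy_uses_myoblasts: bool = True  # growth is myonuclear accretion

    # damage / cytokine plumbing
    damaged_collagen: float = 0.2
    il6_deposit_amount: float = 1e-12
    diffusion_weight: float = 0.0
    steady_state_exit: bool = True

    def _density_count(self, density: float, n_fibers: int, slice_um: float,
                       rng: np.random.Generator | None) -> int:
        x = density * n_fibers * slice_um / 10.0
        base = math.floor(x)
        frac = x - base
        if frac == 0.0:
            return base
        if rng is None:
            return round(x)
        return base + int(rng.random() < frac)

    def initial_sc_count(self, n_fibers: int, slice_um: float,
                         rng: np.random.Generator | None = None) -> int:
        if self.sc_count_override is not None:
            return self.sc_count_override
        return self._density_count(self.sc_per_fiber_per_10um, n_fibers, slice_um, rng)

    def initial_fb_count(self, n_fibers: int, slice_um: float,
                         rng: np.random.Generator | None = None) -> int:
        return self._density_count(self.fb_per_fiber_per_10um, n_fibers, slice_um, rng)


class InitializationError(RuntimeError):
    pass


@dataclass
class SimState:
    grid: TissueGrid
    config: SimConfig
    rng: np.random.Generator
    cyt: CytokineState
    tick: int = 0
    injury_tick: int | None = None
    pre_injury_fibrils: int = 0
    sc_seeded: int = 0  # initially seeded satellite cells (niche size)
    igf_window_opened: bool = False

    # agents (positions are (k, 2) int arrays of x, y)
    neutro_pos: np.ndarray = None
    neutro_cap: np.ndarray = None  # remaining phagocytic capacity
    macro_pos: np.ndarray = None
    macro_cap: np.ndarray = None
    macro_phen: np.ndarray = None  # 1 = M1, 2 = M2
    macro_death: np.ndarray = None
    sc_pos: np.ndarray = None
    sc_active: np.ndarray = None
    sc_div: np.ndarray = None
    sc_age: np.ndarray = None
    fb_pos: np.ndarray = None
    fb_active: np.ndarray = None
    mb_pos: np.ndarray = None
    mb_birth: np.ndarray = None
    mb_yield: np.ndarray = None  # remaining fusion capacity per myoblast
    mb_target: np.ndarray = None  # assigned repair-front pixel per myoblast

    census_log: list = field(default_factory=list)
    cyt_log: list = field(default_factory=list)
    tissue_log: list = field(default_factory=list)  # (fibril, ecm) per tick

    def census(self) -> CellCensus:
        g = self.grid
        return CellCensus(
            N=len(self.neutro_pos),
            PM=int((self.macro_phen == 1).sum()),
            AM=int((self.macro_phen == 2).sum()),
            Fb=len(self.fb_pos),
            SC_q=int((~self.sc_active).sum()),
            SC_a=int(self.sc_active.sum()),
            MB=len(self.mb_pos),
            DE=int((g.damaged & g.ecm).sum()),
            DF=int((g.damaged & (g.fiber_id > 0)).sum()),
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _sample_mask(rng: np.random.Generator, mask: np.ndarray, k: int,
                 replace: bool = False) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    if len(xs) == 0 and k > 0:
        raise InitializationError("no pixels available for agent placement")
    idx = rng.choice(len(xs), size=k, replace=replace or k > len(xs))
    return np.column_stack([xs[idx], ys[idx]]).astype(np.int64)


def _adjacent4(mask: np.ndarray) -> np.ndarray:
    """Pixels with at least one 4-neighbor inside ``mask``."""
    out = np.zeros_like(mask)
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out


def initialize(grid: TissueGrid, config: SimConfig,
               rng: np.random.Generator) -> SimState:
    """Seed all agent populations onto a (possibly already damaged) grid.

    Satellite cells start quiescent on border fibrils (fibril pixels
    4-adjacent to ECM); neutrophils, macrophages and fibroblasts are placed
    uniformly at random on ECM pixels.
    """
    border = grid.fibril_mask & _adjacent4(grid.ecm)
    if not border.any():
        raise InitializationError("grid has no border fibrils for SC seeding")
    n_sc = config.initial_sc_count(grid.n_fibers, grid.slice_thickness, rng)
    n_fb = config.initial_fb_count(grid.n_fibers, grid.slice_thickness, rng)

    state = SimState(
        grid=grid,
        config=config,
        rng=rng,
        cyt=CytokineState(),
        pre_injury_fibrils=int((grid.fibril_mask & ~grid.damaged).sum()
                               + (grid.damaged & grid.fibril_mask).sum()),
        sc_seeded=n_sc,
        neutro_pos=_sample_mask(rng, grid.ecm, config.initial_neutrophils),
        neutro_cap=np.full(config.initial_neutrophils,
                           config.neutrophil_capacity_px),
        macro_pos=_sample_mask(rng, grid.ecm, config.initial_macrophages),
        macro_cap=np.full(config.initial_macrophages,
                          config.macrophage_capacity_px),
        macro_phen=np.ones(config.initial_macrophages, dtype=np.int8),
        macro_death=np.full(config.initial_macrophages, np.inf),
        sc_pos=_sample_mask(rng, border, n_sc),
        sc_active=np.zeros(n_sc, dtype=bool),
        sc_div=np.zeros(n_sc, dtype=np.int64),
        sc_age=np.zeros(n_sc, dtype=np.int64),
        fb_pos=_sample_mask(rng, grid.ecm, n_fb),
        fb_active=np.zeros(n_fb, dtype=bool),
        mb_pos=np.empty((0, 2), dtype=np.int64),
        mb_birth=np.empty(0, dtype=np.int64),
        mb_yield=np.empty(0, dtype=np.int64),
        mb_target=np.empty((0, 2), dtype=np.int64),
    )
    state.cyt.ensure_local(grid.fiber_id.shape)
    _log(state)
    return state


def _log(state: SimState) -> None:
    c = state.census()
    state.census_log.append(c)
    state.cyt_log.append(dict(state.cyt.pools))
    g = state.grid
    intact = int(((g.fiber_id > 0) & ~g.damaged).sum())
    state.tissue_log.append((intact, g.ecm_count))


# ---------------------------------------------------------------------------
# movement primitives
# ---------------------------------------------------------------------------


def _distance_field(target: np.ndarray) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest target pixel."""
    if not target.any():
        return np.full(target.shape, np.inf)
    return ndimage.distance_transform_edt(~target)


def _descend(pos: np.ndarray, fld: np.ndarray, allowed: np.ndarray,
             rng: np.random.Generator, speed: int = 1) -> np.ndarray:
    """Move each agent up to ``speed`` pixels down ``fld`` within ``allowed``."""
    for _ in range(speed - 1):
        pos = _descend(pos, fld, allowed, rng, speed=1)
    if len(pos) == 0:
        return pos
    h, w = fld.shape
    vals = np.empty((len(pos), len(_STEPS5)))
    cand = np.empty((len(pos), len(_STEPS5), 2), dtype=np.int64)
    for j, (dx, dy) in enumerate(_STEPS5):
        nx = np.clip(pos[:, 0] + dx, 0, w - 1)
        ny = np.clip(pos[:, 1] + dy, 0, h - 1)
        ok = allowed[ny, nx] | (j == 0)  # staying put is always legal
        vals[:, j] = np.where(ok, fld[ny, nx], np.inf)
        cand[:, j, 0] = nx
        cand[:, j, 1] = ny
    # noisy argmin: near-equal options diverge, spreading crowded agents
    # along a damage front instead of stacking on one greedy path
    vals += rng.random(vals.shape) * 0.45
    best = vals.argmin(axis=1)
    return cand[np.arange(len(pos)), best]


def _random_walk(pos: np.ndarray, allowed: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    if len(pos) == 0:
        return pos
    flat = np.zeros(allowed.shape)  # uniform field = unbiased walk
    return _descend(pos, flat, allowed, rng)


# ---------------------------------------------------------------------------
# per-class steps
# ---------------------------------------------------------------------------


def _clear_pixels(grid: TissueGrid, ys: np.ndarray, xs: np.ndarray) -> None:
    fib = grid.fiber_id[ys, xs] > 0
    grid.fiber_id[ys[fib], xs[fib]] = 0
    ecm = grid.ecm[ys, xs]
    grid.ecm[ys[ecm], xs[ecm]] = False
    grid.collagen[ys[ecm], xs[ecm]] = 0.0
    grid.damaged[ys, xs] = False
    grid.needs_repair[ys, xs] = True


def _contact_clear(state: SimState, pos: np.ndarray, caps: np.ndarray,
                   spawn_p: float, count_cap: int, deposit_il6: bool,
                   clear_per_agent: float):
    """Shared neutrophil/macrophage damage interaction.

    Agents adjacent (Moore, self included) to a damaged object mark it as
    needing repair, may proliferate, optionally release IL-6 locally, and
    break down damaged objects.  Each agent clears at most
    ``clear_per_agent`` pixels per hour and at most its remaining lifetime
    phagocytic capacity in total, so the cumulative clearance an injury can
    receive is bounded by the recruited cell mass.  Returns updated
    positions/capacities and the number of newborn agents.
    """
    g, rng = state.grid, state.rng
    dmg = g.damaged
    agent_mask = np.zeros(dmg.shape, dtype=bool)
    agent_mask[pos[:, 1], pos[:, 0]] = True
    moore = np.ones((3, 3), dtype=bool)
    reach = ndimage.binary_dilation(agent_mask, structure=moore)
    candidates = dmg & reach
    if not candidates.any():
        return pos, caps, 0
    dmg_reach = ndimage.binary_dilation(dmg, structure=moore)
    in_contact = dmg_reach[pos[:, 1], pos[:, 0]]
    n_contact = int(in_contact.sum())

    g.needs_repair[candidates] = True
    if deposit_il6 and state.config.il6_deposit_amount > 0:
        cpos = pos[in_contact]
        np.add.at(state.cyt.local["IL6"], (cpos[:, 1], cpos[:, 0]),
                  state.config.il6_deposit_amount)
        state.cyt.pools["IL6"] += state.config.il6_deposit_amount * len(cpos)

    # proliferation (capped): a division splits the parent's remaining
    # phagocytic capacity, so only recruitment adds capacity to the tissue
    n_spawn = 0
    if spawn_p > 0 and len(pos) < count_cap:
        spawned = rng.random(n_contact) < spawn_p
        n_spawn = min(int(spawned.sum()), count_cap - len(pos))
        if n_spawn:
            pidx = np.flatnonzero(in_contact)[spawned][:n_spawn]
            caps[pidx] *= 0.5
            pos = np.vstack([pos, pos[pidx]])
            caps = np.append(caps, caps[pidx])

    # breakdown, bounded by hourly rate and remaining capacity
    idx = np.flatnonzero(in_contact)  # indexes agents present pre-spawn
    hourly = np.minimum(clear_per_agent, caps[idx])
    capacity = float(hourly.sum())
    if capacity <= 0:
        return pos, caps, n_spawn
    ys, xs = np.nonzero(candidates)
    k = int(capacity) + int(rng.random() < capacity % 1.0)
    k = min(k, len(ys))
    if k:
        pick = rng.permutation(len(ys))[:k]
        _clear_pixels(g, ys[pick], xs[pick])
        # proportional drawdown of the contributing agents' capacity
        caps[idx] -= hourly * (k / capacity)
    return pos, caps, n_spawn


def _taper(t: int, t0: int, window: float) -> float:
    """Linearly waning recruitment drive (neutrophil burst)."""
    return max(0.0, 1.0 - (t - t0) / window)


def _ramp(t: int, t0: int, window: float) -> float:
    """Linearly building recruitment drive (macrophage invasion)."""
    return min(1.0, max(0.0, (t - t0) / window))


def _invasion_drive(state: SimState) -> float:
    """Triangular macrophage recruitment drive: builds over the invasion
    window, then wanes.  A damage load the waning response cannot finish
    stays uncleared — the model's limit on repairable injury."""
    cfg = state.config
    t0 = state.injury_tick
    up = _ramp(state.tick, t0, cfg.macrophage_recruit_window_h)
    down = _taper(
        state.tick, t0 + cfg.macrophage_recruit_window_h,
        cfg.macrophage_wane_window_h,
    ) if state.tick > t0 + cfg.macrophage_recruit_window_h else 1.0
    return up * min(1.0, max(0.0, down))


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = int(x)
    return base + int(rng.random() < x - base)


def neutrophil_step(state: SimState) -> None:
    g, cfg, rng = state.grid, state.config, state.rng
    pos, caps = state.neutro_pos, state.neutro_cap
    roam = g.ecm | g.cleared_mask | g.damaged
    if state.injury_tick is None or not g.damaged.any():
        state.neutro_pos = _random_walk(pos, roam, rng)
    else:
        # infiltrating cells may squeeze through intact tissue toward damage
        fld = _distance_field(g.damaged)
        pos = _descend(pos, fld, g.occupied, rng,
                       speed=cfg.inflammatory_speed_px_h)
        taper = _taper(state.tick, state.injury_tick,
                       cfg.neutrophil_recruit_window_h)
        pos, caps, _ = _contact_clear(
            state, pos, caps, cfg.neutrophil_spawn_p * taper,
            cfg.max_neutrophils, deposit_il6=True,
            clear_per_agent=cfg.neutrophil_clear_per_h,
        )
        # systemic influx from circulation, waning with the same drive
        n_in = min(_stochastic_round(cfg.neutrophil_influx_per_h * taper, rng),
                   max(0, cfg.max_neutrophils - len(pos)))
        if n_in and g.ecm.any():
            pos = np.vstack([pos, _sample_mask(rng, g.ecm, n_in)])
            caps = np.append(caps, np.full(n_in, cfg.neutrophil_capacity_px))
        state.neutro_pos, state.neutro_cap = pos, caps
    if state.injury_tick is not None and len(state.neutro_pos):
        # spent neutrophils linger (still marking damage) until expiry;
        # a dying cell's residual phagocytic capacity passes to its peers,
        # so the lesion's recruited capacity is what bounds total clearance
        survive = (
            rng.random(len(state.neutro_pos))
            >= 1.0 / cfg.neutrophil_lifespan_mean_h
        )
        lost = float(state.neutro_cap[~survive].sum())
        state.neutro_pos = state.neutro_pos[survive]
        state.neutro_cap = state.neutro_cap[survive]
        if lost > 0 and len(state.neutro_cap) and g.damaged.any():
            state.neutro_cap += lost / len(state.neutro_cap)


def macrophage_step(state: SimState) -> None:
    g, cfg, rng = state.grid, state.config, state.rng
    roam = g.ecm | g.cleared_mask | g.damaged
    m1 = state.macro_phen == 1
    pos = state.macro_pos.copy()
    if state.injury_tick is not None and g.damaged.any():
        # chemotaxis: straight-line descent toward the nearest damage site
        fld = _distance_field(g.damaged)
        pos[m1] = _descend(pos[m1], fld, g.occupied, rng,
                           speed=cfg.inflammatory_speed_px_h)
        state.macro_pos = pos
        drive = _invasion_drive(state)
        p = cfg.macrophage_spawn_p * drive
        m1_idx = np.flatnonzero(m1)
        m1_caps = state.macro_cap[m1_idx]
        newpos, newcaps, n_spawn = _contact_clear(
            state, pos[m1], m1_caps, p,
            cfg.max_macrophages - int((~m1).sum()),
            deposit_il6=False, clear_per_agent=cfg.macrophage_clear_per_h,
        )
        state.macro_cap[m1_idx] = newcaps[: len(m1_idx)]
        if n_spawn:
            state.macro_pos = np.vstack([state.macro_pos, newpos[-n_spawn:]])
            state.macro_phen = np.append(
                state.macro_phen, np.ones(n_spawn, dtype=np.int8)
            )
            state.macro_death = np.append(
                state.macro_death, np.full(n_spawn, np.inf)
            )
            state.macro_cap = np.append(state.macro_cap, newcaps[-n_spawn:])
        # systemic influx following the invasion drive
        n_in = min(_stochastic_round(cfg.macrophage_influx_per_h * drive, rng),
                   max(0, cfg.max_macrophages - len(state.macro_pos)))
        if n_in and g.ecm.any():
            state.macro_pos = np.vstack(
                [state.macro_pos, _sample_mask(rng, g.ecm, n_in)]
            )
            state.macro_phen = np.append(
                state.macro_phen, np.ones(n_in, dtype=np.int8)
            )
            state.macro_death = np.append(
                state.macro_death, np.full(n_in, np.inf)
            )
            state.macro_cap = np.append(
                state.macro_cap, np.full(n_in, cfg.macrophage_capacity_px)
            )
        m1 = state.macro_phen == 1
        pos = state.macro_pos
    else:
        # IL-6 arg-max Moore step when it points anywhere, else random walk
        il6 = state.cyt.local["IL6"]
        if il6.any() and m1.any():
            pos[m1] = _descend(pos[m1], -il6, roam, rng)
        else:
            pos = _random_walk(pos, roam, rng)
        state.macro_pos = pos

    # M1 attrition after injury; once the invasion drive is exhausted,
    # unsupported M1 macrophages die off quickly
    if state.injury_tick is not None and m1.any():
        hazard = cfg.m1_death_hazard
        if g.damaged.any() and _invasion_drive(state) <= 0.0:
            hazard = max(hazard, 1.0 / 20.0)
        die = m1 & (rng.random(len(state.macro_phen)) < hazard)
        # phagocytically spent M1 drop out faster while damage persists
        if g.damaged.any():
            die |= (
                m1 & (state.macro_cap <= 1e-9)
                & (rng.random(len(state.macro_phen)) < 1.0 / 12.0)
            )
        if die.any():
            keep = ~die
            lost = float(state.macro_cap[die].sum())
            state.macro_pos = state.macro_pos[keep]
            state.macro_phen = state.macro_phen[keep]
            state.macro_death = state.macro_death[keep]
            state.macro_cap = state.macro_cap[keep]
            m1 = state.macro_phen == 1
            # residual capacity of dying M1 passes to the surviving M1 pool
            if lost > 0 and m1.any() and g.damaged.any():
                state.macro_cap[m1] += lost / int(m1.sum())

    # phenotype switch once every damaged object has been cleared
    if state.injury_tick is not None and not g.damaged.any() and m1.any():
        lo, hi = cfg.m2_lifespan_range_h
        u = rng.random(int(m1.sum())) ** cfg.m2_lifespan_skew
        life = lo + (hi - lo) * u
        # one resident M2 persists for the full range, so the length of the
        # anti-inflammatory (and hence IGF-1) window does not depend on how
        # many macrophages survive to the phenotype switch
        life[0] = hi
        state.macro_death[m1] = state.tick + life
        state.macro_phen[m1] = 2

    # M2 expiry
    expired = state.macro_death <= state.tick
    if expired.any():
        keep = ~expired
        state.macro_pos = state.macro_pos[keep]
        state.macro_phen = state.macro_phen[keep]
        state.macro_death = state.macro_death[keep]
        state.macro_cap = state.macro_cap[keep]


def division_probability(divisions: int, base_p: float) -> float:
    """Per-hour division chance after ``divisions`` completed divisions.

    The chance drops 20% after each of the first three divisions and a
    further 40% at the fourth: p(d) = base_p · 0.8^min(d,3) · (0.6 if d≥4).
    """
    return base_p * 0.8 ** min(divisions, 3) * (0.6 if divisions >= 4 else 1.0)


def _repair_eligible(grid: TissueGrid) -> np.ndarray:
    """Cleared fibril-owned pixels where a myoblast can fuse.

    A pixel is a valid fusion site if it is 4-adjacent to intact fibril of
    its own fiber (regrowth from the surviving stump) or to intact ECM (the
    ghost-fiber scaffold: regeneration proceeds along the residual basal
    lamina even when a fiber segment was fully necrosed).  Pixels touching
    still-damaged tissue are excluded: debris must be cleared before fusion,
    which also keeps a corridor open so phagocytes are never walled off.
    """
    need = (
        grid.needs_repair & grid.cleared_mask & (grid.owner > 0)
        & ~_adjacent4(grid.damaged)
    )
    if not need.any():
        return need
    anchored = np.zeros_like(need)
    fid = grid.fiber_id
    own = grid.owner
    anchored[1:, :] |= fid[:-1, :] == own[1:, :]
    anchored[:-1, :] |= fid[1:, :] == own[:-1, :]
    anchored[:, 1:] |= fid[:, :-1] == own[:, 1:]
    anchored[:, :-1] |= fid[:, 1:] == own[:, :-1]
    anchored |= _adjacent4(grid.ecm)
    return need & anchored & (fid == 0)


def _hgf_active(state: SimState) -> bool:
    cfg = state.config
    if cfg.sc_activation == "hgf_rising":
        return (
            state.cyt.prev_pools is not None
            and state.cyt.pools["HGF"] > state.cyt.prev_pools["HGF"]
        )
    return state.cyt.pools["HGF"] > cfg.hgf_activation_threshold


def satellite_cell_step(state: SimState) -> None:
    g, cfg, rng = state.grid, state.config, state.rng

    # quiescent -> active while HGF signals damage
    if _hgf_active(state) and (~state.sc_active).any():
        newly = ~state.sc_active
        state.sc_active[newly] = True
        state.sc_age[newly] = 0

    active_idx = np.flatnonzero(state.sc_active)
    eligible = _repair_eligible(g)

    # each active SC heads for its own nearest repair-front pixel (8-dir
    # steps), which spreads the pool along the front instead of crowding
    if len(active_idx) and eligible.any():
        from scipy.spatial import cKDTree

        ys, xs = np.nonzero(eligible)
        targets = np.column_stack([xs, ys])
        _, near = cKDTree(targets).query(state.sc_pos[active_idx])
        goal = targets[near]
        pos = state.sc_pos[active_idx]
        for _ in range(cfg.stromal_speed_px_h):
            pos = pos + np.sign(goal - pos)
        pos[:, 0] = np.clip(pos[:, 0], 0, g.width - 1)
        pos[:, 1] = np.clip(pos[:, 1], 0, g.height - 1)
        state.sc_pos[active_idx] = pos

    # myoblast fusion at needs-repair fibrils (Moore search): each fused
    # myoblast can regrow up to mb_fusion_yield pixels before it is spent
    if len(active_idx) and eligible.any():
        h, w = eligible.shape
        for i in rng.permutation(active_idx):
            x, y = state.sc_pos[i]
            done = 0
            for dx, dy in _MOORE9:
                if done >= cfg.sc_repairs_per_tick:
                    break
                nx, ny = x + dx, y + dy
                if not (0 <= nx < w and 0 <= ny < h) or not eligible[ny, nx]:
                    continue
                if cfg.repair_requires_myoblast:
                    if len(state.mb_yield) == 0:
                        break
                    state.mb_yield[0] -= 1  # oldest myoblast fuses first
                    if state.mb_yield[0] <= 0:
                        state.mb_pos = state.mb_pos[1:]
                        state.mb_birth = state.mb_birth[1:]
                        state.mb_yield = state.mb_yield[1:]
                        state.mb_target = state.mb_target[1:]
                g.fiber_id[ny, nx] = g.owner[ny, nx]
                g.needs_repair[ny, nx] = False
                eligible[ny, nx] = False
                done += 1
                for ddx, ddy in ((0, -1), (1, 0), (0, 1), (-1, 0)):
                    qx, qy = nx + ddx, ny + ddy
                    if (
                        0 <= qx < w and 0 <= qy < h
                        and g.needs_repair[qy, qx]
                        and g.fiber_id[qy, qx] == 0
                        and not g.ecm[qy, qx]
                        and g.owner[qy, qx] == g.fiber_id[ny, nx]
                    ):
                        eligible[qy, qx] = True

    # myoblasts migrate to the debrided front and fuse autonomously,
    # regrowing fibril pixels until their fusion capacity is spent.  Each
    # keeps its own randomly assigned front pixel so the pool spreads over
    # the whole front instead of crowding the nearest breach.
    if len(state.mb_pos) and eligible.any():
        ys, xs = np.nonzero(eligible)
        targets = np.column_stack([xs, ys])
        tx, ty = state.mb_target[:, 0], state.mb_target[:, 1]
        stale = ~eligible[ty, tx]
        if stale.any():
            state.mb_target[stale] = targets[
                rng.integers(0, len(targets), int(stale.sum()))
            ]
        goal = state.mb_target
        pos = state.mb_pos
        for _ in range(cfg.stromal_speed_px_h):
            pos = pos + np.sign(goal - pos)
        pos[:, 0] = np.clip(pos[:, 0], 0, g.width - 1)
        pos[:, 1] = np.clip(pos[:, 1], 0, g.height - 1)
        state.mb_pos = pos
        h, w = eligible.shape
        for i in range(len(state.mb_pos)):
            if state.mb_yield[i] <= 0:
                continue
            x, y = state.mb_pos[i]
            done = 0
            for dx, dy in _MOORE9:
                if done >= cfg.sc_repairs_per_tick or state.mb_yield[i] <= 0:
                    break
                nx, ny = x + dx, y + dy
                if not (0 <= nx < w and 0 <= ny < h) or not eligible[ny, nx]:
                    continue
                g.fiber_id[ny, nx] = g.owner[ny, nx]
                g.needs_repair[ny, nx] = False
                eligible[ny, nx] = False
                state.mb_yield[i] -= 1
                done += 1
                for ddx, ddy in ((0, -1), (1, 0), (0, 1), (-1, 0)):
                    qx, qy = nx + ddx, ny + ddy
                    if (
                        0 <= qx < w and 0 <= qy < h
                        and g.needs_repair[qy, qx]
                        and g.fiber_id[qy, qx] == 0
                        and not g.ecm[qy, qx]
                        and g.owner[qy, qx] == g.fiber_id[ny, nx]
                        and not g.damaged[
                            max(0, qy - 1):qy + 2, max(0, qx - 1):qx + 2
                        ].any()
                    ):
                        eligible[qy, qx] = True
        spent = state.mb_yield <= 0
        if spent.any():
            keep = ~spent
            state.mb_pos = state.mb_pos[keep]
            state.mb_birth = state.mb_birth[keep]
            state.mb_yield = state.mb_yield[keep]
            state.mb_target = state.mb_target[keep]

    # proliferation while the IGF-1 gradient is positive
    igf_up = gradient_positive(state.cyt, "IGF1")
    if igf_up:
        state.igf_window_opened = True
        # active SCs keep placing myoblasts while the regenerative
        # signaling window is open — the steady supply channel for repair.
        # Output saturates at the seeded niche size: a larger transit-
        # amplifying pool does not raise the flux above the niche capacity.
        if cfg.mb_placement_p > 0 and len(active_idx):
            placing = active_idx[
                rng.random(len(active_idx)) < cfg.mb_placement_p
            ]
            cap = _stochastic_round(
                cfg.mb_placement_niche_cap * state.sc_seeded, rng
            )
            placing = placing[:cap]
            if len(placing):
                state.mb_pos = np.vstack([state.mb_pos, state.sc_pos[placing]])
                state.mb_birth = np.append(
                    state.mb_birth, np.full(len(placing), state.tick)
                )
                state.mb_yield = np.append(
                    state.mb_yield,
                    np.full(len(placing), cfg.mb_fusion_yield),
                )
                state.mb_target = np.vstack(
                    [state.mb_target, state.sc_pos[placing]]
                )
        eligible_div = np.flatnonzero(
            state.sc_active & (state.sc_age >= cfg.sc_division_min_age_h)
        )
        # descending order: in-loop deletions never shift pending indices
        for i in sorted(eligible_div, reverse=True):
            d = int(state.sc_div[i])
            if rng.random() >= division_probability(d, cfg.sc_division_base_p):
                continue
            u = rng.random()
            state.sc_div[i] = d + 1
            x, y = state.sc_pos[i]
            # niche homeostasis: differentiation only draws from surplus —
            # a pool at or below its seeded size divides asymmetrically
            if (
                cfg.p_division_sym_sc <= u
                < cfg.p_division_sym_sc + cfg.p_division_sym_mb
                and int(state.sc_active.sum()) <= state.sc_seeded
            ):
                u = 1.0  # fall through to the asymmetric branch
            if u < cfg.p_division_sym_sc:  # two active satellite cells
                state.sc_pos = np.vstack([state.sc_pos, [[x, y]]])
                state.sc_active = np.append(state.sc_active, True)
                state.sc_div = np.append(state.sc_div, d + 1)
                state.sc_age = np.append(state.sc_age, state.sc_age[i])
            elif u < cfg.p_division_sym_sc + cfg.p_division_sym_mb:
                # two myoblasts; the satellite cell differentiates away
                state.sc_active[i] = False
                state.sc_pos = np.delete(state.sc_pos, i, axis=0)
                state.sc_active = np.delete(state.sc_active, i)
                state.sc_div = np.delete(state.sc_div, i)
                state.sc_age = np.delete(state.sc_age, i)
                state.mb_pos = np.vstack([state.mb_pos, [[x, y], [x, y]]])
                state.mb_birth = np.append(
                    state.mb_birth, [state.tick, state.tick]
                )
                state.mb_yield = np.append(
                    state.mb_yield, [cfg.mb_fusion_yield] * 2
                )
                state.mb_target = np.vstack(
                    [state.mb_target, [[x, y], [x, y]]]
                )
            else:  # asymmetric: one quiescent + one active
                state.sc_pos = np.vstack([state.sc_pos, [[x, y]]])
                state.sc_active = np.append(state.sc_active, False)
                state.sc_div = np.append(state.sc_div, d + 1)
                state.sc_age = np.append(state.sc_age, 0)

    # once the proliferative window has closed, active cells wind down
    if state.igf_window_opened and not igf_up and state.sc_active.any():
        gone = state.sc_active & (
            state.rng.random(len(state.sc_active)) < cfg.sc_exit_hazard
        )
        if gone.any():
            keep = ~gone
            state.sc_pos = state.sc_pos[keep]
            state.sc_active = state.sc_active[keep]
            state.sc_div = state.sc_div[keep]
            state.sc_age = state.sc_age[keep]

    state.sc_age[state.sc_active] += 1

    # myoblast expiry
    if len(state.mb_pos):
        keep = state.tick - state.mb_birth < cfg.myoblast_lifespan_h
        state.mb_pos = state.mb_pos[keep]
        state.mb_birth = state.mb_birth[keep]
        state.mb_yield = state.mb_yield[keep]
        state.mb_target = state.mb_target[keep]


def _deposition_eligible(grid: TissueGrid, fallback: bool) -> np.ndarray:
    cleared = grid.cleared_mask & ~_adjacent4(grid.damaged)
    near_ecm = _adjacent4(grid.ecm)
    if fallback:
        return cleared & near_ecm
    return cleared & near_ecm & (grid.owner == 0)


def fibroblast_step(state: SimState) -> None:
    g, cfg, rng = state.grid, state.config, state.rng
    if gradient_positive(state.cyt, "TGFb"):
        state.fb_active[:] = True
    if not state.fb_active.any():
        return
    fallback = (
        state.injury_tick is not None
        and state.igf_window_opened
        and not gradient_positive(state.cyt, "IGF1")
        and not state.sc_active.any()
    )
    eligible = _deposition_eligible(g, fallback)
    act = np.flatnonzero(state.fb_active)
    if eligible.any():
        fld = _distance_field(eligible)
        state.fb_pos[act] = _descend(
            state.fb_pos[act], fld, g.occupied, rng,
            speed=cfg.stromal_speed_px_h,
        )
        h, w = eligible.shape
        for i in act:
            x, y = state.fb_pos[i]
            for dx, dy in _MOORE9:
                nx, ny = x + dx, y + dy
                if (0 <= nx < w and 0 <= ny < h) and eligible[ny, nx]:
                    g.ecm[ny, nx] = True
                    g.collagen[ny, nx] = 1.0
                    g.needs_repair[ny, nx] = False
                    eligible[ny, nx] = False
                    for ddx, ddy in ((0, -1), (1, 0), (0, 1), (-1, 0)):
                        qx, qy = nx + ddx, ny + ddy
                        if (
                            0 <= qx < w and 0 <= qy < h
                            and g.cleared_mask[qy, qx]
                            and (fallback or g.owner[qy, qx] == 0)
                        ):
                            eligible[qy, qx] = True
                    break
    else:
        state.fb_pos[act] = _random_walk(
            state.fb_pos[act], g.ecm | g.cleared_mask, rng
        )


def _growth_candidates(grid: TissueGrid) -> tuple[np.ndarray, np.ndarray]:
    """ECM pixels legally convertible to fibril (ghost-fiber hypertrophy).

    Legal means: interior ECM pixel whose von Neumann fibril neighbors all
    belong to a single fiber — conversion can then never make two distinct
    fibers 4-adjacent, preserving at least a 1-pixel ECM septum.
    """
    fid = grid.fiber_id.astype(np.int64)
    h, w = fid.shape
    stack = np.zeros((4, h, w), dtype=np.int64)
    stack[0, 1:, :] = fid[:-1, :]
    stack[1, :-1, :] = fid[1:, :]
    stack[2, :, 1:] = fid[:, :-1]
    stack[3, :, :-1] = fid[:, 1:]
    pos = np.where(stack > 0, stack, np.iinfo(np.int64).max)
    minid = pos.min(axis=0)
    maxid = stack.max(axis=0)
    interior = np.zeros((h, w), dtype=bool)
    interior[1:-1, 1:-1] = True
    legal = grid.ecm & interior & (maxid > 0) & (minid == maxid)
    return legal, maxid


def reform_borders_and_hypertrophy(state: SimState) -> None:
    g, cfg, rng = state.grid, state.config, state.rng
    if state.injury_tick is None:
        return
    if g.damaged.any() or g.fibril_count < state.pre_injury_fibrils:
        return
    n_active = int(state.sc_active.sum())
    if n_active == 0 or cfg.hypertrophy_p <= 0:
        return
    n_events = int(rng.binomial(n_active, cfg.hypertrophy_p))
    if n_events == 0:
        return
    legal, adj_id = _growth_candidates(g)
    ys, xs = np.nonzero(legal)
    if len(ys) == 0:
        return
    order = rng.permutation(len(ys))
    added = 0
    for j in order:
        if added >= n_events:
            break
        y, x = ys[j], xs[j]
        # re-check against in-tick conversions
        ids = set()
        for dx, dy in ((0, -1), (1, 0), (0, 1), (-1, 0)):
            f = g.fiber_id[y + dy, x + dx]
            if f > 0:
                ids.add(int(f))
        if len(ids) != 1 or not g.ecm[y, x]:
            continue
        if cfg.hypertrophy_uses_myoblasts:
            if len(state.mb_yield) == 0:
                break
            state.mb_yield[0] -= 1
            if state.mb_yield[0] <= 0:
                state.mb_pos = state.mb_pos[1:]
                state.mb_birth = state.mb_birth[1:]
                state.mb_yield = state.mb_yield[1:]
                state.mb_target = state.mb_target[1:]
        fid = ids.pop()
        g.ecm[y, x] = False
        g.collagen[y, x] = 0.0
        g.fiber_id[y, x] = fid
        g.owner[y, x] = fid
        added += 1


# ---------------------------------------------------------------------------
# scheduler
# ---------------------------------------------------------------------------


def step(state: SimState) -> SimState:
    """Advance one hour: cytokines, neutrophils, macrophages, satellite
    cells/myoblasts, fibroblasts, border/hypertrophy, census."""
    state.tick += 1
    if state.injury_tick is None and state.grid.damaged.any():
        state.injury_tick = state.tick
    state.cyt = update_cytokines(state.cyt, state.census_log[-1])
    if state.config.diffusion_weight > 0:
        diffuse_local(state.cyt, state.config.diffusion_weight)
    neutrophil_step(state)
    macrophage_step(state)
    satellite_cell_step(state)
    fibroblast_step(state)
    reform_borders_and_hypertrophy(state)
    _log(state)
    return state


def _quiescent(state: SimState) -> bool:
    """True when no further state change is possible (regeneration over)."""
    if state.injury_tick is None:
        return False
    c = state.census_log[-1]
    g = state.grid
    return (
        c.DF == 0 and c.DE == 0 and c.N == 0 and c.PM == 0 and c.AM == 0
        and c.SC_a == 0 and c.MB == 0
        and not g.needs_repair.any() and not g.cleared_mask.any()
    )


@dataclass
class SimResult:
    """Per-tick logs plus the endpoint grid of one replicate."""

    census: pd.DataFrame
    cytokines: pd.DataFrame
    grid: TissueGrid
    config: SimConfig
    seed: int
    injury_tick: int | None
    pre_injury_fibrils: int

    def clearance_time(self) -> float:
        """First post-injury hour with zero damaged fibrils (NaN if never)."""
        if self.injury_tick is None:
            return float("nan")
        df = self.census
        after = df[(df["tick"] >= self.injury_tick) & (df["DF"] == 0)]
        return float(after["tick"].iloc[0]) if len(after) else float("nan")

    def repair_complete_time(self) -> float:
        """First post-injury hour with fibril count back at pre-injury level."""
        if self.injury_tick is None:
            return float("nan")
        df = self.census
        after = df[
            (df["tick"] > self.injury_tick)
            & (df["fibril_count"] >= self.pre_injury_fibrils)
        ]
        return float(after["tick"].iloc[0]) if len(after) else float("nan")


_CENSUS_COLS = ("N", "PM", "AM", "Fb", "SC_q", "SC_a", "MB", "DE", "DF")


def run_simulation(grid: TissueGrid, config: SimConfig,
                   seed: int | np.random.SeedSequence = 0,
                   copy_grid: bool = True) -> SimResult:
    """Run one replicate for ``config.ticks`` hours and return its logs.

    Damage (if any) must already be seeded on the grid (see
    ``experiments.run_iteration``); injury is detected at the first tick at
    which damaged pixels exist.  Once the tissue reaches a state from which
    no rule can fire again, the remaining census rows are constant and are
    filled without stepping (disable with ``config.steady_state_exit``).
    """
    g = grid.copy() if copy_grid else grid
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
        seed_repr = seed.entropy if isinstance(seed.entropy, int) else 0
    else:
        rng = np.random.default_rng(seed)
        seed_repr = int(seed)
    state = initialize(g, config, rng)
    for _ in range(config.ticks):
        step(state)
        if config.steady_state_exit and _quiescent(state):
            break
    # pad logs out to the full horizon (steady state: census is constant)
    while len(state.census_log) < config.ticks + 1:
        state.tick += 1
        state.cyt = update_cytokines(state.cyt, state.census_log[-1])
        _log(state)

    rows = []
    for t, (c, (fc, ec)) in enumerate(zip(state.census_log, state.tissue_log)):
        rows.append(
            (t, c.N, c.PM, c.AM, c.Fb, c.SC_q, c.SC_a, c.MB, c.DE, c.DF, fc, ec)
        )
    census = pd.DataFrame(
        rows, columns=("tick",) + _CENSUS_COLS + ("fibril_count", "ecm_count")
    )
    cyt = pd.DataFrame(state.cyt_log)
    cyt.insert(0, "tick", np.arange(len(cyt)))
    return SimResult(
        census=census,
        cytokines=cyt,
        grid=g,
        config=config,
        seed=seed_repr,
        injury_tick=state.injury_tick,
        pre_injury_fibrils=state.pre_injury_fibrils,
    )
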