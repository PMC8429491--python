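"""Secreted-factor pools, local fields, and the per-hour secretion rates.

Five factors steer the agent rules: IGF-1 (satellite-cell proliferation),
TNF-α (inflammation bookkeeping), TGF-β (fibroblast activation), HGF
(satellite-cell activation) and IL-6 (macrophage chemotaxis).  Global pools
integrate the census-driven secretion rates (units are arbitrary and differ
by orders of magnitude between factors; only signs, gradients and arg-max
comparisons feed back into agent behavior, so no unit conversion is
attempted).  IL-6 and TGF-β additionally keep sparse local fields so agents
can chemotax toward damage sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FACTORS = ("IGF1", "TNFa", "TGFb", "HGF", "IL6")
LOCAL_FACTORS = ("IL6", "TGFb")

# Moore-neighborhood scan order used for all tie-breaking:
# N, E, S, W, NE, SE, SW, NW, then self.
MOORE_ORDER = (
    (0, -1), (1, 0), (0, 1), (-1, 0),
    (1, -1), (1, 1), (-1, 1), (-1, -1),
)


@dataclass
class CellCensus:
    """Per-tick counts of the mobile agent classes and damaged objects."""

    N: int = 0  # neutrophils
    PM: int = 0  # pro-inflammatory (M1) macrophages
    AM: int = 0  # anti-inflammatory (M2) macrophages
    Fb: int = 0  # fibroblasts
    SC_q: int = 0  # quiescent satellite cells
    SC_a: int = 0  # active satellite cells
    MB: int = 0  # myoblasts
    DE: int = 0  # damaged ECM components
    DF: int = 0  # damaged fibrils

    def validate(self) -> None:
        for name in ("N", "PM", "AM", "Fb", "SC_q", "SC_a", "MB", "DE", "DF"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative census count {name}")

    @property
    def SC(self) -> int:
        return self.SC_q + self.SC_a


def secretion_rates(census: CellCensus) -> dict:
    """Per-hour secretion rate of each factor for a frozen census.

    ΔIGF-1 = 2·(8.8e-5·AM);  ΔTNF-α = 3.21e-12 + 5.8e-12·N + 1.25e-9·PM
    + 4.9e-18·Fb;  ΔTGF-β = 8.75e-3·AM;  ΔHGF = 1.49e-7·DE;
    ΔIL-6 = 2.91e-12 + 1.25e-12·N + 1.25e-12·PM.
    """
    census.validate()
    return {
        "IGF1": 2.0 * (8.8e-5 * census.AM),
        "TNFa": 3.21e-12 + 5.8e-12 * census.N + 1.25e-9 * census.PM
        + 4.9e-18 * census.Fb,
        "TGFb": 8.75e-3 * census.AM,
        "HGF": 1.49e-7 * census.DE,
        "IL6": 2.91e-12 + 1.25e-12 * census.N + 1.25e-12 * census.PM,
    }


@dataclass
class CytokineState:
    """Global pools, previous-tick snapshots, and optional local fields."""

    pools: dict = field(default_factory=lambda: {f: 0.0 for f in FACTORS})
    prev_pools: dict | None = None
    local: dict = field(default_factory=dict)  # factor -> (H, W) float array
    decay_per_hour: float = 0.0  # first-order decay, default none

    def ensure_local(self, shape) -> None:
        for f in LOCAL_FACTORS:
            if f not in self.local:
                self.local[f] = np.zeros(shape)

    def copy(self) -> "CytokineState":
        return CytokineState(
            pools=dict(self.pools),
            prev_pools=None if self.prev_pools is None else dict(self.prev_pools),
            local={k: v.copy() for k, v in self.local.items()},
            decay_per_hour=self.decay_per_hour,
        )


def update_cytokines(
    state: CytokineState, census: CellCensus, dt_hours: float = 1.0
) -> CytokineState:
    """Advance the pools by their printed rates × dt (decay applied after).

    Returns a new state; snapshots the incoming pools so gradient queries
    compare against the previous tick.
    """
    if dt_hours <= 0:
        raise ValueError("dt_hours must be positive")
    rates = secretion_rates(census)
    new = state.copy()
    new.prev_pools = dict(state.pools)
    for f in FACTORS:
        val = state.pools[f] + rates[f] * dt_hours
        if state.decay_per_hour > 0:
            val *= (1.0 - state.decay_per_hour) ** dt_hours
        new.pools[f] = max(0.0, val)
    return new


def deposit_local(
    state: CytokineState, pixel, factor: str, amount: float
) -> CytokineState:
    """Add ``amount`` of a factor at ``pixel`` (x, y), locally and globally."""
    if factor not in LOCAL_FACTORS:
        raise ValueError(f"no local field for factor {factor}")
    if amount < 0:
        raise ValueError("deposit amount must be nonnegative")
    x, y = pixel
    fld = state.local[factor]
    if not (0 <= x < fld.shape[1] and 0 <= y < fld.shape[0]):
        raise ValueError(f"pixel ({x},{y}) outside grid")
    fld[y, x] += amount
    state.pools[factor] += amount
    return state


def diffuse_local(state: CytokineState, weight: float = 0.1) -> None:
    """One mass-conserving 4-neighbor smoothing step of the local fields.

    Each pixel sends ``weight`` of its content to each in-bounds neighbor;
    flux at the canvas boundary stays in place, so total mass is conserved.
    """
    if weight <= 0:
        return
    if weight > 0.25:
        raise ValueError("diffusion weight must be <= 0.25 for stability")
    for f, fld in state.local.items():
        out = fld.copy()
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            moved = np.roll(fld, shift, axis=axis) * weight
            # cancel wrap-around: mass may not cross the canvas edge
            if axis == 0 and shift == 1:
                moved[0, :] = 0.0
            elif axis == 0 and shift == -1:
                moved[-1, :] = 0.0
            elif axis == 1 and shift == 1:
                moved[:, 0] = 0.0
            else:
                moved[:, -1] = 0.0
            out += moved
        sent = np.full(fld.shape, 4.0)
        for edge in (np.s_[0, :], np.s_[-1, :], np.s_[:, 0], np.s_[:, -1]):
            sent[edge] -= 1.0
        out -= fld * weight * sent
        state.local[f] = out


def gradient_positive(state: CytokineState, factor: str) -> bool:
    """True if the global pool strictly rose since the previous tick.

    On the first tick (no snapshot) the gradient is treated as non-positive.
    """
    if state.prev_pools is None:
        return False
    return state.pools[factor] > state.prev_pools[factor]


def local_max_neighbor(state: CytokineState, factor: str, pixel) -> tuple:
    """Moore-neighborhood arg-max of a local field around ``pixel``.

    Scans N, E, S, W, NE, SE, SW, NW, then self; a later candidate must be
    strictly greater to win, so uniform fields return the first neighbor.
    """
    fld = state.local[factor]
    x, y = pixel
    best = None
    best_val = -np.inf
    for dx, dy in MOORE_ORDER + ((0, 0),):
        nx, ny = x + dx, y + dy
        if not (0 <= nx < fld.shape[1] and 0 <= ny < fld.shape[0]):
            continue
        if fld[ny, nx] > best_val:
            best_val = float(fld[ny, nx])
            best = (nx, ny)
    return best
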