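"""Strain → damage → regeneration experiment drivers.

Each *iteration* of the coupled model computes a strain field on the current
geometry, seeds damage at the highest-strain fibrils (plus a necrotic halo),
runs a batch of replicate agent-based simulations of the 28-day regeneration
time course, and carries the representative endpoint geometry (the replicate
whose endpoint fibril count is nearest the replicate mean) into the next
iteration.  Three iterations emulate three monthly damage/regeneration
cycles; the typically developing (TD) and cerebral palsy (CP) milieus differ
only in their initial satellite-cell count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .abm import SimConfig, SimResult, run_simulation
from .geometry import TissueGrid, compute_composition
from .mechanics import (
    ConstitutiveParams,
    ECM_PARAMS,
    FIBER_PARAMS,
    StrainField,
    expand_necrosis,
    import_strain_table,
    select_damage,
    surrogate_strain_field,
)


def replicate_mean_series(replicates, column: str) -> np.ndarray:
    """Per-tick mean of one census column across replicate runs."""
    return np.mean([r.census[column].to_numpy() for r in replicates], axis=0)


def peak_tick(series: np.ndarray) -> int:
    """Tick of the series maximum (first occurrence)."""
    return int(np.argmax(series))


def decline_onset(series: np.ndarray, smooth_window: int = 9) -> float:
    """First tick after the global maximum where the smoothed series falls.

    The series is box-smoothed; returns NaN if it never strictly decreases
    after its maximum.
    """
    kernel = np.ones(smooth_window)
    sm = np.convolve(series, kernel, mode="same") / np.convolve(
        np.ones_like(series), kernel, mode="same"
    )
    start = int(np.argmax(sm))
    for t in range(start + 1, len(sm)):
        if sm[t] < sm[t - 1]:
            return float(t)
    return math.nan


@dataclass
class IterationResult:
    """Aggregate of one damage/regeneration cycle over all replicates."""

    index: int
    endpoint_grid: TissueGrid
    replicates: list  # list[SimResult]
    summary: dict
    clearance_time_h: float
    repair_complete_time_h: float
    representative: int  # replicate index of the carried-forward geometry

    def mean_series(self, column: str) -> np.ndarray:
        return np.mean(
            [r.census[column].to_numpy() for r in self.replicates], axis=0
        )


def _reset_for_new_cycle(grid: TissueGrid) -> TissueGrid:
    """Prepare an endpoint geometry to serve as the next cycle's input.

    Residual flags are dropped; any pixel still cleared at the end of a
    cycle has scarred over and is treated as ECM from then on.
    """
    g = grid.copy()
    leftover = g.cleared_mask
    g.ecm[leftover] = True
    g.collagen[leftover] = 1.0
    # scar is permanent ECM: it no longer belongs to a fiber, so damage in a
    # later cycle cannot be regenerated back into fibril tissue
    g.owner[g.ecm] = 0
    g.damaged[:] = False
    g.needs_repair[:] = False
    return g


def _seed_damage(
    grid: TissueGrid,
    config: SimConfig,
    strain_source,
    rng: np.random.Generator,
    p_fiber: ConstitutiveParams,
    p_ecm: ConstitutiveParams,
) -> TissueGrid:
    """Copy the grid and mark damage + necrotic halo on the copy."""
    g = grid.copy()
    if config.damage_fraction <= 0:
        return g
    if isinstance(strain_source, StrainField):
        field = strain_source
        seeds = select_damage(field, g, config.damage_fraction)
    elif strain_source == "surrogate":
        field = surrogate_strain_field(
            g, p_fiber=p_fiber, p_ecm=p_ecm,
            seed=int(rng.integers(2**31 - 1)),
        )
        seeds = select_damage(field, g, config.damage_fraction)
    elif strain_source == "random":
        # optional placement mode: damage scattered uniformly over fibrils
        fib = g.fibril_mask
        n = math.ceil(config.damage_fraction * int(fib.sum()))
        ys, xs = np.nonzero(fib)
        idx = rng.choice(len(xs), size=n, replace=False)
        seeds = {(int(xs[i]), int(ys[i])) for i in idx}
    else:
        raise ValueError(f"unknown strain source {strain_source!r}")
    expand_necrosis(g, seeds, damaged_collagen=config.damaged_collagen)
    return g


def run_iteration(
    grid: TissueGrid,
    config: SimConfig,
    strain_source="surrogate",
    rng: np.random.Generator | None = None,
    index: int = 1,
    p_fiber: ConstitutiveParams = FIBER_PARAMS,
    p_ecm: ConstitutiveParams = ECM_PARAMS,
) -> IterationResult:
    """One strain→damage→regeneration cycle over ``config.replicates`` runs.

    Each replicate re-samples both the strain-field noise (hence the damage
    placement) and all agent stochasticity from an independent child seed.
    ``strain_source`` may be "surrogate", "random", or a fixed
    :class:`StrainField` (e.g. imported from an external solver table).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    results: list[SimResult] = []
    for _ in range(config.replicates):
        damaged_grid = _seed_damage(grid, config, strain_source, rng,
                                    p_fiber, p_ecm)
        child = int(rng.integers(2**31 - 1))
        results.append(
            run_simulation(damaged_grid, config, seed=child, copy_grid=False)
        )

    endpoints = np.array(
        [r.census["fibril_count"].iloc[-1] for r in results], dtype=float
    )
    mean_end = endpoints.mean()
    rep = int(np.argmin(np.abs(endpoints - mean_end)))  # ties: lowest index

    comps = [compute_composition(r.grid) for r in results]
    summary = {
        "fibril_mean": mean_end,
        "fibril_sd": float(endpoints.std(ddof=1)) if len(endpoints) > 1 else 0.0,
        "ecm_mean": float(np.mean([c.ecm_count for c in comps])),
        "ecm_sd": float(np.std([c.ecm_count for c in comps], ddof=1))
        if len(comps) > 1 else 0.0,
        "muscle_fraction_mean": float(np.mean([c.muscle_fraction for c in comps])),
        "ecm_fraction_mean": float(np.mean([c.ecm_fraction for c in comps])),
        "mean_fiber_csa": float(np.mean([c.mean_fiber_csa for c in comps])),
        "initial_fibrils": float(results[0].pre_injury_fibrils),
    }
    clearance = np.array([r.clearance_time() for r in results])
    repair = np.array([r.repair_complete_time() for r in results])

    def _mean_finite(arr: np.ndarray) -> float:
        finite = arr[np.isfinite(arr)]
        return float(finite.mean()) if len(finite) else math.nan

    return IterationResult(
        index=index,
        endpoint_grid=results[rep].grid,
        replicates=results,
        summary=summary,
        clearance_time_h=_mean_finite(clearance),
        repair_complete_time_h=_mean_finite(repair),
        representative=rep,
    )


def run_coupled(
    initial_grid: TissueGrid,
    config: SimConfig,
    n_iterations: int = 3,
    rng: np.random.Generator | None = None,
    strain_source="surrogate",
    p_fiber: ConstitutiveParams = FIBER_PARAMS,
    p_ecm: ConstitutiveParams = ECM_PARAMS,
) -> list[IterationResult]:
    """Iterate damage/regeneration cycles, re-straining the evolved geometry.

    Constitutive parameters are held fixed across iterations and milieus;
    only the geometry (and hence the strain field and damage placement)
    evolves.  A fiber shrinking toward extinction is an expected outcome of
    the CP milieu (atrophy), not an error.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = initial_grid
    out: list[IterationResult] = []
    for k in range(1, n_iterations + 1):
        res = run_iteration(
            grid, config, strain_source=strain_source, rng=rng, index=k,
            p_fiber=p_fiber, p_ecm=p_ecm,
        )
        out.append(res)
        grid = _reset_for_new_cycle(res.endpoint_grid)
        if grid.fibril_count < grid.n_fibers:
            import warnings

            warnings.warn(
                f"iteration {k}: geometry degenerated to "
                f"{grid.fibril_count} fibril pixels", stacklevel=2
            )
    return out


def damage_sweep(
    grid: TissueGrid,
    config: SimConfig,
    fractions=(0.0, 0.05, 0.10, 0.15, 0.20),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Endpoint fibril count and clearance statistics vs damage level."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for frac in fractions:
        cfg = dc_replace(config, damage_fraction=float(frac))
        res = run_iteration(grid, cfg, rng=rng)
        cleared = np.array(
            [r.census["DF"].iloc[-1] == 0 for r in res.replicates]
        )
        rows.append(
            {
                "damage_fraction": frac,
                "endpoint_fibril_mean": res.summary["fibril_mean"],
                "endpoint_fibril_sd": res.summary["fibril_sd"],
                "clearance_success_rate": float(cleared.mean()),
                "clearance_time_mean_h": res.clearance_time_h,
                "residual_damaged_mean": float(
                    np.mean([r.census["DF"].iloc[-1] for r in res.replicates])
                ),
            }
        )
    return pd.DataFrame(rows)


def sc_sweep(
    grid: TissueGrid,
    config: SimConfig,
    sc_counts=(4, 5, 7, 10, 13),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Endpoint fibril count and recovery time vs seeded satellite cells."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for n_sc in sc_counts:
        cfg = dc_replace(config, sc_count_override=int(n_sc))
        res = run_iteration(grid, cfg, rng=rng)
        recovery = np.array([r.repair_complete_time() for r in res.replicates])
        rows.append(
            {
                "sc_count": n_sc,
                "endpoint_fibril_mean": res.summary["fibril_mean"],
                "endpoint_fibril_sd": res.summary["fibril_sd"],
                "recovery_time_mean_h": float(np.nanmean(recovery))
                if np.isfinite(recovery).any() else math.inf,
                "recovered_rate": float(np.isfinite(recovery).mean()),
            }
        )
    return pd.DataFrame(rows)


_SENSITIVITY_PARAMS = ("c1", "c3", "c4", "c5", "K", "density")


def material_sensitivity(
    grid: TissueGrid,
    p_fiber: ConstitutiveParams = FIBER_PARAMS,
    p_ecm: ConstitutiveParams = ECM_PARAMS,
    delta: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """±10% perturbation of each material constant vs surrogate strain range.

    Each parameter is varied simultaneously for the fiber and ECM materials
    (they share every constant except c1); the same noise seed is reused so
    percentage changes isolate the material effect.  Only the sign and the
    ordering of the changes are meaningful at this level of model.
    """
    base = surrogate_strain_field(grid, p_fiber=p_fiber, p_ecm=p_ecm, seed=seed)
    b_max, b_min = base.max(), base.min()
    rows = []
    for name in _SENSITIVITY_PARAMS:
        for sign in (+1, -1):
            factor = 1.0 + sign * delta
            pf = p_fiber.replace(**{name: getattr(p_fiber, name) * factor})
            pe = p_ecm.replace(**{name: getattr(p_ecm, name) * factor})
            fld = surrogate_strain_field(grid, p_fiber=pf, p_ecm=pe, seed=seed)
            rows.append(
                {
                    "parameter": name,
                    "delta": sign * delta,
                    "pct_change_max_strain": 100.0 * (fld.max() - b_max) / b_max,
                    "pct_change_min_strain": 100.0 * (fld.min() - b_min) / b_min,
                }
            )
    return pd.DataFrame(rows)


def summarize(results: list, outdir=None, plots: bool = False) -> dict:
    """Collect iteration results into tidy tables (and optional figures).

    Returns a dict of DataFrames: ``iterations`` (endpoint summaries and
    timing), ``census`` (replicate-mean trajectories per iteration), and
    writes them as CSV under ``outdir`` when given.
    """
    tables: dict[str, pd.DataFrame] = {}
    if not results:
        tables["iterations"] = pd.DataFrame()
        return tables
    it_rows = []
    census_frames = []
    for res in results:
        it_rows.append(
            {
                "iteration": res.index,
                **res.summary,
                "clearance_time_h": res.clearance_time_h,
                "repair_complete_time_h": res.repair_complete_time_h,
                "representative_replicate": res.representative,
            }
        )
        mean_df = (
            pd.concat([r.census for r in res.replicates])
            .groupby("tick")
            .mean()
            .reset_index()
        )
        mean_df.insert(0, "iteration", res.index)
        census_frames.append(mean_df)
    tables["iterations"] = pd.DataFrame(it_rows)
    tables["census"] = pd.concat(census_frames, ignore_index=True)
    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        if plots:
            _plot_trajectories(tables["census"], outdir)
    return tables


def _plot_trajectories(census: pd.DataFrame, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 8), sharex=True)
    for it, sub in census.groupby("iteration"):
        axes[0].plot(sub["tick"], sub["fibril_count"], label=f"iteration {it}")
        axes[1].plot(sub["tick"], sub["N"], label=f"N (it {it})")
        axes[1].plot(sub["tick"], sub["PM"] + sub["AM"], label=f"Mφ (it {it})")
        axes[1].plot(sub["tick"], sub["SC_q"] + sub["SC_a"], label=f"SC (it {it})")
    axes[0].set_ylabel("fibril count")
    axes[1].set_ylabel("cell count")
    axes[1].set_xlabel("hours post injury")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "trajectories.png", dpi=120)
    plt.close(fig)
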