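# myoregen

Coupled mechanobiological simulation of skeletal-muscle damage and
regeneration, built to explore why muscle in cerebral palsy (CP)
progressively degenerates while typically developing (TD) muscle recovers
from the same mechanical injury.

The package is aimed at computational-biology and mechanobiology
researchers who want a fully scriptable, reproducible re-implementation of
a coupled finite-element-inspired / agent-based muscle regeneration model:
a 2D fiber-bundle cross-section (20 fibers, ~9,864 fibril pixels at
6.45 µm²/pixel, ~15.8% ECM) is strained in silico by an eccentric
contraction surrogate, the highest-strain 10% of fibril pixels become
necrotic, and an hourly-tick agent-based model of neutrophils, M1/M2
macrophages, satellite cells (SCs), myoblasts, fibroblasts and five
secreted factors (IGF-1, TNF-α, TGF-β, HGF, IL-6) plays out 28 days of
regeneration. Iterating strain → damage → regeneration three times
simulates three months of monthly injury. The TD and CP milieus differ only
in seeded satellite cells — `0.10` vs `0.04` per fiber per 10 µm of slice,
i.e. 10 vs 4 cells on the standard bundle:

    SC count = density × n_fibers × slice_thickness/10  →  0.10 × 20 × 5 = 10

Secreted factors follow per-hour secretion rates (AM = M2 macrophages,
N = neutrophils, PM = M1 macrophages, Fb = fibroblasts, DE = damaged ECM):

    dIGF-1/dt = 2(8.8e-5·AM)          dTGF-β/dt = 8.75e-3·AM
    dTNF-α/dt = 3.21e-12 + 5.8e-12·N + 1.25e-9·PM + 4.9e-18·Fb
    dHGF/dt   = 1.49e-7·DE            dIL-6/dt  = 2.91e-12 + 1.25e-12·(N+PM)

Fiber and ECM mechanics use a transversely isotropic Mooney–Rivlin model
with an exponential-toe fiber family (closed-form stress λ̃·∂F2/∂λ̃ and
energy F2 via the exponential integral) and a time-varying elastance active
stress; see `docs/methods.md` for the full model description and every
default parameter.

## Worked example

```python
import numpy as np
from myoregen import SimConfig, compute_composition, generate_synthetic_bundle
from myoregen.experiments import peak_tick, replicate_mean_series, run_iteration

grid = generate_synthetic_bundle(20, 9864, 0.158, seed=1)
comp = compute_composition(grid)
print(f"bundle: {comp.fibril_count} fibril px, {comp.ecm_count} ECM px "
      f"({100*comp.ecm_fraction:.1f}% ECM), mean fiber CSA {comp.mean_fiber_csa:.0f} um2")

cfg = SimConfig(sc_per_fiber_per_10um=0.10, replicates=20, seed=1)
res = run_iteration(grid, cfg)          # strain -> 10% damage -> 672 h ABM, x20
n_peak = peak_tick(replicate_mean_series(res.replicates, "N"))
mac = (replicate_mean_series(res.replicates, "PM")
       + replicate_mean_series(res.replicates, "AM"))
print(f"neutrophil peak at t={n_peak} h, macrophage peak at t={peak_tick(mac)} h")
print(f"damage cleared by t={res.clearance_time_h:.1f} h (mean), "
      f"fibrils restored by t={res.repair_complete_time_h:.1f} h")
print(f"endpoint fibril count {res.summary['fibril_mean']:.0f} +/- "
      f"{res.summary['fibril_sd']:.0f} (initial {res.summary['initial_fibrils']:.0f})")
```

prints

```
bundle: 9864 fibril px, 1852 ECM px (15.8% ECM), mean fiber CSA 3181 um2
neutrophil peak at t=21 h, macrophage peak at t=37 h
damage cleared by t=48.2 h (mean), fibrils restored by t=114.2 h
endpoint fibril count 9936 +/- 45 (initial 9864)
```

i.e. the canonical regeneration cascade: a neutrophil burst peaking within
the first day, macrophage invasion peaking around day two, necrotic tissue
cleared well inside 90 h, the fibril count restored inside the 216-hour
repair horizon, and mild emergent hypertrophy (+0.7%) because active
satellite cells remain once repair completes. Running the same experiment
with `sc_per_fiber_per_10um=0.04` (the CP milieu) leaves repair
incomplete; fibroblasts fibrose the unrepaired territory and the fibril
count ends *below* its starting point — iterating three coupled cycles
(`run_coupled`) drives the divergence (TD grows, CP loses fibrils and
accumulates ECM toward ~20% of tissue area).

## Command line

The same experiments are scriptable from a shell:

```bash
myoregen generate --n-fibers 20 --fibrils 9864 --ecm-fraction 0.158 --seed 1 --out grid.csv
myoregen strain   --grid grid.csv --out strain.csv
myoregen simulate --grid grid.csv --replicates 20 --seed 1 --outdir run/
myoregen couple   --grid grid.csv --milieu cp --replicates 20 --seed 2 --outdir cp_run/
myoregen sweep-damage --grid grid.csv --replicates 12 --outdir sweeps/
myoregen sweep-sc     --grid grid.csv --replicates 20 --outdir sweeps/
myoregen sensitivity  --grid grid.csv --outdir sens/
```

All outputs are CSV/PNG plus a plain-text run manifest recording the full
configuration and seed.

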