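# Model and methods

`myoregen` couples a closed-form constitutive surrogate for eccentric-
contraction strain with an hourly-tick agent-based model (ABM) of skeletal-
muscle damage and regeneration on a 2D fiber-bundle cross-section. Repeated
strain → damage → regeneration cycles contrast a typically developing (TD)
muscle milieu with a cerebral palsy (CP) milieu; the two differ **only** in
the number of seeded satellite cells (SCs): 10 vs 4 on the standard 20-fiber,
50 µm-thick bundle (0.10 vs 0.04 SCs per fiber per 10 µm of slice).

## Tissue geometry

The environment is a pixel lattice (6.45 µm²/pixel) of ~11,700 tissue
pixels: 20 fibers (~9,864 fibril pixels, each a 4-connected region with a
fiber id) embedded in an ECM septum network (~15.8% of tissue area). The
synthetic generator replaces a segmented histological section: fibers are
Lloyd-relaxed Voronoi cells, a mandatory one-pixel ECM wall separates every
fiber pair, and the remaining ECM budget is assigned to the pixels nearest a
Voronoi bisector or the canvas edge, thresholded at the order statistic that
meets the ECM-fraction target to within one pixel. The generator is
deterministic per seed and raises on infeasible targets rather than
silently clipping.

What the generator emulates: fiber-area distribution, septum topology, and
corner/boundary fibers of a real bundle. What it does not: real fiber shape
irregularity, capillaries, neuromuscular junctions, or any biological
heterogeneity between fibers beyond geometry. Passing tests on this
geometry therefore demonstrate the *mechanistic* behavior of the rules, not
agreement with any individual histological section; absolute endpoint counts
from the original segmented image are not reproducible here.

## Mechanics surrogate

Fibers and ECM are transversely isotropic Mooney–Rivlin materials
(c1 fiber/ECM = 15/0.5, c2 = 0, c3 = 2, c4 = 60, c5 = 600, K = 1000,
density = 1). The fiber-family energy F2 has an exponential toe evaluated
with the exponential integral Ei and a linear branch above the transition
stretch λm; the continuity constant c6 is always derived from
c5·λm + c6 = c3(e^{c4(λm−1)}−1). λm is not published; the default 1.06
places the toe in the working range and is configuration-exposed. Active
contraction follows the time-varying elastance model (Tmax = 135.7 kPa,
(Ca0)max = 4.35 µM, B = 4.75 µm⁻¹, l0 = 1.58 µm, refl = 2.04 µm) with the
standard calcium-sensitivity form ECa50 = (Ca0)max/√(e^{B(l−l0)}−1); a
published literal rendering of that expression is available behind a flag
but is dimensionally doubtful, and neither is claimed to match any
particular solver.

No equilibrium problem is solved. Downstream the mechanics only *rank*
pixels by strain, so the surrogate field for a 30% imposed stretch is
`strain = stretch × exposure × corner_amp × compliance × lognormal noise`:
exposure decays exponentially with a pixel's depth from the bundle
boundary (length scale 12% of the bundle width), corner amplification
boosts fibers near the convex-hull corners, and compliance is the inverse
bundle tangent stiffness at 1+stretch normalised to the nominal material.
Depth is evaluated per pixel (not per fiber) so the top-decile strain set
forms a boundary band rather than engulfing whole fibers. The tangent adds
small weighted contributions of the ground substance (0.02·(c1+c2)) and
bulk modulus (0.004·K) so that ±10% parameter sweeps reproduce the known
sensitivity structure: c5 dominates with the correct signs, density has no
effect, c1/c3/c4/K stay below 1%. Only that ordering is meaningful; exact
percentage changes would require the original mesh. Per-pixel noise is
lognormal with σ = 0.05 and is re-sampled per replicate, as is agent
stochasticity. External strain tables (CSV `x,y,strain`, element centers in
pixel coordinates) can replace the surrogate; values map to fibril pixels
by nearest-center lookup.

Damage seeding marks the highest-strain ⌈f·N_fibril⌉ pixels (ties broken in
row-major order) and extends a necrotic halo over their von Neumann
neighborhoods; halo ECM drops to collagen density 0.2. At the standard
f = 0.10 this yields ≈2,300 damaged pixels on the calibrated bundle.

## Agent rules (one tick = one hour)

Update order within a tick is fixed: cytokines → neutrophils → macrophages
→ satellite cells/myoblasts → fibroblasts → border re-formation and
hypertrophy → census. Cytokine pools integrate the per-hour secretion
rates (all in arbitrary units, used only for signs, gradients and arg-max
searches):

    dIGF-1/dt = 2(8.8e-5·AM)        dTGF-β/dt = 8.75e-3·AM
    dTNF-α/dt = 3.21e-12 + 5.8e-12·N + 1.25e-9·PM + 4.9e-18·Fb
    dHGF/dt   = 1.49e-7·DE          dIL-6/dt  = 2.91e-12 + 1.25e-12·(N+PM)

Global pools gate temporal behavior (HGF rising activates quiescent SCs;
a positive IGF-1 gradient opens the proliferative window; a positive TGF-β
gradient activates fibroblasts), while sparse local IL-6/TGF-β fields
support spatial chemotaxis. Movement is distance-field descent toward the
relevant target set with a substantial random tie-break (0.45) that spreads
crowded agents along a front; inflammatory cells move 4 px/h and may
infiltrate through intact fibril pixels, stromal cells move 3 px/h.

**Neutrophils** (5 resident + systemic influx of 10/h waning linearly over
27 h; mean lifespan 17 h) chemotax to damage, mark contacted objects as
needing repair, release IL-6 locally, proliferate weakly on contact, and
break down damaged pixels. **Macrophages** (5 resident + influx of 4.2/h
building over 33 h and waning over 12 h) phagocytose damaged fibrils and
ECM. Each phagocyte carries a finite lifetime phagocytic capacity
(neutrophil 6 px, macrophage 24 px — a pixel is far sub-cellular, so these
are debris masses, not object counts); proliferation splits the parent's
remaining capacity and a dying cell's residue passes to its peers, so the
*recruited capacity of the lesion* is what bounds cumulative clearance.
This is the model's limit on repairable injury: 5–15% damage clears fully,
20% exhausts the response and leaves residual necrosis, matching the
documented failure mode. When the last damaged object is gone, M1
macrophages switch to M2; M2 lifespans are skewed short (u³ on 0–64 h) with
one full-range "resident" M2, so macrophage counts peak at the switch while
the anti-inflammatory window always spans ~64 h regardless of how many
cells survive to the switch.

**Satellite cells** start quiescent on border fibrils and activate while
HGF rises. Division requires 18 h of activation age and a positive IGF-1
gradient and succeeds with probability p(d) = 0.5·0.8^min(d,3)·(0.6 if d≥4)
after d completed divisions. Division type is symmetric-SC (0.40),
symmetric-myoblast (0.27) or asymmetric (0.33), with a niche-homeostasis
floor: a pool at or below its seeded size divides asymmetrically instead of
differentiating, which keeps small (CP) pools from stochastic extinction
without letting large pools explode. While the IGF-1 window is open, active
SCs also place myoblasts at a rate saturating at one per seeded SC per
hour — the steady regenerative supply channel. **Myoblasts** migrate to the
debrided front (each holds a persistent randomly assigned front pixel, so
the pool covers the whole front) and fuse, regrowing up to 6 pixels each
before they are spent; fusion sites must be clear of adjacent necrosis and
anchored on intact same-fiber tissue or on intact ECM (the ghost-fiber
basal-lamina scaffold, which lets a fully necrosed fiber segment regrow).
Total regenerative supply is therefore ≈ seeded SCs × window length ×
yield: ≈2,500 pixels for the 4-cell CP milieu against a ≈2,300-pixel
demand × (shares with fibrosis, below) — the supply just misses for 4 SCs,
barely suffices for 5, and is ample from 7 upward, producing the threshold
nonlinearity in the SC sweep.

**Fibroblasts** (9 seeded on ECM) become myofibroblasts on a positive TGF-β
gradient and deposit collagen on cleared ECM-owned pixels at damaged ECM
edges. Once no active SCs remain after the proliferative window has closed,
they fill *any* remaining cleared space — the fibrosis mechanism that
converts unrepaired fibril territory to ECM in the CP milieu. After the
pre-injury fibril count is restored, fiber borders re-form and each active
SC may add a fibril pixel into adjacent ECM (probability 0.04/h, consuming
myoblast fusion capacity — myonuclear accretion); growth is only legal
where it cannot make two fibers 4-adjacent, so at least a 1-pixel septum
always survives.

## Coupled cycles

Each iteration recomputes strain on the current geometry, seeds damage,
runs `replicates` independent 672-tick simulations, and carries forward
the replicate whose endpoint fibril count is nearest the replicate mean
(ties → lowest replicate index). Between cycles residual cleared pixels
scar over as permanent ECM (their fiber ownership is dropped), so fibrosis
is irreversible across cycles; constitutive parameters are held fixed
across iterations and milieus. Agents are reseeded each cycle.

## Emergent time course

With default parameters the standard TD 10%-damage run reproduces the
canonical cascade: neutrophils peak at ~20 h, macrophages at ~40 h, all
damaged fibrils clear by ~50 h (well inside 90 h), the satellite-cell
census rises through the IGF-1 window and begins declining at ~115–125 h,
fibril count is restored by ~120 h (inside 216 h) and ends ~0.4–0.9% above
baseline through hypertrophy. The CP milieu under identical strain leaves a
supply deficit each cycle, declines strictly across three iterations and
accumulates ECM to ~20% of tissue area. Parameters the source physiology
does not pin down (influx rates, lifespans, capacities, fusion yield,
hypertrophy rate) were calibrated once against this documented surface and
are frozen as `SimConfig` defaults; all are configuration-exposed.

## Numerical choices and scale

Simulations are exactly reproducible per seed (NumPy `default_rng`;
replicate seeds are spawned from the master seed). Pixel ties in damage
selection break in row-major order; Moore-neighborhood searches scan
N, E, S, W, NE, SE, SW, NW, then self. Once no rule can fire again the
remaining census rows are constant and are filled without stepping, which
keeps a 672-tick replicate near 0.5 s. Batch experiments default to 150
replicates per the study design; the packaged tests and the acceptance
script use 20-replicate batches (and 12–24 for sweeps), which give
standard errors of a few tens of fibril pixels — sufficient for every
ordering and timing property asserted.

## Known limitations

- The mechanics surrogate ranks strain; it is not an equilibrium solution,
  so only sensitivity *orderings* and damage placement are meaningful.
- Cytokine fields have no physical diffusivities or units; receptor
  kinetics, capillary-localised sources and systemic transport are absent.
- The 15% damage level clears in most but not all replicates; the
  clearance capacity ceiling is intentionally placed between the 15% and
  20% demands, and replicate noise straddles it at 15%.
- Endpoint census counts depend on the synthetic geometry; only relative
  (TD vs CP, sweep-ordering, timing) statements transfer to real sections.
- Hypertrophy, fibrosis and repair compete only through pixel bookkeeping;
  there is no mechanical feedback of ECM stiffening on strain within a
  cycle beyond the geometry change itself.
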