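"""Constitutive evaluators and the eccentric-contraction strain surrogate.

Muscle fibers and ECM are transversely isotropic Mooney–Rivlin materials with
an exponential-toe fiber reinforcement.  The fiber-family energy F2 and its
stress response are evaluated in closed form (the toe region involves the
exponential integral Ei); active contraction follows the time-varying
elastance model (maximum isometric tension scaled by a calcium sensitivity
that diverges at slack sarcomere length).

A full nonlinear equilibrium solve is deliberately out of scope: downstream,
the mechanics only *rank* pixels by strain so that the highest-strain
fibrils can be marked damaged.  ``surrogate_strain_field`` reproduces the
qualitative features of the eccentric-stretch solution on a fiber-bundle
cross-section — outer fibers, especially corner fibers, carry the highest
strain, and the field scales with the compliance of the along-fiber response
(dominated by the post-toe modulus c5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import expi


class MechanicsError(ValueError):
    """Raised for invalid constitutive evaluations or strain imports."""


@dataclass
class ConstitutiveParams:
    """Transversely isotropic Mooney–Rivlin material constants.

    ``c1, c2`` are the ground-substance Mooney–Rivlin parameters, ``c3, c4``
    the exponential toe of the fiber family, ``c5`` the post-transition
    along-fiber modulus, ``K`` the bulk modulus.  ``lambda_m`` is the stretch
    at which the fiber response transitions from exponential to linear; the
    continuity constant ``c6`` is derived, never set directly.
    """

    c1: float = 15.0
    c2: float = 0.0
    c3: float = 2.0
    c4: float = 60.0
    c5: float = 600.0
    K: float = 1000.0
    lambda_m: float = 1.06
    density: float = 1.0

    @property
    def c6(self) -> float:
        # continuity of the stress response at lambda_m:
        # c5*lm + c6 = c3*(exp(c4*(lm-1)) - 1)
        lm = self.lambda_m
        return self.c3 * (math.exp(self.c4 * (lm - 1.0)) - 1.0) - self.c5 * lm

    def replace(self, **kw) -> "ConstitutiveParams":
        d = {
            "c1": self.c1, "c2": self.c2, "c3": self.c3, "c4": self.c4,
            "c5": self.c5, "K": self.K, "lambda_m": self.lambda_m,
            "density": self.density,
        }
        d.update(kw)
        return ConstitutiveParams(**d)


FIBER_PARAMS = ConstitutiveParams(c1=15.0)
ECM_PARAMS = ConstitutiveParams(c1=0.5)


@dataclass
class ActiveParams:
    """Time-varying elastance active-contraction constants."""

    Tmax: float = 135.7  # kPa, maximum isometric tension
    Ca0_max: float = 4.35  # µM, peak intracellular calcium
    B: float = 4.75  # 1/µm, length sensitivity
    l0: float = 1.58  # µm, slack sarcomere length (zero active tension)
    refl: float = 2.04  # µm, reference sarcomere length
    ascl: float = 1.0
    Ct: float = 1.0  # activation level C(t) in [0, 1]


def fiber_stress_response(lambda_t, p: ConstitutiveParams):
    """Fiber Cauchy stress contribution λ̃·∂F2/∂λ̃ (piecewise, continuous).

    Zero below identity stretch, exponential toe ``c3(exp(c4(λ̃−1))−1)`` up to
    ``lambda_m``, then linear ``c5·λ̃+c6``.  Accepts scalars or arrays.
    """
    lam = np.asarray(lambda_t, dtype=float)
    if np.any(lam <= 0):
        raise MechanicsError("stretch must be positive")
    toe = p.c3 * (np.exp(p.c4 * (lam - 1.0)) - 1.0)
    out = np.where(
        lam <= 1.0, 0.0, np.where(lam <= p.lambda_m, toe, p.c5 * lam + p.c6)
    )
    return out if out.ndim else float(out)


def fiber_tangent_stiffness(lambda_t: float, p: ConstitutiveParams) -> float:
    """d/dλ̃ of the fiber stress response (used for compliance weights)."""
    if lambda_t <= 1.0:
        return 0.0
    if lambda_t <= p.lambda_m:
        return p.c3 * p.c4 * math.exp(p.c4 * (lambda_t - 1.0))
    return p.c5


def fiber_energy(lambda_t, p: ConstitutiveParams):
    """Fiber-family strain energy F2(λ̃), with Ei via scipy.

    The toe branch is ``c3(e^{−c4}(Ei(c4 λ̃)−Ei(c4)) − ln λ̃)``, whose
    derivative times λ̃ recovers :func:`fiber_stress_response`.
    """
    lam = np.asarray(lambda_t, dtype=float)
    if np.any(lam <= 0):
        raise MechanicsError("stretch must be positive")
    if p.c4 == 0 or np.any(p.c4 * lam == 0):
        raise MechanicsError("exponential integral argument is zero")
    toe = p.c3 * (
        np.exp(-p.c4) * (expi(p.c4 * lam) - expi(p.c4)) - np.log(lam)
    )
    linear = p.c5 * (lam - 1.0) + p.c6 * np.log(lam)
    out = np.where(lam <= 1.0, 0.0, np.where(lam <= p.lambda_m, toe, linear))
    return out if out.ndim else float(out)


def active_tension(l: float, a: ActiveParams, literal_eca50: bool = False) -> float:
    """Active fiber tension Ta(l) from the elastance model, in kPa.

    Ta = Tmax · Ca0² / (Ca0² + ECa50²) · C(t), with the calcium sensitivity
    ECa50 = (Ca0)max / sqrt(exp[B(l−l0)] − 1) diverging at slack length, so
    Ta → 0 as l → l0.  Below slack length Ta is zero by convention.  The
    ``literal_eca50`` flag evaluates ECa50 = Tmax·(Ca0)max·exp[B(l−l0)]−1
    instead (an alternative published rendering of the same model).
    """
    if a.Ct <= 0 or l <= a.l0:
        return 0.0
    e = math.exp(a.B * (l - a.l0)) - 1.0
    if literal_eca50:
        eca50 = a.Tmax * a.Ca0_max * (e + 1.0) - 1.0
    else:
        eca50 = a.Ca0_max / math.sqrt(e)
    ca2 = a.Ca0_max**2
    return a.Tmax * ca2 / (ca2 + eca50**2) * a.Ct


@dataclass
class StrainField:
    """Scalar strain per fibril pixel, aligned to a TissueGrid."""

    values: np.ndarray  # (H, W) float, 0 outside fibril pixels
    mask: np.ndarray  # (H, W) bool, where the field is defined
    source: str = "surrogate"  # or "imported"

    def max(self) -> float:
        return float(self.values[self.mask].max())

    def min(self) -> float:
        return float(self.values[self.mask].min())


DEFAULT_STRETCH = 0.30

# tangent contributions of the ground substance and the volumetric term are
# small compared to the along-fiber modulus; these weights keep their strain
# sensitivity under 1% for ±10% parameter changes, as the full solve shows
_ALPHA_MR = 0.02
_BETA_K = 0.004


def _bundle_tangent(stretch: float, p_fiber: ConstitutiveParams,
                    p_ecm: ConstitutiveParams) -> float:
    lam = 1.0 + stretch
    k = 0.0
    for p in (p_fiber, p_ecm):
        k += fiber_tangent_stiffness(lam, p) + _ALPHA_MR * (p.c1 + p.c2) + _BETA_K * p.K
    return k / 2.0


_REFERENCE_TANGENT = _bundle_tangent(DEFAULT_STRETCH, FIBER_PARAMS, ECM_PARAMS)


def surrogate_strain_field(
    grid,
    stretch: float = DEFAULT_STRETCH,
    p_fiber: ConstitutiveParams = FIBER_PARAMS,
    p_ecm: ConstitutiveParams = ECM_PARAMS,
    seed: int = 0,
    noise_sigma: float = 0.05,
    corner_gain: float = 0.6,
) -> StrainField:
    """Closed-form stand-in for the eccentric-stretch strain solution.

    Per fibril pixel: ``strain = stretch × exposure(fiber) × corner_amp(fiber)
    × compliance × lognormal noise``.  Exposure decays with the fiber's depth
    from the bundle boundary, corner amplification boosts fibers near the
    bundle's convex-hull corners, and compliance is the inverse bundle
    tangent stiffness at ``1+stretch`` normalised to the nominal material.
    """
    fib = grid.fibril_mask
    if not fib.any():
        raise MechanicsError("grid has no fibril pixels")
    if stretch <= 0:
        raise MechanicsError("stretch must be positive")

    # depth of each pixel inside the occupied region (distance to outside)
    occ = np.pad(grid.occupied, 1, constant_values=False)
    depth = ndimage.distance_transform_edt(occ)[1:-1, 1:-1]
    scale = max(2.0, 0.12 * min(grid.width, grid.height))

    ys, xs = np.nonzero(grid.occupied)
    corners = [
        (xs.min(), ys.min()), (xs.max(), ys.min()),
        (xs.min(), ys.max()), (xs.max(), ys.max()),
    ]

    exposure = np.zeros(fib.shape)
    for fid in range(1, grid.n_fibers + 1):
        m = grid.fiber_id == fid
        if not m.any():
            continue
        d = float(depth[m].min())
        my, mx = np.nonzero(m)
        cx, cy = mx.mean(), my.mean()
        dc = min(math.hypot(cx - x0, cy - y0) for x0, y0 in corners)
        amp = 1.0 + corner_gain * math.exp(-dc / (2.0 * scale))
        exposure[m] = math.exp(-(d - 1.0) / scale) * amp

    compliance = _REFERENCE_TANGENT / _bundle_tangent(stretch, p_fiber, p_ecm)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2771]))
    noise = np.ones(fib.shape)
    if noise_sigma > 0:
        noise[fib] = rng.lognormal(mean=0.0, sigma=noise_sigma, size=int(fib.sum()))

    values = np.where(fib, stretch * exposure * compliance * noise, 0.0)
    return StrainField(values=values, mask=fib.copy(), source="surrogate")


def export_strain_table(field: StrainField, path) -> None:
    """Write the field in the strain-CSV dialect (header ``x,y,strain``)."""
    ys, xs = np.nonzero(field.mask)
    with open(str(path), "w") as fh:
        fh.write("x,y,strain\n")
        for x, y in zip(xs, ys):
            fh.write(f"{x},{y},{float(field.values[y, x])!r}\n")


def import_strain_table(path, grid) -> StrainField:
    """Map an external per-element strain table onto fibril pixels.

    Expects CSV with header ``x,y,strain`` giving element centers in grid
    pixel coordinates.  Every fibril pixel receives the strain of its nearest
    element center (ties resolved toward the earlier record).
    """
    import pandas as pd

    table = pd.read_csv(str(path), comment="#")
    required = {"x", "y", "strain"}
    if not required.issubset(table.columns):
        raise MechanicsError(f"{path}: expected columns x,y,strain")
    if len(table) == 0:
        raise MechanicsError(f"{path}: empty strain table")
    oob = table[
        (table.x < 0) | (table.x >= grid.width)
        | (table.y < 0) | (table.y >= grid.height)
    ]
    if len(oob):
        rows = ", ".join(str(i) for i in oob.index[:10])
        raise MechanicsError(
            f"{path}: element centers outside grid bounds at rows {rows}"
        )
    centers = table[["x", "y"]].to_numpy(dtype=float)
    strains = table["strain"].to_numpy(dtype=float)
    fib = grid.fibril_mask
    ys, xs = np.nonzero(fib)
    _, idx = cKDTree(centers).query(np.column_stack([xs, ys]))
    values = np.zeros(fib.shape)
    values[ys, xs] = strains[idx]
    return StrainField(values=values, mask=fib.copy(), source="imported")


def select_damage(field: StrainField, grid, damage_fraction: float) -> set:
    """Pick the highest-strain fibril pixels as damage seeds.

    Exactly ``ceil(damage_fraction × fibril_count)`` pixels, in descending
    strain with ties broken by row-major (y, x) pixel order.  Returns a set
    of (x, y) coordinates; the grid is not modified.
    """
    if not 0.0 <= damage_fraction <= 1.0:
        raise MechanicsError("damage_fraction must lie in [0, 1]")
    fib = grid.fibril_mask
    n = math.ceil(damage_fraction * int(fib.sum()))
    if n == 0:
        return set()
    ys, xs = np.nonzero(fib)
    strains = field.values[ys, xs]
    order = np.lexsort((xs, ys, -strains))
    sel = order[:n]
    return {(int(xs[i]), int(ys[i])) for i in sel}


_N4 = ((0, -1), (1, 0), (0, 1), (-1, 0))


def expand_necrosis(grid, damaged: set, damaged_collagen: float = 0.2) -> set:
    """Extend damage to the von Neumann neighborhood (necrotic halo).

    Propagates only from fibril pixels in ``damaged`` that are not already
    flagged on the grid, so re-applying to an already-expanded set is a
    no-op.  Neighboring fibril pixels are flagged damaged; neighboring ECM
    pixels are flagged damaged and have their collagen density lowered to
    ``damaged_collagen``.  Returns ``damaged`` plus the halo.
    """
    out = set(damaged)
    seeds = [
        (x, y)
        for (x, y) in damaged
        if grid.fiber_id[y, x] > 0 and not grid.damaged[y, x]
    ]
    for x, y in seeds:
        grid.damaged[y, x] = True
    for x, y in seeds:
        for dx, dy in _N4:
            nx, ny = x + dx, y + dy
            if not (0 <= nx < grid.width and 0 <= ny < grid.height):
                continue
            if not grid.occupied[ny, nx]:
                continue
            if grid.fiber_id[ny, nx] > 0:
                grid.damaged[ny, nx] = True
                out.add((nx, ny))
            elif grid.ecm[ny, nx]:
                grid.damaged[ny, nx] = True
                grid.collagen[ny, nx] = min(grid.collagen[ny, nx], damaged_collagen)
                out.add((nx, ny))
    return out
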