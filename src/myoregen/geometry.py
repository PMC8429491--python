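"""Fiber-bundle cross-section grids.

The simulation environment is a 2D pixel lattice standing in for a segmented
histological cross-section of a skeletal-muscle fiber bundle: ~20 fibers
(each a 4-connected set of "fibril" pixels sharing a fiber id) embedded in an
extracellular-matrix (ECM) septum network.  Pixels are square, 6.45 µm² each,
and the slice represents 50 µm of tissue thickness.

Label conventions (also used by the file formats):

* ``0``            EMPTY — canvas outside the tissue, or never used
* ``1..n_fibers``  FIBRIL pixel belonging to that fiber
* ``254``          CLEARED — tissue pixel whose content was removed by
  phagocytosis and not yet repaired (transient, mid-simulation only)
* ``255``          ECM pixel (carries a collagen density in [0, 1])

Coordinates are 0-based ``(x, y)`` with y increasing downward (image
convention); arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

ECM_CODE = 255
CLEARED_CODE = 254
EMPTY_CODE = 0

DEFAULT_PIXEL_AREA = 6.45  # µm² per pixel
DEFAULT_SLICE_THICKNESS = 50.0  # µm


class GridError(ValueError):
    """Raised for malformed grids, infeasible generator targets, or bad files."""


@dataclass
class TissueGrid:
    """Label grid plus per-pixel state for one fiber-bundle cross-section.

    Attributes
    ----------
    fiber_id : (H, W) int16
        Fiber id of each intact fibril pixel; 0 elsewhere.
    ecm : (H, W) bool
        Intact ECM pixels.
    occupied : (H, W) bool
        Fixed tissue footprint (fibril ∪ ECM at creation).  Cleared pixels
        remain occupied; pixels outside are EMPTY canvas.
    owner : (H, W) int16
        Fiber id the pixel belonged to at creation (0 for ECM-owned pixels).
        Repair restores a cleared pixel to its owning fiber.
    collagen : (H, W) float64
        Collagen density of ECM pixels, in [0, 1]; 0 elsewhere.
    damaged, needs_repair : (H, W) bool
        Damage and repair-request flags set by the injury and agent rules.
    """

    fiber_id: np.ndarray
    ecm: np.ndarray
    occupied: np.ndarray
    owner: np.ndarray
    collagen: np.ndarray
    damaged: np.ndarray
    needs_repair: np.ndarray
    pixel_area: float = DEFAULT_PIXEL_AREA
    slice_thickness: float = DEFAULT_SLICE_THICKNESS
    n_fibers: int = 20

    # -- basic views ------------------------------------------------------
    @property
    def width(self) -> int:
        return self.fiber_id.shape[1]

    @property
    def height(self) -> int:
        return self.fiber_id.shape[0]

    @property
    def fibril_mask(self) -> np.ndarray:
        return self.fiber_id > 0

    @property
    def cleared_mask(self) -> np.ndarray:
        return self.occupied & ~self.fibril_mask & ~self.ecm

    @property
    def fibril_count(self) -> int:
        return int(self.fibril_mask.sum())

    @property
    def ecm_count(self) -> int:
        return int(self.ecm.sum())

    def label_codes(self) -> np.ndarray:
        """uint8 label image using the module-level code convention."""
        codes = np.zeros(self.fiber_id.shape, dtype=np.uint8)
        codes[self.ecm] = ECM_CODE
        codes[self.cleared_mask] = CLEARED_CODE
        fib = self.fibril_mask
        codes[fib] = self.fiber_id[fib].astype(np.uint8)
        return codes

    def copy(self) -> "TissueGrid":
        return TissueGrid(
            fiber_id=self.fiber_id.copy(),
            ecm=self.ecm.copy(),
            occupied=self.occupied.copy(),
            owner=self.owner.copy(),
            collagen=self.collagen.copy(),
            damaged=self.damaged.copy(),
            needs_repair=self.needs_repair.copy(),
            pixel_area=self.pixel_area,
            slice_thickness=self.slice_thickness,
            n_fibers=self.n_fibers,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TissueGrid):
            return NotImplemented
        return (
            self.fiber_id.shape == other.fiber_id.shape
            and np.array_equal(self.fiber_id, other.fiber_id)
            and np.array_equal(self.ecm, other.ecm)
            and np.array_equal(self.occupied, other.occupied)
            and np.array_equal(self.owner, other.owner)
            and np.allclose(self.collagen, other.collagen, atol=1e-12)
            and np.array_equal(self.damaged, other.damaged)
            and np.array_equal(self.needs_repair, other.needs_repair)
            and np.isclose(self.pixel_area, other.pixel_area)
            and np.isclose(self.slice_thickness, other.slice_thickness)
            and self.n_fibers == other.n_fibers
        )

    def validate(self) -> None:
        """Check structural invariants; raise :class:`GridError` on violation."""
        fib = self.fibril_mask
        if fib.any():
            ids = np.unique(self.fiber_id[fib])
            if ids.min() < 1 or ids.max() > self.n_fibers:
                raise GridError(
                    f"fibril pixels carry fiber ids outside [1, {self.n_fibers}]"
                )
        if (fib & self.ecm).any():
            raise GridError("pixel labelled both fibril and ECM")
        if not self.occupied[fib | self.ecm].all():
            raise GridError("tissue pixel outside the occupied footprint")
        col = self.collagen[self.ecm]
        if col.size and (col.min() < 0 or col.max() > 1):
            raise GridError("collagen density outside [0, 1]")


@dataclass
class TissueComposition:
    """Area bookkeeping over the tissue (fibril + ECM) pixels."""

    fibril_count: int
    ecm_count: int
    muscle_fraction: float
    ecm_fraction: float
    mean_fiber_csa: float  # µm²
    cleared_count: int = 0


def compute_composition(grid: TissueGrid) -> TissueComposition:
    """Count fibril/ECM pixels and derive area fractions.

    Fractions are taken over current tissue pixels (fibril + ECM), so they
    always sum to one; damaged pixels count under their underlying label,
    cleared pixels under neither (they are reported separately).
    """
    fibril = grid.fibril_count
    ecm = grid.ecm_count
    tissue = fibril + ecm
    muscle_fraction = fibril / tissue if tissue else 0.0
    return TissueComposition(
        fibril_count=fibril,
        ecm_count=ecm,
        muscle_fraction=muscle_fraction,
        ecm_fraction=1.0 - muscle_fraction if tissue else 0.0,
        mean_fiber_csa=fibril * grid.pixel_area / grid.n_fibers,
        cleared_count=int(grid.cleared_mask.sum()),
    )


# ---------------------------------------------------------------------------
# Synthetic bundle generator
# ---------------------------------------------------------------------------


def _choose_canvas(total: int, aspect_range=(1.0, 1.6)) -> tuple[int, int]:
    """Pick (W, H) whose product is as close as possible to ``total``."""
    best = None
    h0 = int(np.sqrt(total / aspect_range[1]))
    h1 = int(np.sqrt(total / aspect_range[0])) + 2
    for h in range(max(3, h0), h1 + 1):
        w = int(round(total / h))
        if w < 3:
            continue
        err = abs(w * h - total)
        if best is None or err < best[0]:
            best = (err, w, h)
    if best is None:
        raise GridError(f"cannot build a canvas for {total} pixels")
    return best[1], best[2]


def _adjacent4_bool(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out


def _fibers_separated(fiber_id: np.ndarray) -> bool:
    """No two distinct fibers may touch: an ECM septum must lie between."""
    a, b = fiber_id[1:, :], fiber_id[:-1, :]
    if ((a > 0) & (b > 0) & (a != b)).any():
        return False
    a, b = fiber_id[:, 1:], fiber_id[:, :-1]
    return not ((a > 0) & (b > 0) & (a != b)).any()


def _fiber_connected(fiber_id: np.ndarray, n_fibers: int) -> bool:
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for fid in range(1, n_fibers + 1):
        mask = fiber_id == fid
        if not mask.any():
            return False
        _, n = ndimage.label(mask, structure=structure)
        if n != 1:
            return False
    return True


def generate_synthetic_bundle(
    n_fibers: int = 20,
    target_fibril_count: int = 9864,
    target_ecm_fraction: float = 0.158,
    seed: int = 0,
    pixel_area: float = DEFAULT_PIXEL_AREA,
    slice_thickness: float = DEFAULT_SLICE_THICKNESS,
    lloyd_iterations: int = 4,
) -> TissueGrid:
    """Generate an irregular fiber bundle hitting area-composition targets.

    Fibers are Lloyd-relaxed Voronoi cells on a rectangular tissue canvas,
    separated by ECM septa and rimmed by boundary ECM.  The ECM pixel set is
    chosen as the pixels closest to a Voronoi bisector or the canvas edge,
    thresholded at the order statistic that meets ``target_ecm_fraction``
    exactly (to within one pixel), which in turn pins the fibril count.

    Raises
    ------
    GridError
        If the requested composition is geometrically infeasible (e.g. the
        septum network alone exceeds the ECM budget, or a fiber would be
        disconnected at every attempted seeding).
    """
    if n_fibers < 1:
        raise GridError("n_fibers must be >= 1")
    if not 0.0 < target_ecm_fraction < 1.0:
        raise GridError("target_ecm_fraction must lie strictly in (0, 1)")
    if target_fibril_count < n_fibers:
        raise GridError("fewer target fibril pixels than fibers")

    total = int(round(target_fibril_count / (1.0 - target_ecm_fraction)))
    width, height = _choose_canvas(total)
    n_ecm = width * height - target_fibril_count
    if n_ecm <= 0:
        raise GridError("targets leave no room for ECM on the canvas")

    yy, xx = np.mgrid[0:height, 0:width]
    border_dist = np.minimum.reduce(
        [xx, yy, width - 1 - xx, height - 1 - yy]
    ).astype(float)

    for attempt in range(6):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        pts = np.column_stack(
            [
                rng.uniform(1, width - 2, size=n_fibers),
                rng.uniform(1, height - 2, size=n_fibers),
            ]
        )
        px = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        for _ in range(lloyd_iterations):
            d = np.linalg.norm(px[:, None, :] - pts[None, :, :], axis=2)
            lab = d.argmin(axis=1)
            for k in range(n_fibers):
                sel = lab == k
                if sel.any():
                    pts[k] = px[sel].mean(axis=0)
        d = np.linalg.norm(px[:, None, :] - pts[None, :, :], axis=2)
        order = np.sort(d, axis=1)
        lab = d.argmin(axis=1).reshape(height, width)
        if n_fibers > 1:
            # (d2 - d1)/2 approximates the distance to the Voronoi bisector
            septum_dist = ((order[:, 1] - order[:, 0]) / 2.0).reshape(height, width)
            closeness = np.minimum(septum_dist, border_dist)
        else:
            closeness = border_dist

        # a one-sided 1-pixel wall between differing labels is mandatory ECM:
        # the higher label yields, which guarantees fibers never touch
        mandatory = np.zeros((height, width), dtype=bool)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb = np.roll(lab, shift, axis=axis)
            if axis == 0:
                edge = np.s_[0, :] if shift == 1 else np.s_[-1, :]
            else:
                edge = np.s_[:, 0] if shift == 1 else np.s_[:, -1]
            diff = (nb != lab) & (nb < lab)
            diff[edge] = False
            mandatory |= diff
        n_free = n_ecm - int(mandatory.sum())
        if n_free < 0:
            continue  # septum skeleton alone exceeds the ECM budget

        free_close = np.where(mandatory, np.inf, closeness).ravel()
        ok = False
        for keep_ties in (False, True):
            ecm = mandatory.copy()
            if n_free > 0:
                thresh = np.partition(free_close, n_free - 1)[n_free - 1]
                add = (free_close <= thresh) & np.isfinite(free_close)
                excess = int(add.sum()) - n_free
                if excess > 0 and not keep_ties:
                    # resolve ties at the threshold to hit the count exactly,
                    # preferring ties that touch interior tissue so a pixel
                    # returned to the fiber stays 4-connected to it
                    tie = np.flatnonzero(free_close == thresh)
                    interior = (free_close > thresh).reshape(height, width)
                    touches = _adjacent4_bool(interior).ravel()[tie]
                    tie = np.concatenate([tie[~touches], tie[touches]])
                    add[tie[-excess:]] = False
                ecm.ravel()[add] = True
            fiber_id = np.where(ecm, 0, lab + 1).astype(np.int16)
            if _fiber_connected(fiber_id, n_fibers) and _fibers_separated(fiber_id):
                ok = True
                break
        if ok:
            break
    else:
        raise GridError(
            "could not realise connected, ECM-separated fibers for the "
            "requested composition (infeasible targets)"
        )

    occupied = np.ones((height, width), dtype=bool)
    grid = TissueGrid(
        fiber_id=fiber_id,
        ecm=ecm,
        occupied=occupied,
        owner=fiber_id.copy(),
        collagen=np.where(ecm, 1.0, 0.0),
        damaged=np.zeros((height, width), dtype=bool),
        needs_repair=np.zeros((height, width), dtype=bool),
        pixel_area=pixel_area,
        slice_thickness=slice_thickness,
        n_fibers=n_fibers,
    )
    grid.validate()

    comp = compute_composition(grid)
    if abs(comp.fibril_count - target_fibril_count) > 0.01 * target_fibril_count:
        raise GridError(
            f"achieved fibril count {comp.fibril_count} misses target "
            f"{target_fibril_count} by more than 1%"
        )
    if abs(comp.ecm_fraction - target_ecm_fraction) > 0.005:
        raise GridError(
            f"achieved ECM fraction {comp.ecm_fraction:.4f} misses target "
            f"{target_ecm_fraction:.4f} by more than 0.5 percentage points"
        )
    return grid


# ---------------------------------------------------------------------------
# I/O: label-mask PNG + sidecar, long-format CSV
# ---------------------------------------------------------------------------

_META_KEYS = ("width", "height", "pixel_area", "slice_thickness", "n_fibers")


def _meta_lines(grid: TissueGrid) -> list[str]:
    return [
        f"width: {grid.width}",
        f"height: {grid.height}",
        f"pixel_area: {grid.pixel_area!r}",
        f"slice_thickness: {grid.slice_thickness!r}",
        f"n_fibers: {grid.n_fibers}",
        "coordinates: 0-based (x, y), y increases downward",
    ]


def _coord_list(mask: np.ndarray) -> str:
    ys, xs = np.nonzero(mask)
    return ";".join(f"{x},{y}" for x, y in zip(xs, ys))


def write_grid(grid: TissueGrid, path) -> None:
    """Write a grid to ``path`` (.csv, or .png with a plain-text sidecar)."""
    path = str(path)
    if path.endswith(".csv"):
        _write_csv(grid, path)
    elif path.endswith(".png"):
        _write_png(grid, path)
    else:
        raise GridError(f"unsupported grid format: {path}")


def read_grid(path) -> TissueGrid:
    path = str(path)
    if path.endswith(".csv"):
        return _read_csv(path)
    if path.endswith(".png"):
        return _read_png(path)
    raise GridError(f"unsupported grid format: {path}")


def _write_csv(grid: TissueGrid, path: str) -> None:
    codes = grid.label_codes()
    ys, xs = np.nonzero(grid.occupied)
    with open(path, "w") as fh:
        for line in _meta_lines(grid):
            fh.write(f"# {line}\n")
        fh.write("x,y,label,owner,collagen_density,damaged,needs_repair\n")
        for x, y in zip(xs, ys):
            fh.write(
                f"{x},{y},{int(codes[y, x])},{int(grid.owner[y, x])},"
                f"{float(grid.collagen[y, x])!r},{int(grid.damaged[y, x])},"
                f"{int(grid.needs_repair[y, x])}\n"
            )


def _read_csv(path: str) -> TissueGrid:
    meta: dict[str, str] = {}
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise GridError(f"{path}: no pixels")
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise GridError(f"{path}: line {lineno}: expected 7 fields, got {len(parts)}")
        records.append((lineno, parts))
    if not records:
        raise GridError(f"{path}: no pixels")
    for key in _META_KEYS:
        if key not in meta:
            raise GridError(f"{path}: missing metadata key '{key}'")
    width, height = int(meta["width"]), int(meta["height"])
    n_fibers = int(meta["n_fibers"])
    grid = _empty_grid(width, height, float(meta["pixel_area"]),
                       float(meta["slice_thickness"]), n_fibers)
    for lineno, parts in records:
        x, y, label = int(parts[0]), int(parts[1]), int(parts[2])
        if not (0 <= x < width and 0 <= y < height):
            raise GridError(f"{path}: line {lineno}: pixel ({x},{y}) outside grid")
        _apply_code(grid, x, y, label, n_fibers,
                    err=f"{path}: line {lineno}")
        grid.owner[y, x] = int(parts[3])
        grid.collagen[y, x] = float(parts[4])
        grid.damaged[y, x] = bool(int(parts[5]))
        grid.needs_repair[y, x] = bool(int(parts[6]))
    grid.validate()
    return grid


def _empty_grid(width, height, pixel_area, slice_thickness, n_fibers) -> TissueGrid:
    shape = (height, width)
    return TissueGrid(
        fiber_id=np.zeros(shape, dtype=np.int16),
        ecm=np.zeros(shape, dtype=bool),
        occupied=np.zeros(shape, dtype=bool),
        owner=np.zeros(shape, dtype=np.int16),
        collagen=np.zeros(shape, dtype=float),
        damaged=np.zeros(shape, dtype=bool),
        needs_repair=np.zeros(shape, dtype=bool),
        pixel_area=pixel_area,
        slice_thickness=slice_thickness,
        n_fibers=n_fibers,
    )


def _apply_code(grid: TissueGrid, x: int, y: int, label: int, n_fibers: int, err: str):
    grid.occupied[y, x] = True
    if label == ECM_CODE:
        grid.ecm[y, x] = True
    elif label == CLEARED_CODE:
        pass
    elif 1 <= label <= n_fibers:
        grid.fiber_id[y, x] = label
    else:
        raise GridError(f"{err}: unknown label code {label}")


def _write_png(grid: TissueGrid, path: str) -> None:
    from PIL import Image

    Image.fromarray(grid.label_codes(), mode="L").save(path)
    with open(path + ".meta", "w") as fh:
        for line in _meta_lines(grid):
            fh.write(f"{line}\n")
        fh.write(f"damaged: {_coord_list(grid.damaged)}\n")
        fh.write(f"needs_repair: {_coord_list(grid.needs_repair)}\n")
        low = grid.ecm & (grid.collagen != 1.0)
        ys, xs = np.nonzero(low)
        fh.write(
            "collagen_overrides: "
            + ";".join(
                f"{x},{y},{float(grid.collagen[y, x])!r}"
                for x, y in zip(xs, ys)
            )
            + "\n"
        )
        ys, xs = np.nonzero((grid.owner > 0) & ~grid.fibril_mask)
        fh.write(
            "owner_overrides: "
            + ";".join(f"{x},{y},{int(grid.owner[y, x])}" for x, y in zip(xs, ys))
            + "\n"
        )


def _read_png(path: str) -> TissueGrid:
    from PIL import Image

    codes = np.asarray(Image.open(path), dtype=np.int64)
    if codes.size == 0:
        raise GridError(f"{path}: no pixels")
    meta: dict[str, str] = {}
    try:
        with open(path + ".meta") as fh:
            for line in fh:
                key, _, val = line.strip().partition(":")
                meta[key.strip()] = val.strip()
    except FileNotFoundError as exc:
        raise GridError(f"{path}: missing sidecar {path}.meta") from exc
    n_fibers = int(meta["n_fibers"])
    height, width = codes.shape
    grid = _empty_grid(width, height, float(meta["pixel_area"]),
                       float(meta["slice_thickness"]), n_fibers)
    bad = ~(
        (codes == EMPTY_CODE)
        | (codes == ECM_CODE)
        | (codes == CLEARED_CODE)
        | ((codes >= 1) & (codes <= n_fibers))
    )
    if bad.any():
        y, x = np.argwhere(bad)[0]
        raise GridError(f"{path}: unknown label code {codes[y, x]} at ({x},{y})")
    grid.occupied = codes != EMPTY_CODE
    grid.ecm = codes == ECM_CODE
    fib = (codes >= 1) & (codes <= n_fibers)
    grid.fiber_id[fib] = codes[fib].astype(np.int16)
    grid.owner = grid.fiber_id.copy()
    grid.collagen = np.where(grid.ecm, 1.0, 0.0)

    def _parse_coords(text):
        for item in text.split(";"):
            if item:
                parts = item.split(",")
                yield parts

    for parts in _parse_coords(meta.get("damaged", "")):
        grid.damaged[int(parts[1]), int(parts[0])] = True
    for parts in _parse_coords(meta.get("needs_repair", "")):
        grid.needs_repair[int(parts[1]), int(parts[0])] = True
    for parts in _parse_coords(meta.get("collagen_overrides", "")):
        grid.collagen[int(parts[1]), int(parts[0])] = float(parts[2])
    for parts in _parse_coords(meta.get("owner_overrides", "")):
        grid.owner[int(parts[1]), int(parts[0])] = int(parts[2])
    grid.validate()
    return grid
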