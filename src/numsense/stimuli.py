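"""Controlled numerosity stimulus sets.

Four control sets of 64x64 binary images with n = 1..30 items each, designed so
that numerosity varies while a particular non-numerical visual feature is held
fixed:

* **set 1** — every item has the same area (21 pixels) and the same digital
  perimeter (12 boundary pixels);
* **set 2** — the *total* item area is fixed at 600 pixels;
* **set 3** — the *total* item perimeter is fixed at 180 boundary pixels;
* **set 4** — the convex hull of the items is a regular pentagon (outer-circle
  diameter 60 pixels) and individual item shapes vary (cross, rectangle,
  circle, triangle, square, diamond).

"Perimeter" throughout is the digital boundary-pixel count: the number of item
pixels with at least one 4-neighbour outside the item.  Under this convention
the 5x5 square minus its four corners has exactly area 21 and perimeter 12,
which is the canonical item of set 1.  Item intensity is binary (1 on items,
0 on background) and items are always separated by at least one background
pixel, so the numerosity of an image equals its number of 4-connected
foreground components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

FRAME_SIZE = 64

SHAPE_IDS = (
    "canonical_blob",
    "cross",
    "rectangle",
    "circle",
    "triangle",
    "square",
    "diamond",
)

#: item shapes drawn at random in control set 4
SET4_SHAPES = ("cross", "rectangle", "circle", "triangle", "square", "diamond")


class ConstraintError(ValueError):
    """An item cannot satisfy the requested area/perimeter constraint."""


class PackingError(RuntimeError):
    """Items could not be placed without overlap within the retry budget."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def mask_area(pixels: frozenset) -> int:
    return len(pixels)


def mask_perimeter(pixels: frozenset) -> int:
    """Boundary-pixel count: item pixels with >=1 background 4-neighbour."""
    return sum(
        1
        for (r, c) in pixels
        if any((r + dr, c + dc) not in pixels for dr, dc in _N4)
    )


def _is_4_connected(pixels: frozenset) -> bool:
    if not pixels:
        return False
    seen = set()
    stack = [next(iter(pixels))]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        r, c = p
        for dr, dc in _N4:
            q = (r + dr, c + dc)
            if q in pixels and q not in seen:
                stack.append(q)
    return len(seen) == len(pixels)


@dataclass(frozen=True)
class ItemMask:
    """A single item as a set of (row, col) pixels plus its shape tag."""

    pixels: frozenset
    shape_id: str = "canonical_blob"

    def __post_init__(self):
        if not self.pixels:
            raise ConstraintError("item mask must be non-empty")
        if self.shape_id not in SHAPE_IDS:
            raise ConstraintError(f"unknown shape_id {self.shape_id!r}")

    @property
    def area(self) -> int:
        return mask_area(self.pixels)

    @property
    def perimeter(self) -> int:
        return mask_perimeter(self.pixels)

    @property
    def bounding_box(self):
        rows = [r for r, _ in self.pixels]
        cols = [c for _, c in self.pixels]
        return (min(rows), min(cols), max(rows), max(cols))

    @property
    def centroid(self):
        rows = [r for r, _ in self.pixels]
        cols = [c for _, c in self.pixels]
        return (sum(rows) / len(rows), sum(cols) / len(cols))

    def translate(self, dr: int, dc: int) -> "ItemMask":
        return ItemMask(
            frozenset((r + dr, c + dc) for r, c in self.pixels), self.shape_id
        )


@dataclass(frozen=True)
class ControlSetSpec:
    """Constraint parameters of one control set."""

    set_id: int
    item_area_px: int = 21
    item_perimeter_px: int = 12
    total_area_px: int = 600
    total_perimeter_px: int = 180
    hull_diameter_px: int = 60
    frame_size: int = FRAME_SIZE

    def __post_init__(self):
        if self.set_id not in (1, 2, 3, 4):
            raise ConstraintError(f"set_id must be 1..4, got {self.set_id}")

    @classmethod
    def for_set(cls, set_id: int) -> "ControlSetSpec":
        return cls(set_id=set_id)


@dataclass
class StimulusImage:
    """A 64x64 binary stimulus with per-item masks and metadata."""

    intensities: np.ndarray
    numerosity: int
    items: list
    set_id: int

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.numerosity != len(self.items):
            raise ConstraintError("numerosity must equal the item count")


@dataclass
class FeatureAudit:
    """Measured non-numerical features of one stimulus image."""

    item_areas: list
    item_perimeters: list
    total_area: int = field(init=False)
    total_perimeter: int = field(init=False)
    hull_vertices: list = field(default_factory=list)

    def __post_init__(self):
        self.total_area = int(sum(self.item_areas))
        self.total_perimeter = int(sum(self.item_perimeters))


# ---------------------------------------------------------------------------
# item construction
# ---------------------------------------------------------------------------


def _canonical_blob() -> frozenset:
    # 5x5 square minus its 4 corners: 21 pixels, 12 boundary pixels
    return frozenset(
        (r, c)
        for r in range(5)
        for c in range(5)
        if (r, c) not in ((0, 0), (0, 4), (4, 0), (4, 4))
    )


def _disc_blob(area: int) -> frozenset:
    """The `area` lattice points closest to the origin (deterministic order).

    Any pixel at distance d from the centre has a 4-neighbour strictly closer,
    so the prefix of the (d^2, r, c)-sorted lattice is always 4-connected.
    """
    radius = int(math.isqrt(area)) + 2
    offs = sorted(
        ((r * r + c * c, r, c)
         for r in range(-radius, radius + 1)
         for c in range(-radius, radius + 1)),
    )
    if area > len(offs):
        raise ConstraintError(f"disc blob of area {area} out of range")
    return frozenset((r, c) for _, r, c in offs[:area])


def _rectangle(h: int, w: int, hollow: bool = False) -> set:
    px = {(r, c) for r in range(h) for c in range(w)}
    if hollow:
        px -= {(r, c) for r in range(1, h - 1) for c in range(1, w - 1)}
    return px


def _perimeter_piece(target_perimeter: int, frame_size: int) -> frozenset:
    """A mask with exactly `target_perimeter` boundary pixels.

    Lines for budgets 1..3; solid near-square rectangles for even budgets
    (an h x w rectangle has 2h+2w-4 boundary pixels); odd budgets add a
    single nub pixel outside a corner, which is itself a boundary pixel and
    leaves every other boundary count unchanged.
    """
    p = target_perimeter
    if p < 1:
        raise ConstraintError("perimeter budget must be >= 1")
    if p <= 3:
        return frozenset((0, c) for c in range(p))
    nub = p % 2 == 1
    if nub:
        p -= 1
    half = (p + 4) // 2  # h + w
    h = max(2, (p + 4) // 4)
    w = half - h
    if w > frame_size - 2:
        w = frame_size - 2
        h = half - w
    if h < 2 or h > frame_size - 2:
        raise ConstraintError(
            f"perimeter budget {target_perimeter} infeasible in a "
            f"{frame_size}x{frame_size} frame"
        )
    px = _rectangle(h, w)
    if nub:
        px = {(r + 1, c) for r, c in px}  # make room above the corner
        px.add((0, 0))
    return frozenset(px)


def _named_shape(shape_id: str) -> frozenset:
    """Small (<=5x5) polyomino versions of the six set-4 item shapes."""
    if shape_id == "cross":
        px = {(r, 2) for r in range(5)} | {(2, c) for c in range(5)}
    elif shape_id == "rectangle":
        px = _rectangle(3, 5)
    elif shape_id == "circle":
        px = {(r, c) for r in range(-2, 3) for c in range(-2, 3)
              if r * r + c * c <= 4}
    elif shape_id == "triangle":
        px = {(r, c) for r in range(3) for c in range(2 - r, 3 + r)}
    elif shape_id == "square":
        px = _rectangle(4, 4)
    elif shape_id == "diamond":
        px = {(r, c) for r in range(-2, 3) for c in range(-2, 3)
              if abs(r) + abs(c) <= 2}
    else:
        raise ConstraintError(f"shape {shape_id!r} is not a set-4 shape")
    rmin = min(r for r, _ in px)
    cmin = min(c for _, c in px)
    return frozenset((r - rmin, c - cmin) for r, c in px)


def make_item(
    spec: ControlSetSpec,
    target_area: int | None = None,
    target_perimeter: int | None = None,
    shape_id: str = "canonical_blob",
) -> ItemMask:
    """Build one item mask at the origin satisfying the set's constraint.

    Sets 1-3 use the ``canonical_blob`` shape family (fixed blob for set 1,
    area-exact disc for set 2, perimeter-exact rectangle piece for set 3);
    set 4 uses one of the six named shapes.
    """
    if spec.set_id in (1, 2, 3) and shape_id != "canonical_blob":
        raise ConstraintError(
            f"set {spec.set_id} items must use shape 'canonical_blob'"
        )
    if spec.set_id == 1:
        if target_area is None:
            target_area = spec.item_area_px
        if target_perimeter is None:
            target_perimeter = spec.item_perimeter_px
        if (target_area, target_perimeter) != (21, 12):
            raise ConstraintError(
                "set 1 supports only the canonical (area 21, perimeter 12) item"
            )
        return ItemMask(_canonical_blob(), "canonical_blob")
    if spec.set_id == 2:
        if target_area is None or target_area < 1:
            raise ConstraintError("set 2 requires a positive target area")
        return ItemMask(_disc_blob(target_area), "canonical_blob")
    if spec.set_id == 3:
        if target_perimeter is None or target_perimeter < 1:
            raise ConstraintError("set 3 requires a positive perimeter budget")
        return ItemMask(_perimeter_piece(target_perimeter, spec.frame_size),
                        "canonical_blob")
    # set 4
    if shape_id == "canonical_blob":
        raise ConstraintError("set 4 items must use one of the named shapes")
    return ItemMask(_named_shape(shape_id), shape_id)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

MAX_PLACEMENT_ATTEMPTS = 10_000
_STUCK_LIMIT = 300  # consecutive failures on one item before a full restart

#: pentagon orientation, degrees: rotated 9 deg off the axes so that 5x5 items
#: centred on a vertex still fit the 64x64 frame after rounding
_PENTAGON_ANGLES_DEG = tuple(-90.0 + 9.0 + 72.0 * k for k in range(5))
_INTERIOR_SHRINK = 0.82


def pentagon_vertices(spec: ControlSetSpec) -> np.ndarray:
    """(row, col) vertices of the set-4 regular pentagon, frame-centred."""
    c = (spec.frame_size - 1) / 2.0
    radius = spec.hull_diameter_px / 2.0
    ang = np.deg2rad(_PENTAGON_ANGLES_DEG)
    return np.stack([c - radius * np.cos(ang), c + radius * np.sin(ang)], axis=1)


def _boxes_conflict(a, b) -> bool:
    # expanded-by-1 intersection == adjacency or overlap
    return not (
        a[2] + 1 < b[0] or b[2] + 1 < a[0] or a[3] + 1 < b[1] or b[3] + 1 < a[1]
    )


def _dilate(pixels: frozenset) -> set:
    out = set(pixels)
    for r, c in pixels:
        for dr, dc in _N4:
            out.add((r + dr, c + dc))
    return out


def _in_frame(mask: ItemMask, frame: int) -> bool:
    r0, c0, r1, c1 = mask.bounding_box
    return r0 >= 0 and c0 >= 0 and r1 < frame and c1 < frame


def _point_in_polygon(pt, verts: np.ndarray) -> bool:
    """Ray-cast test; `verts` in order, (row, col)."""
    r, c = pt
    inside = False
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            cx = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
            if c < cx:
                inside = not inside
    return inside


def _place_scattered(items, rng, frame) -> list:
    """Sets 1-3: uniform rejection sampling with >=1 px bounding-box separation."""
    attempts = 0
    while attempts < MAX_PLACEMENT_ATTEMPTS:
        placed, boxes = [], []
        ok = True
        for item in items:
            r0, c0, r1, c1 = item.bounding_box
            h, w = r1 - r0 + 1, c1 - c0 + 1
            if h > frame or w > frame:
                raise PackingError(
                    f"item of size {h}x{w} cannot fit a {frame}x{frame} frame"
                )
            stuck = 0
            while True:
                attempts += 1
                top = int(rng.integers(0, frame - h + 1))
                left = int(rng.integers(0, frame - w + 1))
                box = (top, left, top + h - 1, left + w - 1)
                if not any(_boxes_conflict(box, b) for b in boxes):
                    placed.append(item.translate(top - r0, left - c0))
                    boxes.append(box)
                    break
                stuck += 1
                if stuck > _STUCK_LIMIT or attempts >= MAX_PLACEMENT_ATTEMPTS:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return placed
    raise PackingError(
        f"could not place {len(items)} items after {MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def _place_at(item: ItemMask, target_rc, frame) -> ItemMask:
    """Translate `item` so its centroid lands nearest `target_rc`, clamped in-frame."""
    cr, cc = item.centroid
    r0, c0, r1, c1 = item.bounding_box
    dr = int(round(target_rc[0] - cr))
    dc = int(round(target_rc[1] - cc))
    dr = min(max(dr, -r0), frame - 1 - r1)
    dc = min(max(dc, -c0), frame - 1 - c1)
    return item.translate(dr, dc)


def _place_pentagon(items, rng, spec: ControlSetSpec) -> list:
    """Set 4: first five items on the pentagon vertices, the rest inside it."""
    frame = spec.frame_size
    verts = pentagon_vertices(spec)
    n = len(items)
    if n < 5:
        warnings.warn(
            f"set 4 with n={n} < 5 cannot realise a pentagonal convex hull; "
            "placing items at the first vertices",
            stacklevel=3,
        )
    centre = verts.mean(axis=0)
    inner = centre + _INTERIOR_SHRINK * (verts - centre)

    attempts = 0
    while attempts < MAX_PLACEMENT_ATTEMPTS:
        placed, occupied = [], set()
        ok = True
        for k, item in enumerate(items):
            if k < 5:
                attempts += 1
                cand = _place_at(item, verts[k], frame)
                if occupied & _dilate(cand.pixels):
                    ok = False
                    break
                placed.append(cand)
                occupied |= _dilate(cand.pixels)
                continue
            stuck = 0
            while True:
                attempts += 1
                lo = inner.min(axis=0)
                hi = inner.max(axis=0)
                pt = lo + rng.random(2) * (hi - lo)
                if not _point_in_polygon(pt, inner):
                    stuck += 1
                    if stuck > _STUCK_LIMIT or attempts >= MAX_PLACEMENT_ATTEMPTS:
                        ok = False
                        break
                    continue
                cand = _place_at(item, pt, frame)
                if not (occupied & _dilate(cand.pixels)) and _in_frame(cand, frame):
                    placed.append(cand)
                    occupied |= _dilate(cand.pixels)
                    break
                stuck += 1
                if stuck > _STUCK_LIMIT or attempts >= MAX_PLACEMENT_ATTEMPTS:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return placed
    raise PackingError(
        f"could not place {n} items in the pentagon after "
        f"{MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def place_items(
    items: Sequence[ItemMask],
    set_id: int,
    rng: np.random.Generator,
    spec: ControlSetSpec | None = None,
) -> list:
    """Place item masks in the frame without overlap or adjacency.

    Sets 1-3 draw positions uniformly over the frame (bounding boxes kept at
    least one background pixel apart); set 4 pins the first five items to the
    pentagon vertices and scatters the remainder inside the pentagon.
    """
    spec = spec or ControlSetSpec.for_set(set_id)
    if spec.set_id != set_id:
        raise ConstraintError("spec.set_id does not match set_id")
    if set_id == 4:
        return _place_pentagon(list(items), rng, spec)
    return _place_scattered(list(items), rng, spec.frame_size)


# ---------------------------------------------------------------------------
# image assembly and audit
# ---------------------------------------------------------------------------


def _split_budget(total: int, n: int) -> list:
    """Integer budgets summing exactly to `total`: remainder to the first items."""
    base, rem = divmod(total, n)
    return [base + 1 if i < rem else base for i in range(n)]


def _items_for(spec: ControlSetSpec, n: int, rng: np.random.Generator) -> list:
    if spec.set_id == 1:
        return [make_item(spec) for _ in range(n)]
    if spec.set_id == 2:
        return [make_item(spec, target_area=a)
                for a in _split_budget(spec.total_area_px, n)]
    if spec.set_id == 3:
        return [make_item(spec, target_perimeter=p)
                for p in _split_budget(spec.total_perimeter_px, n)]
    shapes = [SET4_SHAPES[int(rng.integers(len(SET4_SHAPES)))] for _ in range(n)]
    return [make_item(spec, shape_id=s) for s in shapes]


def render(items: Sequence[ItemMask], frame_size: int = FRAME_SIZE) -> np.ndarray:
    grid = np.zeros((frame_size, frame_size), dtype=float)
    for item in items:
        for r, c in item.pixels:
            grid[r, c] = 1.0
    return grid


def make_image(set_id: int, n: int, rng: np.random.Generator,
               spec: ControlSetSpec | None = None) -> StimulusImage:
    spec = spec or ControlSetSpec.for_set(set_id)
    items = _items_for(spec, n, rng)
    placed = place_items(items, set_id, rng, spec)
    return StimulusImage(render(placed, spec.frame_size), n, placed, set_id)


def generate_control_set(
    set_id: int,
    numerosities: Iterable[int] = range(1, 31),
    rng: np.random.Generator | None = None,
    spec: ControlSetSpec | None = None,
) -> list:
    """Generate one control set: one image per requested numerosity (1..30)."""
    rng = rng if rng is not None else np.random.default_rng()
    return [make_image(set_id, n, rng, spec) for n in numerosities]


def audit_features(image: StimulusImage) -> FeatureAudit:
    """Measure per-item areas, boundary perimeters and the centroid hull."""
    areas = [it.area for it in image.items]
    perims = [it.perimeter for it in image.items]
    centroids = np.array([it.centroid for it in image.items])
    if len(centroids) >= 3:
        try:
            hull = ConvexHull(centroids)
            verts = [tuple(centroids[i]) for i in hull.vertices]
        except QhullError:  # collinear centroids
            verts = [tuple(p) for p in centroids]
    else:
        verts = [tuple(p) for p in centroids]
    return FeatureAudit(areas, perims, hull_vertices=verts)
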