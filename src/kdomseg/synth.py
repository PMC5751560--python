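"""Seeded generators of point sets and images with known ground truth.

The shapes emulate the geometric situations the extractor targets:

* jittered convex polygons (sharp vertices, the piecewise-linear case),
* ellipse boundaries (smooth convex contours, the single-embryo case),
* bean shapes — dimpled limacons ``r(theta) = R (c - cos theta)`` with
  ``1 < c < 2`` — concave single contours with exactly two inflection
  points,
* pairs of touching ellipses whose merged outline has exactly two
  concave junction points.

Every spec is fully determined by its ``seed``: identical specs yield
bit-identical samples and images.  Boundary points are laid out at a
fixed arc-length spacing (default 1 px, mimicking an edge map) and
perturbed by isotropic Gaussian jitter (default sigma 0.5 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Polygon

from .geometry import PointSet

__all__ = [
    "ShapeSpec",
    "GroundTruth",
    "sample_boundary",
    "render_image",
    "regular_polygon_spec",
    "l_shape_spec",
    "ellipse_spec",
    "bean_spec",
    "touching_spec",
    "make_benchmark",
]

_KINDS = ("polygon", "ellipse", "bean", "touching")


@dataclass
class ShapeSpec:
    """Geometry + sampling + rendering parameters of one synthetic scene.

    ``params`` holds the kind-specific geometry:

    polygon   vertices: (m, 2) array of corners (simple polygon).
    ellipse   center, axes (a, b), rotation (radians).
    bean      center, radius R, dimple c in (1, 2), rotation.
    touching  ellipse1, ellipse2: dicts with center/axes/rotation; the
              boundaries must intersect in exactly 2 points.
    """

    kind: str
    params: dict = field(default_factory=dict)
    spacing: float = 1.0
    jitter: float = 0.5
    image_size: Optional[tuple[int, int]] = None  # (height, width)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.kind == "touching":
            junctions = _touching_junctions(self.params)
            if junctions.shape[0] != 2:
                raise ValueError(
                    "touching ellipses must intersect in exactly 2 points"
                )
        if self.kind == "polygon":
            poly = Polygon(np.asarray(self.params["vertices"], dtype=float))
            if not poly.is_valid or poly.area <= 0:
                raise ValueError("polygon must be simple with positive area")


@dataclass
class GroundTruth:
    """Known geometry of a generated scene."""

    vertices: Optional[np.ndarray] = None  # true polygon corners
    junctions: Optional[np.ndarray] = None  # (2, 2) touching intersections
    inflections: Optional[np.ndarray] = None  # (2, 2) bean inflection points
    object_curves: list = field(default_factory=list)  # dense closed boundary per object


# ---------------------------------------------------------------------------
# dense curves per kind
# ---------------------------------------------------------------------------


def _ellipse_curve(center, axes, rotation, n: int = 4000) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a, b = axes
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(rotation), np.sin(rotation)
    pts = np.column_stack([c * x - s * y, s * x + c * y])
    return pts + np.asarray(center, dtype=float)


def _bean_curve(center, radius, c, rotation, n: int = 4000) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = radius * (c - np.cos(t))
    x = r * np.cos(t)
    y = r * np.sin(t)
    co, si = np.cos(rotation), np.sin(rotation)
    pts = np.column_stack([co * x - si * y, si * x + co * y])
    return pts + np.asarray(center, dtype=float)


def _bean_inflections(center, radius, c, rotation) -> np.ndarray:
    """Zeros of the limacon curvature numerator r^2 + 2 r'^2 - r r''."""
    # r = R (c - cos t): numerator/R^2 = (c-cos t)^2 + 2 sin^2 t - (c-cos t) cos t
    t = np.linspace(0.0, 2.0 * np.pi, 100000, endpoint=False)
    num = (c - np.cos(t)) ** 2 + 2.0 * np.sin(t) ** 2 - (c - np.cos(t)) * np.cos(t)
    sign = np.sign(num)
    flips = np.where(sign != np.roll(sign, -1))[0]
    ts = t[flips]
    r = radius * (c - np.cos(ts))
    x, y = r * np.cos(ts), r * np.sin(ts)
    co, si = np.cos(rotation), np.sin(rotation)
    pts = np.column_stack([co * x - si * y, si * x + co * y])
    return pts + np.asarray(center, dtype=float)


def _touching_junctions(params: dict) -> np.ndarray:
    e1 = _ellipse_curve(**params["ellipse1"])
    e2 = _ellipse_curve(**params["ellipse2"])
    inter = LineString(np.vstack([e1, e1[:1]])).intersection(
        LineString(np.vstack([e2, e2[:1]]))
    )
    if inter.is_empty:
        return np.empty((0, 2))
    if inter.geom_type == "Point":
        return np.array([[inter.x, inter.y]])
    if inter.geom_type == "MultiPoint":
        return np.array([[g.x, g.y] for g in inter.geoms])
    return np.empty((0, 2))  # tangential/overlapping: not a valid touching pair


def _resample_closed(curve: np.ndarray, spacing: float) -> np.ndarray:
    """Points at fixed arc-length spacing along a dense closed curve."""
    d = np.linalg.norm(np.diff(np.vstack([curve, curve[:1]]), axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(d)))
    total = s[-1]
    n = max(3, int(np.floor(total / spacing + 1e-9)))
    targets = np.arange(n) * (total / n)
    idx = np.searchsorted(s, targets, side="right") - 1
    idx = np.clip(idx, 0, len(curve) - 1)
    nxt = (idx + 1) % len(curve)
    seg = np.where(d[idx] > 0, d[idx], 1.0)
    frac = ((targets - s[idx]) / seg)[:, None]
    return curve[idx] * (1 - frac) + curve[nxt] * frac


def _sample_polygon_edges(vertices: np.ndarray, spacing: float) -> np.ndarray:
    pts = []
    m = len(vertices)
    for i in range(m):
        a, b = vertices[i], vertices[(i + 1) % m]
        length = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(length / spacing - 1e-9)))
        t = (np.arange(n) * spacing / length)[:, None]
        pts.append(a * (1 - t) + b * t)
    return np.concatenate(pts, axis=0)


def _scene_curves(spec: ShapeSpec) -> tuple[list[np.ndarray], GroundTruth]:
    p = spec.params
    if spec.kind == "polygon":
        v = np.asarray(p["vertices"], dtype=float)
        return [v], GroundTruth(vertices=v, object_curves=[v])
    if spec.kind == "ellipse":
        curve = _ellipse_curve(p["center"], p["axes"], p.get("rotation", 0.0))
        return [curve], GroundTruth(object_curves=[curve])
    if spec.kind == "bean":
        curve = _bean_curve(p["center"], p["radius"], p["c"], p.get("rotation", 0.0))
        infl = _bean_inflections(p["center"], p["radius"], p["c"], p.get("rotation", 0.0))
        return [curve], GroundTruth(inflections=infl, object_curves=[curve])
    # touching
    c1 = _ellipse_curve(**p["ellipse1"])
    c2 = _ellipse_curve(**p["ellipse2"])
    junctions = _touching_junctions(p)
    return [c1, c2], GroundTruth(junctions=junctions, object_curves=[c1, c2])


def sample_boundary(spec: ShapeSpec) -> tuple[PointSet, GroundTruth]:
    """Jittered boundary samples of the scene plus its ground truth.

    For the touching kind only the merged outer outline is sampled:
    points of one ellipse strictly inside the other are discarded, as
    an edge detector would only see the outer silhouette.
    """
    rng = np.random.default_rng(spec.seed)
    curves, truth = _scene_curves(spec)

    if spec.kind == "polygon":
        pts = _sample_polygon_edges(truth.vertices, spec.spacing)
    elif spec.kind == "touching":
        poly1 = Polygon(curves[0])
        poly2 = Polygon(curves[1])
        s1 = _resample_closed(curves[0], spec.spacing)
        s2 = _resample_closed(curves[1], spec.spacing)
        keep1 = ~_inside_mask(s1, poly2)
        keep2 = ~_inside_mask(s2, poly1)
        pts = np.concatenate([s1[keep1], s2[keep2]], axis=0)
    else:
        pts = _resample_closed(curves[0], spec.spacing)

    if spec.jitter > 0:
        pts = pts + rng.normal(0.0, spec.jitter, size=pts.shape)
    return PointSet(pts), truth


def _inside_mask(pts: np.ndarray, poly: Polygon) -> np.ndarray:
    from shapely import contains_xy

    return contains_xy(poly, pts[:, 0], pts[:, 1])


def render_image(spec: ShapeSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Grayscale raster of the filled scene plus per-object truth masks.

    Objects are filled at distinct gray levels over a dark background;
    additive Gaussian noise of ``spec.noise_sigma`` gray levels is
    applied and the result clipped to uint8.  Masks are boolean at
    image resolution, one per object (touching pairs: each full
    ellipse, so the overlap lens belongs to both).
    """
    from skimage.draw import polygon as draw_polygon

    if spec.image_size is None:
        raise ValueError("render_image requires spec.image_size")
    h, w = spec.image_size
    curves, _ = _scene_curves(spec)
    for c in curves:
        if (c[:, 0].min() < 0 or c[:, 1].min() < 0
                or c[:, 0].max() >= w or c[:, 1].max() >= h):
            raise ValueError("shape exceeds the canvas")

    img = np.full((h, w), 30.0)
    # touching objects share one gray level: an edge detector sees a
    # single merged silhouette, which is precisely the situation the
    # contour method must untangle
    levels = [160.0, 160.0] if spec.kind == "touching" else [160.0, 200.0]
    masks: list[np.ndarray] = []
    for i, c in enumerate(curves):
        rr, cc = draw_polygon(c[:, 1], c[:, 0], shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        masks.append(mask)
        img[mask] = levels[i % len(levels)]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), masks


# ---------------------------------------------------------------------------
# spec factories (the study conditions)
# ---------------------------------------------------------------------------


def _corner_excess(v: np.ndarray) -> float:
    """Smallest relative sum-distance excess of any corner over its chord."""
    m = len(v)
    worst = np.inf
    for i in range(m):
        u, p, w = v[(i - 1) % m], v[i], v[(i + 1) % m]
        worst = min(
            worst,
            (np.linalg.norm(u - p) + np.linalg.norm(p - w))
            / np.linalg.norm(u - w)
            - 1.0,
        )
    return float(worst)


def _is_convex(v: np.ndarray) -> bool:
    m = len(v)
    def _xp(u, w):
        return u[0] * w[1] - u[1] * w[0]

    cross = [
        _xp(v[(i + 1) % m] - v[i], v[(i + 2) % m] - v[(i + 1) % m])
        for i in range(m)
    ]
    return all(c > 0 for c in cross) or all(c < 0 for c in cross)


def regular_polygon_spec(
    m: int,
    seed: int,
    radius: float = 80.0,
    center: tuple[float, float] = (96.0, 96.0),
    jitter: float = 0.5,
    spacing: float = 1.0,
    perturb: float = 0.15,
    min_corner_excess: float = 0.06,
) -> ShapeSpec:
    """Convex m-gon with radially perturbed corners.

    Perturbations are redrawn until the polygon is convex and every
    corner's relative sum-distance excess over its neighbours' chord
    stays above ``min_corner_excess``: a corner inside the extractor's
    collinearity band is geometrically equivalent to a straight edge
    and would not be a dominant point of the sampled boundary at all.
    """
    rng = np.random.default_rng(seed)
    # a regular m-gon has corner excess 1/cos(pi/m) - 1, which shrinks
    # fast with m; scale the radial perturbation so corners keep enough
    # margin above the requested minimum to stay individually resolvable
    regular_excess = 1.0 / np.cos(np.pi / m) - 1.0
    eff_perturb = min(perturb, max(0.0, regular_excess - min_corner_excess))
    for _ in range(200):
        rot = rng.uniform(0, 2 * np.pi)
        delta = rng.uniform(-eff_perturb, eff_perturb, size=m)
        angles = np.arange(m) * 2.0 * np.pi / m + rot
        radii = radius * (1.0 + delta)
        v = np.column_stack([np.cos(angles), np.sin(angles)]) * radii[:, None]
        v = v + np.asarray(center)
        if _is_convex(v) and _corner_excess(v) >= min_corner_excess:
            break
    else:
        angles = np.arange(m) * 2.0 * np.pi / m + rng.uniform(0, 2 * np.pi)
        v = radius * np.column_stack([np.cos(angles), np.sin(angles)])
        v = v + np.asarray(center)
    return ShapeSpec("polygon", {"vertices": v}, spacing=spacing,
                     jitter=jitter, seed=seed)


def l_shape_spec(
    seed: int,
    size: float = 120.0,
    center: tuple[float, float] = (96.0, 96.0),
    jitter: float = 0.5,
    spacing: float = 1.0,
) -> ShapeSpec:
    """L-shaped hexagon (one reflex corner) with a seeded rotation."""
    rng = np.random.default_rng(seed)
    base = np.array(
        [[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float
    ) - [1.0, 1.0]
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    v = (base / 2.0 * size) @ rot.T + np.asarray(center)
    return ShapeSpec("polygon", {"vertices": v}, spacing=spacing,
                     jitter=jitter, seed=seed)


def ellipse_spec(
    seed: int,
    image_size: tuple[int, int] = (192, 192),
    jitter: float = 0.5,
    noise_sigma: float = 6.0,
) -> ShapeSpec:
    rng = np.random.default_rng(seed)
    h, w = image_size
    a = rng.uniform(45, 62)
    b = rng.uniform(22, 32)
    params = {
        "center": (w / 2 + rng.uniform(-8, 8), h / 2 + rng.uniform(-8, 8)),
        "axes": (a, b),
        "rotation": rng.uniform(0, np.pi),
    }
    return ShapeSpec("ellipse", params, jitter=jitter,
                     image_size=image_size, noise_sigma=noise_sigma, seed=seed)


def bean_spec(
    seed: int,
    image_size: tuple[int, int] = (192, 192),
    jitter: float = 0.5,
    noise_sigma: float = 6.0,
) -> ShapeSpec:
    rng = np.random.default_rng(seed)
    h, w = image_size
    params = {
        "center": (w / 2 + rng.uniform(-6, 6), h / 2 + rng.uniform(-6, 6)),
        "radius": rng.uniform(22, 30),
        "c": rng.uniform(1.3, 1.7),
        "rotation": rng.uniform(0, 2 * np.pi),
    }
    return ShapeSpec("bean", params, jitter=jitter,
                     image_size=image_size, noise_sigma=noise_sigma, seed=seed)


def _junction_v_angle(params: dict, s: float) -> float | None:
    """Worst junction opening angle at contour arc distance ``s``.

    Walks the merged outer contour and measures, at each of the two
    junctions, the angle between the directions to the contour points
    ``s`` pixels away along either arc.  Returns the larger of the two
    angles (degrees), or None when the pair is not a valid touching
    configuration.
    """
    from shapely.ops import unary_union

    junctions = _touching_junctions(params)
    if junctions.shape[0] != 2:
        return None
    union = unary_union(
        [Polygon(_ellipse_curve(**params["ellipse1"])),
         Polygon(_ellipse_curve(**params["ellipse2"]))]
    )
    if union.geom_type != "Polygon":
        return None
    bnd = np.asarray(union.exterior.coords)[:-1]
    seg = np.linalg.norm(np.diff(np.vstack([bnd, bnd[:1]]), axis=0), axis=1)
    cs = np.concatenate(([0.0], np.cumsum(seg)))
    total = cs[-1]
    worst = 0.0
    for j in junctions:
        i = int(np.argmin(np.linalg.norm(bnd - j, axis=1)))

        def at(offset: float) -> np.ndarray:
            t = (cs[i] + offset) % total
            return bnd[(int(np.searchsorted(cs, t)) - 1) % len(bnd)]

        u = at(-s) - bnd[i]
        w = at(s) - bnd[i]
        ang = np.degrees(
            np.arccos(np.clip(u @ w / (np.linalg.norm(u) * np.linalg.norm(w)),
                              -1, 1))
        )
        worst = max(worst, float(ang))
    return worst


def touching_spec(
    seed: int,
    image_size: tuple[int, int] = (192, 192),
    jitter: float = 0.5,
    noise_sigma: float = 6.0,
    max_junction_angle: float = 75.0,
) -> ShapeSpec:
    """Two round-ish ellipses joined by a shallow overlap lens.

    A shallow lens between two convex bodies produces a narrow crease:
    the crease opening approaches zero at tangency and widens with
    overlap depth, while slim ellipse tips flatten it.  Geometry is
    therefore drawn near-circular with a small absolute overlap and
    redrawn until both junction angles, measured on the true contour
    at a dominant-point-like spacing, are at most
    ``max_junction_angle`` degrees — the acute-junction regime that
    separates touching objects from merely concave ones.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    for _ in range(100):
        cy = h / 2 + rng.uniform(-4, 4)
        cx = w / 2 + rng.uniform(-4, 4)
        a1, a2 = rng.uniform(40, 52, size=2)
        b1 = a1 * rng.uniform(0.5, 0.62)
        b2 = a2 * rng.uniform(0.5, 0.62)
        depth = rng.uniform(2.0, 4.0)  # lens depth at the waist
        offset = b1 + b2 - depth
        theta = rng.uniform(0, np.pi)  # common long-axis orientation
        # embryos lying side by side lengthwise: offset perpendicular
        # to the shared long axis, flank against flank, so the contact
        # lens is long and thin and its crease angles start near zero
        dx = -offset * np.sin(theta) / 2
        dy = offset * np.cos(theta) / 2
        slide = rng.uniform(-6, 6)  # slight slip along the shared axis
        sx, sy = slide * np.cos(theta), slide * np.sin(theta)
        params = {
            "ellipse1": {"center": (cx - dx - sx, cy - dy - sy),
                         "axes": (a1, b1),
                         "rotation": theta + rng.uniform(-0.06, 0.06)},
            "ellipse2": {"center": (cx + dx + sx, cy + dy + sy),
                         "axes": (a2, b2),
                         "rotation": theta + rng.uniform(-0.06, 0.06)},
        }
        v = _junction_v_angle(params, s=16.0)
        if v is not None and v <= max_junction_angle:
            return ShapeSpec("touching", params, jitter=jitter,
                             image_size=image_size,
                             noise_sigma=noise_sigma, seed=seed)
    raise ValueError("could not draw a valid touching configuration")


def make_benchmark(
    seed: int,
    n_ellipse: int = 25,
    n_bean: int = 15,
    n_touching: int = 10,
    image_size: tuple[int, int] = (192, 192),
) -> list[ShapeSpec]:
    """The packaged synthetic benchmark: a seeded list of scene specs."""
    rng = np.random.default_rng(seed)
    specs: list[ShapeSpec] = []
    for maker, n in (
        (ellipse_spec, n_ellipse),
        (bean_spec, n_bean),
        (touching_spec, n_touching),
    ):
        for _ in range(n):
            s = int(rng.integers(0, 2**31 - 1))
            for attempt in range(20):  # touching geometry can need a retry
                try:
                    specs.append(maker(s + attempt, image_size=image_size))
                    break
                except ValueError:
                    continue
    return specs
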