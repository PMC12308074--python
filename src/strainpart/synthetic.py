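"""Synthetic confluent-monolayer generator with per-cell strain ground truth.

Builds a space-filling epithelial sheet (Lloyd-relaxed Voronoi cells on a
jittered hexagonal lattice, one interior nucleus ellipse per cell), deforms it
by a uniaxial x-stretch in which each cell partitions its total strain between
nucleus and cytoplasm according to a sampled nucleus/cytoplasm strain ratio,
and rasterizes the result into label masks plus a Hoechst-like nuclear
intensity image. Because the per-cell strains are drawn analytically, every
downstream measurement stage can be validated against known ground truth.

Coordinates are in µm with x = stretch axis = image column (increasing
rightward) and origin at the top-left of the field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon, box
from skimage.draw import polygon as _draw_polygon

from .measure import LabelFrame

logger = logging.getLogger(__name__)

__all__ = [
    "Ellipse",
    "MonolayerGeometry",
    "RatioDistribution",
    "StretchParams",
    "BROAD_RATIO",
    "NARROW_RATIO",
    "UNIFORM_RATIO",
    "generate_geometry",
    "apply_stretch",
    "render_frame",
    "write_frames",
]


# --------------------------------------------------------------------------- #
# geometry primitives
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in µm: centre, semi-axes (a ≥ b) and orientation of the a-axis."""

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    theta: float = 0.0

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def quadratic_form(self) -> np.ndarray:
        """Matrix Q with (p-c)ᵀ Q (p-c) = 1 on the boundary."""
        a, b = self.semi_axes
        c, s = math.cos(self.theta), math.sin(self.theta)
        rot = np.array([[c, -s], [s, c]])
        return rot @ np.diag([1.0 / a**2, 1.0 / b**2]) @ rot.T

    def boundary(self, n: int = 64) -> np.ndarray:
        """(n, 2) polygonal approximation of the boundary."""
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        a, b = self.semi_axes
        c, s = math.cos(self.theta), math.sin(self.theta)
        x = self.centre[0] + a * np.cos(t) * c - b * np.sin(t) * s
        y = self.centre[1] + a * np.cos(t) * s + b * np.sin(t) * c
        return np.column_stack([x, y])

    def chord_x(self) -> tuple[float, float]:
        """x-interval cut by the horizontal line through the centre."""
        q00 = self.quadratic_form()[0, 0]
        half = 1.0 / math.sqrt(q00)
        return self.centre[0] - half, self.centre[0] + half

    def x_scaled(self, scale: float) -> "Ellipse":
        """Image under an affine x-scaling about the ellipse centre."""
        s_inv = np.diag([1.0 / scale, 1.0])
        q2 = s_inv.T @ self.quadratic_form() @ s_inv
        w, v = np.linalg.eigh(q2)
        a2, b2 = 1.0 / math.sqrt(w[0]), 1.0 / math.sqrt(w[1])
        theta2 = math.atan2(v[1, 0], v[0, 0])
        return Ellipse(self.centre, (a2, b2), theta2)

    def translated(self, dx: float, dy: float) -> "Ellipse":
        return replace(self, centre=(self.centre[0] + dx, self.centre[1] + dy))


@dataclass
class MonolayerGeometry:
    """Vector description of a monolayer: cell polygons, nucleus ellipses, ids.

    ``true_strain`` (set by :func:`apply_stretch` on the post geometry) holds
    the per-cell ground truth: the sampled (analytic) strains, the length
    weights used to partition them, and the strains realized by the blended
    vector geometry along each cell's mid-line.
    """

    cells: list[np.ndarray]
    nuclei: list[Ellipse]
    cell_ids: np.ndarray
    field_size: tuple[float, float]
    true_strain: pd.DataFrame | None = None

    def validate(self) -> None:
        if not (len(self.cells) == len(self.nuclei) == len(self.cell_ids)):
            raise ValueError("cells, nuclei and cell_ids must align")
        ids = np.asarray(self.cell_ids)
        if len(np.unique(ids)) != len(ids) or (ids <= 0).any():
            raise ValueError("cell_ids must be unique positive integers")
        if min(self.field_size) <= 0:
            raise ValueError("degenerate field size")


# --------------------------------------------------------------------------- #
# stretch parameters
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class RatioDistribution:
    """Distribution of the nucleus/cytoplasm strain ratio k = ϵn/ϵc.

    ``lognormal`` (default) has support (0, ∞): ``median`` is the median ratio
    (0.5 by default — the nucleus deforms half as much as the cytoplasm,
    i.e. it is stiffer) and ``sigma_log`` the log-standard deviation
    (0 degenerates to a point mass; see :data:`BROAD_RATIO` /
    :data:`NARROW_RATIO` for the named heterogeneity regimes).
    ``fixed`` is a point mass at ``median`` (the "uniform ratio" regime).
    """

    kind: str = "lognormal"
    median: float = 0.5
    sigma_log: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in {"lognormal", "fixed"}:
            raise ValueError(f"unknown ratio distribution kind: {self.kind!r}")
        if self.median <= 0:
            raise ValueError("ratio median must be > 0 (k has support in (0, inf))")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed" or self.sigma_log == 0:
            return np.full(n, self.median)
        return self.median * np.exp(rng.normal(0.0, self.sigma_log, n))

    @classmethod
    def from_string(cls, text: str) -> "RatioDistribution":
        """Parse e.g. ``"lognormal:0.5,0.5"`` or ``"fixed:1.0"``."""
        kind, _, rest = text.partition(":")
        parts = [float(p) for p in rest.split(",") if p] if rest else []
        if kind == "fixed":
            return cls("fixed", parts[0] if parts else 0.5, 0.0)
        if kind == "lognormal":
            med = parts[0] if parts else 0.5
            sig = parts[1] if len(parts) > 1 else 0.5
            return cls("lognormal", med, sig)
        raise ValueError(f"cannot parse ratio distribution {text!r}")


#: "Broad" partition heterogeneity: wide enough that the series-spring
#: anti-correlation survives realistic total-strain heterogeneity (it stays
#: negative up to σϵcell ≈ 15% with mean strain 25%).
BROAD_RATIO = RatioDistribution("lognormal", 0.5, 1.5)
#: Narrow partition heterogeneity: the anti-correlation collapses once the
#: total strain varies between cells.
NARROW_RATIO = RatioDistribution("lognormal", 0.5, 0.5)
#: Point-mass ratio ("uniform ratio" regime): no partition heterogeneity,
#: ϵn and ϵc are both proportional to ϵcell.
UNIFORM_RATIO = RatioDistribution("fixed", 0.5, 0.0)


@dataclass(frozen=True)
class StretchParams:
    """Parameters of the heterogeneous uniaxial stretch.

    ``mean_strain``/``sigma_cell_strain`` define the Gaussian distribution of
    per-cell total strain ϵcell; ``partition_ratio_dist`` the distribution of
    k = ϵn/ϵc; ``length_fractions`` the (wn, wc) weights used to solve the
    series-spring partition (``None`` uses each cell's geometric mid-line
    fractions); ``global_offset`` a rigid (dx, dy) translation in µm applied to
    the whole post-stretch frame (to exercise registration).
    """

    mean_strain: float = 0.25
    sigma_cell_strain: float = 0.05
    partition_ratio_dist: RatioDistribution = BROAD_RATIO
    length_fractions: tuple[float, float] | None = (0.5, 0.5)
    global_offset: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_cell_strain < 0:
            raise ValueError("sigma_cell_strain must be >= 0")
        if self.length_fractions is not None:
            wn, wc = self.length_fractions
            if not (0 < wn < 1 and 0 < wc < 1) or abs(wn + wc - 1) > 1e-9:
                raise ValueError("length fractions must lie in (0,1) and sum to 1")


# --------------------------------------------------------------------------- #
# tessellation
# --------------------------------------------------------------------------- #


def _hex_seeds(n: int, width: float, height: float, rng: np.random.Generator) -> np.ndarray:
    pitch = math.sqrt(2.0 * width * height / (math.sqrt(3.0) * n))
    dy = pitch * math.sqrt(3.0) / 2.0
    pts = []
    for r, y in enumerate(np.arange(dy / 2.0, height, dy)):
        x0 = pitch / 2.0 if r % 2 == 0 else pitch
        for x in np.arange(x0, width, pitch):
            pts.append((x, y))
    pts = np.asarray(pts, dtype=float)
    if len(pts) > n:
        keep = np.sort(rng.choice(len(pts), n, replace=False))
        pts = pts[keep]
    elif len(pts) < n:
        extra = rng.uniform([0.1 * pitch, 0.1 * pitch],
                            [width - 0.1 * pitch, height - 0.1 * pitch],
                            (n - len(pts), 2))
        pts = np.vstack([pts, extra])
    pts = pts + rng.normal(0.0, 0.12 * pitch, pts.shape)
    margin = 0.1 * pitch
    return np.clip(pts, [margin, margin], [width - margin, height - margin])


def _voronoi_cells(seeds: np.ndarray, width: float, height: float) -> list[Polygon]:
    """Voronoi cells of the seeds clipped to the field rectangle.

    Seeds are mirrored across all four field edges so every original region is
    finite and the clipped diagram tiles the rectangle exactly.
    """
    x, y = seeds[:, 0], seeds[:, 1]
    mirrored = np.vstack(
        [
            seeds,
            np.column_stack([-x, y]),
            np.column_stack([2 * width - x, y]),
            np.column_stack([x, -y]),
            np.column_stack([x, 2 * height - y]),
        ]
    )
    vor = Voronoi(mirrored)
    frame = box(0.0, 0.0, width, height)
    polys = []
    for i in range(len(seeds)):
        verts = vor.vertices[vor.regions[vor.point_region[i]]]
        centre = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - centre[1], verts[:, 0] - centre[0]))
        poly = Polygon(verts[order])
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys.append(poly.intersection(frame))
    return polys


def _place_nucleus(
    poly: Polygon,
    area_fraction: float,
    rng: np.random.Generator,
    margin: float,
) -> Ellipse:
    centre = poly.centroid
    if not poly.contains(centre):
        centre = poly.representative_point()
    aspect = rng.uniform(1.2, 1.8)
    theta = rng.uniform(0.0, math.pi)
    b = math.sqrt(area_fraction * poly.area / (math.pi * aspect))
    a = aspect * b
    inner = poly.buffer(-margin)
    if inner.is_empty:
        inner = poly.buffer(-margin / 4.0)
    for _ in range(60):
        ell = Ellipse((centre.x, centre.y), (a, b), theta)
        if inner.contains(Polygon(ell.boundary(64))):
            return ell
        a *= 0.92
        b *= 0.92
    # tiny-cell fallback: inscribe a small circle at the representative point
    r = 0.25 * math.sqrt(poly.area / math.pi)
    return Ellipse((centre.x, centre.y), (r, r * 0.99), 0.0)


def generate_geometry(
    n_cells: int,
    field_size: tuple[float, float] | None = None,
    seed: int = 0,
    nucleus_area_fraction: float = 0.2,
    target_cell_area: float = 900.0,
    lloyd_iterations: int = 3,
    nucleus_margin: float = 0.8,
) -> MonolayerGeometry:
    """Generate a confluent monolayer with one interior nucleus per cell.

    Cells are the Voronoi tessellation of a jittered hexagonal lattice,
    Lloyd-relaxed for a few iterations to give convex-ish, MDCK-like cells
    that tile ``field_size`` (µm) exactly. When ``field_size`` is omitted a
    square field with ``target_cell_area`` µm² per cell is used. Deterministic
    for a given seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0 < nucleus_area_fraction < 0.9):
        raise ValueError("nucleus_area_fraction must lie in (0, 0.9)")
    if field_size is None:
        side = math.sqrt(n_cells * target_cell_area)
        field_size = (side, side)
    width, height = field_size
    if width <= 0 or height <= 0:
        raise ValueError("degenerate field size")

    rng = np.random.default_rng(seed)
    if n_cells == 1:
        polys = [box(0.0, 0.0, width, height)]
    else:
        seeds = _hex_seeds(n_cells, width, height, rng)
        for _ in range(lloyd_iterations):
            polys = _voronoi_cells(seeds, width, height)
            seeds = np.array([[p.centroid.x, p.centroid.y] for p in polys])
        polys = _voronoi_cells(seeds, width, height)

    nuclei = [_place_nucleus(p, nucleus_area_fraction, rng, nucleus_margin) for p in polys]
    cells = [np.asarray(p.exterior.coords)[:-1] for p in polys]
    geom = MonolayerGeometry(
        cells=cells,
        nuclei=nuclei,
        cell_ids=np.arange(1, n_cells + 1),
        field_size=(float(width), float(height)),
    )
    geom.validate()
    return geom


# --------------------------------------------------------------------------- #
# stretching
# --------------------------------------------------------------------------- #


def _midline_interval(poly: Polygon, x_ref: float, y: float) -> tuple[float, float] | None:
    """x-interval of the chord of ``poly`` on row ``y`` containing ``x_ref``."""
    x0, _, x1, _ = poly.bounds
    line = LineString([(x0 - 10.0, y), (x1 + 10.0, y)])
    cut = poly.intersection(line)
    if cut.is_empty:
        return None
    segs = [cut] if isinstance(cut, LineString) else [
        g for g in getattr(cut, "geoms", []) if isinstance(g, LineString)
    ]
    best = None
    for seg in segs:
        xs = [p[0] for p in seg.coords]
        lo, hi = min(xs), max(xs)
        if lo - 1e-9 <= x_ref <= hi + 1e-9:
            return lo, hi
        if best is None or abs((lo + hi) / 2 - x_ref) < abs(sum(best) / 2 - x_ref):
            best = (lo, hi)
    return best


def _cell_xmap(x, xn0, xn1, xc, eps_n, eps_c):
    """Piecewise-linear x-map: slope 1+ϵn over the nucleus chord, 1+ϵc outside."""
    x = np.asarray(x, dtype=float)
    f0 = xc + (1 + eps_n) * (xn0 - xc)
    f1 = xc + (1 + eps_n) * (xn1 - xc)
    return np.where(
        x < xn0,
        f0 + (1 + eps_c) * (x - xn0),
        np.where(x > xn1, f1 + (1 + eps_c) * (x - xn1), xc + (1 + eps_n) * (x - xc)),
    )


def _vertex_key(pt: np.ndarray) -> tuple[float, float]:
    return (round(float(pt[0]), 6), round(float(pt[1]), 6))


def _densify(coords: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample polygon edges at ≤ ``step`` µm with a direction-independent rule.

    Interpolation always runs from the lexicographically smaller endpoint so
    the two cells sharing an edge generate bit-identical intermediate points.
    """
    out = []
    m = len(coords)
    for i in range(m):
        v0, v1 = coords[i], coords[(i + 1) % m]
        length = float(np.hypot(*(v1 - v0)))
        nseg = max(1, int(math.ceil(length / step)))
        lo, hi = (v0, v1) if tuple(v0) <= tuple(v1) else (v1, v0)
        t = np.linspace(0.0, 1.0, nseg + 1)[:, None]
        pts = lo[None, :] * (1 - t) + hi[None, :] * t
        if tuple(v0) > tuple(v1):
            pts = pts[::-1]
        out.append(pts[:-1])
    return np.vstack(out)


def apply_stretch(geom: MonolayerGeometry, params: StretchParams) -> MonolayerGeometry:
    """Deform a monolayer by a heterogeneous uniaxial x-stretch.

    Per cell, the total strain ϵcell ~ Normal(mean_strain, σϵcell) and the
    partition ratio k = ϵn/ϵc are sampled, and the series-spring relation
    ϵc = ϵcell/(wn·k + wc), ϵn = k·ϵc solved. Each cell carries a
    piecewise-affine x-map (nucleus chord scaled by 1+ϵn about the nucleus
    centre, cytoplasmic extents by 1+ϵc) riding on a bulk carrier stretch of
    ``mean_strain`` about the field centre. Per-cell rigid x-shifts are then
    least-squares adjusted and shared boundary vertices averaged between
    neighbours so the deformed cells stay space-filling; the residual blending
    is recorded through the realized mid-line strains (``eps_*_real``) next to
    the sampled analytic values in ``true_strain``. Finally the whole frame is
    translated by ``global_offset``.
    """
    geom.validate()
    n = len(geom.cells)
    rng = np.random.default_rng(params.seed)

    eps_cell = rng.normal(params.mean_strain, params.sigma_cell_strain, n)
    guard = 0
    while (eps_cell <= -1.0).any():
        bad = eps_cell <= -1.0
        logger.warning("resampling %d non-physical total strains (<= -100%%)", bad.sum())
        eps_cell[bad] = rng.normal(params.mean_strain, params.sigma_cell_strain, int(bad.sum()))
        guard += 1
        if guard > 100:
            raise RuntimeError("cannot sample physical strains; check parameters")
    k = params.partition_ratio_dist.sample(rng, n)
    if (k <= 0).any():
        raise ValueError("partition ratio k must be > 0")

    polys = [Polygon(c) for c in geom.cells]
    width, height = geom.field_size
    cx0 = width / 2.0

    # pre-stretch mid-line geometry per cell
    xc = np.array([e.centre[0] for e in geom.nuclei])
    yc = np.array([e.centre[1] for e in geom.nuclei])
    nuc_iv = np.array([e.chord_x() for e in geom.nuclei])
    cell_iv = np.empty((n, 2))
    for i, poly in enumerate(polys):
        iv = _midline_interval(poly, xc[i], yc[i])
        if iv is None:
            raise RuntimeError(f"cell {geom.cell_ids[i]}: no mid-line chord")
        cell_iv[i] = iv
    l_nuc = nuc_iv[:, 1] - nuc_iv[:, 0]
    l_cell = cell_iv[:, 1] - cell_iv[:, 0]
    if params.length_fractions is None:
        wn = l_nuc / l_cell
    else:
        wn = np.full(n, params.length_fractions[0])
    wc = 1.0 - wn

    eps_c = eps_cell / (wn * k + wc)
    eps_n = k * eps_c

    # bulk carrier: mean stretch about the field centre moves each anchor
    base = (1.0 + params.mean_strain) * (xc - cx0) + cx0 - xc

    def local_map(i, x):
        return _cell_xmap(x, nuc_iv[i, 0], nuc_iv[i, 1], xc[i], eps_n[i], eps_c[i])

    # least-squares per-cell rigid x-shifts minimizing boundary mismatch
    shared: dict[tuple[float, float], list[int]] = {}
    for i, coords in enumerate(geom.cells):
        for pt in coords:
            shared.setdefault(_vertex_key(pt), []).append(i)
    rows_a, rows_b = [], []
    for key, owners in shared.items():
        owners = sorted(set(owners))
        if len(owners) < 2:
            continue
        x = key[0]
        for a_idx in range(len(owners) - 1):
            i, j = owners[a_idx], owners[a_idx + 1]
            row = np.zeros(n)
            row[i], row[j] = 1.0, -1.0
            rows_a.append(row)
            rows_b.append(
                (float(local_map(j, x)) + base[j]) - (float(local_map(i, x)) + base[i])
            )
    t = np.zeros(n)
    if rows_a:
        a_mat = np.vstack(rows_a + [np.eye(n) * 1e-3])
        b_vec = np.concatenate([rows_b, np.zeros(n)])
        t = np.linalg.lstsq(a_mat, b_vec, rcond=None)[0]
        t -= t.mean()  # gauge: no net drift beyond the carrier + global offset

    ox, oy = params.global_offset
    shift = base + t + ox

    # map densified boundaries; average shared points between neighbours
    dens = [_densify(c) for c in geom.cells]
    acc: dict[tuple[float, float], list[float]] = {}
    mapped_x = []
    for i, pts in enumerate(dens):
        mx = local_map(i, pts[:, 0]) + shift[i]
        mapped_x.append(mx)
        for key, val in zip(map(_vertex_key, pts), mx):
            acc.setdefault(key, []).append(float(val))
    post_cells = []
    for i, pts in enumerate(dens):
        xs = np.array([np.mean(acc[_vertex_key(p)]) for p in pts])
        post_cells.append(np.column_stack([xs, pts[:, 1] + oy]))

    post_nuclei = [
        geom.nuclei[i].x_scaled(1.0 + eps_n[i]).translated(shift[i], oy) for i in range(n)
    ]

    # realized mid-line strains of the blended vector geometry
    real = np.full((n, 3), np.nan)  # eps_cell, eps_n, eps_c
    for i in range(n):
        poly_post = Polygon(post_cells[i])
        if not poly_post.is_valid:
            poly_post = poly_post.buffer(0)
        nc = post_nuclei[i].centre
        iv = _midline_interval(poly_post, nc[0], nc[1])
        if iv is None:
            continue
        ln2 = np.diff(post_nuclei[i].chord_x())[0]
        lcell2 = iv[1] - iv[0]
        lc1 = l_cell[i] - l_nuc[i]
        real[i] = (
            (lcell2 - l_cell[i]) / l_cell[i],
            (ln2 - l_nuc[i]) / l_nuc[i],
            ((lcell2 - ln2) - lc1) / lc1,
        )

    truth = pd.DataFrame(
        {
            "cell_id": geom.cell_ids,
            "eps_cell": eps_cell,
            "eps_n": eps_n,
            "eps_c": eps_c,
            "k": k,
            "w_n": wn,
            "w_c": wc,
            "eps_cell_real": real[:, 0],
            "eps_n_real": real[:, 1],
            "eps_c_real": real[:, 2],
            "nuc_x_pre": xc,
            "nuc_y_pre": yc,
            "nuc_x_post": [e.centre[0] for e in post_nuclei],
            "nuc_y_post": [e.centre[1] for e in post_nuclei],
        }
    )
    return MonolayerGeometry(
        cells=post_cells,
        nuclei=post_nuclei,
        cell_ids=geom.cell_ids.copy(),
        field_size=geom.field_size,
        true_strain=truth,
    )


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #


def render_frame(
    geom: MonolayerGeometry,
    pixel_size: float = 0.25,
    intensity_cv: float = 0.15,
    seed: int = 0,
) -> LabelFrame:
    """Rasterize a monolayer into 16-bit label masks and an intensity image.

    Cell and nucleus masks share labels for matched pairs (background 0). The
    intensity image is 1.0 on average inside each nucleus with a smoothed
    noise texture rescaled so the within-nucleus coefficient of variation
    equals ``intensity_cv`` (before clipping at zero), 0 elsewhere.
    """
    geom.validate()
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    width, height = geom.field_size
    shape = (int(round(height / pixel_size)), int(round(width / pixel_size)))
    if shape[0] < 2 or shape[1] < 2:
        raise ValueError("field smaller than 2x2 px")

    cell_mask = np.zeros(shape, dtype=np.uint16)
    nucleus_mask = np.zeros(shape, dtype=np.uint16)
    for cid, coords, nucleus in zip(geom.cell_ids, geom.cells, geom.nuclei):
        rr, cc = _draw_polygon(coords[:, 1] / pixel_size - 0.5,
                               coords[:, 0] / pixel_size - 0.5, shape)
        cell_mask[rr, cc] = cid
        nb = nucleus.boundary(128)
        rr, cc = _draw_polygon(nb[:, 1] / pixel_size - 0.5,
                               nb[:, 0] / pixel_size - 0.5, shape)
        nucleus_mask[rr, cc] = cid

    rng = np.random.default_rng(seed)
    intensity = np.zeros(shape, dtype=float)
    if nucleus_mask.any():
        noise = gaussian_filter(rng.standard_normal(shape), 1.0)
        for cid in np.unique(nucleus_mask)[1:]:
            sel = nucleus_mask == cid
            vals = noise[sel]
            sd = vals.std()
            if intensity_cv <= 0 or sd == 0:
                intensity[sel] = 1.0
            else:
                intensity[sel] = 1.0 + (vals - vals.mean()) * (intensity_cv / sd)
        np.clip(intensity, 0.0, None, out=intensity)

    return LabelFrame(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        intensity=intensity,
        pixel_size=pixel_size,
    )


def write_frames(
    pre: LabelFrame,
    post: LabelFrame,
    outdir: str | Path,
    truth: pd.DataFrame | None = None,
) -> list[Path]:
    """Write a frame pair as TIFFs plus the ground-truth CSV; returns the paths."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (("pre", pre), ("post", post)):
        for part, img in (
            ("cells", frame.cell_mask),
            ("nuclei", frame.nucleus_mask),
            ("intensity", frame.intensity),
        ):
            if img is None:
                continue
            path = outdir / f"{name}_{part}.tif"
            tifffile.imwrite(path, np.asarray(img))
            written.append(path)
    if truth is not None:
        path = outdir / "ground_truth.csv"
        truth.to_csv(path, index=False)
        written.append(path)
    return written
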