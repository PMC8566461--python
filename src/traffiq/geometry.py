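"""Spatial scaffolds for per-cell quantification.

A cell is described by two hand-drawn (or simulated) closed polygons — the
cell outline and the nucleus outline — in pixel coordinates, with the
convention ``(x, y) = (column, row)``, 0-based, and half-open rasterization:
a pixel belongs to a mask iff its center lies strictly inside the polygon.

From a :class:`CellROI` this module derives the three scaffolds every
downstream measurement uses:

* perinuclear / peripheral compartment masks (annular bands hugging the
  nucleus and the plasma membrane, respectively),
* radial sampling segments for linescan intensity profiles, drawn from the
  cell boundary inward toward the nucleus centroid,
* an angular sector with its apex at the nucleus centroid, used to score
  front-rear polarity of Golgi and focal-adhesion signal.

Compartment bands are expressed as fractions of the mean nucleus-to-cell
boundary distance R, so the same settings apply across cell sizes. Each
cytoplasmic pixel carries a normalized radial coordinate
``u = d_nuc / (d_nuc + d_cell)`` (0 at the nucleus boundary, 1 at the plasma
membrane); the perinuclear band is ``u <= perinuclear_band`` and the
peripheral band ``u >= 1 - peripheral_band``, which keeps the two masks
disjoint for any cell shape — including nuclei that touch the cell edge —
whenever the band fractions sum to less than one. On concentric circles this
reduces exactly to "within band x R of each boundary".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import LineString, Point, Polygon

from .errors import TraffiqError

__all__ = [
    "CellROI",
    "CompartmentMasks",
    "SamplingSegment",
    "SectorRegion",
    "build_compartment_masks",
    "radial_lines",
    "front_sector",
    "ellipse_polygon",
    "rasterize_polygon",
    "load_rois_json",
    "save_rois_json",
    "load_rois_csv",
    "export_mask_tiff",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CellROI:
    """One cell's geometry: outer outline, nucleus outline, pixel size."""

    cell_outline: np.ndarray  # (N, 2) float, columns (x, y), closed implicitly
    nucleus_outline: np.ndarray
    nucleus_centroid: tuple[float, float] | None = None
    pixel_size: float = 1.0  # µm per pixel
    cell_id: str = "cell"

    def __post_init__(self):
        self.cell_outline = np.asarray(self.cell_outline, dtype=float)
        self.nucleus_outline = np.asarray(self.nucleus_outline, dtype=float)
        if self.nucleus_centroid is None:
            c = Polygon(self.nucleus_outline).centroid
            self.nucleus_centroid = (c.x, c.y)

    @property
    def cell_polygon(self) -> Polygon:
        return Polygon(self.cell_outline)

    @property
    def nucleus_polygon(self) -> Polygon:
        return Polygon(self.nucleus_outline)

    def validate(self) -> None:
        cell, nuc = self.cell_polygon, self.nucleus_polygon
        if not cell.is_valid or not nuc.is_valid:
            raise TraffiqError("degenerate-roi", "self-intersecting outline")
        if cell.area < 10:
            raise TraffiqError("degenerate-roi", f"cell area {cell.area:.1f} px² < 10")
        if not nuc.covered_by(cell):
            raise TraffiqError("degenerate-roi", "nucleus not inside cell outline")
        if not Point(self.nucleus_centroid).covered_by(nuc):
            raise TraffiqError("degenerate-roi", "centroid outside nucleus")

    def raster_shape(self, pad: int = 2) -> tuple[int, int]:
        """(rows, cols) just covering the cell outline."""
        xmax, ymax = self.cell_outline.max(axis=0)
        return (int(np.ceil(ymax)) + 1 + pad, int(np.ceil(xmax)) + 1 + pad)


@dataclass
class CompartmentMasks:
    """Perinuclear and peripheral bands plus the whole-cell mask."""

    perinuclear_mask: np.ndarray
    peripheral_mask: np.ndarray
    cell_mask: np.ndarray
    band_params: dict = field(default_factory=dict)


@dataclass
class SamplingSegment:
    """A fixed-length, fixed-width line from the cell boundary inward."""

    start: tuple[float, float]  # on the cell outline
    end: tuple[float, float]  # toward (at most at) the nucleus centroid
    length: float  # actual length after any truncation, px
    width: float  # px, intensity averaged across this slab
    angle: float  # polar angle of the boundary point about the centroid
    truncated: bool = False


@dataclass
class SectorRegion:
    """Angular sector with apex at the nucleus centroid."""

    apex: tuple[float, float]
    direction: float  # radians, center of the sector
    half_width: float  # radians, in (0, pi)

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        theta = np.arctan2(np.asarray(y) - self.apex[1], np.asarray(x) - self.apex[0])
        d = np.angle(np.exp(1j * (theta - self.direction)))
        return np.abs(d) <= self.half_width

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains_points(xx, yy)


# ---------------------------------------------------------------------------
# rasterization helpers


def rasterize_polygon(polygon: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``polygon``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return shapely.contains_xy(polygon, xx.ravel(), yy.ravel()).reshape(shape)


def ellipse_polygon(
    center: tuple[float, float],
    rx: float,
    ry: float | None = None,
    n_vertices: int = 96,
    fourier_amplitude: float = 0.0,
    fourier_order: int = 4,
    rng: np.random.Generator | None = None,
    rotation: float = 0.0,
) -> np.ndarray:
    """Ellipse outline, optionally perturbed by low-order Fourier boundary noise.

    ``fourier_amplitude`` is a fraction of the radius; the perturbation keeps
    the polygon simple for small amplitudes (< ~0.3).
    """
    ry = rx if ry is None else ry
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r_mod = np.ones_like(t)
    if fourier_amplitude > 0:
        rng = rng or np.random.default_rng()
        for k in range(2, fourier_order + 1):
            a, b = rng.normal(0, fourier_amplitude / fourier_order, 2)
            r_mod += a * np.cos(k * t) + b * np.sin(k * t)
        r_mod = np.clip(r_mod, 0.5, 1.5)
    x = rx * r_mod * np.cos(t)
    y = ry * r_mod * np.sin(t)
    if rotation:
        c, s = np.cos(rotation), np.sin(rotation)
        x, y = c * x - s * y, s * x + c * y
    return np.column_stack([center[0] + x, center[1] + y])


def _radial_coordinate(
    roi: CellROI, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (cell_mask, nucleus_mask, u) where u is the normalized radial
    coordinate of every cytoplasm pixel (NaN elsewhere)."""
    cell_mask = rasterize_polygon(roi.cell_polygon, shape)
    nuc_mask = rasterize_polygon(roi.nucleus_polygon, shape)
    cyto = cell_mask & ~nuc_mask
    u = np.full(shape, np.nan)
    if cyto.any():
        yy, xx = np.nonzero(cyto)
        pts = shapely.points(xx.astype(float), yy.astype(float))
        d_nuc = shapely.distance(pts, roi.nucleus_polygon.exterior)
        d_cell = shapely.distance(pts, roi.cell_polygon.exterior)
        denom = d_nuc + d_cell
        denom[denom == 0] = np.inf  # nucleus touching PM: zero-width locally
        u[yy, xx] = d_nuc / denom
    return cell_mask, nuc_mask, u


# ---------------------------------------------------------------------------
# operations


def mean_nucleus_to_membrane_distance(roi: CellROI, n_samples: int = 180) -> float:
    """Mean distance R from the nucleus boundary to the cell boundary."""
    nuc = roi.nucleus_polygon.exterior
    cell = roi.cell_polygon.exterior
    s = np.linspace(0, nuc.length, n_samples, endpoint=False)
    pts = [nuc.interpolate(si) for si in s]
    return float(np.mean([cell.distance(p) for p in pts]))


def build_compartment_masks(
    roi: CellROI,
    perinuclear_band: float = 0.25,
    peripheral_band: float = 0.15,
    shape: tuple[int, int] | None = None,
) -> CompartmentMasks:
    """Perinuclear and peripheral compartment masks for one cell.

    Bands are fractions of the mean nucleus-to-membrane distance R. The
    perinuclear mask hugs the nucleus (outside it), the peripheral mask hugs
    the plasma membrane (inside the cell); they are disjoint by construction
    whenever the fractions sum to < 1.
    """
    roi.validate()
    if perinuclear_band <= 0 or peripheral_band <= 0:
        raise TraffiqError("bands-overlap", "band fractions must be positive")
    if perinuclear_band + peripheral_band >= 1:
        raise TraffiqError(
            "bands-overlap",
            f"perinuclear_band + peripheral_band = "
            f"{perinuclear_band + peripheral_band:.2f} >= 1",
        )
    shape = shape or roi.raster_shape()
    cell_mask, _, u = _radial_coordinate(roi, shape)
    peri = u <= perinuclear_band  # NaN compares False
    periph = u >= 1 - peripheral_band
    R = mean_nucleus_to_membrane_distance(roi)
    params = {
        "perinuclear_band": perinuclear_band,
        "peripheral_band": peripheral_band,
        "mean_radial_distance_px": R,
        "perinuclear_width_px": perinuclear_band * R,
        "peripheral_width_px": peripheral_band * R,
    }
    return CompartmentMasks(peri, periph, cell_mask, params)


def _boundary_point(roi: CellROI, angle: float) -> tuple[float, float] | None:
    """First crossing of the ray (centroid, angle) with the cell outline."""
    cx, cy = roi.nucleus_centroid
    span = float(np.abs(roi.cell_outline).max()) * 4 + 10
    ray = LineString(
        [(cx, cy), (cx + span * np.cos(angle), cy + span * np.sin(angle))]
    )
    hit = ray.intersection(roi.cell_polygon.exterior)
    if hit.is_empty:
        return None
    pts = (
        [hit]
        if isinstance(hit, Point)
        else [g for g in getattr(hit, "geoms", [hit]) if isinstance(g, Point)]
    )
    if not pts:
        return None
    nearest = min(pts, key=lambda p: (p.x - cx) ** 2 + (p.y - cy) ** 2)
    return (nearest.x, nearest.y)


def radial_lines(
    roi: CellROI,
    n_lines: int = 3,
    length: float = 50.0,
    width: float = 3.0,
    angles: list[float] | None = None,
) -> list[SamplingSegment]:
    """Sampling segments from the cell boundary inward toward the nucleus.

    Default placement spaces ``n_lines`` angles evenly over [0, 2π) starting
    at 0. A segment longer than the boundary-to-centroid distance is
    truncated at the centroid and flagged.
    """
    roi.validate()
    if n_lines < 1 or length < 1 or width < 1:
        raise TraffiqError("degenerate-roi", "n_lines, length, width must be >= 1")
    if angles is None:
        angles = list(np.arange(n_lines) * 2 * np.pi / n_lines)
    cx, cy = roi.nucleus_centroid
    segments = []
    for theta in angles:
        bp = _boundary_point(roi, theta)
        if bp is None:
            continue
        dist = float(np.hypot(bp[0] - cx, bp[1] - cy))
        truncated = length > dist
        actual = min(length, dist)
        # unit vector from boundary toward centroid
        ux, uy = (cx - bp[0]) / dist, (cy - bp[1]) / dist
        end = (bp[0] + actual * ux, bp[1] + actual * uy)
        segments.append(
            SamplingSegment(
                start=bp, end=end, length=actual, width=width,
                angle=float(theta), truncated=truncated,
            )
        )
    return segments


def front_sector(
    roi: CellROI,
    edge_points: tuple[tuple[float, float], tuple[float, float]] | None = None,
    direction: float | None = None,
    half_width: float | None = None,
) -> SectorRegion:
    """Sector from the nucleus centroid spanning the cell's migratory front.

    Give either two edge points on the front (the sector spans the smaller
    arc between them) or a direction angle plus angular half-width, both in
    radians.
    """
    roi.validate()
    apex = roi.nucleus_centroid
    if edge_points is not None:
        (x1, y1), (x2, y2) = edge_points
        if np.hypot(x1 - x2, y1 - y2) < 1e-9:
            raise TraffiqError("degenerate-sector", "edge points coincide")
        t1 = np.arctan2(y1 - apex[1], x1 - apex[0])
        t2 = np.arctan2(y2 - apex[1], x2 - apex[0])
        dt = np.angle(np.exp(1j * (t2 - t1)))  # signed smaller arc
        if abs(dt) < 1e-9:
            raise TraffiqError("degenerate-sector", "edge rays coincide")
        direction = float(t1 + dt / 2)
        half_width = float(abs(dt) / 2)
    elif direction is None or half_width is None:
        raise TraffiqError("degenerate-sector", "need edge_points or direction+half_width")
    if not (0 < half_width < np.pi):
        raise TraffiqError("degenerate-sector", f"half_width {half_width} out of (0, π)")
    return SectorRegion(apex=apex, direction=float(direction), half_width=float(half_width))


# ---------------------------------------------------------------------------
# I/O


def save_rois_json(rois: list[CellROI], path: str | Path) -> None:
    records = [
        {
            "cell_id": r.cell_id,
            "cell_outline": r.cell_outline.tolist(),
            "nucleus_outline": r.nucleus_outline.tolist(),
            "pixel_size": r.pixel_size,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_rois_json(path: str | Path) -> list[CellROI]:
    records = json.loads(Path(path).read_text())
    return [
        CellROI(
            cell_outline=np.array(rec["cell_outline"]),
            nucleus_outline=np.array(rec["nucleus_outline"]),
            pixel_size=rec.get("pixel_size", 1.0),
            cell_id=rec.get("cell_id", f"cell{i}"),
        )
        for i, rec in enumerate(records)
    ]


def load_rois_csv(path: str | Path) -> list[CellROI]:
    """CSV columns: cell_id, structure ∈ {cell, nucleus}, vertex_index, x, y."""
    df = pd.read_csv(path)
    rois = []
    for cid, g in df.groupby("cell_id", sort=False):
        parts = {}
        for structure, gg in g.groupby("structure"):
            gg = gg.sort_values("vertex_index")
            parts[structure] = gg[["x", "y"]].to_numpy(dtype=float)
        if "cell" not in parts or "nucleus" not in parts:
            raise TraffiqError("degenerate-roi", f"cell {cid}: missing outline rows")
        rois.append(
            CellROI(cell_outline=parts["cell"], nucleus_outline=parts["nucleus"],
                    cell_id=str(cid))
        )
    return rois


def export_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 single-channel TIFF."""
    tifffile.imwrite(str(path), (mask.astype(np.uint8) * 255))
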