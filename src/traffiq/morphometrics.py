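"""Focal-adhesion morphometrics, Golgi area, and front-rear polarity scoring.

Focal adhesions (phospho-paxillin puncta) are segmented by thresholding
within the cell mask and labeling 8-connected components, discarding
fragments below ``min_size``; the per-cell count and mean area report FA
maturation state. Golgi compactness is summarized by the suprathreshold
area of the Golgi channel. Polarity toward a migratory front is scored by
the fraction of structure signal (or particle centroids) falling inside an
angular sector rooted at the nucleus centroid: a cell is polarized when the
sector holds a strict majority (> 0.5) of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import TraffiqError
from .geometry import SectorRegion

__all__ = [
    "ParticleTable",
    "PolarityResult",
    "segment_puncta",
    "golgi_area",
    "polarity_score",
    "percent_polarized",
]


@dataclass
class ParticleTable:
    particles: pd.DataFrame  # id, centroid_x, centroid_y, area_px2, area_um2, mean_intensity
    count: int
    mean_area_px2: float  # NaN when count == 0
    cell_id: str = "cell"


@dataclass
class PolarityResult:
    cell_id: str
    in_sector_fraction: float
    polarized: bool
    basis: str  # "intensity" | "count"


def _threshold(image: np.ndarray, mask: np.ndarray, method) -> float:
    if isinstance(method, (int, float)):
        return float(method)
    if method == "otsu":
        vals = image[mask]
        if vals.min() == vals.max():
            return float(vals.min())
        return float(threshold_otsu(vals))
    raise TraffiqError("bad-config", f"unknown threshold method {method!r}")


def segment_puncta(
    image: np.ndarray,
    cell_mask: np.ndarray,
    threshold_method: str | float = "otsu",
    min_size: int = 4,
    pixel_size: float = 1.0,
    cell_id: str = "cell",
) -> ParticleTable:
    """Particle analysis of a puncta channel within one cell.

    Suprathreshold pixels are labeled as 8-connected components; components
    smaller than ``min_size`` px² are discarded. No suprathreshold pixels is
    a valid result (count 0), not an error.
    """
    if not cell_mask.any():
        raise TraffiqError("empty-compartment", "empty cell mask")
    if min_size < 1:
        raise TraffiqError("bad-config", "min_size must be >= 1")
    img = np.asarray(image, dtype=float)
    t = _threshold(img, cell_mask, threshold_method)
    fg = (img > t) & cell_mask
    lab = label(fg, connectivity=2)
    rows = []
    for rp in regionprops(lab, intensity_image=img):
        if rp.area < min_size:
            continue
        cy, cx = rp.centroid
        rows.append(
            {
                "id": rp.label,
                "centroid_x": cx,
                "centroid_y": cy,
                "area_px2": float(rp.area),
                "area_um2": float(rp.area) * pixel_size**2,
                "mean_intensity": float(rp.intensity_mean),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "centroid_x", "centroid_y", "area_px2", "area_um2", "mean_intensity"],
    )
    count = len(df)
    mean_area = float(df["area_px2"].mean()) if count else float("nan")
    return ParticleTable(particles=df, count=count, mean_area_px2=mean_area, cell_id=cell_id)


def golgi_area(
    image: np.ndarray,
    cell_mask: np.ndarray,
    threshold_method: str | float = "otsu",
    pixel_size: float = 1.0,
) -> dict:
    """Total suprathreshold area of the Golgi channel within the cell."""
    if not cell_mask.any():
        raise TraffiqError("empty-compartment", "empty cell mask")
    img = np.asarray(image, dtype=float)
    t = _threshold(img, cell_mask, threshold_method)
    area_px2 = int(((img > t) & cell_mask).sum())
    return {"area_px2": area_px2, "area_um2": area_px2 * pixel_size**2, "threshold": t}


def polarity_score(
    source: ParticleTable | np.ndarray,
    sector: SectorRegion,
    basis: str = "intensity",
    cell_mask: np.ndarray | None = None,
    threshold_method: str | float = "otsu",
    cell_id: str = "cell",
) -> PolarityResult:
    """Fraction of structure signal inside the front sector.

    Intensity basis: fraction of total suprathreshold intensity whose pixels
    fall in the sector (``source`` is an image; ``cell_mask`` required).
    Count basis: fraction of particle centroids in the sector (``source`` is
    a :class:`ParticleTable`). Polarized means strictly more than half.
    """
    if basis == "count":
        if not isinstance(source, ParticleTable):
            raise TraffiqError("bad-config", "count basis needs a ParticleTable")
        if source.count == 0:
            raise TraffiqError("no-structures")
        inside = sector.contains_points(
            source.particles["centroid_x"].to_numpy(),
            source.particles["centroid_y"].to_numpy(),
        )
        frac = float(inside.mean())
    elif basis == "intensity":
        if isinstance(source, ParticleTable):
            raise TraffiqError("bad-config", "intensity basis needs an image")
        if cell_mask is None:
            raise TraffiqError("bad-config", "intensity basis needs a cell_mask")
        img = np.asarray(source, dtype=float)
        t = _threshold(img, cell_mask, threshold_method)
        fg = (img > t) & cell_mask
        if not fg.any():
            raise TraffiqError("no-structures")
        total = img[fg].sum()
        sec = sector.mask(img.shape)
        frac = float(img[fg & sec].sum() / total)
    else:
        raise TraffiqError("bad-config", f"unknown basis {basis!r}")
    return PolarityResult(
        cell_id=cell_id, in_sector_fraction=frac, polarized=frac > 0.5, basis=basis
    )


def percent_polarized(results: list[PolarityResult] | list[bool]) -> float:
    """Fraction of scored cells called polarized."""
    if not results:
        raise TraffiqError("no-cells")
    flags = [r.polarized if isinstance(r, PolarityResult) else bool(r) for r in results]
    return float(np.mean(flags))
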