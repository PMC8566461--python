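"""Synthetic fluorescence scenes with known ground truth.

Every measurement in this package is validated against data whose generative
parameters are known exactly. The simulator emulates the cell geometry of
single-cell trafficking micrographs:

* a cell outline (ellipse with low-order Fourier boundary perturbation) and
  a concentric-ish nucleus;
* cargo puncta (e.g. fluorescent transferrin) rendered as isotropic Gaussian
  spots whose radial position is drawn from a two-component mixture —
  perinuclear band with probability ``perinuclear_weight``, peripheral band
  otherwise — the knob that emulates slow (epithelial-like, peripheral) vs
  fast (mesenchymal-like, perinuclear) trafficking states;
* a DAPI channel (filled nucleus), a Golgi blob abutting the nucleus, and a
  marker channel for colocalization experiments with a controllable
  probability that each cargo punctum lands inside the marker;
* edge-localized focal-adhesion disks with an optional bias toward a front
  sector;
* additive Gaussian read noise and optional Poisson shot noise.

Companion generators emit vesicle/cell track tables (directed or Brownian
motion), pH-sensor maturation movies (linear intensity ramps), in-cell-ELISA
plate tables with known internalized/recycled fractions, and densitometry
tables with a known half-life. All outputs are bit-reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import LineString, Point

from .errors import TraffiqError
from .geometry import CellROI, ellipse_polygon

__all__ = [
    "SceneConfig",
    "Scene",
    "simulate_scene",
    "simulate_tracks",
    "simulate_plate",
    "simulate_decay",
    "simulate_maturation_movie",
    "simulate_coloc_timecourse",
    "write_scenes",
]


@dataclass
class SceneConfig:
    """Generative parameters for a batch of single-cell scenes."""

    n_cells: int = 25
    image_size: int = 160
    cell_radius_range: tuple[float, float] = (45.0, 60.0)
    cell_aspect_range: tuple[float, float] = (0.8, 1.0)
    nucleus_radius_fraction: float = 0.35
    boundary_noise: float = 0.06  # Fourier perturbation amplitude (fraction of radius)
    # cargo puncta
    n_puncta: int = 30
    punctum_amplitude: float = 200.0
    psf_sigma: float = 2.0
    perinuclear_weight: float = 0.5  # p: probability a punctum is perinuclear
    perinuclear_u: tuple[float, float] = (0.03, 0.25)  # normalized radial band
    peripheral_u: tuple[float, float] = (0.85, 0.97)
    # marker / colocalization
    cargo_marker_overlap: float | None = None  # P(cargo punctum inside marker blob)
    # Golgi
    golgi_area_px2: float = 400.0
    golgi_amplitude: float = 150.0
    # focal adhesions
    n_fa: int = 0
    fa_mean_area_px2: float = 60.0
    fa_area_cv: float = 0.1
    fa_amplitude: float = 180.0
    fa_u_band: tuple[float, float] = (0.45, 0.9)
    fa_front_bias: float | None = None  # q: P(FA in front sector); None = uniform
    front_direction_deg: float = 0.0
    front_half_width_deg: float = 60.0
    # DAPI
    dapi_amplitude: float = 150.0
    # noise
    background: float = 10.0
    gaussian_noise_sigma: float = 2.0
    poisson_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.nucleus_radius_fraction < 1):
            raise TraffiqError("bad-config", "nucleus_radius_fraction must be in (0, 1)")
        if not (0 <= self.perinuclear_weight <= 1):
            raise TraffiqError("bad-config", "perinuclear_weight must be in [0, 1]")
        if self.n_puncta < 0 or self.n_fa < 0:
            raise TraffiqError("bad-config", "counts must be >= 0")
        lo, hi = self.cell_radius_range
        if hi * 2 + 10 > self.image_size:
            raise TraffiqError("bad-config", "cells do not fit in the image")


@dataclass
class Scene:
    """One simulated cell: channel images, ROI, and its ground truth."""

    cell_id: str
    images: dict[str, np.ndarray]
    roi: CellROI
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rendering primitives


def _add_gaussian(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


def _add_disk(img: np.ndarray, x: float, y: float, amp: float, radius: float) -> int:
    """Add a hard disk; returns the number of pixels covered."""
    h, w = img.shape
    r = int(np.ceil(radius)) + 1
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    img[y0:y1, x0:x1][inside] += amp
    return int(inside.sum())


def _finalize(img: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    out = img + cfg.background
    if cfg.poisson_noise:
        out = rng.poisson(np.maximum(out, 0)).astype(float)
    if cfg.gaussian_noise_sigma > 0:
        out = out + rng.normal(0, cfg.gaussian_noise_sigma, out.shape)
    return np.maximum(out, 0.0).astype(np.float32)


def _ray_radius(outline_poly, center: tuple[float, float], angle: float, span: float) -> float:
    """Distance from center to the outline along a ray."""
    cx, cy = center
    ray = LineString([(cx, cy), (cx + span * np.cos(angle), cy + span * np.sin(angle))])
    hit = ray.intersection(outline_poly.exterior)
    if hit.is_empty:
        return 0.0
    pts = [hit] if isinstance(hit, Point) else [g for g in hit.geoms if isinstance(g, Point)]
    if not pts:
        return 0.0
    p = min(pts, key=lambda q: (q.x - cx) ** 2 + (q.y - cy) ** 2)
    return float(np.hypot(p.x - cx, p.y - cy))


# ---------------------------------------------------------------------------
# scenes


def _one_cell(cfg: SceneConfig, rng: np.random.Generator, idx: int) -> Scene:
    size = cfg.image_size
    cx = cy = size / 2.0
    r_cell = rng.uniform(*cfg.cell_radius_range)
    aspect = rng.uniform(*cfg.cell_aspect_range)
    rot = rng.uniform(0, 2 * np.pi)
    cell_poly = ellipse_polygon(
        (cx, cy), r_cell, r_cell * aspect,
        fourier_amplitude=cfg.boundary_noise, rng=rng, rotation=rot,
    )
    r_nuc = cfg.nucleus_radius_fraction * r_cell
    # small nucleus offset, kept well inside the cell
    off = rng.uniform(0, 0.15 * r_cell)
    ang = rng.uniform(0, 2 * np.pi)
    ncx, ncy = cx + off * np.cos(ang), cy + off * np.sin(ang)
    nuc_poly = ellipse_polygon((ncx, ncy), r_nuc, r_nuc * rng.uniform(0.85, 1.0))
    roi = CellROI(cell_outline=cell_poly, nucleus_outline=nuc_poly,
                  cell_id=f"cell{idx:03d}")
    roi.validate()
    cell_geo, nuc_geo = roi.cell_polygon, roi.nucleus_polygon
    center = roi.nucleus_centroid
    span = 4.0 * r_cell + 10

    def radial_point(u: float, theta: float) -> tuple[float, float]:
        rn = _ray_radius(nuc_geo, center, theta, span)
        rc = _ray_radius(cell_geo, center, theta, span)
        rr = rn + u * (rc - rn)
        return (center[0] + rr * np.cos(theta), center[1] + rr * np.sin(theta))

    truth: dict = {"cell_id": roi.cell_id, "cell_radius_px": r_cell,
                   "nucleus_radius_px": r_nuc}
    images: dict[str, np.ndarray] = {}

    # --- Golgi blob abutting the nucleus
    g_r = float(np.sqrt(cfg.golgi_area_px2 / np.pi))
    g_theta = rng.uniform(0, 2 * np.pi)
    g_dist = _ray_radius(nuc_geo, center, g_theta, span) + g_r * 0.9
    gx, gy = center[0] + g_dist * np.cos(g_theta), center[1] + g_dist * np.sin(g_theta)
    golgi = np.zeros((size, size))
    golgi_px = _add_disk(golgi, gx, gy, cfg.golgi_amplitude, g_r)
    truth["golgi"] = {"x": gx, "y": gy, "radius_px": g_r, "area_px2": golgi_px}

    # --- cargo puncta: radial mixture, or overlap-driven placement
    cargo = np.zeros((size, size))
    puncta = []
    for _ in range(cfg.n_puncta):
        if cfg.cargo_marker_overlap is not None:
            on_marker = bool(rng.random() < cfg.cargo_marker_overlap)
            if on_marker:
                rho = g_r * np.sqrt(rng.random()) * 0.85
                phi = rng.uniform(0, 2 * np.pi)
                px, py = gx + rho * np.cos(phi), gy + rho * np.sin(phi)
                klass = "on-marker"
            else:
                theta = rng.uniform(0, 2 * np.pi)
                px, py = radial_point(rng.uniform(*cfg.peripheral_u), theta)
                klass = "off-marker"
        else:
            perinuclear = bool(rng.random() < cfg.perinuclear_weight)
            band = cfg.perinuclear_u if perinuclear else cfg.peripheral_u
            theta = rng.uniform(0, 2 * np.pi)
            px, py = radial_point(rng.uniform(*band), theta)
            klass = "perinuclear" if perinuclear else "peripheral"
        _add_gaussian(cargo, px, py, cfg.punctum_amplitude, cfg.psf_sigma)
        puncta.append({"x": px, "y": py, "class": klass})
    truth["puncta"] = puncta
    truth["n_perinuclear_true"] = sum(p["class"] == "perinuclear" for p in puncta)
    if cfg.cargo_marker_overlap is not None:
        truth["fraction_on_marker_true"] = (
            sum(p["class"] == "on-marker" for p in puncta) / max(cfg.n_puncta, 1)
        )

    # --- DAPI: filled nucleus
    dapi = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    nuc_mask = shapely.contains_xy(nuc_geo, xx.ravel(), yy.ravel()).reshape(size, size)
    dapi[nuc_mask] = cfg.dapi_amplitude

    # --- focal adhesions: non-overlapping edge disks, optional front bias
    fa = np.zeros((size, size))
    fa_truth = []
    if cfg.n_fa > 0:
        front = np.deg2rad(cfg.front_direction_deg)
        hw = np.deg2rad(cfg.front_half_width_deg)
        centers: list[tuple[float, float, float]] = []
        attempts = 0
        while len(fa_truth) < cfg.n_fa and attempts < cfg.n_fa * 1000:
            attempts += 1
            if cfg.fa_front_bias is None:
                theta = rng.uniform(0, 2 * np.pi)
                in_front = bool(np.abs(np.angle(np.exp(1j * (theta - front)))) <= hw)
            else:
                in_front = bool(rng.random() < cfg.fa_front_bias)
                if in_front:
                    theta = front + rng.uniform(-hw, hw)
                else:
                    # uniform over the complement arc
                    theta = front + hw + rng.uniform(0, 2 * np.pi - 2 * hw)
            u = rng.uniform(*cfg.fa_u_band)
            px, py = radial_point(u, theta)
            area = max(rng.normal(cfg.fa_mean_area_px2, cfg.fa_area_cv * cfg.fa_mean_area_px2), 4.0)
            r_d = np.sqrt(area / np.pi)
            # 8-connectivity: a >2 px gap keeps components separable
            if any(np.hypot(px - qx, py - qy) < r_d + qr + 2.5 for qx, qy, qr in centers):
                continue
            px_count = _add_disk(fa, px, py, cfg.fa_amplitude, r_d)
            centers.append((px, py, r_d))
            fa_truth.append(
                {"x": px, "y": py, "nominal_area_px2": float(area),
                 "rendered_area_px2": px_count, "in_front_sector": in_front}
            )
        if len(fa_truth) < cfg.n_fa:
            raise TraffiqError("bad-config", "could not place all FAs without overlap")
    truth["fa"] = fa_truth
    if fa_truth:
        truth["fa_in_sector_fraction_true"] = float(
            np.mean([f["in_front_sector"] for f in fa_truth])
        )

    images["cargo"] = _finalize(cargo, cfg, rng)
    images["dapi"] = _finalize(dapi, cfg, rng)
    images["golgi"] = _finalize(golgi, cfg, rng)
    images["marker"] = images["golgi"]  # marker == Golgi blob channel
    if cfg.n_fa > 0:
        images["fa"] = _finalize(fa, cfg, rng)
    return Scene(cell_id=roi.cell_id, images=images, roi=roi, ground_truth=truth)


def simulate_scene(config: SceneConfig) -> list[Scene]:
    """Generate ``config.n_cells`` single-cell scenes (one cell per tile)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return [_one_cell(config, rng, i) for i in range(config.n_cells)]


# ---------------------------------------------------------------------------
# tracks


def simulate_tracks(
    n_tracks: int,
    motion: str = "directed",
    v: float = 0.5,
    jitter: float = 0.05,
    sigma: float = 0.5,
    n_frames: int = 50,
    dt: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Track table with known motion parameters.

    ``directed``: each frame steps v·dt along a per-track fixed unit
    direction plus isotropic Gaussian jitter (per-axis std ``jitter``).
    ``brownian``: per-axis steps N(0, σ²). Returns the tidy table
    (track_id, frame, t, x, y) and the ground-truth parameter record.
    """
    if n_frames < 2:
        raise TraffiqError("bad-config", "n_frames must be >= 2")
    if motion not in ("directed", "brownian"):
        raise TraffiqError("bad-config", f"unknown motion {motion!r}")
    rng = np.random.default_rng(seed)
    rows = []
    directions = []
    for i in range(n_tracks):
        x, y = rng.uniform(0, 100, 2)
        theta = rng.uniform(0, 2 * np.pi)
        directions.append(theta)
        for f in range(n_frames):
            rows.append({"track_id": f"track{i:04d}", "frame": f, "t": f * dt,
                         "x": x, "y": y})
            if motion == "directed":
                x += v * dt * np.cos(theta) + rng.normal(0, jitter)
                y += v * dt * np.sin(theta) + rng.normal(0, jitter)
            else:
                x += rng.normal(0, sigma)
                y += rng.normal(0, sigma)
    truth = {"motion": motion, "v": v, "jitter": jitter, "sigma": sigma,
             "n_frames": n_frames, "dt": dt, "directions": directions}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# plates, decay, maturation movies


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(n)
    s2 = np.log(1 + cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=n)


def simulate_plate(
    true_uptake: float,
    true_recycled: float,
    n_replicates: int = 6,
    noise_cv: float = 0.05,
    condition: str = "sim",
    time_min: float = 10.0,
    surface_signal: float = 1000.0,
    bca_signal: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """In-cell-ELISA plate table with known internalized/recycled fractions.

    Roles: ``surface_total`` wells carry the total surface-bound signal,
    ``sample`` wells the internalized signal (uptake × surface), and
    ``strip_control`` wells the signal remaining after the final strip
    (internalized × (1 − recycled)). Every well gets independent
    multiplicative lognormal noise (unit mean, CV ``noise_cv``) on both the
    detection signal and the BCA protein readout.
    """
    if not (0 <= true_uptake <= 1 and 0 <= true_recycled <= 1):
        raise TraffiqError("bad-config", "fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    roles = (["surface_total"] * n_replicates + ["sample"] * n_replicates
             + ["strip_control"] * n_replicates)
    base = {
        "surface_total": surface_signal,
        "sample": surface_signal * true_uptake,
        "strip_control": surface_signal * true_uptake * (1 - true_recycled),
    }
    n = len(roles)
    sig_noise = _lognormal_factor(rng, noise_cv, n)
    bca_noise = _lognormal_factor(rng, noise_cv, n)
    df = pd.DataFrame(
        {
            "well": [f"{chr(65 + i // 12)}{i % 12 + 1}" for i in range(n)],
            "condition": condition,
            "time_min": time_min,
            "signal": [base[r] for r in roles] * np.ones(n),
            "bca_signal": bca_signal * np.ones(n),
            "role": roles,
        }
    )
    df["signal"] = df["signal"] * sig_noise * (df["bca_signal"] * bca_noise / bca_signal)
    df["bca_signal"] = df["bca_signal"] * bca_noise
    truth = {"true_uptake": true_uptake, "true_recycled": true_recycled,
             "noise_cv": noise_cv, "n_replicates": n_replicates}
    return df, truth


def simulate_decay(
    half_life_min: float,
    times_min: np.ndarray,
    noise_cv: float = 0.05,
    control_noise_cv: float = 0.0,
    band0: float = 1000.0,
    control: float = 500.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Densitometry table (time_min, band, control) with a known half-life.

    Band intensities decay exponentially with multiplicative lognormal noise
    of CV ``noise_cv``. The loading control is constant; give it its own
    ``control_noise_cv`` to emulate uneven loading (which the normalization
    should cancel on average).
    """
    t = np.asarray(times_min, dtype=float)
    rng = np.random.default_rng(seed)
    k = np.log(2) / half_life_min
    band = band0 * np.exp(-k * t) * _lognormal_factor(rng, noise_cv, len(t))
    ctrl = control * _lognormal_factor(rng, control_noise_cv, len(t))
    df = pd.DataFrame({"time_min": t, "band": band, "control": ctrl})
    return df, {"half_life_min": half_life_min, "k": k, "noise_cv": noise_cv}


def simulate_maturation_movie(
    ramp_factor: float = 2.0,
    n_frames: int = 10,
    n_vesicles: int = 15,
    base_amplitude: float = 100.0,
    config: SceneConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, CellROI, dict]:
    """Time-lapse stack whose vesicle amplitude ramps linearly ×ramp_factor.

    Emulates a pH-sensor (pHrodo) movie: fixed vesicle positions, intensity
    rising as vesicles acidify. Returns (movie, roi, truth).
    """
    cfg = dataclasses.replace(
        config or SceneConfig(gaussian_noise_sigma=1.0),
        n_cells=1, n_puncta=n_vesicles, seed=seed, punctum_amplitude=base_amplitude,
    )
    cfg.validate()
    rng = np.random.default_rng(seed)
    scene = _one_cell(cfg, rng, 0)
    size = cfg.image_size
    frames = []
    for f in range(n_frames):
        scale = 1 + (ramp_factor - 1) * f / (n_frames - 1)
        img = np.zeros((size, size))
        for p in scene.ground_truth["puncta"]:
            _add_gaussian(img, p["x"], p["y"], base_amplitude * scale, cfg.psf_sigma)
        frames.append(_finalize(img, cfg, rng))
    truth = {"ramp_factor": ramp_factor, "n_frames": n_frames,
             "base_amplitude": base_amplitude}
    return np.stack(frames), scene.roi, truth


def simulate_coloc_timecourse(
    overlaps: list[float],
    times_min: list[float],
    config: SceneConfig | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray], CellROI, dict]:
    """Cargo/marker frame pairs whose true overlap follows ``overlaps``.

    The marker (Golgi blob) stays fixed; at each time point cargo puncta are
    re-drawn with P(on marker) = overlaps[i], emulating cargo arriving at
    the Golgi over time. Returns (cargo_frames, marker_frames, roi, truth).
    """
    if len(overlaps) != len(times_min):
        raise TraffiqError("length-mismatch")
    cfg = dataclasses.replace(config or SceneConfig(), n_cells=1,
                              cargo_marker_overlap=float(overlaps[0]), seed=seed)
    cfg.validate()
    rng = np.random.default_rng(seed)
    base = _one_cell(cfg, rng, 0)  # fixes geometry, Golgi/marker and frame 0
    roi = base.roi
    g = base.ground_truth["golgi"]
    gx, gy, g_r = g["x"], g["y"], g["radius_px"]
    center = roi.nucleus_centroid
    span = 4.0 * float(np.abs(roi.cell_outline).max()) + 10
    nuc_geo, cell_geo = roi.nucleus_polygon, roi.cell_polygon

    def _peripheral_point(r: np.random.Generator) -> tuple[float, float]:
        theta = r.uniform(0, 2 * np.pi)
        rn = _ray_radius(nuc_geo, center, theta, span)
        rc = _ray_radius(cell_geo, center, theta, span)
        u = r.uniform(*cfg.peripheral_u)
        rr = rn + u * (rc - rn)
        return (center[0] + rr * np.cos(theta), center[1] + rr * np.sin(theta))

    size = cfg.image_size
    cargo_frames, marker_frames, realized = [], [], []
    for i, ov in enumerate(overlaps):
        if i == 0:
            cargo_frames.append(base.images["cargo"])
            realized.append(base.ground_truth.get("fraction_on_marker_true", ov))
        else:
            img = np.zeros((size, size))
            n_on = 0
            for _ in range(cfg.n_puncta):
                if rng.random() < ov:
                    rho = g_r * np.sqrt(rng.random()) * 0.85
                    phi = rng.uniform(0, 2 * np.pi)
                    px, py = gx + rho * np.cos(phi), gy + rho * np.sin(phi)
                    n_on += 1
                else:
                    px, py = _peripheral_point(rng)
                _add_gaussian(img, px, py, cfg.punctum_amplitude, cfg.psf_sigma)
            cargo_frames.append(_finalize(img, cfg, rng))
            realized.append(n_on / max(cfg.n_puncta, 1))
        marker_frames.append(base.images["marker"])
    truth = {"overlaps_true": list(overlaps), "overlaps_realized": realized,
             "times_min": list(times_min)}
    return cargo_frames, marker_frames, roi, truth


# ---------------------------------------------------------------------------
# writers


def write_scenes(scenes: list[Scene], outdir: str | Path) -> dict:
    """Write per-channel TIFFs, ROI JSON and ground-truth JSON; returns paths."""
    from .geometry import save_rois_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channels = sorted({ch for s in scenes for ch in s.images})
    paths: dict = {"tiffs": {}, "rois": str(outdir / "rois.json"),
                   "ground_truth": str(outdir / "ground_truth.json")}
    for ch in channels:
        stack = np.stack([s.images[ch] for s in scenes])
        p = outdir / f"{ch}.tif"
        tifffile.imwrite(str(p), stack)
        paths["tiffs"][ch] = str(p)
    save_rois_json([s.roi for s in scenes], paths["rois"])
    Path(paths["ground_truth"]).write_text(
        json.dumps([s.ground_truth for s in scenes], indent=1, default=float)
    )
    return paths
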