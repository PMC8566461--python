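"""Trajectory statistics, vesicle-maturation series, and plate/densitometry kinetics.

Tracks arrive as tables (tracking itself is done upstream or by the
simulator); this module computes the three statistics reported per
trajectory — speed (path length over elapsed time), net displacement, and
directionality (net displacement / path length, a persistence index in
[0, 1]) — plus:

* per-frame mean vesicle intensity over time for pH-sensor (pHrodo)
  maturation movies, optionally normalized fold-over-t0;
* in-cell-ELISA kinetics: percent of surface-bound cargo internalized at
  each chase time and the recycled fraction lost after a final acid strip,
  both BCA-protein-normalized;
* densitometric degradation curves normalized to a loading control and
  expressed as % of the t = 0 amount, with an optional single-exponential
  fit yielding a half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import TraffiqError

__all__ = [
    "Track",
    "TrackStats",
    "MaturationSeries",
    "KineticsRecord",
    "DecayCurve",
    "track_stats",
    "tracks_from_table",
    "maturation_series",
    "endocytosis_fraction",
    "endocytosis_fraction_from_plate",
    "recycled_fraction",
    "degradation_curve",
]


@dataclass
class Track:
    track_id: str
    t: np.ndarray  # seconds or frame index, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)


@dataclass
class TrackStats:
    track_id: str
    speed: float  # path length / elapsed time
    net_displacement: float
    path_length: float
    directionality: float  # net / path, in [0, 1]


@dataclass
class MaturationSeries:
    cell_id: str
    times: np.ndarray
    mean_vesicle_intensity: np.ndarray  # NaN where a frame had no vesicle pixels
    normalization: str = "raw"  # "raw" | "fold-over-t0"
    missing_frames: list[int] = field(default_factory=list)


@dataclass
class KineticsRecord:
    condition: str
    internalized: float
    surface_bound_total: float
    remaining_after_strip: float = 0.0
    protein_norm: float = 1.0
    protein_norm_reference: float | None = None  # BCA of the surface_total wells


@dataclass
class DecayCurve:
    times: np.ndarray  # minutes
    normalized_intensity: np.ndarray  # % of t=0 after loading-control normalization
    fitted_half_life: float | None = None  # minutes
    fit_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trajectories


def track_stats(track: Track) -> TrackStats:
    """Speed, net displacement, path length and directionality of one track."""
    if len(track.t) < 2:
        raise TraffiqError("track-too-short")
    if not np.all(np.isfinite(track.t)) or not np.all(np.diff(track.t) > 0):
        raise TraffiqError("bad-timebase", "t must be finite and strictly increasing")
    if not (np.all(np.isfinite(track.x)) and np.all(np.isfinite(track.y))):
        raise TraffiqError("bad-timebase", "non-finite coordinates")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(steps.sum())
    net = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    elapsed = float(track.t[-1] - track.t[0])
    speed = path / elapsed
    directionality = net / path if path > 0 else 0.0
    return TrackStats(
        track_id=track.track_id,
        speed=speed,
        net_displacement=net,
        path_length=path,
        directionality=directionality,
    )


def tracks_from_table(df: pd.DataFrame) -> list[Track]:
    """Build tracks from a table with columns track_id, t, x, y (frame optional)."""
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("t")
        tracks.append(Track(track_id=str(tid), t=g["t"].to_numpy(),
                            x=g["x"].to_numpy(), y=g["y"].to_numpy()))
    return tracks


# ---------------------------------------------------------------------------
# maturation (pH-sensor) time series


def maturation_series(
    movie: np.ndarray,
    cell_mask: np.ndarray,
    vesicle_threshold: float,
    times: np.ndarray | None = None,
    normalization: str = "raw",
    fixed_mask: bool = True,
    subtract_background: bool = True,
    cell_id: str = "cell",
) -> MaturationSeries:
    """Mean suprathreshold vesicle intensity per frame within one cell.

    ``movie`` is a (frames, rows, cols) stack. With ``fixed_mask`` (default)
    the vesicle pixel set is determined on the first frame and reused, so
    the series tracks intensity change of the same structures rather than
    the growing suprathreshold footprint of brightening spots; otherwise the
    set is re-thresholded per frame. ``subtract_background`` removes the
    per-frame median intensity outside the cell mask. A frame with no
    vesicle pixels is recorded as NaN and listed in ``missing_frames``.
    Fold-over-t0 normalization divides by the first non-missing frame.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise TraffiqError("bad-config", "movie must be a stack of >= 2 frames")
    times = np.arange(movie.shape[0], dtype=float) if times is None else np.asarray(times, float)
    vals = np.full(movie.shape[0], np.nan)
    missing = []
    base_ves = (movie[0] > vesicle_threshold) & cell_mask
    for i, frame in enumerate(movie):
        ves = base_ves if fixed_mask else (frame > vesicle_threshold) & cell_mask
        if ves.any():
            bg = float(np.median(frame[~cell_mask])) if subtract_background and (~cell_mask).any() else 0.0
            vals[i] = max(frame[ves].mean() - bg, 0.0)
        else:
            missing.append(i)
    if normalization == "fold-over-t0":
        finite = np.flatnonzero(np.isfinite(vals))
        if finite.size == 0:
            raise TraffiqError("no-structures", "no vesicle pixels in any frame")
        vals = vals / vals[finite[0]]
    elif normalization != "raw":
        raise TraffiqError("bad-config", f"unknown normalization {normalization!r}")
    return MaturationSeries(
        cell_id=cell_id, times=times, mean_vesicle_intensity=vals,
        normalization=normalization, missing_frames=missing,
    )


# ---------------------------------------------------------------------------
# plate kinetics


def endocytosis_fraction(record: KineticsRecord) -> float:
    """Percent of total surface-bound cargo internalized, protein-normalized.

    Sample and reference signals are each divided by their BCA protein
    readout before taking the ratio, so a common scaling of all raw signals
    cancels.
    """
    ref_norm = (
        record.protein_norm_reference
        if record.protein_norm_reference is not None
        else record.protein_norm
    )
    if record.protein_norm <= 0 or ref_norm <= 0:
        raise TraffiqError("zero-reference", "non-positive BCA normalizer")
    denom = record.surface_bound_total / ref_norm
    if denom <= 0:
        raise TraffiqError("zero-reference", "surface_bound_total must be > 0")
    return 100.0 * (record.internalized / record.protein_norm) / denom


def endocytosis_fraction_from_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Percent internalized vs time from a tidy plate table.

    Expected columns: well, condition, time_min, signal, bca_signal,
    role ∈ {sample, surface_total, strip_control}. Per condition, each
    well's signal is BCA-normalized; the per-time mean of sample wells is
    expressed as a percentage of the mean surface_total well.
    """
    required = {"condition", "time_min", "signal", "bca_signal", "role"}
    if not required.issubset(plate.columns):
        raise TraffiqError("bad-config", f"plate table needs columns {sorted(required)}")
    out = []
    for cond, g in plate.groupby("condition", sort=False):
        ref = g[g["role"] == "surface_total"]
        if ref.empty or (ref["signal"] <= 0).all():
            raise TraffiqError("zero-reference", f"no surface_total wells for {cond}")
        ref_norm = (ref["signal"] / ref["bca_signal"]).mean()
        samples = g[g["role"] == "sample"]
        for tmin, gg in samples.groupby("time_min"):
            norm = gg["signal"] / gg["bca_signal"]
            out.append(
                {
                    "condition": cond,
                    "time_min": tmin,
                    "percent_internalized": 100.0 * norm.mean() / ref_norm,
                    "sem": 100.0 * norm.sem() / ref_norm if len(norm) > 1 else np.nan,
                    "n_wells": len(norm),
                }
            )
    return pd.DataFrame(out)


def recycled_fraction(record: KineticsRecord) -> tuple[float, bool]:
    """Fraction of internalized cargo lost after the final strip.

    Returns (fraction, clamped). Measurement noise can push the remaining
    signal above the internalized signal; the fraction is clamped to [0, 1]
    and the clamp is flagged rather than silently absorbed.
    """
    if record.internalized <= 0:
        raise TraffiqError("zero-internalized")
    raw = (record.internalized - record.remaining_after_strip) / record.internalized
    clamped = raw < 0 or raw > 1
    return float(min(max(raw, 0.0), 1.0)), clamped


# ---------------------------------------------------------------------------
# densitometry


def degradation_curve(
    band_intensities: np.ndarray,
    loading_control: np.ndarray,
    times: np.ndarray,
    fit: bool = True,
) -> DecayCurve:
    """Loading-control-normalized degradation curve, % of the t = 0 amount.

    normalized(t) = 100 · (band(t)/control(t)) / (band(0)/control(0)).
    When ``fit`` is true a single exponential A·exp(−kt) is least-squares
    fitted on the normalized scale (t = 0 included, unweighted) and the
    half-life ln 2 / k reported.
    """
    band = np.asarray(band_intensities, dtype=float)
    ctrl = np.asarray(loading_control, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (len(band) == len(ctrl) == len(t)):
        raise TraffiqError("length-mismatch")
    if np.any(ctrl <= 0):
        raise TraffiqError("zero-loading-control")
    if t[0] != 0:
        raise TraffiqError("bad-timebase", "t = 0 point required")
    ratio = band / ctrl
    if ratio[0] <= 0:
        raise TraffiqError("zero-reference", "zero band at t = 0")
    norm = 100.0 * ratio / ratio[0]
    half_life = None
    params: dict = {}
    if fit and len(t) >= 3:
        popt, _ = curve_fit(
            lambda tt, A, k: A * np.exp(-k * tt),
            t, norm, p0=(100.0, np.log(2) / max(t[-1] / 2, 1e-9)), maxfev=10000,
        )
        A, k = popt
        if k > 0:
            half_life = float(np.log(2) / k)
        params = {"A": float(A), "k": float(k)}
    return DecayCurve(times=t, normalized_intensity=norm,
                      fitted_half_life=half_life, fit_params=params)
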