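"""Manders-coefficient colocalization.

M1 is the fraction of channel-1 signal that sits on channel-2-positive
pixels; M2 the converse. Both are computed within a cell mask after
per-channel thresholding (Otsu by default, fixed cutoffs accepted). Two
weighting modes are provided:

* ``pixel-count`` (default) — fraction of channel-1 foreground *pixels*
  that are also channel-2 foreground,
* ``intensity`` — the classic intensity-weighted Manders coefficient,
  Σ I1 over double-positive pixels / Σ I1 over channel-1 foreground.

:func:`fraction_colocalized_over_time` applies M1 frame-by-frame to build
cargo-vs-marker time courses (e.g. endocytosed biotin or cholera toxin B
against the Golgi marker GM130, or MET against endosomal markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import TraffiqError

__all__ = ["ColocResult", "ColocTimeCourse", "manders", "fraction_colocalized_over_time"]


@dataclass
class ColocResult:
    m1: float  # fraction of ch1 signal overlapping ch2 foreground
    m2: float
    threshold_1: float
    threshold_2: float
    mode: str  # "pixel-count" | "intensity"
    flags: list[str] = field(default_factory=list)


@dataclass
class ColocTimeCourse:
    time_points: np.ndarray  # minutes, strictly increasing
    fraction_colocalized: pd.DataFrame  # columns: cell_id, time_min, fraction, m1, m2
    marker: str = ""


def _threshold(channel: np.ndarray, mask: np.ndarray, method) -> float:
    if isinstance(method, (int, float)):
        return float(method)
    if method == "otsu":
        vals = channel[mask]
        if vals.min() == vals.max():
            # flat channel: strict > leaves no foreground, flagged upstream
            return float(vals.min())
        return float(threshold_otsu(vals))
    raise TraffiqError("bad-config", f"unknown threshold method {method!r}")


def manders(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    threshold_method: str | float | tuple = "otsu",
    mode: str = "pixel-count",
) -> ColocResult:
    """Manders colocalization coefficients for a channel pair.

    ``threshold_method`` is ``"otsu"``, a single fixed cutoff applied to both
    channels, or a ``(t1, t2)`` pair. A channel with no suprathreshold pixels
    yields NaN for its coefficient and an ``empty-channel`` flag.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise TraffiqError("length-mismatch", "channel rasters differ in shape")
    if mask is None:
        mask = np.ones(ch1.shape, dtype=bool)
    if not mask.any():
        raise TraffiqError("empty-compartment", "empty cell mask")
    if mode not in ("pixel-count", "intensity"):
        raise TraffiqError("bad-config", f"unknown mode {mode!r}")

    if isinstance(threshold_method, tuple):
        t1, t2 = (float(threshold_method[0]), float(threshold_method[1]))
    else:
        t1 = _threshold(ch1, mask, threshold_method)
        t2 = _threshold(ch2, mask, threshold_method)

    fg1 = (ch1 > t1) & mask
    fg2 = (ch2 > t2) & mask
    both = fg1 & fg2
    flags: list[str] = []

    def _coef(fg_self, intensities):
        if not fg_self.any():
            flags.append("empty-channel")
            return float("nan")
        if mode == "pixel-count":
            return float(both.sum() / fg_self.sum())
        return float(intensities[both].sum() / intensities[fg_self].sum())

    m1 = _coef(fg1, ch1)
    m2 = _coef(fg2, ch2)
    return ColocResult(m1=m1, m2=m2, threshold_1=t1, threshold_2=t2, mode=mode, flags=flags)


def fraction_colocalized_over_time(
    cargo_frames: list[np.ndarray],
    marker_frames: list[np.ndarray],
    masks: list[np.ndarray] | np.ndarray,
    times: list[float],
    threshold_method: str | float | tuple = "otsu",
    mode: str = "pixel-count",
    marker: str = "",
    cell_id: str = "cell",
) -> ColocTimeCourse:
    """Per-time-point fraction of cargo colocalized with a marker (M1).

    ``masks`` may be one mask reused for every frame or one per time point.
    """
    if len(cargo_frames) != len(marker_frames) or len(cargo_frames) != len(times):
        raise TraffiqError("length-mismatch", "frames and times must align")
    t = np.asarray(times, dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise TraffiqError("bad-timebase", "time points must be strictly increasing")
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks] * len(t)
    rows = []
    for ti, cargo, mk, msk in zip(t, cargo_frames, marker_frames, masks):
        res = manders(cargo, mk, msk, threshold_method=threshold_method, mode=mode)
        rows.append(
            {"cell_id": cell_id, "time_min": ti, "marker": marker,
             "fraction": res.m1, "m1": res.m1, "m2": res.m2,
             "threshold_1": res.threshold_1, "threshold_2": res.threshold_2}
        )
    return ColocTimeCourse(
        time_points=t, fraction_colocalized=pd.DataFrame(rows), marker=marker
    )
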