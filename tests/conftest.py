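import numpy as np
import pytest

from traffiq.geometry import CellROI, ellipse_polygon


@pytest.fixture
def circle_roi():
    """Circular cell r=100 with a concentric nucleus r=30, centered at (105, 105)."""
    return CellROI(
        cell_outline=ellipse_polygon((105.0, 105.0), 100.0, n_vertices=256),
        nucleus_outline=ellipse_polygon((105.0, 105.0), 30.0, n_vertices=128),
    )


@pytest.fixture
def small_circle_roi():
    """Small circular cell (r=40, nucleus r=14) for cheaper rasterization."""
    return CellROI(
        cell_outline=ellipse_polygon((45.0, 45.0), 40.0, n_vertices=180),
        nucleus_outline=ellipse_polygon((45.0, 45.0), 14.0, n_vertices=90),
    )


def manders_bruteforce(ch1, ch2, mask, t1, t2, mode):
    """Independent per-pixel double loop over the image (the oracle)."""
    num1 = den1 = num2 = den2 = 0.0
    h, w = ch1.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            a, b = float(ch1[i, j]), float(ch2[i, j])
            fg1, fg2 = a > t1, b > t2
            w1 = a if mode == "intensity" else 1.0
            w2 = b if mode == "intensity" else 1.0
            if fg1:
                den1 += w1
                if fg2:
                    num1 += w1
            if fg2:
                den2 += w2
                if fg1:
                    num2 += w2
    m1 = num1 / den1 if den1 else float("nan")
    m2 = num2 / den2 if den2 else float("nan")
    return m1, m2
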