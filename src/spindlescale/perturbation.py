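"""Laser-ablation response statistics and microtubule-class geometry.

Ablation series are distance traces (pole-to-pole, pole-to-chromosome,
chromosome-to-chromosome) re-timed so t = 0 is the cut.  Separation
velocities before and after the cut are slopes of ordinary least-squares
fits in the fixed windows (-8, 0] s and (4, 12) s; unperturbed controls go
through the identical windows.

Microtubule segments from tomogram endpoint tables are classified by
spindle geometry: a segment with both endpoints axially between the two
chromatid-plate planes is *mid-spindle*; otherwise, one with an endpoint
within a proximity radius of either centriole is *interpolar*; everything
else is *other*.  Mid-spindle takes precedence when both rules match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AblationSeries",
    "VelocityResult",
    "SpindleGeometry",
    "MicrotubuleSegment",
    "WINDOW_BEFORE",
    "WINDOW_AFTER",
    "compute_separation_velocities",
    "relative_distance_curves",
    "classify_microtubules",
]

# fitting windows in seconds relative to the cut; before-window is half-open
# at zero, i.e. -8 < t <= 0, and after-window is open, 4 < t < 12
WINDOW_BEFORE = (-8.0, 0.0)
WINDOW_AFTER = (4.0, 12.0)


@dataclass
class AblationSeries:
    """Distance traces around one cut, with t = 0 at the ablation frame."""

    times: np.ndarray
    d_pp: np.ndarray
    d_pc: np.ndarray
    d_cc: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("d_pp", "d_pc", "d_cc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != len(self.times):
                raise ValueError(f"{name} not aligned with times")
            setattr(self, name, arr)


@dataclass(frozen=True)
class VelocityResult:
    v_before: float  # um/s
    v_after: float  # um/s
    delta: float  # um/s, v_after - v_before
    window_before: tuple[float, float]
    window_after: tuple[float, float]
    n_before: int
    n_after: int
    rms_before: float
    rms_after: float


@dataclass(frozen=True)
class SpindleGeometry:
    """Pole and chromatid-plate positions defining the classification frame."""

    centriole_positions: tuple  # two 3-D points, um
    plate_centers: tuple  # two 3-D points, um
    plate_half_thickness: float = 0.25  # um, construction margin for generators
    pole_proximity_radius: float = 1.5  # um, "near a centriole"

    def axis(self) -> np.ndarray:
        c1, c2 = (np.asarray(p, float) for p in self.centriole_positions)
        v = c2 - c1
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError("degenerate spindle axis: coincident centrioles")
        return v / norm

    def __post_init__(self) -> None:
        c1 = np.asarray(self.centriole_positions[0], float)
        u = self.axis()
        z_poles = sorted(float(np.dot(np.asarray(p, float) - c1, u)) for p in self.centriole_positions)
        z_plates = [float(np.dot(np.asarray(p, float) - c1, u)) for p in self.plate_centers]
        if not all(z_poles[0] < z < z_poles[1] for z in z_plates):
            raise ValueError("chromatid plates must lie between the centrioles")


@dataclass
class MicrotubuleSegment:
    end1: np.ndarray
    end2: np.ndarray
    label: str | None = None  # assigned class, if known

    def __post_init__(self) -> None:
        self.end1 = np.asarray(self.end1, dtype=float)
        self.end2 = np.asarray(self.end2, dtype=float)
        if np.allclose(self.end1, self.end2):
            raise ValueError("segment endpoints must differ")


def _fit_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and residual RMS on one window."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return float(slope), float(np.sqrt(np.mean(resid**2)))


def compute_separation_velocities(
    series: AblationSeries,
    which: str = "d_pp",
    window_before: tuple[float, float] = WINDOW_BEFORE,
    window_after: tuple[float, float] = WINDOW_AFTER,
) -> VelocityResult:
    """Pre/post-cut separation velocities from linear fits in fixed windows."""
    if which not in ("d_pp", "d_cc", "d_pc"):
        raise ValueError("which must be one of d_pp, d_cc, d_pc")
    t = series.times
    y = getattr(series, which)
    m_before = (t > window_before[0]) & (t <= window_before[1])
    m_after = (t > window_after[0]) & (t < window_after[1])
    if m_before.sum() < 3 or m_after.sum() < 3:
        raise ValueError("need at least 3 samples in each fitting window")
    v_b, rms_b = _fit_window(t[m_before], y[m_before])
    v_a, rms_a = _fit_window(t[m_after], y[m_after])
    return VelocityResult(
        v_before=v_b, v_after=v_a, delta=v_a - v_b,
        window_before=window_before, window_after=window_after,
        n_before=int(m_before.sum()), n_after=int(m_after.sum()),
        rms_before=rms_b, rms_after=rms_a,
    )


def relative_distance_curves(
    series_list: Sequence[AblationSeries], which: str = "d_pp"
):
    """Baseline-subtracted mean +- SD displacement curves across cuts.

    Each series is shifted by its own value at the last pre-cut frame
    (t <= 0), then all series are interpolated to the time grid of the
    first one and averaged.  Returns a DataFrame (t_s, mean, sd, n).
    """
    import pandas as pd

    if len(series_list) == 0:
        raise ValueError("empty series list")
    grid = series_list[0].times
    curves = []
    for s in series_list:
        y = getattr(s, which)
        pre = np.nonzero(s.times <= 0)[0]
        if len(pre) == 0:
            raise ValueError("series has no pre-ablation frame for the baseline")
        rel = y - y[pre[-1]]
        if np.array_equal(s.times, grid):
            curves.append(rel)
        else:
            curves.append(np.interp(grid, s.times, rel))
    stack = np.vstack(curves)
    return pd.DataFrame(
        {
            "t_s": grid,
            "mean": stack.mean(axis=0),
            "sd": stack.std(axis=0, ddof=0),
            "n": len(curves),
        }
    )


def classify_microtubules(
    segments: Sequence[MicrotubuleSegment], geometry: SpindleGeometry
) -> tuple[list[str], Counter]:
    """Label every segment as mid_spindle, interpolar, or other.

    The partition is exhaustive and mutually exclusive; mid-spindle has
    precedence over interpolar when a segment satisfies both definitions.
    """
    u = geometry.axis()
    origin = np.asarray(geometry.centriole_positions[0], float)
    z_plates = sorted(
        float(np.dot(np.asarray(p, float) - origin, u)) for p in geometry.plate_centers
    )
    centrioles = [np.asarray(p, float) for p in geometry.centriole_positions]
    r_prox = geometry.pole_proximity_radius

    labels = []
    for seg in segments:
        ends = (seg.end1, seg.end2)
        z = [float(np.dot(e - origin, u)) for e in ends]
        between = [z_plates[0] < zi < z_plates[1] for zi in z]
        if all(between):
            labels.append("mid_spindle")
            continue
        near_pole = any(
            np.linalg.norm(e - c) <= r_prox for e in ends for c in centrioles
        )
        labels.append("interpolar" if near_pole else "other")
    return labels, Counter(labels)
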