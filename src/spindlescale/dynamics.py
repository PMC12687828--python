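"""Per-cell quantification of mitotic trajectories.

Turns raw time series of pole-to-pole (D_P-P) and chromosome-to-chromosome
(D_C-C) distances into the six traits used throughout the scaling analyses:
initial and final spindle length, spindle elongation rate, chromosome
segregation rate, final chromosome separation, and (via the atlas metadata)
cell size.

The spindle trace is fit with a four-parameter sigmoid

    D_P-P(t) = L1 + L2 / (1 + exp(-(t - t0)/tau))

whose asymptote gives the final length FL_PP = L1 + L2 and whose inflection
slope gives the elongation rate ER_PP = 60 * L2 / (4 tau) in um/min.  The
chromosome trace after anaphase onset is fit with a saturating exponential

    D_C-C(t) = a * (1 - exp(-t/k))

whose amplitude is the final separation FL_CC = a and whose initial slope
gives the segregation rate SR_CC = 60 * a / k in um/min.  All raw series are
in micrometres and seconds; the factor 60 enters only at the trait level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "VoxelSpacing",
    "GaussianPeakFit",
    "SigmoidFit",
    "ExponentialFit",
    "CellTrajectory",
    "KymographProfile",
    "euclidean_distance",
    "refine_peak_gaussian",
    "detect_anaphase_onset",
    "fit_sigmoid",
    "fit_exponential",
    "average_stage_dynamics",
]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in um along x, y, z (e.g. 0.1, 0.1, 0.5)."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel spacings must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)


@dataclass(frozen=True)
class GaussianPeakFit:
    """Gaussian peak model a*exp(-((x-b)/c)^2) + d fitted to a 1-D profile."""

    a: float
    b: float
    c: float
    d: float
    converged: bool
    residual_rms: float = float("nan")


@dataclass(frozen=True)
class SigmoidFit:
    """Sigmoid fit of a pole-separation trace; FL_PP and ER_PP are closed forms."""

    L1: float
    L2: float
    t0: float
    tau_sig: float
    FL_PP: float
    ER_PP: float
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class ExponentialFit:
    """Saturating-exponential fit of a chromosome-separation trace."""

    a: float
    k: float
    SR_CC: float
    residual_rms: float
    converged: bool


@dataclass
class CellTrajectory:
    """AO-aligned distance time series for one mitotic cell.

    ``times`` is in seconds with t = 0 at anaphase onset; ``d_pp`` and
    ``d_cc`` are in um and share the time grid.  ``ao_index`` is the frame
    index of anaphase onset (the last frame before chromosome separation).
    """

    times: np.ndarray
    d_pp: np.ndarray
    d_cc: np.ndarray
    ao_index: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_pp = np.asarray(self.d_pp, dtype=float)
        self.d_cc = np.asarray(self.d_cc, dtype=float)
        n = len(self.times)
        if len(self.d_pp) != n or len(self.d_cc) != n:
            raise ValueError("times, d_pp and d_cc must have equal length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (0 <= self.ao_index < n):
            raise ValueError("ao_index out of range")


@dataclass
class KymographProfile:
    """1-D intensity profile along the spindle axis at one time point."""

    positions: np.ndarray  # um, pixel centres
    intensities: np.ndarray
    pixel_size: float  # um
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must match in length")


def euclidean_distance(
    p1: Sequence[float], p2: Sequence[float], spacing: VoxelSpacing
) -> float:
    """Distance in um between two voxel-coordinate triples.

    Each axis difference is scaled by the physical voxel size before the
    norm is taken, so anisotropic sampling (0.1 x 0.1 x 0.5 um) is handled.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("positions must be 3-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("positions must be finite")
    return float(np.sqrt(np.sum(((a - b) * spacing.as_array()) ** 2)))


def _gauss(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a * np.exp(-(((x - b) / c) ** 2)) + d


def refine_peak_gaussian(
    profile: KymographProfile,
    init_position: float,
    width_guess: float | None = None,
) -> GaussianPeakFit:
    """Refine a pole position to sub-pixel accuracy by a local Gaussian fit.

    A four-parameter Gaussian (amplitude a, centre b, width c, baseline d)
    is least-squares fitted in a window of +-5 widths around
    ``init_position``.  Failure to converge is reported through the
    ``converged`` flag, never as an exception.
    """
    x = profile.positions
    y = profile.intensities
    if not (x.min() <= init_position <= x.max()):
        raise ValueError("init_position outside profile support")
    if width_guess is None:
        width_guess = 3.0 * profile.pixel_size
    lo, hi = init_position - 5 * width_guess, init_position + 5 * width_guess
    mask = (x >= lo) & (x <= hi)
    xw, yw = x[mask], y[mask]
    if len(xw) < 5 or np.ptp(yw) <= 0:
        return GaussianPeakFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    p0 = [float(np.ptp(yw)), float(init_position), float(width_guess), float(yw.min())]
    try:
        popt, _ = curve_fit(
            _gauss,
            xw,
            yw,
            p0=p0,
            bounds=([0.0, lo, profile.pixel_size * 1e-3, -np.inf], [np.inf, hi, hi - lo, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return GaussianPeakFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    resid = yw - _gauss(xw, *popt)
    # amplitude indistinguishable from noise floor -> no real peak
    ok = popt[0] > 3.0 * (np.std(resid) + 1e-30)
    return GaussianPeakFit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), d=float(popt[3]),
        converged=bool(ok), residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def detect_anaphase_onset(
    d_cc: Sequence[float], times: Sequence[float] | None = None, rise_frames: int = 3
) -> int:
    """Index of anaphase onset: the last frame before sustained chromosome rise.

    The rise is "sustained" at index j when d_cc increases on each of the
    next ``rise_frames`` frames and the total increase exceeds 3x the noise
    SD of the pre-rise segment.  Raises if no such rise exists.
    """
    y = np.asarray(d_cc, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 frames to detect anaphase onset")
    dy = np.diff(y)
    # robust fallback noise scale when the pre-rise segment is too short;
    # MAD of first differences is insensitive to the post-onset ramp
    mad = np.median(np.abs(dy - np.median(dy)))
    sigma_global = 1.4826 * mad / np.sqrt(2.0)
    for j in range(n - rise_frames):
        if np.all(dy[j : j + rise_frames] > 0):
            if j >= 4:
                sigma = np.std(dy[:j]) / np.sqrt(2.0)
            else:
                sigma = sigma_global
            threshold = 3.0 * sigma + 1e-12
            persists = y[min(j + 2 * rise_frames, n - 1)] - y[j] > threshold
            if (y[j + rise_frames] - y[j]) > threshold and persists:
                # onset is the *last* frame before separation: the frame
                # preceding the first value significantly above the
                # pre-rise baseline
                baseline = float(np.median(y[: j + 1]))
                above = np.nonzero(y[j:] > baseline + threshold)[0]
                if len(above) == 0:
                    continue
                return max(j + int(above[0]) - 1, j)
    raise ValueError("no anaphase detected")


def _sigmoid(t: np.ndarray, L1: float, L2: float, t0: float, tau: float) -> np.ndarray:
    return L1 + L2 / (1.0 + np.exp(-(t - t0) / tau))


TAU_BOUNDS = (1.0, 600.0)


def fit_sigmoid(traj: CellTrajectory) -> SigmoidFit:
    """Fit the pole-separation sigmoid and derive FL_PP and ER_PP.

    Times are re-referenced to anaphase onset before fitting.  The trait
    identities FL_PP = L1 + L2 and ER_PP = 60 L2/(4 tau) hold exactly for
    the returned parameters.
    """
    t = traj.times - traj.times[traj.ao_index]
    y = traj.d_pp
    if len(t) < 8:
        raise ValueError("need at least 8 frames for a sigmoid fit")
    span = t[-1] - t[0]
    rng_y = float(np.ptp(y))
    if rng_y <= 0:
        # flat series: degenerate, report non-convergence with the trivial traits
        L1 = float(y[0])
        return SigmoidFit(L1, 0.0, 0.0, np.nan, L1, 0.0, 0.0, converged=False)
    dydt = np.gradient(y, t)
    p0 = [float(np.quantile(y, 0.25)), rng_y, float(t[int(np.argmax(dydt))]), span / 8.0]
    p0[3] = float(np.clip(p0[3], *TAU_BOUNDS))
    lower = [-np.inf, 0.0, t[0] - span, TAU_BOUNDS[0]]
    upper = [np.inf, np.inf, t[-1] + span, TAU_BOUNDS[1]]
    try:
        popt, _ = curve_fit(_sigmoid, t, y, p0=p0, bounds=(lower, upper), maxfev=10000)
    except (RuntimeError, ValueError):
        return SigmoidFit(*p0, np.nan, np.nan, np.nan, converged=False)
    L1, L2, t0, tau = (float(v) for v in popt)
    at_bound = tau <= TAU_BOUNDS[0] * (1 + 1e-9) or tau >= TAU_BOUNDS[1] * (1 - 1e-9)
    resid = y - _sigmoid(t, *popt)
    return SigmoidFit(
        L1=L1, L2=L2, t0=t0, tau_sig=tau,
        FL_PP=L1 + L2, ER_PP=L2 / (4.0 * tau) * 60.0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=not at_bound,
    )


def _satexp(t: np.ndarray, a: float, k: float) -> np.ndarray:
    return a * (1.0 - np.exp(-t / k))


def fit_exponential(traj: CellTrajectory) -> ExponentialFit:
    """Fit the post-onset chromosome-separation exponential; SR_CC = 60 a/k."""
    t_all = traj.times - traj.times[traj.ao_index]
    mask = t_all >= 0
    t, y = t_all[mask], traj.d_cc[mask]
    if len(t) < 4:
        raise ValueError("need at least 4 post-onset frames")
    amax = float(np.max(y))
    if amax <= 0 or np.ptp(y) <= 0:
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    p0 = [amax, max((t[-1] - t[0]) / 4.0, 1e-2)]
    try:
        popt, _ = curve_fit(
            _satexp, t, y, p0=p0,
            bounds=([1e-6, 1e-3], [np.inf, 1e4]), maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    a, k = float(popt[0]), float(popt[1])
    resid = y - _satexp(t, a, k)
    return ExponentialFit(
        a=a, k=k, SR_CC=a / k * 60.0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )


def average_stage_dynamics(trajectories: Sequence[CellTrajectory]):
    """Mean +- SD distance curves over AO-aligned trajectories of one stage.

    Relative times are binned to the median frame interval; a time bin
    contributes whenever at least one trajectory covers it.  Returns a
    pandas DataFrame with columns t_s, mean_pp, sd_pp, mean_cc, sd_cc, n.
    """
    import pandas as pd

    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories to average")
    rows = []
    dts = []
    for traj in trajectories:
        rel = traj.times - traj.times[traj.ao_index]
        dts.append(np.median(np.diff(rel)))
        for t, pp, cc in zip(rel, traj.d_pp, traj.d_cc):
            rows.append((t, pp, cc))
    dt = float(np.median(dts))
    df = pd.DataFrame(rows, columns=["t", "pp", "cc"])
    df["bin"] = np.round(df["t"] / dt).astype(int)
    g = df.groupby("bin")
    out = pd.DataFrame(
        {
            "t_s": g["t"].mean(),
            "mean_pp": g["pp"].mean(),
            "sd_pp": g["pp"].std(ddof=0),
            "mean_cc": g["cc"].mean(),
            "sd_cc": g["cc"].std(ddof=0),
            "n": g["pp"].size(),
        }
    ).reset_index(drop=True)
    return out
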