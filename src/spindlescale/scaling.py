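"""Cell-size scaling statistics for the spindle atlas.

Cell size is the cube root of cell volume; per-stage averages of the fitted
traits are regressed linearly on per-stage average size.  The elongation
rate additionally shows a size threshold (~12 um) below which it falls with
size; that transition is located by a continuous two-segment least-squares
fit with an exhaustive breakpoint grid search.  Stage-versus-lineage
contributions to trait variance are decomposed with a nested random-effects
model sigma_T = sigma_S + sigma_L + eps, estimated either by expected mean
squares (method of moments, default) or by REML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScalingFit",
    "PiecewiseFit",
    "VarianceComponents",
    "cell_size",
    "size_uncertainty",
    "fit_scaling_slope",
    "fit_piecewise_transition",
    "estimate_variance_components",
]


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    intercept: float
    slope_sd: float
    ci95: tuple[float, float]  # 95% CI for the slope
    n_points: int


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint: float  # um
    slope_low: float  # below the breakpoint
    slope_high: float  # above the breakpoint
    value_at_break: float
    sse: float
    sse_single_line: float

    @property
    def distinct(self) -> bool:
        """Whether the two-segment fit meaningfully beats a single line."""
        return self.sse < 0.99 * self.sse_single_line


@dataclass(frozen=True)
class VarianceComponents:
    sigma_S: float  # stage variance component
    sigma_L: float  # lineage-within-stage variance component
    sigma_noise: float  # residual
    ratio_S_over_L: float
    se_sigma_S: float
    se_sigma_L: float
    truncated: bool  # any moment estimate clipped at zero
    method: str


def cell_size(volume: float | np.ndarray) -> float | np.ndarray:
    """Cell size in um as the cube root of cell volume in um^3."""
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cell volume must be positive")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


def size_uncertainty(volume_mean: float, volume_sd: float) -> float:
    """First-order error propagation of volume SD through the cube root."""
    if volume_mean <= 0:
        raise ValueError("volume mean must be positive")
    return float(volume_sd / (3.0 * volume_mean ** (2.0 / 3.0)))


def fit_scaling_slope(
    sizes: Sequence[float],
    traits: Sequence[float],
    trait_sds: Sequence[float] | None = None,
    weighted: bool = False,
    loglog: bool = False,
) -> ScalingFit:
    """Linear regression of a per-stage mean trait on per-stage mean size.

    Unweighted OLS by default; ``weighted=True`` uses 1/sd^2 weights from
    ``trait_sds``.  ``loglog=True`` fits in log-log space instead (slope is
    then a scaling exponent).
    """
    import statsmodels.api as sm

    x = np.asarray(sizes, dtype=float)
    y = np.asarray(traits, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 (size, trait) stage points")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate design: all sizes equal")
    if loglog:
        x, y = np.log(x), np.log(y)
    X = sm.add_constant(x)
    if weighted:
        if trait_sds is None:
            raise ValueError("weighted fit requires trait_sds")
        w = 1.0 / np.asarray(trait_sds, dtype=float) ** 2
        res = sm.WLS(y, X, weights=w).fit()
    else:
        res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return ScalingFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_sd=float(res.bse[1]),
        ci95=(float(ci[1][0]), float(ci[1][1])),
        n_points=len(x),
    )


def _two_segment_sse(x: np.ndarray, y: np.ndarray, b: float):
    """Closed-form LS of y = c + s_low*min(x-b,0) + s_high*max(x-b,0)."""
    xl = np.minimum(x - b, 0.0)
    xh = np.maximum(x - b, 0.0)
    X = np.column_stack([np.ones_like(x), xl, xh])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_piecewise_transition(
    sizes: Sequence[float],
    rates: Sequence[float],
    min_points_per_side: int = 3,
    grid: Sequence[float] | None = None,
) -> PiecewiseFit:
    """Continuous two-segment fit of elongation rate against cell size.

    The breakpoint is searched exhaustively over the midpoints of
    consecutive sorted unique sizes (or a user grid); for each candidate
    the two slopes and the junction value are solved in closed form.  Ties
    resolve to the lowest SSE, then the smallest breakpoint.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(rates, dtype=float)
    if len(x) != len(y) or len(x) < 6:
        raise ValueError("need at least 6 (size, rate) points")
    ux = np.unique(x)
    if grid is None:
        grid = (ux[:-1] + ux[1:]) / 2.0
    candidates = [
        b
        for b in np.asarray(grid, dtype=float)
        if (x < b).sum() >= min_points_per_side and (x > b).sum() >= min_points_per_side
    ]
    if not candidates:
        raise ValueError("no breakpoint candidate leaves enough points on both sides")
    best = None
    for b in candidates:
        sse, coef = _two_segment_sse(x, y, b)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, b, coef)
    sse, b, coef = best
    # single straight line for comparison
    X1 = np.column_stack([np.ones_like(x), x])
    c1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ c1
    return PiecewiseFit(
        breakpoint=float(b),
        slope_low=float(coef[1]),
        slope_high=float(coef[2]),
        value_at_break=float(coef[0]),
        sse=sse,
        sse_single_line=float(r1 @ r1),
    )


def _check_balanced(df: pd.DataFrame) -> tuple[int, int, int]:
    stages = df["stage"].unique()
    a = len(stages)
    per_stage = df.groupby("stage")["lineage"].nunique()
    if per_stage.nunique() != 1:
        raise ValueError("unbalanced design: unequal lineages per stage")
    b = int(per_stage.iloc[0])
    reps = df.groupby(["stage", "lineage"])["value"].size()
    if reps.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicates per lineage")
    n = int(reps.iloc[0])
    return a, b, n


def _moments_components(df: pd.DataFrame) -> tuple[float, float, float, bool]:
    """EMS estimators on the balanced nested (lineage within stage) design."""
    a, b, n = _check_balanced(df)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 stages and >= 2 lineages per stage")
    grand = df["value"].mean()
    stage_means = df.groupby("stage")["value"].mean()
    cell_means = df.groupby(["stage", "lineage"])["value"].mean()

    ss_a = b * n * ((stage_means - grand) ** 2).sum()
    ms_a = ss_a / (a - 1)
    ss_b = n * (
        (cell_means - cell_means.index.get_level_values("stage").map(stage_means)) ** 2
    ).sum()
    ms_b = ss_b / (a * (b - 1))
    within = df["value"] - df.set_index(["stage", "lineage"]).index.map(cell_means)
    if n > 1:
        ms_e = (within**2).sum() / (a * b * (n - 1))
    else:
        ms_e = 0.0
    sigma_e = float(ms_e)
    sigma_l = float((ms_b - ms_e) / n)
    sigma_s = float((ms_a - ms_b) / (b * n))
    truncated = sigma_l < 0 or sigma_s < 0
    return max(sigma_s, 0.0), max(sigma_l, 0.0), sigma_e, truncated


def _reml_components(df: pd.DataFrame) -> tuple[float, float, float, bool]:
    """REML estimates via a mixed model with lineage nested in stage."""
    import statsmodels.formula.api as smf

    d = df.copy()
    d["stage"] = d["stage"].astype(str)
    d["lineage"] = d["lineage"].astype(str)
    model = smf.mixedlm(
        "value ~ 1",
        data=d,
        groups=np.ones(len(d)),
        vc_formula={"stage": "0 + C(stage)", "lineage": "0 + C(stage):C(lineage)"},
    )
    res = model.fit(reml=True, method="lbfgs", maxiter=500)
    names = list(model.exog_vc.names)
    sigma_s = float(res.vcomp[names.index("stage")])
    sigma_l = float(res.vcomp[names.index("lineage")])
    return sigma_s, sigma_l, float(res.scale), False


def estimate_variance_components(
    table: pd.DataFrame,
    method: str = "moments",
    n_boot: int = 100,
    seed: int | None = 0,
) -> VarianceComponents:
    """Decompose trait variance into stage, lineage and noise components.

    ``table`` needs columns stage, lineage, value (replicate optional); the
    design must be balanced for the default expected-mean-squares method.
    Standard errors come from a seeded bootstrap over lineages within stage.
    """
    required = {"stage", "lineage", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    estimator = {"moments": _moments_components, "reml": _reml_components}[method]
    sigma_s, sigma_l, sigma_e, truncated = estimator(table)

    rng = np.random.default_rng(seed)
    boots_s, boots_l = [], []
    groups = {
        s: [g for _, g in sub.groupby("lineage")]
        for s, sub in table.groupby("stage")
    }
    for _ in range(n_boot):
        parts = []
        for s, lin_tables in groups.items():
            idx = rng.integers(0, len(lin_tables), size=len(lin_tables))
            for new_label, i in enumerate(idx):
                g = lin_tables[i].copy()
                g["lineage"] = f"b{new_label}"
                parts.append(g)
        try:
            bs, bl, _, _ = _moments_components(pd.concat(parts, ignore_index=True))
            boots_s.append(bs)
            boots_l.append(bl)
        except ValueError:
            continue
    se_s = float(np.std(boots_s, ddof=1)) if len(boots_s) > 1 else float("nan")
    se_l = float(np.std(boots_l, ddof=1)) if len(boots_l) > 1 else float("nan")
    ratio = sigma_s / sigma_l if sigma_l > 0 else float("inf")
    return VarianceComponents(
        sigma_S=sigma_s, sigma_L=sigma_l, sigma_noise=sigma_e,
        ratio_S_over_L=ratio, se_sigma_S=se_s, se_sigma_L=se_l,
        truncated=truncated, method=method,
    )
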