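"""End-to-end atlas quantification: per-cell trait fits and stage scaling.

This chains the synthetic atlas generator, the per-cell trajectory fits and
the stage-level regression into the analysis used for slope recovery: fit a
sigmoid (pole-to-pole) and an exponential (chromosome separation) to every
cell's trajectory, average the fitted traits per developmental stage, and
regress the stage means on mean cell size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import fit_exponential, fit_sigmoid
from .scaling import ScalingFit, fit_scaling_slope
from .synthetic import TrajectoryGroundTruth, generate_trajectory

__all__ = ["quantify_atlas", "stage_scaling"]


def quantify_atlas(
    atlas: pd.DataFrame, truths: list[TrajectoryGroundTruth]
) -> pd.DataFrame:
    """Fitted per-cell traits for every atlas row.

    Generates each cell's trajectory from its ground truth, fits the
    sigmoid and exponential trait models, and returns a copy of the atlas
    with fitted columns (fl_pp_fit_um, er_pp_fit_um_min, fl_cc_fit_um,
    sr_cc_fit_um_min) plus per-fit convergence flags.
    """
    if len(atlas) != len(truths):
        raise ValueError("atlas rows and trajectory truths must be aligned")
    records = []
    for truth in truths:
        traj = generate_trajectory(truth)
        sig = fit_sigmoid(traj)
        expo = fit_exponential(traj)
        records.append(
            {
                "fl_pp_fit_um": sig.FL_PP,
                "er_pp_fit_um_min": sig.ER_PP,
                "fl_cc_fit_um": expo.a,
                "sr_cc_fit_um_min": expo.SR_CC,
                "sigmoid_converged": sig.converged,
                "exponential_converged": expo.converged,
            }
        )
    out = atlas.reset_index(drop=True).join(pd.DataFrame(records))
    return out


def stage_scaling(
    quantified: pd.DataFrame,
    trait: str = "fl_pp_fit_um",
    require_converged: bool = True,
) -> ScalingFit:
    """Regression of per-stage mean trait on per-stage mean cell size."""
    df = quantified
    if require_converged:
        flag = (
            "sigmoid_converged" if trait in ("fl_pp_fit_um", "er_pp_fit_um_min")
            else "exponential_converged"
        )
        if flag in df.columns:
            df = df[df[flag]]
    means = df.groupby("stage")[["size_um", trait]].mean()
    if len(means) < 3:
        raise ValueError("need at least 3 stages for a stage-level regression")
    return fit_scaling_slope(
        np.asarray(means["size_um"]), np.asarray(means[trait])
    )
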