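"""Seeded generators for every input the analysis modules consume.

The generators emulate the measurement setting of early *C. elegans*
embryogenesis: sigmoid pole-separation and saturating-exponential
chromosome-separation trajectories sampled at the 10.3 s frame interval of
the light-sheet recordings, per-stage cell volumes that roughly halve at
every division round, stage- and lineage-structured trait variance,
ablation series with a velocity jump at the cut, labelled microtubule
endpoint sets built to satisfy their class definitions by construction,
and nested measurement tables for the variance decomposition.

All randomness flows through ``numpy.random.default_rng(seed)``: the same
seed and configuration give bit-identical output.  Noise is additive
i.i.d. Gaussian on distances; per-cell volumes jitter lognormally around
the stage mean (default CV 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import CellTrajectory, KymographProfile
from .perturbation import AblationSeries, MicrotubuleSegment, SpindleGeometry

__all__ = [
    "TrajectoryGroundTruth",
    "AtlasGroundTruth",
    "VarianceDesign",
    "DEFAULT_VOLUMES_BY_STAGE",
    "FRAME_INTERVAL_S",
    "generate_trajectory",
    "generate_atlas",
    "generate_kymograph_profile",
    "generate_ablation_series",
    "generate_microtubule_set",
    "generate_variance_table",
    "generate_rate_size_points",
]

FRAME_INTERVAL_S = 10.3  # light-sheet time resolution

# per-stage mean cell volumes (um^3): cubes of the per-stage cell radii
# 23, 18, 14, 11, 9, 7.3 um; consecutive ratios are ~1/2 per division round
DEFAULT_VOLUMES_BY_STAGE: dict[int, float] = {
    s: float(r**3) for s, r in zip((2, 4, 8, 16, 32, 64), (23.0, 18.0, 14.0, 11.0, 9.0, 7.3))
}

VALID_STAGES = (2, 4, 8, 16, 32, 64)


@dataclass(frozen=True)
class TrajectoryGroundTruth:
    """Parameters of one noiseless trajectory pair plus its noise and seed.

    The pole trace is L1 + L2/(1+exp(-(t-t0)/tau_sig)); the chromosome
    trace is 0 before anaphase onset (t = 0) and a(1-exp(-t/k)) after.
    """

    L1: float  # um, initial pole-to-pole length
    L2: float  # um, total pole-to-pole change
    t0: float  # s, sigmoid inflection time (relative to onset)
    tau_sig: float  # s, sigmoid rate scale
    a: float  # um, final chromosome separation
    k: float  # s, exponential time constant
    n_frames: int = 40
    frame_interval: float = FRAME_INTERVAL_S  # s
    noise_sd: float = 0.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        if not (self.L2 >= 0 and self.tau_sig > 0 and self.a > 0 and self.k > 0):
            raise ValueError("L2 >= 0, tau_sig > 0, a > 0 and k > 0 required")


def generate_trajectory(
    truth: TrajectoryGroundTruth, ao_fraction: float = 1 / 3, metadata: dict | None = None
) -> CellTrajectory:
    """Sample one noisy AO-aligned trajectory from its ground truth.

    The onset frame sits at ``ao_fraction`` of the record, so the sigmoid
    is sampled on both sides of its inflection.  Chromosome noise is
    applied only from onset on; the pre-onset chromatids are unseparated.
    """
    rng = np.random.default_rng(truth.seed)
    ao_index = int(truth.n_frames * ao_fraction)
    t = (np.arange(truth.n_frames) - ao_index) * truth.frame_interval
    d_pp = truth.L1 + truth.L2 / (1.0 + np.exp(-(t - truth.t0) / truth.tau_sig))
    d_cc = np.where(t < 0, 0.0, truth.a * (1.0 - np.exp(-np.maximum(t, 0.0) / truth.k)))
    if truth.noise_sd > 0:
        d_pp = d_pp + rng.normal(0.0, truth.noise_sd, truth.n_frames)
        noise_cc = rng.normal(0.0, truth.noise_sd, truth.n_frames)
        d_cc = d_cc + np.where(t < 0, 0.0, noise_cc)
    return CellTrajectory(
        times=t, d_pp=d_pp, d_cc=d_cc, ao_index=ao_index, metadata=metadata or {}
    )


@dataclass(frozen=True)
class AtlasGroundTruth:
    """Ground truth of a synthetic per-cell atlas with linear size scaling.

    Final spindle length and final chromosome separation are linear in
    cell size (cube root of volume) with the configured slopes and
    intercepts plus Gaussian trait noise.  ``cells_per_stage=None`` uses
    the natural count (a stage-s embryo has s cells).
    """

    slope_spindle: float = 0.75
    intercept_spindle: float = 4.0  # um
    slope_chromosome: float = 0.09
    intercept_chromosome: float = 5.1  # um
    noise_sd_length: float = 0.5  # um, per-cell trait noise
    noise_sd_rate: float = 0.2  # um/min, elongation-rate trait noise
    volumes_by_stage: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUMES_BY_STAGE)
    )
    cells_per_stage: int | None = None
    n_embryos: int = 12
    volume_jitter_cv: float = 0.10
    rate_plateau: float = 3.0  # um/min, elongation rate above the transition
    rate_transition_size: float = 12.0  # um
    rate_slope_below: float = 0.22  # (um/min)/um below the transition
    trajectory_noise_sd: float = 0.2  # um, per-frame noise
    n_frames: int = 40
    frame_interval: float = FRAME_INTERVAL_S
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.volumes_by_stage) <= set(VALID_STAGES):
            raise ValueError(f"stages must be a subset of {VALID_STAGES}")
        if self.cells_per_stage is not None and self.cells_per_stage <= 0:
            raise ValueError("cells_per_stage must be positive")
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be positive")


def _cell_truth(
    fl_pp: float, fl_cc: float, er: float, traj_noise: float, frame_interval: float,
    n_frames: int, seed: int,
) -> TrajectoryGroundTruth:
    """Trajectory parameters realizing given trait endpoints.

    L1/L2 split the final length 55/45 (onset separation is a bit over
    half the final length at every stage); tau comes from the elongation
    rate via ER = 60 L2/(4 tau), and k from a fixed ~15 um/min-scale
    segregation dynamic k = a/6.2*29 s, which keeps segregation kinetics
    nearly size-independent.
    """
    L1 = 0.55 * fl_pp
    L2 = fl_pp - L1
    tau = max(L2 * 60.0 / (4.0 * max(er, 1e-3)), 1.5)
    k = max(fl_cc / 6.2 * 29.0, 1.0)
    return TrajectoryGroundTruth(
        L1=L1, L2=L2, t0=2.0 * tau, tau_sig=tau, a=fl_cc, k=k,
        n_frames=n_frames, frame_interval=frame_interval,
        noise_sd=traj_noise, seed=seed,
    )


def generate_atlas(truth: AtlasGroundTruth) -> tuple[pd.DataFrame, list[TrajectoryGroundTruth]]:
    """Synthetic spindle atlas: per-cell metadata plus trajectory truths.

    Returns a DataFrame with one row per cell (embryo_id, cell_id,
    lineage, stage, volume_um3, size_um, fl_pp_true_um, fl_cc_true_um,
    er_pp_true_um_min) and the matching list of per-cell trajectory ground
    truths, index-aligned with the rows.
    """
    rng = np.random.default_rng(truth.seed)
    jitter_sigma = np.sqrt(np.log(1.0 + truth.volume_jitter_cv**2))
    rows = []
    truths: list[TrajectoryGroundTruth] = []
    for e in range(truth.n_embryos):
        for stage in sorted(truth.volumes_by_stage):
            n_cells = truth.cells_per_stage if truth.cells_per_stage is not None else stage
            v_mean = truth.volumes_by_stage[stage]
            for c in range(n_cells):
                vol = v_mean * rng.lognormal(-0.5 * jitter_sigma**2, jitter_sigma)
                size = vol ** (1.0 / 3.0)
                fl_pp = (
                    truth.slope_spindle * size
                    + truth.intercept_spindle
                    + rng.normal(0.0, truth.noise_sd_length)
                )
                fl_cc = (
                    truth.slope_chromosome * size
                    + truth.intercept_chromosome
                    + rng.normal(0.0, truth.noise_sd_length)
                )
                if size <= truth.rate_transition_size:
                    er = truth.rate_plateau - truth.rate_slope_below * (
                        truth.rate_transition_size - size
                    )
                else:
                    er = truth.rate_plateau
                er += rng.normal(0.0, truth.noise_sd_rate)
                if fl_pp <= 0 or fl_cc <= 0 or er <= 0:
                    raise ValueError(
                        "generated a non-positive trait; atlas parameters out of "
                        "plausible range (check slopes/intercepts/noise)"
                    )
                cell_seed = int(rng.integers(0, 2**31 - 1))
                truths.append(
                    _cell_truth(
                        fl_pp, fl_cc, er, truth.trajectory_noise_sd,
                        truth.frame_interval, truth.n_frames, cell_seed,
                    )
                )
                rows.append(
                    {
                        "embryo_id": f"E{e:02d}",
                        "cell_id": f"E{e:02d}_S{stage}_C{c:02d}",
                        "lineage": f"L{c}",
                        "stage": stage,
                        "volume_um3": vol,
                        "size_um": size,
                        "fl_pp_true_um": fl_pp,
                        "fl_cc_true_um": fl_cc,
                        "er_pp_true_um_min": er,
                    }
                )
    return pd.DataFrame(rows), truths


def generate_kymograph_profile(
    peak_positions: Sequence[float],
    amplitudes: Sequence[float] | float = 100.0,
    width: float = 0.4,
    baseline: float = 10.0,
    noise_sd: float = 0.0,
    pixel_size: float = 0.1,
    n_pixels: int = 256,
    seed: int = 0,
) -> KymographProfile:
    """Sum-of-Gaussians intensity profile with the true peaks recorded."""
    if width <= 0:
        raise ValueError("width must be positive")
    peaks = np.asarray(peak_positions, float)
    extent = n_pixels * pixel_size
    if np.any((peaks < 0) | (peaks > extent)):
        raise ValueError("peaks must lie inside [0, n_pixels*pixel_size]")
    amps = np.broadcast_to(np.asarray(amplitudes, float), peaks.shape)
    x = (np.arange(n_pixels) + 0.5) * pixel_size
    y = np.full(n_pixels, float(baseline))
    for p, a in zip(peaks, amps):
        y = y + a * np.exp(-(((x - p) / width) ** 2))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n_pixels)
    return KymographProfile(
        positions=x, intensities=y, pixel_size=pixel_size,
        metadata={"true_peaks": peaks.tolist(), "width": width, "baseline": baseline},
    )


def generate_ablation_series(
    v_pre: float,
    v_post: float,
    t_ablation: float = 20.0,
    duration: float = 45.0,
    frame_interval: float = 0.5,
    noise_sd: float = 0.0,
    d0: float = 8.0,
    v_pre_cc: float | None = None,
    v_post_cc: float | None = None,
    d0_cc: float = 2.0,
    seed: int = 0,
) -> AblationSeries:
    """Piecewise-linear distance traces with a slope change at the cut.

    The pole channel has slope ``v_pre`` (um/s) before and ``v_post``
    after t = 0 (the ablation); the chromosome channel is generated
    independently with its own slopes (defaulting to an unchanged
    ``v_pre``, emulating cuts that leave segregation unaffected).
    """
    if t_ablation < 8.0 or duration - t_ablation < 12.0:
        raise ValueError(
            "duration must cover both fitting windows: need >= 8 s before and "
            ">= 12 s after the ablation"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-9, frame_interval) - t_ablation
    if v_pre_cc is None:
        v_pre_cc = v_pre
    if v_post_cc is None:
        v_post_cc = v_pre_cc

    def piecewise(d0_, vb, va):
        return np.where(t <= 0, d0_ + vb * t, d0_ + va * t)

    d_pp = piecewise(d0, v_pre, v_post)
    d_cc = piecewise(d0_cc, v_pre_cc, v_post_cc)
    d_pc = 0.5 * (d_pp - d_cc)
    if noise_sd > 0:
        d_pp = d_pp + rng.normal(0.0, noise_sd, len(t))
        d_cc = d_cc + rng.normal(0.0, noise_sd, len(t))
        d_pc = d_pc + rng.normal(0.0, noise_sd, len(t))
    return AblationSeries(
        times=t, d_pp=d_pp, d_pc=d_pc, d_cc=d_cc,
        metadata={"v_pre": v_pre, "v_post": v_post, "t_ablation": t_ablation},
    )


def generate_microtubule_set(
    geometry: SpindleGeometry,
    n_mid: int,
    n_interpolar: int,
    n_other: int = 0,
    seed: int = 0,
) -> list[MicrotubuleSegment]:
    """Labelled endpoint segments satisfying their class rules by construction.

    Mid-spindle segments have both endpoints axially strictly between the
    plate planes; interpolar segments start within the proximity radius of
    a centriole and end between the plates; "other" segments sit between a
    plate and its pole, clear of the centrioles.
    """
    rng = np.random.default_rng(seed)
    u = geometry.axis()
    origin = np.asarray(geometry.centriole_positions[0], float)
    c1 = origin
    c2 = np.asarray(geometry.centriole_positions[1], float)
    z_pole = sorted([0.0, float(np.dot(c2 - c1, u))])
    z_plates = sorted(float(np.dot(np.asarray(p, float) - c1, u)) for p in geometry.plate_centers)
    margin = min(geometry.plate_half_thickness, 0.2 * (z_plates[1] - z_plates[0]))
    r_prox = geometry.pole_proximity_radius

    helper = np.array([0.0, 1.0, 0.0]) if abs(u[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e2 = np.cross(u, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(u, e2)

    def point(z, radial):
        phi = rng.uniform(0, 2 * np.pi)
        return c1 + z * u + radial * (np.cos(phi) * e2 + np.sin(phi) * e3)

    segs: list[MicrotubuleSegment] = []
    for _ in range(n_mid):
        z_a, z_b = rng.uniform(z_plates[0] + margin, z_plates[1] - margin, 2)
        segs.append(
            MicrotubuleSegment(point(z_a, rng.uniform(0, 1.0)), point(z_b, rng.uniform(0, 1.0)), "mid_spindle")
        )
    for _ in range(n_interpolar):
        centriole = c1 if rng.random() < 0.5 else c2
        offset = rng.normal(size=3)
        offset *= rng.uniform(0, 0.8 * r_prox) / np.linalg.norm(offset)
        end1 = centriole + offset
        z_b = rng.uniform(z_plates[0] + margin, z_plates[1] - margin)
        segs.append(MicrotubuleSegment(end1, point(z_b, rng.uniform(0, 1.0)), "interpolar"))
    # "other": between a plate plane and its pole, but clear of the centriole
    for _ in range(n_other):
        if rng.random() < 0.5:
            z_lo, z_hi, centriole = z_pole[0], z_plates[0] - margin, c1
        else:
            z_lo, z_hi, centriole = z_plates[1] + margin, z_pole[1], c2
        for _attempt in range(1000):
            za, zb = rng.uniform(z_lo, z_hi, 2)
            p_a = point(za, rng.uniform(1.2 * r_prox, 2.0 * r_prox))
            p_b = point(zb, rng.uniform(1.2 * r_prox, 2.0 * r_prox))
            if (
                min(np.linalg.norm(p_a - c) for c in (c1, c2)) > r_prox
                and min(np.linalg.norm(p_b - c) for c in (c1, c2)) > r_prox
            ):
                segs.append(MicrotubuleSegment(p_a, p_b, "other"))
                break
        else:
            raise RuntimeError("could not place an 'other' segment; geometry too tight")
    return segs


@dataclass(frozen=True)
class VarianceDesign:
    """Balanced nested design for the stage/lineage variance decomposition.

    ``sigma_*`` are variance components (trait units squared); effects are
    drawn from zero-mean Gaussians with those variances.
    """

    sigma_S: float  # stage variance
    sigma_L: float  # lineage-within-stage variance
    sigma_noise: float  # replicate noise variance
    n_stages: int = 6
    n_lineages_per_stage: int = 8
    n_replicates: int = 4
    grand_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_S, self.sigma_L, self.sigma_noise) < 0:
            raise ValueError("variance components must be non-negative")
        if min(self.n_stages, self.n_lineages_per_stage, self.n_replicates) < 1:
            raise ValueError("design counts must be positive")


def generate_variance_table(design: VarianceDesign) -> pd.DataFrame:
    """Nested measurement table value = mu + stage + lineage(stage) + noise."""
    rng = np.random.default_rng(design.seed)
    rows = []
    for s in range(design.n_stages):
        stage_eff = rng.normal(0.0, np.sqrt(design.sigma_S))
        for l in range(design.n_lineages_per_stage):
            lin_eff = rng.normal(0.0, np.sqrt(design.sigma_L))
            noise = rng.normal(0.0, np.sqrt(design.sigma_noise), design.n_replicates)
            for k in range(design.n_replicates):
                rows.append(
                    {
                        "stage": f"S{s}",
                        "lineage": f"L{l}",
                        "replicate": k,
                        "value": design.grand_mean + stage_eff + lin_eff + noise[k],
                    }
                )
    return pd.DataFrame(rows)


def generate_rate_size_points(
    n_points: int = 60,
    breakpoint: float = 12.0,
    rate_plateau: float = 3.0,
    slope_below: float = 0.22,
    size_range: tuple[float, float] = (5.0, 25.0),
    noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Elongation-rate-vs-size points: flat above, linearly falling below.

    Emulates the per-cell scatter used to locate the elongation-rate
    transition; noise is a fraction of the local rate.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.uniform(*size_range, n_points)
    rates = np.where(
        sizes >= breakpoint,
        rate_plateau,
        rate_plateau - slope_below * (breakpoint - sizes),
    )
    rates = rates + rng.normal(0.0, noise_frac * np.abs(rates))
    return sizes, rates
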