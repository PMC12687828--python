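"""Stoichiometric cortical-pulling model of anaphase spindle elongation.

Two centrosomal asters sit inside a spherical cell of radius R.  Astral
microtubules nucleate at rate n_dot = N_T * lambda, grow at V_g, and
undergo catastrophe at rate lambda, so their steady-state length
distribution is exponential with mean V_g/lambda.  Minus-end-directed
motors of size r are distributed on the cortex at density rho; each motor
binds at most one microtubule at a time (stoichiometric binding) and, when
bound, pulls on the corresponding pole with force f0 along the microtubule.

The cortex carries a coarse-grained surface field P_i(Y, t): the
probability that a motor at cortical position Y is bound to a microtubule
from aster i.  It evolves as

    dP_i/dt = Omega_i (1 - P1 - P2) - kappa P_i,

where Omega_i is the local microtubule impingement rate and kappa the
detachment rate.  The impingement rate combines inverse-square dilution of
the plus-end flux with exponential survival over the pole-cortex distance d:

    Omega = N_T lambda r^2 / (4 d^2) * exp(-lambda d / V_g).

The total pulling force on pole i is the cortex quadrature
F_i = rho f0 * sum_patches P_i * xihat * dA with xihat the unit vector from
the pole to the patch.  Pole motion balances cytoplasmic drag eta and a
viscous pole-chromosome coupling nu along the spindle axis s:

    eta xdot_i + nu ((xdot_i - cdot_i) . s) s = F_i.

Chromosome separation is not modelled mechanistically: the plate-to-plate
vector follows the measured program Delta_c(t) = c_f (1 - exp(-t/tau_c)),
with the plates rigidly straddling the pole midpoint along s.

Everything is deterministic: the surface field is mean-field and time
stepping is explicit Euler with a stability guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "SimulationParams",
    "StageConfig",
    "ChromosomeProgram",
    "SurfaceField",
    "SimulationState",
    "ElongationTrace",
    "STAGE_TABLE",
    "DEFAULT_PARAMS",
    "sphere_patches",
    "impingement_rate",
    "surface_field_steady_state",
    "step_surface_field",
    "motor_force",
    "imposed_chromosome_separation",
    "step_positions",
    "simulate_stage",
]


@dataclass(frozen=True)
class SimulationParams:
    """Global model parameters (units: um, s, pN).

    Defaults are the working values used for every developmental stage;
    only the catastrophe rate ``lam`` varies per stage.
    """

    N_T: int = 5000  # microtubules per aster
    V_g: float = 1.0  # um/s, growth velocity
    lam: float | None = None  # 1/s, catastrophe rate (usually from StageConfig)
    rho: float = 0.12  # motors/um^2, cortical motor density
    r: float = 1.5  # um, motor capture size
    kappa: float = 1.0 / 20.0  # 1/s, motor detachment rate
    f0: float = 5.0  # pN, single-motor pulling force
    eta: float = 450.0  # pN s/um, aster drag coefficient
    nu: float = 50.0  # pN s/um, pole-chromosome viscous coupling

    def __post_init__(self) -> None:
        for name in ("N_T", "V_g", "rho", "r", "kappa", "f0", "eta", "nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")

    @property
    def nucleation_rate(self) -> float:
        """Steady-state plus-end nucleation rate n_dot = N_T * lambda (1/s)."""
        if self.lam is None:
            raise ValueError("lam is unset")
        return self.N_T * self.lam


@dataclass(frozen=True)
class StageConfig:
    """Per-stage geometry: cell radius, anaphase-onset pole distance, rate."""

    stage: int
    R: float  # um, cube root of the mean cell volume at this stage
    initial_pole_distance: float  # um, D_P-P at anaphase onset
    lambda_stage: float  # 1/s, catastrophe rate for this stage

    def __post_init__(self) -> None:
        if self.initial_pole_distance >= 2 * self.R:
            raise ValueError("initial pole distance must fit inside the cell")
        if self.R <= 0 or self.initial_pole_distance <= 0 or self.lambda_stage <= 0:
            raise ValueError("stage parameters must be positive")


# per-stage configurations: radius, initial pole separation, catastrophe rate
STAGE_TABLE: dict[int, StageConfig] = {
    2: StageConfig(2, 23.0, 13.0, 0.038),
    4: StageConfig(4, 18.0, 11.2, 0.086),
    8: StageConfig(8, 14.0, 9.0, 0.164),
    16: StageConfig(16, 11.0, 7.5, 0.332),
    32: StageConfig(32, 9.0, 6.4, 0.615),
    64: StageConfig(64, 7.3, 5.4, 0.945),
}

DEFAULT_PARAMS = SimulationParams()


@dataclass(frozen=True)
class ChromosomeProgram:
    """Imposed plate-separation program Delta_c(t) = c_f (1 - exp(-t/tau_c))."""

    c_f: float = 6.2  # um, final separation
    tau_c: float = 29.0  # s, time constant

    def __post_init__(self) -> None:
        if self.c_f <= 0 or self.tau_c <= 0:
            raise ValueError("program parameters must be positive")


@dataclass
class SurfaceField:
    """Motor-binding probability field on a discretized spherical cortex."""

    points: np.ndarray  # (n, 3) patch centres, um
    areas: np.ndarray  # (n,) patch areas, um^2
    P1: np.ndarray
    P2: np.ndarray
    R: float
    n_clipped: int = 0  # cumulative count of probability clips

    def copy(self) -> "SurfaceField":
        return SurfaceField(
            self.points, self.areas, self.P1.copy(), self.P2.copy(), self.R, self.n_clipped
        )


@dataclass
class SimulationState:
    x1: np.ndarray  # pole positions, um
    x2: np.ndarray
    c1: np.ndarray  # chromatid-plate centres, um
    c2: np.ndarray
    s_hat: np.ndarray  # unit spindle axis
    t: float = 0.0
    clipped: bool = False  # a pole was clipped back inside the sphere


@dataclass
class ElongationTrace:
    times: np.ndarray  # s
    d_pp: np.ndarray  # um
    d_cc: np.ndarray  # um
    states: list = field(default_factory=list)
    field_clips: int = 0


def sphere_patches(n_patches: int, R: float, axis: np.ndarray | None = None):
    """Equal-weight quadrature grid on the sphere of radius R.

    Gauss-Legendre nodes in the polar cosine crossed with a uniform
    azimuthal grid, aligned with ``axis`` (default x).  The product rule is
    azimuthally symmetric about the axis, so on-axis configurations produce
    no spurious transverse force, and the weights sum to 4 pi R^2 to
    machine precision.
    """
    n_theta = max(4, int(round(np.sqrt(n_patches / 1.25))))
    n_phi = max(4, int(round(n_patches / n_theta)))
    mu, w_mu = np.polynomial.legendre.leggauss(n_theta)  # mu = cos(theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    mu_g, phi_g = np.meshgrid(mu, phi, indexing="ij")
    sin_t = np.sqrt(1.0 - mu_g**2)
    # local frame: e1 along axis, (e2, e3) transverse
    if axis is None:
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = np.asarray(axis, float)
        e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 1.0, 0.0]) if abs(e1[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    pts = (
        mu_g[..., None] * e1
        + (sin_t * np.cos(phi_g))[..., None] * e2
        + (sin_t * np.sin(phi_g))[..., None] * e3
    ).reshape(-1, 3) * R
    areas = (np.broadcast_to(w_mu[:, None], mu_g.shape) * (2.0 * np.pi / n_phi)).reshape(-1) * R**2
    return pts, areas


def impingement_rate(
    pole: np.ndarray, patch: np.ndarray, params: SimulationParams, lam: float | None = None
) -> float | np.ndarray:
    """Microtubule impingement rate Omega on cortical patches (1/s).

    Omega(d) = N_T lam r^2 / (4 d^2) * exp(-lam d / V_g): inverse-square
    dilution of the nucleated plus-end flux over the sphere of radius d,
    times the probability that a microtubule survives to length d given the
    exponential length distribution of mean V_g/lam, captured over the
    motor area ~r^2.
    """
    if lam is None:
        lam = params.lam
    if lam is None:
        raise ValueError("catastrophe rate lam is required")
    pole = np.asarray(pole, float)
    patch = np.asarray(patch, float)
    d = np.linalg.norm(np.atleast_2d(patch) - pole, axis=1)
    if np.any(d <= 0):
        raise ValueError("pole coincides with a cortical patch")
    om = params.N_T * lam * params.r**2 / (4.0 * d**2) * np.exp(-lam * d / params.V_g)
    return float(om[0]) if np.ndim(patch) == 1 else om


def surface_field_steady_state(om1, om2, kappa: float):
    """Stationary binding probabilities (P1*, P2*) of the two-aster field.

    Setting dP_i/dt = 0 in the competition equation gives
    P_i* = Omega_i / (kappa + Omega_1 + Omega_2), which always satisfies
    P1* + P2* < 1.
    """
    om1 = np.asarray(om1, float)
    om2 = np.asarray(om2, float)
    denom = kappa + om1 + om2
    return om1 / denom, om2 / denom


def _stability_dt_max(om1, om2, kappa: float) -> float:
    return 0.5 / (kappa + float(np.max(om1 + om2)))


def step_surface_field(
    f: SurfaceField, om1, om2, kappa: float, dt: float, scheme: str = "euler"
) -> SurfaceField:
    """One time step of the binding-probability field.

    ``scheme="euler"`` is the explicit update; it rejects time steps
    violating the linear stability bound dt*(kappa + max(Omega1+Omega2))
    < 0.5 and clips (counting clips) any residual excursion outside
    [0, 1].  ``scheme="exponential"`` integrates the per-patch 2x2 linear
    system exactly with the impingement rates frozen over the step; it is
    unconditionally stable and preserves the probability bounds without
    clipping, which matters close to the cortex where Omega is large and
    stiff.
    """
    om1 = np.asarray(om1, float)
    om2 = np.asarray(om2, float)
    if scheme == "euler":
        if dt >= _stability_dt_max(om1, om2, kappa):
            raise ValueError(
                f"dt={dt} violates stability bound dt*(kappa+max Omega) < 0.5"
            )
        free = 1.0 - f.P1 - f.P2
        P1 = f.P1 + dt * (om1 * free - kappa * f.P1)
        P2 = f.P2 + dt * (om2 * free - kappa * f.P2)
        n_clip = int(np.sum((P1 < 0) | (P1 > 1)) + np.sum((P2 < 0) | (P2 > 1)))
        if n_clip:
            P1 = np.clip(P1, 0.0, 1.0)
            P2 = np.clip(P2, 0.0, 1.0)
        return SurfaceField(f.points, f.areas, P1, P2, f.R, f.n_clipped + n_clip)
    if scheme != "exponential":
        raise ValueError("scheme must be 'euler' or 'exponential'")
    # exact solution over dt with frozen rates: the free fraction
    # u = 1 - P1 - P2 relaxes at rate kappa + Omega_T toward kappa/(kappa+Omega_T);
    # each P_i then follows dP_i/dt = Omega_i u(t) - kappa P_i in closed form.
    om_t = om1 + om2
    u0 = 1.0 - f.P1 - f.P2
    u_star = kappa / (kappa + om_t)
    e_k = np.exp(-kappa * dt)
    # (1 - exp(-x))/x, stable at x -> 0
    x = om_t * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(x > 1e-8, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0 - x / 2.0)
    forced = u_star * -np.expm1(-kappa * dt) / kappa + (u0 - u_star) * e_k * dt * phi
    P1 = f.P1 * e_k + om1 * forced
    P2 = f.P2 * e_k + om2 * forced
    return SurfaceField(f.points, f.areas, P1, P2, f.R, f.n_clipped)


def motor_force(
    f: SurfaceField, pole: np.ndarray, P: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """Total cortical pulling force on one pole (pN).

    Quadrature of (M f0 / A) * P * xihat over the cortex with M = rho A, so
    the patch sum is rho * f0 * sum P xihat dA; xihat points pole -> patch
    (motors pull the pole toward the cortex).
    """
    pole = np.asarray(pole, float)
    diff = f.points - pole
    d = np.linalg.norm(diff, axis=1)
    xi = diff / d[:, None]
    return params.rho * params.f0 * (P * f.areas) @ xi


def imposed_chromosome_separation(t, program: ChromosomeProgram):
    """Plate-to-plate separation Delta_c(t) in um under the imposed program."""
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = program.c_f * (1.0 - np.exp(-t_arr / program.tau_c))
    return float(out) if out.ndim == 0 else out


def step_positions(
    state: SimulationState,
    F1: np.ndarray,
    F2: np.ndarray,
    params: SimulationParams,
    program: ChromosomeProgram,
    dt: float,
    R: float,
    cdot1_par: float,
    cdot2_par: float,
) -> SimulationState:
    """Advance pole and plate positions one step under the force balance.

    The velocity decomposes in closed form: along the spindle axis
    xdot_par = (F_par + nu cdot_par)/(eta + nu); transverse xdot_perp =
    F_perp/eta.  After the pole update the axis is recomputed, and the
    plates are rigidly repositioned at midpoint +- Delta_c(t+dt)/2 along
    it.  ``cdot*_par`` are the plate velocities projected on the axis,
    supplied by the caller (lagged finite differences inside
    ``simulate_stage``).  Poles that would leave the sphere are clipped to
    the surface and the event flagged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state.s_hat
    eta, nu = params.eta, params.nu
    new_x = []
    clipped = state.clipped
    for F, cdot_par in ((F1, cdot1_par), (F2, cdot2_par)):
        F_par = float(np.dot(F, s))
        F_perp = F - F_par * s
        v = (F_par + nu * cdot_par) / (eta + nu) * s + F_perp / eta
        new_x.append((state.x1 if F is F1 else state.x2) + dt * v)
    x1, x2 = new_x
    for i, x in enumerate((x1, x2)):
        r = np.linalg.norm(x)
        if r >= R:
            (x1, x2)[i][:] = x * ((R * (1.0 - 1e-9)) / r)
            clipped = True
    sep = x1 - x2
    d = np.linalg.norm(sep)
    if d < 0.1:
        raise ValueError("pole separation below 0.1 um: degenerate spindle axis")
    s_new = sep / d
    t_new = state.t + dt
    dc = imposed_chromosome_separation(t_new, program)
    mid = 0.5 * (x1 + x2)
    c1 = mid + 0.5 * dc * s_new
    c2 = mid - 0.5 * dc * s_new
    return SimulationState(x1=x1, x2=x2, c1=c1, c2=c2, s_hat=s_new, t=t_new, clipped=clipped)


def simulate_stage(
    stage: StageConfig,
    params: SimulationParams = DEFAULT_PARAMS,
    program: ChromosomeProgram = ChromosomeProgram(),
    duration: float = 300.0,
    dt: float = 0.05,
    n_patches: int = 2000,
    lam: float | None = None,
    field_scheme: str = "exponential",
    record_states: bool = False,
    record_every: int = 20,
) -> ElongationTrace:
    """Deterministic elongation trace for one developmental stage.

    Poles start symmetrically about the cell centre along the x axis at the
    stage's anaphase-onset separation; the surface field starts at its
    per-patch steady state for that configuration.  Chromosome plates start
    coincident at the midpoint and follow the imposed program, so the
    returned D_C-C(t) equals the program exactly.
    """
    if lam is None:
        lam = stage.lambda_stage
    R = stage.R
    points, areas = sphere_patches(n_patches, R)
    axis = np.array([1.0, 0.0, 0.0])
    half = 0.5 * stage.initial_pole_distance
    x1, x2 = half * axis, -half * axis

    om1 = impingement_rate(x1, points, params, lam)
    om2 = impingement_rate(x2, points, params, lam)
    if field_scheme == "euler" and dt >= _stability_dt_max(om1, om2, params.kappa):
        raise ValueError(
            "dt violates the field stability bound dt*(kappa+max Omega) < 0.5; "
            "reduce dt or use the exponential field scheme"
        )
    P1, P2 = surface_field_steady_state(om1, om2, params.kappa)
    f = SurfaceField(points, areas, np.asarray(P1), np.asarray(P2), R)

    mid0 = 0.5 * (x1 + x2)
    state = SimulationState(x1=x1.copy(), x2=x2.copy(), c1=mid0.copy(), c2=mid0.copy(), s_hat=axis.copy(), t=0.0)

    n_steps = int(round(duration / dt))
    times = np.empty(n_steps + 1)
    d_pp = np.empty(n_steps + 1)
    d_cc = np.empty(n_steps + 1)
    times[0], d_pp[0], d_cc[0] = 0.0, stage.initial_pole_distance, 0.0
    states = []
    if record_states:
        states.append((state, f.copy()))

    # fused inner loop: same formulas as the public single-step operations,
    # with geometry shared between the impingement and force quadratures
    om_coef = params.N_T * lam * params.r**2 / 4.0
    force_coef = params.rho * params.f0
    eta, nu, kappa = params.eta, params.nu, params.kappa
    eta_nu = eta + nu
    P1 = np.asarray(f.P1).copy()
    P2 = np.asarray(f.P2).copy()
    n_clipped = 0
    x1 = state.x1.copy()
    x2 = state.x2.copy()
    s = state.s_hat.copy()
    c_prev1, c_prev2 = mid0.copy(), mid0.copy()
    dc0 = program.c_f / program.tau_c
    cdot1_par, cdot2_par = 0.5 * dc0, -0.5 * dc0
    t = 0.0
    for n in range(1, n_steps + 1):
        diff1 = points - x1
        diff2 = points - x2
        dsq1 = np.einsum("ij,ij->i", diff1, diff1)
        dsq2 = np.einsum("ij,ij->i", diff2, diff2)
        d1 = np.sqrt(dsq1)
        d2 = np.sqrt(dsq2)
        om1 = om_coef / dsq1 * np.exp((-lam / params.V_g) * d1)
        om2 = om_coef / dsq2 * np.exp((-lam / params.V_g) * d2)
        F1 = force_coef * ((P1 * areas / d1) @ diff1)
        F2 = force_coef * ((P2 * areas / d2) @ diff2)
        # pole velocities: axial component feels the pole-chromosome coupling
        F1_par = F1 @ s
        F2_par = F2 @ s
        v1 = (F1_par + nu * cdot1_par) / eta_nu * s + (F1 - F1_par * s) / eta
        v2 = (F2_par + nu * cdot2_par) / eta_nu * s + (F2 - F2_par * s) / eta
        x1 = x1 + dt * v1
        x2 = x2 + dt * v2
        clipped = state.clipped
        for x in (x1, x2):
            rr = np.sqrt(x @ x)
            if rr >= R:
                x *= (R * (1.0 - 1e-9)) / rr
                clipped = True
        state.clipped = clipped
        sep = x1 - x2
        dpp = np.sqrt(sep @ sep)
        if dpp < 0.1:
            raise ValueError("pole separation below 0.1 um: degenerate spindle axis")
        s = sep / dpp
        t = n * dt
        dc = program.c_f * (1.0 - np.exp(-t / program.tau_c))
        mid = 0.5 * (x1 + x2)
        c1 = mid + (0.5 * dc) * s
        c2 = mid - (0.5 * dc) * s
        cdot1_par = ((c1 - c_prev1) @ s) / dt
        cdot2_par = ((c2 - c_prev2) @ s) / dt
        c_prev1, c_prev2 = c1, c2
        # field update with the rates at the pre-move pole positions
        if field_scheme == "exponential":
            om_t = om1 + om2
            u0 = 1.0 - P1 - P2
            u_star = kappa / (kappa + om_t)
            e_k = np.exp(-kappa * dt)
            x_arg = om_t * dt
            phi = np.where(
                x_arg > 1e-8,
                -np.expm1(-x_arg) / np.where(x_arg > 0, x_arg, 1.0),
                1.0 - x_arg / 2.0,
            )
            forced = u_star * -np.expm1(-kappa * dt) / kappa + (u0 - u_star) * e_k * dt * phi
            P1 = P1 * e_k + om1 * forced
            P2 = P2 * e_k + om2 * forced
        else:
            if dt >= _stability_dt_max(om1, om2, kappa):
                raise ValueError(
                    f"dt={dt} violates stability bound dt*(kappa+max Omega) < 0.5 "
                    f"at t={t:.2f} s"
                )
            free = 1.0 - P1 - P2
            P1n = P1 + dt * (om1 * free - kappa * P1)
            P2n = P2 + dt * (om2 * free - kappa * P2)
            n_clip = int(np.sum((P1n < 0) | (P1n > 1)) + np.sum((P2n < 0) | (P2n > 1)))
            if n_clip:
                n_clipped += n_clip
                P1n = np.clip(P1n, 0.0, 1.0)
                P2n = np.clip(P2n, 0.0, 1.0)
            P1, P2 = P1n, P2n
        times[n] = t
        d_pp[n] = dpp
        d_cc[n] = dc
        if record_states and (n % record_every == 0 or n == n_steps):
            snap = SimulationState(
                x1=x1.copy(), x2=x2.copy(), c1=c1.copy(), c2=c2.copy(),
                s_hat=s.copy(), t=t, clipped=state.clipped,
            )
            states.append(
                (snap, SurfaceField(points, areas, P1.copy(), P2.copy(), R, n_clipped))
            )
    return ElongationTrace(times=times, d_pp=d_pp, d_cc=d_cc, states=states, field_clips=n_clipped)
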