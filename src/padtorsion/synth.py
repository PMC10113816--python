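"""Synthetic torsion trials with known ground truth.

A flat plate presses on a finger pad (elliptical contact patch), pauses,
then rotates at constant angular velocity about the contact normal.  The
generator reproduces the kinematic and statistical structure such a trial
exhibits at the skin surface:

* a roughly elliptical patch of trackable skin features,
* a stick region that shrinks from the contact periphery towards the
  rotation centre while the plate twists -- skin inside it co-rotates
  rigidly with the plate, skin outside is frozen at its slip-time position,
* a narrow shear transition band at the slip front, across which a
  feature decelerates smoothly from the plate rate to rest (this produces
  the counter-rotation zone seen at the front: in the plate's frame,
  freshly slipped skin rotates backwards),
* peeling of peripheral contact at a constant rate per degree of twist,
* Coulomb-like traction with an optional pressure-weakening friction
  coefficient, integrating to a torque that rises monotonically to an
  analytic plateau,
* isotropic Gaussian feature-tracking noise and force/torque sensor noise.

Everything derives deterministically from ``SynthParams`` and its seed, and
the ``GroundTruth`` record carries the analytic answers (stick radius
schedule, full-slip angle, torque plateau, per-triangle first-slip frames,
peel schedule) that the analysis modules are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import Delaunay

from .friction import TrialTraces
from .strain import TrajectorySet

__all__ = [
    "ContactEllipse",
    "SynthParams",
    "GroundTruth",
    "SimulatedTrial",
    "feature_lattice",
    "simulate_trial",
    "render_frames",
    "torque_curve",
    "simulate_traces",
    "analytic_friction_exponent",
    "full_slip_angle_analytic",
]

STICK_CUTOFF = 0.03  # stuck-area fraction below which the contact counts as fully slipping


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactEllipse:
    """Elliptical contact patch in image coordinates.

    ``tilt_deg`` is the angle between the image y-axis and the major axis,
    in (-90, 90], positive tipping towards +x (matching the tilt the
    contact module estimates from mask moments).
    """

    center_px: tuple[float, float]
    major_mm: float          # semi-major axis
    minor_mm: float          # semi-minor axis
    tilt_deg: float = 0.0
    px_per_mm: float = 85.0

    def __post_init__(self) -> None:
        if not (self.major_mm > 0 and self.minor_mm > 0):
            raise ValueError("ellipse semi-axes must be positive")
        if self.minor_mm > self.major_mm:
            raise ValueError("minor axis exceeds major axis")

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.major_mm * self.minor_mm)

    @property
    def geo_radius_mm(self) -> float:
        """Geometric-mean radius sqrt(a*b): the equivalent circular radius."""
        return float(np.sqrt(self.major_mm * self.minor_mm))

    def _axes(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.radians(self.tilt_deg)
        u = np.array([np.sin(t), np.cos(t)])   # major axis direction
        v = np.array([np.cos(t), -np.sin(t)])  # minor axis direction
        return u, v

    def rho(self, pts_px: np.ndarray) -> np.ndarray:
        """Normalized elliptical radius of points (px): 1 on the boundary."""
        d = (np.asarray(pts_px, dtype=float) - np.asarray(self.center_px)) / self.px_per_mm
        u, v = self._axes()
        a = d @ u
        b = d @ v
        return np.sqrt((a / self.major_mm) ** 2 + (b / self.minor_mm) ** 2)

    def mask(self, shape: tuple[int, int], scale: float = 1.0) -> np.ndarray:
        """Boolean raster of the ellipse shrunk uniformly by ``scale``."""
        h, w = shape
        ys, xs = np.mgrid[0:h, 0:w]
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        return (self.rho(pts) <= scale).reshape(h, w)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SynthParams:
    """Conditions of one synthetic torsion trial.

    Defaults follow the reference experiment: 2 N at 20 deg/s, 80 degrees
    of rotation, 1 frame per degree of plate rotation (so the camera frame
    rate numerically equals the angular velocity in deg/s), 85 px/mm,
    contact-area law A0 = a F_N^b with (a, b) = (113.59 mm^2, 0.21),
    features spaced to give ~0.022 mm^2 Delaunay triangles, and sensor
    noise at the levels of the reference force/torque hardware.

    The friction law is Coulomb-like with an optional pressure weakening,
    mu(p) = mu_local * (p / p_ref)^(-mu_load_exponent): local traction
    falls with nominal pressure, the standard account of why finger
    friction coefficients drop with load.  The defaults (mu_local = 1.57,
    exponent 0.44) make the emergent rotational-friction power law land at
    k ~ 6.7 mm and n ~ 0.76 for the default contact law.
    """

    F_N: float = 2.0                     # normal force, N
    omega: float = 20.0                  # angular velocity, deg/s
    direction: Literal["CW", "CCW"] = "CCW"
    total_rotation: float = 80.0         # deg
    frames_per_degree: float = 1.0
    contact_law: tuple[float, float] = (113.59, 0.21)   # A0 = a * F_N**b, mm^2
    ellipse_aspect: float = 0.8          # minor/major
    ellipse_tilt_deg: float = 15.0
    mu_local: float = 1.57               # friction coefficient at p_ref
    mu_load_exponent: float = 0.44       # pressure-weakening exponent (0 = Coulomb)
    p_ref_pa: float = 1e4
    pressure_profile: Literal["uniform", "hertzian"] = "uniform"
    slip_front_gain: float = 0.025       # stick-radius fraction lost per deg of twist
    band_width: float = 0.3              # shear transition band width, mm
    peel_rate: float = 0.2               # peripheral contact area lost, mm^2/deg
    noise_sd: float = 0.1                # feature tracking noise, px
    fn_noise_sd: float = 0.0069          # normal-force sensor noise, N
    torque_noise_sd: float = 8.7e-5      # torque sensor noise, N.m
    px_per_mm: float = 85.0
    feature_spacing_mm: float = 0.2254   # hex lattice pitch -> 0.022 mm^2 triangles
    lattice_jitter_frac: float = 0.15    # jitter sd as a fraction of the spacing
    pre_frames: int = 2                  # static frames before rotation onset
    pause_s: float = 1.0
    hold_s: float = 1.0
    rotation_center_px: tuple[float, float] | None = None  # default: ellipse centroid
    seed: int | None = None

    def validate(self) -> None:
        if not self.F_N > 0:
            raise ValueError("F_N must be positive")
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        if self.direction not in ("CW", "CCW"):
            raise ValueError("direction must be 'CW' or 'CCW'")
        if self.total_rotation < 0:
            raise ValueError("total_rotation must be non-negative")
        if not (0 < self.ellipse_aspect <= 1):
            raise ValueError("ellipse_aspect must lie in (0, 1]")
        if not self.band_width > 0:
            raise ValueError("band_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.slip_front_gain > 0:
            raise ValueError("slip_front_gain must be positive")
        if self.pressure_profile not in ("uniform", "hertzian"):
            raise ValueError("pressure_profile must be 'uniform' or 'hertzian'")
        if self.seed is None:
            raise ValueError("seed is mandatory for a reproducible trial")
        if self.peel_rate * self.total_rotation > 0.6 * self.contact_area0_mm2:
            raise ValueError("peel schedule would remove most of the contact")

    # derived geometry ------------------------------------------------------

    @property
    def contact_area0_mm2(self) -> float:
        a, b = self.contact_law
        return float(a * self.F_N**b)

    @property
    def direction_sign(self) -> float:
        return 1.0 if self.direction == "CCW" else -1.0

    def ellipse(self) -> ContactEllipse:
        area = self.contact_area0_mm2
        major = float(np.sqrt(area / (np.pi * self.ellipse_aspect)))
        minor = self.ellipse_aspect * major
        margin_px = 24
        half = int(np.ceil(major * self.px_per_mm)) + margin_px
        c = (float(half), float(half)) if self.rotation_center_px is None else self.rotation_center_px
        return ContactEllipse(
            center_px=c, major_mm=major, minor_mm=minor,
            tilt_deg=self.ellipse_tilt_deg, px_per_mm=self.px_per_mm,
        )

    def image_shape(self) -> tuple[int, int]:
        e = self.ellipse()
        side = int(2 * round(e.center_px[0]))
        return side, side

    @property
    def band_deg(self) -> float:
        """Plate-rotation interval over which the front crosses one band width."""
        e = self.ellipse()
        return self.band_width / (self.slip_front_gain * e.geo_radius_mm)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic answers of a simulated trial, for recovery tests."""

    stick_radius_mm_by_frame: np.ndarray   # geometric-mean stick radius, mm
    stick_fraction_by_frame: np.ndarray    # stuck area / contact area
    full_slip_angle_deg: float             # twist at stick fraction 0.03; NaN if never reached
    full_slip_frame: int                   # -1 when the event is absent
    torque_plateau_nm: float               # full traction integral
    triangle_first_slip_frame: np.ndarray  # per GT triangle; -1 = never slips
    gt_triangles: np.ndarray               # (n_tri, 3) over the clean lattice
    feature_slip_angle_deg: np.ndarray     # front-midline passage angle per feature
    peeled_area_mm2_by_frame: np.ndarray
    rotation_center_px: tuple[float, float]
    contact_area0_mm2: float

    def __post_init__(self) -> None:
        d = np.diff(self.stick_radius_mm_by_frame)
        if (d > 1e-9).any():
            raise ValueError("stick radius must be non-increasing")


@dataclass
class SimulatedTrial:
    """Bundle of everything one torsion trial produces."""

    params: SynthParams
    trajectories: TrajectorySet
    masks: np.ndarray          # (n_frames, H, W) bool
    traces: TrialTraces
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# feature lattice
# ---------------------------------------------------------------------------

def feature_lattice(
    ellipse: ContactEllipse,
    spacing_mm: float,
    jitter_sd_mm: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Jittered hexagonal lattice of feature positions clipped to an ellipse.

    With pitch s the mean Delaunay triangle area is s^2*sqrt(3)/4, so the
    0.2254 mm default pitch reproduces the ~0.022 mm^2 elements of the
    reference data.  Returns (n, 2) pixel coordinates; raises if fewer
    than 3 features survive clipping.
    """
    if not spacing_mm > 0:
        raise ValueError("spacing_mm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = ellipse.major_mm
    dy = spacing_mm * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(2 * a / dy)) + 2
    n_cols = int(np.ceil(2 * a / spacing_mm)) + 2
    rows = (np.arange(n_rows) - (n_rows - 1) / 2.0) * dy
    cols = (np.arange(n_cols) - (n_cols - 1) / 2.0) * spacing_mm
    xx, yy = np.meshgrid(cols, rows)
    xx[1::2] += spacing_mm / 2.0
    pts_mm = np.stack([xx.ravel(), yy.ravel()], axis=1)
    if jitter_sd_mm > 0:
        pts_mm = pts_mm + rng.normal(0.0, jitter_sd_mm, pts_mm.shape)
    pts_px = pts_mm * ellipse.px_per_mm + np.asarray(ellipse.center_px)
    keep = ellipse.rho(pts_px) <= 1.0
    pts_px = pts_px[keep]
    if pts_px.shape[0] < 3:
        raise ValueError("fewer than 3 features inside the contact ellipse")
    return pts_px


# ---------------------------------------------------------------------------
# traction integral
# ---------------------------------------------------------------------------

def _pressure(params: SynthParams, rho: np.ndarray) -> np.ndarray:
    """Contact pressure profile p(rho) in Pa over the initial contact."""
    area_m2 = params.contact_area0_mm2 * 1e-6
    if params.pressure_profile == "uniform":
        return np.full_like(rho, params.F_N / area_m2)
    p0 = 1.5 * params.F_N / area_m2
    return p0 * np.sqrt(np.clip(1.0 - rho**2, 0.0, None))


def _mu(params: SynthParams, p: np.ndarray) -> np.ndarray:
    """Local friction coefficient, optionally weakening with pressure."""
    if params.mu_load_exponent == 0.0:
        return np.full_like(p, params.mu_local)
    with np.errstate(divide="ignore"):
        return np.where(
            p > 0,
            params.mu_local * (p / params.p_ref_pa) ** (-params.mu_load_exponent),
            0.0,
        )


def torque_curve(params: SynthParams, n_rho: int = 2001) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative friction-torque integral C(rho) = int_{rho'<rho} mu p r dA.

    The full integral C(1) is the torque plateau during steady slip; the
    torque while the front sits at rho_s is C(1) - C(rho_s) (only the
    sliding annulus transmits kinetic friction).  Separates into a polar
    angle factor (ellipse arc length) and a radial quadrature; returned in
    N.m with rho on [0, 1].
    """
    e = params.ellipse()
    ra, rb = e.major_mm, e.minor_mm
    psi = np.linspace(0.0, 2 * np.pi, 4097)
    s_psi = np.trapezoid(
        np.sqrt(ra**2 * np.cos(psi) ** 2 + rb**2 * np.sin(psi) ** 2), psi
    )
    rho = np.linspace(0.0, 1.0, n_rho)
    p = _pressure(params, rho)
    integrand = _mu(params, p) * p * rho**2
    radial = np.concatenate(
        [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(rho))]
    )
    # mm^3 * Pa -> N.m
    return rho, 1e-9 * ra * rb * s_psi * radial


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _smoothstep_integral(a: np.ndarray) -> np.ndarray:
    """Antiderivative of the clamped smoothstep 3a^2-2a^3 (0 below 0, 1 above 1)."""
    a = np.asarray(a, dtype=float)
    mid = a**3 - 0.5 * a**4
    return np.where(a <= 0.0, 0.0, np.where(a >= 1.0, a - 0.5, mid))


def _feature_angles(
    theta_mag: np.ndarray, theta_slip: np.ndarray, band_deg: float
) -> np.ndarray:
    """Accumulated rotation of each feature for each plate twist magnitude, deg.

    A feature co-rotates with the plate until the slip front reaches it at
    plate twist ``theta_slip``, then decelerates smoothly (smoothstep) over
    ``band_deg`` of further plate rotation, after which it is frozen.
    Returns (n_frames, n_features).
    """
    a = (theta_mag[:, None] - theta_slip[None, :]) / band_deg
    return theta_mag[:, None] - band_deg * _smoothstep_integral(a)


def _stick_fraction(theta_mag: np.ndarray, gain: float, band_deg: float) -> np.ndarray:
    """Ground-truth stuck-area fraction vs twist: front midline at rho_c.

    The front centreline (half the band has stopped) sits at
    rho_c = 1 - gain*(theta - band/2); the stuck fraction of an ellipse is
    rho_c^2.
    """
    rho_c = 1.0 - gain * np.clip(theta_mag - 0.5 * band_deg, 0.0, None)
    return np.clip(rho_c, 0.0, 1.0) ** 2


def full_slip_angle_analytic(params: SynthParams, cutoff: float = STICK_CUTOFF) -> float:
    """Closed-form twist magnitude at which the stuck fraction crosses ``cutoff``."""
    return (1.0 - np.sqrt(cutoff)) / params.slip_front_gain + 0.5 * params.band_deg


def analytic_friction_exponent(
    params: SynthParams, forces_n: np.ndarray | list[float]
) -> float:
    """Configured rotational-friction exponent n-1 of the generator.

    mu_rot(F) = plateau(F)/F follows a power law whose exponent emerges from
    the contact-area law and the pressure-weakening friction; it is
    evaluated here from the noiseless traction integrals over the given
    force ladder (log-log slope).
    """
    import dataclasses as _dc

    forces = np.asarray(forces_n, dtype=float)
    mu = np.empty_like(forces)
    for i, f in enumerate(forces):
        p = _dc.replace(params, F_N=float(f))
        _, cum = torque_curve(p)
        mu[i] = cum[-1] / f
    slope, _ = np.polyfit(np.log(forces), np.log(mu), 1)
    return float(slope)


def simulate_traces(
    params: SynthParams, rng: np.random.Generator | None = None
) -> tuple[TrialTraces, float]:
    """1 kHz force/torque/angle traces of a trial, plus the analytic plateau.

    The torque is the friction integral over the slipping annulus: zero
    while everything sticks, rising monotonically to the plateau as the
    front closes on the centre, held there afterwards.  Cheap enough to run
    standalone for friction ladders that need no imagery.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed).spawn(3)[2]
    rho_grid, cum_t = torque_curve(params)
    plateau = float(cum_t[-1])
    gain, band_deg = params.slip_front_gain, params.band_deg
    duration = params.pause_s + params.total_rotation / params.omega + params.hold_s
    t_tr = np.arange(0.0, duration + 0.5e-3, 1e-3)
    ang_mag = np.clip((t_tr - params.pause_s) * params.omega, 0.0, params.total_rotation)
    rho_front = np.clip(
        1.0 - gain * np.clip(ang_mag - 0.5 * band_deg, 0.0, None), 0.0, 1.0
    )
    torque_mag = plateau - np.interp(rho_front, rho_grid, cum_t)
    fn = np.full_like(t_tr, params.F_N)
    torque = params.direction_sign * torque_mag
    if params.fn_noise_sd > 0:
        fn = fn + rng.normal(0.0, params.fn_noise_sd, fn.shape)
    if params.torque_noise_sd > 0:
        torque = torque + rng.normal(0.0, params.torque_noise_sd, torque.shape)
    traces = TrialTraces(
        time_s=t_tr,
        fn_n=fn,
        torque_nm=torque,
        angle_deg=params.direction_sign * ang_mag,
        direction=params.direction,
    )
    return traces, plateau


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

def simulate_trial(params: SynthParams) -> SimulatedTrial:
    """Generate one complete synthetic torsion trial.

    Returns trajectories (sampled at 1 frame per ``1/frames_per_degree``
    degrees of plate rotation, preceded by ``pre_frames`` static frames),
    a per-frame boolean contact-mask stack shrinking at the peel rate,
    1 kHz force/torque/angle traces whose torque rises monotonically to the
    analytic traction plateau, and the ground truth.  Identical params
    (including seed) give bit-identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rng_lattice, rng_track, rng_sensor = rng.spawn(3)

    ellipse = params.ellipse()
    if ellipse.minor_mm < 3.0 * params.feature_spacing_mm:
        raise ValueError(
            "contact radius below 3 feature spacings: mesh would be degenerate"
        )
    center = np.asarray(ellipse.center_px)

    ref = feature_lattice(
        ellipse,
        params.feature_spacing_mm,
        params.lattice_jitter_frac * params.feature_spacing_mm,
        rng_lattice,
    )
    n_feat = ref.shape[0]
    rho = ellipse.rho(ref)

    # frame schedule
    n_rot = int(round(params.total_rotation * params.frames_per_degree))
    mag_rot = np.arange(n_rot + 1) / params.frames_per_degree
    theta_mag = np.concatenate([np.zeros(params.pre_frames), mag_rot])
    n_frames = len(theta_mag)
    fps = params.omega * params.frames_per_degree
    t_rot = params.pause_s + mag_rot / params.omega
    t_pre = params.pause_s - (np.arange(params.pre_frames, 0, -1)) / fps
    time_s = np.concatenate([t_pre, t_rot])
    plate_angle = params.direction_sign * theta_mag

    # kinematics: rigid co-rotation inside the stick region, smooth-step
    # deceleration across the band, frozen beyond
    gain = params.slip_front_gain
    band_deg = params.band_deg
    theta_slip = np.clip(1.0 - rho, 0.0, None) / gain
    phi_mag = _feature_angles(theta_mag, theta_slip, band_deg)
    phi = np.radians(params.direction_sign * phi_mag)
    rel = ref - center
    cos, sin = np.cos(phi), np.sin(phi)
    positions = np.empty((n_frames, n_feat, 2))
    positions[..., 0] = center[0] + cos * rel[:, 0] - sin * rel[:, 1]
    positions[..., 1] = center[1] + sin * rel[:, 0] + cos * rel[:, 1]
    if params.noise_sd > 0:
        positions = positions + rng_track.normal(0.0, params.noise_sd, positions.shape)

    traj = TrajectorySet(
        positions=positions,
        time_s=time_s,
        plate_angle_deg=plate_angle,
        px_per_mm=params.px_per_mm,
    )

    # masks: peeling removes an outer *material* annulus, so the contact
    # region at frame f is the forward image of the material disc
    # rho0 <= rho_peel(f) under the twist map -- a scaled copy of the
    # initial ellipse rigidly rotated by the accumulated twist of the
    # boundary material (the twist map is a bijection, so membership of
    # skin in the contact is exactly material membership).
    shape = params.image_shape()
    area0 = params.contact_area0_mm2
    areas = area0 - params.peel_rate * theta_mag
    rho_peel = np.sqrt(areas / area0)
    theta_slip_b = np.clip(1.0 - rho_peel, 0.0, None) / gain
    phi_b_mag = theta_mag - band_deg * _smoothstep_integral(
        (theta_mag - theta_slip_b) / band_deg
    )
    phi_b = np.radians(params.direction_sign * phi_b_mag)
    masks = np.empty((n_frames, *shape), dtype=bool)
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    pix = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    rel_pix = pix - center
    for f in range(n_frames):
        cb, sb = np.cos(-phi_b[f]), np.sin(-phi_b[f])
        back = np.stack(
            [cb * rel_pix[:, 0] - sb * rel_pix[:, 1],
             sb * rel_pix[:, 0] + cb * rel_pix[:, 1]],
            axis=1,
        ) + center
        masks[f] = (ellipse.rho(back) <= rho_peel[f]).reshape(h, w)

    # 1 kHz traces
    traces, plateau = simulate_traces(params, rng_sensor)

    # ground truth
    frac = _stick_fraction(theta_mag, gain, band_deg)
    rho_c = np.sqrt(frac)
    fs_angle = full_slip_angle_analytic(params)
    below = frac < STICK_CUTOFF
    if below.any():
        fs_frame = int(np.argmax(below))
    else:
        # rotation too short to reach full slip: the event is absent
        fs_frame = -1
        fs_angle = float("nan")
    tri = Delaunay(ref).simplices
    cent_rho = ellipse.rho(ref[tri].mean(axis=1))
    tri_slip_angle = np.clip(1.0 - cent_rho, 0.0, None) / gain + 0.5 * band_deg
    first_slip = np.searchsorted(theta_mag[params.pre_frames :], tri_slip_angle)
    first_slip = np.where(
        tri_slip_angle <= theta_mag[-1], first_slip + params.pre_frames, -1
    )
    feat_slip_angle = theta_slip + 0.5 * band_deg
    gt = GroundTruth(
        stick_radius_mm_by_frame=rho_c * ellipse.geo_radius_mm,
        stick_fraction_by_frame=frac,
        full_slip_angle_deg=float(fs_angle),
        full_slip_frame=fs_frame,
        torque_plateau_nm=plateau,
        triangle_first_slip_frame=first_slip,
        gt_triangles=tri,
        feature_slip_angle_deg=feat_slip_angle,
        peeled_area_mm2_by_frame=params.peel_rate * theta_mag,
        rotation_center_px=tuple(center),
        contact_area0_mm2=area0,
    )
    return SimulatedTrial(
        params=params, trajectories=traj, masks=masks, traces=traces, ground_truth=gt
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frames(
    trial: SimulatedTrial, dot_density: float = 1.0, dot_radius_px: int = 3
) -> np.ndarray:
    """Render 8-bit grayscale frames: dark background, brighter contact, bright dots.

    ``dot_density`` is the fraction of features rendered as fingerprint-like
    dots (sampled deterministically from the trial seed).  Gives a
    downstream threshold segmenter something to chew on.
    """
    if dot_radius_px < 1:
        raise ValueError("dot_radius_px must be >= 1")
    if not (0.0 <= dot_density <= 1.0):
        raise ValueError("dot_density must lie in [0, 1]")
    pos = trial.trajectories.positions
    n_frames, n_feat, _ = pos.shape
    h, w = trial.masks.shape[1:]
    frames = np.full((n_frames, h, w), 16, dtype=np.uint8)
    frames[trial.masks] = 96
    if n_feat and dot_density > 0:
        rng = np.random.default_rng(trial.params.seed)
        n_keep = int(round(dot_density * n_feat))
        keep = rng.permutation(n_feat)[:n_keep]
        r = dot_radius_px
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        disc = (dy**2 + dx**2) <= r**2
        for f in range(n_frames):
            img = frames[f]
            for x, y in pos[f, keep]:
                cx, cy = int(round(x)), int(round(y))
                if not (r <= cx < w - r and r <= cy < h - r):
                    continue
                patch = img[cy - r : cy + r + 1, cx - r : cx + r + 1]
                patch[disc] = 224
    return frames
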