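"""Force/torque trace processing and rotational friction.

Traces come in at 1 kHz (time, normal force F_N, torque about the contact
normal T, plate angle).  The processing chain is: zero-phase low-pass
filtering, extraction of the torque plateau T_slip (mean |T| over the 0.5 s
window ending where the twist first reaches 75 degrees, chosen short of the
full 80 degrees to stay clear of the plate's deceleration), the rotational
friction coefficient mu_rot = T_slip / F_N (units of length), power-law
fits mu_rot = k F_N^(n-1) and A0 = a F_N^b across force ladders, the
external work W = int T dtheta done on the finger, and sensor SNR
arithmetic.

Torque magnitudes |T| are used throughout so clockwise and counterclockwise
trials share one code path; the direction is carried as metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTraces",
    "PowerLawFit",
    "filter_signals",
    "extract_t_slip",
    "mu_rot",
    "fit_power_law",
    "external_work",
    "snr_db",
    "tangential_force_from_torque",
]


@dataclass
class TrialTraces:
    """1 kHz force/torque/angle traces of one torsion trial."""

    time_s: np.ndarray
    fn_n: np.ndarray
    torque_nm: np.ndarray
    angle_deg: np.ndarray
    direction: str = "CCW"
    filtered: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fn_n = np.asarray(self.fn_n, dtype=float)
        self.torque_nm = np.asarray(self.torque_nm, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        n = len(self.time_s)
        if not (len(self.fn_n) == len(self.torque_nm) == len(self.angle_deg) == n):
            raise ValueError("trace arrays must share one length")
        if n >= 2 and (np.diff(self.time_s) <= 0).any():
            raise ValueError("time must be strictly increasing")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "Fn_N": self.fn_n,
                "Tz_Nm": self.torque_nm,
                "angle_deg": self.angle_deg,
            }
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame, direction: str = "CCW") -> "TrialTraces":
        required = {"time_s", "Fn_N", "Tz_Nm", "angle_deg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        return cls(
            time_s=df["time_s"].to_numpy(),
            fn_n=df["Fn_N"].to_numpy(),
            torque_nm=df["Tz_Nm"].to_numpy(),
            angle_deg=df["angle_deg"].to_numpy(),
            direction=direction,
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law y = prefactor * x^exponent.

    For the friction model mu_rot = k F_N^(n-1) the exponent is n-1; for
    the contact-area model A0 = a F_N^b it is b.  r2 is the coefficient of
    determination in linear space; r2_log the one in log-log space.
    """

    prefactor: float
    exponent: float
    r2: float
    r2_log: float
    model: str = "generic"

    @property
    def k(self) -> float:
        return self.prefactor

    @property
    def n(self) -> float:
        return self.exponent + 1.0

    @property
    def a(self) -> float:
        return self.prefactor

    @property
    def b(self) -> float:
        return self.exponent


def filter_signals(
    traces: TrialTraces, order: int = 2, cutoff_hz: float = 5.0
) -> TrialTraces:
    """Zero-phase Butterworth low-pass of force and torque traces.

    Forward-backward filtering (filtfilt): unit DC gain and no group delay,
    at the cost of squaring the magnitude response.  The plate angle is a
    commanded kinematic signal and is left untouched.
    """
    fs = traces.fs_hz
    if cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist ({fs / 2.0} Hz)")
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = signal.butter(order, cutoff_hz, fs=fs)
    return replace(
        traces,
        fn_n=signal.filtfilt(b, a, traces.fn_n),
        torque_nm=signal.filtfilt(b, a, traces.torque_nm),
        filtered=True,
    )


def extract_t_slip(
    traces: TrialTraces, anchor_deg: float = 75.0, window_s: float = 0.5
) -> float | None:
    """Torque plateau T_slip: mean |T| over the window preceding 75 deg of twist.

    Returns None (with a warning) if the trial never reaches the anchor
    angle.
    """
    twist = np.abs(traces.angle_deg)
    reached = np.nonzero(twist >= anchor_deg)[0]
    if reached.size == 0:
        warnings.warn(
            f"twist never reaches {anchor_deg} deg; T_slip undefined", stacklevel=2
        )
        return None
    t_anchor = traces.time_s[reached[0]]
    sel = (traces.time_s > t_anchor - window_s) & (traces.time_s <= t_anchor)
    return float(np.mean(np.abs(traces.torque_nm[sel])))


def mu_rot(t_slip_nm: float, f_n: float) -> float:
    """Rotational friction coefficient mu_rot = T_slip / F_N, in metres."""
    if not f_n > 0:
        raise ValueError("F_N must be positive")
    return t_slip_nm / f_n


def fit_power_law(
    x: np.ndarray, y: np.ndarray, model: str = "mu", space: str = "linear"
) -> PowerLawFit:
    """Fit y = c * x^e by least squares over a force ladder.

    model="mu" labels the rotational-friction convention (k, n with
    e = n-1); model="area" the contact-area convention (a, b with e = b).
    space="linear" (default) runs nonlinear least squares on the raw values
    initialized from a log-log line; space="log" keeps the log-log line
    itself (requires strictly positive y).  Both r^2 values are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if model not in ("mu", "area", "generic"):
        raise ValueError("model must be 'mu', 'area' or 'generic'")
    if space not in ("linear", "log"):
        raise ValueError("space must be 'linear' or 'log'")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x levels")
    if (x <= 0).any():
        raise ValueError("x must be positive")
    if (y <= 0).any():
        raise ValueError("y must be positive for a power-law fit")

    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    c0, e0 = float(np.exp(intercept)), float(slope)
    if space == "linear":
        popt, _ = optimize.curve_fit(
            lambda xx, c, e: c * xx**e, x, y, p0=(c0, e0), maxfev=10000
        )
        c, e = float(popt[0]), float(popt[1])
    else:
        c, e = c0, e0

    pred = c * x**e
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ly, lp = np.log(y), np.log(pred)
    ss_res_l = float(np.sum((ly - lp) ** 2))
    ss_tot_l = float(np.sum((ly - ly.mean()) ** 2))
    r2_log = 1.0 - ss_res_l / ss_tot_l if ss_tot_l > 0 else 1.0
    return PowerLawFit(prefactor=c, exponent=e, r2=r2, r2_log=r2_log, model=model)


def external_work(traces: TrialTraces) -> tuple[float, np.ndarray]:
    """External work W = int T dtheta done on the finger by the plate, J.

    Trapezoidal in the (unsigned) twist angle with |T|, so the work done on
    the finger is positive regardless of rotation direction; hold phases
    (dtheta = 0) contribute nothing.  Returns (W, cumulative series).
    """
    theta = np.radians(np.abs(traces.angle_deg))
    t_abs = np.abs(traces.torque_nm)
    if len(theta) != len(t_abs):
        raise ValueError("misaligned torque/angle series")
    increments = 0.5 * (t_abs[1:] + t_abs[:-1]) * np.diff(theta)
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    return float(cumulative[-1]), cumulative


def snr_db(signal_level: float, noise_level: float) -> float:
    """Amplitude signal-to-noise ratio in dB: 20 log10(signal / noise)."""
    if signal_level <= 0 or noise_level <= 0:
        raise ValueError("signal and noise levels must be positive")
    return 20.0 * np.log10(signal_level / noise_level)


def tangential_force_from_torque(torque_nm: float, lever_m: float) -> float:
    """Tangential force a torque produces at a lever arm: F = T / r.

    The sensor-mounting arithmetic: a 0.01 N.m torque read 0.1 m off-centre
    appears as a 0.1 N tangential force.
    """
    if not lever_m > 0:
        raise ValueError("lever arm must be positive")
    return torque_nm / lever_m
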