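"""Shared fixtures: small, fast synthetic trials and helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import padtorsion as pt


@pytest.fixture(scope="session")
def small_params() -> pt.SynthParams:
    """A coarse, noiseless trial: fast to simulate, exact to reason about."""
    return pt.SynthParams(
        feature_spacing_mm=0.45,
        noise_sd=0.0,
        fn_noise_sd=0.0,
        torque_noise_sd=0.0,
        lattice_jitter_frac=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_trial(small_params) -> pt.SimulatedTrial:
    return pt.simulate_trial(small_params)


@pytest.fixture(scope="session")
def small_result(small_trial) -> pt.TrialResult:
    return pt.analyze_simulated(small_trial)


@pytest.fixture(scope="session")
def noisy_params(small_params) -> pt.SynthParams:
    """Same geometry with default sensor and tracking noise."""
    return dataclasses.replace(
        small_params, noise_sd=0.1, fn_noise_sd=0.0069, torque_noise_sd=8.7e-5
    )


def rigid_motion(points: np.ndarray, angle_rad: float, shift: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T + shift


@pytest.fixture()
def two_frame_traj():
    """Factory: a TrajectorySet from two position arrays."""

    def make(p0: np.ndarray, p1: np.ndarray, px_per_mm: float = 85.0) -> pt.TrajectorySet:
        return pt.TrajectorySet(
            positions=np.stack([p0, p1]),
            time_s=np.array([0.0, 1.0]),
            plate_angle_deg=np.array([0.0, 0.0]),
            px_per_mm=px_per_mm,
        )

    return make
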