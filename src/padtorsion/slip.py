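"""Slip classification, stick ratio and the slip-front boundary.

A triangular skin element counts as slipping on a frame interval when its
rotation rate about its own centroid differs from the rigid plate's by more
than 0.6 degrees per frame.  With acquisition at one frame per degree of
plate rotation this per-frame threshold is equivalent to 0.6 x the plate
rate at every angular velocity, so it transfers across speeds.

The stick ratio is the area of in-contact non-slipping skin over the total
in-contact area; full slip is declared the first time it drops below 0.03
(slip near the rotation centre is below displacement resolution, hence the
non-zero cutoff).  The stuck/slipping boundary is traced by interpolating
slip flags onto a regular pixel grid and contouring the largest connected
stuck component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import griddata
from scipy.spatial import Delaunay
from skimage import measure

from .strain import TriangleMesh

__all__ = [
    "SlipSeries",
    "triangle_rotation_rate",
    "rotation_rates",
    "classify_slip",
    "stick_ratio",
    "full_slip_event",
    "slip_boundary",
    "compute_slip_series",
]


@dataclass
class SlipSeries:
    """Per-trial slip description.

    ``slip_flag[t, j]`` covers the interval from frame j to j+1;
    ``stick_ratio[j]`` is evaluated with the areas and contact membership
    of frame j+1, and ``twist_deg[j]`` is the twist magnitude there.
    """

    slip_flag: np.ndarray          # (n_tri, n_intervals) bool
    rates_deg_per_frame: np.ndarray
    stick_ratio: np.ndarray        # (n_intervals,)
    twist_deg: np.ndarray          # (n_intervals,)
    full_slip_frame: int | None
    full_slip_angle_deg: float | None

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(1, len(self.stick_ratio) + 1),
                "angle_deg": self.twist_deg,
                "stick_ratio": self.stick_ratio,
            }
        )


def triangle_rotation_rate(
    mesh: TriangleMesh, frame_a: int, frame_b: int
) -> np.ndarray:
    """Signed rotation (deg) of each triangle about its centroid between frames.

    Mean over the three vertices of the angle swept by the
    centroid-to-vertex vector.  Vertices coincident with the centroid are
    excluded; a triangle with all three coincident is NaN.
    """
    va = mesh.vertex_coords(frame_a)
    vb = mesh.vertex_coords(frame_b)
    ra = va - va.mean(axis=1, keepdims=True)
    rb = vb - vb.mean(axis=1, keepdims=True)
    cross = ra[..., 0] * rb[..., 1] - ra[..., 1] * rb[..., 0]
    dot = (ra * rb).sum(axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    norm = np.linalg.norm(ra, axis=-1) * np.linalg.norm(rb, axis=-1)
    ok = norm > 1e-12
    rate = np.where(ok, ang, np.nan)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        out = np.nanmean(rate, axis=1)
    return out


def rotation_rates(mesh: TriangleMesh) -> np.ndarray:
    """(n_tri, n_frames-1) rotation rates for all consecutive frame pairs."""
    return np.stack(
        [triangle_rotation_rate(mesh, j, j + 1) for j in range(mesh.n_frames - 1)],
        axis=1,
    )


def classify_slip(
    rates: np.ndarray,
    plate_rate_deg_per_frame: np.ndarray | float,
    threshold: float = 0.6,
) -> np.ndarray:
    """Flag triangles whose rotation rate deviates from the plate's by > threshold.

    The flag is instantaneous (no persistence); frozen skin under a moving
    plate and counter-rotating skin at the slip front both exceed the
    threshold.  NaN rates (degenerate triangles) are flagged as slipping.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    plate = np.asarray(plate_rate_deg_per_frame, dtype=float)
    diff = np.abs(rates - plate)
    return np.where(np.isnan(diff), True, diff > threshold)


def stick_ratio(
    slip_flag: np.ndarray,
    areas_mm2: np.ndarray,
    in_contact: np.ndarray | None = None,
) -> float:
    """Area of stuck in-contact skin over total in-contact area, in [0, 1].

    NaN (flagged) when there is no in-contact area at all.
    """
    a = np.asarray(areas_mm2, dtype=float)
    if in_contact is None:
        in_contact = np.ones(len(a), dtype=bool)
    total = a[in_contact].sum()
    if total <= 0:
        warnings.warn("no in-contact area; stick ratio undefined", stacklevel=2)
        return float("nan")
    stuck = a[in_contact & ~slip_flag].sum()
    return float(stuck / total)


def full_slip_event(
    stick_ratio_series: np.ndarray,
    twist_deg: np.ndarray,
    cutoff: float = 0.03,
) -> tuple[int, float] | None:
    """First frame where the stick ratio drops below the cutoff.

    Returns (frame index into the series, twist angle there) or None if the
    ratio never crosses -- a valid outcome, not an error.
    """
    s = np.asarray(stick_ratio_series, dtype=float)
    below = np.nonzero(s < cutoff)[0]
    if below.size == 0:
        return None
    k = int(below[0])
    return k, float(twist_deg[k])


def slip_boundary(
    slip_flag: np.ndarray,
    centroids_px: np.ndarray,
    grid_px: float = 4.0,
    method: str = "nearest",
) -> list[np.ndarray]:
    """Outer boundary polyline(s) of the largest connected stuck region.

    Slip flags at triangle centroids are interpolated onto a regular grid
    of pitch ``grid_px`` (nearest-neighbour by default, linear optional),
    restricted to the convex hull of the centroids; the largest connected
    stuck component is contoured (marching squares).  Returns a list of
    (m, 2) arrays of (x, y) pixel coordinates; empty if nothing is stuck.
    """
    if method not in ("nearest", "linear"):
        raise ValueError("method must be 'nearest' or 'linear'")
    stuck = ~np.asarray(slip_flag, dtype=bool)
    pts = np.asarray(centroids_px, dtype=float)
    if not stuck.any():
        return []
    x0, y0 = pts.min(axis=0) - grid_px
    x1, y1 = pts.max(axis=0) + grid_px
    gx = np.arange(x0, x1 + grid_px, grid_px)
    gy = np.arange(y0, y1 + grid_px, grid_px)
    gxx, gyy = np.meshgrid(gx, gy)
    grid_pts = np.stack([gxx.ravel(), gyy.ravel()], axis=1)
    vals = griddata(pts, stuck.astype(float), grid_pts, method=method, fill_value=0.0)
    vals = np.nan_to_num(vals, nan=0.0)
    inside = Delaunay(pts).find_simplex(grid_pts) >= 0
    field = ((vals >= 0.5) & inside).reshape(gyy.shape)
    if not field.any():
        return []
    labels, n = ndimage.label(field)
    if n > 1:
        sizes = ndimage.sum_labels(field, labels, index=np.arange(1, n + 1))
        field = labels == (1 + int(np.argmax(sizes)))
    padded = np.pad(field, 1, constant_values=False)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return []
    outer = max(contours, key=lambda c: c.shape[0])
    # padded (row, col) -> pixel (x, y)
    xy = np.stack(
        [x0 + (outer[:, 1] - 1) * grid_px, y0 + (outer[:, 0] - 1) * grid_px], axis=1
    )
    return [xy]


def compute_slip_series(
    mesh: TriangleMesh,
    plate_angle_deg: np.ndarray,
    threshold: float = 0.6,
    cutoff: float = 0.03,
) -> SlipSeries:
    """Full slip pipeline for a mesh: rates, flags, stick ratio, full-slip event."""
    angle = np.asarray(plate_angle_deg, dtype=float)
    rates = rotation_rates(mesh)
    plate_rate = np.diff(angle)
    flags = classify_slip(rates, plate_rate[None, :], threshold)
    n_int = rates.shape[1]
    ratios = np.empty(n_int)
    for j in range(n_int):
        contact = mesh.in_contact[:, j + 1] if mesh.in_contact is not None else None
        ratios[j] = stick_ratio(flags[:, j], mesh.areas(j + 1), contact)
    twist = np.abs(angle[1:] - angle[0])
    event = full_slip_event(ratios, twist, cutoff)
    if event is None:
        frame, fs_angle = None, None
    else:
        # series index j corresponds to mesh frame j+1
        frame, fs_angle = event[0] + 1, event[1]
    return SlipSeries(
        slip_flag=flags,
        rates_deg_per_frame=rates,
        stick_ratio=ratios,
        twist_deg=twist,
        full_slip_frame=frame,
        full_slip_angle_deg=fs_angle,
    )
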