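"""Surface strain fields from tracked skin features.

The skin in contact with a rotating plate is observed as a cloud of tracked
features (fingerprint-scale landmarks).  A Delaunay triangulation over their
reference positions tessellates the contact into small triangular skin
elements; the affine map carrying each triangle from one frame to another
defines a deformation gradient F, from which the finite (Green-Lagrange)
strain tensor

    E = (F^T F - I) / 2

is exact for the triangle's motion and vanishes identically for rigid
motions.  Principal strains (e1 >= e2), their Mohr-circle invariants --
the area invariant e_a = (e1+e2)/2 and maximum shear e_s = (e1-e2)/2 --
and a plane-strain strain-energy density complete the per-element
description.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySet",
    "TriangleMesh",
    "ElasticParams",
    "StrainField",
    "smooth_displacements",
    "build_mesh",
    "green_lagrange",
    "principal_strains",
    "mohr_invariants",
    "strain_energy_density",
    "total_energy",
    "compute_strain_field",
    "accumulate_strain",
    "energy_series",
    "integrate_rate",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Per-feature, per-frame 2-D positions of tracked skin features.

    Parameters
    ----------
    positions : (n_frames, n_features, 2) float array, pixel coordinates
        ``positions[f, i] = (x, y)`` of feature ``i`` at frame ``f``.
    time_s : (n_frames,) acquisition time of each frame, seconds.
    plate_angle_deg : (n_frames,) signed plate rotation at each frame,
        degrees; counterclockwise positive.
    px_per_mm : image scale (85 px/mm for the reference apparatus).
    """

    positions: np.ndarray
    time_s: np.ndarray
    plate_angle_deg: np.ndarray
    px_per_mm: float = 85.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.plate_angle_deg = np.asarray(self.plate_angle_deg, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (frames, features, 2)")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if len(self.time_s) != self.n_frames or len(self.plate_angle_deg) != self.n_frames:
            raise ValueError("time_s/plate_angle_deg must match the frame count")
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")
        if np.isnan(self.positions).any():
            raise ValueError("positions contain NaN; mask invalid features upstream")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_features(self) -> int:
        return self.positions.shape[1]

    def displacements(self) -> np.ndarray:
        """Displacement of every feature from its reference (frame 0), px."""
        return self.positions - self.positions[0]

    def to_table(self) -> pd.DataFrame:
        """Long-format table (frame, feature_id, x_px, y_px, plate_angle_deg, time_s)."""
        f, n, _ = self.positions.shape
        frames = np.repeat(np.arange(f), n)
        feats = np.tile(np.arange(n), f)
        xy = self.positions.reshape(-1, 2)
        return pd.DataFrame(
            {
                "frame": frames,
                "feature_id": feats,
                "x_px": xy[:, 0],
                "y_px": xy[:, 1],
                "plate_angle_deg": np.repeat(self.plate_angle_deg, n),
                "time_s": np.repeat(self.time_s, n),
            }
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame, px_per_mm: float = 85.0) -> "TrajectorySet":
        required = {"frame", "feature_id", "x_px", "y_px", "plate_angle_deg", "time_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        df = df.sort_values(["frame", "feature_id"])
        frames = df["frame"].to_numpy()
        n_frames = int(frames.max()) + 1
        n_feat = int(df["feature_id"].max()) + 1
        if len(df) != n_frames * n_feat:
            raise ValueError("trajectory table is not a complete frame x feature grid")
        pos = df[["x_px", "y_px"]].to_numpy().reshape(n_frames, n_feat, 2)
        per_frame = df.drop_duplicates("frame").sort_values("frame")
        return cls(
            positions=pos,
            time_s=per_frame["time_s"].to_numpy(),
            plate_angle_deg=per_frame["plate_angle_deg"].to_numpy(),
            px_per_mm=px_per_mm,
        )


@dataclass
class TriangleMesh:
    """Delaunay triangles over reference features, carried through all frames.

    ``triangles`` are vertex index triples into the feature axis of
    ``positions``; all reference triangles are counterclockwise (positive
    signed area).  ``in_contact`` is filled in by the contact module once
    masks are available (all three vertices inside the segmented contact).
    """

    triangles: np.ndarray            # (n_tri, 3) int
    positions: np.ndarray            # (n_frames, n_features, 2) px
    px_per_mm: float
    in_contact: np.ndarray | None = field(default=None)  # (n_tri, n_frames) bool

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def ref_positions(self) -> np.ndarray:
        return self.positions[0]

    def vertex_coords(self, frame: int) -> np.ndarray:
        """(n_tri, 3, 2) vertex coordinates at ``frame``, px."""
        return self.positions[frame][self.triangles]

    def signed_areas(self, frame: int) -> np.ndarray:
        """Signed triangle areas at ``frame``, mm^2 (positive = CCW reference)."""
        v = self.vertex_coords(frame)
        e1 = v[:, 1] - v[:, 0]
        e2 = v[:, 2] - v[:, 0]
        area_px = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
        return area_px / self.px_per_mm**2

    def areas(self, frame: int) -> np.ndarray:
        return np.abs(self.signed_areas(frame))

    def centroids(self, frame: int) -> np.ndarray:
        """(n_tri, 2) triangle centroids at ``frame``, px."""
        return self.vertex_coords(frame).mean(axis=1)


@dataclass(frozen=True)
class ElasticParams:
    """Linear-elastic skin surface parameters for the energy estimate.

    E and nu follow prior finger-pad surface work (1 MPa, 0.4); p_depth is
    the assumed depth over which the surface deformation is homogeneous
    (2 mm) -- an acknowledged order-of-magnitude convention, so energies
    should only be compared against numbers sharing it.
    """

    E: float = 1e6        # Pa
    nu: float = 0.4       # dimensionless
    p_depth: float = 2e-3  # m

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("E must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5); 0.5 is singular in plane strain")


@dataclass
class StrainField:
    """Per-triangle, per-frame-interval strain description.

    Interval ``j`` spans frames ``j`` to ``j+1``; all arrays are
    (n_tri, n_intervals).  ``valid`` marks tensors from non-degenerate
    reference triangles; invalid entries are excluded from medians.
    """

    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    orientation_deg: np.ndarray
    e_a: np.ndarray
    e_s: np.ndarray
    u_d: np.ndarray              # J/m^3
    valid: np.ndarray            # bool
    in_contact: np.ndarray | None = None   # (n_tri, n_frames) bool

    @property
    def n_intervals(self) -> int:
        return self.exx.shape[1]

    def _mask(self, j: int) -> np.ndarray:
        m = self.valid[:, j]
        if self.in_contact is not None:
            m = m & self.in_contact[:, j + 1]
        return m

    def median_abs(self, name: str, j: int) -> float:
        """Median of |field| over valid in-contact triangles at interval j."""
        vals = getattr(self, name)[:, j]
        m = self._mask(j)
        if not m.any():
            return float("nan")
        return float(np.median(np.abs(vals[m])))

    def median_series(self, name: str) -> np.ndarray:
        return np.array([self.median_abs(name, j) for j in range(self.n_intervals)])

    def to_table(self) -> pd.DataFrame:
        """Long table (triangle_id, frame, exx..u_d, in_contact)."""
        t, j = self.exx.shape
        tri = np.repeat(np.arange(t), j)
        frame = np.tile(np.arange(j), t)
        cols = {
            "triangle_id": tri,
            "frame": frame,
            "exx": self.exx.ravel(),
            "eyy": self.eyy.ravel(),
            "exy": self.exy.ravel(),
            "e1": self.e1.ravel(),
            "e2": self.e2.ravel(),
            "orient_deg": self.orientation_deg.ravel(),
            "e_a": self.e_a.ravel(),
            "e_s": self.e_s.ravel(),
            "u_d": self.u_d.ravel(),
        }
        if self.in_contact is not None:
            cols["in_contact"] = self.in_contact[:, 1:].ravel()
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _gaussian_kernel(window_n: int, sigma_frames: float) -> np.ndarray:
    """Symmetric zero-phase Gaussian kernel, renormalized after truncation.

    The window is interpreted temporally (frames axis).  A nominal even
    window length is widened to the symmetric odd support -N/2..N/2 so the
    kernel is exactly zero-phase on the sample grid.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    if sigma_frames <= 0:
        raise ValueError("sigma_frames must be positive")
    half = window_n // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (offsets / sigma_frames) ** 2)
    return k / k.sum()


def smooth_displacements(
    traj: TrajectorySet, window_n: int = 16, sigma_frames: float = 0.75
) -> TrajectorySet:
    """Temporally smooth each feature coordinate with a Gaussian window.

    Each coordinate of each feature is convolved along the frame axis with a
    normalized Gaussian (nominal length ``window_n``, sigma
    ``sigma_frames``), with reflection padding at the sequence ends.
    Constant and (away from the edges) linear trajectories pass through
    unchanged.
    """
    k = _gaussian_kernel(window_n, sigma_frames)
    smoothed = ndimage.convolve1d(traj.positions, k, axis=0, mode="reflect")
    return replace(traj, positions=smoothed)


def build_mesh(traj: TrajectorySet, min_area_mm2: float = 1e-6) -> TriangleMesh:
    """Delaunay-triangulate reference features and carry triangles to all frames.

    Degenerate reference triangles (area below ``min_area_mm2``) are dropped
    with a logged count.  Raises ``ValueError`` if the reference features
    are collinear or fewer than three.
    """
    ref = traj.positions[0]
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 reference features to triangulate")
    try:
        dt = Delaunay(ref)
    except QhullError as err:
        raise ValueError("reference features are degenerate (collinear?)") from err
    if dt.simplices.shape[0] == 0:
        raise ValueError("triangulation produced no triangles (collinear input?)")
    tri = dt.simplices.copy()

    v = ref[tri]
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    signed_px = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    flip = signed_px < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]

    area_mm2 = np.abs(signed_px) / traj.px_per_mm**2
    keep = area_mm2 >= min_area_mm2
    dropped = int((~keep).sum())
    if dropped:
        logger.info("build_mesh: dropped %d degenerate reference triangles", dropped)
    return TriangleMesh(
        triangles=tri[keep], positions=traj.positions, px_per_mm=traj.px_per_mm
    )


def green_lagrange(
    mesh: TriangleMesh, frame_a: int, frame_b: int, degenerate_tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Green-Lagrange strain tensors of every triangle between two frames.

    The deformation gradient F is the (exact) affine map taking a
    triangle's edge vectors at ``frame_a`` to those at ``frame_b``;
    E = (F^T F - I)/2.  Rigid motions of any magnitude yield the zero
    tensor.  Triangles degenerate at ``frame_a`` are flagged invalid.

    Returns
    -------
    exx, eyy, exy, valid : (n_tri,) arrays
    """
    va = mesh.vertex_coords(frame_a)
    vb = mesh.vertex_coords(frame_b)
    # edge matrices: columns are the two edge vectors from vertex 0
    dX = np.stack([va[:, 1] - va[:, 0], va[:, 2] - va[:, 0]], axis=-1)  # (T,2,2)
    dx = np.stack([vb[:, 1] - vb[:, 0], vb[:, 2] - vb[:, 0]], axis=-1)
    det = dX[:, 0, 0] * dX[:, 1, 1] - dX[:, 0, 1] * dX[:, 1, 0]
    scale = np.abs(det)
    valid = scale > degenerate_tol * np.maximum(1.0, (dX**2).sum(axis=(1, 2)))
    safe_det = np.where(valid, det, 1.0)
    inv = np.empty_like(dX)
    inv[:, 0, 0] = dX[:, 1, 1]
    inv[:, 0, 1] = -dX[:, 0, 1]
    inv[:, 1, 0] = -dX[:, 1, 0]
    inv[:, 1, 1] = dX[:, 0, 0]
    inv /= safe_det[:, None, None]
    F = dx @ inv
    C = np.swapaxes(F, 1, 2) @ F
    exx = 0.5 * (C[:, 0, 0] - 1.0)
    eyy = 0.5 * (C[:, 1, 1] - 1.0)
    exy = 0.5 * C[:, 0, 1]
    bad = ~valid
    exx[bad] = eyy[bad] = exy[bad] = np.nan
    return exx, eyy, exy, valid


def principal_strains(
    exx: np.ndarray | float, eyy: np.ndarray | float, exy: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose 2-D strain tensors into (e1, e2, orientation).

    e1 >= e2; the orientation is the angle of the e1 eigenvector in
    (-90, 90] degrees.  Rotating the input coordinates by alpha shifts the
    orientation by alpha and leaves (e1, e2) unchanged (a rotation of alpha
    in the physical plane is a rotation of 2*alpha on Mohr's circle).
    Isotropic tensors have no preferred direction; the orientation is
    tie-broken to 0.
    """
    exx = np.asarray(exx, dtype=float)
    eyy = np.asarray(eyy, dtype=float)
    exy = np.asarray(exy, dtype=float)
    c = 0.5 * (exx + eyy)
    r = np.hypot(0.5 * (exx - eyy), exy)
    e1 = c + r
    e2 = c - r
    orient = 0.5 * np.degrees(np.arctan2(2.0 * exy, exx - eyy))
    iso = r <= 1e-14 * np.maximum(1.0, np.abs(c))
    orient = np.where(iso, 0.0, orient)
    orient = np.where(orient <= -90.0, orient + 180.0, orient)
    return e1, e2, orient


def mohr_invariants(
    e1: np.ndarray | float, e2: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Mohr-circle invariants: area invariant e_a (centre) and max shear e_s (radius).

    e_a = (e1+e2)/2 is the local relative area change; e_s = (e1-e2)/2 is
    the largest shear over all local frame rotations.  Both are invariant
    to the choice of coordinate system.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    return 0.5 * (e1 + e2), 0.5 * (e1 - e2)


def strain_energy_density(
    exx: np.ndarray | float,
    eyy: np.ndarray | float,
    exy: np.ndarray | float,
    elastic: ElasticParams = ElasticParams(),
) -> np.ndarray:
    """Plane-strain strain-energy density u_d (J/m^3) of a strain tensor.

    u_d = E(1-nu)/(2(1+nu)(1-2nu)) (exx^2+eyy^2)
        + E nu/((1+nu)(1-2nu)) exx eyy + E/(1+nu) exy^2

    Symmetric under exx <-> eyy and non-negative for admissible nu.
    """
    E, nu = elastic.E, elastic.nu
    exx = np.asarray(exx, dtype=float)
    eyy = np.asarray(eyy, dtype=float)
    exy = np.asarray(exy, dtype=float)
    c1 = E * (1 - nu) / (2 * (1 + nu) * (1 - 2 * nu))
    c2 = E * nu / ((1 + nu) * (1 - 2 * nu))
    c3 = E / (1 + nu)
    return c1 * (exx**2 + eyy**2) + c2 * exx * eyy + c3 * exy**2


def total_energy(
    u_d: np.ndarray,
    areas_mm2: np.ndarray,
    p_depth_m: float = 2e-3,
    include: np.ndarray | None = None,
) -> float:
    """Total elastic energy U = p * sum(u_d * A) over (in-contact) triangles, J.

    ``areas_mm2`` are converted to m^2; ``include`` restricts the sum (e.g.
    to in-contact triangles).  Negative areas are rejected.
    """
    u_d = np.asarray(u_d, dtype=float)
    a = np.asarray(areas_mm2, dtype=float)
    if (a < 0).any():
        raise ValueError("triangle areas must be non-negative")
    if include is None:
        include = np.ones(len(a), dtype=bool)
    sel = include & np.isfinite(u_d)
    return float(p_depth_m * np.sum(u_d[sel] * a[sel] * 1e-6))


def compute_strain_field(
    mesh: TriangleMesh, elastic: ElasticParams = ElasticParams()
) -> StrainField:
    """Per-interval Green-Lagrange strains, invariants and SED for a mesh."""
    n_int = mesh.n_frames - 1
    shape = (mesh.n_triangles, n_int)
    exx = np.empty(shape)
    eyy = np.empty(shape)
    exy = np.empty(shape)
    valid = np.empty(shape, dtype=bool)
    for j in range(n_int):
        exx[:, j], eyy[:, j], exy[:, j], valid[:, j] = green_lagrange(mesh, j, j + 1)
    e1, e2, orient = principal_strains(exx, eyy, exy)
    e_a, e_s = mohr_invariants(e1, e2)
    u_d = strain_energy_density(exx, eyy, exy, elastic)
    return StrainField(
        exx=exx, eyy=eyy, exy=exy, e1=e1, e2=e2, orientation_deg=orient,
        e_a=e_a, e_s=e_s, u_d=u_d, valid=valid, in_contact=mesh.in_contact,
    )


def accumulate_strain(
    sf: StrainField, method: str = "sum", intervals: slice | None = None
) -> dict[str, np.ndarray | float]:
    """Cumulative per-triangle strain totals over the rotation.

    method="sum" (default) sums per-interval invariant values; exact for
    small increments and matching the per-frame "rate" pictures.  The
    medians of |e_s| and |e_a| over in-contact triangles give the trial
    summaries |e_s,end| and |e_a,total|.
    """
    if method not in ("sum", "endpoints"):
        raise ValueError("method must be 'sum' or 'endpoints'")
    sel = intervals if intervals is not None else slice(None)
    if method == "sum":
        es_vals = np.where(sf.valid[:, sel], sf.e_s[:, sel], 0.0)
        ea_vals = np.where(sf.valid[:, sel], sf.e_a[:, sel], 0.0)
        any_valid = sf.valid[:, sel].any(axis=1)
        e_s_cum = es_vals.sum(axis=1)
        e_a_cum = ea_vals.sum(axis=1)
        e_s_cum[~any_valid] = np.nan
        e_a_cum[~any_valid] = np.nan
    else:
        raise ValueError(
            "endpoints accumulation needs mesh access; use endpoint_strain()"
        )
    mask = np.isfinite(e_s_cum)
    if sf.in_contact is not None:
        mask = mask & sf.in_contact[:, -1]
    es_end = float(np.median(np.abs(e_s_cum[mask]))) if mask.any() else float("nan")
    ea_total = float(np.median(np.abs(e_a_cum[mask]))) if mask.any() else float("nan")
    return {
        "e_s_cum": e_s_cum,
        "e_a_cum": e_a_cum,
        "median_es_end": es_end,
        "median_ea_total": ea_total,
    }


def endpoint_strain(mesh: TriangleMesh) -> dict[str, np.ndarray]:
    """Alternative 'total' strain: last frame compared directly with the first.

    Agrees with interval summation only for small increments; offered for
    cross-checking the default accumulation.
    """
    exx, eyy, exy, valid = green_lagrange(mesh, 0, mesh.n_frames - 1)
    e1, e2, _ = principal_strains(exx, eyy, exy)
    e_a, e_s = mohr_invariants(e1, e2)
    return {"e_s_cum": e_s, "e_a_cum": e_a, "valid": valid}


def energy_series(
    mesh: TriangleMesh,
    time_s: np.ndarray,
    elastic: ElasticParams = ElasticParams(),
    sf: StrainField | None = None,
) -> dict[str, np.ndarray]:
    """Cumulative strain energy U(t) and its rate dU/dt over the trial.

    The stored-energy state at frame k is evaluated from the summed
    incremental strain tensors up to k (small-increment accumulation); U is
    then p * sum(u_d * A) over in-contact triangles at that frame.  The
    rate is the discrete derivative over frame times, reported at interval
    midpoints so its rectangle integral reproduces U exactly.
    """
    if sf is None:
        sf = compute_strain_field(mesh, elastic)
    t = np.asarray(time_s, dtype=float)
    n_frames = mesh.n_frames
    exx_c = np.cumsum(np.where(sf.valid, sf.exx, 0.0), axis=1)
    eyy_c = np.cumsum(np.where(sf.valid, sf.eyy, 0.0), axis=1)
    exy_c = np.cumsum(np.where(sf.valid, sf.exy, 0.0), axis=1)
    U = np.zeros(n_frames)
    for k in range(1, n_frames):
        u_d = strain_energy_density(
            exx_c[:, k - 1], eyy_c[:, k - 1], exy_c[:, k - 1], elastic
        )
        include = None
        if mesh.in_contact is not None:
            include = mesh.in_contact[:, k]
        U[k] = total_energy(u_d, mesh.areas(k), elastic.p_depth, include)
    dt = np.diff(t)
    rate = np.diff(U) / dt
    t_mid = 0.5 * (t[:-1] + t[1:])
    return {"time_s": t, "U": U, "rate_time_s": t_mid, "dU_dt": rate}


def integrate_rate(rate: np.ndarray, time_s: np.ndarray) -> float:
    """Integrate a midpoint rate series back over the frame grid (exact inverse)."""
    return float(np.sum(np.asarray(rate) * np.diff(np.asarray(time_s))))
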