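"""Contact-area size, orientation, and the peeling/deformation accounting.

The apparent contact area is a per-frame binary mask; its size is the pixel
count converted at the image scale (85 px/mm reference), its tilt the angle
between the image y-axis and the major axis of the moment-equivalent
ellipse.  During rotation the contact shrinks through two mechanisms that
are separated on the triangle mesh: *peeling* (triangles leaving contact at
the periphery -- all three vertices must sit inside the mask to count as in
contact) and *surface deformation* (in-contact triangles changing area).
A residual closes the accounting exactly, since boundary triangles straddle
the mask edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import binary_closing, disk

from .strain import TriangleMesh

__all__ = [
    "ContactSeries",
    "segment_contact",
    "contact_area",
    "contact_tilt",
    "tilt_change",
    "triangles_in_contact",
    "peeling_laying",
    "deformation_area_change",
    "compute_contact_series",
    "area_reduction_decomposition",
]


@dataclass
class ContactSeries:
    """Per-frame contact accounting for one trial.

    ``peeled``/``laid``/``deformation``/``residual`` are per frame interval
    (length n_frames-1); the accounting identity

        laid - peeled + deformation + residual == diff(area_mm2)

    holds exactly by construction of the residual.
    """

    area_mm2: np.ndarray
    tilt_deg: np.ndarray
    peeled_mm2: np.ndarray
    laid_mm2: np.ndarray
    deformation_mm2: np.ndarray
    residual_mm2: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.area_mm2)

    def to_table(self) -> pd.DataFrame:
        n = self.n_frames
        pad = lambda x: np.concatenate([[np.nan], x])  # noqa: E731
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "area_mm2": self.area_mm2,
                "tilt_deg": self.tilt_deg,
                "peeled_mm2": pad(self.peeled_mm2),
                "laid_mm2": pad(self.laid_mm2),
                "deformation_mm2": pad(self.deformation_mm2),
                "residual_mm2": pad(self.residual_mm2),
            }
        )


def segment_contact(
    frame: np.ndarray,
    threshold: float | None = None,
    close_px: int = 0,
) -> tuple[np.ndarray, bool]:
    """Threshold-segment the contact region of a grayscale frame.

    Global threshold (Otsu when not given), optional morphological closing
    (for dotted renders), largest connected component, holes filled.
    Returns (mask, ok); ok is False when the frame segments to nothing.
    """
    img = np.asarray(frame)
    if img.ndim != 2:
        raise ValueError("expected a single grayscale frame")
    if threshold is None:
        if img.min() == img.max():
            return np.zeros(img.shape, dtype=bool), False
        threshold = threshold_otsu(img)
    mask = img > threshold
    if not mask.any():
        return mask, False
    if close_px > 0:
        mask = binary_closing(mask, disk(close_px))
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask), True


def contact_area(mask: np.ndarray, px_per_mm: float = 85.0) -> float:
    """Contact area in mm^2: pixel count over the squared image scale."""
    if not px_per_mm > 0:
        raise ValueError("px_per_mm must be positive")
    return float(np.count_nonzero(mask) / px_per_mm**2)


def contact_tilt(mask: np.ndarray, circular_tol: float = 0.99) -> float:
    """Tilt of the contact: angle (deg) between image y-axis and the major axis.

    Estimated from the second central moments of the mask (equivalent to an
    ellipse fit for filled regions), positive tipping towards +x, range
    (-90, 90].  NaN (flagged) for an empty or near-circular mask (axis
    ratio above ``circular_tol``), where the major axis is undefined.
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        warnings.warn("empty mask; tilt undefined", stacklevel=2)
        return float("nan")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mxx = float(np.mean(x * x))
    myy = float(np.mean(y * y))
    mxy = float(np.mean(x * y))
    half_diff = np.hypot(0.5 * (mxx - myy), mxy)
    lam1 = 0.5 * (mxx + myy) + half_diff
    lam2 = 0.5 * (mxx + myy) - half_diff
    if lam1 <= 0 or np.sqrt(max(lam2, 0.0) / lam1) > circular_tol:
        warnings.warn("mask is (near-)circular; tilt undefined", stacklevel=2)
        return float("nan")
    theta_x = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))  # from x-axis
    tilt = 90.0 - theta_x
    if tilt > 90.0:
        tilt -= 180.0
    return float(tilt)


def tilt_change(initial_mask: np.ndarray, full_slip_mask: np.ndarray) -> float:
    """Contact re-orientation: tilt at full slip minus tilt at initial contact."""
    t0 = contact_tilt(initial_mask)
    t1 = contact_tilt(full_slip_mask)
    d = t1 - t0
    if d > 90.0:
        d -= 180.0
    elif d <= -90.0:
        d += 180.0
    return float(d)


def triangles_in_contact(mesh: TriangleMesh, masks: np.ndarray) -> np.ndarray:
    """(n_tri, n_frames) flag: all three vertex pixels inside the frame's mask.

    Vertex coordinates are continuous pixels; 'inside' means the
    nearest-pixel sample of the mask is true.
    """
    masks = np.asarray(masks)
    if masks.shape[0] != mesh.n_frames:
        raise ValueError("mask stack does not match the mesh frame count")
    h, w = masks.shape[1:]
    out = np.empty((mesh.n_triangles, mesh.n_frames), dtype=bool)
    for f in range(mesh.n_frames):
        v = mesh.vertex_coords(f)
        xi = np.rint(v[..., 0]).astype(int)
        yi = np.rint(v[..., 1]).astype(int)
        inb = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        val = np.zeros(v.shape[:2], dtype=bool)
        val[inb] = masks[f][yi[inb], xi[inb]]
        out[:, f] = val.all(axis=1)
    return out


def peeling_laying(
    mesh: TriangleMesh, in_contact: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval peeled and laid triangle areas (mm^2, both >= 0).

    A triangle passing from inside to outside the contact between frames f
    and f+1 contributes its frame-f area to peeling; outside to inside
    contributes its frame-(f+1) area to laying.
    """
    ic = in_contact if in_contact is not None else mesh.in_contact
    if ic is None:
        raise ValueError("in_contact flags are required (see triangles_in_contact)")
    n_int = mesh.n_frames - 1
    peeled = np.zeros(n_int)
    laid = np.zeros(n_int)
    for j in range(n_int):
        leaving = ic[:, j] & ~ic[:, j + 1]
        entering = ~ic[:, j] & ic[:, j + 1]
        peeled[j] = mesh.areas(j)[leaving].sum()
        laid[j] = mesh.areas(j + 1)[entering].sum()
    return peeled, laid


def deformation_area_change(
    mesh: TriangleMesh, in_contact: np.ndarray | None = None
) -> np.ndarray:
    """Per-interval area change (mm^2) of triangles in contact at both frames."""
    ic = in_contact if in_contact is not None else mesh.in_contact
    if ic is None:
        raise ValueError("in_contact flags are required (see triangles_in_contact)")
    n_int = mesh.n_frames - 1
    out = np.zeros(n_int)
    for j in range(n_int):
        both = ic[:, j] & ic[:, j + 1]
        out[j] = (mesh.areas(j + 1)[both] - mesh.areas(j)[both]).sum()
    return out


def compute_contact_series(
    mesh: TriangleMesh, masks: np.ndarray, px_per_mm: float = 85.0
) -> ContactSeries:
    """Contact areas, tilts and the full peeling/deformation accounting."""
    ic = mesh.in_contact
    if ic is None:
        ic = triangles_in_contact(mesh, masks)
        mesh.in_contact = ic
    areas = np.array([contact_area(m, px_per_mm) for m in masks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tilts = np.array([contact_tilt(m) for m in masks])
    peeled, laid = peeling_laying(mesh, ic)
    deform = deformation_area_change(mesh, ic)
    residual = np.diff(areas) - (laid - peeled + deform)
    return ContactSeries(
        area_mm2=areas,
        tilt_deg=tilts,
        peeled_mm2=peeled,
        laid_mm2=laid,
        deformation_mm2=deform,
        residual_mm2=residual,
    )


def area_reduction_decomposition(series: ContactSeries) -> dict[str, float]:
    """Split the initial-to-final contact-area change by mechanism.

    Returns absolute (mm^2) and relative (fractions of the initial area)
    contributions of net peeling (peeled - laid, sign flipped so it reduces
    the area), surface deformation, and the residual; they sum to the total
    change exactly.
    """
    a0 = series.area_mm2[0]
    if a0 <= 0:
        raise ValueError("initial contact area is zero")
    total = float(series.area_mm2[-1] - a0)
    peel_net = float((series.laid_mm2 - series.peeled_mm2).sum())
    deform = float(series.deformation_mm2.sum())
    residual = float(series.residual_mm2.sum())
    return {
        "total_change_mm2": total,
        "peeling_mm2": peel_net,
        "deformation_mm2": deform,
        "residual_mm2": residual,
        "total_change_rel": total / a0,
        "peeling_rel": peel_net / a0,
        "deformation_rel": deform / a0,
        "residual_rel": residual / a0,
    }
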