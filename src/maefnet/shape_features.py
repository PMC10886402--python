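"""Shape morphometrics of a binary pectoral-muscle mask.

Fifteen descriptors are computed from the largest 8-connected foreground
component: square roots of region and convex-hull pixel counts, boundary
pixel count, moment-ellipse axis lengths, axis-aligned bounding box height
and width and derived rectangle area / aspect, minimum-enclosing-circle
diameter, equivalent diameter, Heywood circularity factor, curvature
(region-to-circumscribed-circle area ratio) and complexity (perimeter
squared over area).  All are translation invariant; the dimensionless ones
(El, As, Hcf, Cu, Cl) are also scale invariant up to discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure

#: canonical feature order
FEATURE_NAMES = ("Ar", "Co", "P", "Mal", "Mil", "H", "W", "Ra", "El", "D",
                 "Ed", "Hcf", "As", "Cu", "Cl")


@dataclass(frozen=True)
class RegionGeometry:
    A: float       # foreground pixel count
    Ca: float      # convex-hull pixel count
    P: float       # boundary pixel count
    Mal: float     # moment-ellipse major axis length (px)
    Mil: float     # moment-ellipse minor axis length (px)
    H: float       # bounding-box height (rows, px)
    W: float       # bounding-box width (cols, px)
    D: float       # minimum enclosing circle diameter (px)
    centroid: tuple[float, float]  # (x, y)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _boundary_pixel_count(component: np.ndarray) -> int:
    # foreground pixels with >=1 background 4-neighbour; the image border
    # counts as background (erosion border_value=0)
    eroded = ndimage.binary_erosion(component, structure=_CROSS,
                                    border_value=0)
    return int((component & ~eroded).sum())


def _contour_length(component: np.ndarray) -> float:
    # crofton perimeter, the standard digital contour-length estimator
    return float(measure.perimeter_crofton(component, directions=4))


def extract_geometry(mask: np.ndarray,
                     diameter_mode: str = "min_enclosing_circle",
                     perimeter_mode: str = "contour_length") -> RegionGeometry:
    """Geometric primitives of the largest 8-connected component.

    diameter_mode: "min_enclosing_circle" (circle circumscribing the region)
    or "centroid_farthest" (2x the centroid-to-farthest-boundary distance).
    perimeter_mode: "contour_length" (Crofton estimate of the contour arc
    length; unbiased for smooth shapes, so the Heywood factor of a digital
    disk is ~1) or "boundary_pixels" (raw count of foreground pixels with a
    4-neighbour in the background, which underestimates a circle's perimeter
    by ~11%).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    binary = mask > 0
    if not binary.any():
        raise ValueError("no foreground region")
    labels = measure.label(binary, connectivity=2)
    props = max(measure.regionprops(labels), key=lambda p: p.area)
    component = labels == props.label

    a = float(props.area)
    ca = float(props.area_convex)
    if perimeter_mode == "boundary_pixels":
        p = float(_boundary_pixel_count(component))
    elif perimeter_mode == "contour_length":
        p = _contour_length(component)
    else:
        raise ValueError(f"unknown perimeter_mode {perimeter_mode!r}")

    mal = float(props.axis_major_length)
    mil = float(props.axis_minor_length)
    r0, c0, r1, c1 = props.bbox
    h, w = float(r1 - r0), float(c1 - c0)

    boundary = component & ~ndimage.binary_erosion(component, _CROSS,
                                                   border_value=0)
    rows, cols = np.nonzero(boundary)
    pts = np.column_stack([cols + 0.5, rows + 0.5])  # pixel centers (x, y)
    cy, cx = props.centroid
    if diameter_mode == "min_enclosing_circle":
        d = 2.0 * float(shapely.minimum_bounding_radius(
            shapely.MultiPoint(pts)))
    elif diameter_mode == "centroid_farthest":
        dist = np.hypot(pts[:, 0] - (cx + 0.5), pts[:, 1] - (cy + 0.5))
        d = 2.0 * float(dist.max())
    else:
        raise ValueError(f"unknown diameter_mode {diameter_mode!r}")

    return RegionGeometry(A=a, Ca=ca, P=p, Mal=mal, Mil=mil, H=h, W=w, D=d,
                          centroid=(cx + 0.5, cy + 0.5))


def compute_features(geom: RegionGeometry) -> dict[str, float]:
    """The 15 named shape descriptors of a region, in canonical order."""
    if geom.Mil <= 0 or geom.W <= 0:
        raise ValueError("degenerate region (zero minor axis or width)")
    a, ca, p = geom.A, geom.Ca, geom.P
    feats = {
        "Ar": np.sqrt(a),
        "Co": np.sqrt(ca),
        "P": p,
        "Mal": geom.Mal,
        "Mil": geom.Mil,
        "H": geom.H,
        "W": geom.W,
        "Ra": np.sqrt(geom.H * geom.W),
        "El": geom.Mal / geom.Mil,
        "D": geom.D,
        "Ed": 2.0 * np.sqrt(a / np.pi),
        "Hcf": p / (2.0 * np.sqrt(np.pi * a)),
        "As": geom.H / geom.W,
        "Cu": 4.0 * a / (np.pi * geom.D ** 2),
        "Cl": p ** 2 / a,
    }
    return {k: float(feats[k]) for k in FEATURE_NAMES}


def extract_features(mask: np.ndarray, **geometry_kwargs) -> dict[str, float]:
    """Mask -> 15-feature vector (largest component, canonical order)."""
    return compute_features(extract_geometry(mask, **geometry_kwargs))


def features_table(masks: dict[str, np.ndarray], **geometry_kwargs):
    """Feature rows for a set of masks keyed by sample_id (a DataFrame with
    sample_id plus the 15 feature columns)."""
    import pandas as pd

    rows = []
    for sample_id, mask in masks.items():
        row = {"sample_id": sample_id}
        row.update(extract_features(mask, **geometry_kwargs))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *FEATURE_NAMES])
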