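"""Image, mask and polygon-annotation IO plus preprocessing/augmentation.

Conventions: coordinates are 0-based with origin at the top-left corner,
x rightward, y downward, in (x, y) order as LabelMe emits them.  Pixel (r, c)
covers the unit square [c, c+1) x [r, r+1); its center is (c + 0.5, r + 0.5).
Masks are {0, 1} uint8 in memory and 0/255 8-bit PNG on disk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
from scipy import ndimage
from skimage import transform as sktransform


@dataclass(frozen=True)
class PolygonAnnotation:
    label: str
    points: tuple[tuple[float, float], ...]  # (x, y) vertices, >= 3

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError(
                f"polygon {self.label!r} has {len(self.points)} points; "
                "need at least 3")
        poly = shapely.Polygon(self.points)
        if not poly.is_valid:
            raise ValueError(f"polygon {self.label!r} is self-intersecting")


def read_labelme(path) -> tuple[list[PolygonAnnotation], tuple[int, int]]:
    """Parse a LabelMe-dialect JSON file.

    Returns the polygon annotations and the (height, width) of the annotated
    image.  Missing required keys raise a parse error naming the key.
    """
    data = json.loads(Path(path).read_text())
    for key in ("shapes", "imageHeight", "imageWidth"):
        if key not in data:
            raise ValueError(f"annotation file {path} is missing key {key!r}")
    polys = []
    for shape in data["shapes"]:
        if "points" not in shape:
            raise ValueError(f"shape in {path} is missing key 'points'")
        points = tuple((float(x), float(y)) for x, y in shape["points"])
        polys.append(PolygonAnnotation(label=shape.get("label", ""),
                                       points=points))
    return polys, (int(data["imageHeight"]), int(data["imageWidth"]))


def polygons_to_mask(polys: list[PolygonAnnotation], height: int,
                     width: int) -> np.ndarray:
    """Rasterize polygons to a {0,1} mask by the pixel-center rule.

    Pixel (r, c) is foreground iff its center (c + 0.5, r + 0.5) lies inside
    or on the boundary of any polygon; overlapping polygons union.
    """
    if height <= 0 or width <= 0:
        raise ValueError("mask dimensions must be positive")
    mask = np.zeros((height, width), dtype=np.uint8)
    if not polys:
        return mask
    cx, cy = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
    xs, ys = cx.ravel(), cy.ravel()
    for ann in polys:
        poly = shapely.Polygon(ann.points)
        minx, miny, maxx, maxy = poly.bounds
        if maxx < 0 or maxy < 0 or minx > width or miny > height:
            warnings.warn(f"polygon {ann.label!r} lies entirely outside the "
                          f"{height}x{width} frame and contributes nothing")
            continue
        # intersects == inside-or-on-boundary for point vs polygon
        inside = shapely.intersects_xy(poly, xs, ys).reshape(height, width)
        mask |= inside.astype(np.uint8)
    return mask


@dataclass(frozen=True)
class PreprocessSpec:
    crop_box: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1)
    output_side: int = 512
    is_mask: bool = False  # masks use nearest-neighbour interpolation

    def __post_init__(self):
        if self.output_side <= 0:
            raise ValueError("output_side must be positive")


def preprocess(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Crop (optional) then scale to output_side x output_side.

    Images are resampled bilinearly; masks through nearest neighbour so the
    output stays binary.
    """
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    if spec.crop_box is not None:
        x0, y0, x1, y1 = spec.crop_box
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"crop_box {spec.crop_box} outside the "
                             f"{h}x{w} image")
        image = image[y0:y1, x0:x1]
    side = spec.output_side
    if image.shape[0] == side and image.shape[1] == side:
        return image.copy()
    if spec.is_mask:
        out = sktransform.resize(image.astype(np.float32), (side, side),
                                 order=0, anti_aliasing=False,
                                 preserve_range=True)
        return (out > 0.5).astype(image.dtype)
    out = sktransform.resize(image.astype(np.float32), (side, side),
                             order=1, anti_aliasing=image.shape[0] > side,
                             preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255)
    return out.astype(image.dtype)


@dataclass(frozen=True)
class AugmentationSpec:
    """Paired image/mask augmentation: the same spatial transform is applied
    to both; masks stay binary (nearest-neighbour + defensive re-binarize)."""
    rotation_p: float = 0.5
    vertical_flip_p: float = 0.5
    horizontal_flip_p: float = 0.5
    perspective_p: float = 0.5
    elastic_p: float = 0.5
    rotation_limit: float = 30.0        # degrees
    perspective_scale: float = 0.05     # corner jitter, fraction of side
    elastic_alpha: float = 20.0         # displacement magnitude, pixels
    elastic_sigma: float = 6.0          # displacement smoothness, pixels
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_p", "vertical_flip_p", "horizontal_flip_p",
                     "perspective_p", "elastic_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _warp_pair(image, mask, tform):
    img = sktransform.warp(image.astype(np.float32), tform, order=1,
                           preserve_range=True)
    msk = sktransform.warp(mask.astype(np.float32), tform, order=0,
                           preserve_range=True)
    return img, (msk > 0.5).astype(mask.dtype)


def augment(image: np.ndarray, mask: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured stochastic transforms to an (image, mask) pair."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dtype = image.dtype
    img = image.astype(np.float32)
    msk = mask.copy()

    if rng.uniform() < spec.rotation_p:
        angle = rng.uniform(-spec.rotation_limit, spec.rotation_limit)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk.astype(np.float32), angle, reshape=False,
                             order=0, mode="constant")
        msk = (msk > 0.5).astype(mask.dtype)
    if rng.uniform() < spec.vertical_flip_p:
        img, msk = img[::-1].copy(), msk[::-1].copy()
    if rng.uniform() < spec.horizontal_flip_p:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if rng.uniform() < spec.perspective_p:
        h, w = img.shape
        jitter = spec.perspective_scale * min(h, w)
        src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=np.float64)
        dst = src + rng.uniform(-jitter, jitter, size=(4, 2))
        tform = sktransform.ProjectiveTransform()
        tform.estimate(dst, src)
        img, msk = _warp_pair(img, msk, tform)
    if rng.uniform() < spec.elastic_p:
        h, w = img.shape
        disp = rng.normal(0, 1, size=(2, h, w))
        for k in range(2):
            disp[k] = ndimage.gaussian_filter(disp[k], spec.elastic_sigma)
            disp[k] *= spec.elastic_alpha / max(np.abs(disp[k]).max(), 1e-8)
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = np.array([rr + disp[0], cc + disp[1]])
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        msk = ndimage.map_coordinates(msk.astype(np.float32), coords, order=0,
                                      mode="constant")
        msk = (msk > 0.5).astype(mask.dtype)

    if np.issubdtype(dtype, np.integer):
        img = np.clip(np.rint(img), 0, 255)
    return img.astype(dtype), msk


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF image as a 2-D uint8 array."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask PNG as a {0,1} uint8 array."""
    return (read_image(path) > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
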