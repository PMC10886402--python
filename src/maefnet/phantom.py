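"""Synthetic radiograph phantoms with known masks and weight model.

The study's radiographs and dissection weights are private, so every
downstream stage (segmentation, morphometrics, regression) is exercised on
phantoms: a bright body silhouette (large ellipse) on a dark background, a
brighter smooth muscle blob (ellipse with low-frequency radial perturbation)
whose exact pixel set is the ground-truth mask, plus Gaussian sensor noise.
Breast-muscle weight follows a known affine generative model

    bm_weight = beta0 + beta1 * live_weight + beta2 * A_true + eps,

with A_true the mask's foreground pixel count and eps ~ N(0, sigma_w).
Muscle area is positively correlated with live weight so that feature
selection faces correlated candidates, as it would on real birds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

#: reference image side for which the default weight coefficients are stated
REFERENCE_SIDE = 512


@dataclass(frozen=True)
class PhantomConfig:
    image_side: int = 512
    n_samples: int = 100
    muscle_area_range: tuple[float, float] = (0.05, 0.15)
    body_intensity: float = 140.0
    muscle_intensity_delta: float = 45.0
    background_intensity: float = 20.0
    noise_sigma: float = 8.0
    # (beta0 grams, beta1 per gram live weight, beta2 grams per pixel)
    weight_coeffs: tuple[float, float, float] = (50.0, 0.15, 0.008)
    weight_noise_sigma: float = 15.0
    live_weight_range: tuple[float, float] = (1500.0, 3500.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.muscle_area_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("muscle_area_range must satisfy 0 < min < max < 1")
        if self.noise_sigma < 0 or self.weight_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.image_side % 16:
            raise ValueError("image_side must be divisible by 16 "
                             "(segmentation output stride)")
        lw_lo, lw_hi = self.live_weight_range
        if not (0 < lw_lo < lw_hi):
            raise ValueError("live_weight_range must be increasing, positive")

    @classmethod
    def for_side(cls, side: int, **overrides) -> "PhantomConfig":
        """Config at a smaller canvas with the area coefficient rescaled so
        the generative weight model is scale-invariant in physical terms
        (one phantom pixel at side s covers (REFERENCE_SIDE/s)^2 reference
        pixels)."""
        b0, b1, b2 = overrides.pop("weight_coeffs", cls.weight_coeffs)
        scale = (REFERENCE_SIDE / side) ** 2
        return cls(image_side=side, weight_coeffs=(b0, b1, b2 * scale),
                   **overrides)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("muscle_area_range", "weight_coeffs", "live_weight_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PhantomSample:
    image: np.ndarray          # uint8, side x side
    mask: np.ndarray           # uint8 {0,1}, side x side
    live_weight: float         # grams
    breast_muscle_weight: float  # grams
    sample_id: str


def _body_ellipse(side: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean silhouette of the bird body: a large, slightly jittered
    ellipse centred on the frame."""
    cy = side * (0.5 + rng.uniform(-0.02, 0.02))
    cx = side * (0.5 + rng.uniform(-0.02, 0.02))
    ay = side * rng.uniform(0.42, 0.46)
    ax = side * rng.uniform(0.36, 0.42)
    yy, xx = np.mgrid[0:side, 0:side]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _muscle_mask(side: int, target_area: float, area_bounds: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Rasterize a perturbed-ellipse blob with ~target_area foreground pixels.

    The boundary is r(theta) = ellipse_radius(theta) * (1 + sum_h a_h
    cos(h theta + phi_h)) with 3-5 harmonics of total amplitude <= 15% of the
    radius; the radial form keeps the region star-convex, hence a single
    connected component.
    """
    aspect = rng.uniform(1.1, 1.6)
    psi = rng.uniform(-0.4, 0.4)          # orientation jitter
    n_harm = int(rng.integers(3, 6))
    amps = rng.uniform(0.02, 0.15 / n_harm, size=n_harm)
    orders = rng.choice(np.arange(2, 7), size=n_harm, replace=False)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)

    # semi-axes from the target area; perturbation inflates area by
    # ~ (1 + sum a^2 / 2)
    ab = target_area / (np.pi * (1 + 0.5 * float(np.sum(amps ** 2))))
    a = np.sqrt(ab * aspect)
    b = np.sqrt(ab / aspect)
    r_max = max(a, b) * 1.15
    margin = r_max + 2
    lo = margin
    hi = side - margin
    if hi <= lo:
        raise ValueError("muscle blob does not fit the image at this size")
    # breast region: upper-central part of the body
    cy = np.clip(side * (0.42 + rng.uniform(-0.06, 0.06)), lo, hi)
    cx = np.clip(side * (0.5 + rng.uniform(-0.08, 0.08)), lo, hi)

    yy, xx = np.mgrid[0:side, 0:side]
    dy = (yy - cy).astype(np.float64)
    dx = (xx - cx).astype(np.float64)
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    tr = theta - psi
    base = (a * b) / np.sqrt((b * np.cos(tr)) ** 2 + (a * np.sin(tr)) ** 2)
    pert = np.ones_like(theta)
    for order, amp, phase in zip(orders, amps, phases):
        pert += amp * np.cos(order * theta + phase)
    radius = base * pert

    lo_px = area_bounds[0] * side * side
    hi_px = area_bounds[1] * side * side
    scale = 1.0
    for _ in range(12):
        mask = rho <= radius * scale
        count = int(mask.sum())
        if lo_px <= count <= hi_px:
            break
        goal = np.clip(target_area, lo_px + 1, hi_px - 1)
        scale *= np.sqrt(goal / max(count, 1))
    else:
        raise RuntimeError("could not fit muscle area into the configured range")
    return mask.astype(np.uint8)


def generate_phantom(config: PhantomConfig, index: int) -> PhantomSample:
    """Deterministically generate the ``index``-th phantom of a dataset."""
    if not 0 <= index < config.n_samples:
        raise IndexError(f"index {index} out of range [0, {config.n_samples})")
    rng = np.random.default_rng([config.seed, index])
    side = config.image_side

    lw_lo, lw_hi = config.live_weight_range
    live_weight = float(rng.uniform(lw_lo, lw_hi))
    z = (live_weight - lw_lo) / (lw_hi - lw_lo)
    a_lo, a_hi = config.muscle_area_range
    # area fraction tracks live weight with some independent scatter
    frac = a_lo + (a_hi - a_lo) * float(
        np.clip(0.65 * z + 0.35 * rng.uniform(), 0.0, 1.0))
    target_area = frac * side * side

    body = _body_ellipse(side, rng)
    mask = _muscle_mask(side, target_area, config.muscle_area_range, rng)

    img = np.full((side, side), config.background_intensity, dtype=np.float64)
    img[body] = config.body_intensity
    img[mask.astype(bool)] += config.muscle_intensity_delta
    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    b0, b1, b2 = config.weight_coeffs
    a_true = float(mask.sum())
    bm = b0 + b1 * live_weight + b2 * a_true
    if config.weight_noise_sigma > 0:
        bm += float(rng.normal(0.0, config.weight_noise_sigma))
    if bm <= 0:
        raise ValueError("generative coefficients produced a non-positive "
                         "breast-muscle weight")
    return PhantomSample(image=image, mask=mask, live_weight=live_weight,
                         breast_muscle_weight=float(bm),
                         sample_id=f"phantom_{index:04d}")


def split_indices(n_samples: int, seed: int) -> dict[str, np.ndarray]:
    """Seeded 7:2:1 train/val/test partition of sample indices."""
    rng = np.random.default_rng([seed, 0x5914])
    order = rng.permutation(n_samples)
    n_train = int(np.floor(0.7 * n_samples))
    n_val = int(np.floor(0.2 * n_samples))
    return {
        "train": np.sort(order[:n_train]),
        "val": np.sort(order[n_train:n_train + n_val]),
        "test": np.sort(order[n_train + n_val:]),
    }


@dataclass
class PhantomDataset:
    config: PhantomConfig
    samples: list[PhantomSample]
    manifest: pd.DataFrame  # sample_id, split, live_weight_g, breast_muscle_weight_g

    def subset(self, split: str) -> list[PhantomSample]:
        ids = set(self.manifest.loc[self.manifest["split"] == split,
                                    "sample_id"])
        return [s for s in self.samples if s.sample_id in ids]


def generate_dataset(config: PhantomConfig,
                     out_dir: str | Path | None = None) -> PhantomDataset:
    """Generate all samples, assign the 7:2:1 split, optionally write
    images/*.png, masks/*.png and manifest.csv under ``out_dir``."""
    if config.n_samples < 10:
        raise ValueError("need at least 10 samples for a 7:2:1 split")
    samples = [generate_phantom(config, i) for i in range(config.n_samples)]
    splits = split_indices(config.n_samples, config.seed)
    split_of = {}
    for name, idx in splits.items():
        for i in idx:
            split_of[int(i)] = name
    manifest = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "split": [split_of[i] for i in range(config.n_samples)],
        "live_weight_g": [s.live_weight for s in samples],
        "breast_muscle_weight_g": [s.breast_muscle_weight for s in samples],
    })
    dataset = PhantomDataset(config=config, samples=samples, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for s in samples:
            iio.imwrite(out / "images" / f"{s.sample_id}.png", s.image)
            iio.imwrite(out / "masks" / f"{s.sample_id}.png",
                        (s.mask * 255).astype(np.uint8))
        manifest.to_csv(out / "manifest.csv", index=False)
        config.to_yaml(out / "config.yaml")
    return dataset
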