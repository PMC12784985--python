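"""Virtual broiler cohort generator.

Produces daily bird-day records (live weight, back length/width, pixel
area) with the statistical structure the downstream stages assume, plus
rendered top-view images with exact ground-truth masks.

Generation model
----------------
* Weight trajectories follow the Richards curve with bird-level
  multiplicative perturbation of (A, k) and day-level multiplicative
  log-normal noise.
* Back length and width follow allometric power laws
  ``L = alpha_L * LW**beta_L * (1 + eps)`` (same for width), with
  default exponents 1/3 (linear dimension vs. mass).
* Pixel areas are obtained by inverting the group log-pixel relation
  ``logP = (logLW - b0 - b1*Day) / (b2 + b3*Day)`` per the bird's sex,
  then applying multiplicative noise. The denominator is checked to be
  positive for every day in range.
* One RNG stream per cohort, spawned into independent sub-streams per
  bird, so adding birds never reshuffles existing ones.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from broilerweight.growth_model import RichardsParams, richards_evaluate
from broilerweight.pixel_regression import REFERENCE_COEFFICIENTS

__all__ = [
    "CameraGeometry",
    "CohortConfig",
    "BirdRecord",
    "generate_cohort",
    "render_bird_image",
    "records_to_csv",
    "records_from_csv",
    "CSV_HEADER",
]

CSV_HEADER = [
    "bird_id",
    "sex",
    "day",
    "back_length_mm",
    "back_width_mm",
    "live_weight_g",
    "pixel_area",
]


@dataclass(frozen=True)
class CameraGeometry:
    """Fixed top-down acquisition geometry.

    The black reference floor (600 x 400 mm) maps to a centred rectangle
    of the image at a constant scale; ``mm_per_px`` is that scale
    (floor_width_mm / floor width in pixels), constant across a cohort
    because the camera height is fixed.
    """

    floor_width_mm: float = 600.0
    floor_height_mm: float = 400.0
    camera_height_m: float = 1.0
    mm_per_px: float = 1.0
    margin_px: int = 30

    @property
    def floor_width_px(self) -> int:
        return int(round(self.floor_width_mm / self.mm_per_px))

    @property
    def floor_height_px(self) -> int:
        return int(round(self.floor_height_mm / self.mm_per_px))

    @property
    def image_width_px(self) -> int:
        return self.floor_width_px + 2 * self.margin_px

    @property
    def image_height_px(self) -> int:
        return self.floor_height_px + 2 * self.margin_px


def _default_sex_params() -> dict[str, RichardsParams]:
    # asymptotes chosen so day-1 weights sit near 30 g and day-42 near
    # the top of the observed range; B, k, m are generator conventions
    return {
        "male": RichardsParams(A=6000.87, B=200.0, k=0.1327, m=1.0),
        "female": RichardsParams(A=4788.52, B=200.0, k=0.1327, m=1.0),
    }


def _default_logpixel_params() -> dict[str, tuple[float, float, float, float]]:
    return {
        "male": REFERENCE_COEFFICIENTS["male"],
        "female": REFERENCE_COEFFICIENTS["female"],
    }


@dataclass
class CohortConfig:
    n_birds: int = 100
    sex_ratio: float = 0.5
    n_days: int = 42
    replicate_images: int = 5
    noise_cv_weight: float = 0.03
    morphometric_noise_cv: float = 0.02
    pixel_noise_cv: float = 0.02
    bird_effect_cv: float = 0.04
    seed: int = 0
    log_base: float = 10.0
    alpha_length: float = 14.3
    beta_length: float = 1.0 / 3.0
    alpha_width: float = 10.4
    beta_width: float = 1.0 / 3.0
    sex_params: dict[str, RichardsParams] = field(default_factory=_default_sex_params)
    logpixel_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_logpixel_params
    )
    camera: CameraGeometry = field(default_factory=CameraGeometry)

    def validate(self) -> None:
        if self.n_birds < 1 or self.n_days < 1:
            raise ValueError("n_birds and n_days must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for name in ("noise_cv_weight", "morphometric_noise_cv", "pixel_noise_cv", "bird_effect_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for sex in ("male", "female"):
            if sex in self.logpixel_params:
                b0, b1, b2, b3 = self.logpixel_params[sex]
                denom = b2 + b3 * np.arange(1, self.n_days + 1)
                if np.any(denom <= 0):
                    bad = int(np.argmax(denom <= 0)) + 1
                    raise ValueError(
                        f"log-pixel inversion denominator b2 + b3*Day is not "
                        f"positive for sex={sex!r} at day {bad}"
                    )
        missing = {"male", "female"} - set(self.sex_params)
        if missing:
            raise ValueError(f"sex_params missing entries for {sorted(missing)}")


@dataclass
class BirdRecord:
    """One bird-day observation."""

    bird_id: str
    sex: str
    day: int
    back_length: float  # mm
    back_width: float  # mm
    live_weight: float  # g
    pixel_area: Optional[float] = None  # mean foreground pixel count
    true_area_mm2: Optional[float] = None  # synthetic ground truth only

    def __post_init__(self) -> None:
        if self.live_weight <= 0:
            raise ValueError(f"live_weight must be positive ({self.bird_id} day {self.day})")
        if self.back_length <= 0 or self.back_width <= 0:
            raise ValueError(f"morphometrics must be positive ({self.bird_id} day {self.day})")
        if self.day < 1:
            raise ValueError("day index is 1-based")
        if self.pixel_area is not None and self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive when present")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(config: CohortConfig) -> list[BirdRecord]:
    """Generate ``n_birds * n_days`` bird-day records, deterministically.

    With all noise CVs at zero the emitted (Day, logP, logLW) triples
    satisfy the generating log-pixel equation exactly and weights equal
    the Richards curve of the bird's sex.
    """
    config.validate()
    # interleaved sex assignment: depends only on the bird index, so
    # growing the cohort never changes the sex of an existing bird
    sexes = [
        "male"
        if int(np.floor((i + 1) * config.sex_ratio)) > int(np.floor(i * config.sex_ratio))
        else "female"
        for i in range(config.n_birds)
    ]
    days = np.arange(1, config.n_days + 1, dtype=float)
    ln_base = np.log(config.log_base)

    children = np.random.SeedSequence(config.seed).spawn(config.n_birds)
    records: list[BirdRecord] = []
    for i, (sex, child) in enumerate(zip(sexes, children)):
        rng = np.random.default_rng(child)
        base = config.sex_params[sex]
        # bird-level random effect on asymptote and rate
        bird = replace(
            base,
            A=base.A * float(_lognormal_factor(rng, config.bird_effect_cv)),
            k=base.k * float(_lognormal_factor(rng, config.bird_effect_cv / 2)),
        )
        weights = np.asarray(richards_evaluate(bird, days))
        weights = weights * _lognormal_factor(rng, config.noise_cv_weight, size=days.size)

        length = (
            config.alpha_length
            * weights**config.beta_length
            * _lognormal_factor(rng, config.morphometric_noise_cv, size=days.size)
        )
        width = (
            config.alpha_width
            * weights**config.beta_width
            * _lognormal_factor(rng, config.morphometric_noise_cv, size=days.size)
        )

        b0, b1, b2, b3 = config.logpixel_params[sex]
        log_lw = np.log(weights) / ln_base
        log_p = (log_lw - b0 - b1 * days) / (b2 + b3 * days)
        pixel_area = config.log_base**log_p * _lognormal_factor(
            rng, config.pixel_noise_cv, size=days.size
        )
        true_area = np.pi / 4.0 * length * width  # projected ellipse, mm^2

        bird_id = f"bird{i:03d}"
        for j, day in enumerate(days.astype(int)):
            records.append(
                BirdRecord(
                    bird_id=bird_id,
                    sex=sex,
                    day=int(day),
                    back_length=float(length[j]),
                    back_width=float(width[j]),
                    live_weight=float(weights[j]),
                    pixel_area=float(pixel_area[j]),
                    true_area_mm2=float(true_area[j]),
                )
            )
    return records


def render_bird_image(
    record: BirdRecord,
    replicate_index: int,
    camera: CameraGeometry,
    seed: int = 0,
    jitter_frac: float = 0.05,
    noise_sd: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one top-view RGB image and its exact ground-truth mask.

    The bird is a light elliptical blob (axes = back length x width,
    mm -> px via the camera scale) on a near-black floor, with
    per-replicate axis jitter (up to ``jitter_frac``), random rotation,
    random sub-floor placement and additive pixel noise. Returns
    ``(image_uint8_rgb, mask_bool)``; the mask is the rasterized ellipse
    before noise, so ``mask.sum()`` is the exact foreground count.
    """
    entropy = [seed, replicate_index, record.day, zlib.crc32(record.bird_id.encode())]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))

    h, w = camera.image_height_px, camera.image_width_px
    m = camera.margin_px
    fh, fw = camera.floor_height_px, camera.floor_width_px

    a_px = record.back_length / camera.mm_per_px / 2.0  # semi-major
    b_px = record.back_width / camera.mm_per_px / 2.0  # semi-minor
    if jitter_frac > 0:
        a_px *= 1.0 + rng.uniform(-jitter_frac, jitter_frac)
        b_px *= 1.0 + rng.uniform(-jitter_frac, jitter_frac)
    theta = rng.uniform(0, np.pi) if jitter_frac > 0 else 0.0

    # bounding half-extent of the rotated ellipse along each image axis
    ext_x = np.hypot(a_px * np.cos(theta), b_px * np.sin(theta))
    ext_y = np.hypot(a_px * np.sin(theta), b_px * np.cos(theta))
    if 2 * ext_x >= fw or 2 * ext_y >= fh:
        raise ValueError(
            f"bird {record.bird_id} day {record.day}: ellipse "
            f"({2 * ext_x:.0f} x {2 * ext_y:.0f} px) exceeds floor ({fw} x {fh} px)"
        )
    slack_x = (fw - 2 * ext_x) / 2.0 - 1
    slack_y = (fh - 2 * ext_y) / 2.0 - 1
    cx = m + fw / 2.0 + (rng.uniform(-1, 1) * min(slack_x, 0.1 * fw) if jitter_frac > 0 else 0)
    cy = m + fh / 2.0 + (rng.uniform(-1, 1) * min(slack_y, 0.1 * fh) if jitter_frac > 0 else 0)

    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a_px
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b_px
    ellipse = u**2 + v**2 <= 1.0

    floor = np.zeros((h, w), dtype=bool)
    floor[m : m + fh, m : m + fw] = True
    mask = ellipse & floor

    img = np.full((h, w), 120.0)  # surround outside the reference floor
    img[floor] = 18.0
    img[mask] = 175.0
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return np.stack([img] * 3, axis=-1), mask


def records_to_csv(records: Sequence[BirdRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.bird_id,
                    r.sex,
                    r.day,
                    f"{r.back_length:.6g}",
                    f"{r.back_width:.6g}",
                    f"{r.live_weight:.6g}",
                    "" if r.pixel_area is None else f"{r.pixel_area:.6g}",
                ]
            )


def records_from_csv(path: str) -> list[BirdRecord]:
    records: list[BirdRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"missing CSV columns: {sorted(missing)}")
        for row in reader:
            pix = row["pixel_area"]
            records.append(
                BirdRecord(
                    bird_id=row["bird_id"],
                    sex=row["sex"],
                    day=int(row["day"]),
                    back_length=float(row["back_length_mm"]),
                    back_width=float(row["back_width_mm"]),
                    live_weight=float(row["live_weight_g"]),
                    pixel_area=float(pix) if pix not in ("", None) else None,
                )
            )
    return records
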