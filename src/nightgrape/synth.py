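"""Seeded synthetic night-scene generator with ground truth.

Emulates the red-channel statistics of green grape clusters photographed
at night under warm-white LED light: berry pixels concentrated in a high
R band (160-215), foliage and ground well below 150, and a thin bright
near-vertical stem rising from the top of the cluster.  Every scene is
deterministic for a fixed seed and comes with its ground truth (fruit
mask, stem segment, parameters), so every pipeline stage can be tested
without field images.

What it does NOT model: specular highlight spots, motion blur, berry-level
shading, and real foliage texture — results on these scenes bound the
geometry and arithmetic of the pipeline, not its field performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .levelset import BinaryMask
from .picking import LineSegment
from .preprocessing import InvalidInputError, RgbImage


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters of one synthetic night scene.

    Intensity units are 8-bit R-channel values.  ``illumination`` scales
    fruit/stem/leaf brightness globally (off-center clusters away from the
    light source are dimmer); ``vignette_strength`` adds the depth effect:
    a global plus radial light falloff that emulates increasing
    camera-to-fruit distance (0 = the reference depth).
    """

    seed: int = 0
    image_size: tuple[int, int] = (300, 450)  # (width, height)
    berry_count: int = 40
    berry_radius_range: tuple[float, float] = (6.0, 14.0)
    cluster_center: tuple[float, float] = (150.0, 250.0)
    cluster_spread: float = 50.0
    berry_R_range: tuple[float, float] = (160.0, 215.0)
    background_R_mean: float = 60.0
    background_R_sd: float = 15.0
    leaf_R_mean: float = 110.0
    leaf_R_sd: float = 15.0
    leaf_blob_count: int = 6
    stem_length_range: tuple[float, float] = (30.0, 60.0)
    stem_width_range: tuple[int, int] = (2, 4)
    stem_angle_deg: float = 0.0
    stem_R: float = 175.0
    noise_sd: float = 4.0
    vignette_strength: float = 0.0
    illumination: float = 1.0
    fruit_present: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.berry_R_range
        if not (150.0 <= lo <= hi <= 250.0):
            raise InvalidInputError("berry_R_range must lie within [150, 250]")
        if self.background_R_mean >= 150.0 or self.leaf_R_mean >= 150.0:
            raise InvalidInputError("background and leaf means must stay below 150")
        w, h = self.image_size
        cx, cy = self.cluster_center
        if self.fruit_present and not (0 <= cx < w and 0 <= cy < h):
            raise InvalidInputError("cluster_center must lie inside the frame")


@dataclass
class SceneTruth:
    """Ground truth accompanying a rendered scene."""

    fruit_mask: BinaryMask
    stem: LineSegment | None
    params: SceneParams
    present: bool = True

    def to_dict(self) -> dict:
        return {
            "present": self.present,
            "stem": self.stem.to_dict() if self.stem else None,
            "fruit_pixels": self.fruit_mask.count,
            "seed": self.params.seed,
        }


def _smooth_noise(rng: np.random.Generator, shape, sd: float, sigma: float = 6.0):
    """Zero-mean smooth random field with the requested pointwise sd."""
    raw = rng.normal(0.0, 1.0, shape)
    sm = ndimage.gaussian_filter(raw, sigma)
    s = sm.std()
    return sm / s * sd if s > 0 else sm


def generate_scene(params: SceneParams | None = None) -> tuple[RgbImage, SceneTruth]:
    """Render one scene and its ground truth, deterministically per seed."""
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    w, h = params.image_size
    shape = (h, w)

    # background: smooth mottled ground/sky well below the bright band
    R = params.background_R_mean + _smooth_noise(
        rng, shape, params.background_R_sd
    )

    # foliage: random rotated ellipses at leaf brightness, shaded darker
    # toward the rim (a flat blob would cross a brightness threshold as one
    # block, which real leaves do not)
    for _ in range(params.leaf_blob_count):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(15, 40)
        rx = rng.uniform(15, 40)
        rot = rng.uniform(-np.pi / 2, np.pi / 2)
        val = rng.normal(params.leaf_R_mean, params.leaf_R_sd)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape, rotation=rot)
        if rr.size == 0:
            continue
        t2 = ((rr - cy) ** 2 + (cc - cx) ** 2) / max(ry, rx) ** 2
        R[rr, cc] = val * (1.0 - 0.35 * np.clip(t2, 0, 1)) * params.illumination

    fruit_mask = np.zeros(shape, dtype=bool)
    stem = None
    if params.fruit_present and params.berry_count > 0:
        for bx, by, r, val in _berry_layout(params, rng):
            rot = rng.uniform(-0.3, 0.3)
            # elongated-oval berry, long axis roughly vertical
            rr, cc = draw_ellipse(by, bx, 1.3 * r, r, shape=shape, rotation=rot)
            if rr.size == 0:
                continue
            R[rr, cc] = val * params.illumination
            fruit_mask[rr, cc] = True

        if fruit_mask.any():
            stem, R = _draw_stem(params, rng, fruit_mask, R)

    # depth effect: global + radial illumination falloff
    if params.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        d2 = ((xx - w / 2) ** 2 + (yy - h / 2) ** 2) / ((w / 2) ** 2 + (h / 2) ** 2)
        R *= 1.0 - params.vignette_strength * (0.5 + 0.5 * d2)

    if params.noise_sd > 0:
        R += rng.normal(0.0, params.noise_sd, shape)

    R8 = np.clip(np.rint(R), 0, 255).astype(np.uint8)
    # green grapes under warm-white LED: R dominates; G and B sit below it
    G = np.clip(R8.astype(np.float64) - rng.uniform(30, 60, shape), 0, 255)
    B = np.clip(R8.astype(np.float64) - rng.uniform(60, 100, shape), 0, 255)
    rgb = np.stack([R8, G.astype(np.uint8), B.astype(np.uint8)], axis=-1)

    truth = SceneTruth(
        fruit_mask=BinaryMask(fruit_mask),
        stem=stem,
        params=params,
        present=params.fruit_present and bool(fruit_mask.any()),
    )
    return RgbImage(rgb), truth


def _berry_layout(params, rng):
    """Berry centers, radii and R values for a packed conical cluster.

    Grape clusters hang as a cone, widest at the shoulder and tapering
    downward, with berries pressed against each other.  Candidate centers
    are laid out row by row inside a cone whose dimensions scale with
    ``cluster_spread`` (height 2.9 s, shoulder width 2.7 s, tapering to
    0.35 of that at the tip), with overlapping spacing so the rendered
    union is a single connected region.  ``berry_count`` trims or pads the
    candidate set: extras are dropped at random; shortfalls are resampled
    uniformly inside the cone.
    """
    cx0, cy0 = params.cluster_center
    s = params.cluster_spread
    r_lo, r_hi = params.berry_radius_range
    v_lo, v_hi = params.berry_R_range
    r_mean = 0.5 * (r_lo + r_hi)
    height = 2.9 * s
    top_half_w = 0.5 * 2.7 * s
    dy = 1.9 * r_mean
    dx = 1.7 * r_mean
    y_top = cy0 - height / 2.0
    candidates = []
    n_rows = max(1, int(round(height / dy)))
    for i in range(n_rows):
        frac = (i + 0.5) / n_rows
        y = y_top + frac * height
        half_w = top_half_w * (1.0 - 0.65 * frac)
        n_in_row = max(1, int(round(2 * half_w / dx)))
        for k in range(n_in_row):
            x = cx0 - half_w + (k + 0.5) * (2 * half_w / n_in_row)
            candidates.append(
                (x + rng.uniform(-3, 3), y + rng.uniform(-3, 3))
            )
    rng.shuffle(candidates)
    if len(candidates) > params.berry_count:
        candidates = candidates[: params.berry_count]
    while len(candidates) < params.berry_count:
        frac = rng.uniform(0, 1)
        half_w = top_half_w * (1.0 - 0.65 * frac)
        candidates.append(
            (cx0 + rng.uniform(-half_w, half_w), y_top + frac * height)
        )
    return [
        (bx, by, rng.uniform(r_lo, r_hi), rng.uniform(v_lo, v_hi))
        for bx, by in candidates
    ]


def _draw_stem(params, rng, fruit_mask, R):
    """Bright bar from the top of the cluster's bounding box, angled
    ``stem_angle_deg`` off vertical; returns the truth segment and canvas."""
    h, w = fruit_mask.shape
    rows, cols = np.nonzero(fruit_mask)
    y_top = int(rows.min())
    near_top = rows <= y_top + 5
    x_base = float(cols[near_top].mean())
    length = rng.uniform(*params.stem_length_range)
    theta = np.deg2rad(params.stem_angle_deg)
    x_tip = x_base + length * np.sin(theta)
    y_tip = y_top - length * np.cos(theta)
    # keep the whole bar inside the frame
    x_tip = min(max(x_tip, 1.0), w - 2.0)
    y_tip = max(y_tip, 1.0)
    width = int(rng.integers(params.stem_width_range[0], params.stem_width_range[1] + 1))
    rr, cc = draw_line(int(round(y_tip)), int(round(x_tip)), y_top, int(round(x_base)))
    bar = np.zeros_like(fruit_mask)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    bar[rr[keep], cc[keep]] = True
    if width > 1:
        bar = ndimage.binary_dilation(
            bar, structure=np.ones((1, width), dtype=bool)
        )
    R[bar] = params.stem_R * params.illumination
    stem = LineSegment((x_tip, y_tip), (x_base, float(y_top)))
    return stem, R


#: the four scene conditions: near-center cluster, near-center cluster at
#: the frame edge (both "present"), dim off-center cluster, and no cluster
#: (both "absent")
CONDITIONS = ("centered", "centered_edge", "off_center", "absent")


def scene_seed(base_seed: int, index: int) -> int:
    """Counter-based per-scene seed below 2**31."""
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def condition_params(
    base: SceneParams, condition: str, rng: np.random.Generator, seed: int
) -> SceneParams:
    """Instantiate one scene of the given condition from base parameters."""
    w, h = base.image_size
    if condition == "centered":
        return replace(
            base,
            seed=seed,
            cluster_center=(rng.uniform(0.4 * w, 0.6 * w), rng.uniform(0.5 * h, 0.62 * h)),
        )
    if condition == "centered_edge":
        side = rng.uniform(0.18 * w, 0.26 * w)
        cx = side if rng.random() < 0.5 else w - side
        return replace(
            base,
            seed=seed,
            cluster_center=(cx, rng.uniform(0.5 * h, 0.62 * h)),
        )
    if condition == "off_center":
        # cluster at the frame edge, away from the light center: dim + cropped
        side = rng.uniform(0.02 * w, 0.10 * w)
        cx = side if rng.random() < 0.5 else w - side
        return replace(
            base,
            seed=seed,
            cluster_center=(cx, rng.uniform(0.45 * h, 0.7 * h)),
            illumination=rng.uniform(0.55, 0.7),
        )
    if condition == "absent":
        return replace(base, seed=seed, fruit_present=False, berry_count=0)
    raise InvalidInputError(f"unknown condition {condition!r}")


def generate_batch(
    n: int,
    base: SceneParams | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> list[tuple[RgbImage, SceneTruth, str, bool]]:
    """Render n scenes cycling through the conditions.

    Returns (image, truth, condition, present_label) tuples; the presence
    label is True for the two near-center conditions.  Per-scene seeds are
    derived from the base seed with a counter, so batches are reproducible
    element-wise.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    base = base or SceneParams()
    out = []
    for i in range(n):
        cond = conditions[i % len(conditions)]
        seed = scene_seed(base.seed, i)
        rng = np.random.default_rng(seed ^ 0x5EED)
        params = condition_params(base, cond, rng, seed)
        img, truth = generate_scene(params)
        present = cond in ("centered", "centered_edge")
        truth.present = present
        out.append((img, truth, cond, present))
    return out


def write_scene(out_dir, name: str, image: RgbImage, truth: SceneTruth) -> dict:
    """Write scene PNG, truth-mask PNG and truth JSON side by side."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{name}.png"
    mask_path = out / f"{name}_mask.png"
    json_path = out / f"{name}_truth.json"
    iio.imwrite(img_path, image.pixels)
    iio.imwrite(mask_path, (truth.fruit_mask.labels * 255).astype(np.uint8))
    json_path.write_text(json.dumps(truth.to_dict(), indent=2))
    return {
        "image": str(img_path),
        "truth_mask": str(mask_path),
        "truth_json": str(json_path),
    }
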