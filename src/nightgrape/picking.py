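"""Stem localization and picking-point computation.

Grape clusters hang vertically, so the stem appears as a bright,
near-vertical bar directly above the fruit.  The picking point is found by
(1) taking the axis-aligned minimum enclosing rectangle of the fruit mask
and its centroid, (2) searching the region of interest above the rectangle
for straight lines with a probabilistic Hough transform, discarding lines
more than 15 degrees off vertical, (3) keeping the most vertical surviving
line and returning the midpoint of its segment as the picking point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import skeletonize
from skimage.transform import probabilistic_hough_line

from .gate import GateDecision, GateParams, evaluate_gate
from .levelset import BinaryMask, CvParams, segment_pyramid
from .morphology import MorphParams, clean_mask
from .preprocessing import (
    ChannelImage,
    InvalidInputError,
    PipelineConfig,
    RgbImage,
    extract_red,
    rotate_channel,
    standardize,
)

#: fixed seed of the (randomized) probabilistic Hough sampler, so identical
#: inputs give byte-identical results
_HOUGH_SEED = 0


@dataclass(frozen=True)
class PickingParams:
    """Stem-search operating point.

    ``stem_threshold`` binarizes the rotated R channel inside the ROI; 175
    is the gate's ">140" brightness criterion carried through the +35
    value rotation.
    """

    max_vertical_angle: float = 15.0
    stem_threshold: int = 175
    hough_threshold: int = 10
    hough_min_length: int = 15
    hough_max_gap: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.max_vertical_angle < 90.0):
            raise InvalidInputError("max_vertical_angle must lie in (0, 90)")


@dataclass(frozen=True)
class LineSegment:
    """Segment between two pixel coordinates (x, y); x right, y down."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    @property
    def vertical_angle(self) -> float:
        """Angle to the image-column direction, degrees in [0, 90]."""
        dx = abs(self.p2[0] - self.p1[0])
        dy = abs(self.p2[1] - self.p1[1])
        if dx == 0 and dy == 0:
            return 0.0
        return math.degrees(math.atan2(dx, dy))

    @property
    def length(self) -> float:
        return math.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1])

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            (self.p1[0] + self.p2[0]) / 2.0,
            (self.p1[1] + self.p2[1]) / 2.0,
        )

    def x_at(self, y: float) -> float:
        """x of the (clamped) segment at row y."""
        (x1, y1), (x2, y2) = self.p1, self.p2
        if y1 == y2:
            return (x1 + x2) / 2.0
        t = (y - y1) / (y2 - y1)
        t = min(max(t, 0.0), 1.0)
        return x1 + t * (x2 - x1)

    def to_dict(self) -> dict:
        return {
            "p1": list(self.p1),
            "p2": list(self.p2),
            "angle_deg": self.vertical_angle,
        }


@dataclass
class PickingResult:
    """Outcome of the end-to-end detection and picking-point run."""

    status: str  # point_found | no_line | no_fruit | gate_stopped
    gate: GateDecision | None = None
    rect: tuple[int, int, int, int] | None = None  # x_min, y_min, x_max, y_max
    centroid: tuple[float, float] | None = None
    stem: LineSegment | None = None
    point: tuple[int, int] | None = None
    mask: BinaryMask | None = None
    lines: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "gate": self.gate.to_dict() if self.gate else None,
            "rect": list(self.rect) if self.rect else None,
            "centroid": list(self.centroid) if self.centroid else None,
            "stem": self.stem.to_dict() if self.stem else None,
            "picking_point": list(self.point) if self.point else None,
        }


def enclosing_rect(
    mask: BinaryMask,
) -> tuple[tuple[int, int, int, int], tuple[float, float]]:
    """Axis-aligned bounding box and center of mass of the foreground."""
    rows, cols = np.nonzero(mask.labels)
    if rows.size == 0:
        raise InvalidInputError("mask has no foreground pixels")
    rect = (int(cols.min()), int(rows.min()), int(cols.max()), int(rows.max()))
    centroid = (float(cols.mean()), float(rows.mean()))
    return rect, centroid


def roi_above(
    rect: tuple[int, int, int, int], image_shape: tuple[int, int]
) -> tuple[int, int, int, int] | None:
    """Region of interest above the rectangle: its x-range, rows 0..y_min-1.

    Returns None when the rectangle touches the top edge (empty ROI).
    """
    x_min, y_min, x_max, _ = rect
    if y_min <= 0:
        return None
    return (x_min, 0, x_max, y_min - 1)


def detect_lines(
    channel: ChannelImage,
    roi: tuple[int, int, int, int] | None,
    params: PickingParams | None = None,
) -> list[LineSegment]:
    """Hough line detection on the binarized, skeletonized ROI.

    The rotated R channel inside the ROI is thresholded at the bright
    criterion, thinned to one-pixel skeletons, and fed to the
    probabilistic Hough transform.  Segments come back in full-image
    coordinates.
    """
    params = params or PickingParams()
    if roi is None:
        return []
    x_min, y_min, x_max, y_max = roi
    window = channel.values[y_min : y_max + 1, x_min : x_max + 1]
    if window.size == 0:
        return []
    binary = window > params.stem_threshold
    if not binary.any():
        return []
    skeleton = skeletonize(binary)
    lines = probabilistic_hough_line(
        skeleton,
        threshold=params.hough_threshold,
        line_length=params.hough_min_length,
        line_gap=params.hough_max_gap,
        rng=np.random.default_rng(_HOUGH_SEED),
    )
    out = []
    for (x1, y1), (x2, y2) in lines:
        out.append(
            LineSegment(
                (float(x1 + x_min), float(y1 + y_min)),
                (float(x2 + x_min), float(y2 + y_min)),
            )
        )
    return out


def select_stem(
    segments: list[LineSegment], params: PickingParams | None = None
) -> LineSegment | None:
    """Pick the most vertical segment after the angle filter.

    Segments more than ``max_vertical_angle`` off vertical are discarded;
    among survivors the minimal-angle one wins, ties going to the longer
    segment and then to the one with the topmost midpoint.
    """
    params = params or PickingParams()
    survivors = [s for s in segments if s.vertical_angle <= params.max_vertical_angle]
    if not survivors:
        return None
    return min(
        survivors, key=lambda s: (s.vertical_angle, -s.length, s.midpoint[1])
    )


def picking_point(stem: LineSegment) -> tuple[int, int]:
    """Midpoint of the stem segment, rounded to the nearest pixel."""
    mx, my = stem.midpoint
    return (int(round(mx)), int(round(my)))


def analyze(
    image: RgbImage,
    config: PipelineConfig | None = None,
    gate_params: GateParams | None = None,
    cv_params: CvParams | None = None,
    morph_params: MorphParams | None = None,
    picking_params: PickingParams | None = None,
    with_mask: bool = True,
) -> PickingResult:
    """Run the full pipeline on one RGB image.

    standardize -> extract R -> gate -> rotate -> coarse-to-fine level set
    -> morphological cleanup -> stem search -> picking point.  A stopped
    gate, an empty mask or an empty line set yield the corresponding
    non-error status rather than an exception.
    """
    config = config or PipelineConfig()
    std = standardize(image, config)
    red = extract_red(std)
    decision = evaluate_gate(red, gate_params)
    if not decision.proceed:
        return PickingResult(status="gate_stopped", gate=decision)
    rotated = rotate_channel(red, config)
    raw_mask = segment_pyramid(rotated, cv_params, config)
    mask = clean_mask(raw_mask, morph_params)
    result = PickingResult(
        status="no_fruit", gate=decision, mask=mask if with_mask else None
    )
    if mask.count == 0:
        return result
    rect, centroid = enclosing_rect(mask)
    result.rect, result.centroid = rect, centroid
    roi = roi_above(rect, rotated.shape)
    lines = detect_lines(rotated, roi, picking_params)
    result.lines = lines
    stem = select_stem(lines, picking_params)
    if stem is None:
        result.status = "no_line"
        return result
    result.stem = stem
    result.point = picking_point(stem)
    result.status = "point_found"
    return result
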