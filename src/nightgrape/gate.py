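"""Histogram-ratio presence gate.

A grape cluster sitting near the light-source center produces a heavy tail
of bright red-channel pixels.  Counting the pixels whose R value exceeds a
brightness threshold (a) against the total pixel count (b), the ratio a/b
separates scenes with a well-lit cluster from empty or off-center scenes:
the picking run proceeds only when a/b exceeds the ratio threshold.  The
gate consumes the un-rotated R channel, before the value rotation is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .preprocessing import ChannelImage, InvalidInputError


@dataclass(frozen=True)
class GateParams:
    """Brightness threshold (strict >) and ratio threshold (strict >)."""

    bright_threshold: int = 140
    ratio_threshold: float = 0.0775

    def __post_init__(self) -> None:
        if not (0 <= self.bright_threshold <= 255):
            raise InvalidInputError("bright_threshold must lie in [0, 255]")
        if not (0.0 < self.ratio_threshold < 1.0):
            raise InvalidInputError("ratio_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class GateDecision:
    """Outcome of the presence gate on one image."""

    bright_count: int
    total_count: int
    ratio: float
    proceed: bool

    def to_dict(self) -> dict:
        return {
            "a": self.bright_count,
            "b": self.total_count,
            "ratio": self.ratio,
            "proceed": self.proceed,
        }


@dataclass(frozen=True)
class GateConfusion:
    """2x2 confusion of gate decisions against true presence labels."""

    true_proceed: int
    false_stop: int
    false_proceed: int
    true_stop: int

    @property
    def n(self) -> int:
        return self.true_proceed + self.false_stop + self.false_proceed + self.true_stop

    @property
    def accuracy(self) -> float:
        return (self.true_proceed + self.true_stop) / self.n

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accuracy"] = self.accuracy
        return d


def evaluate_gate(
    channel: ChannelImage, params: GateParams | None = None
) -> GateDecision:
    """Count bright pixels and decide whether a cluster is present.

    ``a`` counts pixels strictly above the brightness threshold, ``b`` is
    the total pixel count, and the run proceeds iff a/b strictly exceeds
    the ratio threshold.
    """
    params = params or GateParams()
    if channel.channel_tag != "R":
        raise InvalidInputError("the gate consumes the un-rotated R channel")
    values = channel.values
    a = int(np.count_nonzero(values > params.bright_threshold))
    b = int(values.size)
    ratio = a / b
    return GateDecision(a, b, ratio, proceed=ratio > params.ratio_threshold)


def gate_confusion(
    decisions: Sequence[GateDecision], truths: Sequence[bool]
) -> GateConfusion:
    """Tally gate decisions against ground-truth presence labels."""
    if len(decisions) != len(truths):
        raise InvalidInputError(
            f"length mismatch: {len(decisions)} decisions vs {len(truths)} labels"
        )
    tp = fn = fp = tn = 0
    for dec, present in zip(decisions, truths):
        if present and dec.proceed:
            tp += 1
        elif present:
            fn += 1
        elif dec.proceed:
            fp += 1
        else:
            tn += 1
    return GateConfusion(tp, fn, fp, tn)
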