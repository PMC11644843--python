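"""Tilt-threshold classification of lying vs. standing.

A leg-mounted logger reports degrees of vertical tilt at 1 Hz; a sample is
classified as lying when the angle exceeds a fixed threshold (default 60°).
Samples exactly at the threshold classify as standing (strict ``>``) — the
boundary convention is not standardized, so it is pinned here and covered
by a test. Non-finite samples propagate as missing labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import BehaviorStream, TiltSeries

__all__ = ["TiltThresholdRule", "classify_tilt"]


@dataclass(frozen=True)
class TiltThresholdRule:
    threshold: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 180:
            raise ValueError("threshold must lie in (0, 180) degrees")


def classify_tilt(
    tilt: TiltSeries, rule: TiltThresholdRule = TiltThresholdRule()
) -> BehaviorStream:
    """Label each second lying (1) iff angle > threshold.

    Raising the threshold never increases total classified lying time.
    """
    angle = np.asarray(tilt.angle, dtype=float)
    if len(angle) == 0:
        raise ValueError("cannot classify an empty tilt series")
    labels = np.where(angle > rule.threshold, 1.0, 0.0)
    labels[~np.isfinite(angle)] = np.nan
    return BehaviorStream(tilt.start_time, labels, channel="lying")
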