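"""Segmentation of electrodermal-activity recordings by task durations.

The whole recording of one annotator is cut into consecutive half-open
windows [t_i, t_i + d_i), one per triplet, starting at the experiment
start.  Each segment is summarised as the mean of readings taken at
10-second offsets from the segment start (sample-and-hold: the last
recorded sample at or before each offset); a segment shorter than 10 s
yields a single reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import EDATimeSeries

SAMPLE_INTERVAL_S = 10.0


class SegmentationError(ValueError):
    pass


@dataclass
class EDASegment:
    annotator_id: str
    triplet_id: int
    start: float
    end: float
    timestamps: np.ndarray
    values: np.ndarray


def segment_series(
    s: EDATimeSeries,
    durations: Sequence[float],
    triplet_ids: Sequence[int] | None = None,
    tolerance_s: float = 1.0,
) -> list[EDASegment]:
    """Cut a recording into one segment per task, in task order.

    ``durations`` are the recorded per-triplet processing times in
    seconds; they must fit inside the recording (up to ``tolerance_s``).
    """
    durations = [float(d) for d in durations]
    if any(d <= 0 for d in durations):
        raise SegmentationError("durations must be positive")
    if triplet_ids is None:
        triplet_ids = list(range(1, len(durations) + 1))
    if len(triplet_ids) != len(durations):
        raise SegmentationError("triplet_ids and durations must have equal length")

    total = sum(durations)
    available = s.experiment_end - s.experiment_start
    if total > available + tolerance_s:
        raise SegmentationError(
            f"durations overrun the recording by {total - available:.2f} s"
        )

    segments = []
    start = s.experiment_start
    for triplet_id, d in zip(triplet_ids, durations):
        end = start + d
        mask = (s.timestamps >= start) & (s.timestamps < end)
        segments.append(
            EDASegment(
                annotator_id=s.annotator_id,
                triplet_id=int(triplet_id),
                start=start,
                end=end,
                timestamps=s.timestamps[mask],
                values=s.values[mask],
            )
        )
        start = end
    return segments


def eda_mean(seg: EDASegment, interval_s: float = SAMPLE_INTERVAL_S) -> float:
    """Mean EDA of a segment when read at fixed-interval offsets.

    Readings are taken at offsets 0, interval, 2*interval, ... from the
    segment start, each as the last recorded sample at or before the
    offset.  Offsets before the first recorded sample are skipped.
    """
    if seg.values.size == 0:
        raise ValueError(
            f"segment (annotator {seg.annotator_id}, triplet {seg.triplet_id}) "
            "contains no samples"
        )
    offsets = np.arange(seg.start, seg.end, interval_s)
    # last sample at or before each offset; 'right' side makes ties inclusive
    idx = np.searchsorted(seg.timestamps, offsets, side="right") - 1
    idx = idx[idx >= 0]
    if idx.size == 0:
        idx = np.array([0])
    return float(np.mean(seg.values[idx]))


def segment_means(
    series: EDATimeSeries,
    durations: Sequence[float],
    triplet_ids: Sequence[int] | None = None,
) -> dict[int, float]:
    """Per-triplet 10-second-sampled EDA means for one annotator."""
    segments = segment_series(series, durations, triplet_ids)
    return {seg.triplet_id: eda_mean(seg) for seg in segments}
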