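"""Time-lapse tracking of mitochondria and dynamic-range quantification.

Mitochondria move little between ~2-s frames, so linking is by greedy
maximum spatial overlap: labelled organelles in consecutive frames are
matched in descending intersection-over-union order (admissible above IoU
0.1). A previous-frame organelle overlapping two current ones records a
fission event; two previous organelles collapsing onto one record a fusion.

Per-track metric traces (cristae density, mean area, mean circularity, mean
aspect ratio, count) are summarized as *SD per minute*: the sample standard
deviation of the trace normalized linearly to a one-minute observation
window, SD x (60 s / window duration). Frames where a mitochondrion has no
cristae contribute density 0 and count 0 but missing shape means, excluded
pairwise per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .morphometry import MitoRecord

__all__ = [
    "Track",
    "TraceSeries",
    "DynamicRangeSummary",
    "link_mitochondria",
    "trace_metrics",
    "dynamic_range",
    "event_shape_report",
    "TRACE_METRICS",
    "DEFAULT_IOU_THRESHOLD",
]

DEFAULT_IOU_THRESHOLD = 0.1

TRACE_METRICS = (
    "cristae_density_per_um2",
    "mean_cristae_area_um2",
    "mean_circularity",
    "mean_aspect_ratio",
    "cristae_count",
)


@dataclass
class Track:
    """One mitochondrion followed through the frame sequence."""

    track_id: int
    assignments: dict[int, int] = field(default_factory=dict)  # frame -> label
    events: list[tuple[int, str, tuple[int, ...]]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return sorted(self.assignments)


@dataclass(frozen=True)
class TraceSeries:
    """Per-track metric-versus-time traces (NaN marks missing shape means)."""

    track_id: int
    times_s: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=np.float64)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, seq in self.values.items():
            if len(seq) != len(t):
                raise ValueError(f"metric {name} length != number of times")
        object.__setattr__(self, "times_s", t)


@dataclass(frozen=True)
class DynamicRangeSummary:
    """SD-per-minute of each metric over the trace window."""

    track_id: int
    window_s: float
    sd_per_min: dict[str, float]
    n_frames: dict[str, int]


def _overlap_table(prev: np.ndarray, curr: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU for every pair of overlapping labels between two frames."""
    both = (prev > 0) & (curr > 0)
    pairs, counts = np.unique(
        np.stack([prev[both], curr[both]]), axis=1, return_counts=True
    )
    areas_prev = dict(zip(*np.unique(prev[prev > 0], return_counts=True)))
    areas_curr = dict(zip(*np.unique(curr[curr > 0], return_counts=True)))
    table = {}
    for (a, b), inter in zip(pairs.T, counts):
        union = areas_prev[a] + areas_curr[b] - inter
        table[(int(a), int(b))] = inter / union
    return table


def link_mitochondria(
    frame_labels: Sequence[np.ndarray],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> list[Track]:
    """Link labelled mitochondria across frames by greedy maximum overlap.

    Candidate links with IoU >= ``iou_threshold`` are accepted one-to-one in
    descending IoU order (ties broken by label ids, so the result is
    deterministic and invariant to label permutation up to track numbering).
    Remaining overlapping labels record fission (one previous, two current)
    or fusion (two previous, one current) events; organelles without any
    admissible overlap start or end tracks.
    """
    if len(frame_labels) < 2:
        raise ValueError("need at least 2 frames to link")
    shape = frame_labels[0].shape
    if any(fl.shape != shape for fl in frame_labels):
        raise ValueError("all frames must have the same shape")

    tracks: list[Track] = []
    active: dict[int, Track] = {}  # current-frame label -> track
    for lbl in np.unique(frame_labels[0]):
        if lbl == 0:
            continue
        t = Track(len(tracks), {0: int(lbl)})
        tracks.append(t)
        active[int(lbl)] = t

    for f in range(1, len(frame_labels)):
        prev, curr = frame_labels[f - 1], frame_labels[f]
        table = _overlap_table(prev, curr)
        candidates = sorted(
            ((iou, a, b) for (a, b), iou in table.items() if iou >= iou_threshold),
            key=lambda x: (-x[0], x[1], x[2]),
        )
        matched_prev: dict[int, int] = {}
        matched_curr: dict[int, int] = {}
        for iou, a, b in candidates:
            if a not in matched_prev and b not in matched_curr:
                matched_prev[a] = b
                matched_curr[b] = a
        new_active: dict[int, Track] = {}
        for a, b in matched_prev.items():
            track = active[a]
            track.assignments[f] = b
            new_active[b] = track
        # fission: unmatched current label overlapping a matched previous label
        for iou, a, b in candidates:
            if b in matched_curr or a not in matched_prev:
                continue
            parent = active[a]
            child = Track(len(tracks), {f: int(b)})
            tracks.append(child)
            parent.events.append((f, "fission", (child.track_id,)))
            child.events.append((f, "fission", (parent.track_id,)))
            new_active[b] = child
            matched_curr[b] = a
        # fusion: unmatched previous label overlapping a matched current label
        for iou, a, b in candidates:
            if a in matched_prev or b not in matched_curr:
                continue
            absorbed = active[a]
            survivor = new_active[b]
            absorbed.events.append((f, "fusion", (survivor.track_id,)))
            survivor.events.append((f, "fusion", (absorbed.track_id,)))
            matched_prev[a] = b
        # labels with no admissible overlap at all start fresh tracks
        for lbl in np.unique(curr):
            lbl = int(lbl)
            if lbl == 0 or lbl in new_active or lbl in matched_curr:
                continue
            t = Track(len(tracks), {f: lbl})
            tracks.append(t)
            new_active[lbl] = t
        active = new_active
    return tracks


def trace_metrics(
    track: Track,
    per_frame_records: Mapping[int, Mapping[int, MitoRecord]],
    times_s: Mapping[int, float] | Sequence[float],
) -> TraceSeries:
    """Collect the track's per-frame metrics into time-ordered sequences.

    ``per_frame_records`` maps frame -> (mito label -> MitoRecord);
    ``times_s`` gives each frame's acquisition time. A frame where the
    organelle holds zero cristae contributes density 0 and count 0 but NaN
    shape means. A frame with no record at all is an error.
    """
    frames = track.frames
    values = {m: [] for m in TRACE_METRICS}
    times = []
    for f in frames:
        label = track.assignments[f]
        frame_records = per_frame_records.get(f, {})
        if label not in frame_records:
            raise ValueError(f"track {track.track_id}: no record for frame {f}")
        rec = frame_records[label]
        times.append(times_s[f])
        values["cristae_density_per_um2"].append(rec.cristae_density_per_um2)
        values["cristae_count"].append(float(rec.cristae_count))
        values["mean_cristae_area_um2"].append(rec.mean_cristae_area_um2)
        values["mean_circularity"].append(rec.mean_circularity)
        values["mean_aspect_ratio"].append(rec.mean_aspect_ratio)
    return TraceSeries(
        track.track_id,
        np.asarray(times, dtype=np.float64),
        {m: np.asarray(v, dtype=np.float64) for m, v in values.items()},
    )


MIN_TRACE_SAMPLES = 3
MIN_TRACE_SPAN_S = 10.0


def dynamic_range(trace: TraceSeries) -> DynamicRangeSummary:
    """SD-per-minute of each metric: sample SD x (60 / window seconds).

    The window is last minus first sample time. Missing values (NaN) are
    excluded per metric; their count is reflected in ``n_frames``. Requires
    at least 3 non-missing samples and a span of at least 10 s.
    """
    window = float(trace.times_s[-1] - trace.times_s[0])
    if window < MIN_TRACE_SPAN_S:
        raise ValueError(f"trace spans {window:.1f} s; need >= {MIN_TRACE_SPAN_S} s")
    sd, n = {}, {}
    for metric, seq in trace.values.items():
        finite = seq[np.isfinite(seq)]
        n[metric] = int(len(finite))
        if len(finite) < MIN_TRACE_SAMPLES:
            raise ValueError(
                f"metric {metric}: {len(finite)} non-missing samples; "
                f"need >= {MIN_TRACE_SAMPLES}"
            )
        if np.ptp(finite) == 0.0:  # constant trace: exactly zero, not round-off
            sd[metric] = 0.0
        else:
            sd[metric] = float(np.std(finite, ddof=1)) * (60.0 / window)
    return DynamicRangeSummary(trace.track_id, window, sd, n)


def event_shape_report(
    track: Track,
    trace: TraceSeries,
    events: Optional[Sequence[tuple[int, str]]] = None,
) -> pd.DataFrame:
    """Metric values immediately before/after each event and their fold change.

    ``events`` defaults to the track's lineage events; user-marked events can
    be supplied as (frame, type) pairs. Events at the trace boundary have the
    missing side reported as NaN (fold change NaN as well).
    """
    if events is None:
        events = [(f, kind) for f, kind, _ in track.events]
    frames = track.frames
    rows = []
    for frame, kind in events:
        idx_after = next((i for i, f in enumerate(frames) if f >= frame), None)
        idx_before = idx_after - 1 if idx_after is not None and idx_after > 0 else None
        if idx_after is not None and frames[idx_after] > frame:
            # event frame itself absent from this track; keep nearest sides
            idx_before = idx_after - 1 if idx_after > 0 else None
        for metric in TRACE_METRICS:
            seq = trace.values[metric]
            before = float(seq[idx_before]) if idx_before is not None else float("nan")
            after = float(seq[idx_after]) if idx_after is not None else float("nan")
            fold = after / before if before not in (0.0,) else float("nan")
            rows.append(
                {
                    "track_id": track.track_id,
                    "frame": frame,
                    "event": kind,
                    "metric": metric,
                    "before": before,
                    "after": after,
                    "fold_change": fold,
                }
            )
    columns = ["track_id", "frame", "event", "metric", "before", "after", "fold_change"]
    return pd.DataFrame(rows, columns=columns)
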