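"""Tracking by overlap, metric traces, SD-per-minute, event reports."""

import numpy as np
import pandas as pd
import pytest

from cristaseg.dynamics import (
    DynamicRangeSummary,
    TraceSeries,
    Track,
    dynamic_range,
    event_shape_report,
    link_mitochondria,
    trace_metrics,
)
from cristaseg.morphometry import MitoRecord, _mito_record, measure_particle


def _blob(shape, top, left, h=4, w=4, label=1):
    grid = np.zeros(shape, dtype=int)
    grid[top : top + h, left : left + w] = label
    return grid


# ---------------------------------------------------------------------------
# linking


def test_translating_blob_yields_single_track_without_events():
    frames = [_blob((32, 32), 5, 5 + 2 * f) for f in range(5)]
    tracks = link_mitochondria(frames)
    assert len(tracks) == 1
    assert tracks[0].frames == [0, 1, 2, 3, 4]
    assert tracks[0].events == []


def test_fission_splits_into_parent_and_child_tracks():
    before = _blob((32, 32), 10, 8, h=4, w=12)
    after = _blob((32, 32), 10, 8, h=4, w=5) + _blob((32, 32), 10, 16, h=4, w=4, label=2)
    frames = [before, before, after, after]
    tracks = link_mitochondria(frames)
    assert len(tracks) == 2
    parent, child = tracks
    assert parent.events == [(2, "fission", (child.track_id,))]
    assert child.events == [(2, "fission", (parent.track_id,))]
    assert child.frames == [2, 3]


def test_fusion_records_event_on_both_tracks():
    two = _blob((32, 32), 10, 5, h=4, w=5) + _blob((32, 32), 10, 14, h=4, w=5, label=2)
    merged = _blob((32, 32), 10, 5, h=4, w=14)
    frames = [two, two, merged]
    tracks = link_mitochondria(frames)
    assert len(tracks) == 2
    kinds = [ev for t in tracks for ev in t.events]
    assert sum(1 for f, kind, _ in kinds if kind == "fusion") == 2
    survivor = [t for t in tracks if 2 in t.assignments]
    assert len(survivor) == 1


def test_label_permutation_leaves_topology_unchanged():
    frames = [_blob((32, 32), 5, 5 + 2 * f) for f in range(4)]
    permuted = [np.where(f > 0, 7, 0) for f in frames]
    a = link_mitochondria(frames)
    b = link_mitochondria(permuted)
    assert len(a) == len(b) == 1
    assert a[0].frames == b[0].frames


def test_shape_mismatch_and_short_sequences_rejected():
    with pytest.raises(ValueError, match="2 frames"):
        link_mitochondria([_blob((16, 16), 2, 2)])
    with pytest.raises(ValueError, match="shape"):
        link_mitochondria([_blob((16, 16), 2, 2), _blob((20, 20), 2, 2)])


def test_no_overlap_starts_a_new_track():
    frames = [_blob((32, 32), 2, 2), _blob((32, 32), 20, 20)]
    tracks = link_mitochondria(frames)
    assert len(tracks) == 2
    assert tracks[0].frames == [0]
    assert tracks[1].frames == [1]


# ---------------------------------------------------------------------------
# traces


def _record(label, count, density=None):
    return MitoRecord(
        mito_id=label,
        mito_area_um2=2.0,
        cristae_count=count,
        cristae_density_per_um2=density if density is not None else count / 2.0,
        mean_cristae_area_um2=0.02 if count else float("nan"),
        mean_circularity=0.5 if count else float("nan"),
        mean_aspect_ratio=3.0 if count else float("nan"),
    )


def test_static_mito_gives_constant_traces():
    track = Track(0, {f: 1 for f in range(15)})
    records = {f: {1: _record(1, 5)} for f in range(15)}
    trace = trace_metrics(track, records, {f: 2.0 * f for f in range(15)})
    for seq in trace.values.values():
        assert np.all(seq == seq[0])


def test_count_step_change_lands_on_the_scripted_frame():
    track = Track(0, {f: 1 for f in range(15)})
    records = {f: {1: _record(1, 5 if f < 8 else 4)} for f in range(15)}
    trace = trace_metrics(track, records, {f: 2.0 * f for f in range(15)})
    counts = trace.values["cristae_count"]
    assert np.array_equal(np.unique(counts[:8]), [5])
    assert np.array_equal(np.unique(counts[8:]), [4])


def test_zero_cristae_frames_have_missing_shape_means():
    track = Track(0, {f: 1 for f in range(6)})
    records = {f: {1: _record(1, 0 if f == 3 else 2)} for f in range(6)}
    trace = trace_metrics(track, records, {f: 3.0 * f for f in range(6)})
    assert trace.values["cristae_density_per_um2"][3] == 0.0
    assert np.isnan(trace.values["mean_circularity"][3])
    dr = dynamic_range(trace)
    assert dr.n_frames["mean_circularity"] == 5
    assert dr.n_frames["cristae_count"] == 6


def test_missing_frame_record_is_an_error():
    track = Track(0, {0: 1, 1: 1})
    with pytest.raises(ValueError, match="frame 1"):
        trace_metrics(track, {0: {1: _record(1, 2)}}, {0: 0.0, 1: 2.0})


# ---------------------------------------------------------------------------
# dynamic range


def _trace(values, times=None):
    values = np.asarray(values, dtype=float)
    times = np.asarray(times if times is not None else 2.0 * np.arange(len(values)))
    return TraceSeries(0, times, {m: values for m in (
        "cristae_density_per_um2", "mean_cristae_area_um2", "mean_circularity",
        "mean_aspect_ratio", "cristae_count")})


def test_constant_trace_has_zero_dynamic_range():
    dr = dynamic_range(_trace(np.full(10, 3.7)))
    assert all(v == 0.0 for v in dr.sd_per_min.values())


def test_time_rescaled_constant_trace_still_zero():
    dr = dynamic_range(_trace(np.full(8, 1.1), times=np.array([0, 1, 3, 9, 12, 20, 40, 80.0])))
    assert all(v == 0.0 for v in dr.sd_per_min.values())


def test_sixty_second_window_closed_form():
    # over exactly 60 s the normalization factor is 1: SD-per-min = plain SD
    dr = dynamic_range(_trace([1.0, 3.0, 1.0], times=[0.0, 30.0, 60.0]))
    expected = np.std([1, 3, 1], ddof=1) * 1.0
    assert dr.sd_per_min["cristae_count"] == pytest.approx(expected)
    # halving the window doubles the reported dynamic range
    dr2 = dynamic_range(_trace([1.0, 3.0, 1.0], times=[0.0, 15.0, 30.0]))
    assert dr2.sd_per_min["cristae_count"] == pytest.approx(2 * expected)


def test_short_traces_rejected():
    with pytest.raises(ValueError, match="span"):
        dynamic_range(_trace([1, 2, 3], times=[0, 2, 4]))
    with pytest.raises(ValueError, match="non-missing"):
        values = np.array([1.0, np.nan, np.nan, np.nan, 2.0, np.nan, np.nan, np.nan])
        trace = _trace(np.arange(8.0))
        broken = TraceSeries(0, trace.times_s, {m: values for m in trace.values})
        dynamic_range(broken)


def test_known_jitter_recovery_within_30_percent():
    """White Gaussian jitter of known sigma on a 16-frame, 2-s-interval trace
    (30-s window): mean recovered SD-per-min over 20 seeds within 30% of
    sigma x (60/30)."""
    sigma = 0.4
    recovered = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        values = 5.0 + rng.normal(0, sigma, 16)
        dr = dynamic_range(_trace(values))
        recovered.append(dr.sd_per_min["cristae_count"])
    expected = sigma * (60.0 / 30.0)
    assert np.mean(recovered) == pytest.approx(expected, rel=0.30)


# ---------------------------------------------------------------------------
# event reports


def test_event_report_before_after_and_folds():
    track = Track(0, {f: 1 for f in range(6)}, events=[(3, "fission", (1,))])
    values = {m: np.array([2.0, 2.0, 2.0, 4.0, 4.0, 4.0]) for m in (
        "cristae_density_per_um2", "mean_cristae_area_um2", "mean_circularity",
        "mean_aspect_ratio", "cristae_count")}
    trace = TraceSeries(0, 2.0 * np.arange(6), values)
    report = event_shape_report(track, trace)
    row = report[report.metric == "mean_circularity"].iloc[0]
    assert (row.before, row.after) == (2.0, 4.0)
    assert row.fold_change == pytest.approx(2.0)


def test_event_at_trace_boundary_reports_missing_side():
    track = Track(0, {f: 1 for f in range(4)})
    values = {m: np.ones(4) for m in (
        "cristae_density_per_um2", "mean_cristae_area_um2", "mean_circularity",
        "mean_aspect_ratio", "cristae_count")}
    trace = TraceSeries(0, 2.0 * np.arange(4), values)
    report = event_shape_report(track, trace, events=[(0, "fusion")])
    assert report.before.isna().all()


def test_no_events_gives_empty_table():
    track = Track(0, {0: 1, 1: 1})
    values = {m: np.ones(2) for m in (
        "cristae_density_per_um2", "mean_cristae_area_um2", "mean_circularity",
        "mean_aspect_ratio", "cristae_count")}
    trace = TraceSeries(0, np.array([0.0, 2.0]), values)
    report = event_shape_report(track, trace)
    assert report.empty
    assert list(report.columns) == [
        "track_id", "frame", "event", "metric", "before", "after", "fold_change"
    ]


def test_scripted_fusion_and_fission_fold_directions():
    """Two high-AR bars fusing into an arch lower the mean aspect ratio
    (fold < 1); a bar breaking into compact fragments raises the mean
    circularity (fold > 1) — measured via real morphometry on pixel sets."""
    s = 0.04

    def bars_record(n):
        particles = [
            measure_particle(
                np.column_stack([np.arange(20), np.full(20, 5 * i)]), s, i
            )
            for i in range(n)
        ]
        return _mito_record(1, 4.0, particles)

    def arch_record():
        yy, xx = np.mgrid[-12:13, -12:13]
        ring = (np.abs(np.hypot(yy, xx) - 10) <= 1.2) & (yy <= 0)
        return _mito_record(1, 4.0, [measure_particle(np.column_stack(np.nonzero(ring)), s)])

    def fragments_record():
        yy, xx = np.mgrid[-3:4, -3:4]
        blob = np.column_stack(np.nonzero(yy**2 + xx**2 <= 9))
        return _mito_record(
            1, 4.0, [measure_particle(blob, s, 0), measure_particle(blob + 20, s, 1)]
        )

    track = Track(0, {f: 1 for f in range(6)}, events=[(3, "fusion", ())])
    fusion_records = {f: {1: (bars_record(2) if f < 3 else arch_record())} for f in range(6)}
    trace = trace_metrics(track, fusion_records, {f: 2.0 * f for f in range(6)})
    report = event_shape_report(track, trace)
    ar_fold = report[report.metric == "mean_aspect_ratio"].fold_change.iloc[0]
    assert ar_fold < 1.0

    track2 = Track(0, {f: 1 for f in range(6)}, events=[(3, "fission", ())])
    fission_records = {f: {1: (bars_record(1) if f < 3 else fragments_record())} for f in range(6)}
    trace2 = trace_metrics(track2, fission_records, {f: 2.0 * f for f in range(6)})
    report2 = event_shape_report(track2, trace2)
    circ_fold = report2[report2.metric == "mean_circularity"].fold_change.iloc[0]
    assert circ_fold > 1.0
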