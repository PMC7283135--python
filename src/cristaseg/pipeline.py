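"""End-to-end orchestration: configuration, the full pipeline, comparisons.

``run_pipeline`` composes preprocess -> features -> probability map ->
threshold -> particles -> area filter -> mitochondrial-network segmentation
-> morphometry (-> tracking and dynamic ranges for time-lapse input) and
writes CSV tables plus the exact configuration used, so any output directory
can be re-run reproducibly. ``compare_methods`` is the harness that pits the
classifier route against direct intensity thresholding (manual, MaxEntropy,
Shanbhag, Otsu) with identical particle filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .classifier import PixelClassifier, predict_probability
from .dynamics import (
    TRACE_METRICS,
    dynamic_range,
    link_mitochondria,
    trace_metrics,
)
from .features import FeatureConfig, build_feature_stack
from .image import CalibratedImage
from .morphometry import (
    DEFAULT_MIN_AREA_UM2,
    CellSummary,
    MitoRecord,
    Particle,
    aggregate_cell,
)
from .preprocess import DEFAULT_BALL_RADIUS_PX, subtract_background
from .segment import (
    connected_particles,
    filter_particles,
    label_mask,
    segment_mito_network,
    threshold_intensity,
    threshold_probability,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_methods", "BASELINE_METHODS"]

BASELINE_METHODS = ("manual", "max_entropy", "shanbhag", "otsu")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; serialized alongside every output."""

    pixel_size_um: Optional[float] = None
    frame_interval_s: Optional[float] = None
    ball_radius_px: int = DEFAULT_BALL_RADIUS_PX
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    n_trees: int = 200
    features_per_split: Optional[int] = None
    classifier_seed: int = 42
    prob_threshold: float = 0.5
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    connectivity: int = 8
    mito_strategy: str = "otsu_on_smoothed"
    manual_threshold: Optional[float] = None
    output_dir: Optional[str] = None

    def to_text(self) -> str:
        lines = [f"# cristaseg {_version} run configuration"]
        for f_ in dataclasses.fields(self):
            value = getattr(self, f_.name)
            if f_.name == "feature_config":
                lines.append(value.to_text())
            elif value is not None:
                lines.append(f"{f_.name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        feature_config = FeatureConfig.from_text(text)
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = (p.strip() for p in line.split("=", 1))
            kv[k] = v
        kwargs: dict = {"feature_config": feature_config}
        converters = {
            "pixel_size_um": float,
            "frame_interval_s": float,
            "ball_radius_px": int,
            "n_trees": int,
            "features_per_split": int,
            "classifier_seed": int,
            "prob_threshold": float,
            "min_area_um2": float,
            "connectivity": int,
            "mito_strategy": str,
            "manual_threshold": float,
            "output_dir": str,
        }
        for name, conv in converters.items():
            if name in kv:
                kwargs[name] = conv(kv[name])
        return cls(**kwargs)

    def to_file(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())


@dataclass
class RunResult:
    """In-memory results of one pipeline run."""

    particles: pd.DataFrame
    mitochondria: pd.DataFrame
    cells: pd.DataFrame
    tracks: Optional[pd.DataFrame] = None
    traces: Optional[pd.DataFrame] = None
    dynamic_ranges: Optional[pd.DataFrame] = None
    log_lines: list[str] = field(default_factory=list)


def _particle_row(p: Particle, frame: int) -> dict:
    return {
        "id": p.id,
        "frame": frame,
        "area_um2": p.area_um2,
        "perimeter_um": p.perimeter_um,
        "circularity": p.circularity,
        "aspect_ratio": p.aspect_ratio,
        "centroid_row": p.centroid[0],
        "centroid_col": p.centroid[1],
    }


def segment_frame(
    image: CalibratedImage, classifier: PixelClassifier, config: RunConfig
) -> tuple[list[Particle], np.ndarray]:
    """One frame through preprocess -> probability -> particles -> mito labels."""
    pre = subtract_background(image, config.ball_radius_px)
    stack = build_feature_stack(pre, config.feature_config)
    prob = predict_probability(classifier, stack, pre)
    mask = threshold_probability(prob, config.prob_threshold)
    particles = filter_particles(
        connected_particles(mask, config.connectivity), config.min_area_um2
    )
    net_mask, _ = segment_mito_network(pre, strategy=config.mito_strategy)
    return particles, label_mask(net_mask, config.connectivity)


def run_pipeline(
    images: Sequence[CalibratedImage],
    classifier: PixelClassifier,
    config: RunConfig,
) -> RunResult:
    """Run the full analysis over one or more frames.

    Multi-frame input is treated as a time-lapse and additionally tracked;
    this requires time stamps on the frames (set ``frame_interval_s`` when
    reading). Output tables are written under ``config.output_dir`` when set,
    together with the configuration and a deterministic run log.
    """
    if len(images) == 0:
        raise ValueError("no input images")
    timelapse = len(images) > 1
    if timelapse and any(im.time_s is None for im in images):
        raise ValueError(
            "time-lapse input requires frame time stamps; set frame_interval_s"
        )
    log = [f"cristaseg {_version}", f"frames = {len(images)}"]
    particle_rows, mito_rows, cell_rows = [], [], []
    frame_label_masks = []
    per_frame_records: dict[int, dict[int, MitoRecord]] = {}
    times: dict[int, float] = {}
    for f, image in enumerate(images):
        try:
            particles, labels = segment_frame(image, classifier, config)
            summary, records = aggregate_cell(
                particles, labels, image.pixel_size_um, cell_id=f"frame{f}"
            )
        except Exception as exc:  # noqa: BLE001 - annotate stage context
            raise RuntimeError(f"pipeline failed on frame {f}: {exc}") from exc
        log.append(f"frame {f}: {len(particles)} particles, {len(records)} mitochondria")
        particle_rows += [_particle_row(p, f) for p in particles]
        for rec in records:
            row = dataclasses.asdict(rec)
            row["frame"] = f
            mito_rows.append(row)
        cell_row = dataclasses.asdict(summary)
        cell_row["frame"] = f
        cell_rows.append(cell_row)
        frame_label_masks.append(labels)
        per_frame_records[f] = {rec.mito_id: rec for rec in records}
        times[f] = image.time_s if image.time_s is not None else float(f)

    result = RunResult(
        particles=pd.DataFrame(particle_rows),
        mitochondria=pd.DataFrame(mito_rows),
        cells=pd.DataFrame(cell_rows),
        log_lines=log,
    )
    if timelapse:
        tracks = link_mitochondria(frame_label_masks)
        track_rows, trace_rows, dr_rows = [], [], []
        for track in tracks:
            for f in track.frames:
                track_rows.append(
                    {
                        "track_id": track.track_id,
                        "frame": f,
                        "mito_label": track.assignments[f],
                        "events": ";".join(
                            f"{kind}@{ef}" for ef, kind, _ in track.events if ef == f
                        ),
                    }
                )
            trace = trace_metrics(track, per_frame_records, times)
            for metric in TRACE_METRICS:
                for t, v in zip(trace.times_s, trace.values[metric]):
                    trace_rows.append(
                        {"track_id": track.track_id, "time_s": t, "metric": metric, "value": v}
                    )
            try:
                dr = dynamic_range(trace)
            except ValueError:
                continue
            for metric in TRACE_METRICS:
                dr_rows.append(
                    {
                        "track_id": track.track_id,
                        "metric": metric,
                        # SD normalized linearly to a 1-minute window
                        "sd_per_min_linear": dr.sd_per_min[metric],
                        "window_s": dr.window_s,
                        "n_frames": dr.n_frames[metric],
                    }
                )
        result.tracks = pd.DataFrame(track_rows)
        result.traces = pd.DataFrame(trace_rows)
        result.dynamic_ranges = pd.DataFrame(dr_rows)
        log.append(f"tracks = {len(tracks)}")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.particles.to_csv(out / "particles.csv", index=False)
        result.mitochondria.to_csv(out / "mitochondria.csv", index=False)
        result.cells.to_csv(out / "cells.csv", index=False)
        if timelapse:
            result.tracks.to_csv(out / "tracks.csv", index=False)
            result.traces.to_csv(out / "traces.csv", index=False)
            result.dynamic_ranges.to_csv(out / "dynamic_ranges.csv", index=False)
        config.to_file(out / "config.txt")
        (out / "run.log").write_text("\n".join(log) + "\n")
    return result


def compare_methods(
    image: CalibratedImage,
    classifier: PixelClassifier,
    methods: Sequence[str],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Classifier pipeline versus intensity-thresholding baselines.

    Every method sees the same background-subtracted image and identical
    particle filtering; cristae density uses the same mitochondrial-network
    area for all rows. The ``manual`` baseline requires
    ``config.manual_threshold`` (a fixed intensity cut chosen by the user).
    """
    config = config or RunConfig()
    unknown = set(methods) - set(BASELINE_METHODS)
    if unknown:
        raise ValueError(f"unknown baseline(s) {sorted(unknown)}; expected {BASELINE_METHODS}")
    pre = subtract_background(image, config.ball_radius_px)
    _, net_area = segment_mito_network(pre, strategy=config.mito_strategy)
    rows = []

    def _metrics(name: str, particles: list[Particle]) -> dict:
        areas = [p.area_um2 for p in particles]
        ars = [p.aspect_ratio for p in particles]
        return {
            "method": name,
            "n_cristae": len(particles),
            "density_per_um2": len(particles) / net_area if net_area else float("nan"),
            "mean_area_um2": float(np.mean(areas)) if areas else float("nan"),
            "total_area_um2": float(np.sum(areas)) if areas else 0.0,
            "mean_aspect_ratio": float(np.mean(ars)) if ars else float("nan"),
        }

    stack = build_feature_stack(pre, config.feature_config)
    prob = predict_probability(classifier, stack, pre)
    mask = threshold_probability(prob, config.prob_threshold)
    classifier_particles = filter_particles(
        connected_particles(mask, config.connectivity), config.min_area_um2
    )
    rows.append(_metrics("classifier", classifier_particles))

    for method in methods:
        if method == "manual":
            if config.manual_threshold is None:
                raise ValueError("manual baseline requires config.manual_threshold")
            bmask, _ = threshold_intensity(pre, manual_threshold=config.manual_threshold)
        else:
            bmask, _ = threshold_intensity(pre, method=method)
        particles = filter_particles(
            connected_particles(bmask, config.connectivity), config.min_area_um2
        )
        rows.append(_metrics(method, particles))
    return pd.DataFrame(rows)
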