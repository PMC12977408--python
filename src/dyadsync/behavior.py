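"""Communication features and team-performance error score.

Speech is consumed as binary on/off series at 10 Hz (one per role); the
cursor trajectory and the reference path are polylines in normalized screen
coordinates.  All features are computed separately before and after the
mid-task split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config


class DataError(ValueError):
    pass


@dataclass
class SpeechSeries:
    values: np.ndarray  # {0, 1}, sampled at fs
    fs: float
    role: str  # "Guide" | "Drawer"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise DataError("speech series must be binary")


@dataclass
class Trajectory:
    xy: np.ndarray  # (n, 2) screen coordinates, uniform sampling
    fs: float


@dataclass
class ReferencePath:
    vertices: np.ndarray  # (k, 2), ordered polyline
    icons: np.ndarray | None = None  # icon positions, when known

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise DataError("reference path needs at least 2 vertices")
        if not np.isfinite(self.vertices).all():
            raise DataError("reference path vertices must be finite")


@dataclass
class CommFeatures:
    period: str
    total_speaking_time: float  # s, Guide + Drawer
    speech_ratio: float  # Guide / Drawer speaking time
    valid: bool  # False when the Drawer never spoke (ratio undefined)


@dataclass
class PerformanceScore:
    period: str
    local_errors: np.ndarray  # per-sample distance to the reference path
    sum_error: float
    mean_error: float


def comm_features(guide: SpeechSeries, drawer: SpeechSeries,
                  split_time: float) -> tuple[CommFeatures, CommFeatures]:
    """Total speaking time and Guide/Drawer speech ratio, pre and post.

    A ratio greater than 1 reflects the expected asymmetry of the task (the
    Guide giving instructions); a Drawer who never speaks in a period makes
    the ratio undefined and the feature is flagged invalid rather than
    dividing by zero.
    """
    if guide.values.size != drawer.values.size or guide.fs != drawer.fs:
        raise DataError("speech series must be aligned and equal length")
    fs = guide.fs
    t = np.arange(guide.values.size) / fs
    out = []
    for period, sel in (("pre", t < split_time), ("post", t >= split_time)):
        g = guide.values[sel].sum() / fs
        d = drawer.values[sel].sum() / fs
        if d > 0:
            out.append(CommFeatures(period, g + d, g / d, True))
        else:
            out.append(CommFeatures(period, g + d, float("nan"), False))
    return tuple(out)


def point_to_polyline(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest point of a polyline.

    Exact point-to-segment projection over every segment (the continuous
    path, not just recorded vertices).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = vertices[:-1]  # (k-1, 2)
    b = vertices[1:]
    ab = b - a
    ab2 = (ab ** 2).sum(axis=1)
    best = np.full(points.shape[0], np.inf)
    for i in range(a.shape[0]):
        ap = points - a[i]
        if ab2[i] > 0:
            tt = np.clip(ap @ ab[i] / ab2[i], 0.0, 1.0)
        else:
            tt = np.zeros(points.shape[0])
        proj = a[i] + tt[:, None] * ab[i]
        d = np.hypot(*(points - proj).T)
        np.minimum(best, d, out=best)
    return best


def path_error(traj: Trajectory, ref: ReferencePath, split_time: float
               ) -> tuple[PerformanceScore, PerformanceScore]:
    """Per-sample Euclidean distance to the reference path, pre and post.

    The local error at each recorded cursor position is the distance to the
    nearest point anywhere on the polyline; the period score sums the local
    errors, and the mean per sample is reported alongside (a sampling-rate-
    independent summary on the same screen-unit scale).
    """
    if traj.xy.size == 0 or ref.vertices.size == 0:
        raise DataError("empty trajectory or reference path")
    t = np.arange(traj.xy.shape[0]) / traj.fs
    errors = point_to_polyline(traj.xy, ref.vertices)
    out = []
    for period, sel in (("pre", t < split_time), ("post", t >= split_time)):
        e = errors[sel]
        out.append(PerformanceScore(period, e, float(e.sum()),
                                    float(e.mean()) if e.size else float("nan")))
    return tuple(out)


def behavior_table(dyads: list[dict], split_time: float):
    """Long-format behavioral feature table.

    ``dyads`` holds dicts with keys ``dyad_id, group, guide, drawer, traj,
    ref`` (speech series and geometry).  Returns one row per (dyad, period)
    with total speaking time, speech ratio, and error scores.
    """
    import pandas as pd

    rows = []
    for d in dyads:
        comm = comm_features(d["guide"], d["drawer"], split_time)
        perf = path_error(d["traj"], d["ref"], split_time)
        for c, p in zip(comm, perf):
            rows.append({
                "dyad_id": d["dyad_id"], "group": d["group"],
                "period": c.period,
                "total_speaking_time": c.total_speaking_time,
                "speech_ratio": c.speech_ratio,
                "speech_ratio_valid": c.valid,
                "sum_error": p.sum_error, "mean_error": p.mean_error,
            })
    return pd.DataFrame(rows)
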