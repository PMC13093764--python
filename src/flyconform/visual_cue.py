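"""Per-frame visual cue from neighbors in the forward 180° sector.

The visual cue of a focal individual at a frame is the summed movement of all
other individuals located in the half-plane ahead of the focal heading, each
weighted by its apparent angular size:

    cue_f(t) = sum_{i != f, forward} speed_i(t) * 2*arctan( w / (2 * d_fi(t)) )

where ``w`` is the projected body width (the 3.0 mm major axis of the ellipse
body model; the 1.5 mm minor axis is stored but does not enter the cue) and
``d_fi`` is the focal-to-neighbor distance. Neighbors behind the focal
contribute nothing; the 90° boundary is inclusive, so the sector is exactly a
half-plane. For the downstream regression the raw cue is made strictly
positive (zeros replaced by the stratum's minimum non-zero value),
log-transformed, and z-scored within species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GroupRecording

__all__ = [
    "CueConfig",
    "KinematicsSeries",
    "CueSeries",
    "compute_kinematics",
    "angular_size",
    "in_forward_sector",
    "compute_cue",
    "transform_cue",
    "transform_cues",
    "cue_table",
]

# Numerical floor on distances inside angular_size itself: keeps the angular
# term finite (< pi) at coincident points without ever raising.
_DISTANCE_EPS_MM = 1e-12


@dataclass(frozen=True)
class CueConfig:
    """Parameters of the cue computation and its transform.

    body_major_mm / body_minor_mm
        Ellipse body model; the major axis is the projected width used in the
        angular term for every neighbor regardless of its orientation.
    distance_clamp_mm
        Distances below this are clamped before the angular term, preventing
        unbounded terms from tracking jitter; defaults to the minor semi-axis.
    heading_source
        'displacement' derives heading from the displacement vector (default);
        'file' uses the tracker heading column when present.
    stationary_epsilon_mm
        Displacements at or below this leave the heading unchanged
        (carry-forward).
    standardize_pool
        'stratum' z-scores within species x group-type; 'species' pools both
        group types per species.
    """

    body_major_mm: float = 3.0
    body_minor_mm: float = 1.5
    distance_clamp_mm: float = 0.75
    heading_source: str = "displacement"
    stationary_epsilon_mm: float = 1e-6
    standardize_pool: str = "stratum"

    def __post_init__(self) -> None:
        if self.heading_source not in ("displacement", "file"):
            raise ValueError(f"unknown heading_source {self.heading_source!r}")
        if self.standardize_pool not in ("stratum", "species"):
            raise ValueError(f"unknown standardize_pool {self.standardize_pool!r}")


@dataclass(frozen=True)
class KinematicsSeries:
    """Per-frame speed (mm/s) and heading (rad) for every individual.

    Arrays have shape (n_frames, n_individuals) in the recording's trajectory
    order. Speeds come from forward differences; the last frame carries the
    previous value so speed stays frame-aligned with the cue. Headings follow
    the displacement direction, carried forward through stationary frames.
    """

    speed_mm_s: np.ndarray
    heading_rad: np.ndarray
    individual_ids: tuple[str, ...]

    @property
    def n_frames(self) -> int:
        return int(self.speed_mm_s.shape[0])


@dataclass(frozen=True)
class CueSeries:
    """Raw and (optionally) transformed visual cue, (n_frames, n_individuals)."""

    raw_cue: np.ndarray
    individual_ids: tuple[str, ...]
    transformed_cue: np.ndarray | None = None
    body_major_mm: float = 3.0
    body_minor_mm: float = 1.5

    @property
    def n_frames(self) -> int:
        return int(self.raw_cue.shape[0])


def compute_kinematics(
    rec: GroupRecording, config: CueConfig = CueConfig()
) -> KinematicsSeries:
    """Derive speed and heading series from a recording's coordinates.

    Speed at frame t is the displacement t -> t+1 divided by the frame
    interval; the final frame repeats the previous speed. Heading is the
    direction of that displacement; when the displacement magnitude is at or
    below ``stationary_epsilon_mm`` the last defined heading is carried
    forward, and initial undefined frames are backfilled from the first
    defined one (an individual that never moves gets heading 0).
    """
    if rec.n_frames < 2:
        raise ValueError("compute_kinematics requires a recording with >= 2 frames")
    pos = rec.positions_array()  # (T, N, 2)
    dt = rec.arena.frame_interval_s
    disp = np.diff(pos, axis=0)  # (T-1, N, 2)
    step = np.hypot(disp[..., 0], disp[..., 1])  # (T-1, N)
    speed = np.vstack([step, step[-1:]]) / dt  # (T, N)

    if config.heading_source == "file" and all(
        t.heading_rad is not None for t in rec.trajectories
    ):
        heading = np.stack([t.heading_rad for t in rec.trajectories], axis=1)
        return KinematicsSeries(speed, heading, tuple(rec.individual_ids))

    moved = step > config.stationary_epsilon_mm
    raw_heading = np.arctan2(disp[..., 1], disp[..., 0])  # (T-1, N)
    T, N = pos.shape[0], pos.shape[1]
    heading = np.zeros((T, N))
    for j in range(N):
        idx = np.flatnonzero(moved[:, j])
        if idx.size == 0:
            continue
        h = np.empty(T)
        # heading at frame t describes the step t -> t+1; carry forward after,
        # backfill before the first defined value
        h[:] = np.nan
        h[idx] = raw_heading[idx, j]
        filled = pd.Series(h).ffill().bfill().to_numpy()
        heading[:, j] = filled
    return KinematicsSeries(speed, heading, tuple(rec.individual_ids))


def angular_size(
    distance_mm: float | np.ndarray, body_major_mm: float = 3.0
) -> float | np.ndarray:
    """Apparent angular size 2*arctan(w / (2 d)) of a body of width w at distance d.

    Strictly decreasing in distance and bounded in (0, pi); non-positive
    distances are floored to a tiny value (giving a value approaching pi)
    rather than raising.
    """
    d = np.maximum(np.asarray(distance_mm, dtype=float), _DISTANCE_EPS_MM)
    out = 2.0 * np.arctan(body_major_mm / (2.0 * d))
    return float(out) if np.isscalar(distance_mm) else out


def in_forward_sector(
    focal_heading: float, focal_pos: Sequence[float], other_pos: Sequence[float]
) -> bool:
    """True iff ``other_pos`` lies in the closed half-plane ahead of the focal.

    The boundary at exactly 90° from the heading is inclusive (dot product
    >= 0), so the sector covers exactly 180°.
    """
    dx = other_pos[0] - focal_pos[0]
    dy = other_pos[1] - focal_pos[1]
    return bool(np.cos(focal_heading) * dx + np.sin(focal_heading) * dy >= 0.0)


def compute_cue(
    rec: GroupRecording,
    kin: KinematicsSeries,
    config: CueConfig = CueConfig(),
) -> CueSeries:
    """Raw visual cue per focal individual and frame (vectorized over pairs).

    For each focal f and frame t the cue sums, over every other individual i
    in f's forward sector, ``speed_i(t) * angular_size(distance(f, i, t))``.
    Distances below ``distance_clamp_mm`` (coincident detections included) are
    clamped before the angular term.
    """
    pos = rec.positions_array()  # (T, N, 2)
    T, N = pos.shape[0], pos.shape[1]
    if kin.speed_mm_s.shape != (T, N):
        raise ValueError("kinematics not aligned with recording")

    # pairwise focal -> other vectors per frame: (T, focal, other, 2)
    rel = pos[:, None, :, :] - pos[:, :, None, :]
    dist = np.hypot(rel[..., 0], rel[..., 1])
    np.maximum(dist, config.distance_clamp_mm, out=dist)
    ang = 2.0 * np.arctan(config.body_major_mm / (2.0 * dist))

    hx = np.cos(kin.heading_rad)  # (T, N)
    hy = np.sin(kin.heading_rad)
    forward = hx[:, :, None] * rel[..., 0] + hy[:, :, None] * rel[..., 1] >= 0.0

    terms = kin.speed_mm_s[:, None, :] * ang * forward  # (T, focal, other)
    idx = np.arange(N)
    terms[:, idx, idx] = 0.0  # exclude self
    raw = terms.sum(axis=2)
    return CueSeries(
        raw_cue=raw,
        individual_ids=tuple(rec.individual_ids),
        body_major_mm=config.body_major_mm,
        body_minor_mm=config.body_minor_mm,
    )


def _log_standardize(values: np.ndarray) -> tuple[np.ndarray, dict]:
    """Zero-offset + natural log + z-score for one standardization stratum.

    Zero observations are replaced by the stratum's minimum non-zero value
    before the log; the z-score uses the stratum mean and (population) sd.
    """
    v = np.asarray(values, dtype=float)
    positive = v[v > 0]
    if positive.size == 0:
        raise ValueError("all-zero cue series in stratum: zero offset undefined")
    m = positive.min()
    logged = np.log(np.where(v > 0, v, m))
    mu = logged.mean()
    sd = logged.std()
    if sd == 0:
        raise ValueError("cue has zero variance in stratum after transform")
    return (logged - mu) / sd, {"offset": float(m), "mean": float(mu), "sd": float(sd)}


def transform_cues(
    pairs: Iterable[tuple[GroupRecording, CueSeries]],
    config: CueConfig = CueConfig(),
) -> list[CueSeries]:
    """Apply the zero-offset/log/z-score transform across recordings.

    Standardization strata pool all individuals x frames of a species across
    the given recordings — within species x group-type by default, or within
    species only when ``standardize_pool='species'``.
    """
    pairs = list(pairs)
    strata: dict[tuple, list[tuple[int, int]]] = {}
    for r, (rec, cues) in enumerate(pairs):
        if cues.raw_cue.shape[1] != rec.n_individuals:
            raise ValueError("cue series not aligned with recording")
        for j, sp in enumerate(rec.species):
            key = (sp,) if config.standardize_pool == "species" else (sp, rec.group_type)
            strata.setdefault(key, []).append((r, j))

    transformed = [np.empty_like(c.raw_cue) for _, c in pairs]
    for key, members in strata.items():
        pooled = np.concatenate(
            [pairs[r][1].raw_cue[:, j] for r, j in members]
        )
        z, _ = _log_standardize(pooled)
        offset = 0
        for r, j in members:
            T = pairs[r][1].n_frames
            transformed[r][:, j] = z[offset : offset + T]
            offset += T

    return [
        CueSeries(
            raw_cue=c.raw_cue,
            individual_ids=c.individual_ids,
            transformed_cue=transformed[r],
            body_major_mm=c.body_major_mm,
            body_minor_mm=c.body_minor_mm,
        )
        for r, (_, c) in enumerate(pairs)
    ]


def transform_cue(
    cues: CueSeries,
    rec: GroupRecording,
    config: CueConfig = CueConfig(),
) -> CueSeries:
    """Single-recording convenience wrapper around :func:`transform_cues`."""
    return transform_cues([(rec, cues)], config)[0]


def cue_table(rec: GroupRecording, cues: CueSeries) -> pd.DataFrame:
    """Long-format cue table: (individual_id, frame, raw_cue[, transformed_cue])."""
    T, N = cues.raw_cue.shape
    d = pd.DataFrame(
        {
            "individual_id": np.repeat(cues.individual_ids, T),
            "frame": np.tile(np.arange(T), N),
            "raw_cue": cues.raw_cue.T.ravel(),
        }
    )
    if cues.transformed_cue is not None:
        d["transformed_cue"] = cues.transformed_cue.T.ravel()
    return d
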