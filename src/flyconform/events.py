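"""Walk/stationary state segmentation and locomotion-event labeling.

Each individual's speed series is thresholded into a two-state
walking/stationary sequence (with optional absorption of sub-minimum bouts),
and the four locomotion events are labeled on top of it:

* ``walk``   — the frame immediately preceding a stationary -> walking transition
* ``stop``   — the frame immediately preceding a walking -> stationary transition
* ``walking``— walking frames outside those transition frames
* ``stay``   — stationary frames outside those transition frames

If individuals conform to the activity of those around them, the visual cue
should rise going into ``walk`` frames and fall after ``stop`` frames; the
event-aligned cue summaries and the paired sign-flip permutation contrast
below quantify that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GroupRecording
from .visual_cue import CueSeries

__all__ = [
    "StateConfig",
    "StateSeries",
    "ContrastResult",
    "classify_states",
    "label_events",
    "compute_states",
    "event_aligned_cues",
    "event_contrast",
]

STATIONARY, WALKING = 0, 1
EVENT_TYPES = ("stay", "walk", "walking", "stop")


@dataclass(frozen=True)
class StateConfig:
    """Walking-speed threshold (mm/s) and minimum bout length (frames)."""

    walk_threshold_mm_s: float = 2.0
    min_bout_frames: int = 1

    def __post_init__(self) -> None:
        if self.walk_threshold_mm_s <= 0:
            raise ValueError("walk_threshold_mm_s must be positive")
        if self.min_bout_frames < 1:
            raise ValueError("min_bout_frames must be >= 1")


@dataclass(frozen=True)
class StateSeries:
    """Per-frame binary state and event labels, (n_frames, n_individuals)."""

    state: np.ndarray  # int {STATIONARY, WALKING}
    event: np.ndarray  # str in EVENT_TYPES
    individual_ids: tuple[str, ...]
    config: StateConfig


@dataclass(frozen=True)
class ContrastResult:
    """Paired event contrast with a sign-flip permutation p-value."""

    pair: tuple[str, str]
    estimate: float  # mean over individuals of (cue at second - cue at first)
    p_raw: float
    p_bonferroni: float
    n_individuals: int
    n_perm: int
    seed: int


def _runs(x: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a 1D array: list of (value, start, length)."""
    out = []
    start = 0
    for i in range(1, len(x) + 1):
        if i == len(x) or x[i] != x[start]:
            out.append((int(x[start]), start, i - start))
            start = i
    return out


def classify_states(
    speed_mm_s: np.ndarray,
    walk_threshold_mm_s: float = 2.0,
    min_bout_frames: int = 1,
) -> np.ndarray:
    """Threshold a speed series into {stationary, walking} with bout absorption.

    A frame is walking iff speed >= threshold. Runs shorter than
    ``min_bout_frames`` are then absorbed into the preceding state in a single
    left-to-right pass (the first run is exempt — there is no preceding state
    to absorb it into). Absorption merges runs, so a later short run is judged
    against the already-merged sequence; the pass is deterministic.
    """
    speed = np.asarray(speed_mm_s, dtype=float)
    if speed.ndim != 1 or speed.size == 0:
        raise ValueError("speed series must be a non-empty 1D array")
    states = np.where(speed >= walk_threshold_mm_s, WALKING, STATIONARY)
    if min_bout_frames <= 1:
        return states

    merged: list[list[int]] = []  # [value, length]
    for value, _, length in _runs(states):
        if merged and value == merged[-1][0]:
            merged[-1][1] += length
        elif merged and length < min_bout_frames:
            merged[-1][1] += length  # absorb into preceding state
        else:
            merged.append([value, length])
    return np.repeat([v for v, _ in merged], [n for _, n in merged])


def label_events(states: np.ndarray) -> np.ndarray:
    """Label each frame stay/walk/walking/stop from the binary state series.

    A stationary frame directly followed by a walking frame is ``walk``; a
    walking frame directly followed by a stationary frame is ``stop``; the
    remaining frames keep their state's resting label. The final frame has no
    successor and can never be ``walk`` or ``stop``.
    """
    s = np.asarray(states)
    events = np.where(s == WALKING, "walking", "stay").astype(object)
    if len(s) > 1:
        nxt = s[1:]
        cur = s[:-1]
        events[:-1][(cur == STATIONARY) & (nxt == WALKING)] = "walk"
        events[:-1][(cur == WALKING) & (nxt == STATIONARY)] = "stop"
    return events.astype("U7")


def compute_states(
    rec: GroupRecording,
    speed_mm_s: np.ndarray,
    config: StateConfig = StateConfig(),
) -> StateSeries:
    """Segment every individual's speed column and label its events."""
    T, N = speed_mm_s.shape
    state = np.empty((T, N), dtype=int)
    event = np.empty((T, N), dtype="U7")
    for j in range(N):
        state[:, j] = classify_states(
            speed_mm_s[:, j], config.walk_threshold_mm_s, config.min_bout_frames
        )
        event[:, j] = label_events(state[:, j])
    return StateSeries(state, event, tuple(rec.individual_ids), config)


def event_aligned_cues(
    cues: CueSeries, states: StateSeries, rec: GroupRecording
) -> pd.DataFrame:
    """Per-individual mean transformed cue at each event type.

    Returns one row per (individual, event type) with the frame count and the
    mean transformed cue over the frames carrying that label; individuals with
    zero frames of an event type get n_frames=0 and a NaN mean (flagged, not
    an error). The pooled distribution for any event type can be recovered by
    weighting the per-individual means by n_frames, or by masking the cue
    array with ``states.event`` directly.
    """
    if cues.transformed_cue is None:
        raise ValueError("event_aligned_cues requires a transformed CueSeries")
    z = cues.transformed_cue
    rows = []
    species = dict(zip(rec.individual_ids, rec.species))
    strain = {t.individual_id: t.strain for t in rec.trajectories}
    for j, ind in enumerate(states.individual_ids):
        for ev in EVENT_TYPES:
            mask = states.event[:, j] == ev
            n = int(mask.sum())
            rows.append(
                {
                    "individual_id": ind,
                    "species": species[ind],
                    "strain": strain[ind],
                    "event_type": ev,
                    "n_frames": n,
                    "mean_transformed_cue": float(z[mask, j].mean()) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def event_contrast(
    aligned: pd.DataFrame,
    pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    n_contrasts: int = 1,
) -> ContrastResult:
    """Paired contrast of per-individual mean cues between two event types.

    The statistic is the mean over individuals of (mean cue at ``pair[1]`` −
    mean cue at ``pair[0]``), restricted to individuals observed in both
    states. The null distribution flips the sign of each individual's
    difference independently (the per-individual pairing makes the flip
    exchangeable under the no-difference null); the two-sided p-value uses the
    add-one permutation estimator. Bonferroni multiplies by ``n_contrasts``,
    capped at 1.
    """
    a, b = pair
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    wide = aligned.pivot_table(
        index="individual_id", columns="event_type", values="mean_transformed_cue"
    )
    missing = [e for e in pair if e not in wide.columns]
    if missing:
        raise ValueError(f"no individual has events of type {missing}")
    diffs = (wide[b] - wide[a]).dropna().to_numpy()
    if diffs.size < 2:
        raise ValueError(
            f"contrast {pair} needs >= 2 individuals with both event types, "
            f"got {diffs.size}"
        )
    observed = diffs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = (signs * diffs).mean(axis=1)
    p_raw = (1 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_perm + 1)
    return ContrastResult(
        pair=(a, b),
        estimate=float(observed),
        p_raw=float(p_raw),
        p_bonferroni=float(min(1.0, p_raw * n_contrasts)),
        n_individuals=int(diffs.size),
        n_perm=int(n_perm),
        seed=int(seed),
    )
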