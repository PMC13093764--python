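"""Core data types and tabular trajectory I/O.

The atomic analysis unit is a :class:`GroupRecording`: the 2D trajectories of
every individual in one arena run, plus per-individual species/strain labels
and group-level metadata (single- vs. mixed-species composition, replicate id).

Trajectory files are neutral long-format delimited text with a header row and
columns ``frame, individual_id, x_mm, y_mm`` (optionally ``heading_rad``) —
tracker-agnostic by design; converting tracker-specific exports into this
dialect is out of scope. Coordinates are in millimetres with the origin at the
arena center, frame indices are 0-based, and time windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "GroupRecording",
    "read_recording",
    "write_recording",
    "read_metadata",
    "write_metadata",
    "clip_to_analysis_window",
]

#: Slack (mm) allowed beyond the arena radius before a coordinate is rejected,
#: absorbing tracker edge jitter on walls.
ARENA_RADIUS_TOLERANCE_MM = 2.0

GROUP_TYPES = ("single", "mixed")

TRAJECTORY_COLUMNS = ("frame", "individual_id", "x_mm", "y_mm")


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and the timing of the analysis window.

    Defaults match a 140 mm circular arena recorded at one analysis frame per
    0.5 s for 60 min, of which the final 30 min (1800–3600 s) are analyzed;
    the first half is an acclimation period.
    """

    diameter_mm: float = 140.0
    frame_interval_s: float = 0.5
    analysis_start_s: float = 1800.0
    analysis_end_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")
        if self.frame_interval_s <= 0:
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        if self.analysis_start_s < 0:
            raise ValueError(
                f"analysis_start_s must be >= 0, got {self.analysis_start_s}"
            )
        if self.analysis_end_s <= self.analysis_start_s:
            raise ValueError(
                "analysis_end_s must exceed analysis_start_s "
                f"({self.analysis_end_s} <= {self.analysis_start_s})"
            )

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def analysis_frames(self) -> tuple[int, int]:
        """Half-open frame range [start, end) of the analysis window."""
        start = int(round(self.analysis_start_s / self.frame_interval_s))
        end = int(round(self.analysis_end_s / self.frame_interval_s))
        return start, end


@dataclass(frozen=True)
class Trajectory:
    """One individual's positions over the recording, with identity labels."""

    individual_id: str
    species: str
    strain: str
    positions: np.ndarray  # (n_frames, 2) float64, mm
    heading_rad: np.ndarray | None = None  # optional (n_frames,) tracker heading

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError(
                f"positions must have shape (n_frames, 2), got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            bad = int(np.flatnonzero(~np.isfinite(pos).all(axis=1))[0])
            raise ValueError(
                f"non-finite coordinate for individual {self.individual_id!r} "
                f"at frame {bad}"
            )
        object.__setattr__(self, "positions", pos)
        if self.heading_rad is not None:
            h = np.asarray(self.heading_rad, dtype=float)
            if h.shape != (pos.shape[0],):
                raise ValueError(
                    f"heading_rad must have shape ({pos.shape[0]},), got {h.shape}"
                )
            object.__setattr__(self, "heading_rad", h)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])


@dataclass(frozen=True)
class GroupRecording:
    """All trajectories of one arena run plus group metadata."""

    arena: ArenaConfig
    trajectories: tuple[Trajectory, ...]
    group_type: str
    replicate_id: str = "r0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        if not self.trajectories:
            raise ValueError("GroupRecording requires at least one trajectory")
        if self.group_type not in GROUP_TYPES:
            raise ValueError(
                f"group_type must be one of {GROUP_TYPES}, got {self.group_type!r}"
            )
        lengths = {t.n_frames for t in self.trajectories}
        if len(lengths) != 1:
            raise ValueError(
                f"all trajectories must share n_frames, got lengths {sorted(lengths)}"
            )
        ids = [t.individual_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual_id in recording")
        species = sorted({t.species for t in self.trajectories})
        if self.group_type == "single" and len(species) != 1:
            raise ValueError(
                f"single-species group must contain exactly 1 species, got {species}"
            )
        if self.group_type == "mixed":
            if len(species) != 2:
                raise ValueError(
                    f"mixed group must contain exactly 2 species, got {species}"
                )
            counts = {
                sp: sum(t.species == sp for t in self.trajectories) for sp in species
            }
            if len(set(counts.values())) != 1:
                raise ValueError(
                    f"mixed group requires equal species counts, got {counts}"
                )
        limit = self.arena.radius_mm + ARENA_RADIUS_TOLERANCE_MM
        for t in self.trajectories:
            r = np.hypot(t.positions[:, 0], t.positions[:, 1])
            if np.any(r > limit):
                bad = int(np.argmax(r > limit))
                raise ValueError(
                    f"individual {t.individual_id!r} outside arena at frame {bad} "
                    f"(radius {r[bad]:.2f} mm > {limit:.2f} mm)"
                )

    @property
    def n_frames(self) -> int:
        return self.trajectories[0].n_frames

    @property
    def n_individuals(self) -> int:
        return len(self.trajectories)

    @property
    def individual_ids(self) -> list[str]:
        return [t.individual_id for t in self.trajectories]

    @property
    def species(self) -> list[str]:
        """Per-individual species labels, in trajectory order."""
        return [t.species for t in self.trajectories]

    @property
    def species_present(self) -> list[str]:
        return sorted({t.species for t in self.trajectories})

    def positions_array(self) -> np.ndarray:
        """Stacked positions, shape (n_frames, n_individuals, 2)."""
        return np.stack([t.positions for t in self.trajectories], axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table in the on-disk dialect, sorted (individual, frame)."""
        parts = []
        for t in self.trajectories:
            d = pd.DataFrame(
                {
                    "frame": np.arange(t.n_frames, dtype=int),
                    "individual_id": t.individual_id,
                    "x_mm": t.positions[:, 0],
                    "y_mm": t.positions[:, 1],
                }
            )
            if t.heading_rad is not None:
                d["heading_rad"] = t.heading_rad
            parts.append(d)
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["individual_id", "frame"], kind="stable").reset_index(
            drop=True
        )

    def metadata(self) -> dict:
        """Group metadata in the flat key-value form the readers accept."""
        return {
            "group_type": self.group_type,
            "replicate_id": self.replicate_id,
            "individuals": {
                t.individual_id: {"species": t.species, "strain": t.strain}
                for t in self.trajectories
            },
            "arena": {
                "diameter_mm": self.arena.diameter_mm,
                "frame_interval_s": self.arena.frame_interval_s,
                "analysis_start_s": self.arena.analysis_start_s,
                "analysis_end_s": self.arena.analysis_end_s,
            },
        }


def _normalize_metadata(metadata: Mapping | str | Path) -> dict:
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)
    meta = dict(metadata)
    if "individuals" not in meta:
        raise ValueError("metadata must contain an 'individuals' mapping")
    if "group_type" not in meta:
        raise ValueError("metadata must contain 'group_type'")
    return meta


def read_metadata(path: str | Path) -> dict:
    """Read the flat YAML metadata file for a recording."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_metadata(metadata: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(metadata), fh, sort_keys=True)
    return path


def read_recording(
    trajectory_file: str | Path,
    metadata: Mapping | str | Path,
    arena: ArenaConfig | None = None,
) -> GroupRecording:
    """Read a delimited trajectory file plus metadata into a GroupRecording.

    The file must be TSV or CSV with a header row and columns
    ``frame, individual_id, x_mm, y_mm`` (optional ``heading_rad``). Every
    individual must be present at every frame: missing frames are an error,
    never interpolated. Frames are re-indexed contiguously from 0.

    Parameters
    ----------
    trajectory_file
        Path to the delimited text file.
    metadata
        Mapping (or path to a YAML file) with keys ``group_type``,
        ``replicate_id`` and ``individuals`` (individual_id -> species/strain);
        may carry an ``arena`` section.
    arena
        Overrides any arena section in the metadata.
    """
    meta = _normalize_metadata(metadata)
    if arena is None:
        arena = ArenaConfig(**meta.get("arena", {}))

    sep = "\t" if str(trajectory_file).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        trajectory_file, sep=sep, comment="#", float_precision="round_trip"
    )
    missing_cols = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"trajectory file missing columns {sorted(missing_cols)}")
    df["individual_id"] = df["individual_id"].astype(str)
    df = df.sort_values(["individual_id", "frame"], kind="stable")

    frames = np.sort(df["frame"].unique())
    frame_index = {f: i for i, f in enumerate(frames)}
    n_frames = len(frames)

    indiv_meta = {str(k): v for k, v in meta["individuals"].items()}
    has_heading = "heading_rad" in df.columns

    trajectories = []
    for ind, sub in df.groupby("individual_id", sort=True):
        if ind not in indiv_meta:
            raise ValueError(f"metadata missing species/strain for individual {ind!r}")
        got = set(sub["frame"])
        if len(got) != n_frames or len(sub) != n_frames:
            absent = sorted(set(frames) - got)
            where = absent[0] if absent else "duplicate frames"
            raise ValueError(
                f"individual {ind!r} missing at frame {where} "
                f"({len(got)} of {n_frames} frames present)"
            )
        # re-index contiguously from 0
        order = np.argsort([frame_index[f] for f in sub["frame"]], kind="stable")
        sub = sub.iloc[order]
        info = indiv_meta[ind]
        trajectories.append(
            Trajectory(
                individual_id=str(ind),
                species=str(info["species"]),
                strain=str(info.get("strain", "na")),
                positions=np.column_stack([sub["x_mm"], sub["y_mm"]]),
                heading_rad=sub["heading_rad"].to_numpy() if has_heading else None,
            )
        )

    return GroupRecording(
        arena=arena,
        trajectories=tuple(trajectories),
        group_type=str(meta["group_type"]),
        replicate_id=str(meta.get("replicate_id", "r0")),
    )


def write_recording(
    rec: GroupRecording,
    path: str | Path,
    metadata_path: str | Path | None = None,
    float_format: str | None = None,
) -> Path:
    """Write a recording as TSV in the dialect :func:`read_recording` accepts.

    Row order is (individual_id, frame), column order fixed. By default
    floats use the shortest exact decimal representation, so the write/read
    round trip reproduces coordinates bit-exactly. If ``metadata_path`` is
    given the group metadata is written there as YAML.
    """
    path = Path(path)
    df = rec.to_frame()
    buf = _stdio.StringIO()
    if float_format is None:
        # shortest decimal that round-trips to the same float64
        float_format = lambda x: repr(float(x))  # noqa: E731
    df.to_csv(buf, sep="\t", index=False, float_format=float_format)
    path.write_text(buf.getvalue())
    if metadata_path is not None:
        write_metadata(rec.metadata(), metadata_path)
    return path


def clip_to_analysis_window(rec: GroupRecording) -> GroupRecording:
    """Restrict a recording to its arena's analysis window.

    Keeps frames in the half-open window ``[analysis_start_s, analysis_end_s)``
    and re-zeroes frame indices; the returned recording's arena has its window
    re-anchored at 0 so clipping is idempotent.
    """
    start, end = rec.arena.analysis_frames
    if rec.n_frames < end:
        raise ValueError(
            f"recording has {rec.n_frames} frames but the analysis window "
            f"requires frames [{start}, {end})"
        )
    duration = rec.arena.analysis_end_s - rec.arena.analysis_start_s
    new_arena = replace(rec.arena, analysis_start_s=0.0, analysis_end_s=duration)
    new_trajs = tuple(
        replace(
            t,
            positions=t.positions[start:end].copy(),
            heading_rad=None if t.heading_rad is None else t.heading_rad[start:end].copy(),
        )
        for t in rec.trajectories
    )
    return GroupRecording(
        arena=new_arena,
        trajectories=new_trajs,
        group_type=rec.group_type,
        replicate_id=rec.replicate_id,
    )
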