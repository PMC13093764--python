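"""End-to-end orchestration: recordings -> cues -> events -> conformity report.

A run is fully described by a :class:`RunConfig` (input recordings, every
module parameter, seed, output directory); the config is echoed verbatim into
a header comment block of every output table, so each report is
self-describing and a run is reproducible byte-for-byte from its config and
seed. Stages per recording: clip to the analysis window -> kinematics -> raw
cue; then cue standardization pooled across recordings (per species x
group-type stratum); then state segmentation, event labeling, event-aligned
cue summaries and cue-sensitivity regressions per recording; finally the
cross-recording statistics (event contrasts, species- and group-level
conformity, sensitivity comparisons).
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformity as _conf
from . import events as _events
from . import visual_cue as _vc
from .events import StateConfig
from .io import GroupRecording, clip_to_analysis_window, read_recording
from .visual_cue import CueConfig

__all__ = [
    "RunConfig",
    "ReportBundle",
    "load_recordings",
    "analyze_recordings",
    "run_pipeline",
    "summarize",
]

EVENT_CONTRAST_PAIRS = (
    ("stay", "walk"),
    ("walk", "walking"),
    ("walking", "stop"),
    ("stop", "stay"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    ``recordings`` is a list of ``{"trajectory": path, "metadata": path}``
    mappings (paths relative to ``base_dir`` if given). Unset parameters take
    the documented module defaults.
    """

    recordings: tuple = ()
    out_dir: str = "flyconform_out"
    base_dir: str = ""
    cue: CueConfig = CueConfig()
    states: StateConfig = StateConfig()
    lag_frames: int = 1
    n_perm: int = 1000
    seed: int = 0
    write_stage_tables: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recordings"] = [dict(r) for r in self.recordings]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cue" in d and isinstance(d["cue"], dict):
            d["cue"] = CueConfig(**d["cue"])
        if "states" in d and isinstance(d["states"], dict):
            d["states"] = StateConfig(**d["states"])
        d["recordings"] = tuple(
            {k: str(v) for k, v in r.items()} for r in d.get("recordings", ())
        )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(d)
        if not cfg.base_dir:
            cfg = dataclasses.replace(cfg, base_dir=str(Path(path).parent))
        return cfg


@dataclass
class ReportBundle:
    """All tables a pipeline run produces, plus the config and stage counts."""

    config: RunConfig
    labels: list[str]
    mean_speeds: pd.DataFrame
    event_summary: pd.DataFrame
    contrasts: pd.DataFrame
    sensitivity: pd.DataFrame
    species_conformity: pd.DataFrame | None
    group_conformity: pd.DataFrame | None
    sensitivity_tests: pd.DataFrame | None
    counts: dict


def load_recordings(config: RunConfig) -> tuple[list[GroupRecording], list[str]]:
    """Read every recording in the config's manifest; returns (recordings, labels)."""
    if not config.recordings:
        raise ValueError("config lists no recordings")
    base = Path(config.base_dir) if config.base_dir else Path(".")
    recs, labels = [], []
    for i, entry in enumerate(config.recordings):
        traj = base / entry["trajectory"]
        meta = base / entry["metadata"]
        label = entry.get("label", Path(entry["trajectory"]).stem)
        try:
            recs.append(read_recording(traj, meta))
        except Exception as exc:
            raise RuntimeError(f"recording {label!r}: read stage failed: {exc}") from exc
        labels.append(label)
    return recs, labels


def _recording_label(rec: GroupRecording, idx: int) -> str:
    sp = "+".join(rec.species_present)
    return f"{rec.group_type}_{sp}_{rec.replicate_id}_{idx:02d}"


def analyze_recordings(
    recs: list[GroupRecording],
    config: RunConfig = RunConfig(),
    labels: list[str] | None = None,
) -> ReportBundle:
    """Run the full analysis on in-memory recordings (no disk I/O)."""
    if not recs:
        raise ValueError("no recordings to analyze")
    if labels is None:
        labels = [_recording_label(r, i) for i, r in enumerate(recs)]

    counts: dict = {"n_recordings": len(recs)}
    clipped, kins, raw_cues = [], [], []
    for label, rec in zip(labels, recs):
        try:
            c = clip_to_analysis_window(rec)
            k = _vc.compute_kinematics(c, config.cue)
            raw = _vc.compute_cue(c, k, config.cue)
        except Exception as exc:
            raise RuntimeError(f"recording {label!r}: cue stage failed: {exc}") from exc
        clipped.append(c)
        kins.append(k)
        raw_cues.append(raw)

    cues = _vc.transform_cues(zip(clipped, raw_cues), config.cue)

    mean_speed_parts, event_parts, sens_parts = [], [], []
    states_by_rec = []
    for label, rec, kin, cue in zip(labels, clipped, kins, cues):
        try:
            st = _events.compute_states(rec, kin.speed_mm_s, config.states)
            aligned = _events.event_aligned_cues(cue, st, rec)
            sens = _conf.sensitivity_table(rec, kin, cue, config.lag_frames)
            speeds = _conf.individual_mean_speeds(rec, kin)
        except Exception as exc:
            raise RuntimeError(
                f"recording {label!r}: event/sensitivity stage failed: {exc}"
            ) from exc
        for d in (aligned, sens, speeds):
            d.insert(0, "recording", label)
        states_by_rec.append(st)
        event_parts.append(aligned)
        sens_parts.append(sens)
        mean_speed_parts.append(speeds)

    mean_speeds = pd.concat(mean_speed_parts, ignore_index=True)
    event_summary = pd.concat(event_parts, ignore_index=True)
    sensitivity = pd.concat(sens_parts, ignore_index=True)
    counts["n_individuals"] = int(len(mean_speeds))
    counts["n_frames_analyzed"] = int(mean_speeds["n_frames"].sum())
    counts["event_frames"] = {
        ev: int(event_summary.loc[event_summary.event_type == ev, "n_frames"].sum())
        for ev in _events.EVENT_TYPES
    }

    # event contrasts per species, Bonferroni over the four requested pairs
    contrast_rows = []
    for sp, sub in event_summary.groupby("species"):
        for pair in EVENT_CONTRAST_PAIRS:
            try:
                res = _events.event_contrast(
                    sub, pair, n_perm=config.n_perm, seed=config.seed,
                    n_contrasts=len(EVENT_CONTRAST_PAIRS),
                )
            except ValueError:
                continue  # species lacks individuals with both event types
            contrast_rows.append(
                {
                    "species": sp,
                    "contrast": f"{pair[0]}->{pair[1]}",
                    "estimate": res.estimate,
                    "p_raw": res.p_raw,
                    "p_bonferroni": res.p_bonferroni,
                    "n_individuals": res.n_individuals,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
            )
    contrasts = pd.DataFrame(contrast_rows)

    single = mean_speeds[mean_speeds.group_type == "single"]
    mixed = mean_speeds[mean_speeds.group_type == "mixed"]

    species_conformity = None
    if not single.empty and not mixed.empty:
        common = set(single.species) & set(mixed.species)
        if common:
            species_conformity = _conf.species_level_conformity(
                single[single.species.isin(common)],
                mixed[mixed.species.isin(common)],
            ).drop(columns=["individual_rates"], errors="ignore")

    group_conformity = None
    if not mixed.empty and not single.empty:
        rows = []
        pairs = {
            tuple(sorted(set(mixed.loc[mixed.recording == lab, "species"])))
            for lab in mixed.recording.unique()
        }
        for sp_a, sp_b in sorted(p for p in pairs if len(p) == 2):
            sa = single[single.species == sp_a]
            sb = single[single.species == sp_b]
            ma = mixed[mixed.species == sp_a]
            mb = mixed[mixed.species == sp_b]
            if sa.empty or sb.empty:
                continue
            gc = _conf.group_level_conformity(
                sa, sb, ma, mb, n_perm=config.n_perm, seed=config.seed
            )
            rows.append(
                {
                    "species_a": sp_a,
                    "species_b": sp_b,
                    "delta_single": gc.delta_single,
                    "delta_mixed": gc.delta_mixed,
                    "reduction": gc.reduction,
                    "ratio": gc.ratio,
                    "p_value": gc.p_value,
                    "n_perm": gc.n_perm,
                    "seed": gc.seed,
                }
            )
        if rows:
            group_conformity = pd.DataFrame(rows)

    sensitivity_tests = None
    try:
        sensitivity_tests = _conf.sensitivity_comparison(
            sensitivity, n_perm=config.n_perm, seed=config.seed
        )
    except ValueError:
        pass  # a single homogeneous stratum: nothing to compare

    return ReportBundle(
        config=config,
        labels=list(labels),
        mean_speeds=mean_speeds,
        event_summary=event_summary,
        contrasts=contrasts,
        sensitivity=sensitivity,
        species_conformity=species_conformity,
        group_conformity=group_conformity,
        sensitivity_tests=sensitivity_tests,
        counts=counts,
    )


def _config_header(config: RunConfig) -> str:
    d = config.to_dict()
    # filesystem locations are not analysis parameters; keeping them out makes
    # re-runs of the same analysis byte-identical wherever they are written
    # (the verbatim config including paths is saved as run_config.yaml)
    d.pop("out_dir", None)
    d.pop("base_dir", None)
    lines = yaml.safe_dump(d, sort_keys=True).rstrip().splitlines()
    return "\n".join(f"# {line}" for line in ["flyconform run config:"] + lines) + "\n"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    buf = _stdio.StringIO()
    buf.write(_config_header(config))
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Load, analyze, and write the full report bundle under config.out_dir."""
    recs, labels = load_recordings(config)
    bundle = analyze_recordings(recs, config, labels)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    _write_table(bundle.mean_speeds, out / "mean_speeds.tsv", config)
    _write_table(bundle.event_summary, out / "event_summary.tsv", config)
    _write_table(bundle.contrasts, out / "contrasts.tsv", config)
    _write_table(bundle.sensitivity, out / "sensitivity.tsv", config)
    if bundle.species_conformity is not None or bundle.group_conformity is not None:
        report = _conformity_report_table(bundle)
        _write_table(report, out / "conformity_report.tsv", config)
    with open(out / "counts.yaml", "w") as fh:
        yaml.safe_dump(bundle.counts, fh, sort_keys=True)

    if config.write_stage_tables:
        stage_dir = out / "stages"
        stage_dir.mkdir(exist_ok=True)
        # per-recording per-individual event frame counts keep stage outputs
        # auditable without re-running the pipeline
        for label in bundle.labels:
            sub = bundle.event_summary[bundle.event_summary.recording == label]
            _write_table(
                sub, stage_dir / f"{label}_events.tsv", config
            )

    text, _ = summarize(bundle)
    (out / "summary.txt").write_text(text)
    return bundle


def _conformity_report_table(bundle: ReportBundle) -> pd.DataFrame:
    parts = []
    if bundle.species_conformity is not None:
        sc = bundle.species_conformity.copy()
        sc.insert(0, "section", "species_level")
        parts.append(sc)
    if bundle.group_conformity is not None:
        gc = bundle.group_conformity.copy()
        gc.insert(0, "section", "group_level")
        parts.append(gc)
    return pd.concat(parts, ignore_index=True)


def summarize(bundle: ReportBundle, n_boot: int = 1000) -> tuple[str, dict]:
    """Human-readable and machine-readable summary of a report bundle.

    Reports per-species mean speeds by group type, species-level conformity
    rates, group-level convergence ratios (flagged when the permutation test
    rejects at 0.05 and the ratio is < 1), and mean sensitivity slopes with
    seeded bootstrap confidence intervals over individuals.
    """
    if bundle.mean_speeds.empty:
        raise ValueError("cannot summarize an empty report bundle")
    rng = np.random.default_rng(bundle.config.seed)
    lines = ["flyconform summary", "=================="]
    machine: dict = {"per_species": {}, "convergence": [], "sensitivity": {}}

    speed_tab = (
        bundle.mean_speeds.groupby(["species", "group_type"])["mean_speed"]
        .agg(["mean", "count"])
        .reset_index()
    )
    lines.append("\nMean locomotive speed (mm/s, mean of per-individual means):")
    for _, row in speed_tab.iterrows():
        lines.append(
            f"  {row.species:<12} {row.group_type:<7} "
            f"{row['mean']:8.3f}  (n={int(row['count'])})"
        )
        machine["per_species"].setdefault(row.species, {})[row.group_type] = {
            "mean_speed": float(row["mean"]),
            "n": int(row["count"]),
        }

    if bundle.species_conformity is not None:
        lines.append("\nSpecies-level conformity (rate of change single -> mixed):")
        sp_rows = bundle.species_conformity
        for _, row in sp_rows[sp_rows.level == "species"].iterrows():
            lines.append(f"  {row.species:<12} rate = {row.rate_of_change:+.3f}")
            machine["per_species"].setdefault(row.species, {})[
                "rate_of_change"
            ] = float(row.rate_of_change)

    if bundle.group_conformity is not None:
        lines.append("\nGroup-level conformity (interspecific speed difference):")
        for _, row in bundle.group_conformity.iterrows():
            converged = row.ratio < 1 and (
                row.p_value is not None and row.p_value < 0.05
            )
            flag = "CONVERGENCE" if converged else "no convergence"
            lines.append(
                f"  {row.species_a} vs {row.species_b}: "
                f"delta_single={row.delta_single:.3f} "
                f"delta_mixed={row.delta_mixed:.3f} "
                f"ratio={row.ratio:.3f} p={row.p_value:.4g}  [{flag}]"
            )
            machine["convergence"].append(
                {
                    "pair": [row.species_a, row.species_b],
                    "delta_single": float(row.delta_single),
                    "delta_mixed": float(row.delta_mixed),
                    "ratio": float(row.ratio),
                    "p_value": float(row.p_value),
                    "converged": bool(converged),
                }
            )

    lines.append("\nSensitivity to visual cue (slope, mm/s per sd of cue):")
    for sp, sub in bundle.sensitivity.groupby("species"):
        slopes = sub["slope"].to_numpy()
        boots = np.array(
            [
                rng.choice(slopes, size=slopes.size, replace=True).mean()
                for _ in range(n_boot)
            ]
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lines.append(
            f"  {sp:<12} mean slope = {slopes.mean():+.4f} "
            f"(95% bootstrap CI {lo:+.4f} .. {hi:+.4f}, n={slopes.size})"
        )
        machine["sensitivity"][sp] = {
            "mean_slope": float(slopes.mean()),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "n": int(slopes.size),
        }

    return "\n".join(lines) + "\n", machine
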