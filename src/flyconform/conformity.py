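"""Conformity quantities: cue sensitivity, species-level and group-level indices.

Three complementary measures are computed, all on per-individual summaries
(the individual, not the frame, is the statistical unit):

* **sensitivity** — the slope of the lagged ordinary-least-squares regression
  of an individual's speed at frame t+lag on the standardized visual cue at
  frame t (default lag one frame = 0.5 s, allowing for the behavioral delay);
* **species-level conformity** — the signed relative change of a species'
  mean speed from single- to mixed-species groups, baselined strain-by-strain
  against the same strain's single-group mean;
* **group-level conformity** — the reduction of the absolute interspecific
  difference in mean speed when two species are mixed, relative to their
  single-species groups (ratio < 1 means convergence).

Hypothesis tests are permutation-based: a group-type relabeling test for the
convergence of the interspecific difference, and one-way permutation F-tests
for differences in sensitivity slopes among species or group types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GroupRecording
from .visual_cue import CueSeries, KinematicsSeries

__all__ = [
    "SensitivityEstimate",
    "GroupConformity",
    "individual_mean_speeds",
    "lagged_sensitivity",
    "sensitivity_table",
    "species_level_conformity",
    "group_level_conformity",
    "sensitivity_comparison",
]


@dataclass(frozen=True)
class SensitivityEstimate:
    """OLS slope of speed[t+lag] on transformed cue[t] for one individual."""

    individual_id: str
    slope: float  # mm/s per sd of cue
    intercept: float
    r_squared: float
    lag_frames: int


@dataclass(frozen=True)
class GroupConformity:
    """Interspecific speed difference in single vs mixed groups."""

    species_pair: tuple[str, str]
    delta_single: float  # |mean_A - mean_B| across single-group individuals, mm/s
    delta_mixed: float
    reduction: float  # delta_single - delta_mixed
    ratio: float  # delta_mixed / delta_single (inf when delta_single == 0)
    p_value: float | None  # permutation test of reduction > 0 (None if not run)
    n_perm: int
    seed: int


def individual_mean_speeds(
    rec: GroupRecording, kin: KinematicsSeries
) -> pd.DataFrame:
    """Mean per-frame speed per individual, one row each.

    Columns: individual_id, species, strain, group_type, replicate_id,
    mean_speed (mm/s), n_frames.
    """
    return pd.DataFrame(
        {
            "individual_id": list(rec.individual_ids),
            "species": rec.species,
            "strain": [t.strain for t in rec.trajectories],
            "group_type": rec.group_type,
            "replicate_id": rec.replicate_id,
            "mean_speed": kin.speed_mm_s.mean(axis=0),
            "n_frames": kin.n_frames,
        }
    )


def lagged_sensitivity(
    speed_mm_s: np.ndarray,
    cue: np.ndarray,
    lag_frames: int = 1,
    individual_id: str = "",
) -> SensitivityEstimate:
    """OLS regression of speed shifted ``lag_frames`` later on the cue.

    ``speed[t + lag]`` is regressed on ``cue[t]`` over all valid t.
    """
    speed = np.asarray(speed_mm_s, dtype=float)
    z = np.asarray(cue, dtype=float)
    if lag_frames < 0:
        raise ValueError("lag_frames must be non-negative")
    if speed.shape != z.shape or speed.ndim != 1:
        raise ValueError("speed and cue must be 1D series of equal length")
    if speed.size <= lag_frames + 2:
        raise ValueError(
            f"series of length {speed.size} too short for lag {lag_frames}"
        )
    x = z[: len(z) - lag_frames] if lag_frames else z
    y = speed[lag_frames:]
    if np.ptp(x) == 0:
        raise ValueError("cue series has zero variance; slope undefined")
    fit = stats.linregress(x, y)
    return SensitivityEstimate(
        individual_id=individual_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        lag_frames=int(lag_frames),
    )


def sensitivity_table(
    rec: GroupRecording,
    kin: KinematicsSeries,
    cues: CueSeries,
    lag_frames: int = 1,
) -> pd.DataFrame:
    """Per-individual sensitivity estimates for one recording."""
    if cues.transformed_cue is None:
        raise ValueError("sensitivity requires a transformed CueSeries")
    rows = []
    for j, t in enumerate(rec.trajectories):
        est = lagged_sensitivity(
            kin.speed_mm_s[:, j],
            cues.transformed_cue[:, j],
            lag_frames,
            individual_id=t.individual_id,
        )
        rows.append(
            {
                "individual_id": t.individual_id,
                "species": t.species,
                "strain": t.strain,
                "group_type": rec.group_type,
                "replicate_id": rec.replicate_id,
                "slope": est.slope,
                "intercept": est.intercept,
                "r_squared": est.r_squared,
                "lag_frames": est.lag_frames,
            }
        )
    return pd.DataFrame(rows)


def species_level_conformity(
    single_means: pd.DataFrame,
    mixed_means: pd.DataFrame,
    method: str = "relative",
) -> pd.DataFrame:
    """Rate of change of mean speed from single- to mixed-species groups.

    Each strain observed in mixed groups is baselined against the same
    (species, strain)'s single-group mean; unmatched strains are an error
    rather than being silently pooled. ``method='relative'`` (default) reports
    the signed relative change (mixed − single)/single, so 0 means no change
    and positive means faster in mixed; ``method='ratio'`` reports
    mixed/single. Returns one row per (species, strain) plus the species-level
    aggregate of strain rates; per-individual rates (each mixed individual
    against its strain baseline) are attached for downstream tests.
    """
    if method not in ("relative", "ratio"):
        raise ValueError(f"unknown method {method!r}")
    if single_means.empty or mixed_means.empty:
        raise ValueError("species_level_conformity requires non-empty tables")

    base = single_means.groupby(["species", "strain"])["mean_speed"].mean()
    rows = []
    for (sp, st), sub in mixed_means.groupby(["species", "strain"]):
        if (sp, st) not in base.index:
            raise ValueError(
                f"no single-group baseline for species {sp!r} strain {st!r}"
            )
        b = base.loc[(sp, st)]
        if b == 0:
            raise ValueError(f"single-group mean speed is 0 for {sp!r}/{st!r}")
        mixed_mean = sub["mean_speed"].mean()
        rate = mixed_mean / b if method == "ratio" else (mixed_mean - b) / b
        indiv = sub["mean_speed"] / b
        if method == "relative":
            indiv = indiv - 1.0
        rows.append(
            {
                "species": sp,
                "strain": st,
                "n_individuals": len(sub),
                "single_mean_speed": float(b),
                "mixed_mean_speed": float(mixed_mean),
                "rate_of_change": float(rate),
                "individual_rates": indiv.to_numpy(),
            }
        )
    out = pd.DataFrame(rows)
    agg = (
        out.groupby("species", as_index=False)
        .agg(rate_of_change=("rate_of_change", "mean"))
        .assign(strain="(all)", level="species")
    )
    out["level"] = "strain"
    return pd.concat([out, agg], ignore_index=True)


def group_level_conformity(
    single_a: pd.DataFrame,
    single_b: pd.DataFrame,
    mixed_a: pd.DataFrame,
    mixed_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupConformity:
    """Interspecific |mean speed difference| in single vs mixed groups.

    ``delta_single = |mean(single_a) − mean(single_b)|`` and likewise for
    mixed (means of per-individual means). Convergence is tested by permuting
    the single/mixed labels within each species and asking how often the
    permuted reduction (delta_single − delta_mixed) is at least the observed
    one; pass ``n_perm=0`` to skip the test.
    """
    for name, t in (("single_a", single_a), ("single_b", single_b),
                    ("mixed_a", mixed_a), ("mixed_b", mixed_b)):
        if t.empty:
            raise ValueError(f"{name} table is empty")
    sp_a = single_a["species"].iloc[0]
    sp_b = single_b["species"].iloc[0]
    if set(mixed_a["species"]) != {sp_a} or set(mixed_b["species"]) != {sp_b}:
        raise ValueError("mixed tables must contain the same species pair")

    sa = single_a["mean_speed"].to_numpy()
    sb = single_b["mean_speed"].to_numpy()
    ma = mixed_a["mean_speed"].to_numpy()
    mb = mixed_b["mean_speed"].to_numpy()

    def deltas(sa_, ma_, sb_, mb_):
        d_s = abs(sa_.mean() - sb_.mean())
        d_m = abs(ma_.mean() - mb_.mean())
        return d_s, d_m

    d_single, d_mixed = deltas(sa, ma, sb, mb)
    observed = d_single - d_mixed

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pool_a = np.concatenate([sa, ma])
        pool_b = np.concatenate([sb, mb])
        count = 0
        for _ in range(n_perm):
            pa = rng.permutation(pool_a)
            pb = rng.permutation(pool_b)
            ds, dm = deltas(pa[: len(sa)], pa[len(sa):], pb[: len(sb)], pb[len(sb):])
            if ds - dm >= observed:
                count += 1
        p_value = (1 + count) / (n_perm + 1)

    return GroupConformity(
        species_pair=(sp_a, sp_b),
        delta_single=float(d_single),
        delta_mixed=float(d_mixed),
        reduction=float(observed),
        ratio=float(d_mixed / d_single) if d_single > 0 else float("inf"),
        p_value=None if p_value is None else float(p_value),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def _one_way_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F statistic (0 when there is no between-group variance)."""
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0:
        return 0.0 if ss_between == 0 else float("inf")
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def sensitivity_comparison(
    estimates: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation one-way F-tests on individual slopes.

    Tests whether the sensitivity slope differs among species and among group
    types (single vs mixed), each as a separate one-way permutation F-test
    with label reshuffling. Each stratum needs >= 2 individuals.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for factor in ("species", "group_type"):
        if factor not in estimates.columns:
            continue
        labels = estimates[factor].to_numpy()
        uniq = np.unique(labels)
        if len(uniq) < 2:
            continue
        counts = pd.Series(labels).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"{factor} strata {small} have < 2 individuals")
        values = estimates["slope"].to_numpy(dtype=float)
        codes = np.searchsorted(uniq, labels)
        observed = _one_way_f(values, codes, len(uniq))
        count = 0
        for _ in range(n_perm):
            if _one_way_f(values, rng.permutation(codes), len(uniq)) >= observed:
                count += 1
        rows.append(
            {
                "factor": factor,
                "n_levels": len(uniq),
                "f_statistic": float(observed),
                "p_value": (1 + count) / (n_perm + 1),
                "n_perm": n_perm,
                "seed": seed,
            }
        )
    if not rows:
        raise ValueError("sensitivity_comparison needs >= 2 groups in some factor")
    return pd.DataFrame(rows)
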