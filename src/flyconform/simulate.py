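"""Agent-based arena simulator with ground-truth conformity parameters.

Agents are two-state (stationary/walking) Markov walkers in a circular arena
whose transition probabilities are coupled to the same visual cue the analysis
pipeline measures. Per frame, each agent

1. computes its raw visual cue from all other agents in its forward 180°
   sector (the cue model of :mod:`flyconform.visual_cue`),
2. standardizes it with species-specific constants obtained from a
   zero-coupling calibration run (see below),
3. if stationary, starts walking next frame with probability
   ``logistic(logit(base_walk_rate) + coupling_beta * z)``; if walking, stops
   with probability ``logistic(logit(base_stop_rate) + stop_coupling * z)``,
4. if walking, advances along its heading at a lognormal per-frame speed with
   Gaussian heading noise; a stationary agent stays in place apart from a
   0.05 mm micro-jitter (grooming/pivoting and tracking noise in real data)
   whose direction follows the same per-frame heading law as a walking step.

The micro-jitter is not cosmetic. The analysis derives heading from the
displacement vector, so a stationary individual's measured heading is the
direction of its most recent displacement. If stationary agents held position
exactly, their measured heading would be the *incoming* direction of the step
on which they stopped while walking agents show their *outgoing* direction —
and near the arena wall those two distributions necessarily differ (steps
arriving at the wall point outward, steps leaving it are reflected inward),
which would correlate the forward-sector cue with the behavioral state even
at zero coupling. Letting every agent's heading evolve each frame by the same
rule (turn noise plus reflection of the full-length step it would take) and
expressing it as a sub-threshold jitter makes the measured cue independent of
the walk/stay state when ``coupling_beta = 0``, so the zero-coupling null is
genuinely null.

``coupling_beta`` is the ground-truth conformity: the log-odds increment of
walk onset per standard deviation of cue. ``stop_coupling`` is a sociality
knob (positive = more likely to stop where others are active). The logistic
link keeps transition probabilities valid at arbitrarily extreme cues.

Cue standardization constants are calibrated per species from a
zero-coupling single-species run with identical speed parameters and a fixed
internal seed, so they do not depend on the composition the species is later
simulated in. This avoids circularity between online standardization and
behavior, and it makes the behavioral response depend on the *absolute* cue
level: an agent surrounded by faster heterospecifics sees a positive z and
raises its activity, which is precisely the mechanism whose signatures
(convergence, asymmetry) the pipeline is meant to recover.

Boundary handling is an approximate specular reflection at the wall; real
flies instead follow arena edges, which this generator does not emulate.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import ArenaConfig, GroupRecording, Trajectory, write_recording

__all__ = [
    "SpeciesParams",
    "SimParams",
    "DEFAULT_SPECIES",
    "HOST_SPECIES",
    "simulate",
    "make_validation_suite",
]

#: Minimum run length; shorter runs cannot support the cue calibration burn-in.
SIM_MIN_FRAMES = 10

#: Frames discarded at the start of the calibration run, and its length.
_CALIBRATION_BURN_IN = 100
_CALIBRATION_FRAMES = 900
_CALIBRATION_SEED = 987654321  # fixed: constants depend on params only


@dataclass(frozen=True)
class SpeciesParams:
    """Generative behavioral parameters of one (synthetic) species.

    base_walk_rate / base_stop_rate
        Per-frame transition probabilities at zero standardized cue; their
        ratio sets the baseline walking fraction
        ``base_walk_rate / (base_walk_rate + base_stop_rate)``.
    coupling_beta
        Ground-truth conformity: log-odds increment of walk onset per sd of
        cue.
    stop_coupling
        Log-odds increment of stopping per sd of cue.
    walk_speed_mu_mm_s
        Mean walking speed; per-frame speeds are lognormal with this mean and
        log-scale sd ``walk_speed_sigma``, so an agent's long-run mean speed is
        ``walking_fraction * walk_speed_mu_mm_s``.
    turn_sd_rad
        Heading noise per walking frame.
    """

    name: str
    base_walk_rate: float = 0.12
    base_stop_rate: float = 0.36
    coupling_beta: float = 0.0
    stop_coupling: float = 0.0
    walk_speed_mu_mm_s: float = 8.0
    walk_speed_sigma: float = 0.3
    turn_sd_rad: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("base_walk_rate", "base_stop_rate"):
            v = getattr(self, attr)
            if not 0 < v < 1:
                raise ValueError(f"{attr} must be in (0, 1), got {v}")
        if self.walk_speed_mu_mm_s <= 0:
            raise ValueError("walk_speed_mu_mm_s must be positive")
        if self.walk_speed_sigma < 0:
            raise ValueError("walk_speed_sigma must be >= 0")

    @property
    def walking_fraction(self) -> float:
        """Stationary-distribution walking probability at zero coupling."""
        return self.base_walk_rate / (self.base_walk_rate + self.base_stop_rate)

    @property
    def mean_speed_mm_s(self) -> float:
        """Expected long-run mean speed at zero coupling."""
        return self.walking_fraction * self.walk_speed_mu_mm_s


#: Synthetic species panel spanning the ~10x range of baseline mean speeds
#: observed across real species (means 1, 2, 4, 10 mm/s at zero coupling).
#: The panel mirrors the qualitative structure of the real system: the host
#: is the intermediate-activity species with the strongest conformity, and
#: the fastest species is a weakly conforming "influencer" that changes
#: little itself while pulling its partners.
DEFAULT_SPECIES: dict[str, SpeciesParams] = {
    "speciesA": SpeciesParams(name="speciesA", walk_speed_mu_mm_s=4.0,
                              coupling_beta=1.0),
    "speciesB": SpeciesParams(name="speciesB", walk_speed_mu_mm_s=8.0,
                              coupling_beta=1.0),
    "speciesC": SpeciesParams(name="speciesC", walk_speed_mu_mm_s=16.0,
                              coupling_beta=1.2),
    "speciesD": SpeciesParams(name="speciesD", walk_speed_mu_mm_s=40.0,
                              coupling_beta=0.2),
}
HOST_SPECIES = "speciesC"  # intermediate baseline activity


@dataclass(frozen=True)
class SimParams:
    """Full specification of one simulated recording."""

    species_a: SpeciesParams
    species_b: SpeciesParams | None = None
    n_per_species: int = 24  # 24 single / 12+12 mixed by default
    n_frames: int = 1800
    seed: int = 0
    arena_diameter_mm: float = 140.0
    frame_interval_s: float = 0.5
    strain_a: str = "s1"
    strain_b: str = "s1"
    replicate_id: str = "r0"
    #: Frames simulated before the recording starts and then discarded,
    #: mirroring the acclimation period of the real protocol: agents are
    #: released clustered near the arena center and the recording represents
    #: the stationarized regime after dispersal.
    burn_in_frames: int = 600

    def __post_init__(self) -> None:
        if self.burn_in_frames < 0:
            raise ValueError("burn_in_frames must be >= 0")
        if self.n_frames < SIM_MIN_FRAMES:
            raise ValueError(
                f"n_frames={self.n_frames} below the minimum burn-in-compatible "
                f"length {SIM_MIN_FRAMES}"
            )
        if self.n_per_species < 2:
            raise ValueError("n_per_species must be >= 2")
        if (
            self.species_b is not None
            and self.species_b.name == self.species_a.name
        ):
            raise ValueError("mixed group requires two distinct species")

    @property
    def group_type(self) -> str:
        return "single" if self.species_b is None else "mixed"

    @property
    def n_agents(self) -> int:
        return self.n_per_species * (1 if self.species_b is None else 2)

    @property
    def arena(self) -> ArenaConfig:
        return ArenaConfig(
            diameter_mm=self.arena_diameter_mm,
            frame_interval_s=self.frame_interval_s,
            analysis_start_s=0.0,
            analysis_end_s=self.n_frames * self.frame_interval_s,
        )


def _raw_cue_frame(
    pos: np.ndarray, hx: np.ndarray, hy: np.ndarray, speed: np.ndarray,
    body_major_mm: float, distance_clamp_mm: float,
) -> np.ndarray:
    """Raw cue of every focal at one frame (same model as visual_cue.compute_cue)."""
    rel = pos[None, :, :] - pos[:, None, :]  # (focal, other, 2)
    dist = np.hypot(rel[..., 0], rel[..., 1])
    np.maximum(dist, distance_clamp_mm, out=dist)
    ang = 2.0 * np.arctan(body_major_mm / (2.0 * dist))
    forward = hx[:, None] * rel[..., 0] + hy[:, None] * rel[..., 1] >= 0.0
    terms = speed[None, :] * ang * forward
    np.fill_diagonal(terms, 0.0)
    return terms.sum(axis=1)


def _simulate_core(
    walk_logit: np.ndarray,
    stop_logit: np.ndarray,
    beta: np.ndarray,
    stop_beta: np.ndarray,
    speed_mu: np.ndarray,
    speed_sigma: np.ndarray,
    turn_sd: np.ndarray,
    cue_offset: np.ndarray,
    cue_mean: np.ndarray,
    cue_sd: np.ndarray,
    init_pos: np.ndarray,
    radius_mm: float,
    dt: float,
    n_frames: int,
    rng: np.random.Generator,
    collect_raw_cue: bool = False,
    jitter_mm: float = 0.05,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Run the agent loop; all per-agent parameter vectors are length N.

    Returns positions (n_frames, N, 2) and, optionally, the raw cue trace.
    """
    n = init_pos.shape[0]
    pos = np.empty((n_frames, n, 2))
    heading = rng.uniform(-np.pi, np.pi, size=n)
    # start from the zero-coupling stationary walking fraction
    p_walk0 = 1.0 / (1.0 + np.exp(-walk_logit))
    p_stop0 = 1.0 / (1.0 + np.exp(-stop_logit))
    walking = rng.random(n) < p_walk0 / (p_walk0 + p_stop0)

    # bulk randomness (sequential dependence is only through positions/states)
    u_trans = rng.random((n_frames, n))
    z_speed = rng.standard_normal((n_frames, n))
    z_turn = rng.standard_normal((n_frames, n))

    log_adj = -0.5 * speed_sigma**2  # lognormal mean correction
    raw_trace = np.empty((n_frames, n)) if collect_raw_cue else None

    cur = init_pos.copy()
    for t in range(n_frames):
        pos[t] = cur
        # Heading evolves identically for every agent regardless of state:
        # turn noise, then reflection of the full-length step the agent would
        # take this frame (virtual for stationary agents). Stationary agents
        # express the resulting direction as a micro-jitter displacement, so
        # the measured (displacement-derived) heading of a stationary agent
        # follows the same law as a walking one and, at zero coupling, the
        # measured cue is independent of the behavioral state.
        heading = heading + turn_sd * z_turn[t]
        v_full = speed_mu * np.exp(speed_sigma * z_speed[t] + log_adj)
        ux, uy = np.cos(heading), np.sin(heading)
        length = v_full * dt
        endpoint = cur + length[:, None] * np.column_stack([ux, uy])
        out = np.hypot(endpoint[:, 0], endpoint[:, 1]) > radius_mm
        if np.any(out):
            # edge-following wall: walk straight to the wall, then slide the
            # remaining step length along it (direction of the tangential
            # motion component); step length is preserved, so wall contacts
            # never masquerade as stationary frames
            px, py = cur[out, 0], cur[out, 1]
            vx, vy = ux[out], uy[out]
            pu = px * vx + py * vy
            t_hit = -pu + np.sqrt(
                np.maximum(pu**2 + radius_mm**2 - (px**2 + py**2), 0.0)
            )
            t_hit = np.minimum(t_hit, length[out])
            qx, qy = px + t_hit * vx, py + t_hit * vy
            spin = np.where(qx * vy - qy * vx >= 0, 1.0, -1.0)
            phi = spin * (length[out] - t_hit) / radius_mm
            c, s = np.cos(phi), np.sin(phi)
            endpoint[out, 0] = c * qx - s * qy
            endpoint[out, 1] = s * qx + c * qy
        d = endpoint - cur
        heading = np.arctan2(d[:, 1], d[:, 0])  # realized step direction

        speed = np.where(walking, v_full, jitter_mm / dt)
        raw = _raw_cue_frame(cur, np.cos(heading), np.sin(heading), speed,
                             body_major_mm=3.0, distance_clamp_mm=0.75)
        if raw_trace is not None:
            raw_trace[t] = raw
        z = (np.log(np.where(raw > 0, raw, cue_offset)) - cue_mean) / cue_sd

        p_start = 1.0 / (1.0 + np.exp(-(walk_logit + beta * z)))
        p_stop = 1.0 / (1.0 + np.exp(-(stop_logit + stop_beta * z)))
        next_walking = np.where(walking, u_trans[t] >= p_stop, u_trans[t] < p_start)

        step_len = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)
        unit = d / step_len[:, None]
        cur = np.where(walking[:, None], endpoint, cur + jitter_mm * unit)
        walking = next_walking

    return pos, raw_trace


def _species_vectors(species_list, attr):
    return np.array([getattr(sp, attr) for sp in species_list])


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


@functools.lru_cache(maxsize=64)
def _cue_standardization(
    sp: SpeciesParams, n_agents: int, arena_diameter_mm: float, dt: float
) -> tuple[float, float, float]:
    """(offset, mean, sd) of the log cue from a zero-coupling calibration run.

    The run uses ``n_agents`` conspecifics with ``sp``'s speed parameters,
    zero coupling, and a fixed internal seed, so the constants are a pure
    function of the species parameters and group size.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    radius = arena_diameter_mm / 2.0
    init = _init_positions_single(rng, n_agents, radius)
    n = n_agents
    ones = np.ones(n)
    _, raw = _simulate_core(
        walk_logit=_logit(ones * sp.base_walk_rate),
        stop_logit=_logit(ones * sp.base_stop_rate),
        beta=np.zeros(n),
        stop_beta=np.zeros(n),
        speed_mu=ones * sp.walk_speed_mu_mm_s,
        speed_sigma=ones * sp.walk_speed_sigma,
        turn_sd=ones * sp.turn_sd_rad,
        cue_offset=ones,  # unused at beta = 0
        cue_mean=np.zeros(n),
        cue_sd=ones,
        init_pos=init,
        radius_mm=radius,
        dt=dt,
        n_frames=_CALIBRATION_BURN_IN + _CALIBRATION_FRAMES,
        rng=rng,
        collect_raw_cue=True,
    )
    raw = raw[_CALIBRATION_BURN_IN:].ravel()
    positive = raw[raw > 0]
    if positive.size == 0:
        raise RuntimeError("calibration run produced an all-zero cue")
    m = float(positive.min())
    logged = np.log(np.where(raw > 0, raw, m))
    return m, float(logged.mean()), float(logged.std())


def _init_positions_single(rng, n, radius):
    """Uniform in a small disk near the arena center."""
    r = 0.28 * radius * np.sqrt(rng.random(n))
    th = rng.uniform(-np.pi, np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _init_positions_mixed(rng, n_per, radius):
    """Two clusters at symmetric positions on the arena y-axis."""
    out = []
    for sign in (+1, -1):
        r = 0.12 * radius * np.sqrt(rng.random(n_per))
        th = rng.uniform(-np.pi, np.pi, n_per)
        out.append(
            np.column_stack(
                [r * np.cos(th), sign * 0.2 * radius + r * np.sin(th)]
            )
        )
    return np.vstack(out)


def simulate(params: SimParams) -> GroupRecording:
    """Generate one GroupRecording; identical params + seed give identical output."""
    rng = np.random.default_rng(params.seed)
    radius = params.arena_diameter_mm / 2.0

    if params.species_b is None:
        species_list = [params.species_a] * params.n_per_species
        strains = [params.strain_a] * params.n_per_species
        init = _init_positions_single(rng, params.n_per_species, radius)
    else:
        species_list = (
            [params.species_a] * params.n_per_species
            + [params.species_b] * params.n_per_species
        )
        strains = (
            [params.strain_a] * params.n_per_species
            + [params.strain_b] * params.n_per_species
        )
        init = _init_positions_mixed(rng, params.n_per_species, radius)

    n = len(species_list)
    uniq = list(dict.fromkeys(sp.name for sp in species_list))
    by_name = {sp.name: sp for sp in species_list}
    consts = {
        name: _cue_standardization(
            by_name[name], n, params.arena_diameter_mm, params.frame_interval_s
        )
        for name in uniq
    }
    offset = np.array([consts[sp.name][0] for sp in species_list])
    mean = np.array([consts[sp.name][1] for sp in species_list])
    sd = np.array([consts[sp.name][2] for sp in species_list])

    pos, _ = _simulate_core(
        walk_logit=_logit(_species_vectors(species_list, "base_walk_rate")),
        stop_logit=_logit(_species_vectors(species_list, "base_stop_rate")),
        beta=_species_vectors(species_list, "coupling_beta"),
        stop_beta=_species_vectors(species_list, "stop_coupling"),
        speed_mu=_species_vectors(species_list, "walk_speed_mu_mm_s"),
        speed_sigma=_species_vectors(species_list, "walk_speed_sigma"),
        turn_sd=_species_vectors(species_list, "turn_sd_rad"),
        cue_offset=offset,
        cue_mean=mean,
        cue_sd=sd,
        init_pos=init,
        radius_mm=radius,
        dt=params.frame_interval_s,
        n_frames=params.burn_in_frames + params.n_frames,
        rng=rng,
    )
    pos = pos[params.burn_in_frames:]

    trajectories = tuple(
        Trajectory(
            individual_id=f"{species_list[j].name}_{strains[j]}_{j:02d}",
            species=species_list[j].name,
            strain=strains[j],
            positions=pos[:, j, :],
        )
        for j in range(n)
    )
    return GroupRecording(
        arena=params.arena,
        trajectories=trajectories,
        group_type=params.group_type,
        replicate_id=params.replicate_id,
    )


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_validation_suite(
    out_dir: str | Path,
    seed: int = 0,
    n_frames: int = 1800,
    n_replicates: int = 3,
    strains: tuple[str, str] = ("s1", "s2"),
    species: dict[str, SpeciesParams] | None = None,
    host: str = HOST_SPECIES,
    n_per_species_mixed: int = 12,
    n_single: int = 24,
) -> dict:
    """Write the fixed panel of recordings used for end-to-end validation.

    Four synthetic species (baseline mean speeds spanning ~10x) each recorded
    in single-species groups, plus the three mixed pairings of the
    intermediate-activity host against every other species, with two
    pseudo-strains (identical parameters, distinct labels) and ``n_replicates``
    recordings per strain/pairing. Returns (and writes) a manifest listing
    every file with its generating parameters, seed, and checksum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = dict(DEFAULT_SPECIES if species is None else species)
    if host not in panel:
        raise ValueError(f"host species {host!r} not in panel {sorted(panel)}")

    master = np.random.default_rng(seed)
    entries = []

    def emit(params: SimParams, label: str) -> None:
        rec = simulate(params)
        traj = out_dir / f"{label}.tsv"
        meta = out_dir / f"{label}.meta.yaml"
        write_recording(rec, traj, metadata_path=meta)
        entries.append(
            {
                "label": label,
                "trajectory": traj.name,
                "metadata": meta.name,
                "group_type": params.group_type,
                "species": [params.species_a.name]
                + ([params.species_b.name] if params.species_b else []),
                "strains": sorted({params.strain_a, params.strain_b}),
                "seed": params.seed,
                "n_frames": params.n_frames,
                "checksum_sha256": _file_checksum(traj),
            }
        )

    for name, sp in panel.items():
        for strain in strains:
            for rep in range(n_replicates):
                emit(
                    SimParams(
                        species_a=sp,
                        n_per_species=n_single,
                        n_frames=n_frames,
                        seed=int(master.integers(2**31)),
                        strain_a=strain,
                        replicate_id=f"r{rep}",
                    ),
                    f"single_{name}_{strain}_r{rep}",
                )
    for name, sp in panel.items():
        if name == host:
            continue
        for strain in strains:
            for rep in range(n_replicates):
                emit(
                    SimParams(
                        species_a=panel[host],
                        species_b=sp,
                        n_per_species=n_per_species_mixed,
                        n_frames=n_frames,
                        seed=int(master.integers(2**31)),
                        strain_a=strain,
                        strain_b=strain,
                        replicate_id=f"r{rep}",
                    ),
                    f"mixed_{host}_{name}_{strain}_r{rep}",
                )

    manifest = {
        "seed": seed,
        "n_frames": n_frames,
        "n_replicates": n_replicates,
        "host": host,
        "species_params": {
            name: {
                "base_walk_rate": sp.base_walk_rate,
                "base_stop_rate": sp.base_stop_rate,
                "coupling_beta": sp.coupling_beta,
                "stop_coupling": sp.stop_coupling,
                "walk_speed_mu_mm_s": sp.walk_speed_mu_mm_s,
                "walk_speed_sigma": sp.walk_speed_sigma,
                "turn_sd_rad": sp.turn_sd_rad,
            }
            for name, sp in panel.items()
        },
        "recordings": entries,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
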