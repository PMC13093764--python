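"""Shared fixtures: hand-built recordings and small simulated ones."""

from __future__ import annotations

import numpy as np
import pytest

from flyconform import (
    ArenaConfig,
    GroupRecording,
    SimParams,
    SpeciesParams,
    Trajectory,
    simulate,
)


def make_recording(
    positions: np.ndarray,
    species: list[str] | None = None,
    group_type: str = "single",
    frame_interval_s: float = 0.5,
    strain: str = "s1",
) -> GroupRecording:
    """Build a GroupRecording from a (n_frames, n_individuals, 2) array."""
    T, N, _ = positions.shape
    if species is None:
        species = ["specX"] * N
    arena = ArenaConfig(
        diameter_mm=140.0,
        frame_interval_s=frame_interval_s,
        analysis_start_s=0.0,
        analysis_end_s=T * frame_interval_s,
    )
    trajs = tuple(
        Trajectory(
            individual_id=f"ind{j:02d}",
            species=species[j],
            strain=strain,
            positions=positions[:, j, :],
        )
        for j in range(N)
    )
    return GroupRecording(arena, trajs, group_type)


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture(scope="session")
def coupled_recording():
    """One moderately coupled 24-agent recording, reused across tests."""
    sp = SpeciesParams(name="fixture_sp", walk_speed_mu_mm_s=8.0, coupling_beta=1.0)
    return simulate(SimParams(species_a=sp, n_per_species=24, n_frames=900, seed=42))


@pytest.fixture(scope="session")
def null_recording():
    """One zero-coupling 24-agent recording (agents are independent walkers)."""
    sp = SpeciesParams(name="fixture_null", walk_speed_mu_mm_s=8.0)
    return simulate(SimParams(species_a=sp, n_per_species=24, n_frames=900, seed=7))
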