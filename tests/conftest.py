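"""Shared fixtures: the two reference simulations used across the suite.

Both are session-scoped because the 128 x 128 reaction-diffusion runs
dominate the suite's runtime; every test reads them without mutation.
"""

from __future__ import annotations

import numpy as np
import pytest

from rotormap.phase import (
    detect_singularities_movie,
    instantaneous_phase,
    track_singularities,
)
from rotormap.preprocess import FilterSpec, preprocess_movie
from rotormap.synth import (
    MediumParams,
    OpticsModel,
    StimulusProtocol,
    render_movie,
    simulate_medium,
)

SPIRAL_SEED = 1
PLANAR_SEED = 2


@pytest.fixture(scope="session")
def spiral_run():
    """Cross-field-initiated spiral on 128x128, 10 s at 5 ms/frame,
    analysed end to end (render -> condition -> phase -> detect -> track),
    with the isopotential tip oracle as ground truth."""
    params = MediumParams(seed=SPIRAL_SEED)
    protocol = StimulusProtocol(kind="cross_field_s2", onset_ms=10.0, s2_offset_ms=850.0, count=1)
    stack, interval, truth = simulate_medium(params, protocol, duration_ms=10_000.0, store_interval_ms=5.0)
    movie = render_movie(stack, interval, OpticsModel(noise_sd=0.02), seed=7)
    pre, flags = preprocess_movie(movie, FilterSpec())
    pm = instantaneous_phase(pre, flags)
    detections = detect_singularities_movie(pm)
    tracks = track_singularities(detections, pm.frame_interval_ms)
    return dict(
        params=params,
        stack=stack,
        interval=interval,
        truth=truth,
        movie=movie,
        pre=pre,
        flags=flags,
        pm=pm,
        detections=detections,
        tracks=tracks,
    )


@pytest.fixture(scope="session")
def planar_paced_run():
    """Planar 10 Hz burst pacing of the same medium (no reentry), analysed
    with the same chain — the specificity control for rotor detection."""
    params = MediumParams(seed=PLANAR_SEED)
    protocol = StimulusProtocol(kind="planar_s1", onset_ms=10.0, period_ms=100.0, count=100)
    stack, interval, truth = simulate_medium(params, protocol, duration_ms=10_000.0, store_interval_ms=5.0)
    movie = render_movie(stack, interval, OpticsModel(noise_sd=0.02), seed=8)
    pre, flags = preprocess_movie(movie, FilterSpec())
    pm = instantaneous_phase(pre, flags)
    detections = detect_singularities_movie(pm)
    tracks = track_singularities(detections, pm.frame_interval_ms)
    return dict(
        params=params, stack=stack, interval=interval, truth=truth,
        pm=pm, detections=detections, tracks=tracks,
    )


def random_vortex_scene(rng: np.random.Generator, shape=(64, 64), max_vortices=4,
                        min_separation=14.0, border=10.0):
    """Random planted-vortex configuration used by detector validation."""
    n = int(rng.integers(0, max_vortices + 1))
    centers: list[tuple[float, float]] = []
    chis: list[int] = []
    while len(centers) < n:
        cand = (
            float(rng.uniform(border, shape[0] - border)),
            float(rng.uniform(border, shape[1] - border)),
        )
        if all(np.hypot(cand[0] - a, cand[1] - b) > min_separation for a, b in centers):
            centers.append(cand)
            chis.append(int(rng.choice([-1, 1])))
    return centers, chis
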