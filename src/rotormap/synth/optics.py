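"""Forward optical model: excitation variable -> fluorescence movie.

Emulates voltage- (FluoVolt-like) or calcium-indicator imaging of a
monolayer: linear gain on the simulated excitation variable, an optional
mono-exponential photobleaching envelope, additive per-pixel Gaussian
read noise, and temporal decimation to the camera frame interval
(5 ms by default, i.e. 200 frames/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..datatypes import ConfigurationError, FluorescenceMovie


@dataclass
class OpticsModel:
    """Camera/indicator model.

    polarity -1 models indicators whose fluorescence falls on
    depolarisation; downstream analysis declares the polarity and flips
    the trace back.
    """

    frame_interval_ms: float = 5.0
    gain: float = 1.0
    baseline: float = 0.0
    bleach_tau_ms: float = math.inf
    noise_sd: float = 0.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if not self.frame_interval_ms > 0:
            raise ConfigurationError("frame_interval_ms must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gain == 0:
            raise ConfigurationError("gain must be nonzero")
        if self.polarity not in (1, -1):
            raise ConfigurationError("polarity must be +1 or -1")


def render_movie(
    u_stack: np.ndarray,
    source_interval_ms: float,
    optics: OpticsModel | None = None,
    seed: int | None = 0,
    mask: np.ndarray | None = None,
    modality: str = "voltage",
) -> FluorescenceMovie:
    """Render a fluorescence movie from a simulated excitation stack.

    Frames are picked from the source stack by nearest-frame decimation at
    ``optics.frame_interval_ms``; intensities are
    ``baseline + polarity * gain * u`` scaled by ``exp(-t / bleach_tau_ms)``
    plus Gaussian noise with SD ``noise_sd``.
    """
    optics = optics or OpticsModel()
    u_stack = np.asarray(u_stack, dtype=float)
    if not np.all(np.isfinite(u_stack)):
        raise ValueError("u_stack contains non-finite values")
    if optics.frame_interval_ms < source_interval_ms - 1e-9:
        raise ConfigurationError(
            "frame_interval_ms is finer than the source stack interval"
        )
    step = optics.frame_interval_ms / source_interval_ms
    idx = np.round(np.arange(0, u_stack.shape[0] - 0.5, step)).astype(int)
    idx = idx[idx < u_stack.shape[0]]
    frames = optics.baseline + optics.polarity * optics.gain * u_stack[idx]
    t = idx * source_interval_ms
    if math.isfinite(optics.bleach_tau_ms):
        frames = frames * np.exp(-t / optics.bleach_tau_ms)[:, None, None]
    if optics.noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, optics.noise_sd, size=frames.shape)
    return FluorescenceMovie(
        frames=frames,
        frame_interval_ms=optics.frame_interval_ms,
        mask=mask,
        modality=modality,
        provenance=[f"render_movie(gain={optics.gain}, noise_sd={optics.noise_sd})"],
    )
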