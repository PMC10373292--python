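"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* time is in milliseconds, space in pixels, with ``dx`` (mm/pixel) carried
  as metadata;
* arrays are indexed ``(frame, row, col)``, 0-based;
* a boolean ``mask`` marks tissue pixels (True = analyse); masked-out
  pixels are excluded from every statistic;
* ``provenance`` is an append-only list naming each operation applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A parameter combination violates a documented precondition."""


@dataclass
class FluorescenceMovie:
    """A T x H x W stack of fluorescence intensities (a.u.).

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
    frame_interval_ms : float
        Sampling interval between frames.
    mask : ndarray of bool, shape (H, W)
        True where tissue is present.
    modality : str
        ``"voltage"`` or ``"calcium"``.
    provenance : list of str
        Names of operations applied so far, oldest first.
    """

    frames: np.ndarray
    frame_interval_ms: float
    mask: np.ndarray | None = None
    modality: str = "voltage"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ConfigurationError(
                "frames must be a (T, H, W) stack with T >= 2, got shape "
                f"{self.frames.shape}"
            )
        if not self.frame_interval_ms > 0:
            raise ConfigurationError("frame_interval_ms must be positive")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ConfigurationError("mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times_ms(self) -> np.ndarray:
        """Frame timestamps in ms (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_ms

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.frame_interval_ms

    def with_frames(self, frames: np.ndarray, step: str) -> "FluorescenceMovie":
        """Return a copy holding ``frames`` with ``step`` appended to provenance."""
        return replace(
            self,
            frames=np.asarray(frames, dtype=float),
            provenance=self.provenance + [step],
        )


@dataclass
class PhaseMovie:
    """Per-pixel instantaneous phase in (-pi, pi].

    ``untrusted`` flags frames inside the filter settling interval; phase
    and singularity analyses skip them.  Masked pixels hold NaN and are
    excluded from every ring sum.
    """

    phase: np.ndarray
    frame_interval_ms: float
    mask: np.ndarray
    untrusted: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.untrusted = np.asarray(self.untrusted, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def trusted_frames(self) -> np.ndarray:
        return np.nonzero(~self.untrusted)[0]


@dataclass
class GroundTruth:
    """Simulator-side truth used to validate every downstream estimator.

    Attributes
    ----------
    activation_times : list of ndarray (H, W)
        One map per detected beat: time (ms) at which the excitation
        variable crossed the upstroke threshold, NaN where that beat never
        arrived.  Per pixel, successive beats are non-decreasing in time.
    apd_maps : dict fraction -> list of ndarray (H, W)
        Per-beat action-potential duration at each repolarisation fraction.
    tip_trajectory : DataFrame with columns frame, row, col, chirality
        Spiral-tip positions from the isopotential-intersection oracle.
    plane_velocity_cm_s : float or None
        Fitted planar conduction velocity, present for planar stimuli.
    """

    activation_times: list[np.ndarray] = field(default_factory=list)
    apd_maps: dict[float, list[np.ndarray]] = field(default_factory=dict)
    tip_trajectory: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["frame", "row", "col", "chirality"]
        )
    )
    plane_velocity_cm_s: float | None = None


@dataclass
class ElectrogramSet:
    """Per-electrode extracellular traces on a rectangular grid.

    ``data`` is (n_samples, n_electrodes); electrode k sits at
    ``positions[k] = (row, col)`` grid coordinates with physical
    ``pitch_mm`` spacing.  Electrodes over dead tissue are emitted flat and
    flagged in ``quality``.
    """

    data: np.ndarray
    sample_interval_ms: float
    positions: list[tuple[int, int]]
    pitch_mm: float
    quality: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.positions) != self.data.shape[1]:
            raise ConfigurationError("one position per electrode is required")
        if not self.pitch_mm > 0:
            raise ConfigurationError("pitch_mm must be positive")
        if not self.quality:
            self.quality = ["ok"] * self.data.shape[1]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.sample_interval_ms

    @property
    def names(self) -> list[str]:
        return [f"r{r}c{c}" for r, c in self.positions]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: column 0 is time_ms, one column per electrode."""
        out = pd.DataFrame({"time_ms": self.times_ms})
        for k, name in enumerate(self.names):
            out[name] = self.data[:, k]
        return out


def extract_trace(
    movie: FluorescenceMovie,
    roi: tuple[int, int, int, int] | Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean fluorescence over a region of interest, per frame.

    Parameters
    ----------
    movie : FluorescenceMovie
    roi : (row0, row1, col0, col1) half-open rectangle, or a sequence of
        (row, col) pixels.

    Returns
    -------
    times_ms, trace : ndarray
        Frame times and the per-frame mean over ``roi`` intersected with
        the tissue mask.

    Raises
    ------
    ValueError
        If the ROI does not intersect the mask.
    """
    sel = np.zeros(movie.mask.shape, dtype=bool)
    if len(roi) == 4 and np.isscalar(roi[0]):
        r0, r1, c0, c1 = roi
        sel[r0:r1, c0:c1] = True
    else:
        rows, cols = zip(*roi)
        sel[list(rows), list(cols)] = True
    sel &= movie.mask
    if not sel.any():
        raise ValueError("ROI does not intersect the tissue mask")
    trace = movie.frames[:, sel].mean(axis=1)
    return movie.times_ms, trace
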