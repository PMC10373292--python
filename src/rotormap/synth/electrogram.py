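"""Synthetic extracellular electrograms over a rectangular electrode grid.

Emulates multi-electrode-array recordings of a monolayer: each electrode
sees a biphasic depolarisation spike at its local activation time, with
amplitude proportional to the local upstroke slope, followed by a smaller
repolarisation ("T-wave") deflection at activation + local APD90.  The
spike waveform is the derivative of a Gaussian (the classic biphasic
extracellular signature); the T-wave is a low, broad Gaussian bump.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import ConfigurationError, ElectrogramSet


def _dgauss(t: np.ndarray, sigma: float) -> np.ndarray:
    """Negative-then-positive biphasic pulse, unit peak-to-peak span 2."""
    w = -t / sigma * np.exp(0.5 - t**2 / (2 * sigma**2))
    return w


def plane_wave_spike_times(
    grid_shape: tuple[int, int],
    pitch_mm: float,
    velocity_cm_s: float,
    angle_deg: float = 0.0,
    n_beats: int = 1,
    period_ms: float = 1000.0,
    t0_ms: float = 50.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Kinematic ground-truth activation times for a planar wave.

    A wave travelling at ``velocity_cm_s`` in direction ``angle_deg``
    (0 = along columns) reaches electrode (r, c) with delay
    ``(x . n) / v``.  Returns an (n_beats, n_electrodes) array of spike
    times in ms and the electrode (row, col) positions.
    """
    if velocity_cm_s <= 0:
        raise ConfigurationError("velocity must be positive")
    nr, nc = grid_shape
    positions = [(r, c) for r in range(nr) for c in range(nc)]
    theta = np.deg2rad(angle_deg)
    nvec = np.array([np.sin(theta), np.cos(theta)])  # (row, col) direction
    v_mm_ms = velocity_cm_s / 100.0  # cm/s -> mm/ms
    delays = np.array(
        [pitch_mm * (r * nvec[0] + c * nvec[1]) / v_mm_ms for r, c in positions]
    )
    delays -= delays.min()
    beats = t0_ms + np.arange(n_beats)[:, None] * period_ms + delays[None, :]
    return beats, positions


def electrograms_from_events(
    spike_times: np.ndarray,
    positions: list[tuple[int, int]],
    pitch_mm: float,
    duration_ms: float,
    fpd_ms: float | np.ndarray = 250.0,
    spike_amplitude: float | np.ndarray = 1.0,
    twave_amplitude: float = 0.2,
    sample_interval_ms: float = 1.0,
    spike_sigma_ms: float = 2.0,
    twave_sigma_ms: float = 12.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    metadata: dict | None = None,
) -> ElectrogramSet:
    """Build an ElectrogramSet from known per-beat, per-electrode spike times.

    ``spike_times`` is (n_beats, n_electrodes) in ms (NaN = missed beat);
    ``fpd_ms`` and ``spike_amplitude`` may be scalars or per-electrode
    arrays.  A NaN-only column is emitted flat with a quality flag.
    """
    spike_times = np.atleast_2d(np.asarray(spike_times, dtype=float))
    n_el = spike_times.shape[1]
    if len(positions) != n_el:
        raise ConfigurationError("positions must match spike_times columns")
    fpd = np.broadcast_to(np.asarray(fpd_ms, dtype=float), (n_el,))
    amp = np.broadcast_to(np.asarray(spike_amplitude, dtype=float), (n_el,))
    t = np.arange(0.0, duration_ms, sample_interval_ms)
    data = np.zeros((t.size, n_el))
    quality = []
    for e in range(n_el):
        events = spike_times[:, e]
        events = events[np.isfinite(events)]
        if events.size == 0:
            quality.append("flat")
            continue
        quality.append("ok")
        for ts in events:
            data[:, e] += amp[e] * _dgauss(t - ts, spike_sigma_ms)
            data[:, e] += (
                amp[e]
                * twave_amplitude
                * np.exp(-((t - ts - fpd[e]) ** 2) / (2 * twave_sigma_ms**2))
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return ElectrogramSet(
        data=data,
        sample_interval_ms=sample_interval_ms,
        positions=list(positions),
        pitch_mm=pitch_mm,
        quality=quality,
        metadata=metadata or {},
    )


def synth_electrograms(
    u_stack: np.ndarray,
    source_interval_ms: float,
    dx_mm: float,
    grid_shape: tuple[int, int] = (4, 4),
    pitch_mm: float = 1.0,
    mask: np.ndarray | None = None,
    act_threshold: float = 0.5,
    apd_level: float = 0.1,
    spike_gain: float = 1.0,
    twave_amplitude: float = 0.2,
    sample_interval_ms: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> ElectrogramSet:
    """Electrograms sampled from a simulated excitation stack.

    An electrode grid of ``grid_shape`` with physical ``pitch_mm`` is
    centred on the tissue; each electrode reads the pixel nearest its
    position.  Activation times are upward crossings of ``act_threshold``,
    local APD90 the time to fall below ``apd_level``, and spike amplitude
    is proportional to the local maximum upstroke slope times
    ``spike_gain``.  Electrodes outside the tissue mask give flat,
    flagged traces.
    """
    u_stack = np.asarray(u_stack, dtype=float)
    n, h, w = u_stack.shape
    pitch_px = pitch_mm / dx_mm
    nr, nc = grid_shape
    r0 = (h - 1 - (nr - 1) * pitch_px) / 2.0
    c0 = (w - 1 - (nc - 1) * pitch_px) / 2.0
    pix = [
        (int(round(r0 + i * pitch_px)), int(round(c0 + j * pitch_px)))
        for i in range(nr)
        for j in range(nc)
    ]
    if any(not (0 <= r < h and 0 <= c < w) for r, c in pix):
        raise ConfigurationError("electrode grid does not fit inside the tissue")
    positions = [(i, j) for i in range(nr) for j in range(nc)]

    duration = n * source_interval_ms
    spikes = np.full((64, nr * nc), np.nan)
    fpd = np.full(nr * nc, 250.0)
    amps = np.zeros(nr * nc)
    max_beats = 0
    for e, (r, c) in enumerate(pix):
        if mask is not None and not mask[r, c]:
            continue
        trace = u_stack[:, r, c]
        up = np.nonzero((trace[1:] >= act_threshold) & (trace[:-1] < act_threshold))[0]
        max_beats = max(max_beats, up.size)
        slopes = []
        for b, i in enumerate(up[:64]):
            frac = (act_threshold - trace[i]) / max(trace[i + 1] - trace[i], 1e-12)
            spikes[b, e] = (i + frac) * source_interval_ms
            lo, hi = max(0, i - 3), min(n - 1, i + 4)
            slopes.append(np.max(np.diff(trace[lo : hi + 1])) / source_interval_ms)
            down = np.nonzero(trace[i + 1 :] < apd_level)[0]
            if down.size:
                fpd[e] = down[0] * source_interval_ms
        if slopes:
            amps[e] = spike_gain * float(np.mean(slopes))
    spikes = spikes[:max_beats] if max_beats else spikes[:1]
    return electrograms_from_events(
        spikes,
        positions,
        pitch_mm,
        duration_ms=duration,
        fpd_ms=fpd,
        spike_amplitude=amps,
        twave_amplitude=twave_amplitude,
        sample_interval_ms=sample_interval_ms,
        noise_sd=noise_sd,
        seed=seed,
        metadata={"dx_mm": dx_mm, "grid_shape": list(grid_shape)},
    )
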