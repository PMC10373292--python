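"""Piecewise-analytic action-potential trace generator.

Produces single-ROI optical AP (or calcium-transient) traces whose
APD30/APD90 crossing times are known in closed form, for validating the
beat segmentation and APD estimators against exact truth.

Beat shape, measured from the activation onset ``t0`` of each beat:

* linear upstroke from baseline to peak over ``upstroke_ms``;
* full-amplitude plateau of duration ``plateau_fraction * apd90_ms``;
* repolarisation, either linear over ``D`` ms or exponential with time
  constant ``tau``; in both cases ``D``/``tau`` is solved so that the 90 %
  repolarisation crossing falls exactly at ``apd90_ms`` after ``t0``.

The analytic duration at fraction ``x`` is then::

    linear:       APD_x = up + P + x * D,        D  = (apd90 - up - P) / 0.9
    exponential:  APD_x = up + P + tau*ln(1/(1-x)), tau = (apd90 - up - P)/ln 10

with ``up = upstroke_ms`` and ``P = plateau_fraction * apd90_ms``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ..datatypes import ConfigurationError


def analytic_apd(
    fraction: float,
    apd90_ms: float,
    upstroke_ms: float,
    plateau_fraction: float,
    repol: str,
) -> float:
    """Closed-form APD at ``fraction`` repolarisation for the beat shape.

    Durations are measured from the maximum-upstroke-slope instant — the
    midpoint of the linear ramp — matching the activation convention of
    the feature extractor.  ``apd90_ms`` itself is specified from the
    ramp onset, so the returned APD90 equals
    ``apd90_ms - upstroke_ms / 2``.
    """
    up = upstroke_ms
    plateau = plateau_fraction * apd90_ms
    span = apd90_ms - up - plateau
    if span < 0:
        raise ConfigurationError(
            "upstroke + plateau exceed apd90_ms: inconsistent beat shape"
        )
    ref = up / 2.0
    if span == 0:  # square pulse: every fraction crosses at the cliff
        return apd90_ms - ref
    if repol == "linear":
        return up + plateau + fraction * (span / 0.9) - ref
    if repol == "exponential":
        tau = span / math.log(10.0)
        return up + plateau + tau * math.log(1.0 / (1.0 - fraction)) - ref
    raise ConfigurationError(f"unknown repolarisation shape {repol!r}")


def _beat_shape(
    tau_rel: np.ndarray,
    amplitude: float,
    upstroke_ms: float,
    plateau_ms: float,
    span_ms: float,
    repol: str,
) -> np.ndarray:
    out = np.zeros_like(tau_rel)
    if upstroke_ms > 0:
        rising = (tau_rel >= 0) & (tau_rel < upstroke_ms)
        out[rising] = amplitude * tau_rel[rising] / upstroke_ms
    top_end = upstroke_ms + plateau_ms
    out[(tau_rel >= upstroke_ms) & (tau_rel < top_end)] = amplitude
    s = tau_rel - top_end
    if repol == "linear":
        dur = span_ms / 0.9
        falling = (s >= 0) & (s < dur)
        if dur > 0:
            out[falling] = amplitude * (1.0 - s[falling] / dur)
    else:
        tau = span_ms / math.log(10.0)
        falling = s >= 0
        if tau > 0:
            out[falling] = amplitude * np.exp(-s[falling] / tau)
    return out


def synth_ap_trace(
    baseline: float = 0.0,
    amplitude: float = 1.0,
    upstroke_ms: float = 10.0,
    plateau_fraction: float = 0.15,
    apd90_ms: float = 300.0,
    beat_period_ms: float = 1000.0,
    n_beats: int = 5,
    frame_interval_ms: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    repol: str = "exponential",
    onset_ms: float = 100.0,
    fractions: tuple[float, ...] = (0.3, 0.9),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a sampled AP trace plus its exact per-beat feature table.

    Returns
    -------
    times_ms, trace : ndarray
        Sample times and fluorescence values (a.u.).
    truth : DataFrame
        One row per beat with ``activation_ms`` (upstroke onset),
        ``apd{int(100x)}_ms`` for each requested fraction, and
        ``beat_period_ms``.

    Raises
    ------
    ConfigurationError
        If ``apd90_ms >= beat_period_ms`` or the shape is inconsistent
        (e.g. a requested low-fraction APD exceeding the 90 % one cannot
        arise: fractions are monotone by construction).
    """
    if apd90_ms >= beat_period_ms:
        raise ConfigurationError("apd90_ms must be shorter than beat_period_ms")
    if not 0 <= plateau_fraction <= 1:
        raise ConfigurationError("plateau_fraction must lie in [0, 1]")
    plateau_ms = plateau_fraction * apd90_ms
    span_ms = apd90_ms - upstroke_ms - plateau_ms
    if span_ms < 0:
        raise ConfigurationError("upstroke + plateau exceed apd90_ms")

    duration = onset_ms + n_beats * beat_period_ms
    times = np.arange(0.0, duration, frame_interval_ms)
    trace = np.zeros_like(times)
    for k in range(n_beats):
        t0 = onset_ms + k * beat_period_ms
        trace = np.maximum(
            trace,
            _beat_shape(times - t0, amplitude, upstroke_ms, plateau_ms, span_ms, repol),
        )
    trace = baseline + trace
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)

    rows = []
    for k in range(n_beats):
        # activation reference = max-upstroke-slope instant (mid-ramp)
        row = {"beat": k, "activation_ms": onset_ms + k * beat_period_ms + upstroke_ms / 2.0}
        for x in fractions:
            row[f"apd{int(round(100 * x))}_ms"] = analytic_apd(
                x, apd90_ms, upstroke_ms, plateau_fraction, repol
            )
        row["beat_period_ms"] = beat_period_ms if k < n_beats - 1 else np.nan
        rows.append(row)
    return times, trace, pd.DataFrame(rows)
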