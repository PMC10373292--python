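"""Beat segmentation and action-potential duration (APD) metrics.

Computes the per-beat features used to characterise atrial- versus
ventricular-like electrophysiology in monolayer recordings: beat period,
APD30, APD90 and the APD30:90 ratio (a shape index — low for triangular
atrial-like APs, high for plateaued ventricular-like APs).  The same
machinery serves calcium transients with fractions {0.5, 0.9}.

Conventions
-----------
* Activation time is the instant of maximum upstroke slope (max dF/dt);
  with ties, the earliest sample wins.  APDs are measured from activation,
  the usual optical-mapping convention.
* Baseline is the median over the diastolic 30 % of the preceding
  inter-beat interval closest to activation — robust to residual drift.
* APD_x is the first time after the peak at which fluorescence falls
  below ``peak - x * (peak - baseline)``, with sub-frame precision by
  linear interpolation.  Beats with no crossing before the next
  activation are flagged, not raised.
* No rate correction is applied to APDs (rate correction exists only for
  MEA field-potential durations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError

#: default repolarisation fractions for calcium transients (CaD50 / CaD90);
#: voltage traces use (0.3, 0.9)
CALCIUM_FRACTIONS = (0.5, 0.9)


def condition_trace(
    trace: np.ndarray, fs_hz: float, lowpass_hz: float | None = 30.0, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass conditioning for feature extraction.

    Unlike the band-pass used for phase analysis, this keeps the DC level
    and AP morphology intact while suppressing out-of-band noise.
    ``lowpass_hz=None`` (or a cutoff at/above Nyquist) returns a copy.
    """
    from scipy.signal import butter, sosfiltfilt

    x = np.asarray(trace, dtype=float)
    if lowpass_hz is None or lowpass_hz >= fs_hz / 2:
        return x.copy()
    sos = butter(order, lowpass_hz, btype="lowpass", fs=fs_hz, output="sos")
    return sosfiltfilt(sos, x)


def detect_beats(
    times_ms: np.ndarray,
    trace: np.ndarray,
    min_period_ms: float = 200.0,
    prominence_fraction: float = 0.3,
    polarity: int = 1,
    conditioned: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Locate beats on a single-ROI trace.

    Returns ``(activation_times_ms, peak_times_ms, flags)``.  Peaks are
    found on the conditioned trace (``conditioned`` defaults to the raw
    trace); the activation instant is the maximum-dF/dt point on the raw
    upstroke (earliest sample on ties), refined to sub-sample precision
    by the centroid of the derivative bump.  Peaks closer than
    ``min_period_ms`` are merged keeping the larger-amplitude event.  A
    flat or beat-free trace yields empty arrays plus a ``"no_beats"``
    flag rather than an exception.
    """
    from scipy.signal import find_peaks

    if min_period_ms <= 0:
        raise ConfigurationError("min_period_ms must be positive")
    times_ms = np.asarray(times_ms, dtype=float)
    x_raw = np.asarray(trace, dtype=float) * polarity
    x = x_raw if conditioned is None else np.asarray(conditioned, dtype=float) * polarity
    span = np.ptp(x)
    if x.size < 3 or span == 0:
        return np.array([]), np.array([]), ["no_beats"]
    dt = float(np.median(np.diff(times_ms)))
    distance = max(1, int(round(min_period_ms / dt)))
    peaks, _ = find_peaks(x, prominence=prominence_fraction * span, distance=distance)
    if peaks.size == 0:
        return np.array([]), np.array([]), ["no_beats"]

    deriv = np.diff(x_raw)
    acts = []
    for i, p in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else 0
        lo = max(lo, p - distance)
        if p <= lo:
            lo = max(0, p - 1)
        seg = deriv[lo:p] if p > lo else deriv[max(0, p - 1) : p]
        j = int(np.argmax(seg)) + lo
        # sub-sample refinement: centroid of the derivative bump; the
        # diff sample j spans (t_j, t_{j+1}), centred at j + 0.5
        j0, j1 = max(0, j - 1), min(deriv.size, j + 2)
        w = np.clip(deriv[j0:j1], 0, None)
        centre = (np.arange(j0, j1) + 0.5) @ w / w.sum() if w.sum() > 0 else j + 0.5
        acts.append(times_ms[0] + centre * dt)
    return np.asarray(acts), times_ms[peaks], []


def compute_apd(
    times_ms: np.ndarray,
    trace: np.ndarray,
    activation_ms: float,
    fraction: float,
    next_activation_ms: float | None = None,
    prev_activation_ms: float | None = None,
    polarity: int = 1,
    default_diastole_ms: float = 300.0,
) -> tuple[float, float, float]:
    """APD at one repolarisation fraction for one beat.

    Returns ``(apd_ms, peak_time_ms, amplitude)``; ``apd_ms`` is NaN when
    the trace never crosses the repolarisation level before the next
    activation (fusion/alternans guard).
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must lie in (0, 1]")
    times_ms = np.asarray(times_ms, dtype=float)
    x = np.asarray(trace, dtype=float) * polarity

    # diastolic baseline: median over the 30% of the preceding interval
    # nearest to activation
    if prev_activation_ms is not None:
        win = 0.3 * (activation_ms - prev_activation_ms)
    else:
        win = default_diastole_ms
    base_sel = (times_ms >= activation_ms - win) & (times_ms < activation_ms)
    baseline = float(np.median(x[base_sel])) if base_sel.any() else float(x[0])

    end = next_activation_ms if next_activation_ms is not None else times_ms[-1] + 1
    beat_sel = np.nonzero((times_ms >= activation_ms) & (times_ms < end))[0]
    if beat_sel.size < 2:
        return np.nan, np.nan, np.nan
    seg = x[beat_sel]
    tseg = times_ms[beat_sel]
    pk = int(np.argmax(seg))
    # noise-adaptive peak: a first pass takes the contiguous run within
    # 2.5 noise-SD of the maximum; its median re-centres the plateau
    # level, and the mean over the run within +/- 2 SD of that median is
    # free of the max-of-noise selection bias (and averages a flat
    # plateau without shape bias)
    sigma_hat = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    centre_val = float(np.median(seg[seg >= seg[pk] - 2.5 * sigma_hat]))
    tol2 = max(2.0 * sigma_hat, 1e-12)

    def _expand(start: int, step: int) -> int:
        # extend while above centre - tol2, tolerating isolated noise dips
        # (stop only at two consecutive below-threshold samples)
        k, last_good, misses = start, start, 0
        while 0 <= k + step < seg.size and misses < 2:
            k += step
            if seg[k] >= centre_val - tol2:
                last_good, misses = k, 0
            else:
                misses += 1
        return last_good

    lo_pk2, hi_pk2 = _expand(pk, -1), _expand(pk, +1)
    peak_val = float(np.median(seg[lo_pk2 : hi_pk2 + 1]))
    peak_time = float(tseg[pk])
    amplitude = peak_val - baseline
    if amplitude <= 0:
        return np.nan, peak_time, amplitude
    level = peak_val - fraction * amplitude
    below = np.nonzero(seg[pk:] < level)[0]
    if below.size == 0:
        return np.nan, peak_time, amplitude
    j = below[0] + pk
    if j == 0:
        return np.nan, peak_time, amplitude
    # refine the crossing by a linear fit of the falling limb.  A pilot
    # slope over +/- 6 samples converts value bounds to a time window
    # (up to 50% of the amplitude above the level, but past the peak; at
    # most 75% of the remaining drop to baseline below it, keeping the
    # fit off the flat diastolic tail).  A residual-based curvature guard
    # then trims the far (upper) end until the window is locally linear,
    # so straight limbs use all their samples while curved ones shrink
    # to a local fit.  Falls back to two-point interpolation.
    dt = float(np.median(np.diff(tseg))) if tseg.size > 1 else 1.0
    p0, p1 = max(pk + 1, j - 6), min(seg.size, j + 7)
    t_cross = None
    if p1 - p0 >= 3:
        s_pilot = np.polyfit(tseg[p0:p1], seg[p0:p1], 1)[0]
        # near-vertical repolarisation (square-pulse-like): regression
        # around the cliff is meaningless; interpolation is exact there
        if seg[j - 1] - seg[j] > 0.3 * amplitude:
            s_pilot = 0.0
        if s_pilot < 0:
            up_bound = float(
                np.clip((peak_val - level) - 0.15 * amplitude, 0.15 * amplitude, 0.75 * amplitude)
            )
            h_up = min(60.0, up_bound / (-s_pilot) / dt)
            h_dn = min(25.0, 0.75 * (level - baseline) / (-s_pilot) / dt)
            lo = max(pk + 1, j - int(h_up))
            hi = min(seg.size, j + 1 + int(h_dn))
            while hi - lo >= 3:
                slope, intercept = np.polyfit(tseg[lo:hi], seg[lo:hi], 1)
                resid = seg[lo:hi] - (slope * tseg[lo:hi] + intercept)
                if (
                    hi - lo <= 8
                    or float(np.sqrt(np.mean(resid**2))) <= max(1.3 * sigma_hat, 1e-12)
                ):
                    break
                lo += max(1, (j - lo) // 4)  # trim the high-leverage top end
            if hi - lo >= 3 and slope < 0:
                t_fit = (level - intercept) / slope
                if tseg[lo] - 2 * dt <= t_fit <= tseg[hi - 1] + 2 * dt:
                    t_cross = float(t_fit)
    if t_cross is None:
        y1v, y0v = seg[j], seg[j - 1]
        t1v, t0v = tseg[j], tseg[j - 1]
        t_cross = (
            t0v + (y0v - level) / (y0v - y1v) * (t1v - t0v) if y0v != y1v else float(t1v)
        )
    return t_cross - activation_ms, peak_time, amplitude


def beat_period(activations_ms: np.ndarray) -> np.ndarray:
    """Successive inter-activation intervals (empty for < 2 activations)."""
    a = np.asarray(activations_ms, dtype=float)
    if a.size < 2:
        return np.array([])
    return np.diff(a)


def analyze_trace(
    times_ms: np.ndarray,
    trace: np.ndarray,
    fractions: tuple[float, ...] = (0.3, 0.9),
    min_period_ms: float = 200.0,
    prominence_fraction: float = 0.3,
    polarity: int = 1,
    modality: str = "voltage",
    lowpass_hz: float | None = None,
) -> pd.DataFrame:
    """Per-beat feature table for one trace.

    ``lowpass_hz`` optionally applies zero-phase low-pass conditioning
    (off by default: the level-crossing and peak estimators are already
    noise-adaptive, and IIR smoothing overshoots at sharp AP corners);
    activation timing always uses the raw derivative.  Columns: ``activation_time_ms, peak_time_ms,
    apd{..}_ms`` per fraction, ``apd_ratio`` (first / last requested
    fraction), ``beat_period_ms`` (NaN for the last beat),
    ``amplitude``, ``flag``.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    fs = 1000.0 / float(np.median(np.diff(times_ms)))
    cond = condition_trace(trace, fs, lowpass_hz)
    acts, peaks, flags = detect_beats(
        times_ms, trace, min_period_ms, prominence_fraction, polarity, conditioned=cond
    )
    rows = []
    periods = beat_period(acts)
    for i, act in enumerate(acts):
        nxt = acts[i + 1] if i + 1 < len(acts) else None
        prv = acts[i - 1] if i > 0 else None
        row: dict = {"activation_time_ms": act, "modality": modality, "flag": ""}
        apds = {}
        for f in fractions:
            apd, pk_t, amp = compute_apd(
                times_ms, cond, act, f,
                next_activation_ms=nxt, prev_activation_ms=prv, polarity=polarity,
            )
            apds[f] = apd
            row[f"apd{int(round(100 * f))}_ms"] = apd
            row["peak_time_ms"] = pk_t
            row["amplitude"] = amp
        lo_f, hi_f = min(fractions), max(fractions)
        if np.isfinite(apds[lo_f]) and np.isfinite(apds[hi_f]) and apds[hi_f] > 0:
            row["apd_ratio"] = apds[lo_f] / apds[hi_f]
        else:
            row["apd_ratio"] = np.nan
            row["flag"] = "missing_apd"
        row["beat_period_ms"] = periods[i] if i < len(periods) else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["flags"] = flags
    return df


def summarize_trace(
    beats: pd.DataFrame, identifiers: dict | None = None
) -> pd.DataFrame:
    """One summary row per trace: mean and median of each metric.

    Flagged beats are excluded from the summaries.  ``identifiers``
    (line, differentiation N, technical replicate n, protocol label) are
    attached verbatim as leading columns.
    """
    identifiers = identifiers or {}
    metrics = [
        c
        for c in beats.columns
        if c.endswith("_ms") or c in ("apd_ratio", "amplitude")
        if c not in ("activation_time_ms", "peak_time_ms")
    ]
    good = beats[beats["flag"] == ""] if "flag" in beats and len(beats) else beats
    row = dict(identifiers)
    row["n_beats"] = int(len(beats))
    row["n_flagged"] = int((beats["flag"] != "").sum()) if len(beats) else 0
    for m in metrics:
        vals = good[m].dropna() if len(good) else pd.Series(dtype=float)
        row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
        row[f"{m}_median"] = vals.median() if len(vals) else np.nan
    return pd.DataFrame([row])
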