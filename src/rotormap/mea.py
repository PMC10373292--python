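"""Field-potential metrics from multi-electrode-array electrograms.

Per electrode and beat: depolarisation spike time and amplitude, field
potential duration (FPD, spike to the repolarisation "T-wave" extremum)
and its Fridericia rate-corrected value FPDc = FPD / (RR_s)^(1/3) with
the beat period RR expressed in seconds (the standard cardiology
convention).  Across the grid: conduction velocity by a least-squares
plane fit of activation time on electrode position.  Paired pre/post
drug comparisons are reported as vehicle-adjusted ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, ElectrogramSet


def detect_spikes(
    trace: np.ndarray,
    sample_interval_ms: float,
    min_period_ms: float = 200.0,
    k_mad: float = 6.0,
    amp_window_ms: float = 10.0,
    min_amp_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Depolarisation spikes on one electrogram.

    The spike instant is the extremum of the first derivative within each
    suprathreshold burst (threshold ``k_mad`` times the MAD of the
    derivative — adaptive to the noise floor), refined to sub-sample
    precision by parabolic interpolation of the derivative magnitude;
    amplitude is max - min of the biphasic complex within
    +/- ``amp_window_ms``.  Detections whose amplitude falls below
    ``min_amp_fraction`` of the median detected amplitude are discarded
    as noise outliers.  Returns ``(spike_times_ms, amplitudes)``, both
    empty for a flat trace.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 4:
        return np.array([]), np.array([])
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0 and np.ptp(np.abs(d)) == 0:
        return np.array([]), np.array([])
    thr = k_mad * (mad if mad > 0 else np.max(np.abs(d)) / k_mad / 2)
    above = np.nonzero(np.abs(d) > thr)[0]
    if above.size == 0:
        return np.array([]), np.array([])
    gap = max(1, int(round(min_period_ms / sample_interval_ms)))
    half_w = max(1, int(round(amp_window_ms / sample_interval_ms)))
    splits = np.nonzero(np.diff(above) > gap)[0] + 1
    times, amps = [], []
    ad = np.abs(d)
    for cluster in np.split(above, splits):
        i = cluster[int(np.argmax(ad[cluster]))]
        shift = 0.0
        if 0 < i < ad.size - 1:
            y0, y1, y2 = ad[i - 1], ad[i], ad[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        t = (i + 0.5 + shift) * sample_interval_ms
        lo, hi = max(0, i - half_w), min(x.size, i + half_w + 1)
        times.append(t)
        amps.append(float(x[lo:hi].max() - x[lo:hi].min()))
    times_arr, amps_arr = np.asarray(times), np.asarray(amps)
    if amps_arr.size > 1:
        keep = amps_arr >= min_amp_fraction * np.median(amps_arr)
        times_arr, amps_arr = times_arr[keep], amps_arr[keep]
    return times_arr, amps_arr


def measure_fpd(
    trace: np.ndarray,
    sample_interval_ms: float,
    spike_time_ms: float,
    next_spike_time_ms: float | None = None,
    blanking_ms: float = 50.0,
    margin_ms: float = 50.0,
    noise_floor_k: float = 4.0,
) -> float:
    """FPD: spike to the T-wave extremum, polarity-agnostic.

    The T-wave is the largest absolute deflection from the local baseline
    within ``(spike + blanking, next_spike - margin)``, refined to
    sub-sample precision by parabolic interpolation.  Returns NaN when no
    deflection clears ``noise_floor_k`` robust-SD of the search window.
    """
    x = np.asarray(trace, dtype=float)
    t_end = (
        next_spike_time_ms - margin_ms
        if next_spike_time_ms is not None
        else x.size * sample_interval_ms
    )
    i0 = int(np.ceil((spike_time_ms + blanking_ms) / sample_interval_ms))
    i1 = int(np.floor(t_end / sample_interval_ms))
    if i1 - i0 < 3 or i0 < 0 or i1 > x.size:
        return np.nan
    win = x[i0:i1]
    baseline = np.median(win)
    dev = np.abs(win - baseline)
    noise = 1.4826 * np.median(np.abs(win - np.median(win)))
    j = int(np.argmax(dev))
    if dev[j] <= noise_floor_k * max(noise, 1e-30):
        return np.nan
    # parabolic sub-sample refinement on the absolute deflection
    if 0 < j < win.size - 1:
        y0, y1, y2 = dev[j - 1], dev[j], dev[j + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    t_peak = (i0 + j + shift) * sample_interval_ms
    return t_peak - spike_time_ms


def fridericia(fpd_ms: float, beat_period_ms: float) -> float:
    """Fridericia rate correction: FPDc = FPD / (RR in seconds)^(1/3)."""
    if fpd_ms <= 0 or beat_period_ms <= 0:
        raise ValueError("fpd_ms and beat_period_ms must be positive")
    return fpd_ms / (beat_period_ms / 1000.0) ** (1.0 / 3.0)


@dataclass
class ConductionEstimate:
    """Planar conduction-velocity fit across the electrode grid."""

    velocity_cm_s: float
    direction: tuple[float, float]  # unit (row, col) components
    residual_rms_ms: float
    n_electrodes: int
    n_beats: int = 1
    flag: str = ""


def conduction_velocity(
    spike_times_ms: np.ndarray,
    positions: list[tuple[int, int]],
    pitch_mm: float,
    v_max_cm_s: float = 200.0,
) -> ConductionEstimate:
    """CV from a least-squares plane fit of activation time on position.

    ``spike_times_ms`` is (n_beats, n_electrodes) (one row allowed); the
    per-beat fits give slowness vectors (ms/mm) that are averaged before
    inversion, so timing noise cancels across beats.  Collinear
    electrode geometry raises; a gradient too small to resolve (implied
    speed above ``v_max_cm_s``) is flagged ``"unresolvable"``.
    """
    st = np.atleast_2d(np.asarray(spike_times_ms, dtype=float))
    pos = np.asarray(positions, dtype=float) * pitch_mm  # (row_mm, col_mm)
    slowness = []
    residuals = []
    n_used = 0
    for beat in st:
        good = np.isfinite(beat)
        if good.sum() < 3:
            continue
        p = pos[good]
        if np.linalg.matrix_rank(p - p.mean(axis=0)) < 2:
            raise ValueError("electrode positions are collinear; planar fit impossible")
        a = np.column_stack([np.ones(good.sum()), p[:, 0], p[:, 1]])
        coef, *_ = np.linalg.lstsq(a, beat[good], rcond=None)
        fit = a @ coef
        slowness.append(coef[1:])
        residuals.append(np.sqrt(np.mean((beat[good] - fit) ** 2)))
        n_used = max(n_used, int(good.sum()))
    if not slowness:
        raise ValueError("need at least 3 electrodes with spike times for a beat")
    s = np.mean(slowness, axis=0)  # ms/mm
    s_norm = float(np.hypot(*s))
    v_min_slowness = 100.0 / max(v_max_cm_s, 1e-9)  # ms/mm at v_max
    if s_norm < v_min_slowness:
        return ConductionEstimate(
            velocity_cm_s=np.inf,
            direction=(0.0, 0.0),
            residual_rms_ms=float(np.mean(residuals)),
            n_electrodes=n_used,
            n_beats=len(slowness),
            flag="unresolvable",
        )
    v_cm_s = 100.0 / s_norm  # mm/ms -> cm/s
    direction = (float(s[0] / s_norm), float(s[1] / s_norm))
    return ConductionEstimate(
        velocity_cm_s=float(v_cm_s),
        direction=direction,
        residual_rms_ms=float(np.mean(residuals)),
        n_electrodes=n_used,
        n_beats=len(slowness),
    )


def analyze_electrograms(
    egs: ElectrogramSet,
    min_period_ms: float = 200.0,
    k_mad: float = 6.0,
    blanking_ms: float = 50.0,
    margin_ms: float = 50.0,
) -> tuple[pd.DataFrame, ConductionEstimate | None]:
    """Per-beat, per-electrode feature table plus a grid CV estimate.

    Beats are matched across electrodes against the electrode with the
    most spikes (nearest spike within half a beat period).  Returns the
    tidy feature table (``electrode, row, col, beat, spike_time_ms,
    spike_amplitude, beat_period_ms, fpd_ms, fpdc_ms, flag``) and the
    conduction estimate (None when fewer than 3 electrodes have beats).
    """
    spikes: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    for e in range(egs.n_electrodes):
        t, a = detect_spikes(egs.data[:, e], egs.sample_interval_ms, min_period_ms, k_mad)
        spikes.append(t)
        amps.append(a)
    ref = int(np.argmax([len(t) for t in spikes]))
    ref_times = spikes[ref]
    if ref_times.size == 0:
        return pd.DataFrame(), None
    period = float(np.median(np.diff(ref_times))) if ref_times.size > 1 else np.inf
    tol = period / 2 if np.isfinite(period) else np.inf

    n_beats = ref_times.size
    beat_matrix = np.full((n_beats, egs.n_electrodes), np.nan)
    amp_matrix = np.full((n_beats, egs.n_electrodes), np.nan)
    for e in range(egs.n_electrodes):
        for b, t_ref in enumerate(ref_times):
            if spikes[e].size == 0:
                continue
            k = int(np.argmin(np.abs(spikes[e] - t_ref)))
            if abs(spikes[e][k] - t_ref) <= tol:
                beat_matrix[b, e] = spikes[e][k]
                amp_matrix[b, e] = amps[e][k]

    rows = []
    for e in range(egs.n_electrodes):
        st = beat_matrix[:, e]
        own = st[np.isfinite(st)]
        per_e_period = float(np.median(np.diff(own))) if own.size > 1 else np.nan
        for b in range(n_beats):
            if not np.isfinite(st[b]):
                continue
            nxt = st[b + 1] if b + 1 < n_beats and np.isfinite(st[b + 1]) else None
            fpd = measure_fpd(
                egs.data[:, e], egs.sample_interval_ms, st[b], nxt,
                blanking_ms=blanking_ms, margin_ms=margin_ms,
            )
            bp = (nxt - st[b]) if nxt is not None else per_e_period
            fpdc = (
                fridericia(fpd, bp)
                if np.isfinite(fpd) and fpd > 0 and np.isfinite(bp) and bp > 0
                else np.nan
            )
            rows.append(
                dict(
                    electrode=egs.names[e],
                    row=egs.positions[e][0],
                    col=egs.positions[e][1],
                    beat=b,
                    spike_time_ms=st[b],
                    spike_amplitude=amp_matrix[b, e],
                    beat_period_ms=bp,
                    fpd_ms=fpd,
                    fpdc_ms=fpdc,
                    flag="" if np.isfinite(fpd) else "no_twave",
                )
            )
    table = pd.DataFrame(rows)
    cv = None
    if np.isfinite(beat_matrix).sum(axis=1).max(initial=0) >= 3:
        try:
            cv = conduction_velocity(beat_matrix, egs.positions, egs.pitch_mm)
        except ValueError:
            cv = None
    return table, cv


def paired_drug_delta(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    vehicle_pre: pd.DataFrame,
    vehicle_post: pd.DataFrame,
    metrics: tuple[str, ...] = ("beat_period_ms", "fpd_ms", "fpdc_ms", "spike_amplitude"),
) -> pd.DataFrame:
    """Vehicle-adjusted paired drug effects per electrode.

    Each input is a per-electrode table (one row per electrode, indexed
    or keyed by ``electrode``) of metric medians.  For each metric m:
    ``delta = (m_post / m_pre) / (m_vehicle_post / m_vehicle_pre)``, so a
    shared drift in the vehicle cancels; absolute differences
    ``m_post - m_pre`` are reported alongside.  Electrode sets must match
    exactly (recordings are taken from the same "golden" electrodes).
    """
    frames = {"pre": pre, "post": post, "vehicle_pre": vehicle_pre, "vehicle_post": vehicle_post}
    keyed = {}
    for name, df in frames.items():
        d = df.set_index("electrode") if "electrode" in df.columns else df
        keyed[name] = d
    ref = set(keyed["pre"].index)
    for name, d in keyed.items():
        if set(d.index) != ref:
            offenders = sorted(set(d.index) ^ ref)
            raise ValueError(f"electrode sets differ in {name!r}: {offenders}")
    rows = []
    for el in sorted(ref):
        row = {"electrode": el}
        for m in metrics:
            p0 = keyed["pre"].loc[el, m]
            p1 = keyed["post"].loc[el, m]
            v0 = keyed["vehicle_pre"].loc[el, m]
            v1 = keyed["vehicle_post"].loc[el, m]
            with np.errstate(divide="ignore", invalid="ignore"):
                row[f"{m}_delta"] = (p1 / p0) / (v1 / v0)
            row[f"{m}_diff"] = p1 - p0
        rows.append(row)
    out = pd.DataFrame(rows)
    med = out.select_dtypes("number").median()
    out.attrs["recording_medians"] = med.to_dict()
    return out
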