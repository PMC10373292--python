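"""Two-variable excitable-medium simulation (Aliev–Panfilov kinetics).

Serves as the ground-truth generator for the whole pipeline: it produces
voltage stacks with *known* activation times, action-potential durations
and spiral-tip trajectories, so that every downstream estimator (optical
preprocessing, APD features, phase mapping, MEA metrics) can be validated
without any experimental recording.

Model
-----
The Aliev–Panfilov monodomain system in dimensionless time ``t'``::

    du/dt' = D' lap(u) - k u (u - a)(u - 1) - u v
    dv/dt' = (eps0 + mu1 v / (u + mu2)) * (-v - k u (u - a - 1))

with no-flux boundaries (mirrored edges, matching the edge of a cultured
monolayer).  One dimensionless time unit corresponds to
``time_scale_ms`` milliseconds (12.9 ms by default, the conventional
scaling for this model), so the diffusion coefficient in mm^2/ms and the
pixel pitch ``dx`` in mm/pixel convert to a per-pixel diffusion
``D' = diffusion * time_scale_ms / dx**2``.

Integration is forward Euler; the explicit stability bound
``dt_sim <= dx**2 / (4 * diffusion)`` is enforced at construction.

The spiral-tip oracle implemented here (`isopotential_tips`) locates tips
as intersections of the ``u = u_iso`` isoline at two nearby times.  It is
deliberately independent of the Hilbert-phase singularity detector in
:mod:`rotormap.phase`: the two share no code and the oracle never sees a
phase map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString
from shapely.ops import unary_union
from skimage import measure

from ..datatypes import ConfigurationError, GroundTruth

DEFAULT_KINETICS = {"k": 8.0, "a": 0.1, "eps0": 0.002, "mu1": 0.2, "mu2": 0.3}


@dataclass
class MediumParams:
    """Geometry, diffusion and kinetics of the simulated monolayer.

    ``dx`` is mm/pixel; ``dt_sim`` ms; ``diffusion`` mm^2/ms.  The default
    set sustains a stable spiral on a 128 x 128 grid under cross-field
    stimulation.
    """

    grid_height: int = 128
    grid_width: int = 128
    dx: float = 1.0
    dt_sim: float = 0.5
    diffusion: float = 0.1
    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    time_scale_ms: float = 12.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_height < 16 or self.grid_width < 16:
            raise ConfigurationError("grid dimensions must be >= 16")
        bound = self.dx**2 / (4.0 * self.diffusion)
        if self.dt_sim > bound + 1e-12:
            raise ConfigurationError(
                f"dt_sim={self.dt_sim} violates the explicit stability bound "
                f"dx^2/(4 D) = {bound:.4g} ms"
            )
        kin = dict(DEFAULT_KINETICS, **self.kinetics)
        if not 0 < kin["a"] < 0.5:
            raise ConfigurationError("kinetics parameter a must lie in (0, 0.5)")
        if any(kin[name] <= 0 for name in ("k", "eps0", "mu1", "mu2")):
            raise ConfigurationError("all kinetics constants must be positive")
        self.kinetics = kin


@dataclass
class StimulusProtocol:
    """Stimulation sequence applied to the medium.

    kind
        ``planar_s1`` — repeated planar pulses from an edge strip;
        ``cross_field_s2`` — one planar S1 followed by a half-field S2
        timed into the S1 repolarisation tail (classic spiral initiation);
        ``point_burst`` — repeated pulses in a small central region.
    region
        (row0, row1, col0, col1) half-open rectangle; ``None`` chooses a
        sensible default for the kind.
    s2_offset_ms
        Delay from S1 onset to the S2 pulse (cross_field_s2 only).
    """

    kind: str = "planar_s1"
    onset_ms: float = 10.0
    period_ms: float = 100.0
    count: int = 1
    region: tuple[int, int, int, int] | None = None
    s2_offset_ms: float = 850.0
    stim_duration_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("planar_s1", "cross_field_s2", "point_burst"):
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}")
        if self.count > 1 and not self.period_ms > 0:
            raise ConfigurationError("period_ms must be positive when count > 1")


def _default_region(kind: str, h: int, w: int) -> tuple[int, int, int, int]:
    if kind in ("planar_s1", "cross_field_s2"):
        return (0, h, 0, max(3, w // 32))
    size = max(3, min(h, w) // 16)
    r0 = h // 2 - size // 2
    c0 = w // 2 - size // 2
    return (r0, r0 + size, c0, c0 + size)


def _check_region(region: tuple[int, int, int, int], h: int, w: int) -> None:
    r0, r1, c0, c1 = region
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ConfigurationError(f"stimulus region {region} outside {h}x{w} grid")


def _laplacian_noflux(u: np.ndarray, out: np.ndarray) -> np.ndarray:
    """5-point Laplacian with mirrored (no-flux) boundaries, pixel units."""
    out[:] = -4.0 * u
    out[1:, :] += u[:-1, :]
    out[0, :] += u[0, :]
    out[:-1, :] += u[1:, :]
    out[-1, :] += u[-1, :]
    out[:, 1:] += u[:, :-1]
    out[:, 0] += u[:, 0]
    out[:, :-1] += u[:, 1:]
    out[:, -1] += u[:, -1]
    return out


def simulate_medium(
    params: MediumParams,
    protocol: StimulusProtocol,
    duration_ms: float,
    store_interval_ms: float | None = None,
    apd_fractions: tuple[float, ...] = (0.9,),
    tip_delta_ms: float = 20.0,
    progress: bool = False,
) -> tuple[np.ndarray, float, GroundTruth]:
    """Integrate the medium and record ground truth.

    Returns
    -------
    u_stack : ndarray (T, H, W), float32 in [0, 1]
        Excitation variable sampled every ``store_interval_ms``
        (``dt_sim`` if not given).
    store_interval_ms : float
        The actual sampling interval of the returned stack.
    truth : GroundTruth
        Per-pixel activation times and APD maps (threshold crossings of
        ``u`` at 0.5 up / (1 - fraction) down, linearly interpolated
        between steps), the isopotential tip trajectory, and — for planar
        S1 — the conduction velocity fitted from activation times.
    """
    h, w = params.grid_height, params.grid_width
    region = protocol.region or _default_region(protocol.kind, h, w)
    _check_region(region, h, w)
    if protocol.count >= 1 and duration_ms < protocol.onset_ms:
        raise ConfigurationError("duration_ms must cover at least stimulus onset")

    kin = params.kinetics
    k, a, eps0, mu1, mu2 = (kin[n] for n in ("k", "a", "eps0", "mu1", "mu2"))
    dt = params.dt_sim / params.time_scale_ms  # dimensionless step
    d_px = params.diffusion * params.time_scale_ms / params.dx**2

    if store_interval_ms is None:
        store_interval_ms = params.dt_sim
    store_every = max(1, int(round(store_interval_ms / params.dt_sim)))
    store_interval_ms = store_every * params.dt_sim

    n_steps = int(round(duration_ms / params.dt_sim))
    n_store = n_steps // store_every + 1

    u = np.zeros((h, w))
    v = np.zeros((h, w))
    lap = np.empty_like(u)
    stack = np.empty((n_store, h, w), dtype=np.float32)
    stack[0] = 0.0

    # stimulus schedule: (step, rectangle), pulse held for stim_duration_ms
    stim_steps = max(1, int(round(protocol.stim_duration_ms / params.dt_sim)))
    pulses: list[tuple[int, tuple[int, int, int, int]]] = []
    for i in range(protocol.count):
        t_on = protocol.onset_ms + i * protocol.period_ms
        pulses.append((int(round(t_on / params.dt_sim)), region))
    if protocol.kind == "cross_field_s2":
        s2_step = int(round((protocol.onset_ms + protocol.s2_offset_ms) / params.dt_sim))
        pulses.append((s2_step, (h // 2, h, 0, w)))
    pulse_map: dict[int, list[tuple[int, int, int, int]]] = {}
    for start, rect in pulses:
        for s in range(start, start + stim_steps):
            pulse_map.setdefault(s, []).append(rect)

    # ground-truth trackers
    act_thresh = 0.5
    above_act = np.zeros((h, w), dtype=bool)
    beat_idx = np.zeros((h, w), dtype=np.int32)
    act_maps: list[np.ndarray] = []
    repol_levels = {f: 1.0 - f for f in apd_fractions}
    above_rep = {f: np.zeros((h, w), dtype=bool) for f in apd_fractions}
    apd_maps: dict[float, list[np.ndarray]] = {f: [] for f in apd_fractions}
    rows_idx, cols_idx = np.indices((h, w))

    def _record_crossing(maps, idx_arr, where, t_interp):
        kmax = int(idx_arr[where].max()) if where.any() else -1
        while len(maps) <= kmax:
            maps.append(np.full((h, w), np.nan))
        for kb in range(kmax + 1):
            sel = where & (idx_arr == kb)
            if sel.any():
                maps[kb][sel] = t_interp[sel]

    u_prev = u.copy()
    for step in range(1, n_steps + 1):
        _laplacian_noflux(u, lap)
        eps = eps0 + mu1 * v / (u + mu2)
        du = d_px * lap - k * u * (u - a) * (u - 1.0) - u * v
        dv = eps * (-v - k * u * (u - a - 1.0))
        np.copyto(u_prev, u)
        u += dt * du
        v += dt * dv
        for rect in pulse_map.get(step, ()):
            r0, r1, c0, c1 = rect
            u[r0:r1, c0:c1] = 1.0
        np.clip(u, 0.0, 1.2, out=u)

        t_now = step * params.dt_sim
        # upstroke crossings (linear interpolation between steps)
        newly_up = (u >= act_thresh) & ~above_act
        if newly_up.any():
            frac = (act_thresh - u_prev) / np.where(u - u_prev == 0, 1, u - u_prev)
            t_interp = t_now - params.dt_sim + np.clip(frac, 0, 1) * params.dt_sim
            _record_crossing(act_maps, beat_idx, newly_up, t_interp)
            beat_idx[newly_up] += 1
        above_act = u >= act_thresh
        # repolarisation crossings
        for f, level in repol_levels.items():
            was_above = above_rep[f]
            newly_down = was_above & (u < level)
            if newly_down.any():
                frac = (u_prev - level) / np.where(u_prev - u == 0, 1, u_prev - u)
                t_interp = t_now - params.dt_sim + np.clip(frac, 0, 1) * params.dt_sim
                kb_arr = beat_idx - 1  # APD belongs to the most recent beat
                valid = newly_down & (kb_arr >= 0)
                dur = np.full((h, w), np.nan)
                maps = apd_maps[f]
                while len(maps) < len(act_maps):
                    maps.append(np.full((h, w), np.nan))
                for kb in range(len(act_maps)):
                    sel = valid & (kb_arr == kb)
                    if sel.any():
                        maps[kb][sel] = t_interp[sel] - act_maps[kb][sel]
            above_rep[f] = u >= level

        if step % store_every == 0:
            stack[step // store_every] = np.clip(u, 0.0, 1.0)

    truth = GroundTruth(activation_times=act_maps, apd_maps=apd_maps)
    truth.tip_trajectory = isopotential_tips(
        stack, store_interval_ms, delta_ms=tip_delta_ms
    )
    if protocol.kind == "planar_s1" and act_maps:
        truth.plane_velocity_cm_s = _planar_velocity(act_maps[0], region, params.dx)
    return stack, store_interval_ms, truth


def _planar_velocity(
    act_map: np.ndarray, region: tuple[int, int, int, int], dx_mm: float
) -> float | None:
    """CV (cm/s) from regressing first-beat activation time on distance.

    The propagation axis is taken perpendicular to the stimulus strip
    (columns if the strip spans full height, rows otherwise).
    """
    r0, r1, c0, c1 = region
    axis = 1 if (r1 - r0) >= (c1 - c0) else 0
    coords = np.indices(act_map.shape)[axis].ravel() * dx_mm
    t = act_map.ravel()
    good = np.isfinite(t)
    if good.sum() < 10:
        return None
    slope = np.polyfit(coords[good], t[good], 1)[0]  # ms / mm
    if abs(slope) < 1e-12:
        return None
    return abs(1.0 / slope) * 100.0  # mm/ms -> cm/s


# ---------------------------------------------------------------------------
# Isopotential-intersection spiral-tip oracle
# ---------------------------------------------------------------------------


def _contour_lines(field: np.ndarray, level: float):
    segs = [
        LineString(c[:, ::-1])  # (row, col) -> (x=col, y=row)
        for c in measure.find_contours(field, level)
        if len(c) >= 2
    ]
    if not segs:
        return None
    return unary_union(MultiLineString(segs))


def _ring_offsets(radius: int) -> np.ndarray:
    """Ordered (drow, dcol) offsets of a discrete circle, CCW in atan2 order."""
    from skimage.draw import circle_perimeter

    rr, cc = circle_perimeter(0, 0, radius)
    ang = np.arctan2(rr, cc)
    order = np.argsort(ang)
    return np.stack([rr[order], cc[order]], axis=1)


_CHIRALITY_RING = None


def _vector_winding(f1: np.ndarray, f2: np.ndarray, row: int, col: int) -> int:
    """Sign of the winding of the vector field (f1, f2) around (row, col).

    Traverses a radius-2 discrete ring in the same angular order as the
    phase detector's rings, so the sign convention matches the phase
    winding without sharing any phase computation.
    """
    global _CHIRALITY_RING
    if _CHIRALITY_RING is None:
        _CHIRALITY_RING = _ring_offsets(2)
    h, w = f1.shape
    rr = _CHIRALITY_RING[:, 0] + row
    cc = _CHIRALITY_RING[:, 1] + col
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
        return 0
    ang = np.arctan2(f2[rr, cc], f1[rr, cc])
    d = np.diff(np.append(ang, ang[0]))
    d = (d + np.pi) % (2 * np.pi) - np.pi
    total = d.sum()
    if abs(total) < np.pi:
        return 0
    return 1 if total > 0 else -1


def isopotential_tips(
    u_stack: np.ndarray,
    frame_interval_ms: float,
    u_iso: float = 0.5,
    delta_ms: float = 20.0,
    merge_px: float = 3.0,
    border_px: int = 2,
) -> pd.DataFrame:
    """Spiral-tip trajectory by the isopotential-intersection method.

    A tip at frame ``t`` is an intersection point of the ``u = u_iso``
    isoline at ``t`` with the same isoline ``delta_ms`` earlier: on a
    rotating wave the isoline pivots around the tip, so the two curves
    cross there.  Chirality is the winding sign of the vector field
    ``(u_t - u_iso, u_{t-delta} - u_iso)`` around the intersection, which
    matches the sign of the local phase winding.

    Returns a DataFrame with columns ``frame, row, col, chirality``
    (sub-pixel positions; one row per merged tip per frame).
    """
    delta = max(1, int(round(delta_ms / frame_interval_ms)))
    n, h, w = u_stack.shape
    records = []
    prev_geom: dict[int, object] = {}
    for t in range(delta, n):
        if t - delta in prev_geom:
            g_old = prev_geom.pop(t - delta)
        else:
            g_old = _contour_lines(u_stack[t - delta].astype(float), u_iso)
        g_new = _contour_lines(u_stack[t].astype(float), u_iso)
        prev_geom[t] = g_new
        if g_old is None or g_new is None:
            continue
        inter = g_new.intersection(g_old)
        pts = []
        for geom in getattr(inter, "geoms", [inter]):
            if geom.is_empty:
                continue
            if geom.geom_type == "Point":
                pts.append((geom.y, geom.x))
            elif geom.geom_type in ("LineString", "LinearRing"):
                c = np.asarray(geom.coords)
                pts.append((c[:, 1].mean(), c[:, 0].mean()))
            elif geom.geom_type == "MultiPoint":
                pts.extend((p.y, p.x) for p in geom.geoms)
        # drop border artefacts, merge clusters, assign chirality
        pts = [
            (r, c)
            for r, c in pts
            if border_px <= r <= h - 1 - border_px and border_px <= c <= w - 1 - border_px
        ]
        f1 = u_stack[t].astype(float) - u_iso
        f2 = u_stack[t - delta].astype(float) - u_iso
        for r, c in _merge_points(pts, merge_px):
            chir = _vector_winding(f1, f2, int(round(r)), int(round(c)))
            if chir != 0:
                records.append((t, r, c, chir))
    return pd.DataFrame(records, columns=["frame", "row", "col", "chirality"])


def _merge_points(pts: list[tuple[float, float]], radius: float):
    """Greedy clustering of nearby intersection points; returns centroids."""
    out: list[list[tuple[float, float]]] = []
    for p in pts:
        for cluster in out:
            cy, cx = np.mean(cluster, axis=0)
            if (p[0] - cy) ** 2 + (p[1] - cx) ** 2 <= radius**2:
                cluster.append(p)
                break
        else:
            out.append([p])
    return [tuple(np.mean(c, axis=0)) for c in out]
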