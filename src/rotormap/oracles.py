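"""Independent reference computations used to validate the detectors.

These deliberately avoid the vectorised ring machinery of
:mod:`rotormap.phase`: the winding integral here is evaluated pixel by
pixel with trigonometric ring sampling, so that agreement between the
two is a genuine cross-check rather than a tautology.  (The third
independent oracle, isopotential-intersection tip tracking, lives with
the simulator in :mod:`rotormap.synth.medium`.)
"""

from __future__ import annotations

import math

import numpy as np


def vortex_phase_field(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    chiralities: list[int],
    offset: float = 0.0,
) -> np.ndarray:
    """Synthetic phase field with planted vortices of known chirality.

    phase(r, c) = offset + sum_i chir_i * atan2(r - r_i, c - c_i),
    wrapped to (-pi, pi].  Each well-separated vortex carries winding
    2*pi*chir_i around it.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    phi = np.full((h, w), offset, dtype=float)
    for (r0, c0), chir in zip(centers, chiralities):
        phi += chir * np.arctan2(rr - r0, cc - c0)
    return np.pi - (np.pi - phi) % (2 * np.pi)


def winding_number(phase: np.ndarray, row: int, col: int, radius: float = 2.0) -> int:
    """Winding number of the phase field around one pixel.

    Samples a circle of ``radius`` at 8*ceil(radius) angles (duplicate
    pixels collapsed), accumulates wrapped successive differences and
    rounds the total to a multiple of 2*pi.  Returns 0 if the circle
    leaves the image or touches a non-finite pixel.
    """
    h, w = phase.shape
    m = 8 * math.ceil(radius)
    pts = []
    for k in range(m):
        th = 2 * math.pi * k / m
        r = int(round(row + radius * math.sin(th)))
        c = int(round(col + radius * math.cos(th)))
        if not (0 <= r < h and 0 <= c < w):
            return 0
        if not pts or pts[-1] != (r, c):
            pts.append((r, c))
    if len(pts) > 1 and pts[0] == pts[-1]:
        pts.pop()
    if len(pts) < 4:
        return 0
    total = 0.0
    for i in range(len(pts)):
        a = phase[pts[i]]
        b = phase[pts[(i + 1) % len(pts)]]
        if not (math.isfinite(a) and math.isfinite(b)):
            return 0
        d = b - a
        d = math.pi - (math.pi - d) % (2 * math.pi)
        total += d
    return int(round(total / (2 * math.pi)))


def brute_force_singularities(
    phase: np.ndarray, radius: float = 2.0
) -> list[tuple[float, float, int]]:
    """All singularities of a phase frame by exhaustive winding integrals.

    Every pixel within ``radius`` of a singular core reports a non-zero
    winding; connected blobs of equal sign are merged and their centroid
    returned as ``(row, col, chirality)``.
    """
    h, w = phase.shape
    wind = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            wind[r, c] = winding_number(phase, r, c, radius)
    out: list[tuple[float, float, int]] = []
    visited = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if wind[r, c] == 0 or visited[r, c]:
                continue
            sign = 1 if wind[r, c] > 0 else -1
            stack = [(r, c)]
            blob = []
            visited[r, c] = True
            while stack:
                rr, cc = stack.pop()
                blob.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < h
                            and 0 <= c2 < w
                            and not visited[r2, c2]
                            and np.sign(wind[r2, c2]) == sign
                        ):
                            visited[r2, c2] = True
                            stack.append((r2, c2))
            rows = [b[0] for b in blob]
            cols = [b[1] for b in blob]
            out.append((float(np.mean(rows)), float(np.mean(cols)), sign))
    out.sort()
    return out
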