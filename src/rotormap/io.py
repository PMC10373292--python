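"""File formats: multi-page TIFF movies with JSON sidecars, CSV tables.

Movies are stored as 16-bit multi-page TIFF with an affine intensity map
(``value = scale * dn + offset``) recorded in the JSON sidecar together
with frame interval, mask, modality, provenance and seed.  Electrograms
are plain CSV (column 0 ``time_ms``, one column per electrode named
``r{row}c{col}``) with the grid geometry in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ElectrogramSet, FluorescenceMovie


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(path: str | Path, movie: FluorescenceMovie, seed: int | None = None) -> None:
    """Write a movie as 16-bit TIFF + JSON sidecar."""
    path = Path(path)
    lo = float(movie.frames.min())
    hi = float(movie.frames.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    dn = np.round((movie.frames - lo) / scale).astype(np.uint16)
    tifffile.imwrite(path, dn, photometric="minisblack")
    meta = {
        "frame_interval_ms": movie.frame_interval_ms,
        "modality": movie.modality,
        "provenance": movie.provenance,
        "intensity_scale": scale,
        "intensity_offset": lo,
        "mask": movie.mask.astype(int).tolist(),
        "seed": seed,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_movie(path: str | Path) -> FluorescenceMovie:
    path = Path(path)
    dn = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    frames = dn * meta["intensity_scale"] + meta["intensity_offset"]
    return FluorescenceMovie(
        frames=frames,
        frame_interval_ms=meta["frame_interval_ms"],
        mask=np.asarray(meta["mask"], dtype=bool),
        modality=meta.get("modality", "voltage"),
        provenance=list(meta.get("provenance", [])),
    )


def write_trace(path: str | Path, times_ms: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"time_ms": times_ms, "value": values}).to_csv(path, index=False)


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(), df["value"].to_numpy()


def write_electrograms(path: str | Path, egs: ElectrogramSet) -> None:
    path = Path(path)
    egs.to_frame().to_csv(path, index=False)
    meta = {
        "sample_interval_ms": egs.sample_interval_ms,
        "positions": [list(p) for p in egs.positions],
        "pitch_mm": egs.pitch_mm,
        "quality": egs.quality,
        "metadata": egs.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_electrograms(path: str | Path) -> ElectrogramSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    data = df.drop(columns=["time_ms"]).to_numpy()
    return ElectrogramSet(
        data=data,
        sample_interval_ms=meta["sample_interval_ms"],
        positions=[tuple(p) for p in meta["positions"]],
        pitch_mm=meta["pitch_mm"],
        quality=list(meta.get("quality", [])),
        metadata=meta.get("metadata", {}),
    )


def write_tip_trajectory(path: str | Path, tips: pd.DataFrame) -> None:
    tips.to_csv(path, index=False)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
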