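"""Run configuration: YAML schema, validation and hashing.

A run is driven by a single YAML file with one block per pipeline stage.
Exactly one of ``simulation`` (synthetic data spec) or ``inputs`` (paths
to an existing movie / electrogram CSV) must be present; every parameter
block is validated against module bounds before any computation starts.
The configuration hash stamped into all outputs is the SHA-256 of the
canonical JSON rendering, so it changes iff any parameter changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datatypes import ConfigurationError
from .preprocess import FilterSpec
from .synth import MediumParams, OpticsModel, StimulusProtocol

_STAGES = ("simulate", "preprocess", "ap", "phase", "mea", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict
    seed: int = 0
    output_dir: Path = Path("rotormap_out")
    identifiers: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return config_hash(self.raw)

    def block(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    @property
    def has_simulation(self) -> bool:
        return "simulation" in self.raw

    def medium_params(self) -> MediumParams:
        sim = self.block("simulation")
        keys = (
            "grid_height", "grid_width", "dx", "dt_sim", "diffusion",
            "kinetics", "time_scale_ms", "seed",
        )
        kwargs = {k: sim[k] for k in keys if k in sim}
        kwargs.setdefault("seed", self.seed)
        return MediumParams(**kwargs)

    def stimulus(self) -> StimulusProtocol:
        sim = self.block("simulation")
        keys = (
            "kind", "onset_ms", "period_ms", "count", "region",
            "s2_offset_ms", "stim_duration_ms",
        )
        kwargs = {k: sim[k] for k in keys if k in sim}
        if "region" in kwargs and kwargs["region"] is not None:
            kwargs["region"] = tuple(kwargs["region"])
        return StimulusProtocol(**kwargs)

    def optics(self) -> OpticsModel:
        opt = dict(self.block("simulation").get("optics") or {})
        if opt.get("bleach_tau_ms") in ("inf", None) and "bleach_tau_ms" in opt:
            opt["bleach_tau_ms"] = float("inf")
        return OpticsModel(**opt)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(**self.block("preprocess"))


def config_hash(raw: dict) -> str:
    canon = json.dumps(raw, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None, out: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``seed`` and ``out`` override the file's values (command-line takes
    precedence).  Raises ConfigurationError on any invalid block, before
    any computation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    has_sim = "simulation" in raw
    has_inputs = "inputs" in raw
    if has_sim == has_inputs:
        raise ConfigurationError(
            "config must contain exactly one of 'simulation' or 'inputs'"
        )
    if has_inputs:
        inputs = raw["inputs"] or {}
        for key, p in inputs.items():
            if not Path(p).exists():
                raise ConfigurationError(f"input path for {key!r} not found: {p}")
    cfg = RunConfig(
        raw=raw,
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        output_dir=Path(out if out is not None else raw.get("output_dir", "rotormap_out")),
        identifiers=dict(raw.get("identifiers") or {}),
    )
    # validate every present block eagerly
    if has_sim:
        cfg.medium_params()
        cfg.stimulus()
        cfg.optics()
    cfg.filter_spec()
    for key in ("ap", "phase", "mea"):
        blk = cfg.block(key)
        for bound_key in ("min_period_ms",):
            if bound_key in blk and not blk[bound_key] > 0:
                raise ConfigurationError(f"{key}.{bound_key} must be positive")
    phase_blk = cfg.block("phase")
    if phase_blk.get("r_inner", 2) >= phase_blk.get("r_outer", 4):
        raise ConfigurationError("phase.r_inner must be < phase.r_outer")
    return cfg


def aggregate(tables: list, identifiers_required: bool = True):
    """Concatenate replicate-level long tables and summarise per protocol.

    Each table has columns (protocol, line, N, n, metric, value).  The
    summary reports, per protocol and metric, the mean of per-replicate
    means, its SD, and the N / n counts — descriptive statistics only,
    not mixed-model estimates.  Duplicated (protocol, N, n, metric) keys
    raise a schema error.
    """
    import pandas as pd

    if not tables:
        raise ConfigurationError("aggregate requires at least one table")
    frames = []
    for t in tables:
        df = t.copy()
        missing = {"protocol", "N", "n", "metric", "value"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"replicate table missing columns: {sorted(missing)}")
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    dup = long.duplicated(subset=["protocol", "N", "n", "metric"])
    if dup.any():
        raise ConfigurationError(
            f"duplicated replicate keys: {long.loc[dup, ['protocol', 'N', 'n', 'metric']].values.tolist()}"
        )
    rows = []
    for (proto, metric), grp in long.groupby(["protocol", "metric"], sort=True):
        vals = grp["value"].astype(float)
        ok = vals.dropna()
        rows.append(
            {
                "protocol": proto,
                "metric": metric,
                "mean": ok.mean() if len(ok) else float("nan"),
                "sd": ok.std(ddof=1) if len(ok) > 1 else float("nan"),
                "N": grp["N"].nunique(),
                "n": len(grp),
                "note": "descriptive summary (not a mixed-model estimate)",
            }
        )
    return long, pd.DataFrame(rows)
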