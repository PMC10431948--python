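"""File formats and run configuration.

Trace CSV: two required columns ``time_s,o2_uM``; optional leading
``# key=value`` comment lines carry protocol metadata.  Scheme and run
configurations are YAML; schemes round-trip bit-exactly through
:meth:`KineticScheme.to_dict`.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .kinetic_schemes import ConfigurationError, KineticScheme
from .protocol_sim import Protocol, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "load_scheme",
    "save_scheme",
    "RunConfig",
    "load_config",
    "config_hash",
]


def write_trace(path, trace: Trace) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in sorted(trace.metadata.items()):
            fh.write(f"# {k}={v}\n")
        if trace.sigma is not None:
            fh.write(f"# sigma_uM={trace.sigma}\n")
        fh.write("time_s,o2_uM\n")
        for t, o in zip(trace.times, trace.o2):
            fh.write(f"{float(t)!r},{float(o)!r}\n")


def read_trace(path) -> Trace:
    path = Path(path)
    metadata = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                metadata[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:  # pandas reports the offending line
        raise ConfigurationError(f"malformed trace CSV {path}: {exc}") from exc
    missing = {"time_s", "o2_uM"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"trace CSV {path} lacks columns {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ConfigurationError(f"trace CSV {path}: time_s must be strictly increasing")
    sigma = metadata.pop("sigma_uM", None)
    return Trace(
        times,
        df["o2_uM"].to_numpy(dtype=float),
        sigma=float(sigma) if sigma is not None else None,
        metadata=metadata,
    )


def save_scheme(path, scheme: KineticScheme) -> None:
    Path(path).write_text(yaml.safe_dump(scheme.to_dict(), sort_keys=True))


def load_scheme(path) -> KineticScheme:
    return KineticScheme.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration (schema-validated; unknown keys rejected)
# ---------------------------------------------------------------------------

class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end: float = 1400.0
    dt: float = 1.0
    t_respiration_on: float = 50.0
    t_open: float = 1000.0
    o2_initial: float = 183.0
    o2_air: float = 183.0
    hb_heme_total: float = 50.0
    oxidase_total: float = 0.05

    def build(self) -> Protocol:
        return Protocol.default(
            t_end=self.t_end,
            dt=self.dt,
            t_respiration_on=self.t_respiration_on,
            t_open=self.t_open,
            o2_initial=self.o2_initial,
            o2_air=self.o2_air,
            hb_heme_total=self.hb_heme_total,
            oxidase_total=self.oxidase_total,
        )


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    free: dict[str, float] | None = None  # None -> the model's refined labels
    fixed: dict[str, float] = Field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    phase: Literal["both", "deox", "reox"] = "both"
    n_starts: int = 5
    sim_rtol: float = 1e-7
    sim_atol: float = 1e-9


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha_um_per_mmhg: float = 1.223
    hill_window: float = 0.2
    cgain_grid: Literal["odc_points"] = "odc_points"


class RunConfig(BaseModel):
    """Single config that drives every CLI command."""

    model_config = ConfigDict(extra="forbid")
    model: Literal["minimalist", "adair", "perutz", "mwc", "independent_sites"] = (
        "minimalist"
    )
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    rates: dict[str, float] = Field(default_factory=dict)  # overrides of nominal values
    sigma: float = 0.5
    seed: int = 0
    outdir: str = "hbodc_out"

    @model_validator(mode="after")
    def _check(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        return self


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
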