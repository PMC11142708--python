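"""Run configuration, validation and stamped result files.

A run config resolves to physical constants, kinetic rates, the model
flag, the assay design and seeds/budgets; omitted keys fall back to the
package defaults (the fitted ADP-model rates and the measured assay
constants).  Unknown keys are rejected so typos cannot silently revert a
parameter to its default.  Result files are stamped with the seed, a hash
of the resolved config and the package version, so any output can be
regenerated from its own metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import (MODEL_ADP, MODEL_DIFFUSION, ExperimentCondition,
                     ParameterVector, PhysicalParams, DEFAULT_GAPS,
                     DEFAULT_MOTOR_LENGTHS)

__all__ = ["RunConfig", "load_config", "write_results", "config_hash"]


@dataclass
class RunConfig:
    """Fully resolved configuration of a pipeline run."""

    physical: PhysicalParams = field(default_factory=PhysicalParams)
    rates: ParameterVector = field(default_factory=ParameterVector)
    d_mt: float = 5.0
    F_d: float = 4.0
    lengths: tuple = DEFAULT_MOTOR_LENGTHS
    gaps: tuple = DEFAULT_GAPS
    seed: int = 0
    n: int = 100
    max_time: float = 100.0

    def __post_init__(self) -> None:
        if self.d_mt <= 0 or self.F_d <= 0:
            raise ValueError("d_mt and F_d must be strictly positive")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")
        self.lengths = tuple(float(v) for v in self.lengths)
        self.gaps = tuple(float(v) for v in self.gaps)

    def design(self):
        return [ExperimentCondition(motor_length=L, gap=g)
                for L in self.lengths for g in self.gaps]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.physical)
        return {
            "physical": d,
            "rates": self.rates.as_dict(),
            "d_mt": self.d_mt, "F_d": self.F_d,
            "design": {"lengths": list(self.lengths),
                       "gaps": list(self.gaps)},
            "seed": self.seed, "n": self.n, "max_time": self.max_time,
        }

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config; omitted keys take package defaults."""
    path = Path(path)
    raw = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    return config_from_dict(raw or {})


def config_from_dict(raw: dict) -> RunConfig:
    top_keys = {"physical", "rates", "model", "d_mt", "F_d", "design",
                "seed", "n", "max_time"}
    _check_keys(raw, top_keys, "top level")
    phys_fields = {f.name for f in dataclasses.fields(PhysicalParams)}
    phys_raw = dict(raw.get("physical") or {})
    _check_keys(phys_raw, phys_fields, "'physical'")
    try:
        physical = PhysicalParams(**phys_raw)
    except ValueError as err:
        raise ValueError(f"invalid 'physical' section: {err}") from err
    rate_raw = dict(raw.get("rates") or {})
    _check_keys(rate_raw, set(ParameterVector.FREE_NAMES) | {"model"},
                "'rates'")
    model = raw.get("model", rate_raw.pop("model", MODEL_ADP))
    base = (ParameterVector.fitted_diffusion() if model == MODEL_DIFFUSION
            else ParameterVector.fitted_adp())
    rates = base.replace_values(**rate_raw)
    design_raw = dict(raw.get("design") or {})
    _check_keys(design_raw, {"lengths", "gaps"}, "'design'")
    return RunConfig(
        physical=physical, rates=rates,
        d_mt=float(raw.get("d_mt", 5.0)), F_d=float(raw.get("F_d", 4.0)),
        lengths=design_raw.get("lengths", DEFAULT_MOTOR_LENGTHS),
        gaps=design_raw.get("gaps", DEFAULT_GAPS),
        seed=int(raw.get("seed", 0)), n=int(raw.get("n", 100)),
        max_time=float(raw.get("max_time", 100.0)))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(cfg: RunConfig | None, seed: int | None) -> dict:
    from . import __version__
    return {"seed": seed if seed is not None else (cfg.seed if cfg else None),
            "config_hash": config_hash(cfg) if cfg else None,
            "kinbind_version": __version__}


def write_results(objects: dict, outdir, cfg: RunConfig | None = None,
                  seed: int | None = None) -> list:
    """Write tabular results as CSV and mappings as JSON, stamped.

    ``objects`` maps a base filename (no extension) to a DataFrame or a
    JSON-serializable mapping.  CSV files carry the stamp as '#'-prefixed
    comment lines (readable back with ``pd.read_csv(..., comment='#')``);
    JSON payloads embed it under ``"_meta"``.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg, seed)
    written = []
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            with open(path, "w") as fh:
                for k, v in stamp.items():
                    fh.write(f"# {k}: {v}\n")
                obj.to_csv(fh, index=False)
        else:
            path = outdir / f"{name}.json"
            payload = dict(obj)
            payload["_meta"] = stamp
            path.write_text(json.dumps(payload, indent=2, default=_json_default))
        written.append(path)
    return written


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
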