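"""Configuration loading, output writing, manifests.

A run is fully described by a :class:`RunConfig`: model parameters,
lesion gains, task settings, subject count and base seed.  Omitted
fields resolve to the documented defaults; unknown keys are rejected
with the path to the offending field.  ``write_outputs`` persists the
per-subject trial logs (CSV, 17 significant digits so replays compare
exactly), the cohort summary (JSON), a config echo and a checksum
manifest; identical (config, seed) runs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .experiments import CohortResult
from .params import LesionSpec, ModelParams
from .tasks import EffortSpec

__all__ = ["RunConfig", "load_config", "save_config", "write_outputs"]

FLOAT_FORMAT = "%.17g"


class RunConfig(BaseModel):
    """Everything a reproducible run needs."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    params: ModelParams = ModelParams()
    lesion: LesionSpec = LesionSpec()
    effort: EffortSpec = EffortSpec()
    n_subjects: int = 12
    base_seed: int = 0
    sim1_n_trials: int = 432
    conditioning_max_order: int = 3
    conditioning_trials_per_stage: int = 100
    sweep_n_runs: int = 40


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON config; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ValueError(f"invalid config {path}:\n{exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(
    result: CohortResult,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    extra_tables: Optional[dict[str, pd.DataFrame]] = None,
) -> dict:
    """Write trial logs, summary, config echo and manifest; return manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    for subj, frame in result.trials.groupby("subject"):
        name = f"trials_subject_{int(subj):03d}.csv"
        frame.to_csv(out / name, index=False, float_format=FLOAT_FORMAT)
        files.append(name)

    summary = {
        "schema_version": "1.0",
        "seeds": result.seeds,
        "meta": result.meta,
        "summaries": json.loads(
            result.summaries.to_json(orient="records", double_precision=15)
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append("summary.json")

    if extra_tables:
        for name, frame in extra_tables.items():
            fname = f"{name}.csv"
            frame.to_csv(out / fname, index=False, float_format=FLOAT_FORMAT)
            files.append(fname)

    if config is not None:
        save_config(config, out / "config.yaml")
        files.append("config.yaml")

    manifest = {
        "seeds": result.seeds,
        "files": {name: _sha256(out / name) for name in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
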