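"""YAML experiment configuration and the auditable run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .estimators import CFConfig, GLMConfig
from .harness import ExperimentConfig
from .pool import default_ess_path, default_pool_path

__all__ = ["parse_config", "config_to_dict", "RunManifest"]

_TOP_LEVEL_FIELDS = {
    "n_per_sample": int,
    "prevalence_A": float,
    "prevalence_B": float,
    "iterations": int,
    "seed": int,
    "missing_sd": float,
    "run_glm": bool,
    "drop_empty_specimens": bool,
    "weight_transform": str,
    "pool_path": str,
    "ess_path": str,
    "max_glm_failure_pct": float,
}


def _err(field: str, msg: str) -> ValueError:
    return ValueError(f"config field {field!r}: {msg}")


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Parse a YAML experiment config; omitted fields take the defaults
    used throughout the study (n=500, prevalences 10/30, sd 20, 1000
    iterations, CF threshold 75, 10,000 draws over 75–100%).

    ``overrides`` (e.g. from CLI flags) are applied on top of the file.
    Raises ``ValueError`` with a field-level message on schema violations.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a YAML mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    kwargs: dict = {}
    known = set(_TOP_LEVEL_FIELDS) | {"scenarios", "cf", "glm"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")

    for field_name, typ in _TOP_LEVEL_FIELDS.items():
        if field_name in raw and raw[field_name] is not None:
            value = raw[field_name]
            try:
                kwargs[field_name] = typ(value)
            except (TypeError, ValueError):
                raise _err(field_name, f"cannot coerce {value!r} to {typ.__name__}")

    if "scenarios" in raw:
        scenarios = raw["scenarios"]
        if not isinstance(scenarios, (list, tuple)) or not scenarios:
            raise _err("scenarios", "must be a non-empty list of percentages")
        kwargs["scenarios"] = tuple(float(s) for s in scenarios)

    if "cf" in raw:
        cf = raw["cf"]
        if not isinstance(cf, dict) or set(cf) - {"threshold"}:
            raise _err("cf", "must be a mapping with key 'threshold'")
        try:
            kwargs["cf"] = CFConfig(threshold=float(cf.get("threshold", 75.0)))
        except ValueError as exc:
            raise _err("cf.threshold", str(exc))

    if "glm" in raw:
        glm = raw["glm"]
        allowed = {"n_param_draws", "predict_range", "grid_step", "clip_predictions"}
        if not isinstance(glm, dict) or set(glm) - allowed:
            raise _err("glm", f"must be a mapping with keys among {sorted(allowed)}")
        glm_kwargs: dict = {}
        if "n_param_draws" in glm:
            glm_kwargs["n_param_draws"] = int(glm["n_param_draws"])
        if "predict_range" in glm:
            pr = glm["predict_range"]
            if not isinstance(pr, (list, tuple)) or len(pr) != 2:
                raise _err("glm.predict_range", "must be [lo, hi]")
            glm_kwargs["predict_range"] = (float(pr[0]), float(pr[1]))
        if "grid_step" in glm:
            glm_kwargs["grid_step"] = float(glm["grid_step"])
        if "clip_predictions" in glm:
            glm_kwargs["clip_predictions"] = bool(glm["clip_predictions"])
        try:
            kwargs["glm"] = GLMConfig(**glm_kwargs)
        except ValueError as exc:
            raise _err("glm", str(exc))

    try:
        return ExperimentConfig(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def config_to_dict(cfg: ExperimentConfig) -> dict:
    """Serialize an ExperimentConfig to a YAML/JSON-ready mapping that
    round-trips through :func:`parse_config`."""
    out = dataclasses.asdict(cfg)
    out["scenarios"] = list(cfg.scenarios)
    out["cf"] = {"threshold": cfg.cf.threshold}
    out["glm"] = {
        "n_param_draws": cfg.glm.n_param_draws,
        "predict_range": list(cfg.glm.predict_range),
        "grid_step": cfg.glm.grid_step,
        "clip_predictions": cfg.glm.clip_predictions,
    }
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to replay an experiment exactly: the full config,
    the master seed, fixture hashes, package version and failure counts."""

    config: dict
    seed: int
    fixture_hashes: dict[str, str]
    package_version: str
    glm_fallback_counts: dict[str, int]
    glm_failure_counts: dict[str, int]
    started: str
    finished: str
    python: str = ""

    @classmethod
    def collect(cls, cfg: ExperimentConfig, results, started: datetime) -> "RunManifest":
        from . import __version__

        pool = Path(cfg.pool_path) if cfg.pool_path else default_pool_path()
        ess = Path(cfg.ess_path) if cfg.ess_path else default_ess_path()
        return cls(
            config=config_to_dict(cfg),
            seed=cfg.seed,
            fixture_hashes={"trauma_pool": _sha256(pool), "bone_ess": _sha256(ess)},
            package_version=__version__,
            glm_fallback_counts={
                str(k): v for k, v in results.glm_fallback_counts.items()
            },
            glm_failure_counts={
                str(k): v for k, v in results.glm_failure_counts.items()
            },
            started=started.isoformat(),
            finished=datetime.now(timezone.utc).isoformat(),
            python=platform.python_version(),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
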