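"""YAML application configuration: defaults, loading, validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "project": {
        "name": "dea-project",
        "workunit": "",
        "description": "",
    },
    "software": "DIANN",
    "normalization": {"method": "robscale"},
    "aggregation": {"method": "median_polish"},
    "processing": {
        "prior_df": 10.0,
        "missing_strategy": "model",
        "detection_quantile": 0.05,
    },
    "thresholds": {"fdr": 0.05, "log2fc": 1.0},
    "filters": {
        "diann_pg_qvalue": 0.01,
        "diann_precursor_qvalue": None,
        "tmt_purity": 0.5,
        "tmt_probability": 0.9,
    },
    "fasta": {"min_peptide_length": 6, "max_peptide_length": 30},
}

_VALID_NORMALIZATION = {"robscale", "quantile", "none"}
_VALID_MISSING = {"model", "omit"}


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def write_default_yaml(path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(default_config(), fh, sort_keys=False)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML config, fill defaults, and validate the knobs that matter."""
    path = Path(path)
    try:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigError(f"YAML root of {path} must be a mapping")
    cfg = _deep_merge(default_config(), user)
    validate_config(cfg)
    return cfg


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> None:
    norm = cfg["normalization"]["method"]
    if norm not in _VALID_NORMALIZATION:
        raise ConfigError(f"normalization.method must be one of {_VALID_NORMALIZATION}, got {norm!r}")
    ms = cfg["processing"]["missing_strategy"]
    if ms not in _VALID_MISSING:
        raise ConfigError(f"processing.missing_strategy must be one of {_VALID_MISSING}, got {ms!r}")
    if cfg["processing"]["prior_df"] < 0:
        raise ConfigError("processing.prior_df must be >= 0")
    dq = cfg["processing"]["detection_quantile"]
    if not 0 <= dq <= 1:
        raise ConfigError("processing.detection_quantile must be in [0, 1]")
    fdr = cfg["thresholds"]["fdr"]
    if not 0 < fdr <= 1:
        raise ConfigError("thresholds.fdr must be in (0, 1]")
    if cfg["thresholds"]["log2fc"] < 0:
        raise ConfigError("thresholds.log2fc must be >= 0")


def reader_filter_kwargs(cfg: dict, software_key: str) -> dict:
    """Translate YAML filter overrides into keyword arguments for the reader."""
    f = cfg.get("filters", {})
    key = software_key.upper()
    if key.startswith("DIANN"):
        kw = {"pg_qvalue": f.get("diann_pg_qvalue", 0.01)}
        if f.get("diann_precursor_qvalue") is not None:
            kw["precursor_qvalue"] = f["diann_precursor_qvalue"]
        return kw
    if key.startswith("FP_TMT"):
        return {
            "purity": f.get("tmt_purity", 0.5),
            "probability": f.get("tmt_probability", 0.9),
        }
    return {}
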