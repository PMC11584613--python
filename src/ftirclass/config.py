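"""Run configuration: YAML/JSON loading, schema validation, defaults.

Unknown keys are rejected with the full key path so a typo in a config
file fails before any computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .classify import ClassifierSpec, PipelineConfig


class ConfigError(ValueError):
    pass


_NUM = (int, float)

# schema: key -> (validator predicate, default)
SCHEMA = {
    "seed": (lambda v: isinstance(v, int), 0),
    "preprocess": {
        "z_threshold": (lambda v: isinstance(v, _NUM) and v > 0, 3.0),
        "remove_outliers": (lambda v: isinstance(v, bool), True),
        "normalize": (lambda v: isinstance(v, bool), True),
        "alss": {
            "lambda": (lambda v: isinstance(v, _NUM) and v > 0, 1e5),
            "p": (lambda v: isinstance(v, _NUM) and 0 < v < 1, 0.01),
            "iters": (lambda v: isinstance(v, int) and v >= 1, 10),
        },
    },
    "features": {
        "mode": (lambda v: v in ("single_pca", "dual_pca", "none"), "dual_pca"),
        "variance_target": (lambda v: isinstance(v, _NUM) and 0 < v <= 1, 0.999),
        "k": (lambda v: v is None or (isinstance(v, int) and v >= 1), None),
        "per_class_k": (lambda v: isinstance(v, bool), False),
        "use_lda": (lambda v: isinstance(v, bool), True),
    },
    "classifier": {
        "kernels": (lambda v: isinstance(v, list) and v and
                    all(k in ("linear", "rbf") for k in v), ["linear", "rbf"]),
        "C": (lambda v: isinstance(v, list) and v and
              all(isinstance(c, _NUM) and c > 0 for c in v), [0.1, 1.0, 10.0, 100.0]),
        "gamma": (lambda v: isinstance(v, list) and
                  all(g == "scale" or (isinstance(g, _NUM) and g > 0) for g in v),
                  [1e-3, 1e-2, 1e-1, "scale"]),
        "class_weight": (lambda v: v in ("balanced", "none"), "balanced"),
        "inner_cv_folds": (lambda v: isinstance(v, int) and v >= 2, 5),
    },
    "evaluate": {
        "scheme": (lambda v: v in ("loocv", "kfold", "holdout"), "kfold"),
        "folds": (lambda v: isinstance(v, int) and v >= 2, 10),
        "test_fraction": (lambda v: isinstance(v, _NUM) and 0 < v < 1, 0.2),
        "repeats": (lambda v: isinstance(v, int) and v >= 1, 1),
    },
    "synthesize": {
        "n_groups": (lambda v: isinstance(v, int) and v >= 1, 15),
        "mu0": (lambda v: isinstance(v, _NUM), 1.0),
        "mu1": (lambda v: isinstance(v, _NUM), 1.12),
        "sd0": (lambda v: isinstance(v, _NUM) and v >= 0, 0.05),
        "sd1": (lambda v: isinstance(v, _NUM) and v >= 0, 0.05),
        "n_per_class": (lambda v: isinstance(v, int) and v >= 1, 100),
        "noise_sd": (lambda v: v is None or (isinstance(v, _NUM) and v >= 0), None),
        "replicates_per_specimen": (lambda v: isinstance(v, int) and v >= 1, 3),
        "grid_start": (lambda v: isinstance(v, _NUM), 700.0),
        "grid_stop": (lambda v: isinstance(v, _NUM), 4000.0),
        "grid_step": (lambda v: isinstance(v, _NUM) and v > 0, 1.0),
    },
}


def _validate(raw: dict, schema: dict, path: str = "") -> dict:
    out = {}
    for key, value in raw.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key: {here}")
        node = schema[key]
        if isinstance(node, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            out[key] = _validate(value, node, here)
        else:
            pred, _default = node
            if not pred(value):
                raise ConfigError(f"invalid value for config key {here}: {value!r}")
            out[key] = value
    for key, node in schema.items():
        if key in out:
            if isinstance(node, dict):
                continue
        elif isinstance(node, dict):
            out[key] = _validate({}, node, f"{path}.{key}" if path else key)
        else:
            out[key] = node[1]
    return out


def validate_config(raw: dict | None) -> dict:
    """Validate a raw config mapping against the schema, filling defaults."""
    return _validate(raw or {}, SCHEMA)


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML or JSON config file (None -> all defaults)."""
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(raw)


def to_pipeline_config(cfg: dict) -> PipelineConfig:
    """Translate a validated config mapping into a PipelineConfig."""
    p, f, c = cfg["preprocess"], cfg["features"], cfg["classifier"]
    return PipelineConfig(
        z_threshold=p["z_threshold"], remove_outliers=p["remove_outliers"],
        alss_lambda=p["alss"]["lambda"], alss_p=p["alss"]["p"],
        alss_iters=p["alss"]["iters"], normalize=p["normalize"],
        feature_mode=f["mode"], variance_target=f["variance_target"],
        k=f["k"], per_class_k=f["per_class_k"], use_lda=f["use_lda"],
        classifier=ClassifierSpec(
            kernels=tuple(c["kernels"]), C_grid=tuple(c["C"]),
            gamma_grid=tuple(c["gamma"]), class_weight_mode=c["class_weight"]),
        inner_cv_folds=c["inner_cv_folds"],
    )
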