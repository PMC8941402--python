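"""Configuration I/O, result writers and reproducible fixtures.

Configurations are JSON documents with keys ``hairs`` (list of objects
with ``base_x, base_y, length, charge, spring, resting_angle``), ``K``
and ``threshold``.  Writers sort keys and rely on Python's shortest
round-trip float repr, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, SchemaError
from .model_core import ArrayConfig, HairSpec, PointCharge, make_row_array

__all__ = [
    "read_config",
    "write_config",
    "config_to_dict",
    "write_results",
    "generate_fixtures",
]

_HAIR_KEYS = ("base_x", "base_y", "length", "charge", "spring", "resting_angle")
_HAIR_REQUIRED = ("base_x", "base_y")


def config_to_dict(config: ArrayConfig) -> dict:
    return {
        "hairs": [
            {k: getattr(h, k) for k in _HAIR_KEYS} for h in config.hairs
        ],
        "K": config.K,
        "threshold": config.threshold,
    }


def write_config(config: ArrayConfig, path) -> None:
    Path(path).write_text(
        json.dumps(config_to_dict(config), sort_keys=True, indent=2) + "\n"
    )


def _config_from_dict(doc: dict) -> ArrayConfig:
    violations = []
    if not isinstance(doc, dict):
        raise SchemaError(["top-level document must be a JSON object"])
    known_top = {"hairs", "K", "threshold"}
    extra = set(doc) - known_top
    if extra:
        warnings.warn(f"ignoring unknown configuration keys: {sorted(extra)}",
                      stacklevel=2)
    hairs_doc = doc.get("hairs")
    if not isinstance(hairs_doc, list) or not hairs_doc:
        violations.append("'hairs' must be a non-empty list")
        hairs_doc = []
    specs = []
    for i, h in enumerate(hairs_doc):
        if not isinstance(h, dict):
            violations.append(f"hairs[{i}] must be an object")
            continue
        extra_h = set(h) - set(_HAIR_KEYS)
        if extra_h:
            warnings.warn(f"hairs[{i}]: ignoring unknown keys {sorted(extra_h)}",
                          stacklevel=2)
        missing = [k for k in _HAIR_REQUIRED if k not in h]
        if missing:
            violations.append(f"hairs[{i}] missing required keys: {missing}")
            continue
        bad = [k for k in _HAIR_KEYS
               if k in h and not isinstance(h[k], (int, float))]
        if bad:
            violations.append(f"hairs[{i}]: non-numeric values for {bad}")
            continue
        try:
            specs.append(HairSpec(**{k: h[k] for k in _HAIR_KEYS if k in h}))
        except InvalidParameterError as exc:
            violations.append(f"hairs[{i}]: {exc}")
    for key in ("K", "threshold"):
        if key in doc and not isinstance(doc[key], (int, float)):
            violations.append(f"'{key}' must be numeric")
    if violations:
        raise SchemaError(violations)
    try:
        return ArrayConfig(
            hairs=tuple(specs),
            K=doc.get("K", 1.0),
            threshold=doc.get("threshold", 1e-3),
        )
    except InvalidParameterError as exc:
        raise SchemaError([str(exc)]) from exc


def read_config(path) -> ArrayConfig:
    """Load and schema-validate a configuration JSON."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError([f"malformed JSON: {exc}"]) from exc
    return _config_from_dict(doc)


def write_results(records, path) -> None:
    """Write a list of flat dicts as CSV, byte-stable for identical input."""
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)


def generate_fixtures(kind: str, parameters: dict | None = None, seed: int = 0):
    """Reproducible named configurations.

    Kinds
    -----
    figure1d : two unit hairs, delta=10, K=1, charges q_p in {1, 2, 3, 4}.
    figure3_cell : identical pair at (K, delta) from ``parameters``.
    figure5_panel : unequal pair, L1 = ratio * L2 with L1 + L2 = 2.
    random_array : N hairs in a row (spacing ``delta``), lengths drawn
        uniformly from [0.5, 1.5] with the given seed.

    Returns ``(ArrayConfig, [PointCharge, ...])``.
    """
    p = dict(parameters or {})
    if kind == "figure1d":
        cfg = make_row_array(2, delta=10.0, K=1.0)
        charges = [PointCharge(0.0, 0.0, float(m)) for m in (1, 2, 3, 4)]
        return cfg, charges
    if kind == "figure3_cell":
        cfg = make_row_array(2, delta=float(p.get("delta", 1.0)),
                             K=float(p.get("K", 1.0)))
        return cfg, [PointCharge(0.0, 0.0, float(p.get("qp", 10.0)))]
    if kind == "figure5_panel":
        ratio = float(p.get("ratio", 1.0))
        L2 = 2.0 / (1.0 + ratio)
        L1 = ratio * L2
        cfg = make_row_array(2, delta=float(p.get("delta", 1.0)),
                             lengths=[L1, L2], K=float(p.get("K", 1.0)))
        return cfg, [PointCharge(0.0, 0.0, float(p.get("qp", 10.0)))]
    if kind == "random_array":
        N = int(p.get("N", 3))
        delta = float(p.get("delta", 1.0))
        rng = np.random.default_rng(seed)
        lengths = rng.uniform(0.5, 1.5, size=N).tolist()
        cfg = make_row_array(N, delta=delta, lengths=lengths,
                             K=float(p.get("K", 1.0)))
        return cfg, [PointCharge(0.0, 0.0, float(p.get("qp", 10.0)))]
    raise InvalidParameterError(
        f"unknown fixture kind {kind!r}; expected one of figure1d, "
        f"figure3_cell, figure5_panel, random_array")
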