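"""Readers and writers for the pipeline's on-disk formats.

Tabular outputs are UTF-8 TSV with a provenance header ('#'-prefixed
lines recording tool version, seed and config hash); nested results are
JSON with a ``provenance`` block.  Fields are written as 2-channel
16-bit TIFF (channel 0 DAPI, channel 1 stain) and masks as 8-bit 0/255
TIFF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__

__all__ = [
    "config_hash",
    "provenance",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "write_field_tiff",
    "read_field_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "load_config_file",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance(seed: int, config: dict | None = None) -> dict:
    return {
        "tool": "ccapipe",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj: dict, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["provenance"] = meta
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_field_tiff(channels: np.ndarray, path: str | Path) -> Path:
    """Save a (2, H, W) field as 16-bit TIFF; intensities are rounded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(channels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_field_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) field TIFF, got shape {arr.shape}")
    return arr.astype(float)


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))
    return path


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        return json.loads(text)
    return yaml.safe_load(text)
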