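"""Configuration loading and artifact output.

Run configuration is a single JSON document; every field has a default that
reproduces the reference instrument (488 nm excitation, 520 nm emission,
water immersion n = 1.33, detection NA 1.0, excitation objective NA 0.60,
objective tilt 32.45 degrees).  Arrays are written as float32 TIFF stacks
(complex fields as paired real/imaginary pages), tables as CSV and metadata
as JSON; a manifest records SHA-256 hashes and the config snapshot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .core import OpticalConfig
from .pipeline import NoiseModel, StripePhantomSpec
from .pupils import SheetSpec

__all__ = ["RunConfig", "load_config", "write_outputs", "ConfigError"]


class ConfigError(ValueError):
    """Configuration validation failure, with the offending field path."""


@dataclass
class GridConfig:
    n_k: int = 1001
    na_span: float = 2.6
    y_extent_nm: float = 0.0
    n_y: int = 1


@dataclass
class RunConfig:
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    sheet: SheetSpec | None = None
    preset: str | None = None
    phantom: StripePhantomSpec = field(default_factory=StripePhantomSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0


_OPTICAL_KEYS = {
    "lambda_exc_nm", "lambda_det_nm", "n_medium", "na_det", "na_exc_obj",
    "tilt_alpha_deg",
}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    An empty file (or empty object) yields the full default configuration.
    Unknown keys and invalid values raise :class:`ConfigError` naming the
    field path.
    """
    path = Path(path)
    text = path.read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a JSON object")
    known = {"optical", "grid", "sheet", "preset", "phantom", "noise", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")
    cfg = RunConfig()
    if "optical" in data:
        cfg.optical = _build(OpticalConfig, data["optical"], "optical")
    if "grid" in data:
        cfg.grid = _build(GridConfig, data["grid"], "grid")
    if "sheet" in data:
        sheet = dict(data["sheet"])
        if "increments_px" in sheet:
            raise ConfigError("sheet: phantom keys belong under 'phantom'")
        cfg.sheet = _build(SheetSpec, sheet, "sheet")
    if "preset" in data:
        cfg.preset = str(data["preset"])
    if "phantom" in data:
        ph = dict(data["phantom"])
        for key in ("increments_px", "volume_shape"):
            if key in ph:
                ph[key] = tuple(ph[key])
        cfg.phantom = _build(StripePhantomSpec, ph, "phantom")
    if "noise" in data:
        cfg.noise = _build(NoiseModel, data["noise"], "noise")
    if "seed" in data:
        cfg.seed = int(data["seed"])
    return cfg


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _write_array_tiff(path: Path, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    if np.iscomplexobj(arr):
        stack = np.stack([arr.real, arr.imag]).astype(np.float32)
        tifffile.imwrite(path, stack, metadata={"pages": "real,imag"})
    else:
        tifffile.imwrite(path, arr.astype(np.float32))


def write_outputs(artifacts: dict, out_dir: str | Path,
                  config: RunConfig | None = None) -> dict:
    """Write a dictionary of artifacts and return the manifest.

    Arrays go to ``<name>.tif``, dictionaries/dataclasses to ``<name>.json``,
    and 2D float tables supplied as ``(header, rows)`` tuples to
    ``<name>.csv``.  The manifest (also written as ``manifest.json``) maps
    each file to its SHA-256 hash and embeds the config snapshot.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, value in artifacts.items():
        if isinstance(value, np.ndarray):
            fname = f"{name}.tif"
            _write_array_tiff(out / fname, value)
        elif isinstance(value, tuple) and len(value) == 2 and isinstance(value[0], (list, tuple)):
            header, rows = value
            fname = f"{name}.csv"
            lines = [",".join(map(str, header))]
            lines += [",".join(f"{x:.10g}" if isinstance(x, float) else str(x)
                               for x in row) for row in rows]
            (out / fname).write_text("\n".join(lines) + "\n")
        else:
            fname = f"{name}.json"
            (out / fname).write_text(json.dumps(_to_jsonable(value), indent=2))
        digest = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        files[fname] = digest
    manifest = {"files": files}
    if config is not None:
        manifest["config"] = _to_jsonable(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
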