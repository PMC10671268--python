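"""File formats and run configuration.

Curves travel as two-column UTF-8 CSV with ``# key=value`` header comments
carrying the metadata (an optional YAML/JSON sidecar with the same keys is
also honoured).  Column pairs by kind: kinetic (time_s, intensity), nonagg
(time_min, gamma), acf (tau_s, g2), dsc (temperature_C, signal).  Writing is
canonical (sorted keys, %.10g numbers) so read/write round-trips are
bytewise stable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .datatypes import ACF, DSCTrace, KineticTrace, NonAggTrace, TraceMeta

__all__ = [
    "read_trace",
    "write_trace",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "result_envelope",
]

_COLUMNS = {
    "kinetic": ("time_s", "intensity"),
    "nonagg": ("time_min", "gamma"),
    "acf": ("tau_s", "g2"),
    "dsc": ("temperature_C", "signal"),
}

_META_FIELDS = ("protein_conc", "ligand_conc", "temperature", "viscosity",
                "refractive_index", "label")


def _parse_value(text: str):
    text = text.strip()
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def _read_header_and_sidecar(path: Path) -> dict:
    meta = {}
    for suffix in (".yaml", ".yml", ".json"):
        side = path.with_suffix(path.suffix + suffix)
        if side.exists():
            with open(side, encoding="utf-8") as fh:
                loaded = yaml.safe_load(fh) if suffix != ".json" else json.load(fh)
            if loaded:
                meta.update(loaded)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = _parse_value(val)
    return meta


def read_trace(path, kind: Optional[str] = None):
    """Read a curve file, dispatching on the declared or supplied kind.

    The kind comes from the ``kind`` header key when not passed explicitly.
    Malformed rows (non-numeric, duplicated or non-increasing abscissa) are
    reported with their row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_header_and_sidecar(path)
    kind = kind or meta.get("kind")
    if kind not in _COLUMNS:
        raise ValueError(f"unknown or undeclared trace kind {kind!r}")
    xcol, ycol = _COLUMNS[kind]
    df = pd.read_csv(path, comment="#")
    for col in (xcol, ycol):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path.name}")
    x = df[xcol].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(x) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"{path.name}: non-increasing {xcol} at data row {int(bad[0]) + 2}")
    y = df[ycol].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        row = int(np.nonzero(~(np.isfinite(x) & np.isfinite(y)))[0][0]) + 1
        raise ValueError(f"{path.name}: non-numeric value at data row {row}")

    tmeta = TraceMeta(**{k: meta[k] for k in _META_FIELDS if k in meta})
    if kind == "kinetic":
        return KineticTrace(t=x, I=y, meta=tmeta)
    if kind == "nonagg":
        return NonAggTrace(t=x, gamma=y, meta=tmeta)
    if kind == "acf":
        return ACF(tau=x, g2=y, q=float(meta["q"]), T=float(meta["T"]),
                   eta=float(meta["eta"]),
                   beta=float(meta["beta"]) if "beta" in meta else None,
                   meta=tmeta)
    return DSCTrace(T=x, signal=y,
                    scan_rate=float(meta.get("scan_rate", 1.0)),
                    conc=float(meta.get("conc", 0.73)),
                    cell_volume=float(meta.get("cell_volume", 0.130)),
                    molar_mass=float(meta.get("molar_mass", 150000.0)),
                    signal_units=str(meta.get("signal_units", "kJ/mol/K")))


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def write_trace(obj, path) -> None:
    """Write a curve in canonical CSV form with ``# key=value`` headers."""
    path = Path(path)
    if isinstance(obj, KineticTrace):
        kind, x, y = "kinetic", obj.t, obj.I
    elif isinstance(obj, NonAggTrace):
        kind, x, y = "nonagg", obj.t, obj.gamma
    elif isinstance(obj, ACF):
        kind, x, y = "acf", obj.tau, obj.g2
    elif isinstance(obj, DSCTrace):
        kind, x, y = "dsc", obj.T, obj.signal
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    meta = {"kind": kind}
    if kind == "acf":
        meta.update(q=obj.q, T=obj.T, eta=obj.eta)
        if obj.beta is not None:
            meta["beta"] = obj.beta
    elif kind == "dsc":
        meta.update(scan_rate=obj.scan_rate, conc=obj.conc,
                    cell_volume=obj.cell_volume, molar_mass=obj.molar_mass,
                    signal_units=obj.signal_units)
    tmeta = getattr(obj, "meta", None)
    if tmeta is not None and kind != "dsc":
        for k in _META_FIELDS:
            v = getattr(tmeta, k)
            if v is not None and v != "":
                meta[k] = v
    xcol, ycol = _COLUMNS[kind]
    buf = _io.StringIO()
    for k in sorted(meta):
        buf.write(f"# {k}={_fmt(meta[k])}\n")
    buf.write(f"{xcol},{ycol}\n")
    for xi, yi in zip(x, y):
        buf.write(f"{_fmt(float(xi))},{_fmt(float(yi))}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    # trace segmentation / fitting
    k_sigma: float = 4.0
    baseline_frac: float = 0.10
    growth_end_frac: float = 0.95
    smooth_frac: float = 0.02
    rounding_threshold: float = 0.35
    gamma_agg_min: float = 0.15
    # physical constants
    protein_molar_mass: float = 150000.0
    wavelength_nm: float = 632.8
    scatter_angle_deg: float = 90.0
    # simulator
    preset: str = "A"
    protein_conc: float = 0.4
    # DLS inversion
    inversion_grid_size: int = 64
    inversion_alpha: Optional[float] = None


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def result_envelope(payload: dict, config: RunConfig) -> dict:
    """Wrap a result dict with the reproducibility header."""
    from . import __version__
    return {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "result": payload,
    }
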