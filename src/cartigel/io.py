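"""Curve files, configuration files and analysis reports.

Curve file format: UTF-8 text, comma-delimited, with ``#``-prefixed
``key=value`` metadata header lines followed by two numeric columns
(hydration, pressure_kpa).  Recognized metadata keys: label, ph,
salt_mol_per_l, temperature_k, tissue_state, seed.  Reading then
writing then reading a file is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .curves import CurveValidationError, SwellingCurve
from .params import BathConditions

__all__ = ["read_curve", "write_curve", "CurveParseError",
           "read_config", "write_report"]

log = logging.getLogger("cartigel")

_META_KEYS = {"label", "ph", "salt_mol_per_l", "temperature_k",
              "tissue_state", "seed", "strict"}


class CurveParseError(ValueError):
    """Malformed curve file; the message carries the line number."""


def write_curve(curve: SwellingCurve, path: str | Path) -> Path:
    """Write a curve file (see module docstring for the format)."""
    path = Path(path)
    lines = [f"# label={curve.label}"]
    if curve.bath is not None:
        lines.append(f"# ph={curve.bath.pH:.10g}")
        lines.append(f"# salt_mol_per_l={curve.bath.salt_concentration:.10g}")
        lines.append(f"# temperature_k={curve.bath.temperature:.10g}")
    if curve.tissue_state is not None:
        lines.append(f"# tissue_state={curve.tissue_state}")
    if curve.seed is not None:
        lines.append(f"# seed={curve.seed}")
    if not curve.strict:
        lines.append("# strict=false")
    lines.append("hydration,pressure_kpa")
    for h, p in zip(curve.hydration, curve.pressure):
        lines.append(f"{float(h)!r},{float(p)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_curve(path: str | Path) -> SwellingCurve:
    """Read and validate a curve file.

    Missing metadata keys get defaults (with a logged warning for a
    missing bath); malformed headers, non-numeric cells and non-monotone
    hydration raise :class:`CurveParseError` naming the line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    h_vals: list[float] = []
    p_vals: list[float] = []
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if not body:
                continue
            if "=" not in body:
                raise CurveParseError(
                    f"{path}:{lineno}: metadata line without '=': {raw!r}"
                )
            key, _, val = body.partition("=")
            key = key.strip()
            if key not in _META_KEYS:
                raise CurveParseError(
                    f"{path}:{lineno}: unknown metadata key {key!r} "
                    f"(known: {', '.join(sorted(_META_KEYS))})"
                )
            meta[key] = val.strip()
            continue
        cells = [c.strip() for c in line.split(",")]
        if cells == ["hydration", "pressure_kpa"]:
            continue  # optional column header
        if len(cells) != 2:
            raise CurveParseError(
                f"{path}:{lineno}: expected 2 columns, got {len(cells)}"
            )
        try:
            h, p = float(cells[0]), float(cells[1])
        except ValueError:
            raise CurveParseError(
                f"{path}:{lineno}: non-numeric cell in {raw!r}"
            ) from None
        if h_vals and h <= h_vals[-1]:
            raise CurveParseError(
                f"{path}:{lineno}: hydration {h:g} not greater than "
                f"previous value {h_vals[-1]:g}"
            )
        h_vals.append(h)
        p_vals.append(p)

    if len(h_vals) < 2:
        raise CurveParseError(f"{path}: fewer than two data rows")

    bath: Optional[BathConditions] = None
    bath_keys = {"ph", "salt_mol_per_l", "temperature_k"}
    if bath_keys & set(meta):
        missing = bath_keys - set(meta)
        if missing:
            log.warning(
                "%s: missing metadata %s; using defaults",
                path, ", ".join(sorted(missing)),
            )
        bath = BathConditions(
            pH=float(meta.get("ph", 7.0)),
            salt_concentration=float(meta.get("salt_mol_per_l", 0.1)),
            temperature=float(meta.get("temperature_k", 298.15)),
        )
    else:
        log.warning("%s: no bath metadata; curve carries none", path)

    strict = meta.get("strict", "true").lower() != "false"
    try:
        return SwellingCurve(
            hydration=np.asarray(h_vals),
            pressure=np.asarray(p_vals),
            label=meta.get("label", path.stem),
            bath=bath,
            tissue_state=meta.get("tissue_state"),
            seed=int(meta["seed"]) if "seed" in meta else None,
            strict=strict,
        )
    except CurveValidationError as err:
        raise CurveParseError(f"{path}: {err}") from err


def read_config(path: str | Path) -> dict:
    """Load a YAML configuration file as a nested mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_report(report: dict, path: str | Path) -> Path:
    """Write an analysis report as flat ``key,value`` CSV (stable names)."""
    path = Path(path)
    lines = ["quantity,value"]
    for key, val in report.items():
        if isinstance(val, float):
            lines.append(f"{key},{val:.10g}")
        else:
            lines.append(f"{key},{val}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
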