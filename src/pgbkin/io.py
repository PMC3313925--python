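"""Delimited-text I/O for traces, spectra and reports, plus run configuration.

Trace files are two-column text (time_s, signal) with '#'-prefixed
``key = value`` metadata header lines.  Spectra files are matrices whose
first row holds the delays and first column the wavelengths.  Readers are
tolerant: unknown metadata keys are preserved verbatim (with a logged
warning) so files written by newer versions still round-trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .scheme import RATE_PRESETS, Conditions, KineticTrace, RateSet
from .synth import SpectraSet

__all__ = [
    "ParseError",
    "read_trace",
    "write_trace",
    "read_spectra",
    "write_spectra",
    "RunConfig",
    "load_config",
]

log = logging.getLogger("pgbkin")

_CONDITION_KEYS = {
    "temperature_K": float,
    "co_atm": float,
    "co_molar": float,
    "phi": float,
    "protein_molar": float,
    "mode": str,
    "pseudo_first_order": lambda s: s in ("True", "true", "1"),
}
_TRACE_KEYS = {"sigma": float}
# generator provenance keys: recognized pass-through metadata
_KNOWN_EXTRAS = {"seed", "generator", "dead_time", "n_components"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _format_header(meta: Mapping[str, Any]) -> list[str]:
    return [f"# {k} = {v}" for k, v in meta.items() if v is not None]


def _parse_header(lines: list[tuple[int, str]], path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for lineno, line in lines:
        body = line.lstrip("#").strip()
        if not body:
            continue
        if "=" not in body:
            raise ParseError(f"{path}:{lineno}: malformed header line {line!r}")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def write_trace(trace: KineticTrace, path: str | Path) -> Path:
    """Write a trace with its full conditions metadata header."""
    path = Path(path)
    c = trace.conditions
    meta: dict[str, Any] = {
        "temperature_K": c.temperature_K,
        "co_atm": c.co_atm,
        "co_molar": c.co_molar,
        "phi": c.phi,
        "protein_molar": c.protein_molar,
        "mode": c.mode,
        "pseudo_first_order": c.pseudo_first_order,
        "sigma": trace.sigma,
    }
    meta.update({k: v for k, v in trace.meta.items() if v is not None})
    lines = _format_header(meta)
    lines.append("# time_s\tsignal")
    for t, y in zip(trace.times, trace.signal):
        lines.append(f"{t:.17e}\t{y:.17e}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path: str | Path) -> KineticTrace:
    """Read a trace file; lossless round trip of values and metadata."""
    path = Path(path)
    header: list[tuple[int, str]] = []
    times, signal = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "\t" in line and "=" not in line:
                continue  # column-title line
            header.append((lineno, line))
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            signal.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    raw = _parse_header(header, path)
    cond_kwargs: dict[str, Any] = {}
    extras: dict[str, str] = {}
    sigma = None
    for key, value in raw.items():
        if value == "None":
            continue
        if key in _CONDITION_KEYS:
            cond_kwargs[key] = _CONDITION_KEYS[key](value)
        elif key in _TRACE_KEYS:
            sigma = _TRACE_KEYS[key](value)
        else:
            extras[key] = value
            if key not in _KNOWN_EXTRAS:
                log.warning(
                    "%s: unknown metadata key %r preserved verbatim", path, key
                )
    conditions = Conditions(**cond_kwargs)
    times = np.asarray(times)
    if times.size and np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ParseError(
            f"{path}: time column not strictly increasing at sample {bad + 1}"
        )
    return KineticTrace(times, np.asarray(signal), conditions, sigma=sigma,
                        meta=extras)


def write_spectra(spectra: SpectraSet, path: str | Path) -> Path:
    """Write a spectra matrix: first row delays, first column wavelengths."""
    path = Path(path)
    meta = {"sigma": spectra.sigma}
    meta.update({k: v for k, v in spectra.meta.items() if v is not None})
    lines = _format_header(meta)
    lines.append("\t".join(["wavelength_nm"] + [f"{d:.17e}" for d in spectra.delays]))
    for wl, row in zip(spectra.wavelengths, spectra.dA):
        lines.append("\t".join([f"{wl:.17g}"] + [f"{v:.17e}" for v in row]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectra(path: str | Path) -> SpectraSet:
    path = Path(path)
    header: list[tuple[int, str]] = []
    rows: list[list[float]] = []
    delays: np.ndarray | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            header.append((lineno, line))
            continue
        parts = line.split("\t")
        if delays is None:
            delays = np.array([float(p) for p in parts[1:]])
            continue
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    if delays is None or not rows:
        raise ParseError(f"{path}: no data rows found")
    raw = _parse_header(header, path)
    sigma = float(raw.pop("sigma")) if raw.get("sigma", "None") != "None" else None
    raw.pop("sigma", None)
    arr = np.asarray(rows)
    return SpectraSet(arr[:, 0], delays, arr[:, 1:], sigma=sigma, meta=raw)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated YAML-backed configuration for a pipeline run.

    Unknown top-level keys are rejected outright; the rates block accepts
    either a preset name (solution / co_gel / deoxy_co_gel) or a flat
    key-value mapping of the 17 rate constants.
    """

    rates: RateSet = None  # type: ignore[assignment]
    conditions: Conditions = None  # type: ignore[assignment]
    seed: int = 0
    noise: float = 2e-3
    n_points: int = 150
    output_dir: Path = Path("pgbkin-out")
    stages: tuple[str, ...] = ("simulate",)
    fit_free: tuple[str, ...] = ("kin_r", "kin_t", "kg_r", "kg_t", "k3", "km3", "kout")
    extras: dict = field(default_factory=dict)

    _FIELDS = {"rates", "conditions", "seed", "noise", "n_points",
               "output_dir", "stages", "fit_free"}

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - cls._FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        rates = raw.get("rates", "solution")
        if isinstance(rates, str):
            if rates not in RATE_PRESETS:
                raise ValueError(
                    f"unknown rate preset {rates!r}; "
                    f"expected one of {sorted(RATE_PRESETS)}"
                )
            kwargs["rates"] = RATE_PRESETS[rates]
        else:
            kwargs["rates"] = RateSet.from_dict(rates)
        cond = raw.get("conditions", {})
        kwargs["conditions"] = cond if isinstance(cond, Conditions) else Conditions(**cond)
        for key in ("seed", "noise", "n_points"):
            if key in raw:
                kwargs[key] = raw[key]
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        for key in ("stages", "fit_free"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def dump_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
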