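"""File formats, run configuration and provenance.

Text dialects used across the pipeline:

* SensorTraceArray — CSV with header ``time_ms,taxel_r0c0,...,taxel_r5c5``,
  or a JSON variant carrying dt, layout and event annotations.
* SpikeTrain — JSON ``{unit_id, unit_type, duration_ms, times_ms}``;
  populations are newline-delimited JSON.
* TransferFunctionModel — JSON ``{structure, num, den, fit, dt}``.

All numeric text output is formatted at 9 significant digits so that
re-running an identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .encoder import SensorTraceArray, SpikeTrain

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_json",
    "read_trace_json",
    "write_spike_trains",
    "read_spike_trains",
    "fmt",
]

#: significant digits in all numeric text output
SIG_DIGITS = 12


def fmt(x: float) -> str:
    return f"{float(x):.{SIG_DIGITS}g}"


# ---------------------------------------------------------------- run config

_KNOWN_SECTIONS: dict[str, set[str]] = {
    "encoder": {"unit", "dt", "params", "signed_derivative"},
    "cuneate": {"tau_fast", "tau_slow", "divergence", "convergence",
                "inhibitory_fraction", "gain_cuneate"},
    "metrics": {"q", "bin_ms"},
    "discrimination": {"shapes", "diameters_mm", "baseline_diameter_mm",
                       "touches_per_object", "features", "vp_pairing"},
    "synergy": {"max_k", "restarts", "max_iter", "threshold", "max_increment",
                "band", "lowpass_hz", "target_fs"},
    "sysid": {"structure", "dt", "n_starts", "candidates"},
    "synthetic": {"shape", "diameter_mm", "mode", "duration_ms", "dt",
                  "impact_time_ms", "impact_mass_g", "base_amplitude",
                  "curvature_gain", "noise_sd", "amplitude_jitter_sd",
                  "emg_csv"},
}
_TOP_LEVEL = set(_KNOWN_SECTIONS) | {"seed", "out_dir", "log_level"}


@dataclass
class RunConfig:
    """Validated pipeline configuration; every stochastic stage receives a
    seed derived from the global one."""

    seed: int = 0
    out_dir: str = "tactosense_out"
    log_level: str = "INFO"
    sections: dict = field(default_factory=dict)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def derived_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "out_dir": self.out_dir,
             "log_level": self.log_level}
        d.update({k: dict(v) for k, v in sorted(self.sections.items())})
        return d


def _validate(raw: dict) -> None:
    for key, value in raw.items():
        if key not in _TOP_LEVEL:
            raise ValueError(f"unknown config key: {key!r}")
        if key in _KNOWN_SECTIONS:
            unknown = set(value) - _KNOWN_SECTIONS[key]
            if unknown:
                raise ValueError(
                    f"unknown key(s) in section {key!r}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _validate(raw)
    sections = {k: v for k, v in raw.items() if k in _KNOWN_SECTIONS}
    return RunConfig(seed=raw.get("seed", 0),
                     out_dir=raw.get("out_dir", "tactosense_out"),
                     log_level=raw.get("log_level", "INFO"),
                     sections=sections)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ------------------------------------------------------------ trace formats

def _taxel_headers(rows: int, cols: int) -> list[str]:
    return [f"taxel_r{r}c{c}" for r in range(rows) for c in range(cols)]


def write_trace_csv(trace: SensorTraceArray, path: str | Path) -> None:
    headers = ["time_ms"] + _taxel_headers(trace.rows, trace.cols)
    lines = [",".join(headers)]
    times = trace.times_ms
    for k in range(trace.n_samples):
        lines.append(",".join([fmt(times[k])] + [fmt(x) for x in trace.data[:, k]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_csv(path: str | Path, rows: int = 6, cols: int = 6) -> SensorTraceArray:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(",")
    expected = ["time_ms"] + _taxel_headers(rows, cols)
    if header != expected:
        raise ValueError(f"{path}: line 1: malformed header (expected "
                         f"'time_ms,taxel_r0c0,...')")
    times, values = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(expected):
            raise ValueError(f"{path}: line {ln}: expected {len(expected)} fields, "
                             f"got {len(parts)}")
        times.append(float(parts[0]))
        values.append([float(x) for x in parts[1:]])
    t = np.asarray(times)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = float(t[1] - t[0])
    return SensorTraceArray(np.asarray(values).T, dt, rows, cols)


def write_trace_json(trace: SensorTraceArray, path: str | Path,
                     provenance: dict | None = None) -> None:
    doc = {
        "dt": float(fmt(trace.dt)),
        "layout": {"rows": trace.rows, "cols": trace.cols},
        "events": {k: float(fmt(v)) for k, v in trace.annotations.items()},
        "data": [[float(fmt(x)) for x in row] for row in trace.data],
    }
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc))


def read_trace_json(path: str | Path) -> SensorTraceArray:
    doc = json.loads(Path(path).read_text())
    layout = doc.get("layout", {"rows": 6, "cols": 6})
    return SensorTraceArray(np.asarray(doc["data"]), doc["dt"],
                            layout["rows"], layout["cols"],
                            annotations=doc.get("events", {}))


# ------------------------------------------------------------ spike formats

def _train_doc(train: SpikeTrain) -> dict:
    return {
        "unit_id": train.unit_id,
        "unit_type": train.unit_type,
        "duration_ms": float(fmt(train.duration)),
        "times_ms": [float(fmt(t)) for t in train.times],
    }


def write_spike_trains(trains: SpikeTrain | list[SpikeTrain], path: str | Path,
                       provenance: dict | None = None) -> None:
    """One JSON object per line; a provenance line (prefixed #) first."""
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    lines = []
    if provenance:
        lines.append("#" + json.dumps(provenance, sort_keys=True))
    lines.extend(json.dumps(_train_doc(t), sort_keys=True) for t in trains)
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    trains = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        d = json.loads(line)
        trains.append(SpikeTrain(np.asarray(d["times_ms"]), d["duration_ms"],
                                 d.get("unit_id", ""), d.get("unit_type", "SAI")))
    return trains
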