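"""Readers/writers, run records, error summaries and the replay microscope.

Conventions: z is always micrometres, increasing toward the objective in the
simulator; hardware adapters declare their own sign and are normalised by
the controller.  Headline autofocus errors are absolute deviations from the
optimal plane reported as mean +/- standard error of the mean; signed errors
are retained for bias diagnosis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .metrics import SharpnessSample
from .search import AutofocusConfig, FocusResult, SearchEvent, SearchTrace

__all__ = [
    "FormatError",
    "ErrorReport",
    "RunRecord",
    "summarise_errors",
    "write_stack",
    "read_stack",
    "write_trace",
    "read_trace",
    "load_config",
    "TiffStackMicroscope",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending field."""


@dataclass(frozen=True)
class ErrorReport:
    """Autofocus error summary over repeated runs (mean +/- SEM convention)."""

    mean_abs_um: float
    sem_um: float
    signed_mean_um: float
    n: int


def summarise_errors(errors_um) -> ErrorReport:
    """Summarise signed focus errors: absolute mean +/- SEM, plus signed mean.

    The SEM uses the sample (divisor n-1) standard deviation of the absolute
    errors divided by sqrt(n).
    """
    e = np.asarray(errors_um, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("summarise_errors needs at least 2 error values")
    a = np.abs(e)
    return ErrorReport(
        mean_abs_um=float(a.mean()),
        sem_um=float(a.std(ddof=1) / np.sqrt(a.size)),
        signed_mean_um=float(e.mean()),
        n=int(e.size),
    )


# --- stacks -------------------------------------------------------------------


def write_stack(path, planes, sidecar: Optional[dict] = None) -> None:
    """Write a multi-page TIFF; optional JSON sidecar next to it (.json)."""
    planes = np.asarray(planes)
    tifffile.imwrite(str(path), planes)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path):
    """Read a multi-page TIFF; returns (array, sidecar dict or None)."""
    try:
        arr = tifffile.imread(str(path))
    except (FileNotFoundError, OSError) as exc:
        raise FormatError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    sidecar = None
    sidecar_path = Path(path).with_suffix(".json")
    if sidecar_path.exists():
        try:
            sidecar = json.loads(sidecar_path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    return arr, sidecar


# --- run records --------------------------------------------------------------


@dataclass
class RunRecord:
    """One complete autofocus run: config, trace, result, timing, seed."""

    config: AutofocusConfig
    result: FocusResult
    seed: Optional[int] = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        tr = self.result.trace
        return {
            "config": asdict(self.config),
            "seed": self.seed,
            "notes": self.notes,
            "result": {
                "z_focus_um": self.result.z_focus_um,
                "source": self.result.source,
                "fit_peak_z_um": self.result.fit_peak_z_um,
                "best_measured_z_um": self.result.best_measured_z_um,
                "niqe_scores": list(self.result.niqe_scores)
                if self.result.niqe_scores is not None else None,
                "timing_s": self.result.timing_s,
            },
            "trace": {
                "direction": tr.direction,
                "samples": [[s.z_um, s.sharpness] for s in tr.samples],
                "step_history": list(tr.step_history),
                "events": [asdict(e) for e in tr.events],
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunRecord":
        try:
            cfg = AutofocusConfig(**payload["config"])
            tr = payload["trace"]
            res = payload["result"]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"run record missing field: {exc}") from exc
        trace = SearchTrace(
            samples=[SharpnessSample(z_um=z, sharpness=s) for z, s in tr["samples"]],
            step_history=list(tr["step_history"]),
            events=[SearchEvent(**e) for e in tr["events"]],
            direction=int(tr["direction"]),
        )
        result = FocusResult(
            z_focus_um=res["z_focus_um"],
            source=res["source"],
            fit_peak_z_um=res["fit_peak_z_um"],
            best_measured_z_um=res["best_measured_z_um"],
            trace=trace,
            niqe_scores=tuple(res["niqe_scores"]) if res["niqe_scores"] else None,
            timing_s=res["timing_s"],
        )
        return cls(config=cfg, result=result, seed=payload.get("seed"),
                   notes=payload.get("notes", {}))


def write_trace(path, record: RunRecord) -> None:
    Path(path).write_text(json.dumps(record.to_dict(), indent=1))


def read_trace(path) -> RunRecord:
    try:
        payload = json.loads(Path(path).read_text())
    except (FileNotFoundError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read trace {path!r}: {exc}") from exc
    return RunRecord.from_dict(payload)


def trace_to_csv(path, trace: SearchTrace) -> None:
    """Flat CSV of the search trace (z, sharpness, step in effect)."""
    lines = ["z_um,sharpness,step_um"]
    for s, st in zip(trace.samples, trace.step_history):
        lines.append(f"{s.z_um!r},{s.sharpness!r},{st!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# --- config files -------------------------------------------------------------


def load_config(path, overrides: Optional[dict] = None) -> AutofocusConfig:
    """Load an AutofocusConfig from a TOML-style key=value file.

    CLI flags (``overrides``) win over file values; unknown keys raise a
    :class:`FormatError` naming the key.
    """
    import tomllib

    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError as exc:
        raise FormatError(f"config file not found: {path}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise FormatError(f"malformed config {path}: {exc}") from exc
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(AutofocusConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    try:
        return AutofocusConfig(**data)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid config value: {exc}") from exc


# --- replay microscope --------------------------------------------------------


class TiffStackMicroscope:
    """Replay a pre-acquired z-stack as if it were a microscope.

    ``move_to`` snaps to the nearest recorded plane (so NIQE verification at
    a fitted peak uses the nearest acquired plane); travel limits are the
    recorded z range.
    """

    def __init__(self, planes, z_positions_um) -> None:
        self.planes = np.asarray(planes, dtype=float)
        self.z = np.asarray(z_positions_um, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != self.z.size:
            raise FormatError("stack/z_positions mismatch in replay source")
        self._idx = 0

    @classmethod
    def from_file(cls, path) -> "TiffStackMicroscope":
        arr, sidecar = read_stack(path)
        if sidecar is None or "z_positions_um" not in sidecar:
            raise FormatError(
                f"replay stack {path!r} needs a JSON sidecar with z_positions_um"
            )
        return cls(arr, np.asarray(sidecar["z_positions_um"], dtype=float))

    @property
    def z_limits_um(self) -> tuple[float, float]:
        return float(self.z.min()), float(self.z.max())

    def move_to(self, z_um: float) -> None:
        lo, hi = self.z_limits_um
        if not (lo - 1e-9 <= z_um <= hi + 1e-9):
            from .search import StageTravelError

            raise StageTravelError(
                f"replay z={z_um:.3f} outside recorded range [{lo}, {hi}]"
            )
        self._idx = int(np.argmin(np.abs(self.z - z_um)))

    def capture(self) -> np.ndarray:
        return self.planes[self._idx]
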