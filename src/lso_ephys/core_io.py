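"""Domain types, bundle readers/writers, and elementary trace corrections.

A *cell bundle* is a directory holding one ``metadata.json`` plus one
long-format CSV per protocol (columns ``time_ms, rep_index, vm_mV``).  All
times are in milliseconds with time 0 at stimulus (or current-step) onset;
analysis windows are half-open ``[a, b)``.  Membrane potential is in mV,
sampling rates in Hz, current in pA, sound levels in dB SPL.

The interaural level difference convention is ``ILD = contra SPL - ipsi SPL``
so negative ILDs mean the ipsilateral (excitatory) ear is louder.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ToneStimulus",
    "CurrentStep",
    "Sweep",
    "CellRecord",
    "JUNCTION_POTENTIAL_MV",
    "read_cell_bundle",
    "write_cell_bundle",
    "correct_junction_potential",
    "baseline_median",
]

#: Liquid junction potential subtracted from raw pipette recordings (mV).
JUNCTION_POTENTIAL_MV = 10.0


class SchemaError(KeyError):
    """A bundle metadata file is missing a required key."""


class ValidationError(ValueError):
    """Bundle contents violate a structural invariant."""


@dataclass(frozen=True)
class ToneStimulus:
    """Pure-tone stimulus delivered to one or both ears.

    ``level_ipsi`` / ``level_contra`` are dB SPL and are ``None`` for an
    unused ear.  ``onset`` is 0 ms by convention; ``duration`` in ms.
    """

    ear: str  # "ipsi" | "contra" | "binaural"
    frequency: float  # Hz
    duration: float  # ms
    level_ipsi: Optional[float] = None
    level_contra: Optional[float] = None
    onset: float = 0.0
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.ear not in ("ipsi", "contra", "binaural"):
            raise ValidationError(f"unknown ear {self.ear!r}")
        if not self.duration > 0:
            raise ValidationError("stimulus duration must be positive")
        if self.ear == "binaural" and (
            self.level_ipsi is None or self.level_contra is None
        ):
            raise ValidationError("binaural stimulus needs both ear levels")
        if self.ear == "ipsi" and self.level_ipsi is None:
            raise ValidationError("ipsi stimulus needs level_ipsi")
        if self.ear == "contra" and self.level_contra is None:
            raise ValidationError("contra stimulus needs level_contra")

    @property
    def ild(self) -> Optional[float]:
        """ILD in dB (contra - ipsi); ``None`` unless binaural."""
        if self.level_ipsi is None or self.level_contra is None:
            return None
        return self.level_contra - self.level_ipsi


@dataclass(frozen=True)
class CurrentStep:
    """Square current step injected through the pipette (pA, ms)."""

    amplitude: float  # pA; negative = hyperpolarizing
    duration: float = 100.0  # ms
    onset: float = 0.0  # ms

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError("step duration must be positive")


Stimulus = Union[ToneStimulus, CurrentStep, str]


@dataclass
class Sweep:
    """One uniformly sampled membrane-potential trace.

    ``t0_offset`` is the time of the first sample relative to stimulus onset
    (ms, typically negative: the recording starts before the stimulus).
    """

    samples: np.ndarray  # mV
    sampling_rate: float  # Hz
    t0_offset: float = 0.0  # ms
    stimulus: Stimulus = "spontaneous"
    series_resistance: Optional[float] = None  # MOhm
    junction_corrected: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (1e3 <= self.sampling_rate <= 200e3):
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} Hz outside [1, 200] kHz"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1e3

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_offset + np.arange(self.n_samples) / self.sampling_rate * 1e3

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Index slice for the half-open window [start_ms, stop_ms)."""
        fs_ms = self.sampling_rate / 1e3
        i0 = int(math.ceil((start_ms - self.t0_offset) * fs_ms - 1e-9))
        i1 = int(math.ceil((stop_ms - self.t0_offset) * fs_ms - 1e-9))
        return slice(max(i0, 0), max(min(i1, self.n_samples), 0))


@dataclass
class CellRecord:
    """One recorded neuron: protocol-keyed sweep collections plus anatomy."""

    cell_id: str
    anatomical_class: str = "unknown"  # principal|class5|marginal|multiplanar|unknown
    cf: Optional[float] = None  # Hz, characteristic frequency
    bf: Optional[float] = None  # Hz, best frequency
    normalized_position: Optional[float] = None  # 0 lateral .. 1 medial
    coverage_percent: Optional[float] = None
    protocols: Dict[str, List[Sweep]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normalized_position is not None and not (
            0.0 <= self.normalized_position <= 1.0
        ):
            raise ValidationError("normalized_position must lie in [0, 1]")
        if self.coverage_percent is not None and not (
            0.0 <= self.coverage_percent <= 100.0
        ):
            raise ValidationError("coverage_percent must lie in [0, 100]")
        for name, sweeps in self.protocols.items():
            _check_protocol(name, sweeps)

    def protocols_with_prefix(self, prefix: str) -> Dict[str, List[Sweep]]:
        return {k: v for k, v in self.protocols.items() if k.startswith(prefix)}


def _check_protocol(name: str, sweeps: List[Sweep]) -> None:
    rates = {s.sampling_rate for s in sweeps}
    if len(rates) > 1:
        raise ValidationError(
            f"protocol {name!r}: sweeps mix sampling rates {sorted(rates)}"
        )


# ---------------------------------------------------------------------------
# trace corrections


def correct_junction_potential(
    sweep: Sweep, junction_mv: float = JUNCTION_POTENTIAL_MV
) -> Sweep:
    """Subtract the liquid junction potential from a raw sweep.

    Returns a new sweep with every sample decreased by ``junction_mv`` and
    ``junction_corrected`` set.  Applying the correction twice is an error.
    """
    if sweep.junction_corrected:
        raise ValidationError("double correction: sweep is already junction-corrected")
    return replace(
        sweep, samples=sweep.samples - junction_mv, junction_corrected=True
    )


def baseline_median(sweep: Sweep, window_ms: tuple) -> float:
    """Median membrane potential over the half-open window ``[a, b)`` (ms)."""
    a, b = window_ms
    sl = sweep.window_slice(a, b)
    if sl.stop <= sl.start:
        raise ValidationError(f"empty baseline window [{a}, {b}) ms")
    return float(np.median(sweep.samples[sl]))


# ---------------------------------------------------------------------------
# bundle serialization

_REQUIRED_CELL_KEYS = ("cell_id", "protocols")
_REQUIRED_PROTO_KEYS = ("sampling_rate_hz", "t0_offset_ms", "stimulus")


def _stimulus_to_json(stim: Stimulus) -> dict:
    if isinstance(stim, ToneStimulus):
        return {
            "kind": "tone",
            "ear": stim.ear,
            "frequency_hz": stim.frequency,
            "duration_ms": stim.duration,
            "level_ipsi_db": stim.level_ipsi,
            "level_contra_db": stim.level_contra,
            "onset_ms": stim.onset,
            "n_reps": stim.n_reps,
        }
    if isinstance(stim, CurrentStep):
        return {
            "kind": "step",
            "amplitude_pa": stim.amplitude,
            "duration_ms": stim.duration,
            "onset_ms": stim.onset,
        }
    return {"kind": "spontaneous"}


def _stimulus_from_json(d: dict) -> Stimulus:
    kind = d.get("kind", "spontaneous")
    if kind == "tone":
        return ToneStimulus(
            ear=d["ear"],
            frequency=d["frequency_hz"],
            duration=d["duration_ms"],
            level_ipsi=d.get("level_ipsi_db"),
            level_contra=d.get("level_contra_db"),
            onset=d.get("onset_ms", 0.0),
            n_reps=d.get("n_reps", 1),
        )
    if kind == "step":
        return CurrentStep(
            amplitude=d["amplitude_pa"],
            duration=d["duration_ms"],
            onset=d.get("onset_ms", 0.0),
        )
    return "spontaneous"


def write_cell_bundle(cell: CellRecord, path: Union[str, Path]) -> Path:
    """Write a :class:`CellRecord` as a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "cell_id": cell.cell_id,
        "anatomical_class": cell.anatomical_class,
        "cf_hz": cell.cf,
        "bf_hz": cell.bf,
        "normalized_position": cell.normalized_position,
        "coverage_percent": cell.coverage_percent,
        "protocols": {},
    }
    for name, sweeps in cell.protocols.items():
        if not sweeps:
            continue
        first = sweeps[0]
        meta["protocols"][name] = {
            "sampling_rate_hz": first.sampling_rate,
            "t0_offset_ms": first.t0_offset,
            "stimulus": _stimulus_to_json(first.stimulus),
            "series_resistance_mohm": first.series_resistance,
            "junction_corrected": first.junction_corrected,
            "n_reps": len(sweeps),
        }
        frames = []
        for rep, sw in enumerate(sweeps):
            frames.append(
                pd.DataFrame(
                    {"time_ms": sw.times, "rep_index": rep, "vm_mV": sw.samples}
                )
            )
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(path / f"{name}.csv", index=False, float_format="%.12g")
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_cell_bundle(path: Union[str, Path]) -> CellRecord:
    """Read a bundle directory written by :func:`write_cell_bundle`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SchemaError("metadata.json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in _REQUIRED_CELL_KEYS:
        if key not in meta:
            raise SchemaError(key)
    protocols: Dict[str, List[Sweep]] = {}
    for name, pmeta in meta["protocols"].items():
        for key in _REQUIRED_PROTO_KEYS:
            if key not in pmeta:
                raise SchemaError(f"protocols.{name}.{key}")
        fs = float(pmeta["sampling_rate_hz"])
        t0 = float(pmeta["t0_offset_ms"])
        stim = _stimulus_from_json(pmeta["stimulus"])
        table = pd.read_csv(path / f"{name}.csv")
        sweeps: List[Sweep] = []
        for rep, grp in table.groupby("rep_index", sort=True):
            t = grp["time_ms"].to_numpy()
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"protocol {name!r} rep {rep}: time column is not monotone"
                )
            sweeps.append(
                Sweep(
                    samples=grp["vm_mV"].to_numpy(),
                    sampling_rate=fs,
                    t0_offset=t0,
                    stimulus=stim,
                    series_resistance=pmeta.get("series_resistance_mohm"),
                    junction_corrected=bool(pmeta.get("junction_corrected", False)),
                )
            )
        protocols[name] = sweeps
    return CellRecord(
        cell_id=meta["cell_id"],
        anatomical_class=meta.get("anatomical_class", "unknown"),
        cf=meta.get("cf_hz"),
        bf=meta.get("bf_hz"),
        normalized_position=meta.get("normalized_position"),
        coverage_percent=meta.get("coverage_percent"),
        protocols=protocols,
    )
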