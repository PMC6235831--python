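"""Data model and file I/O for evoked-EPSC sweep recordings.

The elementary datum is the peak magnitude (pA) of the excitatory postsynaptic
current evoked by each light/electrical stimulus.  A *sweep* is one run of a
stimulation protocol (a single pulse, a pair of pulses, or a train); a
:class:`Recording` holds a ``sweeps x stimuli`` matrix of amplitudes under one
protocol and condition.

Conventions
-----------
* Amplitudes are stored as non-negative magnitudes in pA (EPSCs are inward
  currents; the sign is dropped at ingestion).
* Stimulus indices are 1-based, matching the "first EPSC" convention used when
  normalizing facilitation curves.
* On disk a recording is a CSV with columns ``sweep_id, stimulus_index,
  amplitude_pA`` (comma separator, dot decimal, UTF-8, header required); the
  protocol travels separately as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ValidationError

__all__ = [
    "StimulusProtocol",
    "Recording",
    "FailureMask",
    "read_recording",
    "write_recording",
    "load_protocol",
    "dump_protocol",
    "classify_failures",
]

_CSV_COLUMNS = ("sweep_id", "stimulus_index", "amplitude_pA")


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of one stimulation protocol.

    Parameters
    ----------
    frequency_hz
        Within-sweep stimulation frequency (Hz); the inter-stimulus interval
        is ``1 / frequency_hz`` seconds.
    n_stimuli
        Number of stimuli per sweep.
    inter_sweep_interval_s
        Rest period between sweeps (s).  Recorded as metadata; sweeps are
        treated as independent realizations.
    label
        Free-text tag, e.g. ``"train20"`` or ``"paired40ms"``.
    """

    frequency_hz: float
    n_stimuli: int
    inter_sweep_interval_s: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ValidationError("frequency_hz must be > 0")
        if int(self.n_stimuli) != self.n_stimuli or self.n_stimuli < 1:
            raise ValidationError("n_stimuli must be an integer >= 1")
        object.__setattr__(self, "n_stimuli", int(self.n_stimuli))
        if self.inter_sweep_interval_s < 0:
            raise ValidationError("inter_sweep_interval_s must be >= 0")

    @property
    def isi_s(self) -> float:
        """Inter-stimulus interval in seconds (derived)."""
        return 1.0 / self.frequency_hz


@dataclass
class Recording:
    """A set of sweeps of per-stimulus EPSC amplitude magnitudes.

    ``sweeps`` is a float matrix of shape ``(n_sweeps, n_stimuli)`` (pA,
    non-negative); row order is acquisition order, column ``j`` holds stimulus
    ``j + 1`` (1-based stimulus indexing at the API surface).
    """

    sweeps: np.ndarray
    protocol: StimulusProtocol
    condition_label: str = ""
    noise_sd_pA: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.sweeps, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.ndim != 2:
            raise ValidationError("sweeps must be a 2-D matrix")
        if arr.shape[1] != self.protocol.n_stimuli:
            raise ValidationError(
                f"sweep matrix has {arr.shape[1]} columns but the protocol "
                f"declares {self.protocol.n_stimuli} stimuli"
            )
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("all amplitudes must be finite")
        if arr.size and arr.min() < 0:
            raise ValidationError("amplitudes are magnitudes and must be >= 0")
        if self.noise_sd_pA < 0:
            raise ValidationError("noise_sd_pA must be >= 0")
        self.sweeps = arr

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.sweeps.shape[1]


@dataclass
class FailureMask:
    """Boolean matrix flagging transmission failures (True = failure)."""

    mask: np.ndarray
    threshold_pA: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.threshold_pA < 0:
            raise ValidationError("threshold_pA must be >= 0")

    @property
    def failure_rate(self) -> float:
        """Fraction of (sweep, stimulus) entries classified as failures."""
        if self.mask.size == 0:
            raise ValidationError("failure rate of an empty mask is undefined")
        return float(self.mask.mean())


def load_protocol(path: str | Path) -> StimulusProtocol:
    """Read a stimulus protocol from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        return StimulusProtocol(
            frequency_hz=obj["frequency_hz"],
            n_stimuli=obj["n_stimuli"],
            inter_sweep_interval_s=obj.get("inter_sweep_interval_s", 10.0),
            label=obj.get("label", ""),
        )
    except KeyError as exc:  # pragma: no cover - trivial
        raise FormatError(f"protocol JSON missing key {exc}") from exc


def dump_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    """Write a stimulus protocol to a JSON file."""
    obj = {
        "frequency_hz": protocol.frequency_hz,
        "n_stimuli": protocol.n_stimuli,
        "inter_sweep_interval_s": protocol.inter_sweep_interval_s,
        "label": protocol.label,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def read_recording(
    path: str | Path,
    protocol: StimulusProtocol,
    *,
    condition_label: str = "",
    noise_sd_pA: float = 0.0,
) -> Recording:
    """Read a recording CSV into a :class:`Recording`.

    The CSV must carry the columns ``sweep_id, stimulus_index, amplitude_pA``;
    every sweep must contain exactly one row per stimulus index in
    ``1..protocol.n_stimuli``.  Rows are reordered by ``(sweep_id,
    stimulus_index)``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"recording CSV missing column(s) {missing}")
    if df.empty:
        return Recording(
            np.empty((0, protocol.n_stimuli)), protocol,
            condition_label=condition_label, noise_sd_pA=noise_sd_pA,
        )
    if df[list(_CSV_COLUMNS)].isna().any().any():
        raise ValidationError("recording CSV contains missing cells")
    stim = df["stimulus_index"]
    if (stim < 1).any() or (stim > protocol.n_stimuli).any():
        raise ValidationError(
            "stimulus_index out of range 1..n_stimuli (indices are 1-based)"
        )
    if (df["amplitude_pA"] < 0).any():
        raise ValidationError("negative amplitude in recording CSV")
    wide = df.pivot_table(
        index="sweep_id", columns="stimulus_index", values="amplitude_pA",
        aggfunc="first", dropna=False,
    ).sort_index()
    dupes = df.duplicated(subset=["sweep_id", "stimulus_index"])
    if dupes.any():
        raise ValidationError("duplicate (sweep_id, stimulus_index) pair")
    wide = wide.reindex(columns=range(1, protocol.n_stimuli + 1))
    if wide.isna().any().any():
        raise ValidationError("incomplete sweep: every stimulus index needs a row")
    return Recording(
        wide.to_numpy(dtype=float), protocol,
        condition_label=condition_label, noise_sd_pA=noise_sd_pA,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to CSV in the canonical long format.

    Rows are ordered by sweep then stimulus; sweep ids are renumbered 1..n.
    """
    n_sweeps, n_stim = rec.sweeps.shape
    df = pd.DataFrame(
        {
            "sweep_id": np.repeat(np.arange(1, n_sweeps + 1), n_stim),
            "stimulus_index": np.tile(np.arange(1, n_stim + 1), n_sweeps),
            # repr gives the shortest decimal that round-trips bit-exactly
            "amplitude_pA": [repr(float(v)) for v in rec.sweeps.ravel()],
        }
    )
    df.to_csv(path, index=False)


def classify_failures(
    rec: Recording, threshold_pA: float | str = "auto"
) -> FailureMask:
    """Classify each (sweep, stimulus) entry as failure or success.

    An entry is a failure when its amplitude falls below ``threshold_pA``.
    With ``threshold_pA="auto"`` the threshold is three times the recording's
    baseline noise standard deviation, a conventional detection limit; the
    recording must then declare ``noise_sd_pA > 0``.
    """
    if isinstance(threshold_pA, str):
        if threshold_pA != "auto":
            raise ConfigurationError(f"unknown threshold mode {threshold_pA!r}")
        if rec.noise_sd_pA <= 0:
            raise ConfigurationError(
                "auto threshold needs noise_sd_pA > 0 on the recording"
            )
        threshold = 3.0 * rec.noise_sd_pA
    else:
        threshold = float(threshold_pA)
        if threshold < 0:
            raise ValidationError("threshold_pA must be >= 0")
    return FailureMask(mask=rec.sweeps < threshold, threshold_pA=threshold)
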