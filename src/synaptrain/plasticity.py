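"""Short-term-plasticity metrics.

Facilitation is quantified as EPSC amplitude normalized to the first EPSC of
the protocol.  The normalization convention throughout is *means of columns
then ratio*: per unit (neuron/recording), the per-stimulus mean amplitude is
divided by that unit's first-stimulus mean, and curves are then averaged
across units.  This matches normalization applied to averaged responses and
avoids dividing by near-zero single-sweep baselines.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .io import Recording

__all__ = [
    "FacilitationCurve",
    "SpikeTransmissionCurve",
    "paired_pulse_ratio",
    "frequency_facilitation",
    "train_facilitation",
    "steady_state_amplitude",
    "spike_transmission_curve",
]


@dataclass
class FacilitationCurve:
    """Across-unit mean normalized amplitude per stimulus index.

    ``values[0]`` corresponds to stimulus 1 and equals 1.0 exactly.
    """

    values: np.ndarray
    sem: np.ndarray
    n_units: int


@dataclass
class SpikeTransmissionCurve:
    """Per-stimulus spike probability, averaged per unit then across units."""

    fraction: np.ndarray
    n_units: int
    sweeps_per_unit: tuple[int, ...]


def paired_pulse_ratio(rec: Recording) -> float:
    """Mean second-pulse amplitude over mean first-pulse amplitude.

    Requires a two-stimulus protocol.  The ratio of column means is used, not
    the mean of per-sweep ratios.
    """
    if rec.n_stimuli != 2:
        raise ValidationError("paired-pulse ratio needs exactly 2 stimuli")
    if rec.n_sweeps == 0:
        raise ValidationError("no sweeps")
    m1, m2 = rec.sweeps.mean(axis=0)
    if m1 <= 0:
        raise ValidationError("degenerate baseline: mean first amplitude is 0")
    return float(m2 / m1)


def frequency_facilitation(rec_low: Recording, rec_high: Recording) -> float:
    """Ratio of mean amplitudes between two single-stimulus protocols.

    Quantifies facilitation observed when raising the stimulation rate (e.g.
    0.1 Hz -> 1 Hz): ``mean(high) / mean(low)``.
    """
    for rec in (rec_low, rec_high):
        if rec.n_stimuli != 1:
            raise ValidationError(
                "frequency facilitation needs single-stimulus protocols"
            )
        if rec.n_sweeps == 0:
            raise ValidationError("no sweeps")
    m_low = float(rec_low.sweeps.mean())
    if m_low <= 0:
        raise ValidationError("degenerate baseline: zero low-frequency mean")
    return float(rec_high.sweeps.mean() / m_low)


def _as_units(recs: Recording | Iterable[Recording]) -> list[Recording]:
    if isinstance(recs, Recording):
        return [recs]
    units = list(recs)
    if not units:
        raise ValidationError("need at least one unit")
    n = units[0].n_stimuli
    if any(u.n_stimuli != n for u in units):
        raise ValidationError("all units must share the stimulus count")
    return units


def train_facilitation(recs: Recording | Iterable[Recording]) -> FacilitationCurve:
    """Across-unit facilitation curve of a stimulus train.

    Each unit's per-stimulus mean amplitudes are normalized by its own
    first-stimulus mean; curves are averaged across units with SEM.  Units
    with a zero first-pulse mean are excluded with a warning.
    """
    units = _as_units(recs)
    if units[0].n_stimuli < 2:
        raise ValidationError("train facilitation needs >= 2 stimuli")
    normalized = []
    for idx, unit in enumerate(units):
        if unit.n_sweeps == 0:
            warnings.warn(f"unit {idx} has no sweeps; excluded")
            continue
        col_means = unit.sweeps.mean(axis=0)
        if col_means[0] <= 0:
            warnings.warn(f"unit {idx} has zero first-pulse mean; excluded")
            continue
        normalized.append(col_means / col_means[0])
    if not normalized:
        raise ValidationError("all units excluded (zero first-pulse means)")
    arr = np.vstack(normalized)
    values = arr.mean(axis=0)
    if arr.shape[0] > 1:
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    else:
        sem = np.zeros(arr.shape[1])
    return FacilitationCurve(values=values, sem=sem, n_units=arr.shape[0])


def steady_state_amplitude(
    rec: Recording, window: tuple[int, int]
) -> float:
    """Mean raw amplitude (pA) over a 1-based inclusive stimulus window."""
    lo, hi = window
    if not (1 <= lo <= hi <= rec.n_stimuli):
        raise ValidationError("window must satisfy 1 <= lo <= hi <= n_stimuli")
    if rec.n_sweeps == 0:
        raise ValidationError("no sweeps")
    return float(rec.sweeps[:, lo - 1: hi].mean())


def spike_transmission_curve(
    spikes_per_unit: Sequence[np.ndarray],
) -> SpikeTransmissionCurve:
    """Per-stimulus spike transmission fraction.

    ``spikes_per_unit`` is one boolean (sweeps x stimuli) matrix per unit
    (neuron).  Fractions are computed per unit (mean over its sweeps) and
    then averaged across units, so every neuron weighs equally.
    """
    if len(spikes_per_unit) == 0:
        raise ValidationError("need at least one unit")
    mats = []
    for idx, mat in enumerate(spikes_per_unit):
        arr = np.asarray(mat)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValidationError(
                f"unit {idx}: expected a 2-D (sweeps x stimuli) matrix"
            )
        mats.append(arr.astype(bool))
    n_stim = mats[0].shape[1]
    if any(m.shape[1] != n_stim for m in mats):
        raise ValidationError("ragged sweep lengths across units")
    per_unit = np.vstack([m.mean(axis=0) for m in mats])
    return SpikeTransmissionCurve(
        fraction=per_unit.mean(axis=0),
        n_units=len(mats),
        sweeps_per_unit=tuple(m.shape[0] for m in mats),
    )
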