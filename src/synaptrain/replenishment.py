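"""Cumulative-amplitude estimator of the vesicle replenishment rate.

During a sustained high-frequency train the EPSC amplitude settles to a
steady state in which release is limited by the resupply of release-competent
vesicles.  Plotting the running sum of per-stimulus mean amplitudes against
stimulus number then yields a late linear segment whose slope (pA per
stimulus) equals the steady-state amplitude per stimulus; dividing by the
quantal size converts it to vesicles resupplied per inter-stimulus interval.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io import Recording, StimulusProtocol

__all__ = [
    "CumulativeCurve",
    "ReplenishmentFit",
    "ReplenishmentGroup",
    "cumulative_amplitude",
    "fit_replenishment",
    "replenishment_per_neuron",
]


@dataclass
class CumulativeCurve:
    """Running sum of per-stimulus mean amplitudes (pA); index 0 = stimulus 1."""

    values: np.ndarray
    protocol: StimulusProtocol


@dataclass
class ReplenishmentFit:
    """Linear fit of the late cumulative-amplitude segment.

    ``rate_sv_per_isi = slope_pA_per_stim / quantal_pA`` exactly;
    ``rate_sv_per_s`` multiplies by the stimulation frequency.
    """

    slope_pA_per_stim: float
    intercept_pA: float
    window: tuple[int, int]
    r_squared: float
    quantal_pA: float
    rate_sv_per_isi: float
    rate_sv_per_s: float


@dataclass
class ReplenishmentGroup:
    """Per-neuron fits with the across-neuron mean and SEM of the rate."""

    fits: list[ReplenishmentFit]
    mean_rate_sv_per_isi: float
    sem_rate_sv_per_isi: float


def cumulative_amplitude(rec: Recording) -> CumulativeCurve:
    """Cumulative per-stimulus mean amplitude of a train recording."""
    if rec.n_stimuli < 2:
        raise ValidationError("cumulative curve needs >= 2 stimuli")
    if rec.n_sweeps == 0:
        raise ValidationError("no sweeps")
    return CumulativeCurve(
        values=np.cumsum(rec.sweeps.mean(axis=0)), protocol=rec.protocol
    )


def _auto_window(n: int) -> tuple[int, int]:
    # second half of the train: stimuli ceil(n/2)+1 .. n
    return (math.ceil(n / 2) + 1, n)


def fit_replenishment(
    curve: CumulativeCurve,
    window: tuple[int, int] | str = "auto",
    quantal_pA: float = 42.4,
) -> ReplenishmentFit:
    """Ordinary least squares on the late segment of the cumulative curve.

    ``window`` is a 1-based inclusive stimulus range; ``"auto"`` uses the
    second half of the train.  A fit with r^2 < 0.9 under the auto window
    raises a warning (steady state may not be reached) but is still returned.
    """
    n = curve.values.size
    auto = isinstance(window, str)
    if auto:
        if window != "auto":
            raise ValidationError(f"unknown window mode {window!r}")
        window = _auto_window(n)
    lo, hi = window
    if not (1 <= lo <= hi <= n):
        raise ValidationError("window must lie within the train")
    if hi - lo + 1 < 5:
        raise ValidationError("fit window must span at least 5 stimuli")
    if quantal_pA <= 0:
        raise ValidationError("quantal_pA must be > 0")
    x = np.arange(lo, hi + 1, dtype=float)
    y = curve.values[lo - 1: hi]
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    if auto and r2 < 0.9:
        warnings.warn(
            f"auto-window fit has r^2 = {r2:.3f} < 0.9; "
            "steady state may not be reached"
        )
    slope = float(res.slope)
    rate = slope / quantal_pA
    return ReplenishmentFit(
        slope_pA_per_stim=slope,
        intercept_pA=float(res.intercept),
        window=(lo, hi),
        r_squared=r2,
        quantal_pA=quantal_pA,
        rate_sv_per_isi=rate,
        rate_sv_per_s=rate * curve.protocol.frequency_hz,
    )


def replenishment_per_neuron(
    recs: Iterable[Recording],
    window: tuple[int, int] | str = "auto",
    quantal_pA: float = 42.4,
) -> ReplenishmentGroup:
    """One replenishment fit per neuron plus the group mean and SEM.

    Neurons whose fit fails are excluded with a warning; if all fail a
    :class:`ValidationError` is raised.
    """
    fits: list[ReplenishmentFit] = []
    recs = list(recs)
    if not recs:
        raise ValidationError("need at least one neuron")
    for idx, rec in enumerate(recs):
        try:
            fits.append(
                fit_replenishment(
                    cumulative_amplitude(rec), window=window,
                    quantal_pA=quantal_pA,
                )
            )
        except ValidationError as exc:
            warnings.warn(f"neuron {idx} excluded: {exc}")
    if not fits:
        raise ValidationError("no neuron produced a valid fit")
    rates = np.array([f.rate_sv_per_isi for f in fits])
    sem = (
        float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
    )
    return ReplenishmentGroup(
        fits=fits,
        mean_rate_sv_per_isi=float(rates.mean()),
        sem_rate_sv_per_isi=sem,
    )
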