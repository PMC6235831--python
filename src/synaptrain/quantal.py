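"""Quantal analysis of multi-release-site transmission.

Under strong partial Ca2+-channel block (e.g. 32 uM Cd2+) release is so sparse
that almost every success is the release of a single vesicle.  For a bouton
with ``N`` equivalent release sites, the per-stimulus total release
probability ``p_tot`` (one minus the failure rate) decomposes into single-site
events and concomitant two-site events (three or more sites are negligible at
this rate):

    p_tot = N * P(s) + C(N, 2) * P(s + s),        P(s + s) = P(s)**2

which gives the quadratic in the per-site probability ``x = P(s)``:

    C(N, 2) * x**2 + N * x - p_tot = 0.

The positive root is the per-site release probability; the *bi-quantal
contamination* is the fraction of successes that are actually two-site
events,

    contamination = C(N, 2) * P(s+s) / (N * P(s)) = (N - 1) * P(s) / 2.

Two evaluation modes are provided.  ``solve_release_quadratic`` carries exact
algebra.  ``rounded_contamination`` reproduces the printed-arithmetic
convention in which the positive root is first rounded to two significant
figures and the two-site probability is then recovered by back-substitution,
``P(s+s) = (p_tot - N*x) / C(N, 2)``; the two modes disagree slightly (for
``p_tot = 0.12, N = 20``: 5.26% rounded vs 5.41% exact) and the exact mode is
the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptySampleError, ValidationError
from .io import FailureMask, Recording

__all__ = [
    "MultisiteModel",
    "QuantalModelResult",
    "QuantalStats",
    "solve_release_quadratic",
    "rounded_contamination",
    "quantal_stats",
]


@dataclass(frozen=True)
class MultisiteModel:
    """Release-site bookkeeping for the quadratic model."""

    n_sites: int
    p_tot: float

    def __post_init__(self) -> None:
        if int(self.n_sites) != self.n_sites or self.n_sites < 2:
            raise ValidationError("n_sites must be an integer >= 2")
        object.__setattr__(self, "n_sites", int(self.n_sites))
        if not 0.0 <= self.p_tot < 1.0:
            raise ValidationError("p_tot must lie in [0, 1)")

    @property
    def pair_count(self) -> int:
        """Number of unordered site pairs, C(N, 2)."""
        return self.n_sites * (self.n_sites - 1) // 2


@dataclass(frozen=True)
class QuantalModelResult:
    """Solution of the multi-site quadratic.

    Attributes
    ----------
    p_site
        Per-site release probability (positive root).
    p_site_negative_root
        The rejected negative root, kept for reporting.
    p_pair
        Two-site release probability ``P(s+s)``.
    contamination
        Ratio of two-site to one-site release events (dimensionless;
        multiply by 100 for %).
    mode
        ``"exact"`` or ``"rounded"`` (two-significant-figure convention).
    """

    n_sites: int
    p_tot: float
    p_site: float
    p_site_negative_root: float
    p_pair: float
    contamination: float
    mode: str


def _roots(p_tot: float, n_sites: int) -> tuple[float, float, int]:
    model = MultisiteModel(n_sites=n_sites, p_tot=p_tot)
    c, n = model.pair_count, model.n_sites
    disc = n * n + 4.0 * c * p_tot
    sq = math.sqrt(disc)
    pos = (-n + sq) / (2.0 * c)
    neg = (-n - sq) / (2.0 * c)
    if not 0.0 <= pos <= 1.0:  # unreachable for p_tot in [0, 1)
        raise AssertionError("no root in [0, 1]")
    return pos, neg, c


def solve_release_quadratic(p_tot: float, n_sites: int) -> QuantalModelResult:
    """Solve the multi-site quadratic exactly.

    Parameters
    ----------
    p_tot
        Total release probability per stimulus, ``1 - failure_rate``,
        in ``[0, 1)``.
    n_sites
        Number of equivalent release sites (>= 2).
    """
    pos, neg, c = _roots(p_tot, n_sites)
    p_pair = pos * pos
    contamination = 0.0 if pos == 0.0 else (n_sites - 1) * pos / 2.0
    return QuantalModelResult(
        n_sites=n_sites, p_tot=p_tot, p_site=pos, p_site_negative_root=neg,
        p_pair=p_pair, contamination=contamination, mode="exact",
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def rounded_contamination(p_tot: float, n_sites: int) -> QuantalModelResult:
    """Solve the quadratic under the two-significant-figure convention.

    The positive root is rounded to two significant figures before the
    two-site probability is recovered by back-substitution into the linear
    relation; the contamination ratio then uses the rounded root as well.
    For ``(0.12, 20)`` this yields ``P(s+s) = 3.16e-5`` and 5.26%.
    """
    pos, neg, c = _roots(p_tot, n_sites)
    if pos == 0.0:
        raise EmptySampleError(
            "contamination is undefined at zero release probability"
        )
    x = _round_sig(pos, 2)
    p_pair = (p_tot - n_sites * x) / c
    contamination = c * p_pair / (n_sites * x)
    return QuantalModelResult(
        n_sites=n_sites, p_tot=p_tot, p_site=x, p_site_negative_root=neg,
        p_pair=p_pair, contamination=contamination, mode="rounded",
    )


@dataclass
class QuantalStats:
    """Summary statistics over success (release-event) amplitudes."""

    mean_pA: float
    median_pA: float
    n_success: int
    n_failure: int
    ecdf_amplitudes_pA: np.ndarray
    ecdf_fractions: np.ndarray

    @property
    def failure_rate(self) -> float:
        return self.n_failure / (self.n_failure + self.n_success)


def quantal_stats(rec: Recording, mask: FailureMask) -> QuantalStats:
    """Mean, median and empirical CDF of success amplitudes.

    Failures are excluded: a quantal amplitude is the amplitude of a release
    event.  Raises :class:`EmptySampleError` when no entry is a success.
    """
    if mask.mask.shape != rec.sweeps.shape:
        raise ValidationError("mask shape must match the sweep matrix")
    successes = rec.sweeps[~mask.mask]
    if successes.size == 0:
        raise EmptySampleError("no success amplitudes to summarize")
    srt = np.sort(successes)
    frac = np.arange(1, srt.size + 1) / srt.size
    return QuantalStats(
        mean_pA=float(successes.mean()),
        median_pA=float(np.median(successes)),
        n_success=int(successes.size),
        n_failure=int(mask.mask.sum()),
        ecdf_amplitudes_pA=srt,
        ecdf_fractions=frac,
    )
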