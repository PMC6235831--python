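"""Frozen simulator presets for the three study conditions.

Three presets are provided:

``"Cd"``
    Quantal regime under partial Ca2+-channel block: facilitation and
    depletion disabled, per-vesicle release probability set analytically so
    that the failure rate over the 20 sites is 88%,
    ``p0 = 1 - 0.88**(1/20)``.
``"WT"``
    Facilitating synapse whose steady-state resupply during 20 Hz trains is
    13 vesicles per inter-stimulus interval (50 ms).
``"PSKO"``
    Same quantal parameters as WT (quantal amplitude is unchanged by the
    genotype) but weaker facilitation and slower replenishment: resupply
    target 7 vesicles per 50 ms, and spike-transmission fraction 0.45 at
    stimulus 15 of a 20 Hz train under the WT-frozen spike threshold.

Quantal amplitude distribution
------------------------------
The single-vesicle amplitude is gamma(k, theta).  Measured success
amplitudes in the quantal regime are a *mixture* over the number of vesicles
released (about 5% of successes are two-site events), so (k, theta) are
calibrated such that the mixture — binomial(20, p0_Cd) release counts
conditioned on >= 1 — has mean 42.4 pA and median 38.0 pA, the measured
success statistics.  This puts the single-vesicle mean at
``k * theta ~ 39.9 pA``.

Calibration-derived entries (marked CAL below) were obtained once with the
calibration routines in :mod:`synaptrain.simulate` and frozen; the routines
reproduce them from the targets at run time.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import yaml
from scipy import optimize, stats

from .exceptions import ConfigurationError
from .io import StimulusProtocol
from .simulate import SpikeModelParams, SynapseParams

__all__ = [
    "make_preset",
    "default_spike_model",
    "quantal_gamma_params",
    "success_mixture_weights",
    "preset_table",
    "preset_table_yaml",
    "cd_p0",
    "TRAIN_20HZ_100",
    "N_SITES",
    "CD_FAILURE_RATE",
    "QUANTAL_MEAN_PA",
    "QUANTAL_MEDIAN_PA",
    "WT_SV_PER_ISI",
    "PSKO_SV_PER_ISI",
    "WT_TRANSMISSION_AT_15",
    "PSKO_TRANSMISSION_AT_15",
]

# --- condition-defining constants (measured values the presets are pinned to)
N_SITES = 20                 # release sites per bouton (model assumption)
CD_FAILURE_RATE = 0.88       # failure rate in the quantal (Cd2+) regime
QUANTAL_MEAN_PA = 42.4       # mean measured success amplitude (pA)
QUANTAL_MEDIAN_PA = 38.0     # median measured success amplitude (pA)
WT_SV_PER_ISI = 13.0         # steady-state resupply, WT, 20 Hz (SV / 50 ms)
PSKO_SV_PER_ISI = 7.0        # steady-state resupply, PSKO, 20 Hz
WT_TRANSMISSION_AT_15 = 0.63   # spike fraction at stimulus 15, 20 Hz train
PSKO_TRANSMISSION_AT_15 = 0.45

# --- free design constants of the generator (see docs/methods.md)
POOL_SIZE = 300              # docked vesicles M (15 per site)
BASAL_P0 = 0.015             # basal per-vesicle release probability
FACIL_INCREMENT_WT = 1.0     # additive facilitation per stimulus, WT
FACIL_TAU_S = 0.4            # facilitation decay time constant (s)
NOISE_SD_PA = 3.5            # baseline recording noise SD (pA)

# --- postsynaptic spike stage (phenomenological)
SPIKE_TAU_M_S = 0.35         # integration time constant (s)
SPIKE_WEIGHT = 1.0           # pA -> membrane units
SPIKE_RESET = 0.0
SPIKE_V_NOISE_SD = 100.0     # membrane noise per stimulus (pA-equivalents)

# --- calibration-derived entries (CAL), frozen from one calibration run;
#     the calibrate_* routines reproduce them from the targets above
REFILL_RATE_WT = 1.28173828125    # CAL calibrate_refill(WT, 20 Hz, 13)
REFILL_RATE_PSKO = 0.67138671875  # CAL (inner loop of the joint PSKO fit)
FACIL_INCREMENT_PSKO = 0.484375   # CAL calibrate_facilitation_increment
SPIKE_THRESHOLD = 699.2787075930663  # CAL calibrate_spike_threshold(WT, (15, 0.63))

#: 100-stimulus 20 Hz train protocol used by the calibration targets.
TRAIN_20HZ_100 = StimulusProtocol(frequency_hz=20.0, n_stimuli=100, label="train20")


def cd_p0() -> float:
    """Per-vesicle release probability of the quantal regime.

    Analytic inversion of the failure rate over 20 independent sites:
    ``(1 - p0) ** 20 = 0.88``.
    """
    return 1.0 - CD_FAILURE_RATE ** (1.0 / N_SITES)


@lru_cache(maxsize=1)
def success_mixture_weights(max_count: int = 8) -> np.ndarray:
    """P(R = r | R >= 1) for the quantal-regime release count R, r = 1..max."""
    pmf = stats.binom.pmf(np.arange(max_count + 1), N_SITES, cd_p0())
    w = pmf[1:] / (1.0 - pmf[0])
    return w / w.sum()


@lru_cache(maxsize=1)
def quantal_gamma_params() -> tuple[float, float]:
    """Gamma (shape, scale) of the single-vesicle amplitude.

    Solved numerically so that the success-amplitude mixture over release
    counts has mean ``QUANTAL_MEAN_PA`` and median ``QUANTAL_MEDIAN_PA``.
    """
    w = success_mixture_weights()
    counts = np.arange(1, w.size + 1)
    mean_count = float((w * counts).sum())
    ktheta = QUANTAL_MEAN_PA / mean_count  # single-vesicle mean, fixed

    def mixture_median(k: float) -> float:
        theta = ktheta / k

        def cdf(x: float) -> float:
            return float(
                (w * stats.gamma.cdf(x, a=k * counts, scale=theta)).sum()
            )

        return optimize.brentq(lambda x: cdf(x) - 0.5, 1e-6, 20 * ktheta)

    k = optimize.brentq(
        lambda k_: mixture_median(k_) - QUANTAL_MEDIAN_PA, 0.3, 80.0
    )
    return float(k), float(ktheta / k)


def make_preset(name: str) -> SynapseParams:
    """Return the frozen parameter set for ``"WT"``, ``"PSKO"`` or ``"Cd"``."""
    key = name.strip().lower()
    k, theta = quantal_gamma_params()
    common = dict(
        n_sites=N_SITES,
        quantal_shape=k,
        quantal_scale=theta,
        noise_sd_pA=NOISE_SD_PA,
    )
    if key == "cd":
        # sparse-release regime: facilitation off, instant refill, one
        # releasable vesicle per site
        return SynapseParams(
            p0=cd_p0(), facil_increment=0.0, facil_tau_s=FACIL_TAU_S,
            pool_size=N_SITES, refill_rate=np.inf, label="Cd", **common,
        )
    if key == "wt":
        return SynapseParams(
            p0=BASAL_P0, facil_increment=FACIL_INCREMENT_WT,
            facil_tau_s=FACIL_TAU_S, pool_size=POOL_SIZE,
            refill_rate=REFILL_RATE_WT, label="WT", **common,
        )
    if key == "psko":
        return SynapseParams(
            p0=BASAL_P0, facil_increment=FACIL_INCREMENT_PSKO,
            facil_tau_s=FACIL_TAU_S, pool_size=POOL_SIZE,
            refill_rate=REFILL_RATE_PSKO, label="PSKO", **common,
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; expected 'WT', 'PSKO' or 'Cd'"
    )


def default_spike_model() -> SpikeModelParams:
    """Spike stage with the threshold frozen from the WT calibration."""
    return SpikeModelParams(
        tau_m_s=SPIKE_TAU_M_S, weight=SPIKE_WEIGHT,
        threshold=SPIKE_THRESHOLD, reset=SPIKE_RESET,
        v_noise_sd=SPIKE_V_NOISE_SD,
    )


def preset_table() -> dict:
    """Full preset table as plain built-ins (for inspection/export)."""
    table: dict = {"spike_model": {
        "tau_m_s": SPIKE_TAU_M_S, "weight": SPIKE_WEIGHT,
        "threshold": SPIKE_THRESHOLD, "reset": SPIKE_RESET,
        "v_noise_sd": SPIKE_V_NOISE_SD,
    }}
    for name in ("WT", "PSKO", "Cd"):
        p = make_preset(name)
        table[name] = {
            "n_sites": p.n_sites,
            "p0": p.p0,
            "facil_increment": p.facil_increment,
            "facil_tau_s": p.facil_tau_s,
            "pool_size": p.pool_size,
            "refill_rate": None if np.isinf(p.refill_rate) else p.refill_rate,
            "quantal_shape": p.quantal_shape,
            "quantal_scale": p.quantal_scale,
            "quantal_mean_pA": p.quantal_mean_pA,
            "noise_sd_pA": p.noise_sd_pA,
        }
    return table


def preset_table_yaml() -> str:
    """YAML rendering of :func:`preset_table` (``refill_rate: null`` = instant)."""
    return yaml.safe_dump(preset_table(), sort_keys=False)
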