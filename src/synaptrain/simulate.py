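"""Stochastic multi-release-site synapse simulator.

The generator emulates evoked-EPSC experiments at a large facilitating bouton
(hippocampal mossy-fiber type) as an event-driven model evaluated only at
stimulus times:

* A pool of up to ``M`` docked vesicles (``pool_size``), starting full.
* At stimulus ``i`` each docked vesicle releases independently with
  probability ``min(1, p0 * F_i)`` where the facilitation factor

      F_i = 1 + a * sum_{j < i} exp(-(t_i - t_j) / tau_F)

  grows with preceding stimuli and decays with time constant
  ``facil_tau_s`` (a phenomenological residual-Ca2+ / Ca2+-sensor variable).
* Between stimuli every empty docking slot refills independently with
  probability ``1 - exp(-r * dt)`` (``refill_rate`` r per second).
* Each released vesicle contributes an i.i.d. gamma(k, theta) amplitude;
  Gaussian baseline noise (``noise_sd_pA``) is added to the measured sweep
  amplitude, which is clipped at zero because amplitudes are magnitudes.
* A postsynaptic stage converts amplitude trains into spike trains with a
  leaky integrator: V <- V * exp(-dt/tau_m) + weight * A, a spike is emitted
  when V crosses ``threshold`` and V is then reset.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import CalibrationError, ValidationError
from .io import FailureMask, Recording, StimulusProtocol

__all__ = [
    "SynapseParams",
    "SpikeModelParams",
    "SimResult",
    "simulate_train",
    "simulate_quantal_condition",
    "simulate_spike_response",
    "failure_mask_from_releases",
    "calibrate_refill",
    "calibrate_spike_threshold",
    "calibrate_facilitation_increment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynapseParams:
    """Parameterization of the release model.

    Parameters
    ----------
    n_sites
        Number of release sites (active zones) of the bouton.
    p0
        Basal per-vesicle release probability in [0, 1].
    facil_increment
        Additive facilitation ``a`` contributed by each preceding stimulus.
    facil_tau_s
        Facilitation decay time constant (s).
    pool_size
        Maximum number of docked vesicles ``M`` (>= n_sites).
    refill_rate
        Per-empty-slot refill rate (1/s); ``numpy.inf`` means instant refill.
    quantal_shape, quantal_scale
        Gamma shape/scale of the single-vesicle EPSC amplitude (pA).
    noise_sd_pA
        Baseline recording noise SD added to measured amplitudes (pA).
    label
        Free-text tag (preset name).
    """

    n_sites: int
    p0: float
    facil_increment: float
    facil_tau_s: float
    pool_size: int
    refill_rate: float
    quantal_shape: float
    quantal_scale: float
    noise_sd_pA: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValidationError("p0 must lie in [0, 1]")
        if self.facil_increment < 0:
            raise ValidationError("facil_increment must be >= 0")
        if not self.facil_tau_s > 0:
            raise ValidationError("facil_tau_s must be > 0")
        if self.pool_size < max(1, self.n_sites):
            raise ValidationError("pool_size must be >= n_sites (and >= 1)")
        if self.refill_rate < 0:
            raise ValidationError("refill_rate must be >= 0")
        if not (self.quantal_shape > 0 and self.quantal_scale > 0):
            raise ValidationError("gamma quantal parameters must be > 0")
        if self.noise_sd_pA < 0:
            raise ValidationError("noise_sd_pA must be >= 0")

    @property
    def quantal_mean_pA(self) -> float:
        """Mean single-vesicle amplitude, shape * scale (pA)."""
        return self.quantal_shape * self.quantal_scale


@dataclass(frozen=True)
class SpikeModelParams:
    """Leaky-integrator postsynaptic spike stage.

    ``tau_m_s`` is the integration time constant; ``weight`` converts pA into
    membrane units; a spike is emitted when V >= ``threshold`` and V is set to
    ``reset`` afterwards.  ``v_noise_sd`` adds an independent Gaussian
    perturbation to V at every stimulus, standing in for the background
    synaptic bombardment that makes spike initiation graded rather than
    all-or-none in pyramidal cells.
    """

    tau_m_s: float
    weight: float
    threshold: float
    reset: float = 0.0
    v_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_m_s > 0:
            raise ValidationError("tau_m_s must be > 0")
        if not self.threshold > self.reset:
            raise ValidationError("threshold must exceed reset")
        if self.v_noise_sd < 0:
            raise ValidationError("v_noise_sd must be >= 0")


@dataclass
class SimResult:
    """Output of :func:`simulate_train`.

    ``recording`` holds measured amplitudes (quantal sum plus noise, clipped
    at zero); ``vesicles_released`` and ``occupancy_pre`` are the ground-truth
    integer matrices (per sweep x stimulus).
    """

    recording: Recording
    vesicles_released: np.ndarray
    occupancy_pre: np.ndarray


def facilitation_factors(
    params: SynapseParams, protocol: StimulusProtocol
) -> np.ndarray:
    """Deterministic facilitation factor F_i at each stimulus (1-based order)."""
    n = protocol.n_stimuli
    decay = math.exp(-protocol.isi_s / params.facil_tau_s)
    f = np.empty(n)
    g = 0.0  # sum of exp(-(t_i - t_j)/tau) over j < i
    for i in range(n):
        f[i] = 1.0 + params.facil_increment * g
        g = (g + 1.0) * decay
    return f


def simulate_train(
    params: SynapseParams,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
) -> SimResult:
    """Simulate ``n_sweeps`` independent sweeps of a stimulus train.

    Each sweep starts with a full pool.  Release probabilities exceeding 1
    after facilitation are clamped (and logged), never an error.
    """
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    n_stim = protocol.n_stimuli
    m = params.pool_size
    f = facilitation_factors(params, protocol)
    p_rel = params.p0 * f
    if np.any(p_rel > 1.0):
        logger.warning(
            "release probability clamped to 1 at %d stimuli (max %.3f)",
            int(np.sum(p_rel > 1.0)), float(p_rel.max()),
        )
        p_rel = np.minimum(p_rel, 1.0)
    if np.isinf(params.refill_rate):
        p_refill = 1.0
    else:
        p_refill = 1.0 - math.exp(-params.refill_rate * protocol.isi_s)

    occ = np.full(n_sweeps, m, dtype=np.int64)
    released = np.empty((n_sweeps, n_stim), dtype=np.int64)
    occupancy_pre = np.empty((n_sweeps, n_stim), dtype=np.int64)
    amps = np.empty((n_sweeps, n_stim), dtype=float)
    k, theta = params.quantal_shape, params.quantal_scale
    for i in range(n_stim):
        occupancy_pre[:, i] = occ
        rel = rng.binomial(occ, p_rel[i])
        released[:, i] = rel
        # sum of `rel` iid gamma(k, theta) draws == gamma(k * rel, theta)
        draw = rng.gamma(np.where(rel > 0, k * rel, 1.0), theta)
        amps[:, i] = np.where(rel > 0, draw, 0.0)
        occ = occ - rel
        if i < n_stim - 1 and p_refill > 0:
            occ = occ + rng.binomial(m - occ, p_refill)
    if params.noise_sd_pA > 0:
        amps = amps + rng.normal(0.0, params.noise_sd_pA, size=amps.shape)
    amps = np.clip(amps, 0.0, None)
    rec = Recording(
        amps, protocol,
        condition_label=params.label, noise_sd_pA=params.noise_sd_pA,
    )
    return SimResult(
        recording=rec, vesicles_released=released, occupancy_pre=occupancy_pre
    )


def simulate_quantal_condition(
    params: SynapseParams, n_trials: int, seed: int, *, frequency_hz: float = 1.0
) -> SimResult:
    """Simulate single-stimulus sweeps in the quantal (sparse-release) regime.

    Used to emulate recordings under partial Ca2+-channel block, where the
    failure rate is high and successes are almost exclusively single-vesicle
    events.  Requires a quantal-regime parameterization (facilitation off).
    The measured sweep table is available as ``result.recording``.
    """
    if params.facil_increment != 0.0:
        raise ValidationError(
            "quantal-condition simulation requires facilitation disabled "
            "(facil_increment == 0)"
        )
    protocol = StimulusProtocol(
        frequency_hz=frequency_hz, n_stimuli=1, label="quantal"
    )
    return simulate_train(params, protocol, n_sweeps=n_trials, seed=seed)


def failure_mask_from_releases(sim: SimResult) -> FailureMask:
    """Ground-truth failure mask: failure = zero vesicles released."""
    return FailureMask(mask=sim.vesicles_released == 0, threshold_pA=0.0)


def simulate_spike_response(
    sim: SimResult, spk: SpikeModelParams, *, seed: int = 0
) -> np.ndarray:
    """Run the leaky-integrator spike stage over a simulated recording.

    Returns a boolean spike matrix congruent with the sweep matrix.  The
    stage is deterministic given the recording when ``v_noise_sd == 0``;
    otherwise the membrane noise is reproducible from ``seed``.
    """
    amps = sim.recording.sweeps
    if amps.shape[0] < 1:
        raise ValidationError("need at least one sweep")
    noise = _membrane_noise(amps.shape, spk.v_noise_sd, seed)
    decay = math.exp(-sim.recording.protocol.isi_s / spk.tau_m_s)
    n_sweeps, n_stim = amps.shape
    spikes = np.zeros((n_sweeps, n_stim), dtype=bool)
    v = np.zeros(n_sweeps)
    for i in range(n_stim):
        v = v * decay + spk.weight * amps[:, i] + noise[:, i]
        fired = v >= spk.threshold
        spikes[:, i] = fired
        v[fired] = spk.reset
    return spikes


def _membrane_noise(
    shape: tuple[int, int], sd: float, seed: int
) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    return np.random.default_rng(seed).normal(0.0, sd, size=shape)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _steady_release(
    params: SynapseParams,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
    n_stimuli: int,
) -> float:
    """Mean vesicles released per stimulus over the last half of a train."""
    proto = StimulusProtocol(
        frequency_hz=protocol.frequency_hz,
        n_stimuli=n_stimuli,
        inter_sweep_interval_s=protocol.inter_sweep_interval_s,
        label=protocol.label,
    )
    sim = simulate_train(params, proto, n_sweeps=n_sweeps, seed=seed)
    half = n_stimuli - n_stimuli // 2
    return float(sim.vesicles_released[:, half:].mean())


def calibrate_refill(
    params: SynapseParams,
    protocol: StimulusProtocol,
    target_sv_per_isi: float,
    *,
    n_sweeps: int = 64,
    n_stimuli: int = 100,
    tol: float = 0.02,
    seed: int = 0,
    r_max: float = 500.0,
    max_iter: int = 60,
) -> float:
    """Find the refill rate whose steady-state release matches a target.

    Bisection on ``refill_rate`` until the mean number of vesicles released
    per stimulus over the last half of an ``n_stimuli``-stimulus train (at the
    protocol's frequency) matches ``target_sv_per_isi`` within relative
    tolerance ``tol``.  The same seed schedule is reused at every bisection
    step (common random numbers), making the result deterministic.
    """
    if target_sv_per_isi < 0:
        raise ValidationError("target must be >= 0")
    if target_sv_per_isi == 0:
        return 0.0
    if target_sv_per_isi > params.pool_size:
        raise CalibrationError(
            "target exceeds the docked pool and is unattainable",
            bracket=(0.0, r_max),
        )

    def response(r: float) -> float:
        p = dataclasses.replace(params, refill_rate=r)
        return _steady_release(p, protocol, n_sweeps, seed, n_stimuli)

    lo, hi = 0.0, r_max
    resp_hi = response(hi)
    if resp_hi < target_sv_per_isi * (1.0 - tol):
        raise CalibrationError(
            f"target {target_sv_per_isi} SV/ISI unattainable: response at "
            f"refill_rate={hi} is {resp_hi:.3f}",
            bracket=(lo, hi),
        )
    resp_lo = response(lo)
    if resp_lo > target_sv_per_isi * (1.0 + tol):
        raise CalibrationError(
            f"target {target_sv_per_isi} SV/ISI below zero-refill response "
            f"{resp_lo:.3f}",
            bracket=(lo, hi),
        )
    r = 0.5 * (lo + hi)
    for _ in range(max_iter):
        r = 0.5 * (lo + hi)
        resp = response(r)
        if abs(resp - target_sv_per_isi) <= tol * target_sv_per_isi:
            return r
        if resp < target_sv_per_isi:
            lo = r
        else:
            hi = r
    return r


def _transmission_fraction(
    amps: np.ndarray, noise: np.ndarray, decay: float, weight: float,
    threshold: float, reset: float, index0: int,
) -> float:
    """Fraction of sweeps spiking at stimulus ``index0`` (0-based)."""
    v = np.zeros(amps.shape[0])
    frac = 0.0
    for i in range(index0 + 1):
        v = v * decay + weight * amps[:, i] + noise[:, i]
        fired = v >= threshold
        if i == index0:
            frac = float(fired.mean())
        v[fired] = reset
    return frac


def calibrate_spike_threshold(
    params: SynapseParams,
    spk: SpikeModelParams,
    protocol: StimulusProtocol,
    target_fraction_at_k: tuple[int, float],
    *,
    n_sweeps: int = 2048,
    tol: float = 0.02,
    seed: int = 0,
    max_iter: int = 80,
) -> float:
    """Find the spike threshold reproducing a target transmission fraction.

    ``target_fraction_at_k = (k, fraction)`` asks for the per-stimulus spike
    probability at (1-based) stimulus ``k`` of the protocol's train.  A single
    set of ``n_sweeps`` amplitude sweeps is simulated once and the threshold
    is bisected on it (the fraction is non-increasing in the threshold).
    """
    k_index, target = target_fraction_at_k
    if not 0.0 < target < 1.0:
        raise ValidationError("target fraction must lie in (0, 1)")
    if not 1 <= k_index <= protocol.n_stimuli:
        raise ValidationError("stimulus index outside the train")
    sim = simulate_train(params, protocol, n_sweeps=n_sweeps, seed=seed)
    amps = sim.recording.sweeps
    noise = _membrane_noise(amps.shape, spk.v_noise_sd, seed + 1)
    decay = math.exp(-protocol.isi_s / spk.tau_m_s)
    i0 = k_index - 1

    def frac(th: float) -> float:
        return _transmission_fraction(
            amps, noise, decay, spk.weight, th, spk.reset, i0
        )

    lo = max(spk.reset, 0.0) + 1e-9
    hi = float(spk.weight * amps.max() / (1.0 - decay) + 1.0)
    f_lo, f_hi = frac(lo), frac(hi)
    if not (f_lo >= target >= f_hi):
        raise CalibrationError(
            f"target {target} outside attainable range [{f_hi:.3f}, {f_lo:.3f}]",
            bracket=(lo, hi),
        )
    th = 0.5 * (lo + hi)
    for _ in range(max_iter):
        th = 0.5 * (lo + hi)
        f = frac(th)
        if abs(f - target) <= tol:
            return th
        if f > target:
            lo = th
        else:
            hi = th
    return th


def calibrate_facilitation_increment(
    params: SynapseParams,
    spk: SpikeModelParams,
    protocol: StimulusProtocol,
    target_fraction_at_k: tuple[int, float],
    refill_target_sv_per_isi: float,
    refill_protocol: StimulusProtocol | None = None,
    *,
    bounds: tuple[float, float] = (0.05, 2.0),
    n_sweeps: int = 2048,
    tol: float = 0.01,
    seed: int = 0,
    max_iter: int = 30,
) -> tuple[float, float]:
    """Jointly set facilitation increment and refill rate of a variant preset.

    Outer bisection on the facilitation increment ``a`` so that, with the
    refill rate re-calibrated (inner loop) to ``refill_target_sv_per_isi`` at
    each step, the simulated spike-transmission fraction at stimulus ``k``
    matches the target under the *given, frozen* spike model.  Returns the
    pair ``(a, refill_rate)``.

    The response is increasing in ``a`` (larger facilitation, larger
    mid-train amplitudes, more spikes).
    """
    k_index, target = target_fraction_at_k
    if refill_protocol is None:
        refill_protocol = protocol
    decay = math.exp(-protocol.isi_s / spk.tau_m_s)
    i0 = k_index - 1

    def response(a: float) -> tuple[float, float]:
        p = dataclasses.replace(params, facil_increment=a)
        r = calibrate_refill(
            p, refill_protocol, refill_target_sv_per_isi, seed=seed
        )
        p = dataclasses.replace(p, refill_rate=r)
        sim = simulate_train(p, protocol, n_sweeps=n_sweeps, seed=seed + 1)
        amps = sim.recording.sweeps
        noise = _membrane_noise(amps.shape, spk.v_noise_sd, seed + 2)
        f = _transmission_fraction(
            amps, noise, decay, spk.weight, spk.threshold, spk.reset, i0,
        )
        return f, r

    lo, hi = bounds
    f_lo, _ = response(lo)
    f_hi, r_hi = response(hi)
    if not (f_lo <= target <= f_hi):
        raise CalibrationError(
            f"target {target} outside attainable range [{f_lo:.3f}, {f_hi:.3f}]"
            " for the facilitation-increment bracket",
            bracket=bounds,
        )
    a, r = hi, r_hi
    for _ in range(max_iter):
        a = 0.5 * (lo + hi)
        f, r = response(a)
        if abs(f - target) <= tol:
            return a, r
        if f < target:
            lo = a
        else:
            hi = a
    return a, r
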