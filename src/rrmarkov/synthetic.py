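"""Synthetic RR and EKG generators with known ground truth.

Three generators make the whole pipeline testable without any external
recordings:

* a hidden two-state Markov chain over {A, N} whose emissions are RR
  durations drawn inside the reference band (state N) or strictly
  outside it (state A), so classifying the emitted series recovers the
  hidden states exactly;
* a respiratory-sinus-arrhythmia-like series: a sinusoid at a breathing
  frequency riding on a mean RR, plus Gaussian noise — a realistic
  fixture shape, not a physiological cardiac model;
* a pulse-train EKG: unit-amplitude triangular pulses at the cumulative
  beat times, for exercising the peak detector against planted truth.

Everything is seeded and bit-reproducible: the same config always
produces the same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .io import EKGSignal, PeakIndexList, RRSeries, RRSource
from .states import A, N, AlphaBand, StateLabel, StateSequence

__all__ = [
    "MarkovEmissionConfig",
    "RSASignalConfig",
    "simulate_markov_rr",
    "simulate_rsa_rr",
    "simulate_ekg_pulsetrain",
]


@dataclass(eq=False)
class MarkovEmissionConfig:
    """Configuration of the hidden two-state chain and its RR emissions.

    ``p_true`` is the 2x2 row-stochastic truth with rows/columns ordered
    (A, N).  State N emits uniformly inside the band; state A emits
    uniformly in a strip of width ``out_of_band_width_ms`` above the
    band (``"above"``), below it (``"below"``), or on either side with
    equal probability (``"mixed"``).  Optional Gaussian jitter is added
    and then clipped so the emission stays on the correct side of the
    band edge (and above 1 ms), preserving label recoverability.
    """

    p_true: np.ndarray
    band: AlphaBand
    n_intervals: int
    out_of_band_mode: str = "above"
    emission_jitter_ms: float = 0.0
    seed: int = 0
    out_of_band_width_ms: float = 200.0
    start_state: Optional[StateLabel] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_true, dtype=float)
        if p.shape != (2, 2) or np.any(p < 0) or np.any(p > 1):
            raise ValidationError("p_true must be a 2x2 matrix of probabilities")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("rows of p_true must sum to 1")
        self.p_true = p
        if self.n_intervals < 2:
            raise ValidationError("n_intervals must be at least 2")
        if self.out_of_band_mode not in ("above", "below", "mixed"):
            raise ValidationError(
                f"unknown out_of_band_mode {self.out_of_band_mode!r}"
            )
        if self.emission_jitter_ms < 0:
            raise ValidationError("emission_jitter_ms must be non-negative")
        if self.out_of_band_width_ms <= 0:
            raise ValidationError("out_of_band_width_ms must be positive")


@dataclass(eq=False)
class RSASignalConfig:
    """Sinusoidally modulated RR series parameters.

    Defaults describe a resting adult: mean RR 900 ms, modulation depth
    80 ms, breathing at 0.25 Hz (15 breaths/min), 10 ms beat-to-beat
    noise.  The constraint mean > amplitude + 3*noise keeps emissions
    positive with overwhelming probability; anything below 1 ms is
    hard-clipped.
    """

    mean_rr_ms: float = 900.0
    modulation_amplitude_ms: float = 80.0
    respiratory_freq_hz: float = 0.25
    noise_sd_ms: float = 10.0
    n_intervals: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.respiratory_freq_hz <= 0:
            raise ValidationError("respiratory_freq_hz must be positive")
        if self.modulation_amplitude_ms < 0 or self.noise_sd_ms < 0:
            raise ValidationError("amplitude and noise SD must be non-negative")
        if self.n_intervals < 1:
            raise ValidationError("n_intervals must be at least 1")
        if not self.mean_rr_ms > self.modulation_amplitude_ms + 3 * self.noise_sd_ms:
            raise ValidationError(
                "mean_rr_ms must exceed modulation_amplitude_ms + 3*noise_sd_ms"
            )


def _stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary (pi_A, pi_N) of a 2x2 chain; uniform if reducible."""
    p_an, p_na = p[0, 1], p[1, 0]
    if p_an + p_na == 0:  # identity chain: any distribution is stationary
        return np.array([0.5, 0.5])
    return np.array([p_na / (p_an + p_na), p_an / (p_an + p_na)])


def simulate_markov_rr(cfg: MarkovEmissionConfig) -> tuple[RRSeries, StateSequence]:
    """Simulate a hidden two-state chain and its RR emissions.

    The chain starts from the stationary distribution of ``p_true``
    (or from ``cfg.start_state`` when forced).  Returns the emitted RR
    series and the hidden state sequence; by construction, classifying
    the RR series against ``cfg.band`` reproduces the hidden states.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p_true
    n = cfg.n_intervals

    states = np.empty(n, dtype=np.uint8)
    if cfg.start_state is not None:
        states[0] = StateLabel(cfg.start_state)
    else:
        states[0] = N if rng.random() < _stationary_distribution(p)[1] else A
    # sequential chain: state k+1 depends on state k
    u = rng.random(n - 1)
    stay_a, stay_n = p[0, 0], p[1, 1]
    prev = int(states[0])
    for k in range(n - 1):
        if prev == A:
            prev = A if u[k] < stay_a else N
        else:
            prev = N if u[k] < stay_n else A
        states[k + 1] = prev

    lower, upper = cfg.band.lower, cfg.band.upper
    width = cfg.out_of_band_width_ms
    just_above = np.nextafter(upper, np.inf)
    just_below = np.nextafter(lower, -np.inf)
    below_low = max(1.0, lower - width)

    rr = np.empty(n, dtype=float)
    is_n = states == N
    rr[is_n] = rng.uniform(lower, upper, int(is_n.sum()))

    n_a = int((~is_n).sum())
    if cfg.out_of_band_mode == "above":
        above = np.ones(n_a, dtype=bool)
    elif cfg.out_of_band_mode == "below":
        above = np.zeros(n_a, dtype=bool)
    else:
        above = rng.random(n_a) < 0.5
    a_vals = np.empty(n_a)
    a_vals[above] = rng.uniform(just_above, upper + width, int(above.sum()))
    a_vals[~above] = rng.uniform(below_low, lower, int((~above).sum()))
    # uniform may hit the closed lower edge; nudge strictly below the band
    a_vals[~above] = np.minimum(a_vals[~above], just_below)
    rr[~is_n] = a_vals

    if cfg.emission_jitter_ms > 0:
        rr = rr + rng.normal(0.0, cfg.emission_jitter_ms, n)
        # re-clip each emission to the correct side of the band edges
        rr[is_n] = np.clip(rr[is_n], lower, upper)
        a_idx = np.flatnonzero(~is_n)
        hi = a_idx[above]
        lo = a_idx[~above]
        rr[hi] = np.clip(rr[hi], just_above, upper + width)
        rr[lo] = np.clip(rr[lo], below_low, just_below)
    rr = np.maximum(rr, 1.0)

    series = RRSeries(rr, subject_id=f"markov-seed{cfg.seed}", source=RRSource.SYNTHETIC)
    truth = StateSequence(states, subject_id=series.subject_id, band_used=cfg.band)
    return series, truth


def simulate_rsa_rr(cfg: RSASignalConfig) -> RRSeries:
    """Simulate a respiratory-modulated RR series.

    RR_k = mean + amplitude * sin(2*pi*f*t_k) + Gaussian noise, where
    t_k is the cumulative elapsed time in seconds (t_0 = 0 and
    t_{k+1} = t_k + RR_k / 1000).  Values are clipped at 1 ms.
    """
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(0.0, cfg.noise_sd_ms, cfg.n_intervals) if cfg.noise_sd_ms else None
    rr = np.empty(cfg.n_intervals)
    t = 0.0
    omega = 2.0 * np.pi * cfg.respiratory_freq_hz
    for k in range(cfg.n_intervals):
        value = cfg.mean_rr_ms + cfg.modulation_amplitude_ms * np.sin(omega * t)
        if noise is not None:
            value += noise[k]
        rr[k] = max(value, 1.0)
        t += rr[k] / 1000.0
    return RRSeries(rr, subject_id=f"rsa-seed{cfg.seed}", source=RRSource.SYNTHETIC)


def simulate_ekg_pulsetrain(
    rr: RRSeries,
    sampling_rate_hz: float = 100.0,
    pulse_width_ms: float = 80.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[EKGSignal, PeakIndexList]:
    """Render an RR series as a synthetic EKG-like pulse train.

    Unit-amplitude triangular pulses are centred at the cumulative beat
    times (a beat at time 0, then after each RR interval), rounded to
    the nearest sample; optional additive Gaussian noise.  Returns the
    signal together with the planted ground-truth peak indices.
    """
    if not sampling_rate_hz > 0:
        raise ValidationError("sampling_rate_hz must be positive")
    if pulse_width_ms <= 0:
        raise ValidationError("pulse_width_ms must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if len(rr) == 0:
        raise ValidationError("RR series must be non-empty")

    beat_times_ms = np.concatenate([[0.0], np.cumsum(rr.intervals)])
    peak_idx = np.round(beat_times_ms * sampling_rate_hz / 1000.0).astype(np.int64)
    if np.any(np.diff(peak_idx) < 2):
        raise ValidationError(
            "sampling rate too low to resolve the shortest RR interval "
            "(peak spacing under 2 samples)"
        )

    half_w = max(1, int(round(pulse_width_ms / 2.0 * sampling_rate_hz / 1000.0)))
    n_samples = int(peak_idx[-1]) + half_w + 1
    signal = np.zeros(n_samples)
    for c in peak_idx:
        lo = max(0, c - half_w)
        hi = min(n_samples, c + half_w + 1)
        offsets = np.arange(lo, hi) - c
        tri = 1.0 - np.abs(offsets) / (half_w + 1)
        signal[lo:hi] = np.maximum(signal[lo:hi], tri)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, n_samples)
    return EKGSignal(signal, sampling_rate_hz), PeakIndexList(peak_idx)
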