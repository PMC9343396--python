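"""Forward simulation of single-channel optoacoustic pulse-train records.

Produces synthetic acquisition records with the structure of a real
raster-scanning optoacoustic system driven by multiplexed pulse trains:
per-pulse bipolar wavelets from each absorber (the primary signal), damped
electromagnetic-interference ringing at every laser trigger, delayed echo
replicas, white detector noise, and pulse-to-pulse energy / timing jitter.
Every stochastic draw is fixed by the noise model's seed.

The acoustic source model treats each optical pulse as an energy impulse:
the transducer's band-limited impulse response (a gaussian-windowed cosine
matched to the stated center frequency and -6 dB fractional bandwidth) is
what shapes the received wavelet.  Pulse widths of a few nanoseconds put
the first spectral node of the pulse envelope far above the detection band,
so the finite width is not modelled acoustically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, gausspulse

from .design import (
    InvalidParameterError,
    Medium,
    MultiplexScheme,
    SchemeKind,
    TransducerBand,
    _require,
)

__all__ = [
    "Absorber",
    "TransducerModel",
    "NoiseModel",
    "AcquisitionRecord",
    "build_excitation",
    "simulate_record",
    "simulate_sine_record",
    "make_bscan",
]

DEFAULT_SAMPLING_RATE = 200e6  # Hz, mirrors a 200 MS/s digitizer


@dataclass(frozen=True)
class Absorber:
    """A point/line absorber on (or off) the acoustic axis.

    ``per_wavelength_amplitude`` holds one absorption weight per wavelength
    in volts per joule of pulse energy (detector voltage produced at the
    wavelet peak by a unit-energy pulse).  An optional delayed echo of the
    primary wavelet models reflections off interfaces or the acoustic lens.
    """

    depth: float                                   # m, along the acoustic axis
    per_wavelength_amplitude: tuple[float, ...]    # V/J, one per wavelength
    lateral_position: float = 0.0                  # m, for B-scans
    reflection_delay: float | None = None          # s after the primary arrival
    reflection_gain: float = 0.0                   # in [0, 1)

    def __post_init__(self) -> None:
        _require(self.depth >= 0, "depth must be >= 0")
        _require(all(a >= 0 for a in self.per_wavelength_amplitude),
                 "absorption weights must be >= 0")
        _require(0 <= self.reflection_gain < 1, "reflection_gain must be in [0, 1)")
        if self.reflection_delay is not None:
            _require(self.reflection_delay > 0, "reflection_delay must be > 0")


@dataclass(frozen=True)
class TransducerModel:
    """Focused detector: band, impulse-response kind, focus and acceptance."""

    band: TransducerBand
    impulse_response_kind: str = "gaussian_bandpass"
    focal_length: float = 3e-3            # m
    acceptance_half_angle: float = math.radians(30.0)  # rad, from 0.5 NA
    user_kernel: np.ndarray | None = None  # used when kind == "user_supplied"

    def __post_init__(self) -> None:
        _require(0 < self.acceptance_half_angle < math.pi / 2,
                 "acceptance_half_angle must lie in (0, pi/2)")
        _require(self.impulse_response_kind in ("gaussian_bandpass", "user_supplied"),
                 "unknown impulse_response_kind")
        if self.impulse_response_kind == "user_supplied":
            _require(self.user_kernel is not None and len(self.user_kernel) % 2 == 1,
                     "user_supplied kernel must be an odd-length array")

    @property
    def _cutoff(self) -> float:
        """Half-width (s) beyond which the wavelet is negligible (-80 dB)."""
        return gausspulse("cutoff", fc=self.band.center,
                          bw=self.band.fractional_bandwidth, bwr=-6, tpr=-80)

    def wavelet(self, t, sampling_rate: float | None = None) -> np.ndarray:
        """Peak-normalized bipolar wavelet evaluated at times t (s, peak at 0).

        The gaussian_bandpass kind is analytic and can be sampled at
        arbitrary (sub-sample) instants; a user-supplied kernel is read off
        its own sample grid by linear interpolation.
        """
        t = np.asarray(t, dtype=float)
        if self.impulse_response_kind == "user_supplied":
            kern = np.asarray(self.user_kernel, dtype=float)
            half = (len(kern) - 1) // 2
            grid = (np.arange(len(kern)) - half) / sampling_rate
            return np.interp(t, grid, kern, left=0.0, right=0.0)
        return gausspulse(t, fc=self.band.center,
                          bw=self.band.fractional_bandwidth, bwr=-6)

    def impulse_response(self, sampling_rate: float) -> np.ndarray:
        """Odd-length, peak-normalized wavelet kernel on the sample grid."""
        if self.impulse_response_kind == "user_supplied":
            return np.asarray(self.user_kernel, dtype=float)
        k = max(1, int(math.ceil(self._cutoff * sampling_rate)))
        return self.wavelet(np.arange(-k, k + 1) / sampling_rate)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic record components; ``seed`` fixes every draw."""

    white_noise_std: float = 0.0        # V
    emi_amplitude: float = 0.0          # V, damped ring at each trigger
    emi_ring_frequency: float | None = None  # Hz, default: transducer center
    emi_decay: float = 100e-9           # s, 1/e decay of the ring
    energy_jitter_cv: float = 0.0       # relative pulse-energy spread
    timing_jitter_std: float = 0.0      # s
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.white_noise_std >= 0 and self.emi_amplitude >= 0
                 and self.emi_decay > 0 and self.energy_jitter_cv >= 0
                 and self.timing_jitter_std >= 0, "noise parameters must be >= 0")


@dataclass
class AcquisitionRecord:
    """One single-channel sampled voltage trace S_r(t) plus its provenance."""

    samples: np.ndarray
    sampling_rate: float
    scheme: MultiplexScheme
    trigger_times: list[np.ndarray]      # commanded pulse instants per laser
    pulse_energy_factors: list[np.ndarray] | None = None  # realized rel. energy
    pulse_timing_offsets: list[np.ndarray] | None = None  # realized jitter (s)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _trigger_times(train) -> np.ndarray:
    return train.start_offset + np.arange(train.n_pulses) / train.rep_rate


def _record_length(scheme: MultiplexScheme, sampling_rate: float) -> int:
    # longest train plus one reference period of tail for late arrivals
    end = max(tr.start_offset + tr.duration for tr in scheme.trains)
    end += 1.0 / scheme.ref_rep_rate
    return int(round(end * sampling_rate))


def _add_pulses(out: np.ndarray, times: np.ndarray, amplitudes: np.ndarray,
                sampling_rate: float, shape, t_pre: float, t_post: float) -> None:
    """Accumulate amp * shape(t_grid - t_event) for every event, in place.

    ``shape`` is an analytic waveform callable evaluated at exact sample
    instants, so off-grid event times introduce no interpolation loss;
    support is limited to [t_event - t_pre, t_event + t_post].
    """
    times = np.asarray(times, dtype=float)
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), times.shape)
    if times.size == 0:
        return
    n = len(out)
    length = int(math.ceil((t_pre + t_post) * sampling_rate)) + 2
    i0 = np.floor((times - t_pre) * sampling_rate).astype(int)
    idx = i0[:, None] + np.arange(length)[None, :]
    t_rel = idx / sampling_rate - times[:, None]
    vals = amps[:, None] * shape(t_rel)
    ok = (idx >= 0) & (idx < n)
    np.add.at(out, idx[ok], vals[ok])


def _emi_shape(noise: NoiseModel, transducer: TransducerModel):
    f_ring = noise.emi_ring_frequency or transducer.band.center
    amp, tau = noise.emi_amplitude, noise.emi_decay

    def shape(t):
        t = np.asarray(t, dtype=float)
        return np.where(t >= 0,
                        amp * np.exp(-np.clip(t, 0, None) / tau)
                        * np.sin(2 * np.pi * f_ring * t), 0.0)

    return shape


def _convolve_centered(series: np.ndarray, kernel: np.ndarray,
                       center: int) -> np.ndarray:
    full = fftconvolve(series, kernel)
    return full[center:center + len(series)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_excitation(scheme: MultiplexScheme, sampling_rate: float,
                     duration: float | None = None) -> np.ndarray:
    """Per-laser optical power series (W) of the commanded pulse trains.

    Rectangular pulses of width t_p and height E/t_p at the commanded
    instants; each train's total optical energy is N_p * pulse_energy.
    Requires at least 4 samples across a pulse so the rectangle is resolved.
    """
    for tr in scheme.trains:
        if tr.pulse_width * sampling_rate < 4.0:
            raise InvalidParameterError(
                f"pulse width {tr.pulse_width:g} s is undersampled at "
                f"{sampling_rate:g} S/s (need >= 4 samples per pulse)")
    if duration is None:
        n = _record_length(scheme, sampling_rate)
    else:
        n = int(round(duration * sampling_rate))
    out = np.zeros((scheme.n_wavelengths, n))
    for row, tr in zip(out, scheme.trains):
        height = (tr.pulse_energy / tr.pulse_width) if tr.pulse_energy > 0 else 1.0
        width = int(round(tr.pulse_width * sampling_rate))
        for k in range(tr.n_pulses):
            i0 = int(round((tr.start_offset + k / tr.rep_rate) * sampling_rate))
            if i0 >= n:
                break
            row[i0:min(i0 + width, n)] = height
    return out


def _simulate_events(scheme: MultiplexScheme,
                     events_per_laser: list[list[tuple[float, float]]],
                     transducer: TransducerModel, noise: NoiseModel,
                     sampling_rate: float, rng: np.random.Generator,
                     quantize_bits: int | None) -> AcquisitionRecord:
    """Shared engine: per-laser (delay, V/J weight) events -> sampled record."""
    if sampling_rate < 2.0 * transducer.band.f_high:
        raise InvalidParameterError(
            f"sampling rate {sampling_rate:g} violates Nyquist for band up to "
            f"{transducer.band.f_high:g} Hz")
    n = _record_length(scheme, sampling_rate)
    t_cut = (transducer._cutoff if transducer.impulse_response_kind ==
             "gaussian_bandpass"
             else (len(transducer.user_kernel) // 2) / sampling_rate)

    def wavelet_shape(t):
        return transducer.wavelet(t, sampling_rate)

    samples = np.zeros(n)
    trigger_times: list[np.ndarray] = []
    e_factors: list[np.ndarray] = []
    t_offsets: list[np.ndarray] = []
    for tr, events in zip(scheme.trains, events_per_laser):
        trig = _trigger_times(tr)
        trigger_times.append(trig)
        if noise.energy_jitter_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise.energy_jitter_cv ** 2))
            e = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=tr.n_pulses)
        else:
            e = np.ones(tr.n_pulses)
        dt = (rng.normal(0.0, noise.timing_jitter_std, size=tr.n_pulses)
              if noise.timing_jitter_std > 0 else np.zeros(tr.n_pulses))
        e_factors.append(e)
        t_offsets.append(dt)
        emission = trig + dt
        energy = tr.pulse_energy * e
        for delay, weight in events:
            _add_pulses(samples, emission + delay, weight * energy,
                        sampling_rate, wavelet_shape, t_cut, t_cut)

    if noise.emi_amplitude > 0:
        trig_all = np.concatenate(trigger_times)
        _add_pulses(samples, trig_all, np.ones_like(trig_all), sampling_rate,
                    _emi_shape(noise, transducer), 0.0, 10.0 * noise.emi_decay)
    if noise.white_noise_std > 0:
        samples = samples + rng.normal(0.0, noise.white_noise_std, n)
    if quantize_bits is not None:
        full_scale = np.max(np.abs(samples))
        if full_scale > 0:
            q = full_scale / (2 ** (quantize_bits - 1))
            samples = np.round(samples / q) * q
    return AcquisitionRecord(samples=samples, sampling_rate=sampling_rate,
                             scheme=scheme, trigger_times=trigger_times,
                             pulse_energy_factors=e_factors,
                             pulse_timing_offsets=t_offsets)


def _axial_events(scheme: MultiplexScheme, phantom: Sequence[Absorber],
                  medium: Medium) -> list[list[tuple[float, float]]]:
    events: list[list[tuple[float, float]]] = [[] for _ in scheme.trains]
    for ab in phantom:
        delay = ab.depth / medium.speed_of_sound
        for j in range(scheme.n_wavelengths):
            w = ab.per_wavelength_amplitude[j] if j < len(ab.per_wavelength_amplitude) else 0.0
            if w == 0.0:
                continue
            events[j].append((delay, w))
            if ab.reflection_delay is not None and ab.reflection_gain > 0:
                events[j].append((delay + ab.reflection_delay,
                                  w * ab.reflection_gain))
    return events


def simulate_record(scheme: MultiplexScheme, phantom: Sequence[Absorber],
                    transducer: TransducerModel, noise: NoiseModel,
                    medium: Medium = Medium(),
                    sampling_rate: float = DEFAULT_SAMPLING_RATE,
                    quantize_bits: int | None = None,
                    rng: np.random.Generator | None = None) -> AcquisitionRecord:
    """Simulate the single-channel record of an on-axis phantom.

    Each laser pulse contributes, per absorber, a band-limited bipolar
    wavelet delayed by depth/v_s, scaled by absorption weight x pulse energy
    (with multiplicative energy jitter and additive timing jitter), plus an
    optional delayed echo.  EMI rings at every trigger; white Gaussian noise
    is added last.  Deterministic for a given seed; an empty phantom yields
    a noise-only record.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    events = _axial_events(scheme, phantom, medium)
    return _simulate_events(scheme, events, transducer, noise, sampling_rate,
                            rng, quantize_bits)


def simulate_sine_record(modulation_freq: float, scheme: MultiplexScheme,
                         phantom: Sequence[Absorber],
                         transducer: TransducerModel, noise: NoiseModel,
                         medium: Medium = Medium(),
                         sampling_rate: float = DEFAULT_SAMPLING_RATE,
                         rng: np.random.Generator | None = None) -> AcquisitionRecord:
    """Sinusoidally modulated excitation with the pulse train's mean power.

    Models classical frequency-domain operation: optical power
    P(t) = P_mean * (1 - cos(2*pi*f*t)) with P_mean = pulse_energy * f_rep of
    the first train, sent through the same absorber/transducer/noise
    pipeline, so SNR comparisons against pulsed excitation are like for like.
    """
    band = transducer.band
    _require(band.f_low <= modulation_freq <= band.f_high,
             "modulation_freq must lie within the transducer band")
    if sampling_rate < 2.0 * band.f_high:
        raise InvalidParameterError("sampling rate violates Nyquist")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    tr = scheme.trains[0]
    p_mean = tr.pulse_energy * tr.rep_rate
    n = _record_length(scheme, sampling_rate)
    t = np.arange(n) / sampling_rate
    active = t < tr.duration
    power = p_mean * (1.0 - np.cos(2 * np.pi * modulation_freq * t)) * active
    kernel = transducer.impulse_response(sampling_rate)
    base = _convolve_centered(power / sampling_rate, kernel, len(kernel) // 2)

    samples = np.zeros(n)
    for ab in phantom:
        w = ab.per_wavelength_amplitude[0]
        if w == 0.0:
            continue
        delay = ab.depth / medium.speed_of_sound
        samples += w * np.interp(t - delay, t, base, left=0.0, right=0.0)
        if ab.reflection_delay is not None and ab.reflection_gain > 0:
            samples += (w * ab.reflection_gain *
                        np.interp(t - delay - ab.reflection_delay, t, base,
                                  left=0.0, right=0.0))
    if noise.white_noise_std > 0:
        samples = samples + rng.normal(0.0, noise.white_noise_std, n)
    trig = [np.array([tr.start_offset]) for tr in scheme.trains]
    return AcquisitionRecord(samples=samples, sampling_rate=sampling_rate,
                             scheme=scheme, trigger_times=trig)


def make_bscan(scheme: MultiplexScheme, phantom: Sequence[Absorber],
               scan_positions: Sequence[float], transducer: TransducerModel,
               noise: NoiseModel, medium: Medium = Medium(),
               sampling_rate: float = DEFAULT_SAMPLING_RATE) -> list[AcquisitionRecord]:
    """One record per lateral scan position of a focused-detector sweep.

    The wavelet delay uses the Euclidean distance between absorber and the
    detector position; an absorber contributes only while it sits inside the
    detector's acceptance cone (apex at the focus, axis vertical).  Each
    position draws its noise from an independent, reproducible substream of
    the seed.
    """
    positions = np.asarray(scan_positions, dtype=float)
    _require(positions.size >= 1, "scan_positions must be non-empty")
    _require(np.all(np.diff(positions) > 0), "scan_positions must be strictly increasing")
    tan_a = math.tan(transducer.acceptance_half_angle)
    records = []
    for i, x in enumerate(positions):
        events: list[list[tuple[float, float]]] = [[] for _ in scheme.trains]
        for ab in phantom:
            dx = ab.lateral_position - x
            if abs(dx) > tan_a * abs(ab.depth - transducer.focal_length):
                continue
            delay = math.hypot(dx, ab.depth) / medium.speed_of_sound
            for j in range(scheme.n_wavelengths):
                w = ab.per_wavelength_amplitude[j] if j < len(ab.per_wavelength_amplitude) else 0.0
                if w == 0.0:
                    continue
                events[j].append((delay, w))
                if ab.reflection_delay is not None and ab.reflection_gain > 0:
                    events[j].append((delay + ab.reflection_delay,
                                      w * ab.reflection_gain))
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, i]))
        records.append(_simulate_events(scheme, events, transducer, noise,
                                        sampling_rate, rng, None))
    return records
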