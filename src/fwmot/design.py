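"""Multiplexing design calculator for pulse-train optoacoustics.

Frequency-wavelength multiplexing (FWM) drives N laser diodes with pulse
trains at slightly offset repetition rates, ``f_rep,j = f_rep,1 + (j-1)*δf``,
so that each wavelength occupies its own harmonic comb in the Fourier domain
of a single-channel acoustic record.  This module holds the pure-arithmetic
design layer: depth-of-view, acquisition time, frequency resolution, the
in-band harmonic index range of the detecting ultrasound transducer, the
admissible window ``[δf_min, δf_max]`` for the repetition-rate offset, the
minimum pulse count that makes a scheme feasible, wavelength-capacity limits
for frequency- and time-multiplexed operation, exposure and SNR bookkeeping.

Feasibility questions are decided with exact rational arithmetic
(:class:`fractions.Fraction`) so that band-edge ties never flip on
floating-point rounding.  An exact brute-force comb-separation validator
(:func:`comb_separation_ok`) enumerates every in-band line of every laser
and is used to cross-check the closed-form bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SPEED_OF_SOUND",
    "MPE_PULSE_FLUENCE_J_CM2",
    "MPE_MEAN_IRRADIANCE_W_CM2",
    "InvalidParameterError",
    "EmptyHarmonicRangeError",
    "SchemeKind",
    "Medium",
    "TransducerBand",
    "PulseTrain",
    "MultiplexScheme",
    "HarmonicRange",
    "DeltaFBounds",
    "DesignLimits",
    "ExposureReport",
    "SNRReport",
    "depth_of_view",
    "acquisition_time",
    "frequency_resolution",
    "harmonic_indices",
    "delta_f_bounds",
    "max_wavelengths_fwm",
    "max_wavelengths_td",
    "min_pulses",
    "snr_db",
    "averaging_gain_db",
    "exposure",
    "scheme_tradeoffs",
    "design_limits",
    "comb_separation_ok",
    "brute_force_delta_f_feasible",
    "brute_force_max_wavelengths",
]

#: Soft-tissue speed of sound (m/s).  Not a free parameter of the method but
#: the value that makes DoV = v_s/f_rep come out at 7.5 mm for 200 kHz.
DEFAULT_SPEED_OF_SOUND = 1500.0

#: ANSI skin limits used for the compliance flag.
MPE_PULSE_FLUENCE_J_CM2 = 20e-3
MPE_MEAN_IRRADIANCE_W_CM2 = 18.0


class InvalidParameterError(ValueError):
    """A design parameter violates its precondition."""


class EmptyHarmonicRangeError(ValueError):
    """No harmonic of the repetition rate falls inside the detection band."""


def _frac(x) -> Fraction:
    """Exact rational view of a number (binary floats convert exactly)."""
    return x if isinstance(x, Fraction) else Fraction(x)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class SchemeKind(str, Enum):
    """How multiple wavelengths share the acquisition."""

    FWM = "fwm"                    # offset repetition rates, frequency-separated
    TD_INTERLEAVE = "td_interleave"  # same rate, time shift T/N (DoV / N)
    TD_SLOW = "td_slow"            # rate f/N, N_p/N pulses (SNR / sqrt(N))
    TD_LONG = "td_long"            # rate f/N, N_p pulses (t_acq * N)


@dataclass(frozen=True)
class Medium:
    """Acoustic propagation medium."""

    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND  # m/s

    def __post_init__(self) -> None:
        _require(self.speed_of_sound > 0, "speed_of_sound must be > 0")


@dataclass(frozen=True)
class TransducerBand:
    """Detection band [f_low, f_high] of the ultrasound transducer, in Hz."""

    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        _require(0 < self.f_low < self.f_high, "need 0 < f_low < f_high")

    @classmethod
    def from_center(cls, center: float, fractional_bandwidth: float) -> "TransducerBand":
        """Band from center frequency and fractional (relative) bandwidth."""
        _require(center > 0 and 0 < fractional_bandwidth < 2,
                 "center > 0 and 0 < fractional_bandwidth < 2 required")
        half = fractional_bandwidth / 2.0
        return cls(center * (1.0 - half), center * (1.0 + half))

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def fractional_bandwidth(self) -> float:
        return (self.f_high - self.f_low) / self.center


@dataclass(frozen=True)
class PulseTrain:
    """One wavelength's excitation: N_p pulses of width t_p at rate f_rep,j.

    ``start_offset`` (t_sh) delays the whole train; time-interleaved schemes
    use t_sh = j*T/N.  ``pulse_energy`` is the optical energy per pulse in J.
    """

    wavelength_id: int
    rep_rate: float            # Hz
    n_pulses: int
    pulse_width: float = 6.7e-9   # s
    pulse_energy: float = 0.0     # J
    start_offset: float = 0.0     # s, in [0, 1/rep_rate)
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        _require(self.wavelength_id >= 1, "wavelength_id must be >= 1")
        _require(self.rep_rate > 0, "rep_rate must be > 0")
        _require(self.n_pulses >= 1, "n_pulses must be >= 1")
        _require(self.pulse_energy >= 0, "pulse_energy must be >= 0")
        _require(0 < self.pulse_width < 1.0 / self.rep_rate,
                 "pulse_width must satisfy 0 < t_p < 1/rep_rate")
        _require(0 <= self.start_offset < 1.0 / self.rep_rate,
                 "start_offset must lie in [0, 1/rep_rate)")

    @property
    def period(self) -> float:
        return 1.0 / self.rep_rate

    @property
    def duration(self) -> float:
        """Time from the first to one period past the last pulse."""
        return self.n_pulses / self.rep_rate


@dataclass(frozen=True)
class MultiplexScheme:
    """An ordered set of pulse trains plus the multiplexing strategy."""

    trains: tuple[PulseTrain, ...]
    kind: SchemeKind
    delta_f: float = 0.0   # Hz; FWM repetition-rate offset between neighbours

    def __post_init__(self) -> None:
        _require(len(self.trains) >= 1, "scheme needs at least one train")
        f1 = self.trains[0].rep_rate
        if self.kind is SchemeKind.FWM and len(self.trains) > 1:
            _require(0 <= self.delta_f < f1, "need 0 <= delta_f < f_rep,1")
            for j, tr in enumerate(self.trains):
                expected = f1 + j * self.delta_f
                _require(abs(tr.rep_rate - expected) <= 1e-9 * f1,
                         f"FWM train {j} rate {tr.rep_rate} != f_rep,1 + {j}*delta_f")
        if self.kind is SchemeKind.TD_INTERLEAVE and len(self.trains) > 1:
            n = len(self.trains)
            for j, tr in enumerate(self.trains):
                _require(abs(tr.rep_rate - f1) <= 1e-9 * f1,
                         "TD interleave requires equal repetition rates")
                _require(abs(tr.start_offset - j / (n * f1)) <= 1e-9 / f1,
                         "TD interleave requires start offsets j*T/N")

    @property
    def n_wavelengths(self) -> int:
        return len(self.trains)

    @property
    def ref_rep_rate(self) -> float:
        return self.trains[0].rep_rate

    # -- factories ----------------------------------------------------------

    @staticmethod
    def _per_train(value, n, name) -> list:
        if np.isscalar(value):
            return [value] * n
        value = list(value)
        _require(len(value) == n, f"{name} must be scalar or length {n}")
        return value

    @classmethod
    def fwm(cls, ref_rep_rate: float, delta_f: float, n_pulses,
            pulse_widths=6.7e-9, pulse_energies=0.0, wavelengths_nm=None,
            n_wavelengths: int | None = None) -> "MultiplexScheme":
        """FWM scheme: rates f_rep,1 + (j-1)*δf, all trains starting at t=0."""
        if n_wavelengths is None:
            n_wavelengths = max(len(np.atleast_1d(n_pulses)),
                                len(np.atleast_1d(pulse_widths)),
                                len(np.atleast_1d(pulse_energies)))
        n = n_wavelengths
        np_ = cls._per_train(n_pulses, n, "n_pulses")
        tp = cls._per_train(pulse_widths, n, "pulse_widths")
        en = cls._per_train(pulse_energies, n, "pulse_energies")
        wl = cls._per_train(wavelengths_nm, n, "wavelengths_nm") if wavelengths_nm is not None else [None] * n
        trains = tuple(
            PulseTrain(wavelength_id=j + 1, rep_rate=ref_rep_rate + j * delta_f,
                       n_pulses=int(np_[j]), pulse_width=tp[j], pulse_energy=en[j],
                       wavelength_nm=wl[j])
            for j in range(n))
        return cls(trains, SchemeKind.FWM, delta_f=delta_f)

    @classmethod
    def td_interleaved(cls, rep_rate: float, n_wavelengths: int, n_pulses: int,
                       pulse_widths=6.7e-9, pulse_energies=0.0) -> "MultiplexScheme":
        """Same rate for all wavelengths, start offsets j*T/N (DoV shared N ways)."""
        n = n_wavelengths
        tp = cls._per_train(pulse_widths, n, "pulse_widths")
        en = cls._per_train(pulse_energies, n, "pulse_energies")
        trains = tuple(
            PulseTrain(wavelength_id=j + 1, rep_rate=rep_rate, n_pulses=n_pulses,
                       pulse_width=tp[j], pulse_energy=en[j],
                       start_offset=j / (n * rep_rate))
            for j in range(n))
        return cls(trains, SchemeKind.TD_INTERLEAVE)

    @classmethod
    def td_slow(cls, full_rep_rate: float, n_wavelengths: int, full_n_pulses: int,
                pulse_widths=6.7e-9, pulse_energies=0.0) -> "MultiplexScheme":
        """Rate f/N and N_p/N pulses per wavelength within the same t_acq."""
        n = n_wavelengths
        rate = full_rep_rate / n
        npul = max(1, full_n_pulses // n)
        tp = cls._per_train(pulse_widths, n, "pulse_widths")
        en = cls._per_train(pulse_energies, n, "pulse_energies")
        trains = tuple(
            PulseTrain(wavelength_id=j + 1, rep_rate=rate, n_pulses=npul,
                       pulse_width=tp[j], pulse_energy=en[j],
                       start_offset=j / (n * rate))
            for j in range(n))
        return cls(trains, SchemeKind.TD_SLOW)

    @classmethod
    def td_long(cls, full_rep_rate: float, n_wavelengths: int, n_pulses: int,
                pulse_widths=6.7e-9, pulse_energies=0.0) -> "MultiplexScheme":
        """Rate f/N with the full pulse count: acquisition time grows N-fold."""
        n = n_wavelengths
        rate = full_rep_rate / n
        tp = cls._per_train(pulse_widths, n, "pulse_widths")
        en = cls._per_train(pulse_energies, n, "pulse_energies")
        trains = tuple(
            PulseTrain(wavelength_id=j + 1, rep_rate=rate, n_pulses=n_pulses,
                       pulse_width=tp[j], pulse_energy=en[j],
                       start_offset=j / (n * rate))
            for j in range(n))
        return cls(trains, SchemeKind.TD_LONG)


@dataclass(frozen=True)
class HarmonicRange:
    """Inclusive harmonic index range [k_low, k_high] inside the band."""

    k_low: int
    k_high: int

    @property
    def empty(self) -> bool:
        return self.k_low > self.k_high

    @property
    def n_harmonics(self) -> int:
        return 0 if self.empty else self.k_high - self.k_low + 1

    def indices(self) -> np.ndarray:
        return np.arange(self.k_low, self.k_high + 1)


@dataclass(frozen=True)
class DeltaFBounds:
    """Admissible repetition-rate offset window for an FWM scheme."""

    delta_f_min: float
    delta_f_max: float
    feasible: bool

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.delta_f_min + self.delta_f_max)

    def contains(self, delta_f: float) -> bool:
        return self.feasible and self.delta_f_min <= delta_f <= self.delta_f_max


@dataclass(frozen=True)
class DesignLimits:
    """Derived design quantities for one operating point."""

    dov: float                # m
    t_acq: float              # s
    df: float                 # Hz
    k_low: int
    k_high: int
    n_harmonics: int
    delta_f_min: float | None
    delta_f_max: float | None
    n_p_min: int | None
    n_max_wavelengths: int
    feasible: bool


@dataclass(frozen=True)
class ExposureReport:
    """Sample exposure versus the two printed skin MPE limits."""

    fluence_per_pulse: float   # J/cm^2
    mean_irradiance: float     # W/cm^2
    mpe_pulse_limit: float = MPE_PULSE_FLUENCE_J_CM2
    mpe_mean_limit: float = MPE_MEAN_IRRADIANCE_W_CM2

    @property
    def compliant(self) -> bool:
        return (self.fluence_per_pulse < self.mpe_pulse_limit
                and self.mean_irradiance < self.mpe_mean_limit)


@dataclass(frozen=True)
class SNRReport:
    """Signal amplitude, noise floor standard deviation and their dB ratio."""

    signal_amplitude: float    # V
    noise_std: float           # V
    snr_db: float              # 10*log10(S/N)
    has_signal: bool = True


# ---------------------------------------------------------------------------
# elementary design operations
# ---------------------------------------------------------------------------

def depth_of_view(rep_rate: float, medium: Medium = Medium(),
                  n_shared: int = 1) -> float:
    """Maximum unambiguous imaging depth, DoV = v_s * T / n_shared (m).

    ``n_shared`` > 1 models time-interleaved wavelengths that split one
    period into N slots, reducing the per-wavelength depth-of-view N-fold.
    """
    _require(rep_rate > 0, "rep_rate must be > 0")
    _require(int(n_shared) == n_shared and n_shared >= 1, "n_shared must be int >= 1")
    return medium.speed_of_sound / rep_rate / n_shared


def acquisition_time(n_pulses: int, rep_rate: float) -> float:
    """Acquisition time of a pulse train, t_acq = N_p / f_rep (s)."""
    _require(int(n_pulses) == n_pulses and n_pulses >= 1, "n_pulses must be int >= 1")
    _require(rep_rate > 0, "rep_rate must be > 0")
    return n_pulses / rep_rate


def frequency_resolution(t_acq: float) -> float:
    """Frequency resolution of the record, df = 1/t_acq (Hz)."""
    _require(t_acq > 0, "t_acq must be > 0")
    return 1.0 / t_acq


def harmonic_indices(rep_rate: float, band: TransducerBand) -> HarmonicRange:
    """Smallest/largest harmonic k of ``rep_rate`` inside the band (inclusive).

    Band edges count as in-band.  Returns an empty :class:`HarmonicRange`
    (``k_low > k_high``) when no harmonic falls inside the band.
    """
    _require(rep_rate > 0, "rep_rate must be > 0")
    f = _frac(rep_rate)
    k_low = max(1, math.ceil(_frac(band.f_low) / f))
    k_high = math.floor(_frac(band.f_high) / f)
    return HarmonicRange(k_low, k_high)


def _delta_f_bounds_frac(ref_rep_rate, n_pulses, n_wavelengths, band):
    """Exact-rational (δf_min, δf_max) used by all feasibility decisions."""
    rng = harmonic_indices(ref_rep_rate, band)
    if rng.empty:
        raise EmptyHarmonicRangeError(
            f"no harmonic of {ref_rep_rate} Hz lies in "
            f"[{band.f_low}, {band.f_high}] Hz")
    f1 = _frac(ref_rep_rate)
    df = f1 / n_pulses
    lo = df / rng.k_low
    hi = (f1 - df) / (rng.k_high * (n_wavelengths - 1))
    return lo, hi, rng


def delta_f_bounds(ref_rep_rate: float, n_pulses: int, n_wavelengths: int,
                   band: TransducerBand) -> DeltaFBounds:
    """Admissible window [δf_min, δf_max] for the repetition-rate offset.

    With df = f_rep,1/N_p the record resolves comb lines spaced by at least
    df.  δf ≥ δf_min = df/k_low keeps adjacent lasers' harmonics resolved at
    the low edge of the band; δf ≤ δf_max = (f_rep,1 - df)/(k_high*(N-1))
    keeps laser N's k-th harmonic clear of laser 1's (k+1)-th at the high
    edge.  Ties are feasible.  The harmonic index range of laser 1 stands in
    for all lasers (δf << f_rep,1 makes the drift negligible).
    """
    _require(int(n_wavelengths) == n_wavelengths and n_wavelengths >= 2,
             "n_wavelengths must be int >= 2")
    _require(int(n_pulses) == n_pulses and n_pulses >= 1, "n_pulses must be int >= 1")
    lo, hi, _ = _delta_f_bounds_frac(ref_rep_rate, n_pulses, n_wavelengths, band)
    return DeltaFBounds(float(lo), float(hi), feasible=lo <= hi)


def max_wavelengths_fwm(ref_rep_rate: float, n_pulses: int,
                        band: TransducerBand, n_cap: int = 10_000) -> int:
    """Largest wavelength count N with a non-empty [δf_min, δf_max] window.

    Scans N upward; feasibility is monotone in N because δf_max shrinks as
    1/(N-1) while δf_min is fixed.  N = 1 is always feasible.
    """
    rng = harmonic_indices(ref_rep_rate, band)
    if rng.empty:
        raise EmptyHarmonicRangeError("no in-band harmonic")
    n = 1
    while n < n_cap:
        lo, hi, _ = _delta_f_bounds_frac(ref_rep_rate, n_pulses, n + 1, band)
        if lo > hi:
            break
        n += 1
    return n


def max_wavelengths_td(rep_rate: float, medium: Medium,
                       dov_per_wavelength: float) -> int:
    """Wavelength slots of depth ``dov_per_wavelength`` fitting in one period."""
    _require(rep_rate > 0 and dov_per_wavelength > 0, "inputs must be > 0")
    # decimal lengths (e.g. 1.5 mm) are not exact binary floats; count slots
    # with an inclusive 1e-9 relative tolerance so exact fits are not lost
    ratio = medium.speed_of_sound / (rep_rate * dov_per_wavelength)
    return int(math.floor(ratio * (1.0 + 1e-9)))


def min_pulses(ref_rep_rate: float, n_wavelengths: int, band: TransducerBand,
               n_cap: int = 1_000_000) -> int:
    """Smallest N_p for which [δf_min, δf_max] is non-empty (linear scan).

    A single wavelength needs no frequency separation, so N = 1 returns 1.
    """
    _require(int(n_wavelengths) == n_wavelengths and n_wavelengths >= 1,
             "n_wavelengths must be int >= 1")
    if n_wavelengths == 1:
        return 1
    rng = harmonic_indices(ref_rep_rate, band)
    if rng.empty:
        raise EmptyHarmonicRangeError("no in-band harmonic")
    for n_p in range(1, n_cap + 1):
        lo, hi, _ = _delta_f_bounds_frac(ref_rep_rate, n_p, n_wavelengths, band)
        if lo <= hi:
            return n_p
    raise InvalidParameterError(f"no feasible pulse count below {n_cap}")


def snr_db(signal_amplitude: float, noise_std: float) -> float:
    """SNR in dB: 10*log10(S/N) with S the signal intensity, N the noise std."""
    _require(signal_amplitude > 0 and noise_std > 0, "S and N must be > 0")
    return 10.0 * math.log10(signal_amplitude / noise_std)


def averaging_gain_db(n_after: int, n_before: int) -> float:
    """dB gain from coherent averaging: amplitude SNR grows as sqrt(N_p)."""
    _require(n_after >= 1 and n_before >= 1, "pulse counts must be >= 1")
    return 10.0 * math.log10(math.sqrt(n_after / n_before))


def exposure(pulse_energies: Sequence[float], spot_area_cm2: float,
             combined_rep_rate: float) -> ExposureReport:
    """Per-pulse fluence and mean irradiance of simultaneous illumination.

    ``pulse_energies`` are the per-wavelength energies (J) delivered within
    one shot; ``combined_rep_rate`` is the shot rate (Hz).  Fluence is
    Σ energies / area (J/cm²); mean irradiance is fluence × rate (W/cm²).
    """
    energies = np.asarray(pulse_energies, dtype=float)
    _require(np.all(energies >= 0), "pulse energies must be >= 0")
    _require(spot_area_cm2 > 0, "spot_area_cm2 must be > 0")
    _require(combined_rep_rate > 0, "combined_rep_rate must be > 0")
    fluence = float(energies.sum()) / spot_area_cm2
    return ExposureReport(fluence_per_pulse=fluence,
                          mean_irradiance=fluence * combined_rep_rate)


def scheme_tradeoffs(scheme: MultiplexScheme, band: TransducerBand | None = None,
                     medium: Medium = Medium()) -> pd.DataFrame:
    """Per-wavelength DoV, pulse count, relative SNR factor and total t_acq.

    The relative SNR factor is quoted against single-wavelength operation at
    the same total acquisition time: only the slow time-interleaved scheme
    (rate and pulse count divided by N) pays a 1/sqrt(N) penalty.
    """
    n = scheme.n_wavelengths
    kind = scheme.kind
    rel_snr = 1.0 / math.sqrt(n) if kind is SchemeKind.TD_SLOW else 1.0
    t_total = max(tr.start_offset + tr.duration for tr in scheme.trains)
    rows = []
    for tr in scheme.trains:
        shared = n if kind is SchemeKind.TD_INTERLEAVE else 1
        rows.append({
            "wavelength_id": tr.wavelength_id,
            "rep_rate_hz": tr.rep_rate,
            "n_pulses": tr.n_pulses,
            "dov_m": depth_of_view(tr.rep_rate, medium, shared),
            "rel_snr_factor": rel_snr,
            "total_acquisition_time_s": t_total,
        })
    return pd.DataFrame(rows)


def design_limits(ref_rep_rate: float, n_pulses: int, n_wavelengths: int,
                  band: TransducerBand, medium: Medium = Medium()) -> DesignLimits:
    """Full derived-quantity report for one FWM operating point."""
    t_acq = acquisition_time(n_pulses, ref_rep_rate)
    df = frequency_resolution(t_acq)
    rng = harmonic_indices(ref_rep_rate, band)
    if rng.empty:
        raise EmptyHarmonicRangeError("no in-band harmonic")
    if n_wavelengths >= 2:
        b = delta_f_bounds(ref_rep_rate, n_pulses, n_wavelengths, band)
        npmin = min_pulses(ref_rep_rate, n_wavelengths, band)
        lo, hi, feas = b.delta_f_min, b.delta_f_max, b.feasible
    else:
        lo = hi = npmin = None
        feas = True
    return DesignLimits(
        dov=depth_of_view(ref_rep_rate, medium),
        t_acq=t_acq, df=df,
        k_low=rng.k_low, k_high=rng.k_high, n_harmonics=rng.n_harmonics,
        delta_f_min=lo, delta_f_max=hi, n_p_min=npmin,
        n_max_wavelengths=max_wavelengths_fwm(ref_rep_rate, n_pulses, band),
        feasible=feas)


# ---------------------------------------------------------------------------
# brute-force comb-separation validation
# ---------------------------------------------------------------------------

def comb_separation_ok(rep_rates: Sequence[float], df: float,
                       band: TransducerBand) -> bool:
    """Exact check that every pair of in-band comb lines is spaced >= df.

    Enumerates every harmonic of every repetition rate inside the band
    (each laser's true comb, edges inclusive) and verifies that consecutive
    lines of the pooled, sorted set are at least ``df`` apart.  All
    arithmetic is rational, so band-edge ties are decided exactly.
    """
    df = _frac(df)
    lines: list[Fraction] = []
    for rate in rep_rates:
        f = _frac(rate)
        rng = harmonic_indices(f, band)
        if rng.empty:
            continue
        lines.extend(f * k for k in range(rng.k_low, rng.k_high + 1))
    if len(lines) < 2:
        return True
    lines.sort()
    return all(b - a >= df for a, b in zip(lines, lines[1:]))


def _fwm_rates(ref_rep_rate, delta_f, n_wavelengths):
    f1 = _frac(ref_rep_rate)
    d = _frac(delta_f)
    return [f1 + j * d for j in range(n_wavelengths)]


def _comb_separation_ok_float(rep_rates, df, band, rtol=1e-9) -> bool:
    """Vectorized float version of :func:`comb_separation_ok` (interior use)."""
    lines = []
    for rate in rep_rates:
        rate = float(rate)
        k_low = max(1, math.ceil(band.f_low / rate - rtol))
        k_high = math.floor(band.f_high / rate + rtol)
        if k_low <= k_high:
            lines.append(np.arange(k_low, k_high + 1) * rate)
    if not lines:
        return True
    pooled = np.sort(np.concatenate(lines))
    if pooled.size < 2:
        return True
    return bool(np.all(np.diff(pooled) >= df * (1.0 - 1e-9)))


def brute_force_delta_f_feasible(ref_rep_rate: float, n_pulses: int,
                                 n_wavelengths: int, band: TransducerBand,
                                 n_grid: int = 512) -> bool:
    """Search a δf grid in the small-shift regime for a separable comb.

    The small-shift regime keeps the comb line ordering of δf → 0, i.e.
    (N-1)*k_high*δf < f_rep,1, which is the method's operating regime
    (δf << f_rep).  Within it feasibility is decided by enumerating each
    laser's true comb.  Grid candidates use fast float enumeration; the
    closed-form endpoints (where ties can occur) are re-checked with exact
    rational arithmetic.
    """
    _require(n_wavelengths >= 2, "n_wavelengths must be >= 2")
    rng = harmonic_indices(ref_rep_rate, band)
    if rng.empty:
        raise EmptyHarmonicRangeError("no in-band harmonic")
    f1 = float(ref_rep_rate)
    df = f1 / n_pulses
    upper = f1 / ((n_wavelengths - 1) * rng.k_high)
    for i in range(n_grid, 0, -1):     # feasible offsets cluster near the top
        cand = upper * i / (n_grid + 1)
        rates = [f1 + j * cand for j in range(n_wavelengths)]
        if _comb_separation_ok_float(rates, df, band):
            return True
    # closed-form endpoints: ties are feasible, decide them exactly
    lo, hi, _ = _delta_f_bounds_frac(ref_rep_rate, n_pulses, n_wavelengths, band)
    for cand in (lo, hi, (lo + hi) / 2):
        if 0 < cand and comb_separation_ok(
                _fwm_rates(ref_rep_rate, cand, n_wavelengths),
                _frac(ref_rep_rate) / n_pulses, band):
            return True
    return False


def brute_force_max_wavelengths(ref_rep_rate: float, n_pulses: int,
                                band: TransducerBand, n_cap: int = 64,
                                n_grid: int = 512) -> int:
    """Largest N for which the brute-force δf search succeeds."""
    n = 1
    while n < n_cap and brute_force_delta_f_feasible(
            ref_rep_rate, n_pulses, n + 1, band, n_grid=n_grid):
        n += 1
    return n
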