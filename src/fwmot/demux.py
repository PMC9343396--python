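"""Per-wavelength recovery from one interleaved optoacoustic record.

Two equivalent averaging routes are implemented.  Time-domain averaging
splits the record into sections of one period T = 1/f_rep and averages them
point by point.  The Fourier route keeps only the harmonic comb of the
repetition rate — the record's spectrum is evaluated at the exact
frequencies k*f_rep and one period is re-synthesized from those components.
On a record holding an integer number of periods, with every harmonic up to
Nyquist retained, the two routes coincide up to the DC term; both raise the
SNR of white noise by sqrt(N_p).

With several lasers at offset repetition rates f_rep,j = f_rep,1 + (j-1)*δf,
each wavelength is recovered by comb selection at its own rate.  Because the
record length is an integer number of periods for at most one laser, comb
frequencies fall between FFT bins; spectra are therefore evaluated by
exact-frequency least-squares projection rather than FFT-bin picking.  The
Gram matrix of the sinusoid basis is computed in closed form (Dirichlet
sums), and :func:`demux_all` solves all lasers' in-band combs jointly, which
removes the spectral-leakage cross-talk of independent per-line projection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .design import (
    InvalidParameterError,
    MultiplexScheme,
    SchemeKind,
    SNRReport,
    TransducerBand,
    delta_f_bounds,
    harmonic_indices,
    _require,
)
from .simulate import AcquisitionRecord

__all__ = [
    "AveragedAScan",
    "project_sinusoids",
    "synthesize",
    "td_average",
    "comb_filter",
    "demux_all",
    "correct_pulse_variations",
    "measure_snr",
    "crosstalk_db",
]


@dataclass
class AveragedAScan:
    """One wavelength's averaged single-period signal S_a(t).

    ``spectrum`` holds the complex amplitude c_k of each retained harmonic,
    with the convention S_a(t) = Re( sum_k c_k * exp(i*2*pi*k*f_rep*t) ), so
    samples and spectrum are a Fourier pair over the period.
    """

    samples: np.ndarray
    sampling_rate: float
    period: float
    wavelength_id: int = 1
    harmonics: np.ndarray | None = None
    spectrum: np.ndarray | None = None
    start_time: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


# ---------------------------------------------------------------------------
# exact-frequency projection machinery
# ---------------------------------------------------------------------------

def _dirichlet(freqs: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Closed-form sum_{k=0}^{n-1} exp(i*2*pi*f*k/fs) for each frequency."""
    theta = np.pi * np.asarray(freqs, dtype=float) / fs      # = half angle
    num = np.sin(n * theta)
    den = np.sin(theta)
    degenerate = np.abs(den) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(degenerate, 1.0, num / np.where(degenerate, 1.0, den))
    out = ratio * np.exp(1j * (n - 1) * theta)
    # f a multiple of fs: every term is exp(i*2*pi*m*k) = 1, no net phase
    return np.where(degenerate, float(n) + 0.0j, out)


def _gram(freqs: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Gram matrix of [cos(2*pi*f*t), sin(2*pi*f*t)] on the n-sample grid."""
    f = np.asarray(freqs, dtype=float)
    diff = f[:, None] - f[None, :]
    summ = f[:, None] + f[None, :]
    ed = _dirichlet(diff, n, fs)
    es = _dirichlet(summ, n, fs)
    ccc = 0.5 * (ed.real + es.real)
    css = 0.5 * (ed.real - es.real)
    ccs = 0.5 * (es.imag - ed.imag)    # <cos_i, sin_j>
    m = len(f)
    g = np.empty((2 * m, 2 * m))
    g[:m, :m] = ccc
    g[m:, m:] = css
    g[:m, m:] = ccs
    g[m:, :m] = ccs.T
    return g


def _basis_dot(samples: np.ndarray, freqs: np.ndarray, fs: float,
               chunk: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """(sum s*cos, sum s*sin) per frequency, chunked to bound memory."""
    t = np.arange(len(samples)) / fs
    rc = np.empty(len(freqs))
    rs = np.empty(len(freqs))
    for i in range(0, len(freqs), chunk):
        w = 2 * np.pi * np.asarray(freqs[i:i + chunk])[:, None] * t[None, :]
        rc[i:i + chunk] = np.cos(w) @ samples
        rs[i:i + chunk] = np.sin(w) @ samples
    return rc, rs


def project_sinusoids(samples: np.ndarray, sampling_rate: float,
                      freqs: np.ndarray, method: str = "lsq") -> np.ndarray:
    """Complex amplitudes c_f of sinusoids at exact frequencies.

    Fits samples ~ Re( sum_f c_f exp(i*2*pi*f*t) ) on the record's grid.
    ``method="lsq"`` solves the joint least-squares problem with a
    closed-form Gram matrix (handles non-integer cycle counts and closely
    spaced bases); ``method="independent"`` projects each frequency on its
    own, normalizing by the exact basis norms (fast, leakage-prone).
    """
    samples = np.asarray(samples, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    _require(freqs.size > 0, "need at least one frequency")
    _require(np.all(freqs > 0), "frequencies must be > 0 (DC is excluded)")
    _require(np.all(freqs <= sampling_rate / 2 * (1 + 1e-12)),
             "frequencies must not exceed Nyquist")
    n = len(samples)
    rc, rs = _basis_dot(samples, freqs, sampling_rate)
    if method == "independent":
        ed = _dirichlet(2 * freqs, n, sampling_rate)
        norm_c = 0.5 * (n + ed.real)
        norm_s = 0.5 * (n - ed.real)
        a = np.where(norm_c > n * 1e-12, rc / np.maximum(norm_c, 1e-300), 0.0)
        b = np.where(norm_s > n * 1e-12, rs / np.maximum(norm_s, 1e-300), 0.0)
        return a - 1j * b
    if method != "lsq":
        raise InvalidParameterError(f"unknown projection method {method!r}")
    g = _gram(freqs, n, sampling_rate)
    rhs = np.concatenate([rc, rs])
    # drop numerically empty columns (sin at Nyquist has zero norm)
    keep = np.diag(g) > n * 1e-12
    gk = g[np.ix_(keep, keep)]
    try:
        sol_k = scipy.linalg.solve(gk, rhs[keep], assume_a="pos")
    except scipy.linalg.LinAlgError:
        sol_k = scipy.linalg.lstsq(gk, rhs[keep])[0]
    sol = np.zeros(2 * len(freqs))
    sol[keep] = sol_k
    a, b = sol[:len(freqs)], sol[len(freqs):]
    return a - 1j * b


def synthesize(freqs: np.ndarray, coeffs: np.ndarray, sampling_rate: float,
               n_out: int, t0: float = 0.0) -> np.ndarray:
    """Evaluate Re( sum_f c_f exp(i*2*pi*f*(t0 + t)) ) on a fresh grid."""
    t = t0 + np.arange(n_out) / sampling_rate
    w = 2 * np.pi * np.asarray(freqs)[:, None] * t[None, :]
    a = np.real(coeffs)
    b = -np.imag(coeffs)
    return a @ np.cos(w) + b @ np.sin(w)


# ---------------------------------------------------------------------------
# averaging routes
# ---------------------------------------------------------------------------

def _samples_fs(record) -> tuple[np.ndarray, float]:
    if isinstance(record, AcquisitionRecord):
        return record.samples, record.sampling_rate
    raise InvalidParameterError("expected an AcquisitionRecord")


def td_average(record: AcquisitionRecord, rep_rate: float, n_pulses: int,
               wavelength_id: int = 1) -> AveragedAScan:
    """Point-by-point average of the first N_p periods of the record.

    White-noise standard deviation shrinks by sqrt(N_p) in expectation.
    When the sampling grid does not hold an integer number of samples per
    period, each period is resampled onto a common grid by linear
    interpolation before averaging.
    """
    samples, fs = _samples_fs(record)
    _require(rep_rate > 0 and n_pulses >= 1, "invalid rep_rate or n_pulses")
    period = 1.0 / rep_rate
    if len(samples) < int(math.floor(n_pulses * period * fs)):
        raise InvalidParameterError("record shorter than n_pulses periods")
    spp = fs / rep_rate
    n_per = int(round(spp))
    if abs(spp - n_per) < 1e-9:
        avg = samples[:n_pulses * n_per].reshape(n_pulses, n_per).mean(axis=0)
    else:
        n_per = int(round(period * fs))
        t = np.arange(len(samples)) / fs
        grid = (np.arange(n_pulses)[:, None] * period
                + np.arange(n_per)[None, :] / fs)
        avg = np.interp(grid.ravel(), t, samples).reshape(n_pulses, n_per).mean(axis=0)
    spectrum = np.fft.rfft(avg)
    c = 2.0 * spectrum / len(avg)
    if len(avg) % 2 == 0:
        c[-1] *= 0.5   # Nyquist bin is not doubled
    return AveragedAScan(samples=avg, sampling_rate=fs, period=period,
                         wavelength_id=wavelength_id,
                         harmonics=np.arange(1, len(c)), spectrum=c[1:])


def comb_filter(record: AcquisitionRecord, rep_rate: float,
                harmonics, method: str = "lsq", window: int | None = None,
                t0: float = 0.0, wavelength_id: int = 1) -> AveragedAScan:
    """Harmonic-comb selection: keep only k*f_rep components, k in harmonics.

    Projects the record onto sinusoids at the exact comb frequencies and
    synthesizes one period from the retained components.  DC is excluded
    (the detector is AC-coupled; the comb starts at k = 1).  ``window``
    restricts the analysis to the first ``window`` samples; ``t0`` shifts
    the synthesized period's time origin (e.g. to a laser's first trigger).
    """
    samples, fs = _samples_fs(record)
    harmonics = np.asarray(harmonics, dtype=int)
    _require(harmonics.size > 0, "harmonics must be non-empty")
    _require(np.all(harmonics >= 1), "harmonics must be >= 1")
    freqs = harmonics * float(rep_rate)
    if np.any(freqs > fs / 2 * (1 + 1e-12)):
        raise InvalidParameterError("harmonic above Nyquist")
    if window is not None:
        samples = samples[:window]
    coeffs = project_sinusoids(samples, fs, freqs, method=method)
    period = 1.0 / rep_rate
    n_out = int(round(period * fs))
    out = synthesize(freqs, coeffs, fs, n_out, t0=t0)
    return AveragedAScan(samples=out, sampling_rate=fs, period=period,
                         wavelength_id=wavelength_id, harmonics=harmonics,
                         spectrum=coeffs, start_time=t0)


def _harmonic_set(rep_rate: float, fs: float, band: TransducerBand | None,
                  scheme: MultiplexScheme | None = None,
                  mode: str = "band") -> np.ndarray:
    nyq_k = int(math.floor(fs / 2 / rep_rate * (1 + 1e-12)))
    if band is None:
        return np.arange(1, nyq_k + 1)
    rng = harmonic_indices(rep_rate, band)
    if rng.empty:
        raise InvalidParameterError("no in-band harmonic for this laser")
    k_lo, k_hi = rng.k_low, rng.k_high
    if mode == "separable" and scheme is not None and scheme.n_wavelengths > 1 \
            and scheme.delta_f > 0:
        # widest harmonic range over which all lasers' lines stay resolved
        t_acq = min(tr.n_pulses / tr.rep_rate for tr in scheme.trains)
        df = 1.0 / t_acq
        f1 = scheme.ref_rep_rate
        n = scheme.n_wavelengths
        k_lo = max(1, int(math.ceil(df / scheme.delta_f)))
        k_hi = int(math.floor((f1 - df) / ((n - 1) * scheme.delta_f)))
    return np.arange(max(1, k_lo), min(k_hi, nyq_k) + 1)


def demux_all(record: AcquisitionRecord, scheme: MultiplexScheme | None = None,
              band: TransducerBand | None = None, method: str = "lsq",
              joint: bool = True, harmonic_mode: str = "band") -> list[AveragedAScan]:
    """Recover one averaged A-scan per wavelength from an interleaved record.

    Comb selection runs at each laser's own repetition rate over the common
    overlap of all trains.  With ``joint=True`` (default) all lasers' combs
    enter one least-squares problem, so one laser's lines cannot leak into
    another's.  ``harmonic_mode="band"`` keeps the transducer band's
    harmonics; ``"separable"`` widens the set to every harmonic at which the
    lasers' combs remain resolved (>= df apart), up to Nyquist.  Each A-scan
    is synthesized over its own period, aligned to its laser's first trigger.
    """
    if scheme is None:
        scheme = record.scheme
    samples, fs = record.samples, record.sampling_rate
    if scheme.kind is SchemeKind.FWM and scheme.n_wavelengths >= 2 and band is not None:
        bounds = delta_f_bounds(scheme.ref_rep_rate, scheme.trains[0].n_pulses,
                                scheme.n_wavelengths, band)
        if not bounds.contains(scheme.delta_f):
            warnings.warn(
                f"delta_f = {scheme.delta_f:g} Hz outside the admissible window "
                f"[{bounds.delta_f_min:g}, {bounds.delta_f_max:g}] Hz; "
                "cross-talk between wavelengths is expected", stacklevel=2)
    for tr in scheme.trains:
        if tr.n_pulses == 0 or len(record.trigger_times) < scheme.n_wavelengths:
            raise InvalidParameterError("record is missing trigger information")
    n_common = int(math.floor(min(tr.start_offset + tr.duration
                                  for tr in scheme.trains) * fs))
    window = samples[:min(n_common, len(samples))]

    k_sets = [_harmonic_set(tr.rep_rate, fs, band, scheme, harmonic_mode)
              for tr in scheme.trains]
    freq_sets = [k * tr.rep_rate for k, tr in zip(k_sets, scheme.trains)]
    if joint and method == "lsq" and scheme.n_wavelengths > 1:
        all_freqs = np.concatenate(freq_sets)
        all_coeffs = project_sinusoids(window, fs, all_freqs, method="lsq")
        splits = np.cumsum([len(f) for f in freq_sets])[:-1]
        coeff_sets = np.split(all_coeffs, splits)
    else:
        coeff_sets = [project_sinusoids(window, fs, f, method=method)
                      for f in freq_sets]
    out = []
    for tr, ks, freqs, coeffs in zip(scheme.trains, k_sets, freq_sets, coeff_sets):
        period = 1.0 / tr.rep_rate
        n_out = int(round(period * fs))
        t0 = tr.start_offset
        y = synthesize(freqs, coeffs, fs, n_out, t0=t0)
        out.append(AveragedAScan(samples=y, sampling_rate=fs, period=period,
                                 wavelength_id=tr.wavelength_id, harmonics=ks,
                                 spectrum=coeffs, start_time=t0))
    return out


def correct_pulse_variations(record: AcquisitionRecord,
                             energy_factors: np.ndarray,
                             timing_offsets: np.ndarray,
                             laser: int = 0) -> AcquisitionRecord:
    """Undo per-pulse energy and timing jitter using a reference monitor.

    Each period of the given laser's train is divided by its relative pulse
    energy and resampled (linear interpolation) to cancel its timing offset,
    mirroring the photodiode-based correction of a real system.  A zero
    reference is the identity.
    """
    tr = record.scheme.trains[laser]
    energy_factors = np.asarray(energy_factors, dtype=float)
    timing_offsets = np.asarray(timing_offsets, dtype=float)
    if len(energy_factors) != tr.n_pulses or len(timing_offsets) != tr.n_pulses:
        raise InvalidParameterError("reference must cover every pulse")
    _require(np.all(energy_factors > 0), "energy factors must be > 0")
    fs = record.sampling_rate
    t = record.times
    out = record.samples.astype(float).copy()
    period = 1.0 / tr.rep_rate
    for k in range(tr.n_pulses):
        t_start = tr.start_offset + k * period
        i0 = int(round(t_start * fs))
        i1 = min(int(round((t_start + period) * fs)), len(out))
        if i0 >= len(out):
            break
        seg_t = t[i0:i1] + timing_offsets[k]
        out[i0:i1] = np.interp(seg_t, t, record.samples) / energy_factors[k]
    return AcquisitionRecord(samples=out, sampling_rate=fs, scheme=record.scheme,
                             trigger_times=record.trigger_times)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def _window_slice(window: tuple[float, float], fs: float, n: int) -> slice:
    lo, hi = window
    _require(hi > lo >= 0, "window must satisfy 0 <= start < stop")
    i0, i1 = int(round(lo * fs)), int(round(hi * fs))
    _require(i1 <= n, "window extends past the period")
    _require(i1 > i0, "window is empty at this sampling rate")
    return slice(i0, i1)


def measure_snr(ascan: AveragedAScan, signal_window: tuple[float, float],
                noise_window: tuple[float, float]) -> SNRReport:
    """SNR of an averaged A-scan: peak |signal| over noise-floor std, in dB.

    Windows are time intervals (s) within the period and must not overlap.
    A signal peak below 3x the noise floor is flagged as no-signal.
    """
    n = len(ascan.samples)
    s_sl = _window_slice(signal_window, ascan.sampling_rate, n)
    n_sl = _window_slice(noise_window, ascan.sampling_rate, n)
    _require(s_sl.stop <= n_sl.start or n_sl.stop <= s_sl.start,
             "signal and noise windows must be disjoint")
    s = float(np.max(np.abs(ascan.samples[s_sl])))
    sigma = float(np.std(ascan.samples[n_sl]))
    _require(s > 0 and sigma > 0, "degenerate window contents")
    return SNRReport(signal_amplitude=s, noise_std=sigma,
                     snr_db=10.0 * math.log10(s / sigma),
                     has_signal=s >= 3.0 * sigma)


def crosstalk_db(ascans: list[AveragedAScan],
                 windows: dict[int, tuple[float, float]]) -> np.ndarray:
    """Cross-talk matrix in dB between demultiplexed wavelengths.

    Entry (i, j) = 10*log10( peak of wavelength-i's A-scan inside
    wavelength-j's signal window / peak inside its own window ); the
    diagonal is 0 by construction.  Windows map wavelength_id -> (t0, t1).
    """
    ids = [a.wavelength_id for a in ascans]
    for wid in ids:
        if wid not in windows:
            raise InvalidParameterError(f"missing window for wavelength {wid}")
    m = len(ascans)
    out = np.zeros((m, m))
    for i, a in enumerate(ascans):
        own = np.max(np.abs(a.samples[_window_slice(windows[ids[i]],
                                                    a.sampling_rate,
                                                    len(a.samples))]))
        for j in range(m):
            if j == i:
                continue
            peak = np.max(np.abs(a.samples[_window_slice(windows[ids[j]],
                                                         a.sampling_rate,
                                                         len(a.samples))]))
            out[i, j] = 10.0 * math.log10(max(peak, 1e-300) / max(own, 1e-300))
    return out
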