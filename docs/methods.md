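# Methods

## Model

A pulse train of N_p rectangular pulses (width t_p, repetition rate f_rep)
is, in the Fourier domain, a comb of lines at the harmonics k·f_rep under a
sinc envelope whose first node sits at 1/t_p. An absorber at depth z
returns, for every pulse, a band-limited bipolar wavelet delayed by z/v_s;
the single-channel record S_r(t) is the superposition of these wavelets,
trigger-synchronous electromagnetic-interference ringing, delayed echo
replicas, and white detector noise. Multi-wavelength operation offsets the
repetition rates by δf per wavelength so each laser's signal occupies its
own comb; recovery evaluates the record's spectrum on each laser's comb and
re-synthesizes one period.

All feasibility algebra reduces to keeping every pair of in-band comb
lines at least df = f_rep,1/N_p apart. With in-band harmonic indices
k_low..k_high of the reference rate (band edges inclusive, which maximizes
the constraint set and matches round-number band edges):

- δf_min = df/k_low  — adjacent lasers resolved at the lowest harmonic;
- δf_max = (f_rep,1 − df)/(k_high·(N − 1)) — laser N's k-th harmonic clear
  of laser 1's (k+1)-th at the highest harmonic;
- N_p,min = ceil((k_high·(N−1) + k_low)/k_low); N_max = 1 + floor((N_p−1)·k_low/k_high).

These closed forms use laser 1's index range for every laser; in the
operating regime δf ≪ f_rep the index drift is negligible. The
exact-rational brute-force validator (`comb_separation_ok`) enumerates each
laser's true comb instead and is the oracle in the property tests; cases
where a shifted laser gains or loses an in-band harmonic are excluded
there, since the closed form is explicitly an index-drift-free
approximation. Feasibility comparisons run on `fractions.Fraction` so
band-edge ties never flip on floating-point rounding; ties are feasible.
Note one non-obvious consequence of the algebra: shrinking the band from
the top (smaller k_high) *increases* the wavelength capacity, because wrap
constraints at high harmonics disappear — capacity is monotone in k_low
and k_high, not in bandwidth as such.

## Demultiplexing: exact-frequency least squares

With trains of 100 and 101 pulses the record holds an integer number of
periods for at most one laser, so comb frequencies fall between FFT bins.
Spectra are therefore evaluated by least-squares projection onto
cos/sin pairs at the exact frequencies k·f_rep,j. The Gram matrix of that
basis is computed in closed form from Dirichlet sums
Σ_n exp(i2πf·n/f_s) = e^{iθ(n−1)} sin(nθ)/sin(θ), θ = πf/f_s, making the
solve exact to solver precision at any record length; a diagonal
"independent" projection mode (the exact-frequency generalization of
FFT-bin picking) is retained for speed. `demux_all` solves all lasers'
combs **jointly** by default, which removes inter-comb spectral leakage —
the mechanism behind cross-talk-free recovery. DC is excluded (AC-coupled
detector; the comb starts at k = 1); zero-norm columns (sine at Nyquist)
are dropped automatically.

Two harmonic-set policies exist: `"band"` keeps the transducer's in-band
harmonics k_low..k_high (the default, mirroring what a band-limited
detector contributes), and `"separable"` widens the set to every harmonic
at which the lasers' combs remain resolved (k from ceil(df/δf) to
floor((f_rep,1 − df)/((N−1)δf)), capped at Nyquist). The joint solve must
not include harmonics below ceil(df/δf): there the four combs are closer
than the record's frequency resolution and the basis becomes degenerate.
Band-restricted synthesis truncates the wavelet spectrum at the −6 dB
edges, which costs ~24% of peak amplitude and leaves ~−25 dB ringing
tails; the separable set recovers the full peak and pushes residual
cross-talk below −26 dB.

The analysis window is the common overlap of all trains (the shortest
t_acq); each wavelength's A-scan is synthesized over its own period
1/f_rep,j on the record's sampling grid, time-aligned to its first
trigger. Time-domain period averaging (`td_average`) is the reference
route; on non-integer samples-per-period grids each period is resampled
onto a common grid by linear interpolation. On integer-period records with
all harmonics retained the two routes agree to numerical precision
(~1e-14 relative), and both reduce white noise by √N_p.

Per-pulse energy and timing jitter are undone by `correct_pulse_variations`
from a reference monitor (each period divided by its relative energy and
resampled by its timing offset). Linear resampling attenuates carriers
sampled near 4 samples/cycle when shifts approach half a sample; for
realistic nanosecond-scale jitter the correction restores the demuxed SNR
to within 1 dB of the jitter-free case, and alignment is always recovered
to within one sample.

## Forward simulator

The wavelet is `scipy.signal.gausspulse` — a gaussian-windowed cosine at
the transducer's center frequency with its −6 dB fractional bandwidth —
peak-normalized, so absorber weights are in volts per joule of pulse
energy. Optical pulses enter as energy impulses: at the reference
operating point the pulse-envelope sinc node (~150 MHz for 6.7 ns) lies
above the 78 MHz band edge, so finite pulse width is modelled only in the
excitation builder (`build_excitation`, which requires ≥ 4 samples per
pulse), not acoustically. Wavelets and EMI rings are evaluated
*analytically at exact sample times* per event rather than deposited on
the grid and convolved — grid deposition acts as a fractional-delay
two-tap filter that dephases the carrier for lasers whose period is a
non-integer number of samples. Energy jitter is multiplicative lognormal
with the stated CV (mean exactly 1); timing jitter is additive Gaussian
per pulse; EMI is an exponentially damped sinusoid at each trigger with a
default ring frequency at band center; white Gaussian noise is added last;
12-bit quantization is off by default. A single integer seed fixes every
draw, and records are bit-identical per seed. B-scan sweeps give each scan
position an independent, reproducible noise substream.

Default sampling rate is 200 MS/s and record duration is the longest
train plus one reference period of tail. The fixture generator's
reference scenario uses the canonical four-diode operating point
(6.7/6.7/10.2/10.2 ns pulses, 200000/200125/200250/200375 Hz,
189/137/142/153 nJ, trains of 100/101/101/101 pulses, δf = 125 Hz,
50 MHz / 112% detector) with absorber weights calibrated so a
fully-averaged wavelength peaks at 12 mV, and a single-period noise floor
of 90.6 µV·√200 ≈ 1.28 mV so that 200-fold averaging reproduces a
~90 µV floor. The speed of sound defaults to 1500 m/s (soft tissue).

What the generator does *not* emulate: acoustic attenuation and
dispersion, depth-dependent fluence, transducer directivity beyond a
uniform acceptance cone, correlated (non-white) electronic noise, and
motion. Passing tests therefore demonstrate the correctness of the
multiplexing/demultiplexing machinery under the stated signal model, not
quantitative in-vivo performance.

## Reconstruction

Plain time-domain delay-and-sum back-projection in two dimensions: each
pixel accumulates A-scan amplitude at the one-way delay
|pixel − detector|/v_s from every scan position whose acceptance cone
(apex at the focus, along the B-scan direction only) contains the pixel,
normalized by the number of contributing positions. Linear interpolation
between time samples; delays outside the A-scan contribute zero; the
lateral grid coincides with the scan positions and the axial grid spans at
most the unambiguous depth v_s·T. `envelope_image` takes the per-column
analytic-signal magnitude (Hilbert transform) normalized to [0, 1] for
display. Exact lateral shift equivariance holds on interior columns whose
cone footprint stays inside the scan range — the equivariance tests use a
narrow-cone geometry so such an interior exists.

## Oxygenation read-outs

Only *relative* oxygenation is derived: the ratio S2/S1 of the two
hemoglobin-weighted wavelengths' intensities per region (denominators
below 5% of their series maximum are masked to avoid noise blow-up) and
the oxygen extraction rate OER = (O_ca − O_cv)/O_ca from artery/vein
traces. Both are invariant to common gain. `assign_channels` is a pure
relabeling of the four wavelengths to their contrast roles
(Hb, HbO2, Evans Blue, ICG).

## Exposure

Fluence per combined shot is Σ pulse energies / spot area (J/cm²), mean
irradiance is fluence × shot rate, flagged against the 20 mJ/cm² and
18 W/cm² skin limits. The spot area is an explicit input: the reference
figures (19.8 µJ/cm², 3.96 W/cm²) correspond to a ~2 mm-diameter
illumination area for the 621 nJ combined shot, and the operation does
not impose a diameter.

## Problem sizes and numerical choices

Unit and property tests run a desk-scale configuration (2–8 MHz band,
20 MS/s, ~10⁴-sample records) that preserves every structural property of
the reference point; the acceptance tests run the reference configuration
itself (100 k-sample records, 281 in-band harmonics per laser, joint
solves over ~2 200 basis functions) in tens of seconds. Monte-Carlo
checks of the √N_p law use N_p ∈ {4, …, 256} with pooled-std estimates
(slope tolerance ±0.05). Gram systems are solved by Cholesky with an
SVD fallback; tie-breaks and degenerate inputs: band-edge harmonics are
in-band, δf-window ties are feasible, empty phantoms yield noise-only
records, all-zero images produce all-zero envelopes.
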