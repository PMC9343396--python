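# fwmot — frequency-wavelength-multiplexed optoacoustic tomography

Optoacoustic (photoacoustic) imaging detects the ultrasound emitted when
absorbed pulsed light heats tissue. Conventional time-domain systems
multiplex excitation wavelengths by time-sharing, which forces a trade-off:
adding a wavelength costs depth-of-view, signal-to-noise ratio, or
acquisition time. Frequency-wavelength multiplexing (FWM) avoids the
trade-off by pulsing every laser diode *simultaneously* at a slightly
offset repetition rate,

    f_rep,j = f_rep,1 + (j − 1)·δf ,

so that each wavelength occupies its own harmonic comb k·f_rep,j in the
Fourier domain of a single acoustic record. Per-wavelength signals are
recovered by comb selection,

    S_a(ω) = S_r(ω) · Σ_k δ(ω − k·ω_0,j),   ω_0,j = 2π f_rep,j ,

which is the Fourier-space equivalent of averaging N_p periods and raises
the SNR by √N_p. The package is aimed at people building or analyzing
pulse-train optoacoustic systems: it computes every multiplexing design
quantity, simulates realistic multi-wavelength acquisition records,
demultiplexes them, reconstructs B-scan images, and derives oxygenation
read-outs.

Key design quantities (v_s the speed of sound, T = 1/f_rep, band
[f_low, f_high] the ultrasound transducer's detection band,
df = 1/t_acq = f_rep,1/N_p the record's frequency resolution):

- depth-of-view `DoV = v_s·T` (shared N ways under time interleaving);
- admissible offsets `δf_min = df/k_low`, `δf_max = (f_rep,1 − df)/(k_high·(N−1))`
  with k_low..k_high the in-band harmonic indices;
- the minimum pulse count N_p,min and the maximum wavelength count
  N_max that keep every pair of in-band comb lines at least df apart.

## Worked example

```python
import fwmot as fw

band = fw.TransducerBand(22e6, 78e6)          # ultrasound detection band
limits = fw.design_limits(200e3, 100, 4, band)
print(f"DoV {limits.dov*1e3:.3f} mm | delta_f window "
      f"[{limits.delta_f_min:.2f}, {limits.delta_f_max:.2f}] Hz | "
      f"N_p,min {limits.n_p_min} | N_max {limits.n_max_wavelengths}")

case = fw.fixture_suite(0, include=["fwm_table1"])["fwm_table1"]
ascans = fw.demux_all(case["record"], band=band)
rep = fw.measure_snr(ascans[0], case["signal_window"], case["noise_window"])
print(f"wavelength-1 peak {rep.signal_amplitude*1e3:.2f} mV | "
      f"noise floor {rep.noise_std*1e6:.1f} uV | SNR {rep.snr_db:.1f} dB")
```

prints

```
DoV 7.500 mm | delta_f window [18.18, 169.23] Hz | N_p,min 12 | N_max 28
wavelength-1 peak 9.06 mV | noise floor 88.4 uV | SNR 20.1 dB
```

The first line is the design report for a four-wavelength system at a
200 kHz reference rate with 100-pulse trains: 7.5 mm unambiguous depth,
and any repetition-rate offset between 18.2 and 169.2 Hz separates all
four combs (the canonical system uses 125 Hz). The second line
demultiplexes a simulated four-laser record of a calibrated absorber:
the recovered wavelength-1 A-scan peaks near the programmed 12 mV (the
in-band harmonic set carries ~76% of the wavelet amplitude) over an
~88 µV noise floor after 100-fold averaging — about 20 dB.

The same stages are scriptable from the shell:

```
fwmot design --frep1 200000 --n-pulses 100 --n-wavelengths 4 --df 125
fwmot simulate --config run.toml --out record.h5
fwmot demux --record record.h5 --out-dir ascans --f-low 22e6 --f-high 78e6
fwmot recon --bscan sweep.h5 --out-dir images --f-low 22e6 --f-high 78e6
```

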