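"""Persistence, configuration and canonical synthetic fixtures.

Acquisition records travel in HDF5 containers with documented dataset
names; design reports and SNR tables are plain CSV; images are TIFF.  Run
configurations round-trip through a flat TOML file with strict schema
checking (unknown keys are errors).  :func:`fixture_suite` packages the
canonical synthetic scenarios — a single-wavelength absorber record, the
three time-domain multiplexing variants, the four-wavelength
frequency-multiplexed record with the reference laser-diode operating
parameters, a noise-only record and a two-wavelength oxygen-challenge
B-scan series — so that every processing stage can be exercised without
hardware.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .design import (
    DesignLimits,
    InvalidParameterError,
    Medium,
    MultiplexScheme,
    SchemeKind,
    TransducerBand,
)
from .recon import BScanImage
from .simulate import (
    Absorber,
    AcquisitionRecord,
    NoiseModel,
    TransducerModel,
    make_bscan,
    simulate_record,
)

__all__ = [
    "FORMAT_VERSION",
    "TABLE1",
    "table1_scheme",
    "reference_transducer",
    "RunConfig",
    "save_record",
    "load_record",
    "save_bscan_records",
    "load_bscan_records",
    "save_image_tiff",
    "design_report_frame",
    "fixture_suite",
]

logger = logging.getLogger("fwmot")

FORMAT_VERSION = "1"

#: Reference four-laser-diode operating point (pulse width s, repetition
#: rate Hz, energy per pulse J, emission wavelength nm).
TABLE1 = {
    "pulse_widths": (6.7e-9, 6.7e-9, 10.2e-9, 10.2e-9),
    "rep_rates": (200_000.0, 200_125.0, 200_250.0, 200_375.0),
    "pulse_energies": (189e-9, 137e-9, 142e-9, 153e-9),
    "wavelengths_nm": (444.3, 460.1, 636.8, 804.9),
    "n_pulses": (100, 101, 101, 101),
    "delta_f": 125.0,
}

#: Demultiplexed primary-signal amplitude (V) and the noise floor (V)
#: measured after 200 averages on the reference system; the single-period
#: noise std follows as NOISE_FLOOR_200 * sqrt(200).
SIGNAL_AMPLITUDE_V = 12e-3
NOISE_FLOOR_200_V = 90.6e-6
SINGLE_PERIOD_NOISE_V = NOISE_FLOOR_200_V * math.sqrt(200.0)


def table1_scheme(n_pulses=None) -> MultiplexScheme:
    """The four-wavelength FWM scheme at the reference operating point."""
    return MultiplexScheme.fwm(
        ref_rep_rate=TABLE1["rep_rates"][0],
        delta_f=TABLE1["delta_f"],
        n_pulses=list(n_pulses if n_pulses is not None else TABLE1["n_pulses"]),
        pulse_widths=list(TABLE1["pulse_widths"]),
        pulse_energies=list(TABLE1["pulse_energies"]),
        wavelengths_nm=list(TABLE1["wavelengths_nm"]),
    )


def reference_transducer() -> TransducerModel:
    """50 MHz center / 112% fractional-bandwidth focused detector."""
    return TransducerModel(band=TransducerBand.from_center(50e6, 1.12),
                           focal_length=3e-3,
                           acceptance_half_angle=math.radians(30.0))


# ---------------------------------------------------------------------------
# HDF5 record container
# ---------------------------------------------------------------------------

def _write_scheme(grp: h5py.Group, scheme: MultiplexScheme) -> None:
    grp.attrs["kind"] = scheme.kind.value
    grp.attrs["delta_f"] = scheme.delta_f
    grp.create_dataset("rep_rates", data=[t.rep_rate for t in scheme.trains])
    grp.create_dataset("n_pulses", data=[t.n_pulses for t in scheme.trains])
    grp.create_dataset("pulse_widths", data=[t.pulse_width for t in scheme.trains])
    grp.create_dataset("pulse_energies", data=[t.pulse_energy for t in scheme.trains])
    grp.create_dataset("start_offsets", data=[t.start_offset for t in scheme.trains])
    grp.create_dataset("wavelengths_nm", data=[
        np.nan if t.wavelength_nm is None else t.wavelength_nm
        for t in scheme.trains])


def _read_scheme(grp: h5py.Group) -> MultiplexScheme:
    from .design import PulseTrain
    rates = grp["rep_rates"][()]
    npul = grp["n_pulses"][()]
    widths = grp["pulse_widths"][()]
    energies = grp["pulse_energies"][()]
    offsets = grp["start_offsets"][()]
    wl = grp["wavelengths_nm"][()]
    trains = tuple(
        PulseTrain(wavelength_id=j + 1, rep_rate=float(rates[j]),
                   n_pulses=int(npul[j]), pulse_width=float(widths[j]),
                   pulse_energy=float(energies[j]),
                   start_offset=float(offsets[j]),
                   wavelength_nm=None if np.isnan(wl[j]) else float(wl[j]))
        for j in range(len(rates)))
    return MultiplexScheme(trains, SchemeKind(grp.attrs["kind"]),
                           delta_f=float(grp.attrs["delta_f"]))


def _write_record(grp, record: AcquisitionRecord) -> None:
    grp.attrs["version"] = FORMAT_VERSION
    grp.attrs["sampling_rate"] = record.sampling_rate
    grp.create_dataset("samples", data=record.samples)
    trig = grp.create_group("trigger_times")
    for j, t in enumerate(record.trigger_times):
        trig.create_dataset(f"laser_{j}", data=t)
    _write_scheme(grp.create_group("scheme"), record.scheme)
    for name, series in (("pulse_energy_factors", record.pulse_energy_factors),
                         ("pulse_timing_offsets", record.pulse_timing_offsets)):
        if series is not None:
            sub = grp.create_group(name)
            for j, arr in enumerate(series):
                sub.create_dataset(f"laser_{j}", data=arr)


def _read_record(grp) -> AcquisitionRecord:
    version = grp.attrs.get("version")
    if version != FORMAT_VERSION:
        raise InvalidParameterError(
            f"record container version {version!r} != {FORMAT_VERSION!r}")
    for name in ("samples", "trigger_times", "scheme"):
        if name not in grp:
            raise InvalidParameterError(f"container is missing {name!r}")
    scheme = _read_scheme(grp["scheme"])
    trig = [grp["trigger_times"][f"laser_{j}"][()]
            for j in range(len(grp["trigger_times"]))]
    opt = {}
    for name in ("pulse_energy_factors", "pulse_timing_offsets"):
        if name in grp:
            opt[name] = [grp[name][f"laser_{j}"][()]
                         for j in range(len(grp[name]))]
    return AcquisitionRecord(samples=grp["samples"][()],
                             sampling_rate=float(grp.attrs["sampling_rate"]),
                             scheme=scheme, trigger_times=trig,
                             pulse_energy_factors=opt.get("pulse_energy_factors"),
                             pulse_timing_offsets=opt.get("pulse_timing_offsets"))


def save_record(record: AcquisitionRecord, path) -> None:
    """Write one acquisition record to an HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        _write_record(f, record)


def load_record(path) -> AcquisitionRecord:
    """Read an acquisition record written by :func:`save_record`."""
    with h5py.File(path, "r") as f:
        return _read_record(f)


def save_bscan_records(records: list[AcquisitionRecord], positions, path) -> None:
    """Write a B-scan sweep (one record per lateral position) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.create_dataset("positions", data=np.asarray(positions, dtype=float))
        for i, rec in enumerate(records):
            _write_record(f.create_group(f"position_{i:04d}"), rec)


def load_bscan_records(path) -> tuple[list[AcquisitionRecord], np.ndarray]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != FORMAT_VERSION:
            raise InvalidParameterError("unsupported B-scan container version")
        positions = f["positions"][()]
        records = [_read_record(f[f"position_{i:04d}"])
                   for i in range(len(positions))]
    return records, positions


def save_image_tiff(image: BScanImage, path) -> None:
    """Write a reconstructed B-scan image as a single-page float TIFF."""
    tifffile.imwrite(path, image.data.astype(np.float32))


def design_report_frame(limits: DesignLimits) -> pd.DataFrame:
    """One row per derived design quantity, ready for CSV export."""
    rows = [
        ("dov_m", limits.dov),
        ("t_acq_s", limits.t_acq),
        ("df_hz", limits.df),
        ("k_low", limits.k_low),
        ("k_high", limits.k_high),
        ("n_harmonics", limits.n_harmonics),
        ("delta_f_min_hz", limits.delta_f_min),
        ("delta_f_max_hz", limits.delta_f_max),
        ("n_p_min", limits.n_p_min),
        ("n_max_wavelengths", limits.n_max_wavelengths),
        ("feasible", limits.feasible),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])


# ---------------------------------------------------------------------------
# run configuration (TOML)
# ---------------------------------------------------------------------------

_SCHEMA = {
    "scheme": {"kind", "ref_rep_rate", "delta_f", "n_wavelengths", "n_pulses",
               "pulse_widths", "pulse_energies", "wavelengths_nm"},
    "transducer": {"f_low", "f_high", "center", "fractional_bandwidth",
                   "focal_length", "acceptance_half_angle_deg"},
    "medium": {"speed_of_sound"},
    "noise": {"white_noise_std", "emi_amplitude", "emi_ring_frequency",
              "emi_decay", "energy_jitter_cv", "timing_jitter_std", "seed"},
    "acquisition": {"sampling_rate", "quantize_bits"},
    "phantom": {"depth", "weights", "lateral_position", "reflection_delay",
                "reflection_gain"},
}


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SCHEMA[section]
    if unknown:
        raise InvalidParameterError(
            f"unknown key(s) {sorted(unknown)} in [{section}]")


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise InvalidParameterError(f"cannot serialize {type(v).__name__} to TOML")


@dataclass
class RunConfig:
    """Flat, schema-checked description of one simulation/processing run."""

    scheme: dict
    transducer: dict
    medium: dict = field(default_factory=lambda: {"speed_of_sound": 1500.0})
    noise: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=lambda: {"sampling_rate": 200e6})
    phantom: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("scheme", "transducer", "medium", "noise", "acquisition"):
            _check_keys(name, getattr(self, name))
        for ab in self.phantom:
            _check_keys("phantom", ab)

    # -- construction of model objects --------------------------------------

    def build_scheme(self) -> MultiplexScheme:
        s = self.scheme
        kind = SchemeKind(s.get("kind", "fwm"))
        common = dict(pulse_widths=s.get("pulse_widths", 6.7e-9),
                      pulse_energies=s.get("pulse_energies", 0.0))
        if kind is SchemeKind.FWM:
            return MultiplexScheme.fwm(
                s["ref_rep_rate"], s.get("delta_f", 0.0), s["n_pulses"],
                wavelengths_nm=s.get("wavelengths_nm"),
                n_wavelengths=s.get("n_wavelengths"), **common)
        n = s["n_wavelengths"]
        n_pulses = s["n_pulses"]
        if kind is SchemeKind.TD_INTERLEAVE:
            return MultiplexScheme.td_interleaved(s["ref_rep_rate"], n, n_pulses, **common)
        if kind is SchemeKind.TD_SLOW:
            return MultiplexScheme.td_slow(s["ref_rep_rate"], n, n_pulses * n, **common)
        return MultiplexScheme.td_long(s["ref_rep_rate"], n, n_pulses, **common)

    def build_transducer(self) -> TransducerModel:
        t = self.transducer
        if "center" in t:
            band = TransducerBand.from_center(t["center"], t["fractional_bandwidth"])
        else:
            band = TransducerBand(t["f_low"], t["f_high"])
        kwargs = {}
        if "focal_length" in t:
            kwargs["focal_length"] = t["focal_length"]
        if "acceptance_half_angle_deg" in t:
            kwargs["acceptance_half_angle"] = math.radians(t["acceptance_half_angle_deg"])
        return TransducerModel(band=band, **kwargs)

    def build_medium(self) -> Medium:
        return Medium(**self.medium)

    def build_noise(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def build_phantom(self) -> list[Absorber]:
        out = []
        for ab in self.phantom:
            out.append(Absorber(
                depth=ab["depth"],
                per_wavelength_amplitude=tuple(ab["weights"]),
                lateral_position=ab.get("lateral_position", 0.0),
                reflection_delay=ab.get("reflection_delay"),
                reflection_gain=ab.get("reflection_gain", 0.0)))
        return out

    @property
    def sampling_rate(self) -> float:
        return self.acquisition.get("sampling_rate", 200e6)

    # -- TOML round trip -----------------------------------------------------

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as f:
            data = tomllib.load(f)
        known = {"scheme", "transducer", "medium", "noise", "acquisition", "phantom"}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown section(s) {sorted(unknown)}")
        return cls(scheme=data.get("scheme", {}),
                   transducer=data.get("transducer", {}),
                   medium=data.get("medium", {"speed_of_sound": 1500.0}),
                   noise=data.get("noise", {}),
                   acquisition=data.get("acquisition", {"sampling_rate": 200e6}),
                   phantom=data.get("phantom", []))

    def to_toml(self, path) -> None:
        lines: list[str] = []
        for name in ("scheme", "transducer", "medium", "noise", "acquisition"):
            section = getattr(self, name)
            if not section:
                continue
            lines.append(f"[{name}]")
            for k, v in section.items():
                if v is not None:
                    lines.append(f"{k} = {_toml_scalar(v)}")
            lines.append("")
        for ab in self.phantom:
            lines.append("[[phantom]]")
            for k, v in ab.items():
                if v is not None:
                    lines.append(f"{k} = {_toml_scalar(v)}")
            lines.append("")
        Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# canonical synthetic fixtures
# ---------------------------------------------------------------------------

def _hb_weights(target_v: float = SIGNAL_AMPLITUDE_V) -> tuple[float, ...]:
    """Absorption weights (V/J) that put each wavelength's peak at target_v."""
    return tuple(target_v / e for e in TABLE1["pulse_energies"])


def fixture_suite(seed: int, include=None) -> dict:
    """Deterministic set of canonical synthetic acquisition scenarios.

    Returns a dict of named cases, each a dict holding the record(s), the
    scheme and measurement metadata (signal/noise windows, ground truth).
    ``include`` restricts generation to the named subset.
    """
    names = ("single_wavelength", "td_interleaved", "td_slow", "td_long",
             "fwm_table1", "fwm_crosstalk", "noise_only", "oxygen_challenge")
    if include is not None:
        names = tuple(n for n in names if n in set(include))
    transducer = reference_transducer()
    medium = Medium()
    fs = 200e6
    w_hb = _hb_weights()
    noisy = NoiseModel(white_noise_std=SINGLE_PERIOD_NOISE_V,
                       emi_amplitude=2e-3, emi_decay=80e-9, seed=seed)
    clean = NoiseModel(seed=seed)
    suite: dict[str, dict] = {}

    def windows_for(depth, lo=0.15e-6):
        t = depth / medium.speed_of_sound
        return (t - lo, t + lo)

    if "single_wavelength" in names:
        scheme = MultiplexScheme.fwm(200e3, 0.0, 200,
                                     pulse_energies=TABLE1["pulse_energies"][0],
                                     n_wavelengths=1)
        phantom = [Absorber(depth=2.25e-3, per_wavelength_amplitude=(w_hb[0],),
                            reflection_delay=1.0e-6, reflection_gain=0.25)]
        rec = simulate_record(scheme, phantom, transducer, noisy, medium, fs)
        suite["single_wavelength"] = {
            "record": rec, "scheme": scheme, "phantom": phantom,
            "signal_window": windows_for(2.25e-3),
            "noise_window": (3.5e-6, 4.8e-6)}

    shared = [Absorber(depth=0.9e-3, per_wavelength_amplitude=w_hb)]
    if "td_interleaved" in names:
        scheme = MultiplexScheme.td_interleaved(
            200e3, 4, 200, pulse_widths=list(TABLE1["pulse_widths"]),
            pulse_energies=list(TABLE1["pulse_energies"]))
        rec = simulate_record(scheme, shared, transducer, noisy, medium, fs)
        suite["td_interleaved"] = {"record": rec, "scheme": scheme,
                                   "phantom": shared}
    if "td_slow" in names:
        scheme = MultiplexScheme.td_slow(
            200e3, 4, 200, pulse_widths=list(TABLE1["pulse_widths"]),
            pulse_energies=list(TABLE1["pulse_energies"]))
        rec = simulate_record(scheme, shared, transducer, noisy, medium, fs)
        suite["td_slow"] = {"record": rec, "scheme": scheme, "phantom": shared}
    if "td_long" in names:
        scheme = MultiplexScheme.td_long(
            200e3, 4, 200, pulse_widths=list(TABLE1["pulse_widths"]),
            pulse_energies=list(TABLE1["pulse_energies"]))
        rec = simulate_record(scheme, shared, transducer, noisy, medium, fs)
        suite["td_long"] = {"record": rec, "scheme": scheme, "phantom": shared}

    if "fwm_table1" in names:
        scheme = table1_scheme()
        phantom = [Absorber(depth=2.25e-3, per_wavelength_amplitude=w_hb)]
        rec = simulate_record(scheme, phantom, transducer, noisy, medium, fs)
        suite["fwm_table1"] = {
            "record": rec, "scheme": scheme, "phantom": phantom,
            "signal_window": windows_for(2.25e-3),
            "noise_window": (3.5e-6, 4.8e-6)}

    if "fwm_crosstalk" in names:
        scheme = table1_scheme()
        depths = (0.9e-3, 1.8e-3, 2.7e-3, 3.6e-3)
        phantom = [
            Absorber(depth=d, per_wavelength_amplitude=tuple(
                w_hb[j] if j == i else 0.0 for j in range(4)))
            for i, d in enumerate(depths)]
        rec = simulate_record(scheme, phantom, transducer, clean, medium, fs)
        suite["fwm_crosstalk"] = {
            "record": rec, "scheme": scheme, "phantom": phantom,
            "depths": depths,
            "windows": {i + 1: windows_for(d) for i, d in enumerate(depths)}}

    if "noise_only" in names:
        scheme = MultiplexScheme.fwm(200e3, 0.0, 100, n_wavelengths=1)
        rec = simulate_record(
            scheme, [], transducer,
            NoiseModel(white_noise_std=SINGLE_PERIOD_NOISE_V, seed=seed),
            medium, fs)
        suite["noise_only"] = {"record": rec, "scheme": scheme}

    if "oxygen_challenge" in names:
        # desk-scale two-wavelength series: scaled-down detector band keeps
        # the per-frame cost low while preserving the ratio read-out
        small_tr = TransducerModel(band=TransducerBand.from_center(12.5e6, 1.2),
                                   focal_length=3e-3,
                                   acceptance_half_angle=math.radians(30.0))
        fs_small = 50e6
        # delta_f sits inside the admissible window for N_p = 50 and this band
        scheme = MultiplexScheme.fwm(200e3, 500.0, 50,
                                     pulse_energies=[189e-9, 137e-9],
                                     n_wavelengths=2)
        ratio_artery = np.array([1.0, 1.0, 1.5, 1.5, 1.0, 1.0])
        ratio_vein = np.full_like(ratio_artery, 0.8)
        positions = np.arange(-0.1e-3, 0.11e-3, 0.05e-3)
        frames = []
        w1, w2 = _hb_weights()[:2]   # per-energy normalization: ratio == program
        for i, (ra, rv) in enumerate(zip(ratio_artery, ratio_vein)):
            phantom = [
                Absorber(depth=1.0e-3, per_wavelength_amplitude=(w1, ra * w2)),
                Absorber(depth=1.5e-3, per_wavelength_amplitude=(w1, rv * w2)),
            ]
            frame_noise = NoiseModel(white_noise_std=0.1e-3,
                                     seed=int(np.random.SeedSequence(
                                         [seed, 7, i]).generate_state(1)[0] % (2**31)))
            frames.append(make_bscan(scheme, phantom, positions, small_tr,
                                     frame_noise, medium, fs_small))
        suite["oxygen_challenge"] = {
            "frames": frames, "scheme": scheme, "positions": positions,
            "transducer": small_tr, "sampling_rate": fs_small,
            "artery_window": windows_for(1.0e-3, 0.12e-6),
            "vein_window": windows_for(1.5e-3, 0.12e-6),
            "ratio_artery": ratio_artery, "ratio_vein": ratio_vein}

    logger.info("fixture_suite(seed=%d): generated %s", seed, sorted(suite))
    return suite
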