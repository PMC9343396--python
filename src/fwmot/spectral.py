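"""Per-wavelength intensity analysis: relative oxygenation and channel roles.

With two hemoglobin-weighted wavelengths (one absorbed preferentially by
deoxygenated, one by oxygenated hemoglobin), the ratio of their signal
intensities S2/S1 tracks relative changes of oxygen saturation in a vessel
over time.  From the artery and vein oxygenation traces the oxygen
extraction rate follows as OER = (O_ca - O_cv) / O_ca.  No absolute sO2
estimation is attempted — the method supports relative changes only.

The four-wavelength channel convention maps wavelength 1 to the
deoxyhemoglobin-weighted blue channel, wavelength 2 to the
oxyhemoglobin-weighted blue channel, wavelength 3 to Evans Blue contrast
and wavelength 4 to indocyanine green (ICG) contrast.
"""

from __future__ import annotations

import numpy as np

from .design import InvalidParameterError, _require

__all__ = ["ratio_series", "oer_series", "assign_channels", "CHANNEL_NAMES"]

#: Channel roles by wavelength position, in order.
CHANNEL_NAMES = ("hb", "hbo2", "evans_blue", "icg")

#: Ratio denominators below this fraction of the series maximum are masked.
S1_FLOOR_FRACTION = 0.05


def ratio_series(s1, s2, floor_fraction: float = S1_FLOOR_FRACTION) -> np.ndarray:
    """Elementwise S2/S1 oxygenation-proxy ratio, NaN-masked on weak S1.

    ``s1`` and ``s2`` are same-length signal-intensity series (e.g. peak
    amplitudes per frame).  Entries where s1 falls below ``floor_fraction``
    of its own maximum are returned as NaN to avoid ratio blow-up in
    noise-only frames.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise InvalidParameterError("s1 and s2 must have the same shape")
    _require(0 <= floor_fraction < 1, "floor_fraction must be in [0, 1)")
    floor = floor_fraction * np.max(s1) if s1.size else 0.0
    ok = s1 > max(floor, 0.0)
    out = np.full(s1.shape, np.nan)
    np.divide(s2, s1, out=out, where=ok)
    return out


def oer_series(o_artery, o_vein) -> np.ndarray:
    """Oxygen extraction rate (O_ca - O_cv) / O_ca, NaN where O_ca <= 0."""
    o_a = np.asarray(o_artery, dtype=float)
    o_v = np.asarray(o_vein, dtype=float)
    if o_a.shape != o_v.shape:
        raise InvalidParameterError("artery and vein series must match in shape")
    out = np.full(o_a.shape, np.nan)
    ok = o_a > 0
    np.divide(o_a - o_v, o_a, out=out, where=ok)
    return out


def assign_channels(per_wavelength):
    """Label four per-wavelength results with their contrast roles.

    Pure relabeling, order preserving: input position j (wavelength j+1)
    becomes CHANNEL_NAMES[j].  Exactly four channels are required.
    """
    items = list(per_wavelength)
    if len(items) != len(CHANNEL_NAMES):
        raise InvalidParameterError(
            f"expected {len(CHANNEL_NAMES)} channels, got {len(items)}")
    return dict(zip(CHANNEL_NAMES, items))
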