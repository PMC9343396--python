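"""Delay-and-sum B-scan reconstruction with a conic sensitivity section.

Averaged A-scans collected along a lateral sweep are back-projected onto a
2-D pixel grid: each pixel accumulates, from every scan position whose
acceptance cone contains it, the A-scan amplitude at the one-way delay
distance(pixel, detector)/v_s, and is normalized by the number of
contributing positions.  The detector sensitivity is approximated as a cone
(apex at the focus) along the B-scan direction only.  Linear interpolation
is used between time samples; delays outside the A-scan contribute zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .design import InvalidParameterError, Medium, _require
from .demux import AveragedAScan
from .simulate import TransducerModel

__all__ = ["BScanImage", "backproject", "envelope_image"]


@dataclass
class BScanImage:
    """2-D amplitude image: rows are depth (one-way), columns scan position.

    Pixel (0, 0) sits at the first scan position and zero depth; the axial
    coordinate is v_s * time.
    """

    data: np.ndarray               # (n_depth, n_lateral)
    lateral_positions: np.ndarray  # m
    depths: np.ndarray             # m
    wavelength_id: int = 1

    @property
    def lateral_spacing(self) -> float:
        return float(self.lateral_positions[1] - self.lateral_positions[0]) \
            if len(self.lateral_positions) > 1 else 0.0

    @property
    def axial_spacing(self) -> float:
        return float(self.depths[1] - self.depths[0]) if len(self.depths) > 1 else 0.0


def backproject(ascans: list[AveragedAScan], positions, medium: Medium,
                transducer: TransducerModel, max_depth: float | None = None,
                axial_spacing: float | None = None) -> BScanImage:
    """Delay-and-sum back-projection of per-position A-scans onto a grid.

    The lateral grid coincides with the scan positions; the axial grid spans
    [0, max_depth] (default: the unambiguous depth v_s * period) at
    ``axial_spacing`` (default: one time sample, v_s / sampling_rate).
    """
    positions = np.asarray(positions, dtype=float)
    if len(ascans) == 0 or positions.size == 0:
        raise InvalidParameterError("need at least one A-scan and position")
    _require(len(ascans) == len(positions), "one A-scan per scan position")
    _require(np.all(np.diff(positions) > 0), "positions must be strictly increasing")
    fs = ascans[0].sampling_rate
    v = medium.speed_of_sound
    period = ascans[0].period
    if max_depth is None:
        max_depth = v * period
    _require(max_depth <= v * period * (1 + 1e-9),
             "axial extent exceeds the unambiguous depth of view")
    if axial_spacing is None:
        axial_spacing = v / fs
    depths = np.arange(0.0, max_depth, axial_spacing)
    tan_a = math.tan(transducer.acceptance_half_angle)
    zz = depths[:, None]                       # (nz, 1)
    xx = positions[None, :]                    # (1, nx)
    acc = np.zeros((len(depths), len(positions)))
    cnt = np.zeros_like(acc)
    t_axis = ascans[0].times
    for x_i, a in zip(positions, ascans):
        cone = np.abs(xx - x_i) <= tan_a * np.abs(zz - transducer.focal_length)
        delay = np.hypot(xx - x_i, zz) / v
        vals = np.interp(delay, t_axis, a.samples, left=0.0, right=0.0)
        vals[delay > t_axis[-1]] = 0.0
        acc += np.where(cone, vals, 0.0)
        cnt += cone
    img = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return BScanImage(data=img, lateral_positions=positions, depths=depths,
                      wavelength_id=ascans[0].wavelength_id)


def envelope_image(image: BScanImage) -> BScanImage:
    """Per-column analytic-signal magnitude, normalized to [0, 1].

    Turns the bipolar delay-and-sum output into a single-lobed display
    image; an all-zero input maps to an all-zero output.
    """
    data = image.data
    if not np.any(data):
        env = np.zeros_like(data)
    else:
        env = np.abs(hilbert(data, axis=0))
        env = env / env.max()
    return BScanImage(data=env, lateral_positions=image.lateral_positions,
                      depths=image.depths, wavelength_id=image.wavelength_id)
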