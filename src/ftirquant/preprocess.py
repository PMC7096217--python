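"""Smoothed derivative transform and analysis-window extraction.

Differentiation uses a Savitzky–Golay convolution filter: a local
least-squares polynomial fit whose analytic derivative is evaluated at the
window center.  It reproduces the derivative of any polynomial up to the
fit order exactly and annihilates constant baselines by construction, which
is what makes the downstream band area a clean concentration response.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Channel, Spectrum, is_uniform, transmittance_to_absorbance


class ChannelPolicy(str, Enum):
    """What to differentiate when handed a %T spectrum."""

    USE_ABSORBANCE = "use_absorbance"  # convert %T → A first (Beer–Lambert additive)
    USE_RAW = "use_raw"  # differentiate the stored channel as-is


@dataclass(frozen=True)
class DerivativeConfig:
    """Savitzky–Golay derivative settings.

    window_points : odd filter length in samples (≥ 5); poly_order : local
    polynomial degree; order : derivative order (1 for this method).
    """

    window_points: int = 9
    poly_order: int = 2
    order: int = 1
    channel_policy: ChannelPolicy = ChannelPolicy.USE_ABSORBANCE

    def __post_init__(self):
        if self.window_points < 5 or self.window_points % 2 == 0:
            raise ValueError("window_points must be an odd integer ≥ 5")
        if not (2 <= self.poly_order < self.window_points):
            raise ValueError("poly_order must be in [2, window_points − 1]")
        if not (1 <= self.order <= self.poly_order):
            raise ValueError("order must be in [1, poly_order]")


def first_derivative(s: Spectrum, cfg: DerivativeConfig | None = None) -> Spectrum:
    """Savitzky–Golay derivative of a uniformly gridded spectrum.

    Output has the same length and axis as the input (polynomial edge
    handling), channel ``derivative`` and units intensity per cm⁻¹.
    """
    cfg = cfg or DerivativeConfig()
    if not is_uniform(s):
        raise ValueError(
            "derivative filters need an equispaced grid; call resample_uniform first"
        )
    if cfg.window_points > len(s):
        raise ValueError(
            f"window_points {cfg.window_points} exceeds spectrum length {len(s)}"
        )
    if s.channel is Channel.TRANSMITTANCE_PCT and cfg.channel_policy is ChannelPolicy.USE_ABSORBANCE:
        s = transmittance_to_absorbance(s)
    delta = float(np.diff(s.wavenumbers).mean())
    dy = savgol_filter(
        s.intensities,
        window_length=cfg.window_points,
        polyorder=cfg.poly_order,
        deriv=cfg.order,
        delta=delta,
        mode="interp",
    )
    meta = dict(s.meta)
    meta["sg_window"] = str(cfg.window_points)
    meta["sg_poly"] = str(cfg.poly_order)
    return Spectrum(
        s.wavenumbers.copy(),
        dy,
        channel=Channel.DERIVATIVE,
        derivative_order=cfg.order,
        meta=meta,
    )


def extract_window(s: Spectrum, w) -> Spectrum:
    """Restrict a spectrum to a closed wavenumber interval.

    Endpoints on the grid are included.  ``w`` is any object with ``lo`` and
    ``hi`` attributes (cm⁻¹) or a (lo, hi) pair.
    """
    lo, hi = (w.lo, w.hi) if hasattr(w, "lo") else (float(w[0]), float(w[1]))
    alo, ahi = s.span
    if lo < alo - 1e-9 or hi > ahi + 1e-9:
        raise ValueError(
            f"window [{lo:g}, {hi:g}] outside axis span [{alo:g}, {ahi:g}]"
        )
    mask = (s.wavenumbers >= lo - 1e-9) & (s.wavenumbers <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"window [{lo:g}, {hi:g}] contains fewer than 2 grid points")
    meta = dict(s.meta)
    meta["parent_span"] = f"{alo:g}..{ahi:g}"
    return Spectrum(
        s.wavenumbers[mask].copy(),
        s.intensities[mask].copy(),
        channel=s.channel,
        derivative_order=s.derivative_order,
        meta=meta,
    )
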