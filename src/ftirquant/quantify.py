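"""Band-area response, univariate calibration, and inverse prediction.

The calibration response Y is the area under the first-derivative trace
over a fixed wavenumber window (default 1550–1605 cm⁻¹, the CO stretch of
carboxylic sodium salts).  Because the signed integral of a derivative over
a window enclosing a full band is ≈ 0 by the fundamental theorem of
calculus, the default area mode integrates |y| — the total variation of the
band — which is proportional to concentration under Beer–Lambert behavior.
Calibration is ordinary least squares Y = S·X + b; concentration is
recovered by inverting the fitted line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .preprocess import extract_window
from .spectra import Channel, Spectrum


class AreaMode(str, Enum):
    ABSOLUTE = "absolute"  # ∫|y| dν — total variation, default
    SIGNED = "signed"      # ∫ y dν
    POSITIVE = "positive"  # ∫ max(y, 0) dν


@dataclass(frozen=True)
class BandWindow:
    """Closed wavenumber interval [lo, hi] in cm⁻¹ used for area measurement."""

    lo: float = 1550.0
    hi: float = 1605.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window lo must be < hi, got [{self.lo:g}, {self.hi:g}]")


#: Default quantification window for the carboxylate CO-stretch band.
CO_STRETCH_WINDOW = BandWindow(1550.0, 1605.0)


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # %w/w (X)
    response: float       # band area (Y)

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be ≥ 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted line Y = slope·X + intercept with fit diagnostics.

    residual_sigma is the residual standard deviation S_y/x =
    sqrt(SS_res / (n − 2)), the σ that feeds the LOD/LOQ formulas.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sigma: float
    points: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.points)


def band_area(
    s: Spectrum,
    w: BandWindow | tuple = CO_STRETCH_WINDOW,
    mode: AreaMode | str = AreaMode.ABSOLUTE,
    *,
    allow_non_derivative: bool = False,
) -> float:
    """Trapezoidal band area of a (derivative) spectrum over ``w``."""
    mode = AreaMode(mode)
    if s.channel is not Channel.DERIVATIVE:
        if not allow_non_derivative:
            warnings.warn(
                f"band_area on non-derivative channel '{s.channel.value}'; "
                "pass allow_non_derivative=True to silence",
                stacklevel=2,
            )
    sub = extract_window(s, w)
    y = sub.intensities
    if mode is AreaMode.ABSOLUTE:
        y = np.abs(y)
    elif mode is AreaMode.POSITIVE:
        y = np.clip(y, 0.0, None)
    return float(np.trapezoid(y, sub.wavenumbers))


def fit_calibration(points) -> CalibrationModel:
    """Unweighted OLS of response on concentration.

    Requires ≥ 3 points spanning at least two distinct concentrations.
    On noiseless collinear data the recovered coefficients are exact to
    machine precision, r² = 1 and σ = 0.
    """
    pts = tuple(
        p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points
    )
    if len(pts) < 3:
        raise ValueError(f"need ≥ 3 calibration points, got {len(pts)}")
    x = np.array([p.concentration for p in pts])
    y = np.array([p.response for p in pts])
    if np.unique(x).size < 2:
        raise ValueError("all concentrations identical; design has rank 1")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sigma = float(np.sqrt(ss_res / (len(pts) - 2)))
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        residual_sigma=sigma,
        points=pts,
    )


def write_model(m: CalibrationModel, path) -> None:
    """Persist a calibration model as a flat key=value text file."""
    with open(path, "w") as fh:
        fh.write(f"slope={m.slope!r}\n")
        fh.write(f"intercept={m.intercept!r}\n")
        fh.write(f"r_squared={m.r_squared!r}\n")
        fh.write(f"residual_sigma={m.residual_sigma!r}\n")
        fh.write(f"n={m.n}\n")
        for p in m.points:
            fh.write(f"point={p.concentration!r},{p.response!r}\n")


def read_model(path) -> CalibrationModel:
    """Read a model written by :func:`write_model`."""
    fields: dict[str, float] = {}
    pts: list[CalibrationPoint] = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        if key == "point":
            c, _, r = val.partition(",")
            pts.append(CalibrationPoint(float(c), float(r)))
        elif key != "n":
            fields[key] = float(val)
    try:
        return CalibrationModel(points=tuple(pts), **fields)
    except TypeError as exc:
        raise ValueError(f"{path}: incomplete model file ({exc})") from exc


def predict_response(m: CalibrationModel, concentration: float) -> float:
    """Forward evaluation Y = S·X + b."""
    return m.slope * concentration + m.intercept


def predict_concentration(m: CalibrationModel, response: float) -> float:
    """Inverse prediction X = (Y − b)/S.

    Negative results are returned as-is (a below-range reading) with a
    warning rather than clipped, so recovery arithmetic stays honest.
    """
    if m.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    x = (response - m.intercept) / m.slope
    if x < 0:
        warnings.warn(f"predicted concentration {x:g} %w/w is below range", stacklevel=2)
    return x
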