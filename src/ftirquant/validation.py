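"""ICH Q2-style method-validation metrics.

Covers detection/quantification limits (LOD = 3.3σ/S, LOQ = 10σ/S with σ
the calibration residual standard deviation by default), accuracy as
percent recovery against the claimed content, intra/inter-day precision
(%RSD), a selectivity diagnostic based on the residual band area after
subtracting the scaled pure-analyte trace, and a robustness harness that
re-runs quantification under perturbed processing settings.

Reported percentages follow a truncate-to-2-decimals convention (the
reporting style of pharmacopeial recovery tables); full-precision values
are kept internally and a rounding-mode flag exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .preprocess import first_derivative
from .quantify import (
    AreaMode,
    BandWindow,
    CalibrationModel,
    band_area,
    predict_concentration,
)
from .spectra import Channel, Spectrum

LOQ_LOD_RATIO = 10.0 / 3.3

#: Selectivity scores above this are flagged non-selective in reports.
SELECTIVITY_THRESHOLD = 0.05


class Rounding(str, Enum):
    TRUNCATE2 = "truncate2"
    ROUND2 = "round2"
    FULL = "full"


def report_value(x: float, mode: Rounding | str = Rounding.TRUNCATE2) -> float:
    """Render a percentage for reporting.

    Truncation (not rounding) to 2 decimals is the default table
    convention; a small epsilon guards against binary-float values that sit
    a hair below an exact decimal.
    """
    mode = Rounding(mode)
    if mode is Rounding.FULL:
        return x
    if mode is Rounding.ROUND2:
        return round(x, 2)
    scaled = abs(x) * 100.0 + 1e-9
    return math.copysign(math.floor(scaled) / 100.0, x)


class SigmaDefinition(str, Enum):
    """Which standard deviation feeds the LOD/LOQ formulas."""

    RESIDUAL = "residual"    # S_y/x of the calibration fit (default)
    INTERCEPT = "intercept"  # standard error of the fitted intercept
    EXPLICIT = "explicit"    # caller-supplied (e.g. SD of blank responses)


def _sigma(m: CalibrationModel, definition: SigmaDefinition, explicit: float | None) -> float:
    if definition is SigmaDefinition.EXPLICIT:
        if explicit is None:
            raise ValueError("explicit sigma definition requires a sigma value")
        return float(explicit)
    if definition is SigmaDefinition.INTERCEPT:
        x = np.array([p.concentration for p in m.points])
        if x.size < 3:
            raise ValueError("intercept sigma needs the fitted design points")
        sxx = float(np.sum((x - x.mean()) ** 2))
        return m.residual_sigma * math.sqrt(float(np.sum(x**2)) / (x.size * sxx))
    return m.residual_sigma


def lod(
    m: CalibrationModel,
    *,
    sigma_definition: SigmaDefinition | str = SigmaDefinition.RESIDUAL,
    sigma: float | None = None,
) -> float:
    """Limit of detection, 3.3·σ/S, in %w/w."""
    if m.slope <= 0:
        raise ValueError(f"LOD requires a positive slope, got {m.slope:g}")
    s = _sigma(m, SigmaDefinition(sigma_definition), sigma)
    if s < 0:
        raise ValueError("sigma must be ≥ 0")
    return 3.3 * s / m.slope


def loq(
    m: CalibrationModel,
    *,
    sigma_definition: SigmaDefinition | str = SigmaDefinition.RESIDUAL,
    sigma: float | None = None,
) -> float:
    """Limit of quantification, 10·σ/S = (10/3.3)·LOD, in %w/w."""
    return LOQ_LOD_RATIO * lod(m, sigma_definition=sigma_definition, sigma=sigma)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryRecord:
    """One accuracy replicate: measured vs claimed analyte content."""

    claimed: float   # %w/w nominal
    measured: float  # %w/w recovered

    @property
    def recovery_pct(self) -> float:
        return self.measured / self.claimed * 100.0

    def reported(self, mode: Rounding | str = Rounding.TRUNCATE2) -> float:
        return report_value(self.recovery_pct, mode)


def recovery(claimed: float, measured: float) -> RecoveryRecord:
    """Percent recovery of a spiked/claimed amount; claimed must be > 0."""
    if claimed <= 0:
        raise ValueError(f"claimed content must be > 0, got {claimed:g}")
    return RecoveryRecord(claimed=claimed, measured=measured)


def mean_recovery(records, *, rounding: Rounding | str = Rounding.TRUNCATE2) -> float:
    """Arithmetic mean of recovery percentages, reported to 2 decimals.

    Accepts RecoveryRecord objects or bare percentage values.
    """
    vals = [r.recovery_pct if isinstance(r, RecoveryRecord) else float(r) for r in records]
    if not vals:
        raise ValueError("mean_recovery needs at least one record")
    return report_value(float(np.mean(vals)), rounding)


# ---------------------------------------------------------------------------
# Precision
# ---------------------------------------------------------------------------

class PrecisionLevel(str, Enum):
    INTRA_DAY = "intra_day"  # repeatability: replicate readings within one day
    INTER_DAY = "inter_day"  # intermediate precision: readings across days


@dataclass(frozen=True)
class PrecisionSummary:
    n: int
    mean: float
    sd: float
    rsd_pct: float | None  # None when mean = 0 (undefined)
    level: PrecisionLevel


def precision_summary(values, level: PrecisionLevel | str) -> PrecisionSummary:
    """Mean, sample (n−1) SD and %RSD of replicate readings."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError(f"precision needs ≥ 2 readings, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    rsd = sd / mean * 100.0 if mean != 0 else None
    return PrecisionSummary(n=vals.size, mean=mean, sd=sd, rsd_pct=rsd, level=PrecisionLevel(level))


# ---------------------------------------------------------------------------
# Selectivity
# ---------------------------------------------------------------------------

def selectivity_score(
    api_only: Spectrum,
    formulated: Spectrum,
    w: BandWindow = BandWindow(),
    *,
    concentration_ratio: float = 1.0,
) -> float:
    """Excipient-interference diagnostic on first-derivative spectra.

    Subtracts the pure-analyte derivative trace, scaled by the formulated /
    pure concentration ratio, from the formulated-product trace and reports
    the residual absolute band area relative to the pure-analyte band area.
    Values ≪ 1 mean everything in the window is explained by the analyte
    (a selective window); large values signal in-window interference.
    """
    for s in (api_only, formulated):
        if s.channel is not Channel.DERIVATIVE:
            raise ValueError("selectivity_score expects first-derivative spectra")
    if api_only.wavenumbers.shape != formulated.wavenumbers.shape or not np.allclose(
        api_only.wavenumbers, formulated.wavenumbers
    ):
        raise ValueError("spectra must share one wavenumber grid")
    diff = Spectrum(
        api_only.wavenumbers.copy(),
        formulated.intensities - concentration_ratio * api_only.intensities,
        channel=Channel.DERIVATIVE,
        derivative_order=api_only.derivative_order,
    )
    denom = band_area(api_only, w, AreaMode.ABSOLUTE)
    if denom == 0:
        raise ValueError("pure-analyte band area is zero in the window")
    return band_area(diff, w, AreaMode.ABSOLUTE) / denom


# ---------------------------------------------------------------------------
# Robustness harness
# ---------------------------------------------------------------------------

def robustness_rsd(
    spectrum: Spectrum,
    model: CalibrationModel,
    variants,
    *,
    mode: AreaMode | str = AreaMode.ABSOLUTE,
) -> PrecisionSummary:
    """%RSD of predicted concentration across deliberate setting perturbations.

    ``variants`` is an iterable of (DerivativeConfig, BandWindow) pairs; the
    spectrum is re-derivatized and re-quantified under each.
    """
    preds = []
    for cfg, win in variants:
        d = first_derivative(spectrum, cfg)
        preds.append(predict_concentration(model, band_area(d, win, mode)))
    if len(preds) < 2:
        raise ValueError("robustness needs ≥ 2 perturbation variants")
    return precision_summary(preds, PrecisionLevel.INTRA_DAY)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    model: CalibrationModel
    lod: float
    loq: float
    window: BandWindow = field(default_factory=BandWindow)
    recoveries: dict = field(default_factory=dict)       # sample id → [RecoveryRecord]
    mean_recovery_pct: dict = field(default_factory=dict)
    precision: list = field(default_factory=list)        # [PrecisionSummary]
    selectivity: dict = field(default_factory=dict)      # {"score": float, "selective": bool}
    rounding: Rounding = Rounding.TRUNCATE2

    def render(self) -> str:
        """Plain-text report mirroring the calibration / recovery table layout."""
        L: list[str] = []
        m = self.model
        L.append("Calibration")
        L.append(
            f"  window {self.window.lo:g}-{self.window.hi:g} cm-1 | "
            f"Y = {m.slope:.4g}X {m.intercept:+.4g} | r2 = {m.r_squared:.4f} | n = {m.n}"
        )
        L.append(f"  LOD (%w/w) = {self.lod:.6f}   LOQ (%w/w) = {self.loq:.6f}")
        if self.recoveries:
            L.append("Accuracy (% recovery)")
            L.append("  sample  claimed  measured  recovery")
            for sid, recs in self.recoveries.items():
                for r in recs:
                    L.append(
                        f"  {sid:<7} {r.claimed:<8.3f} {r.measured:<9.3f} "
                        f"{r.reported(self.rounding):.2f}"
                    )
                L.append(f"  {sid:<7} average {self.mean_recovery_pct[sid]:.2f}")
        if self.precision:
            L.append("Precision")
            for p in self.precision:
                rsd = f"{p.rsd_pct:.5f}" if p.rsd_pct is not None else "undefined"
                L.append(
                    f"  {p.level.value:<10} n={p.n} mean={p.mean:.6f} "
                    f"sd={p.sd:.6f} %RSD={rsd}"
                )
        if self.selectivity:
            verdict = "selective" if self.selectivity["selective"] else "NON-SELECTIVE"
            L.append(f"Selectivity  score={self.selectivity['score']:.4f} → {verdict}")
        return "\n".join(L) + "\n"


def build_report(
    model: CalibrationModel,
    *,
    window: BandWindow = BandWindow(),
    recoveries: dict | None = None,
    precision_readings: dict | None = None,
    selectivity: float | None = None,
    sigma_definition: SigmaDefinition | str = SigmaDefinition.RESIDUAL,
    sigma: float | None = None,
    rounding: Rounding | str = Rounding.TRUNCATE2,
) -> ValidationReport:
    """Assemble a full validation report.

    ``recoveries`` maps sample id → list of (claimed, measured) pairs;
    ``precision_readings`` maps (group, level) → list of readings;
    ``selectivity`` is a precomputed selectivity score.
    """
    d = lod(model, sigma_definition=sigma_definition, sigma=sigma)
    q = loq(model, sigma_definition=sigma_definition, sigma=sigma)
    if d > 0:
        assert abs(q / d - LOQ_LOD_RATIO) < 1e-9, "LOQ/LOD ratio invariant violated"
    rounding = Rounding(rounding)
    rec_map: dict = {}
    mean_map: dict = {}
    for sid, pairs in (recoveries or {}).items():
        recs = [recovery(c, m) for c, m in pairs]
        rec_map[sid] = recs
        mean_map[sid] = mean_recovery(recs, rounding=rounding)
    prec = [
        precision_summary(vals, level)
        for (_group, level), vals in (precision_readings or {}).items()
    ]
    sel = (
        {"score": selectivity, "selective": selectivity <= SELECTIVITY_THRESHOLD}
        if selectivity is not None
        else {}
    )
    return ValidationReport(
        model=model,
        lod=d,
        loq=q,
        window=window,
        recoveries=rec_map,
        mean_recovery_pct=mean_map,
        precision=prec,
        selectivity=sel,
        rounding=rounding,
    )
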