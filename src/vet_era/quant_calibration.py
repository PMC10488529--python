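"""Linear calibration arithmetic: LOD/LOQ, RSD, sample quantification.

An unweighted ordinary-least-squares line of peak area on nominal
concentration yields slope p, intercept, R² and the residual standard
deviation σ of the areas (n−2 denominator).  Detection limits follow the
calibration-curve method::

    LOD = 3.3 σ / p        LOQ = 10 σ / p

Samples are back-calculated through the inverted line and flagged
not-detected below LOD, detected-but-not-quantifiable in [LOD, LOQ).
Weighted fits (1/x, 1/x²) are available for wide calibration ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from vet_era.units import Conc, convert

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0

DETECTION_STATES = ("not_detected", "detected_not_quantifiable", "quantified")


@dataclass(frozen=True)
class CalibrationSeries:
    """Calibration levels: (nominal concentration ng/L, replicate areas)."""

    levels: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.levels]
        if len(set(concs)) < 2:
            raise ValueError("need at least 2 distinct calibration concentrations")
        if any(c <= 0 for c in concs):
            raise ValueError("calibration concentrations must be strictly positive")
        if any(len(areas) == 0 for _, areas in self.levels):
            raise ValueError("every level needs at least one replicate area")

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([c for c, areas in self.levels for _ in areas], dtype=float)
        y = np.array([a for _, areas in self.levels for a in areas], dtype=float)
        return x, y


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line with its detection limits."""

    slope_p: float  # area per ng/L
    intercept: float  # area
    r_squared: float
    sigma_resid: float  # residual SD of areas, n-2 denominator
    lod: float  # ng/L
    loq: float  # ng/L
    n_points: int = 0
    saturated: bool = False  # n == 2: residual SD undefined, set to 0

    def predict(self, concentration: float) -> float:
        """Expected peak area at a concentration (ng/L)."""
        return self.slope_p * concentration + self.intercept


@dataclass(frozen=True)
class MeasuredConcentration:
    """A back-calculated sample concentration with its detection state."""

    sample_id: str
    analyte: str
    value: float  # ng/L; raw back-calculated estimate (may be < LOD)
    status: str  # not_detected | detected_not_quantifiable | quantified
    area: float
    retention_time: Optional[float] = None

    @property
    def detected(self) -> bool:
        return self.status != "not_detected"

    def as_conc(self, unit: str = "ng/L") -> Conc:
        return Conc(convert(self.value, "ng/L", unit), unit)


def fit_calibration(
    series: CalibrationSeries, weighting: str | None = None
) -> CalibrationFit:
    """Least-squares fit of area on concentration.

    ``weighting`` of ``None`` (default), ``"1/x"`` or ``"1/x2"`` selects the
    regression weights.  R² is the squared Pearson correlation of area with
    concentration; σ is the residual SD with an n−2 denominator.  With only
    two points the fit is saturated: σ is set to 0 and flagged.
    """
    x, y = series.flatten()
    n = len(x)
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1.0 / x
    elif weighting == "1/x2":
        w = 1.0 / x**2
    else:
        raise ValueError(f"unknown weighting {weighting!r} (use None, '1/x' or '1/x2')")

    # weighted OLS via the normal equations
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    saturated = n <= 2
    if saturated:
        sigma = 0.0
    else:
        sigma = math.sqrt(float((resid**2).sum()) / (n - 2))

    # R² as squared Pearson correlation (unweighted, as commonly reported)
    ssy = float(((y - y.mean()) ** 2).sum())
    if ssy == 0:
        r2 = 1.0
    else:
        sxx_u = float(((x - x.mean()) ** 2).sum())
        sxy_u = float(((x - x.mean()) * (y - y.mean())).sum())
        r2 = sxy_u**2 / (sxx_u * ssy)

    # detection limits undefined for a flat or inverted response
    has_limits = slope > 0
    return CalibrationFit(
        slope_p=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        sigma_resid=sigma,
        lod=lod(sigma, float(slope)) if has_limits else math.nan,
        loq=loq(sigma, float(slope)) if has_limits else math.nan,
        n_points=n,
        saturated=saturated,
    )


def lod(sigma: float, slope_p: float) -> float:
    """Limit of detection (ng/L): 3.3 σ / p."""
    if slope_p <= 0:
        raise ValueError("calibration slope must be strictly positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return LOD_FACTOR * sigma / slope_p


def loq(sigma: float, slope_p: float) -> float:
    """Limit of quantification (ng/L): 10 σ / p."""
    if slope_p <= 0:
        raise ValueError("calibration slope must be strictly positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return LOQ_FACTOR * sigma / slope_p


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 · sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * float(arr.std(ddof=1)) / float(mean)


def precision_check(values: Sequence[float], limit_percent: float = 10.0) -> bool:
    """True iff the RSD of ``values`` is below the precision limit."""
    return rsd(values) < limit_percent


def quantify(
    area: float,
    fit: CalibrationFit,
    sample_id: str = "",
    analyte: str = "",
    retention_time: Optional[float] = None,
) -> MeasuredConcentration:
    """Back-calculate a sample concentration from its peak area.

    The raw estimate (area − intercept)/slope is always carried; the
    detection state classifies it against the fit's LOD and LOQ.
    """
    if fit.slope_p <= 0:
        raise ValueError("calibration slope must be strictly positive")
    value = (area - fit.intercept) / fit.slope_p
    if value < fit.lod:
        status = "not_detected"
    elif value < fit.loq:
        status = "detected_not_quantifiable"
    else:
        status = "quantified"
    return MeasuredConcentration(
        sample_id=sample_id,
        analyte=analyte,
        value=value,
        status=status,
        area=area,
        retention_time=retention_time,
    )


@dataclass(frozen=True)
class MecComparison:
    """Measured vs predicted concentration ratios for one water sample."""

    mec_over_pec: float
    mec_over_pnec: float
    measured_below_predicted: bool
    measured_risk_acceptable: bool  # MEC/PNEC < 1


def mec_compare(mec: Conc, pec_sw: Conc, pnec_water: Conc) -> MecComparison:
    """Compare a measured surface-water concentration with PEC and PNEC.

    All three are normalized to mg/L; denominators must be positive.
    """
    mec_mgL = convert(mec.value, mec.unit, "mg/L")
    pec_mgL = convert(pec_sw.value, pec_sw.unit, "mg/L")
    pnec_mgL = convert(pnec_water.value, pnec_water.unit, "mg/L")
    if pec_mgL <= 0 or pnec_mgL <= 0:
        raise ValueError("PEC and PNEC denominators must be strictly positive")
    return MecComparison(
        mec_over_pec=mec_mgL / pec_mgL,
        mec_over_pnec=mec_mgL / pnec_mgL,
        measured_below_predicted=mec_mgL < pec_mgL,
        measured_risk_acceptable=mec_mgL / pnec_mgL < 1,
    )
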