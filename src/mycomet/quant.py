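"""Calibration, matrix-effect (SSE) correction and replicate quantification.

Implements the standard external-calibration workflow for ESI-LC-MS
quantification in a suppressing matrix: fit a linear calibration in neat
solvent, fit matrix-matched (spiked-extract) calibrations, express the
matrix effect as the slope ratio

    SSE (%) = slope_spiked / slope_solvent * 100,

back-calculate extract concentrations from the solvent curve, divide by
SSE/100 to undo suppression, convert to per-sample content (ug/kg) from the
extraction volume and sample mass, and summarize replicates as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np

__all__ = [
    "CalibrationLevel",
    "CalibrationFit",
    "MatrixEffect",
    "QuantResult",
    "fit_calibration",
    "compute_sse",
    "replicate_sse",
    "back_calculate",
    "matrix_correct",
    "to_ug_per_kg",
    "replicate_summary",
    "quantify_sample",
]


@dataclass(frozen=True)
class CalibrationLevel:
    """One calibration point: nominal concentration (ng/mL) vs response."""

    nominal_concentration: float
    response: float
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.nominal_concentration <= 0:
            raise ValueError("nominal concentration must be positive")
        if self.response < 0:
            raise ValueError("response must be non-negative")


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares calibration line and its Pearson correlation."""

    slope: float
    intercept: float
    correlation_r: float
    n_points: int


@dataclass(frozen=True)
class MatrixEffect:
    """Signal suppression/enhancement as a percentage of the solvent slope.

    SSE < 100 means suppression; ``sse_sd`` is the spread over replicate
    spiked curves when available.
    """

    sse_percent: float
    sse_sd: float | None = None

    def __post_init__(self) -> None:
        if self.sse_percent <= 0:
            raise ValueError("SSE percent must be positive")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one sample from replicate responses."""

    extract_concentration: float  # ng/mL against the solvent curve
    matrix_corrected_concentration: float  # ng/mL after SSE correction
    per_sample_concentration: float  # ug/kg
    below_loq: bool = False


def fit_calibration(
    levels: list[CalibrationLevel], weighting: str | None = None
) -> CalibrationFit:
    """Least-squares fit of response on nominal concentration.

    ``weighting`` is None (ordinary least squares, the default) or ``"1/x"``
    (weights inversely proportional to concentration, common when low-end
    accuracy matters). Raises on fewer than two points or a design with a
    single distinct concentration. The reported correlation is Pearson's r
    between concentration and response (matching the convention of
    reporting a calibration "R" close to 1 for a good line).
    """
    if len(levels) < 2:
        raise ValueError("calibration requires at least two points")
    x = np.array([lv.nominal_concentration for lv in levels], dtype=float)
    y = np.array([lv.response for lv in levels], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all concentrations identical")
    if weighting is None:
        w = None
    elif weighting == "1/x":
        w = np.sqrt(1.0 / x)  # np.polyfit weights multiply the residuals
    else:
        raise ValueError(f"unknown weighting scheme: {weighting!r}")
    slope, intercept = np.polyfit(x, y, 1, w=w)
    sy = y.std()
    r = 1.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1])
    return CalibrationFit(float(slope), float(intercept), r, len(levels))


def compute_sse(spiked: CalibrationFit, solvent: CalibrationFit) -> MatrixEffect:
    """Matrix effect from one spiked-extract curve and one solvent curve."""
    if solvent.slope == 0:
        raise ValueError("solvent calibration slope must be nonzero")
    return MatrixEffect(sse_percent=spiked.slope / solvent.slope * 100.0)


def replicate_sse(
    spiked_replicates: list[list[CalibrationLevel]],
    solvent: CalibrationFit,
) -> MatrixEffect:
    """SSE mean +/- SD over replicate spiked-extract curves.

    Each replicate curve is fitted separately against the same (mean)
    solvent fit; the spread of per-replicate SSE values gives ``sse_sd``
    (sample SD, n-1 denominator; None for a single replicate).
    """
    if not spiked_replicates:
        raise ValueError("at least one spiked replicate curve is required")
    values = [
        compute_sse(fit_calibration(levels), solvent).sse_percent
        for levels in spiked_replicates
    ]
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return MatrixEffect(sse_percent=fmean(values), sse_sd=sd)


def back_calculate(response: float, fit: CalibrationFit) -> float:
    """Inverse prediction: concentration = (response - intercept) / slope."""
    if fit.slope == 0:
        raise ValueError("cannot back-calculate with zero slope")
    return (response - fit.intercept) / fit.slope


def matrix_correct(extract_concentration: float, me: MatrixEffect) -> float:
    """Undo matrix suppression for a solvent-curve concentration.

    With suppression (SSE < 100%) the solvent curve under-reads the matrix
    sample, so the correction divides by SSE/100 and moves the value up.
    """
    return extract_concentration / (me.sse_percent / 100.0)


def to_ug_per_kg(
    extract_concentration: float, extract_volume_ml: float, sample_mass_g: float
) -> float:
    """Convert an extract concentration (ng/mL) to sample content (ug/kg).

    ng/mL x mL / g = ng/g, and ng/g is numerically ug/kg. The sample mass is
    a required input: it depends on how much material was extracted and has
    no sensible default.
    """
    if extract_volume_ml <= 0 or sample_mass_g <= 0:
        raise ValueError("extract volume and sample mass must be positive")
    return extract_concentration * extract_volume_ml / sample_mass_g


def replicate_summary(values: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1) of replicates."""
    if len(values) < 2:
        raise ValueError("replicate summary requires at least two values")
    return fmean(values), float(np.std(values, ddof=1))


def quantify_sample(
    responses: list[float],
    solvent_fit: CalibrationFit,
    matrix_effect: MatrixEffect,
    extract_volume_ml: float,
    sample_mass_g: float,
) -> list[QuantResult]:
    """Full quantification of one sample's replicate responses.

    Each response is back-calculated on the solvent curve, matrix-corrected,
    and converted to ug/kg. Negative back-calculated concentrations (below
    the calibration intercept) are clamped to 0 and flagged ``below_loq``.
    """
    out = []
    for resp in responses:
        conc = back_calculate(resp, solvent_fit)
        below = conc < 0
        conc = max(conc, 0.0)
        corrected = matrix_correct(conc, matrix_effect)
        out.append(
            QuantResult(
                extract_concentration=conc,
                matrix_corrected_concentration=corrected,
                per_sample_concentration=to_ug_per_kg(
                    corrected, extract_volume_ml, sample_mass_g
                ),
                below_loq=below,
            )
        )
    return out
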