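"""Differential peak screening: sample extract versus blank-medium control.

Centroided chromatographic features (retention time, m/z, intensity) from a
culture extract are compared against the same feature list from an
uninoculated-medium control; features with no control match within retention
time and m/z tolerances are reported as candidate fungal metabolites,
ordered by descending intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ChromPeak", "MatchTolerances", "match_peak", "differential_peaks"]


@dataclass(frozen=True)
class ChromPeak:
    """One detected chromatographic feature."""

    retention_time: float  # minutes
    mz: float  # Da
    intensity: float  # arbitrary detector units

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValueError("retention time must be non-negative")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class MatchTolerances:
    """Tolerances deciding whether two features are the same compound.

    ``rt_tolerance`` in minutes, ``mz_tolerance`` in ppm of the feature m/z,
    ``min_intensity`` an optional floor below which sample features are
    ignored (None applies no floor).
    """

    rt_tolerance: float = 0.2
    mz_tolerance: float = 10.0
    min_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.rt_tolerance <= 0 or self.mz_tolerance <= 0:
            raise ValueError("tolerances must be strictly positive")
        if self.min_intensity is not None and self.min_intensity <= 0:
            raise ValueError("min_intensity must be positive when set")


def match_peak(
    p: ChromPeak, peaks: list[ChromPeak], tol: MatchTolerances
) -> ChromPeak | None:
    """Closest in-tolerance match of ``p`` among ``peaks``, or None.

    Closeness is the normalized squared distance
    ``(d_rt/rt_tol)^2 + (d_mz/mz_tol)^2`` with the m/z difference expressed
    in ppm of the query m/z.
    """
    best, best_d = None, None
    for q in peaks:
        d_rt = abs(q.retention_time - p.retention_time)
        d_ppm = abs(q.mz - p.mz) / p.mz * 1e6
        if d_rt > tol.rt_tolerance or d_ppm > tol.mz_tolerance:
            continue
        d = (d_rt / tol.rt_tolerance) ** 2 + (d_ppm / tol.mz_tolerance) ** 2
        if best_d is None or d < best_d:
            best, best_d = q, d
    return best


def differential_peaks(
    sample: list[ChromPeak],
    control: list[ChromPeak],
    tol: MatchTolerances | None = None,
) -> list[ChromPeak]:
    """Sample features absent from the control, by descending intensity.

    A feature is "novel" when it passes the intensity floor (if any) and has
    no control feature within both tolerances.
    """
    tol = tol or MatchTolerances()
    out = [
        p
        for p in sample
        if (tol.min_intensity is None or p.intensity >= tol.min_intensity)
        and match_peak(p, control, tol) is None
    ]
    return sorted(out, key=lambda p: -p.intensity)
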