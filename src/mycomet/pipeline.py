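"""End-to-end pipeline: screen -> predict formula -> annotate fragments ->
(optionally) quantify.

The pipeline consumes centroided sample/control peak tables, per-peak MSn
spectra and an optional calibration table, and emits a single JSON report
plus per-stage TSVs. Every stage logs its parameters and result counts to
stderr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import io as mio
from .formula import SearchConstraints, enumerate_candidates
from .fragments import FragmentObservation, build_tree
from .quant import (
    fit_calibration,
    quantify_sample,
    replicate_sse,
    replicate_summary,
)
from .screening import ChromPeak, MatchTolerances, differential_peaks

logger = logging.getLogger("mycomet")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_KNOWN_KEYS = {
    "sample_peaks",
    "control_peaks",
    "spectra",
    "calibration",
    "sample_responses",
    "extract_volume_ml",
    "sample_mass_g",
    "rt_tolerance",
    "mz_tolerance",
    "min_intensity",
    "ppm_tolerance",
    "fragment_tolerance_mda",
    "isolation_width_da",
    "seed",
    "output_dir",
}


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Paths may be None when a stage is not exercised (e.g. no calibration
    table means no quantification stage). ``from_dict`` rejects unknown
    keys so that typos in config files fail loudly.
    """

    sample_peaks: str | Path | None = None
    control_peaks: str | Path | None = None
    spectra: str | Path | None = None  # MGF or CSV of MSn observations
    calibration: str | Path | None = None
    sample_responses: list[float] = field(default_factory=list)
    extract_volume_ml: float = 0.5
    sample_mass_g: float | None = None
    rt_tolerance: float = 0.2
    mz_tolerance: float = 10.0
    min_intensity: float | None = None
    ppm_tolerance: float = 10.0
    fragment_tolerance_mda: float = 5.0
    isolation_width_da: float = 1.0
    seed: int = 0
    output_dir: str | Path | None = None

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _read_spectra(path: str | Path):
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        return mio.read_spectra_mgf(path)
    return mio.read_spectra_csv(path)


def run_pipeline(
    config: PipelineConfig,
    sample: list[ChromPeak] | None = None,
    control: list[ChromPeak] | None = None,
    ms2: list[FragmentObservation] | None = None,
    ms3: dict[float, list[FragmentObservation]] | None = None,
) -> dict[str, Any]:
    """Run the full annotation pipeline and return the JSON-able report.

    Inputs may be passed in memory (``sample``/``control``/``ms2``/``ms3``)
    or resolved from the file paths in ``config``. Stages:

    1. differential screening of sample vs control features;
    2. formula enumeration for each novel feature ([M+H]+, ppm window);
    3. fragment-tree annotation for each feature whose precursor m/z
       matches an MS2 block within the isolation width, using the top-ranked
       formula;
    4. quantification, when a calibration table and sample responses are
       configured.

    Writes per-stage TSVs and ``report.json`` under ``config.output_dir``
    when set. Raises :class:`PipelineError` naming the failing stage.
    """
    report: dict[str, Any] = {"parameters": {
        "rt_tolerance": config.rt_tolerance,
        "mz_tolerance": config.mz_tolerance,
        "ppm_tolerance": config.ppm_tolerance,
        "fragment_tolerance_mda": config.fragment_tolerance_mda,
        "seed": config.seed,
    }}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # stage 1: screening
    try:
        if sample is None:
            sample = mio.read_peak_table(config.sample_peaks)
        if control is None:
            control = mio.read_peak_table(config.control_peaks)
        tol = MatchTolerances(
            config.rt_tolerance, config.mz_tolerance, config.min_intensity
        )
        novel = differential_peaks(sample, control, tol)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"screening: {exc}") from exc
    logger.info(
        "screening: %d sample, %d control features -> %d novel",
        len(sample), len(control), len(novel),
    )
    report["n_sample_peaks"] = len(sample)
    report["n_control_peaks"] = len(control)
    report["novel_peaks"] = []
    if outdir:
        mio.write_peak_table(novel, outdir / "novel_peaks.csv")

    # stage 2+3: per-peak formula inference and fragment annotation
    if ms2 is None and ms3 is None and config.spectra:
        try:
            ms2, ms3 = _read_spectra(config.spectra)
        except Exception as exc:
            raise PipelineError(f"spectra input: {exc}") from exc
    ms2 = ms2 or []
    ms3 = ms3 or {}

    constraints = SearchConstraints(ppm_tolerance=config.ppm_tolerance)
    for i, peak in enumerate(novel, start=1):
        entry: dict[str, Any] = {
            "rt_min": peak.retention_time,
            "mz": peak.mz,
            "intensity": peak.intensity,
        }
        try:
            candidates = enumerate_candidates(peak.mz, constraints)
        except Exception as exc:
            raise PipelineError(f"formula inference: {exc}") from exc
        entry["candidates"] = [
            {
                "rank": c.rank,
                "formula": c.formula.hill(),
                "theoretical_mz": c.theoretical_mz,
                "ppm_error": c.ppm_error,
                "rdbe": c.rdbe,
                "total_score": c.total_score,
            }
            for c in candidates
        ]
        logger.info(
            "formula inference: m/z %.4f -> %d candidates", peak.mz, len(candidates)
        )
        if outdir:
            mio.write_candidates_tsv(candidates, outdir / f"candidates_peak{i}.tsv")

        peak_ms2 = [
            o for o in ms2
            if abs(o.precursor_mz - peak.mz) <= config.isolation_width_da
        ]
        if candidates and peak_ms2:
            best = candidates[0]
            peak_ms3 = {
                sel: obs
                for sel, obs in ms3.items()
                if any(
                    abs(o.fragment_mz - sel) <= config.isolation_width_da
                    for o in peak_ms2
                )
            }
            try:
                tree = build_tree(
                    peak.mz,
                    best.formula,
                    peak_ms2,
                    peak_ms3,
                    tolerance_mda=config.fragment_tolerance_mda,
                    isolation_width_da=config.isolation_width_da,
                )
            except Exception as exc:
                raise PipelineError(f"fragment annotation: {exc}") from exc
            entry["fragment_tree"] = mio.tree_to_dict(tree)
            n_assigned = sum(1 for n in tree.all_nodes() if n.assigned)
            logger.info(
                "fragment annotation: m/z %.4f -> %d/%d fragments assigned",
                peak.mz, n_assigned, len(tree.all_nodes()),
            )
            if outdir:
                mio.write_tree_tsv(tree, outdir / f"fragments_peak{i}.tsv")
        report["novel_peaks"].append(entry)

    # stage 4: quantification
    if config.calibration:
        try:
            solvent_levels, spiked_curves = mio.read_calibration(config.calibration)
            solvent_fit = fit_calibration(solvent_levels)
            me = replicate_sse(spiked_curves, solvent_fit) if spiked_curves else None
            quant: dict[str, Any] = {
                "solvent_slope": solvent_fit.slope,
                "solvent_intercept": solvent_fit.intercept,
                "solvent_correlation_r": solvent_fit.correlation_r,
            }
            if me:
                quant["sse_percent"] = me.sse_percent
                quant["sse_sd"] = me.sse_sd
            if config.sample_responses and me:
                if config.sample_mass_g is None:
                    raise ValueError("sample_mass_g is required for quantification")
                results = quantify_sample(
                    config.sample_responses,
                    solvent_fit,
                    me,
                    config.extract_volume_ml,
                    config.sample_mass_g,
                )
                values = [r.per_sample_concentration for r in results]
                quant["per_replicate_ug_per_kg"] = values
                if len(values) >= 2:
                    mean, sd = replicate_summary(values)
                    quant["mean_ug_per_kg"] = mean
                    quant["sd_ug_per_kg"] = sd
            report["quantification"] = quant
            logger.info("quantification: %s", quant)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"quantification: {exc}") from exc

    if outdir:
        mio.write_json_report(report, outdir / "report.json")
    return report
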