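"""Synthetic ESI+ MSn spectra, sample/control feature lists and calibration
data with the statistical structure the pipeline assumes.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_msn` — [M+H]+ spectra of a known formula with its
  theoretical isotope pattern, ppm-scale Gaussian mass error, and MS2/MS3
  fragments defined by neutral-loss formula paths;
* :func:`simulate_sample_and_control` — a shared background feature
  population (the blank-medium control) plus one spiked feature per
  compound in the sample, with ground-truth labels;
* :func:`simulate_calibration_pair` — linear solvent and spiked-extract
  calibration curves related by a multiplicative suppression factor, with
  multiplicative response noise.

Noise models: mass error is additive Gaussian in ppm; abundance and response
noise are multiplicative Gaussian, truncated at -90% to preserve positivity.
Background features are uniform over the 14-min gradient and the 150-1000 Da
scan range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import (
    ELECTRON_MASS,
    ElementalFormula,
    IonSpecies,
    ion_mz,
    isotope_pattern,
    monoisotopic_mass,
    parse_formula,
)
from .fragments import FragmentObservation
from .quant import CalibrationLevel
from .screening import ChromPeak

__all__ = [
    "SpectrumSimSpec",
    "CalibrationSimSpec",
    "REFERENCE_COMPOUNDS",
    "reference_calibration_spec",
    "simulate_msn",
    "simulate_sample_and_control",
    "simulate_calibration_pair",
]


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Recipe for one compound's simulated [M+H]+ MSn data.

    ``loss_paths`` is a list of ordered neutral-loss formula lists; a
    one-element path produces an MS2 fragment, a two-element path produces
    an MS2 fragment (first loss) and an MS3 fragment under it (second loss).
    ``mass_error_ppm_sd`` perturbs every generated m/z independently.
    """

    name: str
    compound_formula: ElementalFormula
    loss_paths: tuple[tuple[ElementalFormula, ...], ...] = ()
    retention_time: float = 5.0
    mass_error_ppm_sd: float = 0.0
    isotope_peaks: int = 3
    abundance_noise_cv: float = 0.0
    intensity: float = 1e6

    def __post_init__(self) -> None:
        if self.mass_error_ppm_sd < 0 or self.abundance_noise_cv < 0:
            raise ValueError("noise levels must be non-negative")
        comp = IonSpecies(self.compound_formula).composition
        for path in self.loss_paths:
            running = comp
            for loss in path:
                if not running.contains(loss):
                    raise ValueError(
                        f"{self.name}: loss path {'+'.join(map(str, path))} "
                        "infeasible from precursor"
                    )
                running = running - loss


@dataclass(frozen=True)
class CalibrationSimSpec:
    """Recipe for a solvent / spiked-extract calibration pair.

    Defaults mirror the reference study design: solvent standards at
    31.25-1000 ng/mL, matrix-matched standards at 125-2000 ng/mL in
    triplicate, matrix suppression factor 0.552 (SSE 55.2%), 2% response
    noise.
    """

    solvent_slope: float = 1.0
    intercept: float = 0.0
    suppression_factor: float = 0.552
    noise_cv: float = 0.02
    solvent_levels: tuple[float, ...] = (31.25, 62.5, 125.0, 250.0, 500.0, 1000.0)
    spiked_levels: tuple[float, ...] = (125.0, 250.0, 500.0, 1000.0, 2000.0)
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.solvent_slope <= 0 or self.suppression_factor <= 0:
            raise ValueError("slopes and suppression factor must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _truncated_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise factor 1 + N(0, cv), truncated at -90%."""
    return np.maximum(1.0 + rng.normal(0.0, cv, size=size), 0.1) if cv > 0 else (
        np.ones(size) if size is not None else 1.0
    )


def _perturb_ppm(rng: np.random.Generator, mz: float, sd_ppm: float) -> float:
    if sd_ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sd_ppm) * 1e-6)


def simulate_msn(
    spec: SpectrumSimSpec, seed: int | np.random.Generator = 0
) -> tuple[list[tuple[float, float]], list[FragmentObservation], dict[float, list[FragmentObservation]]]:
    """Simulate one compound's MS1 isotope peaks, MS2 list and MS3 map.

    Returns ``(ms1_peaks, ms2, ms3)`` where ``ms1_peaks`` is the [M+H]+
    isotope pattern as (m/z, intensity) pairs (base peak at ``intensity``),
    ``ms2`` a list of fragment observations, and ``ms3`` a map from the
    selected MS2 ion m/z (as generated) to its MS3 fragment list.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ion = IonSpecies(spec.compound_formula)
    comp = ion.composition
    precursor_mz = _perturb_ppm(rng, ion_mz(ion), spec.mass_error_ppm_sd)

    pattern = isotope_pattern(comp, max_peaks=spec.isotope_peaks, charge=1)
    ms1 = []
    for mz, abund in pattern.peaks:
        mz_obs = _perturb_ppm(rng, mz, spec.mass_error_ppm_sd)
        inten = spec.intensity * abund * float(_truncated_factor(rng, spec.abundance_noise_cv))
        ms1.append((mz_obs, inten))

    ms2: list[FragmentObservation] = []
    ms3: dict[float, list[FragmentObservation]] = {}
    seen_ms2: dict[ElementalFormula, float] = {}
    for path in spec.loss_paths:
        running = comp
        parent_mz = precursor_mz
        for depth, loss in enumerate(path):
            running = running - loss
            theo = (monoisotopic_mass(running) - ELECTRON_MASS)
            obs_mz = _perturb_ppm(rng, theo, spec.mass_error_ppm_sd)
            inten = spec.intensity * 0.5 ** (depth + 1) * float(
                _truncated_factor(rng, spec.abundance_noise_cv)
            )
            if depth == 0:
                if running in seen_ms2:
                    parent_mz = seen_ms2[running]
                else:
                    ms2.append(FragmentObservation(2, precursor_mz, obs_mz, inten))
                    seen_ms2[running] = obs_mz
                    parent_mz = obs_mz
            else:
                ms3.setdefault(parent_mz, []).append(
                    FragmentObservation(2 + depth, parent_mz, obs_mz, inten)
                )
                parent_mz = obs_mz
    return ms1, ms2, ms3


@dataclass(frozen=True)
class BackgroundSpec:
    """Shared background feature population (blank culture medium)."""

    n_peaks: int = 50
    rt_range: tuple[float, float] = (0.0, 14.0)
    mz_range: tuple[float, float] = (150.0, 1000.0)
    intensity_range: tuple[float, float] = (1e4, 1e6)


def simulate_sample_and_control(
    compounds: list[SpectrumSimSpec],
    background: BackgroundSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ChromPeak], list[ChromPeak], list[ChromPeak]]:
    """Simulate a sample/control feature-list pair with ground truth.

    The control contains only the background features; the sample contains
    the *same realized* background plus one feature per compound at its
    (noise-perturbed) [M+H]+ m/z and retention time. Returns
    ``(sample, control, spiked_truth)`` where ``spiked_truth`` lists the
    spiked features exactly as they appear in the sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    background = background or BackgroundSpec()
    control = []
    for _ in range(background.n_peaks):
        control.append(
            ChromPeak(
                retention_time=float(rng.uniform(*background.rt_range)),
                mz=float(rng.uniform(*background.mz_range)),
                intensity=float(rng.uniform(*background.intensity_range)),
            )
        )
    spiked = []
    for spec in compounds:
        mz = _perturb_ppm(rng, ion_mz(IonSpecies(spec.compound_formula)), spec.mass_error_ppm_sd)
        spiked.append(
            ChromPeak(
                retention_time=spec.retention_time,
                mz=mz,
                intensity=spec.intensity,
            )
        )
    sample = control + spiked
    return sample, control, spiked


def simulate_calibration_pair(
    spec: CalibrationSimSpec, seed: int | np.random.Generator = 0
) -> tuple[list[CalibrationLevel], list[list[CalibrationLevel]]]:
    """Simulate a solvent curve and replicate spiked-extract curves.

    Solvent responses follow ``slope * c + intercept`` and spiked responses
    ``suppression * slope * c + intercept``, each multiplied by independent
    ``1 + N(0, noise_cv)`` factors. Returns ``(solvent_levels,
    spiked_replicate_curves)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    solvent = [
        CalibrationLevel(
            c,
            (spec.solvent_slope * c + spec.intercept)
            * float(_truncated_factor(rng, spec.noise_cv)),
            replicate_id=1,
        )
        for c in spec.solvent_levels
    ]
    spiked = []
    for rep in range(1, spec.replicates + 1):
        spiked.append(
            [
                CalibrationLevel(
                    c,
                    (spec.suppression_factor * spec.solvent_slope * c + spec.intercept)
                    * float(_truncated_factor(rng, spec.noise_cv)),
                    replicate_id=rep,
                )
                for c in spec.spiked_levels
            ]
        )
    return solvent, spiked


def _paths(*specs: str) -> tuple[tuple[ElementalFormula, ...], ...]:
    return tuple(tuple(parse_formula(p) for p in path.split("+")) for path in specs)


#: Worked-example compounds: the three metabolites characterized in a
#: G. smithogilvyi (chestnut brown rot fungus) extract study, with their
#: published CID neutral-loss pathways.
REFERENCE_COMPOUNDS: tuple[SpectrumSimSpec, ...] = (
    SpectrumSimSpec(
        name="adenosine",
        compound_formula=parse_formula("C10H13N5O4"),
        loss_paths=_paths("C5H8O4"),
        retention_time=3.4,
    ),
    SpectrumSimSpec(
        name="oxasetin",
        compound_formula=parse_formula("C21H29NO4"),
        loss_paths=_paths(
            "C2H4O", "C4H8O2", "C4H8O2+C2H4O", "C4H8O2+C4H10O", "C4H8O2+C6H12O"
        ),
        retention_time=5.8,
    ),
    SpectrumSimSpec(
        name="phytosphingosine",
        compound_formula=parse_formula("C18H39NO3"),
        loss_paths=_paths("H2O", "C2H6O2", "C2H6O2+C11H22"),
        retention_time=8.0,
    ),
)


def reference_calibration_spec(**overrides) -> CalibrationSimSpec:
    """The default calibration recipe (study design defaults), overridable."""
    return replace(CalibrationSimSpec(), **overrides) if overrides else CalibrationSimSpec()
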