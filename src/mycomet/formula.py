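"""Candidate molecular-formula enumeration and ranking from accurate mass.

Replaces the vendor formula-prediction stage: exhaustively enumerate every
elemental composition within configured element bounds whose protonated ion
m/z falls inside a ppm window around the measured m/z, filter by H/C ratio,
RDBE window and the nitrogen rule, then score by mass accuracy and (when an
observed isotope pattern is supplied) isotope-pattern agreement.

The enumeration is provably lossless: heavy-element counts are iterated over
their full cross-product (with a monotone mass-based early break) and the
hydrogen count is solved exactly from the residual mass window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem import (
    ELECTRON_MASS,
    PERIODIC_TABLE,
    PROTON_MASS,
    ElementalFormula,
    IonSpecies,
    IsotopePattern,
    ion_mz,
    isotope_pattern,
    nitrogen_rule_consistent,
    ppm_error,
    rdbe,
)

__all__ = [
    "SearchConstraints",
    "CandidateFormula",
    "CHNO_BOUNDS",
    "CHNOPS_BOUNDS",
    "enumerate_candidates",
    "isotope_similarity_score",
    "rank_candidates",
]

#: Default search space for the fungal-metabolite use case (all three worked
#: examples are CHNO); covers the 150-1000 Da scan range comfortably.
CHNO_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 50),
    "H": (0, 100),
    "N": (0, 20),
    "O": (0, 30),
}

#: Wider profile including phosphorus and sulfur.
CHNOPS_BOUNDS: dict[str, tuple[int, int]] = {**CHNO_BOUNDS, "P": (0, 5), "S": (0, 5)}


@dataclass(frozen=True)
class SearchConstraints:
    """Constraint set for formula enumeration.

    Defaults: 10 ppm mass window, H/C ratio 0.2-3.1 (skipped for carbon-free
    formulas), RDBE in [-0.5, 40], nitrogen rule on, equal weighting of mass
    and isotope scores when an observed pattern is available.
    """

    element_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(CHNO_BOUNDS)
    )
    ppm_tolerance: float = 10.0
    hc_ratio_range: tuple[float, float] = (0.2, 3.1)
    rdbe_range: tuple[float, float] = (-0.5, 40.0)
    apply_nitrogen_rule: bool = True
    isotope_weight: float = 0.5

    def __post_init__(self) -> None:
        if not self.element_bounds:
            raise ValueError("element_bounds must be non-empty")
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")
        for name in ("hc_ratio_range", "rdbe_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low must not exceed high")
        for sym, (lo, hi) in self.element_bounds.items():
            if sym not in PERIODIC_TABLE:
                raise ValueError(f"unknown element in bounds: {sym}")
            if lo < 0 or lo > hi:
                raise ValueError(f"bad bounds for {sym}: ({lo}, {hi})")
        if not 0.0 <= self.isotope_weight <= 1.0:
            raise ValueError("isotope_weight must lie in [0, 1]")


@dataclass
class CandidateFormula:
    """One ranked formula hypothesis for a measured ion m/z."""

    formula: ElementalFormula
    theoretical_mz: float
    ppm_error: float
    rdbe: float
    isotope_score: float | None = None
    total_score: float = 0.0
    rank: int = 0

    def __str__(self) -> str:
        return (
            f"#{self.rank} {self.formula.hill()} m/z {self.theoretical_mz:.4f} "
            f"({self.ppm_error:+.2f} ppm, RDBE {self.rdbe:g})"
        )


def _passes_filters(f: ElementalFormula, constraints: SearchConstraints) -> bool:
    c, h = f["C"], f["H"]
    if c > 0:
        lo, hi = constraints.hc_ratio_range
        if not lo <= h / c <= hi:
            return False
    lo, hi = constraints.rdbe_range
    if not lo <= rdbe(f) <= hi:
        return False
    if constraints.apply_nitrogen_rule and not nitrogen_rule_consistent(f):
        return False
    return True


def enumerate_candidates(
    measured_mz: float,
    constraints: SearchConstraints | None = None,
    ion: IonSpecies | None = None,
    observed_pattern: IsotopePattern | None = None,
) -> list[CandidateFormula]:
    """Enumerate, score and rank all formulas consistent with a measured m/z.

    ``ion`` is a template fixing the adduct convention; only its
    ``protons_added``/``charge`` are used (default: [M+H]+, singly charged).
    When ``observed_pattern`` is given, each candidate's theoretical pattern
    is compared to it and the isotope score enters the total score with
    weight ``constraints.isotope_weight``; otherwise ranking is by mass
    accuracy alone.

    Completeness: every formula within ``element_bounds`` whose ion m/z lies
    within the ppm window and which passes the H/C, RDBE and nitrogen-rule
    filters is returned.
    """
    constraints = constraints or SearchConstraints()
    protons = ion.protons_added if ion is not None else 1
    charge = ion.charge if ion is not None else 1

    # neutral monoisotopic mass window implied by the ppm window on m/z
    tol = constraints.ppm_tolerance * 1e-6
    ion_offset = protons * PROTON_MASS - (charge - protons) * ELECTRON_MASS
    lo_mass = measured_mz * (1 - tol) * abs(charge) - ion_offset
    hi_mass = measured_mz * (1 + tol) * abs(charge) - ion_offset

    bounds = dict(constraints.element_bounds)
    h_lo, h_hi = bounds.pop("H", (0, 0))
    heavy = sorted(bounds.items())
    h_mass = PERIODIC_TABLE["H"].monoisotopic_mass

    out: list[CandidateFormula] = []

    def recurse(idx: int, counts: dict[str, int], mass: float) -> None:
        if mass > hi_mass:  # monotone: adding atoms only increases mass
            return
        if idx == len(heavy):
            # solve hydrogen count from the residual mass window
            n_min = max(h_lo, math.ceil((lo_mass - mass) / h_mass - 1e-12))
            n_max = min(h_hi, math.floor((hi_mass - mass) / h_mass + 1e-12))
            for n_h in range(n_min, n_max + 1):
                f = ElementalFormula({**counts, "H": n_h})
                mz = ion_mz(IonSpecies(f, protons, charge))
                err = ppm_error(measured_mz, mz)
                if abs(err) > constraints.ppm_tolerance:
                    continue
                if _passes_filters(f, constraints):
                    out.append(CandidateFormula(f, mz, err, rdbe(f)))
            return
        sym, (lo, hi) = heavy[idx]
        m = PERIODIC_TABLE[sym].monoisotopic_mass
        for n in range(lo, hi + 1):
            new_mass = mass + n * m
            if new_mass > hi_mass:
                break
            recurse(idx + 1, {**counts, sym: n} if n else counts, new_mass)

    recurse(0, {}, 0.0)

    if observed_pattern is not None:
        for cand in out:
            theo = isotope_pattern(
                IonSpecies(cand.formula, protons, charge).composition,
                max_peaks=len(observed_pattern.peaks),
                charge=charge,
            )
            cand.isotope_score = isotope_similarity_score(observed_pattern, theo)
    weight = constraints.isotope_weight if observed_pattern is not None else 0.0
    return rank_candidates(out, constraints.ppm_tolerance, weight)


def isotope_similarity_score(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    rel_sigma: float = 0.10,
    min_abundance: float = 0.01,
) -> float:
    """Agreement between an observed and a theoretical isotope pattern.

    Both patterns are normalized to base peak 1 (making the score invariant
    to overall intensity scaling of the observed spectrum) and aligned by
    nominal-mass offset from each pattern's base peak. The score is a
    Gaussian in the mean squared *relative* abundance deviation over all
    offsets where either pattern exceeds ``min_abundance``::

        score = exp(-0.5 * mean(((obs-theo)/max(obs,theo))^2) / rel_sigma^2)

    ``rel_sigma`` is the assumed relative isotope-ratio accuracy of the
    instrument (default 10%, typical of TOF abundance measurements).
    Identical patterns score exactly 1 and the score decreases
    monotonically as abundance deviations grow.
    """

    def to_bins(p: IsotopePattern) -> dict[int, float]:
        top = max(a for _, a in p.peaks)
        base_mz = min(m for m, a in p.peaks if a == top)
        return {round(m - base_mz): a / top for m, a in p.peaks}

    obs, theo = to_bins(observed), to_bins(theoretical)
    devs = []
    for k in sorted(set(obs) | set(theo)):
        o, t = obs.get(k, 0.0), theo.get(k, 0.0)
        ref = max(o, t)
        if ref >= min_abundance:
            devs.append(((o - t) / ref) ** 2)
    if not devs:
        return 1.0
    return math.exp(-0.5 * (sum(devs) / len(devs)) / rel_sigma**2)


def rank_candidates(
    candidates: list[CandidateFormula],
    ppm_tolerance: float,
    isotope_weight: float = 0.0,
) -> list[CandidateFormula]:
    """Score and rank candidates in place.

    ``total_score = (1 - w) * mass_score + w * isotope_score`` with
    ``mass_score = 1 - |ppm| / ppm_tolerance``. Candidates without an
    isotope score are scored with ``w = 0``. Ordering is by total score
    descending, ties broken by smaller |ppm error| then Hill order.
    """
    for cand in candidates:
        mass_score = 1.0 - abs(cand.ppm_error) / ppm_tolerance
        if isotope_weight > 0 and cand.isotope_score is not None:
            cand.total_score = (
                (1 - isotope_weight) * mass_score + isotope_weight * cand.isotope_score
            )
        else:
            cand.total_score = mass_score
    candidates.sort(
        key=lambda c: (-c.total_score, abs(c.ppm_error), c.formula.hill())
    )
    for i, cand in enumerate(candidates, start=1):
        cand.rank = i
    return candidates
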