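"""Elemental-formula arithmetic and accurate-mass computation.

The numeric substrate of the annotation pipeline: parsing and formatting of
Hill-notation formulas, monoisotopic masses, ion m/z with the charged-species
(electron-subtracted) convention, ppm mass errors, ring-and-double-bond
equivalents (RDBE), the nitrogen rule, and unit-resolution isotope patterns
obtained by convolving per-element natural-abundance distributions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "Element",
    "ElementalFormula",
    "IonSpecies",
    "IsotopePattern",
    "PERIODIC_TABLE",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "ion_mz",
    "ppm_error",
    "rdbe",
    "nitrogen_rule_consistent",
    "isotope_pattern",
]

#: Mass of the proton in Da (CODATA 2018).
PROTON_MASS = 1.007276466621
#: Mass of the electron in Da (CODATA 2018).
ELECTRON_MASS = 0.000548579909


class FormulaError(ValueError):
    """Malformed or chemically infeasible elemental formula."""


@dataclass(frozen=True)
class Element:
    """A chemical element with its naturally occurring isotopes.

    ``isotopes`` is ordered by increasing exact mass as ``(mass_da,
    abundance)`` pairs; the first entry must be the most abundant
    (monoisotopic) isotope and abundances must sum to 1 within 1e-6.
    """

    symbol: str
    isotopes: tuple[tuple[float, float], ...]
    valence: int | None = None

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.isotopes]
        abunds = [a for _, a in self.isotopes]
        if sorted(masses) != masses or len(set(masses)) != len(masses):
            raise ValueError(f"{self.symbol}: isotope masses must strictly increase")
        if abs(sum(abunds) - 1.0) > 1e-6:
            raise ValueError(f"{self.symbol}: abundances must sum to 1")
        if abunds[0] != max(abunds):
            raise ValueError(f"{self.symbol}: first isotope must be the most abundant")

    @property
    def monoisotopic_mass(self) -> float:
        return self.isotopes[0][0]

    @property
    def nominal_mass(self) -> int:
        return round(self.isotopes[0][0])


# Isotopic masses: AME2020 atomic mass evaluation; abundances: IUPAC CIAAW
# representative values. Monoisotopic (most abundant) isotope listed first by
# construction of each tuple's ordering plus the Element invariant.
PERIODIC_TABLE: dict[str, Element] = {
    "C": Element("C", ((12.0, 0.9893), (13.00335483507, 0.0107)), valence=4),
    "H": Element("H", ((1.00782503207, 0.999885), (2.01410177812, 0.000115)), valence=1),
    "N": Element("N", ((14.00307400443, 0.99636), (15.00010889888, 0.00364)), valence=3),
    "O": Element(
        "O",
        ((15.99491461957, 0.99757), (16.99913175650, 0.00038), (17.99915961286, 0.00205)),
        valence=2,
    ),
    "P": Element("P", ((30.97376199842, 1.0),), valence=3),
    "S": Element(
        "S",
        (
            (31.97207117441, 0.9499),
            (32.97145890980, 0.0075),
            (33.96786700400, 0.0425),
            (35.96708071100, 0.0001),
        ),
        valence=2,
    ),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative integer element counts; the unit of all mass arithmetic.

    Immutable and hashable. The all-zero formula is the additive identity.
    Supports ``+`` and ``-`` (elementwise; subtraction raises
    :class:`FormulaError` when infeasible) and ``in``-style containment via
    :meth:`contains`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, n in self.counts.items():
            if sym not in PERIODIC_TABLE:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {sym}: {n!r}")
            if n > 0:
                clean[sym] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    def __hash__(self) -> int:
        return hash(tuple(self.counts.items()))

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other:
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return subtract_formula(self, other)

    def contains(self, other: "ElementalFormula") -> bool:
        """True when ``other`` is an elementwise subformula of ``self``."""
        return all(self[sym] >= n for sym, n in other)

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    @property
    def heavy_atom_count(self) -> int:
        """Number of non-hydrogen atoms."""
        return sum(n for sym, n in self if sym != "H")

    def hill(self) -> str:
        """Hill-notation string: C first, then H, then other symbols sorted."""
        parts: list[str] = []
        order = ["C", "H"] if "C" in self.counts else []
        order += sorted(sym for sym in self.counts if sym not in ("C", "H"))
        if "C" not in self.counts and "H" in self.counts:
            order = sorted(self.counts)
        for sym in order:
            n = self[sym]
            if n:
                parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C10H13N5O4"``.

    Repeated element symbols accumulate. The empty string parses to the
    empty (identity) formula. Raises :class:`FormulaError` on any token that
    is not a known element symbol followed by an optional positive count.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym, digits = match.groups()
        if sym not in PERIODIC_TABLE:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def as_formula(f: "ElementalFormula | str | Mapping[str, int]") -> ElementalFormula:
    """Coerce a string, mapping or formula to an :class:`ElementalFormula`."""
    if isinstance(f, ElementalFormula):
        return f
    if isinstance(f, str):
        return parse_formula(f)
    return ElementalFormula(dict(f))


def subtract_formula(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    """Elementwise ``a - b``; raises :class:`FormulaError` if any count of
    ``b`` exceeds the corresponding count of ``a``."""
    out = dict(a.counts)
    for sym, n in b:
        have = out.get(sym, 0)
        if n > have:
            raise FormulaError(f"cannot subtract {b} from {a}: {sym} deficit")
        out[sym] = have - n
    return ElementalFormula(out)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Neutral monoisotopic mass in Da (most-abundant isotope per element)."""
    return sum(PERIODIC_TABLE[sym].monoisotopic_mass * n for sym, n in f)


def nominal_mass(f: ElementalFormula) -> int:
    """Integer nominal mass (sum of mass numbers of most-abundant isotopes)."""
    return sum(PERIODIC_TABLE[sym].nominal_mass * n for sym, n in f)


@dataclass(frozen=True)
class IonSpecies:
    """An even-electron ion formed by (de)protonating a neutral molecule.

    ``protons_added`` may be negative (deprotonation); ``charge`` carries the
    sign and must be nonzero with sign matching ``polarity``.
    """

    neutral: ElementalFormula
    protons_added: int = 1
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ion charge must be nonzero")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def composition(self) -> ElementalFormula:
        """Elemental composition of the ion including added/removed protons."""
        if self.protons_added >= 0:
            return self.neutral + ElementalFormula({"H": self.protons_added})
        return self.neutral - ElementalFormula({"H": -self.protons_added})

    def mz(self) -> float:
        return ion_mz(self)

    def __str__(self) -> str:
        sign = "+" if self.charge > 0 else "-"
        h = ""
        if self.protons_added:
            op = "+" if self.protons_added > 0 else "-"
            n = abs(self.protons_added)
            h = f" {op} {n if n > 1 else ''}H"
        return f"[M{h}]{abs(self.charge) if abs(self.charge) > 1 else ''}{sign}"


def ion_mz(ion: IonSpecies) -> float:
    """m/z of an ion using the charged-species mass convention.

    The electron mass is subtracted per positive charge (and added per
    negative charge): a protonated molecule weighs neutral + proton, not
    neutral + hydrogen atom. The ~0.55 mDa difference matters at the ppm
    accuracy of TOF data.
    """
    mass = (
        monoisotopic_mass(ion.neutral)
        + ion.protons_added * PROTON_MASS
        # protons_added already accounts for |protons_added| electrons when
        # PROTON_MASS (not the H-atom mass) is used; any residual charge
        # beyond the added protons adjusts by the electron mass.
        - (ion.charge - ion.protons_added) * ELECTRON_MASS
    )
    return mass / abs(ion.charge)


def ppm_error(measured_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured_mz - theoretical_mz) / theoretical_mz * 1e6


def rdbe(f: ElementalFormula, valences: Mapping[str, int] | None = None) -> float:
    """Ring-and-double-bond equivalents: ``1 + sum(n_i * (v_i - 2)) / 2``.

    With CHNO valences (4, 1, 3, 2) this reduces to ``(2C + 2 + N - H) / 2``.
    Half-integer values (open-shell / even-electron ion compositions) are
    returned as-is; plausibility filtering is the caller's concern.
    """
    total = 0.0
    for sym, n in f:
        v = valences.get(sym) if valences is not None else PERIODIC_TABLE[sym].valence
        if v is None:
            raise ValueError(f"no valence configured for element {sym}")
        total += n * (v - 2)
    return 1.0 + total / 2.0


def nitrogen_rule_consistent(f: ElementalFormula) -> bool:
    """Nitrogen rule for a neutral molecule.

    An odd number of nitrogen atoms implies an odd nominal mass; an even (or
    zero) nitrogen count implies an even nominal mass.
    """
    return nominal_mass(f) % 2 == f["N"] % 2


@dataclass(frozen=True)
class IsotopePattern:
    """Unit-resolution isotope pattern: ordered (m/z, relative abundance)
    peaks with the base peak normalized to 1."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        mzs = [m for m, _ in self.peaks]
        abunds = [a for _, a in self.peaks]
        if not self.peaks:
            raise ValueError("isotope pattern must contain at least one peak")
        if sorted(mzs) != mzs:
            raise ValueError("isotope pattern m/z must strictly increase")
        if not all(0 < a <= 1 for a in abunds) or abs(max(abunds) - 1.0) > 1e-12:
            raise ValueError("abundances must lie in (0, 1] with base peak 1")

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.peaks)


def isotope_pattern(
    f: ElementalFormula,
    max_peaks: int = 5,
    charge: int = 0,
    prune: float = 1e-12,
) -> IsotopePattern:
    """Unit-resolution isotope pattern of a formula by abundance convolution.

    Isotopologues are binned by integer nominal-mass offset from the
    monoisotopic peak (M, M+1, M+2, ...); within a bin the reported mass is
    the abundance-weighted centroid, so unresolved fine structure (e.g.
    13C vs 15N at M+1) collapses to one peak, matching unit-resolved vendor
    pattern displays. Abundances are renormalized to base peak = 1 and the
    pattern is truncated to ``max_peaks``. ``charge`` > 0 converts masses to
    m/z of the bare composition ion (mass - charge * electron mass, divided
    by charge); 0 leaves neutral masses.

    Bins with probability below ``prune`` are dropped during convolution;
    this only suppresses peaks far below representable abundance.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    # state: offset bin -> (probability, probability-weighted mass sum)
    state: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for sym, n in f:
        elem = PERIODIC_TABLE[sym]
        mono_m = elem.monoisotopic_mass
        single = [(round(m - mono_m), a, m) for m, a in elem.isotopes]
        for _ in range(n):
            nxt: dict[int, tuple[float, float]] = {}
            for off, (p, wm) in state.items():
                for d_off, a, m in single:
                    if p * a < prune:
                        continue
                    key = off + d_off
                    q, qm = nxt.get(key, (0.0, 0.0))
                    # each isotopologue in the bin gains mass m with prob a
                    nxt[key] = (q + p * a, qm + a * (wm + p * m))
            state = nxt
    rows = []  # (centroid mass, probability) per nominal-offset bin
    for off in sorted(state):
        p, wm = state[off]
        if p > 0:
            rows.append((wm / p, p))
    rows.sort(key=lambda r: r[0])
    rows = rows[:max_peaks]
    top = max(p for _, p in rows)
    peaks = []
    for m, p in rows:
        mz = m
        if charge:
            mz = (m - charge * ELECTRON_MASS) / abs(charge)
        peaks.append((mz, p / top))
    # guard against floating duplicates producing non-increasing mz
    return IsotopePattern(tuple(peaks))
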