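"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library's own enumeration/convolution code
paths: they recompute expected results from first principles (exhaustive
enumeration, closed forms) at small problem sizes.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

from mycomet.chem import (
    ELECTRON_MASS,
    PERIODIC_TABLE,
    PROTON_MASS,
    ElementalFormula,
)


def isotopologue_pattern_oracle(
    formula: ElementalFormula, max_peaks: int, charge: int = 0
) -> list[tuple[float, float]]:
    """Exhaustive isotopologue expansion binned by nominal-mass offset.

    Enumerates, per element, every way of distributing the atoms over the
    element's isotopes (multinomial probabilities), combines elements by
    cartesian product, then bins isotopologues by integer mass offset and
    centroids each bin. Feasible for formulas with <= ~30 atoms.
    """
    per_element = []
    for sym, n in formula:
        isotopes = PERIODIC_TABLE[sym].isotopes
        k = len(isotopes)
        options = []  # (probability, total mass, nominal offset) per assignment
        for counts in itertools.product(range(n + 1), repeat=k):
            if sum(counts) != n:
                continue
            prob = math.factorial(n)
            mass = 0.0
            offset = 0
            for c, (m, a) in zip(counts, isotopes):
                prob = prob // math.factorial(c)
                mass += c * m
                offset += c * round(m - isotopes[0][0])
            p = prob
            for c, (_, a) in zip(counts, isotopes):
                p *= a**c
            options.append((p, mass, offset))
        per_element.append(options)

    bins: dict[int, tuple[float, float]] = defaultdict(lambda: (0.0, 0.0))
    for combo in itertools.product(*per_element):
        p = 1.0
        mass = 0.0
        offset = 0
        for pp, mm, oo in combo:
            p *= pp
            mass += mm
            offset += oo
        q, wm = bins[offset]
        bins[offset] = (q + p, wm + p * mass)
    rows = sorted((wm / p, p) for off, (p, wm) in bins.items() if p > 0)
    rows = rows[:max_peaks]
    top = max(p for _, p in rows)
    out = []
    for m, p in rows:
        mz = (m - charge * ELECTRON_MASS) / abs(charge) if charge else m
        out.append((mz, p / top))
    return out


def enumerate_formulas_oracle(
    measured_mz: float,
    bounds: dict[str, tuple[int, int]],
    ppm_tolerance: float,
    hc_range=(0.2, 3.1),
    rdbe_range=(-0.5, 40.0),
    nitrogen_rule=True,
) -> set[str]:
    """Nested-loop enumeration of [M+H]+ candidate formulas (Hill strings)."""
    syms = sorted(bounds)
    out = set()
    for counts in itertools.product(*(range(lo, hi + 1) for lo, hi in (bounds[s] for s in syms))):
        f = ElementalFormula(dict(zip(syms, counts)))
        mass = sum(PERIODIC_TABLE[s].monoisotopic_mass * n for s, n in f)
        mz = mass + PROTON_MASS
        if abs((measured_mz - mz) / mz * 1e6) > ppm_tolerance:
            continue
        c, h = f["C"], f["H"]
        if c > 0 and not (hc_range[0] <= h / c <= hc_range[1]):
            continue
        r = 1.0 + sum(n * (PERIODIC_TABLE[s].valence - 2) for s, n in f) / 2.0
        if not rdbe_range[0] <= r <= rdbe_range[1]:
            continue
        nominal = sum(PERIODIC_TABLE[s].nominal_mass * n for s, n in f)
        if nitrogen_rule and nominal % 2 != f["N"] % 2:
            continue
        out.add(f.hill())
    return out


def subformula_assignments_oracle(
    precursor: ElementalFormula,
    fragment_mz: float,
    tolerance_mda: float,
    accept_loss=lambda loss: True,
) -> set[str]:
    """All subformula fragment-ion assignments (Hill strings) in tolerance."""
    syms = list(precursor.counts)
    out = set()
    for counts in itertools.product(*(range(precursor[s] + 1) for s in syms)):
        if not any(counts):
            continue
        sub = ElementalFormula(dict(zip(syms, counts)))
        mz = sum(PERIODIC_TABLE[s].monoisotopic_mass * n for s, n in sub) - ELECTRON_MASS
        if abs(fragment_mz - mz) * 1e3 > tolerance_mda:
            continue
        loss = ElementalFormula(
            {s: precursor[s] - sub[s] for s in syms}
        )
        if accept_loss(loss):
            out.add(sub.hill())
    return out


def least_squares_oracle(x: list[float], y: list[float]) -> tuple[float, float]:
    """Closed-form normal-equations solution for a straight-line fit."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
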