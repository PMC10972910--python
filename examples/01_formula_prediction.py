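"""Predict the molecular formula of an unknown ion from its accurate mass.

A fungal-extract feature was measured at m/z 268.1051 ([M+H]+). We enumerate
every CHNO formula within 10 ppm that passes the H/C-ratio, RDBE and
nitrogen-rule filters, then rank with the theoretical isotope pattern of
each candidate scored against the observed one.
"""

from mycomet import (
    IonSpecies,
    SearchConstraints,
    enumerate_candidates,
    isotope_pattern,
    parse_formula,
)

measured_mz = 268.1051

# mass-only ranking
candidates = enumerate_candidates(measured_mz, SearchConstraints(ppm_tolerance=10.0))
print(f"candidates within 10 ppm of m/z {measured_mz}:")
for c in candidates:
    print(f"  {c}")

# supply an observed isotope pattern (here: the theoretical pattern of
# protonated adenosine, i.e. what a clean spectrum of the true compound shows)
observed = isotope_pattern(
    IonSpecies(parse_formula("C10H13N5O4")).composition, max_peaks=4, charge=1
)
ranked = enumerate_candidates(measured_mz, observed_pattern=observed)
print("\nwith isotope-pattern scoring:")
for c in ranked:
    print(f"  {c}  isotope score {c.isotope_score:.3f}  total {c.total_score:.3f}")

# The top line is the accepted identification: C10H13N5O4 (adenosine),
# ~4 ppm from its theoretical [M+H]+ at 268.1040. The isotope pattern
# separates it decisively from the nearer-mass but isotopically wrong
# C11H9N9 alternative.
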