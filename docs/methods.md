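# Methods

This note documents the models, conventions and numerical choices behind
`mycomet`, in the order the pipeline runs them.

## Mass conventions

Atomic masses are a static embedded table (AME2020 atomic-mass evaluation;
isotope abundances from IUPAC/CIAAW representative values) for C, H, N, O,
P, S. Monoisotopic mass uses the most abundant isotope of each element.
Ion m/z uses the charged-species convention: a protonated molecule weighs
M + m_p (proton mass 1.007276466621 Da), i.e. the electron is subtracted
relative to adding a neutral hydrogen atom. The ~0.55 mDa difference is
significant at the ppm accuracy of TOF data. Fragment ions are computed as
composition mass minus one electron; this differs from the neutral+proton
route by the ~1.5 × 10⁻⁸ Da hydrogen binding energy, far below every
tolerance in use.

Nominal mass is the sum of integer mass numbers of most-abundant isotopes
(C=12, H=1, N=14, O=16), the standard convention for the nitrogen rule.

ppm errors of the three bundled worked-example ions against their assigned
formulas are +3.99, −0.93 and −3.36 ppm; the published magnitudes (4.1,
0.83, 3.46) were computed from unrounded instrument masses, and the
4-decimal printed m/z reproduce them only to ±0.15 ppm. Tests therefore
compare |ppm| at that tolerance.

## Isotope patterns

Patterns are computed by convolving per-element single-atom isotope
distributions, binning by integer nominal-mass offset (M, M+1, M+2, …) and
centroiding each bin by abundance weight — i.e. unit-resolution patterns,
matching how vendor software displays them. Fine structure within a bin
(¹³C vs ¹⁵N at M+1) is deliberately not resolved. Bins below 10⁻¹²
probability are pruned during convolution; an exhaustive isotopologue
enumeration oracle in the test suite confirms agreement to 1 × 10⁻⁶
relative abundance for formulas up to ~30 atoms.

## Formula enumeration and scoring

Enumeration iterates the cross-product of heavy-element counts (with a
monotone mass-based early break, which cannot drop candidates because atom
counts only add mass) and solves the hydrogen count exactly from the
residual mass window — exhaustive by construction, and verified against a
nested-loop oracle. Default bounds are a CHNO profile (C ≤ 50, H ≤ 100,
N ≤ 20, O ≤ 30) suited to a 150–1000 Da scan range; a CHNOPS profile adds
P, S ≤ 5. Defaults: 10 ppm tolerance, H/C ∈ [0.2, 3.1] (skipped for
carbon-free formulas, whose ratio is undefined — excluding them would be an
extra rule), RDBE ∈ [−0.5, 40] as a generic plausibility window (the DBE
settings of the original vendor analysis are not public; these bounds are
this package's own defaults and are fully configurable), nitrogen rule on.

Scoring: `total = (1−w)·mass_score + w·isotope_score` with
`mass_score = 1 − |ppm|/tol` and w = 0.5 when an observed pattern is
available (w = 0 otherwise). The isotope score is
`exp(−½ · mean((Δa/a_ref)²) / σ²)` over nominal-offset bins where either
pattern exceeds 1% of base, with relative-abundance sigma σ = 10%, a
typical TOF isotope-ratio accuracy. The Gaussian form was chosen over a
linear deviation penalty because formula discrimination at ~270 Da hinges
on ~15–20% relative M+1 differences: a scorer must convert those into
score gaps comparable to the mass-score spread inside the ppm window, and
a Gaussian with instrument-scale σ does exactly that while remaining 1 for
a perfect match, scale-invariant, and monotone in the deviation. Ties in
total score break by smaller |ppm|, then Hill order, for determinism.

## Fragment annotation

Fragments are modeled as even-electron cations retaining the charge
proton; losses are neutral molecules. The fragment tolerance is absolute
(default 5 mDa) rather than ppm because observed fragment deviations in
ion-trap MSⁿ reach a few mDa independent of mass — larger than the
precursor's ppm-scale error. Candidate losses pass a plausibility filter:

* hydrogen feasibility: H ≤ 2C + N + 3;
* RDBE ≥ −0.5 and, with radical losses disabled (default), integer RDBE
  (a closed-shell neutral has integer RDBE);
* an unsaturation-density cap RDBE ≤ (heavy atoms)/2 + 1, which rejects
  near-fully-unsaturated compositions that are not credible neutral
  molecules while keeping every common loss (water, acetaldehyde, esters,
  alkenes — all RDBE ≤ 2) and even fully aromatic losses such as benzene
  (RDBE 4, cap 4) or adenine (RDBE 6, cap 6), both exactly at the cap.

The cap matters in practice: the adenosine MS² fragment at 136.0601
otherwise acquires a smaller-error but chemically absurd assignment whose
complementary loss, C₆H₄N₄ (RDBE 7 of a possible 9), displaces the correct
adenine ion C₅H₆N₅⁺ / C₅H₈O₄ ribose-moiety loss.

A published notation inconsistency is worth recording: the adenosine
glycosidic loss is written elsewhere as C₅H₄O₄ alongside a printed loss
mass of −132.0450 Da, but C₅H₄O₄ weighs 128.011 Da; the composition
consistent with both the mass (132.0423 Da theoretical, 2.7 mDa off) and
the adenosine structure is C₅H₈O₄, and that is what this package assigns.

MS³ fragments are assigned relative to their MS² parent's best
composition, not re-derived from MS¹, so loss paths concatenate as in
`[M+H − A − B]⁺` notation. MS³ blocks must select an observed MS² fragment
within the ion-trap isolation width (default 1 Da); unassignable fragments
are kept in the tree with an explicit unassigned marker rather than
dropped, since real spectra contain unidentified ions. Ranking is by |mDa
error|, then fewer heavy atoms in the loss, then Hill order.

## Screening

Features are compared by normalized squared distance
(Δrt/rt_tol)² + (Δm/z_ppm/mz_tol)². Defaults rt_tol = 0.2 min (on a
14-min gradient) and 10 ppm are engineering choices — the original
comparison was visual and states no tolerances. No intensity floor is
applied unless configured. Peak lists are consumed already centroided; raw
profile processing and rt alignment are out of scope.

## Quantification

Unweighted least squares by default, with an optional 1/x weighting flag
(no weighting scheme is part of the reference design, so none is applied
unless requested). The reported correlation is Pearson's r
between concentration and response, matching the convention of quoting a
calibration "R". SSE is computed per spiked replicate curve against the
single solvent fit and reported as mean ± SD (n−1), mirroring triplicate
designs. Samples are quantified on the solvent curve and divided by
SSE/100 — algebraically equivalent to quantifying on the matrix-matched
curve when intercepts are negligible, and the convention that matches
computing SSE from two curves in the first place. Negative back-calculated
concentrations are clamped to 0 and flagged below-LOQ rather than
propagated. The µg/kg conversion requires the sample mass as an explicit
input: the mass of extracted material (e.g. agar plugs) is
protocol-specific and has no defensible default.

## Synthetic-data generator

The generator emulates the study conditions the pipeline assumes:

* [M+H]⁺ spectra of known formulas carrying their theoretical isotope
  patterns; mass error additive Gaussian in ppm (default 0 for worked
  examples, configurable); abundance/response noise multiplicative
  Gaussian truncated at −90% to preserve positivity;
* a shared background population, uniform over rt ∈ [0, 14] min and
  m/z ∈ [150, 1000] Da (gradient length and scan range of the emulated
  method), with the control containing exactly the same realized features
  as the sample minus the spiked compounds;
* calibration pairs with solvent levels 31.25–1000 ng/mL (six levels),
  spiked levels 125–2000 ng/mL (five levels) in triplicate, suppression
  factor 0.552 and 2% response CV — the reference study's design.

What it does **not** emulate: chromatographic peak shape, co-elution,
detector saturation, heteroscedastic noise, or correlated matrix
interferences. Passing tests therefore demonstrate correctness of the
computations under the stated noise models, not robustness to every
artifact of real instrument data.

Monte-Carlo sizes in the tests and acceptance script (200 calibration
repetitions, 50 round-trip repetitions, 1000 ppm-noise draws) were chosen
so Monte-Carlo error is well below the effect sizes being checked while
the whole suite stays fast.

## Known limitations

* Adducts other than ±nH (Na⁺, K⁺, NH₄⁺) and multiple charging are not
  enumerated.
* No metabolite-database lookup: candidate formulas are ranked, not named.
* mzML/mzXML input is not parsed; peak lists and MGF/CSV spectra are the
  ingestion boundary.
* LOD/LOQ estimation and extraction-recovery correction are out of scope.
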