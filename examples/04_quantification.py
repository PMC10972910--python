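"""Quantify a metabolite with matrix-effect correction.

Electrospray ionization is suppressed by co-eluting matrix components, so a
solvent calibration under-reads extract samples. We fit a solvent curve and
triplicate matrix-matched (spiked-extract) curves, express the matrix effect
as SSE(%) = slope ratio x 100, then back-calculate sample responses on the
solvent curve and divide by SSE/100.
"""

from mycomet import (
    back_calculate,
    fit_calibration,
    matrix_correct,
    replicate_sse,
    to_ug_per_kg,
    replicate_summary,
)
from mycomet.simulate import CalibrationSimSpec, simulate_calibration_pair

# matrix suppresses the response to 55.2% of the solvent slope; 2% noise
spec = CalibrationSimSpec(suppression_factor=0.552, noise_cv=0.02)
solvent_levels, spiked_curves = simulate_calibration_pair(spec, seed=1)

solvent_fit = fit_calibration(solvent_levels)
me = replicate_sse(spiked_curves, solvent_fit)
print(f"solvent curve: slope {solvent_fit.slope:.4f}, R {solvent_fit.correlation_r:.4f}")
print(f"matrix effect: SSE {me.sse_percent:.1f} +/- {me.sse_sd:.1f} %")

# three replicate responses of one extract whose true content is 400 ng/mL
true_conc = 400.0
responses = [spec.suppression_factor * spec.solvent_slope * true_conc * f
             for f in (0.99, 1.01, 1.00)]
per_sample = []
for resp in responses:
    apparent = back_calculate(resp, solvent_fit)
    corrected = matrix_correct(apparent, me)
    # 0.5 mL extraction solvent over 0.5 g of sampled culture material
    per_sample.append(to_ug_per_kg(corrected, extract_volume_ml=0.5, sample_mass_g=0.5))
    print(f"response {resp:6.1f} -> apparent {apparent:6.1f} ng/mL "
          f"-> corrected {corrected:6.1f} ng/mL")

mean, sd = replicate_summary(per_sample)
print(f"\nsample content: {mean:.1f} +/- {sd:.1f} ug/kg")

# Without the SSE correction the apparent concentrations sit ~45% low
# (~220 ng/mL); dividing by SSE/100 recovers the true 400 ng/mL within the
# few-percent noise of the calibration.
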