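"""Run the complete pipeline: screen -> predict formula -> annotate
fragments -> quantify, on generated input files.

This mirrors the shell workflow (`mycomet simulate` + `mycomet run`) from
Python: write synthetic sample/control peak tables, MGF spectra and a
calibration table, then execute all stages and inspect the JSON report.
"""

import json
import tempfile
from pathlib import Path

from mycomet import PipelineConfig, run_pipeline
from mycomet import io as mio
from mycomet.simulate import (
    REFERENCE_COMPOUNDS,
    BackgroundSpec,
    CalibrationSimSpec,
    simulate_calibration_pair,
    simulate_msn,
    simulate_sample_and_control,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    sample, control, _ = simulate_sample_and_control(
        list(REFERENCE_COMPOUNDS), BackgroundSpec(n_peaks=50), seed=42
    )
    mio.write_peak_table(sample, tmp / "sample.csv")
    mio.write_peak_table(control, tmp / "control.csv")
    ms2, ms3 = [], {}
    for i, spec in enumerate(REFERENCE_COMPOUNDS):
        _, m2, m3 = simulate_msn(spec, seed=100 + i)
        ms2.extend(m2)
        ms3.update(m3)
    mio.write_spectra_mgf(ms2, ms3, tmp / "spectra.mgf")
    solvent, spiked = simulate_calibration_pair(CalibrationSimSpec(), seed=42)
    mio.write_calibration(solvent, spiked, tmp / "calibration.csv")

    report = run_pipeline(
        PipelineConfig(
            sample_peaks=tmp / "sample.csv",
            control_peaks=tmp / "control.csv",
            spectra=tmp / "spectra.mgf",
            calibration=tmp / "calibration.csv",
            sample_responses=[200.0, 210.0, 190.0],
            sample_mass_g=0.5,
            output_dir=tmp / "out",
        )
    )

print(f"novel features: {len(report['novel_peaks'])}")
for entry in report["novel_peaks"]:
    top = entry["candidates"][0]
    n_frag = len(entry.get("fragment_tree", {}).get("fragments", []))
    print(
        f"  m/z {entry['mz']:.4f}: top formula {top['formula']} "
        f"({top['ppm_error']:+.2f} ppm), {n_frag} MS2 fragments annotated"
    )
q = report["quantification"]
print(
    f"quantification: SSE {q['sse_percent']:.1f} +/- {q['sse_sd']:.1f} %, "
    f"sample {q['mean_ug_per_kg']:.1f} +/- {q['sd_ug_per_kg']:.1f} ug/kg"
)

# The report lists the three spiked metabolites with their true formulas at
# rank 1, fully annotated loss paths, and an SSE estimate near the true
# 55.2% suppression used by the generator.
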