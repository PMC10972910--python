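import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mycomet.chem import parse_formula

# the three worked-example metabolites: neutral formula, printed precursor
# m/z, printed |ppm| error, and printed loss paths (MS2 loss or MS2+MS3 path)
WORKED_EXAMPLES = {
    "adenosine": {
        "formula": "C10H13N5O4",
        "measured_mz": 268.1051,
        "printed_ppm": 4.1,
        "rt_min": 3.4,
        "fragments": {136.0601: ["C5H8O4"]},
    },
    "oxasetin": {
        "formula": "C21H29NO4",
        "measured_mz": 360.2166,
        "printed_ppm": 0.83,
        "rt_min": 5.8,
        "fragments": {
            316.1897: ["C2H4O"],
            272.1633: ["C4H8O2"],
            228.1366: ["C4H8O2", "C2H4O"],
            198.0912: ["C4H8O2", "C4H10O"],
            172.0733: ["C4H8O2", "C6H12O"],
        },
    },
    "phytosphingosine": {
        "formula": "C18H39NO3",
        "measured_mz": 318.2992,
        "printed_ppm": 3.46,
        "rt_min": 8.0,
        "fragments": {
            300.2869: ["H2O"],
            256.2626: ["C2H6O2"],
            102.0891: ["C2H6O2", "C11H22"],
        },
    },
}


@pytest.fixture(scope="session")
def worked_examples():
    return {
        name: {**info, "formula": parse_formula(info["formula"])}
        for name, info in WORKED_EXAMPLES.items()
    }
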