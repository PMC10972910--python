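"""Readers and writers for the pipeline's on-disk formats.

* peak tables — CSV with columns ``rt_min, mz, intensity``;
* MSn spectra — MGF (``BEGIN IONS``/``PEPMASS``/``END IONS``) with a
  nonstandard ``MSLEVEL=`` parameter marking MS2 vs MS3 blocks, or a flat
  CSV with columns ``ms_level, precursor_mz, fragment_mz, intensity``;
* calibration tables — CSV with columns ``curve_id`` (``solvent`` or
  ``spiked``), ``replicate``, ``concentration_ng_ml``, ``response``;
* candidate/fragment reports — TSV with fixed float formatting (4 decimals
  for m/z, 2 for ppm/mDa) so repeated runs are byte-identical, plus a JSON
  report retaining full precision.

All readers validate headers and raise :class:`InputError` naming the
missing column or offending row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
from pyteomics import mgf as _mgf

from .fragments import FragmentationTree, FragmentObservation
from .quant import CalibrationLevel
from .screening import ChromPeak

__all__ = [
    "InputError",
    "read_peak_table",
    "write_peak_table",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_spectra_mgf",
    "write_spectra_mgf",
    "read_calibration",
    "write_calibration",
    "write_candidates_tsv",
    "write_tree_tsv",
    "tree_to_dict",
    "write_json_report",
]


class InputError(ValueError):
    """Malformed or incomplete input file."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty input file: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in required:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if not bad.empty:
            row = int(bad.index[0]) + 2  # 1-based, counting the header
            raise InputError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if df[col].isna().any():
            row = int(df[df[col].isna()].index[0]) + 2
            raise InputError(f"{path}: missing value in column {col!r}, row {row}")
    return df


def read_peak_table(path: str | Path) -> list[ChromPeak]:
    df = _read_csv(path, ["rt_min", "mz", "intensity"])
    return [
        ChromPeak(float(r.rt_min), float(r.mz), float(r.intensity))
        for r in df.itertuples()
    ]


def write_peak_table(peaks: list[ChromPeak], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rt_min": [p.retention_time for p in peaks],
            "mz": [p.mz for p in peaks],
            "intensity": [p.intensity for p in peaks],
        }
    ).to_csv(path, index=False)


def read_spectra_csv(
    path: str | Path,
) -> tuple[list[FragmentObservation], dict[float, list[FragmentObservation]]]:
    """Read MSn observations from a flat CSV; returns (ms2, ms3-by-precursor)."""
    df = _read_csv(path, ["ms_level", "precursor_mz", "fragment_mz", "intensity"])
    ms2, ms3 = [], {}
    for r in df.itertuples():
        obs = FragmentObservation(
            int(r.ms_level), float(r.precursor_mz), float(r.fragment_mz), float(r.intensity)
        )
        if obs.ms_level == 2:
            ms2.append(obs)
        else:
            ms3.setdefault(obs.precursor_mz, []).append(obs)
    return ms2, ms3


def write_spectra_csv(
    ms2: list[FragmentObservation],
    ms3: dict[float, list[FragmentObservation]],
    path: str | Path,
) -> None:
    rows = [
        (o.ms_level, o.precursor_mz, o.fragment_mz, o.intensity)
        for o in ms2 + [o for block in ms3.values() for o in block]
    ]
    pd.DataFrame(
        rows, columns=["ms_level", "precursor_mz", "fragment_mz", "intensity"]
    ).to_csv(path, index=False)


def read_spectra_mgf(
    path: str | Path,
) -> tuple[list[FragmentObservation], dict[float, list[FragmentObservation]]]:
    """Read MSn blocks from an MGF file.

    The MS level of each block is taken from a nonstandard ``MSLEVEL=``
    parameter (default 2 when absent); the block's ``PEPMASS`` is the
    selected precursor m/z.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    ms2, ms3 = [], {}
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block["params"]
            level = int(params.get("mslevel", 2))
            pep = params["pepmass"]
            precursor = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            for mz, inten in zip(block["m/z array"], block["intensity array"]):
                obs = FragmentObservation(level, precursor, float(mz), float(inten))
                if level == 2:
                    ms2.append(obs)
                else:
                    ms3.setdefault(precursor, []).append(obs)
    return ms2, ms3


def write_spectra_mgf(
    ms2: list[FragmentObservation],
    ms3: dict[float, list[FragmentObservation]],
    path: str | Path,
) -> None:
    spectra = []

    def block(precursor: float, level: int, obs: list[FragmentObservation]):
        return {
            "params": {"pepmass": precursor, "mslevel": level},
            "m/z array": [o.fragment_mz for o in obs],
            "intensity array": [o.intensity for o in obs],
        }

    by_precursor: dict[float, list[FragmentObservation]] = {}
    for o in ms2:
        by_precursor.setdefault(o.precursor_mz, []).append(o)
    for prec, obs in by_precursor.items():
        spectra.append(block(prec, 2, obs))
    for prec, obs in ms3.items():
        spectra.append(block(prec, 3, obs))
    _mgf.write(spectra, str(path), file_mode="w")


def read_calibration(
    path: str | Path,
) -> tuple[list[CalibrationLevel], list[list[CalibrationLevel]]]:
    """Read a calibration CSV; returns (solvent levels, spiked replicate curves)."""
    df = _read_csv(path, ["replicate", "concentration_ng_ml", "response"])
    if "curve_id" not in df.columns:
        raise InputError(f"{path}: missing column(s) curve_id")
    bad = set(df.curve_id) - {"solvent", "spiked"}
    if bad:
        raise InputError(f"{path}: unknown curve_id value(s) {sorted(bad)}")
    solvent = [
        CalibrationLevel(float(r.concentration_ng_ml), float(r.response), int(r.replicate))
        for r in df[df.curve_id == "solvent"].itertuples()
    ]
    spiked_df = df[df.curve_id == "spiked"]
    spiked = [
        [
            CalibrationLevel(float(r.concentration_ng_ml), float(r.response), int(r.replicate))
            for r in spiked_df[spiked_df.replicate == rep].itertuples()
        ]
        for rep in sorted(spiked_df.replicate.unique())
    ]
    return solvent, spiked


def write_calibration(
    solvent: list[CalibrationLevel],
    spiked: list[list[CalibrationLevel]],
    path: str | Path,
) -> None:
    rows = [
        ("solvent", lv.replicate_id, lv.nominal_concentration, lv.response)
        for lv in solvent
    ] + [
        ("spiked", lv.replicate_id, lv.nominal_concentration, lv.response)
        for curve in spiked
        for lv in curve
    ]
    pd.DataFrame(
        rows, columns=["curve_id", "replicate", "concentration_ng_ml", "response"]
    ).to_csv(path, index=False)


def write_candidates_tsv(candidates, path: str | Path) -> None:
    rows = [
        (
            c.rank,
            c.formula.hill(),
            f"{c.theoretical_mz:.4f}",
            f"{c.ppm_error:.2f}",
            f"{c.rdbe:g}",
            "" if c.isotope_score is None else f"{c.isotope_score:.4f}",
            f"{c.total_score:.4f}",
        )
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "formula", "theoretical_mz", "ppm_error", "rdbe",
                 "isotope_score", "total_score"],
    ).to_csv(path, sep="\t", index=False)


def _loss_path_str(assignment) -> str:
    return "+".join(f.hill() for f in assignment.cumulative_losses) or "-"


def write_tree_tsv(tree: FragmentationTree, path: str | Path) -> None:
    rows = []
    for node in tree.all_nodes():
        b = node.best
        rows.append(
            (
                node.observation.ms_level,
                f"{node.observation.fragment_mz:.4f}",
                b.fragment_formula.hill() if b else "",
                _loss_path_str(b) if b else "unassigned",
                f"{b.mass_error_mda:.2f}" if b else "",
            )
        )
    pd.DataFrame(
        rows, columns=["ms_level", "observed_mz", "ion_formula", "loss_path", "error_mda"]
    ).to_csv(path, sep="\t", index=False)


def tree_to_dict(tree: FragmentationTree) -> dict[str, Any]:
    def node_dict(node):
        b = node.best
        return {
            "ms_level": node.observation.ms_level,
            "observed_mz": node.observation.fragment_mz,
            "intensity": node.observation.intensity,
            "assigned": node.assigned,
            "ion_formula": b.fragment_formula.hill() if b else None,
            "loss": b.loss_formula.hill() if b and b.loss_formula else None,
            "loss_path": [f.hill() for f in b.cumulative_losses] if b else [],
            "theoretical_mz": b.theoretical_mz if b else None,
            "mass_error_mda": b.mass_error_mda if b else None,
            "children": [node_dict(ch) for ch in node.children],
        }

    return {
        "precursor_mz": tree.precursor_mz,
        "precursor_ion_formula": tree.precursor_ion.composition.hill(),
        "neutral_formula": tree.precursor_ion.neutral.hill(),
        "fragments": [node_dict(n) for n in tree.ms2_nodes],
    }


def write_json_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
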