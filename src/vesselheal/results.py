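"""Serialization of simulation results.

Every run artifact embeds the resolved configuration hash so that any
two runs of the same configuration are verifiably identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from .parameters import ParameterRegistry, ScenarioConfig, config_hash
from .vessel import CaseResult

__all__ = ["write_results", "summary_dict"]

_ROW_ORDER = ("elastin", "collagen", "csmc", "ssmc", "endothelium", "inflammation")


def summary_dict(result: CaseResult) -> dict:
    """Case summary in the constituent-fraction table layout."""
    return {
        "case": result.case_id,
        "acute": {k: round(result.acute_fractions[k], 4) for k in _ROW_ORDER},
        "final": {k: round(result.final_fractions[k], 4) for k in _ROW_ORDER},
        "myograph": {
            "gap_preload_mm": result.myograph.gap_preload,
            "stage_forces_N_per_mm": result.myograph.stage_forces,
        },
        "config_hash": result.config_hash,
    }


def write_results(
    result: CaseResult,
    out_dir: str | Path,
    registry: ParameterRegistry | None = None,
    scenario: ScenarioConfig | None = None,
) -> dict[str, Path]:
    """Write the CSV time series, dose-response CSV and JSON summary.

    Returns the mapping of artifact name to path.  The output directory
    must exist or be creatable; an unwritable path raises.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    paths: dict[str, Path] = {}

    ts_path = out / f"{result.case_id}_timeseries.csv"
    result.history.to_csv(ts_path, index=False)
    paths["timeseries"] = ts_path

    myo_path = out / f"{result.case_id}_myograph.csv"
    with open(myo_path, "w") as fh:
        fh.write("displacement_mm,force_N_per_mm\n")
        for d, f in zip(result.myograph.displacement, result.myograph.force):
            fh.write(f"{d:.8g},{f:.8g}\n")
    paths["myograph_curve"] = myo_path

    dose_path = out / f"{result.case_id}_doseresponse.csv"
    with open(dose_path, "w") as fh:
        fh.write("stage,force_N_per_mm\n")
        for stage, f in result.myograph.stage_forces.items():
            fh.write(f"{stage},{f:.8g}\n")
    paths["dose_response"] = dose_path

    summary = summary_dict(result)
    if registry is not None:
        summary["config_hash"] = config_hash(registry, scenario)
    summary_path = out / f"{result.case_id}_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["summary"] = summary_path
    return paths
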