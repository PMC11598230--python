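"""File round-tripping: measurement CSV, calibration JSON, result JSON.

CSV dialect: comma-separated UTF-8 with a required header
``x1_mM,x2_mM,freq_hz,channel,response_v,replicate`` ('.' decimal
separator).  Column order is free — columns are matched by name — and
values round-trip at full float precision (any 3-decimal truncation is
display-only).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .inversion import EstimationResult
from .regression import CalibrationSet, Channel, MeasurementRecord, ModelForm, RegressionModel

__all__ = [
    "CSV_COLUMNS",
    "DEVICE_METADATA",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
    "calibration_to_dict",
    "calibration_from_dict",
    "write_calibration_json",
    "read_calibration_json",
    "result_to_dict",
]

CSV_COLUMNS = ("x1_mM", "x2_mM", "freq_hz", "channel", "response_v", "replicate")

#: Electrode geometry of the prototype sensing device, carried as
#: provenance metadata only — no computation consumes it.
DEVICE_METADATA = {
    "electrode_width_um": 900.0,
    "electrode_length_um": 1800.0,
    "electrode_gap_um": 200.0,
    "insulation": {"material": "PSR-2000", "thickness_um": 10.0},
    "substrate": "PCB copper foil, coplanar working/reference electrodes",
}


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = [
        (r.x1, r.x2, r.frequency, r.channel.value, r.response, r.replicate)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[MeasurementRecord]:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"measurement table is missing column(s): {', '.join(missing)}")
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                MeasurementRecord(
                    x1=float(row["x1_mM"]),
                    x2=float(row["x2_mM"]),
                    frequency=float(row["freq_hz"]),
                    channel=Channel(row["channel"]),
                    response=float(row["response_v"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: 1-based data rows after the header line
            raise ValueError(f"malformed measurement row at line {idx + 2}: {exc}") from exc
    return records


def write_records_csv(path: str | Path, records: Iterable[MeasurementRecord]) -> None:
    # %.17g guarantees bit-exact float round trips through the CSV
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path: str | Path) -> list[MeasurementRecord]:
    # round_trip parser: the default fast parser can be 1 ulp off
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------
# Calibration JSON


def calibration_to_dict(calibration: CalibrationSet) -> dict:
    return {
        "models": [
            {
                "frequency_hz": m.frequency,
                "channel": m.channel.value,
                "form": m.form.value,
                "alpha": list(m.alpha),
                "alpha_interaction": m.alpha_interaction,
                "r": m.r,
            }
            for m in calibration
        ]
    }


def calibration_from_dict(payload: dict) -> CalibrationSet:
    models = [
        RegressionModel(
            alpha=tuple(entry["alpha"]),
            frequency=float(entry["frequency_hz"]),
            channel=Channel(entry["channel"]),
            form=ModelForm(entry.get("form", "quadratic")),
            r=entry.get("r"),
            alpha_interaction=float(entry.get("alpha_interaction", 0.0)),
        )
        for entry in payload["models"]
    ]
    return CalibrationSet.from_models(models)


def write_calibration_json(path: str | Path, calibration: CalibrationSet) -> None:
    Path(path).write_text(json.dumps(calibration_to_dict(calibration), indent=2))


def read_calibration_json(path: str | Path) -> CalibrationSet:
    return calibration_from_dict(json.loads(Path(path).read_text()))


def result_to_dict(result: EstimationResult) -> dict:
    """JSON-ready audit document for one estimation."""
    doc = asdict(result)
    doc["estimate_mM"] = {"NaCl": result.x1_hat, "KCl": result.x2_hat}
    doc["initial_estimate_mM"] = (
        None
        if result.x1_init is None
        else {"NaCl": result.x1_init, "KCl": result.x2_init}
    )
    return doc
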