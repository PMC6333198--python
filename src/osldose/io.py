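"""CSV readers for the plain-text interchange formats.

Readings: one row per read — ``dosimeter_id, batch_id, read_index, counts``
(an optional ``condition`` column groups dosimeters by irradiation).
Sensitivities: ``dosimeter_id, k_s, batch_id, batch_mean``.
Chamber: ``reading_q, temperature_C, pressure_kPa, N_k, P_elec, muen_ratio``
(optional ``condition``).
"""

from __future__ import annotations

import pandas as pd

from .chamber import ChamberCalibration, ChamberMeasurement
from .signal import ElementSensitivity, RawReadingSequence

__all__ = ["read_readings_csv", "read_sensitivity_csv", "read_chamber_csv"]


def read_readings_csv(path) -> dict[object, list[RawReadingSequence]]:
    """Reading sequences grouped by condition (key ``None`` if no column)."""
    df = pd.read_csv(path)
    required = {"dosimeter_id", "batch_id", "read_index", "counts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readings CSV missing columns: {sorted(missing)}")
    has_cond = "condition" in df.columns
    out: dict[object, list[RawReadingSequence]] = {}
    group_cols = (["condition"] if has_cond else []) + ["dosimeter_id"]
    for key, grp in df.groupby(group_cols, sort=True):
        cond = key[0] if has_cond else None
        if hasattr(cond, "item"):
            cond = cond.item()
        grp = grp.sort_values("read_index")
        if list(grp["read_index"]) != list(range(1, len(grp) + 1)):
            raise ValueError(
                f"read_index for dosimeter {key[-1]!r} must be 1..J without gaps"
            )
        seq = RawReadingSequence(
            str(key[-1]), str(grp["batch_id"].iloc[0]), tuple(grp["counts"])
        )
        out.setdefault(cond, []).append(seq)
    return out


def read_sensitivity_csv(path) -> dict[str, ElementSensitivity]:
    df = pd.read_csv(path)
    return {
        str(r.dosimeter_id): ElementSensitivity(
            str(r.dosimeter_id), float(r.k_s), str(r.batch_id), float(r.batch_mean)
        )
        for r in df.itertuples()
    }


def read_chamber_csv(path) -> dict[object, list[tuple[ChamberMeasurement, ChamberCalibration]]]:
    """Chamber measurement/calibration pairs grouped by condition."""
    df = pd.read_csv(path)
    out: dict[object, list[tuple[ChamberMeasurement, ChamberCalibration]]] = {}
    for r in df.itertuples():
        cond = getattr(r, "condition", None)
        m = ChamberMeasurement(float(r.reading_q), float(r.temperature_C), float(r.pressure_kPa))
        cal = ChamberCalibration(float(r.N_k), float(r.P_elec), float(r.muen_ratio))
        out.setdefault(cond, []).append((m, cal))
    return out
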