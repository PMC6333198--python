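"""Absorbed dose to water from a calibrated, corrected OSLD signal.

The general dose equation is multiplicative:

    D = M_corr * N_D,W * k_L * k_F * k_G * k_theta * k_Q

Each protocol specialises it: the vendor path uses only the vendor
coefficient and the vendor's constant energy correction; the free-in-air CT
path has unit geometry correction; the megavoltage path includes
k_G = 1.03.  The variance of the dose follows from the exact product-moment
recursion over the factor chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCoefficient
from .factors import CorrectionFactorSet, MeasurementCondition
from .signal import CorrectedSignal
from .uncertainty import var_chain

__all__ = [
    "DoseResult",
    "ProtocolMismatchError",
    "compute_dose",
    "percent_difference",
    "comparison_summary",
]


class ProtocolMismatchError(ValueError):
    """Calibration coefficient and correction factors come from different protocols."""


@dataclass(frozen=True)
class DoseResult:
    """Absorbed dose to water with its propagated variance."""

    dose_mGy: float
    variance: float
    protocol: str
    condition: MeasurementCondition | None = None

    def __post_init__(self) -> None:
        if self.dose_mGy <= 0:
            raise ValueError("dose must be positive")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")

    @property
    def two_sigma_mGy(self) -> float:
        return 2.0 * math.sqrt(self.variance)

    @property
    def rel_two_sigma_pct(self) -> float:
        return 100.0 * self.two_sigma_mGy / self.dose_mGy


def compute_dose(
    signal: CorrectedSignal,
    nd: CalibrationCoefficient,
    factors: CorrectionFactorSet,
    condition: MeasurementCondition | None = None,
) -> DoseResult:
    """Dose = signal * N_D * k_L * k_F * k_G * k_theta * k_Q with exact variance."""
    if nd.protocol != factors.protocol:
        raise ProtocolMismatchError(
            f"coefficient is {nd.protocol!r} but factors are {factors.protocol!r}"
        )
    if signal.value <= 0:
        raise ValueError("corrected signal must be positive")
    chain = [signal.as_quantity(), nd.as_quantity(), *factors.as_list()]
    total = var_chain(chain)
    return DoseResult(total.expected, total.variance, nd.protocol, condition)


def percent_difference(reference: float | DoseResult, test: float | DoseResult,
                       signed: bool = False) -> float:
    """Percent difference of a test dose from a reference dose.

    Unsigned by default, 100*|ref - test|/ref, the convention used when
    summarising protocol accuracy; ``signed=True`` returns
    100*(ref - test)/ref (positive when the test dose underestimates).
    """
    ref = reference.dose_mGy if isinstance(reference, DoseResult) else float(reference)
    tst = test.dose_mGy if isinstance(test, DoseResult) else float(test)
    if ref <= 0:
        raise ValueError("reference dose must be positive")
    diff = 100.0 * (ref - tst) / ref
    return diff if signed else abs(diff)


def comparison_summary(
    rows: Sequence[dict],
    protocols: Sequence[str] = ("vendor", "ct_air", "megavoltage"),
) -> pd.DataFrame:
    """Per-condition percent differences against a reference dose, plus averages.

    Each row is a mapping with a ``"chamber_mGy"`` reference and one
    ``"<protocol>_mGy"`` dose per protocol (extra keys such as condition ids
    are carried through).  Returns one output row per input condition with
    ``<protocol>_pct_diff`` columns, and a final ``"average"`` row holding
    the unweighted mean of the absolute percent differences per protocol.
    """
    if len(rows) == 0:
        raise ValueError("comparison needs at least one row")
    records = []
    for row in rows:
        rec = dict(row)
        for p in protocols:
            rec[f"{p}_pct_diff"] = percent_difference(row["chamber_mGy"], row[f"{p}_mGy"])
        records.append(rec)
    out = pd.DataFrame(records)
    avg = {f"{p}_pct_diff": float(np.mean(out[f"{p}_pct_diff"])) for p in protocols}
    avg["condition"] = "average"
    return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)
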