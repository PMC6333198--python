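"""Calibration coefficients N_D,W for the three OSLD calibration protocols.

A calibration coefficient converts corrected reader counts to absorbed dose
to water, N_D,W = delivered dose (mGy) / OSLD signal (counts), derived from
standards irradiated to a known dose.  Three protocols are supported:

* ``vendor`` — pre-irradiated standards supplied with the reader (80 kVp on
  PMMA, nominal levels 0/3/20 mGy, delivered-dose uncertainty 5% at
  2 sigma), with a batch-sensitivity adjustment between the calibration and
  experimental production batches;
* ``ct_air`` — standards irradiated free-in-air at isocenter with a 120 kVp
  CT beam, dose defined by a calibrated ion chamber under identical
  conditions;
* ``megavoltage`` — standards irradiated in a Co-60 beam, dose from
  decay-corrected reference dosimetry (0.9% at 2 sigma).

Coefficient variances follow from the exact product-moment identity applied
to the dose-over-signal quotient, treating the delivered dose and the
pooled signal as independent.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal import CorrectedSignal, pool_corrected_signals
from .uncertainty import UncertainQuantity, var_product

__all__ = [
    "CalibrationCoefficient",
    "Co60Source",
    "VendorStandardSet",
    "derive_coefficient",
    "vendor_batch_adjustment",
    "calibrate_vendor",
    "calibrate_ct_air",
    "decay_corrected_dose",
    "calibrate_megavoltage",
]

#: Relative 2-sigma uncertainty of the dose delivered to vendor standards.
VENDOR_DOSE_REL_2SIGMA_PCT = 5.0
#: Relative 2-sigma uncertainty of megavoltage reference dosimetry.
MV_DOSE_REL_2SIGMA_PCT = 0.9
#: Co-60 half-life in days.
CO60_HALF_LIFE_DAYS = 1925.28


@dataclass(frozen=True)
class CalibrationCoefficient:
    """Dose-to-water per reader count, with variance and protocol tag."""

    value: float
    variance: float
    protocol: str
    batch_id: str = ""
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("calibration coefficient must be positive")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")

    @property
    def rel_two_sigma_pct(self) -> float:
        return 200.0 * math.sqrt(self.variance) / self.value

    def as_quantity(self, label: str = "N_D") -> UncertainQuantity:
        return UncertainQuantity(self.value, self.variance, label)

    def to_record(self) -> dict:
        return {
            "value_mGy_per_count": self.value,
            "variance": self.variance,
            "rel_two_sigma_pct": self.rel_two_sigma_pct,
            "protocol": self.protocol,
            "batch_id": self.batch_id,
            **self.provenance,
        }


@dataclass(frozen=True)
class Co60Source:
    """A Co-60 teletherapy source characterised at a reference date."""

    dose_rate_at_ref_mGy_per_min: float
    reference_date: _dt.date
    half_life_days: float = CO60_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if self.dose_rate_at_ref_mGy_per_min <= 0 or self.half_life_days <= 0:
            raise ValueError("dose rate and half-life must be positive")


@dataclass(frozen=True)
class VendorStandardSet:
    """Vendor-irradiated standards: dose levels with their pooled signals."""

    dose_levels_mGy: tuple[float, ...]
    signals: tuple[CorrectedSignal, ...]
    calibration_batch_mean_sensitivity: float
    experimental_batch_mean_sensitivity: float

    def __post_init__(self) -> None:
        if len(self.dose_levels_mGy) != len(self.signals):
            raise ValueError("dose levels and signals must have equal length")
        if any(d < 0 for d in self.dose_levels_mGy):
            raise ValueError("dose levels must be non-negative")
        if (
            self.calibration_batch_mean_sensitivity <= 0
            or self.experimental_batch_mean_sensitivity <= 0
        ):
            raise ValueError("batch mean sensitivities must be positive")


def derive_coefficient(
    delivered_dose: UncertainQuantity,
    signal: CorrectedSignal,
    protocol: str = "ct_air",
    batch_id: str = "",
) -> CalibrationCoefficient:
    """N_D,W = delivered dose / signal, with exact quotient-moment variance.

    The quotient is treated as the product of the dose and the inverse
    signal; the inverse carries the same relative variance as the signal
    (exact to second order in the relative spread, which is well below a
    percent here).
    """
    if signal.value <= 0:
        raise ValueError("signal must be positive to derive a coefficient")
    if delivered_dose.expected <= 0:
        raise ValueError("delivered dose must be positive")
    inv_signal = UncertainQuantity(
        1.0 / signal.value,
        signal.variance / signal.value**4,
        label="1/M_corr",
    )
    q = var_product(delivered_dose, inv_signal)
    return CalibrationCoefficient(q.expected, q.variance, protocol, batch_id)


def vendor_batch_adjustment(v: VendorStandardSet) -> float:
    """Batch-sensitivity ratio applied to the vendor coefficient.

    The vendor's calibration standards and the experimental dosimeters come
    from different production batches; the ratio of mean inherent
    sensitivities (experimental / calibration) rescales the coefficient to
    the experimental batch.
    """
    return v.experimental_batch_mean_sensitivity / v.calibration_batch_mean_sensitivity


def calibrate_vendor(
    v: VendorStandardSet,
    dose_rel_2sigma_pct: float = VENDOR_DOSE_REL_2SIGMA_PCT,
    per_level: bool = False,
) -> CalibrationCoefficient | list[CalibrationCoefficient]:
    """Vendor-protocol coefficient from multi-level standards.

    Fits dose = N_D * signal through the origin across the non-zero dose
    levels (weighted by inverse signal variance where available), then
    applies the batch-sensitivity adjustment.  The delivered-dose
    uncertainty is systematic across levels (one irradiator), so it does not
    average down with the number of levels.  With ``per_level=True`` a
    separate adjusted coefficient is returned for each non-zero level.
    """
    adjustment = vendor_batch_adjustment(v)
    pairs = [
        (d, s) for d, s in zip(v.dose_levels_mGy, v.signals) if d > 0
    ]
    if not pairs:
        raise ValueError("vendor calibration needs at least one non-zero dose level")

    if per_level:
        out = []
        for d, s in pairs:
            dose = UncertainQuantity.from_relative(d, dose_rel_2sigma_pct, "D_vendor")
            c = derive_coefficient(dose, s, protocol="vendor")
            out.append(
                CalibrationCoefficient(
                    c.value * adjustment, c.variance * adjustment**2, "vendor"
                )
            )
        return out

    if len(pairs) < 2:
        raise ValueError("through-origin fit needs at least two non-zero levels")
    doses = np.array([d for d, _ in pairs])
    sigs = np.array([s.value for _, s in pairs])
    svar = np.array([s.variance for _, s in pairs])
    # weights: inverse variance of the dose residual; with constant relative
    # uncertainties this is ~1/d^2, keeping low and high levels comparable
    w = 1.0 / np.square(doses)
    slope = float(np.sum(w * sigs * doses) / np.sum(w * sigs**2))

    # reading-noise contribution to the slope, by WLS error propagation
    denom = float(np.sum(w * sigs**2))
    dslope_dsig = (w * doses - 2.0 * slope * w * sigs) / denom
    var_from_signal = float(np.sum(dslope_dsig**2 * svar))
    rel_var_signal = var_from_signal / slope**2
    # systematic delivered-dose uncertainty, not reduced by the fit
    rel_var_dose = (dose_rel_2sigma_pct / 200.0) ** 2
    q = var_product(
        UncertainQuantity(1.0, rel_var_dose, "D_rel"),
        UncertainQuantity(slope, rel_var_signal * slope**2, "fit"),
    )
    return CalibrationCoefficient(
        q.expected * adjustment,
        q.variance * adjustment**2,
        "vendor",
        provenance={"batch_adjustment": adjustment, "n_levels": len(pairs)},
    )


def calibrate_ct_air(
    osld_signals: Sequence[CorrectedSignal],
    chamber_doses: Sequence[UncertainQuantity],
    batch_id: str = "",
) -> CalibrationCoefficient:
    """Free-in-air CT coefficient: pooled chamber dose over pooled signal.

    Repeated chamber readings share the calibration chain, so the pooled
    dose keeps the systematic relative uncertainty of a single reading
    (the mean of the individual variances) rather than dividing it by the
    number of readings.
    """
    if not osld_signals or not chamber_doses:
        raise ValueError("ct_air calibration needs signals and chamber doses")
    pooled_signal = pool_corrected_signals(list(osld_signals))
    mean_dose = sum(d.expected for d in chamber_doses) / len(chamber_doses)
    dose_var = sum(d.variance for d in chamber_doses) / len(chamber_doses)
    dose = UncertainQuantity(mean_dose, dose_var, label="D_CT")
    c = derive_coefficient(dose, pooled_signal, protocol="ct_air", batch_id=batch_id)
    return CalibrationCoefficient(
        c.value,
        c.variance,
        "ct_air",
        batch_id,
        provenance={
            "n_dosimeters": len(osld_signals),
            "n_chamber_readings": len(chamber_doses),
        },
    )


def decay_corrected_dose(
    src: Co60Source,
    irradiation_date: _dt.date,
    beam_on_time_min: float,
    dose_rel_2sigma_pct: float = MV_DOSE_REL_2SIGMA_PCT,
) -> UncertainQuantity:
    """Delivered dose (mGy) from a decay-corrected Co-60 dose rate.

    dose = rate(ref) * 2^(-dt / T_half) * time, with the configured
    reference-dosimetry relative uncertainty attached.
    """
    if beam_on_time_min <= 0:
        raise ValueError("beam-on time must be positive")
    dt_days = (irradiation_date - src.reference_date).days
    if dt_days < 0:
        raise ValueError("irradiation predates the source reference date")
    rate = src.dose_rate_at_ref_mGy_per_min * 2.0 ** (-dt_days / src.half_life_days)
    return UncertainQuantity.from_relative(
        rate * beam_on_time_min, dose_rel_2sigma_pct, label="D_Co60"
    )


def calibrate_megavoltage(
    signals: Sequence[CorrectedSignal],
    delivered: UncertainQuantity,
    batch_id: str = "",
) -> CalibrationCoefficient:
    """Megavoltage (Co-60) coefficient: delivered dose over pooled signal."""
    if not signals:
        raise ValueError("megavoltage calibration needs at least one signal")
    pooled = pool_corrected_signals(list(signals))
    c = derive_coefficient(delivered, pooled, protocol="megavoltage", batch_id=batch_id)
    return CalibrationCoefficient(
        c.value,
        c.variance,
        "megavoltage",
        batch_id,
        provenance={"n_dosimeters": len(signals)},
    )
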