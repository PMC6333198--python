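"""Ion-chamber dose to water under the point-dose (TG-111 style) formalism.

A vented farmer-type chamber reading q is converted to absorbed dose to
water as

    D_water = q * P_TP * P_elec * N_k * (mu_en/rho)^water_air

with the temperature-pressure factor normalising the open-to-atmosphere air
mass to reference density, the electrometer factor, the air-kerma
calibration coefficient of the chamber, and the water-to-air ratio of mass
energy-absorption coefficients for the beam quality in use.
"""

from __future__ import annotations

from dataclasses import dataclass

from .uncertainty import UncertainQuantity

__all__ = [
    "ChamberMeasurement",
    "ChamberCalibration",
    "ReferenceConditions",
    "pressure_temperature_factor",
    "chamber_dose_to_water",
]

_ZERO_CELSIUS_OFFSET = 273.2

#: Delivered-dose relative 2-sigma uncertainty for a free-in-air CT
#: reference measurement (calibrated chamber + TG-111 conversion).
DEFAULT_CT_DOSE_REL_2SIGMA_PCT = 5.0


@dataclass(frozen=True)
class ReferenceConditions:
    """Calibration reference conditions for the P_TP normalisation.

    Defaults follow the common ADCL convention of 22 degC and 101.33 kPa.
    """

    temperature_C: float = 22.0
    pressure_kPa: float = 101.33


@dataclass(frozen=True)
class ChamberMeasurement:
    """One chamber reading with the ambient conditions at acquisition."""

    reading_q: float
    temperature_C: float = 22.0
    pressure_kPa: float = 101.33

    def __post_init__(self) -> None:
        if self.reading_q <= 0:
            raise ValueError("chamber reading must be positive")
        if self.pressure_kPa <= 0:
            raise ValueError("pressure must be positive")
        if self.temperature_C <= -_ZERO_CELSIUS_OFFSET:
            raise ValueError("temperature below absolute zero")


@dataclass(frozen=True)
class ChamberCalibration:
    """Chamber/electrometer calibration data and the medium conversion ratio.

    ``muen_ratio_water_air`` is the water-to-air mass energy-absorption
    coefficient ratio for the measurement beam quality; it is a required
    physics input (about 1.06 for diagnostic CT qualities) and deliberately
    not hard-coded anywhere else.
    """

    N_k: float
    P_elec: float = 1.0
    muen_ratio_water_air: float = 1.06

    def __post_init__(self) -> None:
        for name in ("N_k", "P_elec", "muen_ratio_water_air"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pressure_temperature_factor(
    m: ChamberMeasurement, ref: ReferenceConditions = ReferenceConditions()
) -> float:
    """Air-density correction ((273.2+T)/(273.2+T_ref)) * (P_ref/P)."""
    return (
        (_ZERO_CELSIUS_OFFSET + m.temperature_C)
        / (_ZERO_CELSIUS_OFFSET + ref.temperature_C)
        * (ref.pressure_kPa / m.pressure_kPa)
    )


def chamber_dose_to_water(
    m: ChamberMeasurement,
    cal: ChamberCalibration,
    ref: ReferenceConditions = ReferenceConditions(),
    dose_rel_2sigma_pct: float = DEFAULT_CT_DOSE_REL_2SIGMA_PCT,
) -> UncertainQuantity:
    """Absorbed dose to water (mGy) from one chamber measurement.

    The expected value is the plain product of the reading and all factors.
    The variance is attached as a single relative 2-sigma uncertainty on the
    delivered dose (default 5%), covering the chamber calibration chain; set
    it to 0 to obtain an exact value, or propagate per-factor uncertainties
    separately with the uncertainty module.
    """
    p_tp = pressure_temperature_factor(m, ref)
    dose = m.reading_q * p_tp * cal.P_elec * cal.N_k * cal.muen_ratio_water_air
    return UncertainQuantity.from_relative(dose, dose_rel_2sigma_pct, label="D_chamber")


def pooled_chamber_dose(
    doses: list[UncertainQuantity],
    systematic_rel_2sigma_pct: float | None = None,
) -> UncertainQuantity:
    """Mean of repeated chamber doses.

    Repeated readings share the chamber calibration chain, so the dominant
    (systematic) uncertainty does not average down with the number of
    readings.  If ``systematic_rel_2sigma_pct`` is given it is applied to the
    mean; otherwise the (conservative) mean of the individual variances is
    kept, again without 1/n reduction.
    """
    if not doses:
        raise ValueError("cannot pool an empty list of doses")
    mean = sum(d.expected for d in doses) / len(doses)
    if systematic_rel_2sigma_pct is not None:
        return UncertainQuantity.from_relative(mean, systematic_rel_2sigma_pct, "D_ref")
    var = sum(d.variance for d in doses) / len(doses)
    return UncertainQuantity(mean, var, label="D_ref")
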