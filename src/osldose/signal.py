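"""Corrected OSLD signal from repeated reader counts.

Each optical readout of an Al2O3:C dosimeter depletes a small fraction of
the trapped signal (about 1.6% per read at the strong-LED, 7-s setting), so
the j-th raw count must be restored to its first-read equivalent before
averaging.  The corrected mean signal for dosimeter i is

    M_corr = k_s,i * [ sum_j M_raw,j,i * c_d^(j-1) ] / J  -  M_bkg

where c_d = 1 / (1 - per-read loss) is the restoring depletion correction,
k_s,i the element sensitivity of the dosimeter relative to its batch, J the
number of reads and M_bkg an optional background in counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .uncertainty import UncertainQuantity

__all__ = [
    "RawReadingSequence",
    "DepletionModel",
    "ElementSensitivity",
    "CorrectedSignal",
    "correct_reading_sequence",
    "pool_corrected_signals",
    "measure_element_sensitivity",
]

#: Default relative 2-sigma reading uncertainty used when only one read is
#: available and no sample variance can be formed (reader repeatability).
DEFAULT_READER_NOISE_REL_2SIGMA_PCT = 0.8


class NonPhysicalSignalError(ValueError):
    """Corrected signal came out non-positive for an irradiated dosimeter."""


@dataclass(frozen=True)
class RawReadingSequence:
    """Ordered raw counts from repeated reads of one dosimeter."""

    dosimeter_id: str
    batch_id: str
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(float(c) for c in self.counts))
        if len(self.counts) == 0:
            raise ValueError("a reading sequence needs at least one read")
        if any(c < 0 for c in self.counts):
            raise ValueError("reader counts must be non-negative")

    @property
    def n_reads(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class DepletionModel:
    """Per-read signal loss of the reader/dosimeter combination.

    ``per_read_loss`` is the physical fraction lost at each readout (0.016
    for the nanoDot at the strong-LED 7-s setting).  ``restoring`` selects
    whether later reads are corrected *up* to first-read equivalence
    (default, the convention required for calibration against a known dose)
    or multiplied by the raw retention factor (1 - loss)^(j-1).
    """

    per_read_loss: float = 0.016
    restoring: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_read_loss < 0.5:
            raise ValueError("per_read_loss must lie in [0, 0.5)")

    def correction(self, read_index: int) -> float:
        """Multiplier for the read at 1-based index j."""
        if read_index < 1:
            raise ValueError("read_index is 1-based")
        retention = 1.0 - self.per_read_loss
        if self.restoring:
            return retention ** -(read_index - 1)
        return retention ** (read_index - 1)


@dataclass(frozen=True)
class ElementSensitivity:
    """Relative sensitivity of one dosimeter within its batch."""

    dosimeter_id: str
    k_s: float
    batch_id: str = ""
    batch_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.k_s <= 0:
            raise ValueError("element sensitivity k_s must be positive")
        if self.batch_mean <= 0:
            raise ValueError("batch mean sensitivity must be positive")


@dataclass(frozen=True)
class CorrectedSignal:
    """Depletion/sensitivity/background-corrected mean signal with variance."""

    value: float
    variance: float = 0.0
    n_dosimeters: int = 1
    n_reads_each: int = 1
    dosimeter_id: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.variance)

    @property
    def rel_two_sigma_pct(self) -> float:
        return 200.0 * self.sigma / abs(self.value)

    def as_quantity(self, label: str = "M_corr") -> UncertainQuantity:
        return UncertainQuantity(self.value, self.variance, label)


def correct_reading_sequence(
    seq: RawReadingSequence,
    dep: DepletionModel | None = None,
    sens: ElementSensitivity | None = None,
    background: float = 0.0,
    reader_noise_rel_2sigma_pct: float = DEFAULT_READER_NOISE_REL_2SIGMA_PCT,
) -> CorrectedSignal:
    """Corrected mean signal of one dosimeter from its ordered reads.

    Each read j is multiplied by the depletion correction c_d^(j-1), the
    mean over reads is scaled by the element sensitivity, and the background
    (treated as exact) is subtracted last.  The variance is the unbiased
    sample variance of the corrected, sensitivity-scaled reads divided by J;
    with a single read it falls back to the configured reader-noise model.
    """
    dep = dep if dep is not None else DepletionModel()
    k_s = sens.k_s if sens is not None else 1.0
    if background < 0:
        raise ValueError("background must be non-negative")

    counts = np.asarray(seq.counts, dtype=float)
    j = np.arange(1, counts.size + 1)
    corrected = k_s * counts * np.array([dep.correction(int(i)) for i in j])
    value = float(corrected.mean()) - background
    if counts.size > 1:
        variance = float(np.var(corrected, ddof=1)) / counts.size
    else:
        sigma = abs(value) * reader_noise_rel_2sigma_pct / 200.0
        variance = sigma * sigma
    if value <= 0:
        raise NonPhysicalSignalError(
            f"corrected signal {value:.3g} counts is non-positive for "
            f"dosimeter {seq.dosimeter_id!r}"
        )
    return CorrectedSignal(
        value,
        variance,
        n_dosimeters=1,
        n_reads_each=counts.size,
        dosimeter_id=seq.dosimeter_id,
        batch_id=seq.batch_id,
    )


def pool_corrected_signals(signals: Sequence[CorrectedSignal]) -> CorrectedSignal:
    """Average the corrected signals of several dosimeters read under one condition.

    The pooled value is the unweighted mean.  Its variance combines the
    between-dosimeter scatter of the values (population variance over n,
    i.e. the plug-in variance of the mean) with the average within-dosimeter
    variance carried by each signal, also reduced by n.
    """
    if len(signals) == 0:
        raise ValueError("cannot pool an empty list of signals")
    values = np.array([s.value for s in signals], dtype=float)
    n = values.size
    between = float(np.var(values)) / n
    within = float(np.mean([s.variance for s in signals])) / n
    reads = {s.n_reads_each for s in signals}
    return CorrectedSignal(
        float(values.mean()),
        between + within,
        n_dosimeters=n,
        n_reads_each=reads.pop() if len(reads) == 1 else 0,
        batch_id=signals[0].batch_id,
    )


def measure_element_sensitivity(
    signals_at_common_dose: Sequence[CorrectedSignal],
    batch_id: str = "",
) -> list[ElementSensitivity]:
    """Element sensitivities from a batch irradiated to one common dose.

    Each dosimeter's k_s is its own corrected signal divided by the batch
    mean signal, so the returned factors average to exactly 1 over the batch
    that defined them.
    """
    if len(signals_at_common_dose) < 2:
        raise ValueError("element sensitivity needs at least two dosimeters")
    values = np.array([s.value for s in signals_at_common_dose], dtype=float)
    if np.any(values <= 0):
        raise ValueError("all common-dose signals must be positive")
    batch_mean = float(values.mean())
    return [
        ElementSensitivity(
            dosimeter_id=s.dosimeter_id,
            k_s=float(s.value / batch_mean),
            batch_id=batch_id or s.batch_id,
            batch_mean=batch_mean,
        )
        for s in signals_at_common_dose
    ]
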