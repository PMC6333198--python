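"""Seeded synthetic OSLD/CT sessions with the statistical structure the
analysis assumes.

The generator builds an internally consistent *scanner truth model*: one
physical dosimeter response per measurement condition, viewed through three
calibration protocols.  The corrected-signal truth for condition ``c`` is

    S(c) = D(c) / (N_CT * k_Q,CT(c))

with k_Q,CT seeded from the shipped energy table, and the other protocols'
true coefficients and beam-quality factors derived from the same response so
that every protocol chain reproduces the same dose:

    N_Co * k_G * k_Q,Co(c) = N_CT * k_Q,CT(c) = N_vendor * k_Q,vendor(c)

Raw counts for dosimeter i, read j are

    counts = S * (s_exp / s_batch) / k_s,i * (1 - d)^(j-1) * noise

so that the depletion correction, the element-sensitivity multiplication and
(for vendor standards) the batch-sensitivity adjustment exactly invert the
generation at zero noise.  Noise is multiplicative lognormal (signals are
positive and uncertainties are quoted relatively); a Gaussian switch is
provided.  Element sensitivities are drawn lognormally around the batch
mean; the sensitivity value *available to the analysis* differs from the
true one by a small assignment error, which is what makes the corrected
signal uncertain even after perfect depletion correction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCoefficient,
    VendorStandardSet,
    calibrate_ct_air,
    calibrate_megavoltage,
    calibrate_vendor,
)
from .chamber import (
    ChamberCalibration,
    ChamberMeasurement,
    ReferenceConditions,
    chamber_dose_to_water,
    pressure_temperature_factor,
)
from .factors import MeasurementCondition, load_factor_tables
from .signal import (
    CorrectedSignal,
    DepletionModel,
    ElementSensitivity,
    RawReadingSequence,
    correct_reading_sequence,
    pool_corrected_signals,
)
from .uncertainty import UncertainQuantity

__all__ = [
    "ScannerTruthModel",
    "SyntheticSession",
    "CalibrationSession",
    "simulate_reading_sequence",
    "simulate_calibration_session",
    "simulate_study",
    "load_reference_conditions",
]

EXPERIMENTAL_BATCH = "experimental"
CALIBRATION_BATCH = "calibration"


def load_reference_conditions() -> pd.DataFrame:
    """The eleven packaged validation conditions with their measured doses."""
    cond = pd.read_csv(
        resources.files("osldose.data").joinpath("measurement_conditions.csv")
    )
    doses = pd.read_csv(
        resources.files("osldose.data").joinpath("dose_comparison.csv")
    )[["condition", "chamber_mGy"]]
    return cond.merge(doses, on="condition")


@dataclass(frozen=True)
class ScannerTruthModel:
    """Ground truth for simulation: doses, response, and noise scales.

    Noise defaults: per-read relative spread 0.4% (1 sigma; 0.8% at 2 sigma),
    element-sensitivity assignment error 0.5% (1.0% at 2 sigma), depletion
    1.6% per read, batch mean inherent sensitivities 0.85 (calibration
    standards batch) and 0.93 (experimental batch).  ``batch_spread_rel`` is
    the manufacturing spread of true sensitivities within a batch (5% at
    1 sigma), which the per-dosimeter correction removes up to the
    assignment error.
    """

    true_dose_mGy: dict[int, float]
    conditions: dict[int, MeasurementCondition]
    true_nd: dict[str, float]
    true_kq: dict[tuple[str, int], float]
    k_g: dict[str, float] = field(
        default_factory=lambda: {"vendor": 1.0, "ct_air": 1.0, "megavoltage": 1.03}
    )
    read_noise_rel: float = 0.004
    sensitivity_error_rel: float = 0.005
    batch_spread_rel: float = 0.05
    depletion_per_read: float = 0.016
    batch_means: dict[str, float] = field(
        default_factory=lambda: {CALIBRATION_BATCH: 0.85, EXPERIMENTAL_BATCH: 0.93}
    )
    dose_ref_rel_2sigma_pct: dict[str, float] = field(
        default_factory=lambda: {"vendor": 5.0, "ct_air": 5.0, "megavoltage": 0.9}
    )
    chamber_repeat_rel: float = 0.003
    ct_cal_dose_mGy: float = 30.0
    mv_cal_dose_mGy: float = 45.0
    vendor_levels_mGy: tuple[float, ...] = (3.0, 20.0)
    noise_family: str = "lognormal"

    @classmethod
    def from_reference_tables(
        cls,
        nd_ct_mGy_per_count: float = 1.0 / 1200.0,
        vendor_response_ratio: float = 0.66,
        **overrides,
    ) -> "ScannerTruthModel":
        """Truth seeded from the packaged condition list and factor tables.

        ``vendor_response_ratio`` is the true vendor coefficient relative to
        the free-in-air CT one (the vendor's softer 80 kVp calibration beam
        over-stimulates the Al2O3:C response, so its dose-per-count is
        lower).  The default 0.66 anchors the vendor chain at the softest
        measured spectrum, where the vendor's constant energy correction is
        nearly adequate; at all harder spectra the constant correction then
        under-corrects by a growing amount, the observed clinical behaviour.
        """
        ref = load_reference_conditions()
        tables = load_factor_tables()
        energy_nodes = dict(tables.kq["ct_air"].by_energy)
        co_nodes = dict(tables.kq["megavoltage"].by_energy)

        conditions: dict[int, MeasurementCondition] = {}
        doses: dict[int, float] = {}
        kq: dict[tuple[str, int], float] = {}
        ratios = []
        for row in ref.itertuples():
            cid = int(row.condition)
            conditions[cid] = MeasurementCondition(
                kvp=int(row.kvp),
                position=str(row.position),
                phantom=str(row.phantom),
                scan_type=str(row.scan_type),
                scan_extent_mm=float(row.scan_extent_mm),
                mean_spectral_energy_keV=float(row.mean_energy_keV),
                condition_id=cid,
            )
            doses[cid] = float(row.chamber_mGy)
            kq_ct = energy_nodes[float(row.mean_energy_keV)]
            kq[("ct_air", cid)] = kq_ct
            ratios.append(kq_ct / co_nodes[float(row.mean_energy_keV)])

        # one consistent Co-60 coefficient: anchor the mean of the implied
        # megavoltage k_Q values on the tabulated ones
        mean_ratio = float(np.mean(ratios))
        k_g_mv = 1.03
        nd_mv = nd_ct_mGy_per_count * mean_ratio / k_g_mv
        nd_vendor = nd_ct_mGy_per_count * vendor_response_ratio
        for cid in conditions:
            kq_ct = kq[("ct_air", cid)]
            kq[("megavoltage", cid)] = kq_ct / mean_ratio
            kq[("vendor", cid)] = kq_ct / vendor_response_ratio
        return cls(
            true_dose_mGy=doses,
            conditions=conditions,
            true_nd={
                "ct_air": nd_ct_mGy_per_count,
                "megavoltage": nd_mv,
                "vendor": nd_vendor,
            },
            true_kq=kq,
            **overrides,
        )

    def signal_counts(self, condition_id: int) -> float:
        """True corrected signal (experimental-batch scale) for a condition."""
        return self.true_dose_mGy[condition_id] / (
            self.true_nd["ct_air"] * self.true_kq[("ct_air", condition_id)]
        )

    def noise_free(self) -> "ScannerTruthModel":
        """Copy with every stochastic component switched off."""
        return dataclasses.replace(
            self,
            read_noise_rel=0.0,
            sensitivity_error_rel=0.0,
            batch_spread_rel=0.0,
            chamber_repeat_rel=0.0,
            dose_ref_rel_2sigma_pct={p: 0.0 for p in self.dose_ref_rel_2sigma_pct},
        )

    def _noise(self, rng: np.random.Generator, rel_sigma: float, size=None):
        if rel_sigma == 0.0:
            return 1.0 if size is None else np.ones(size)
        if self.noise_family == "gaussian":
            return rng.normal(1.0, rel_sigma, size)
        s2 = math.log1p(rel_sigma * rel_sigma)
        return rng.lognormal(-0.5 * s2, math.sqrt(s2), size)


def simulate_reading_sequence(
    truth: ScannerTruthModel,
    true_signal: float,
    dosimeter_id: str,
    rng: np.random.Generator,
    batch: str = EXPERIMENTAL_BATCH,
    n_reads: int = 3,
) -> tuple[RawReadingSequence, ElementSensitivity]:
    """One dosimeter's raw reads plus the sensitivity the analyst would use.

    The true sensitivity scales the counts; the returned ``ElementSensitivity``
    carries the *assigned* value (true times a small assignment error), so a
    perfect correction is only possible at zero ``sensitivity_error_rel``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    batch_mean = truth.batch_means[batch]
    exp_mean = truth.batch_means[EXPERIMENTAL_BATCH]
    k_s_true = batch_mean * float(truth._noise(rng, truth.batch_spread_rel))
    k_s_assigned = k_s_true * float(truth._noise(rng, truth.sensitivity_error_rel))

    base = true_signal * (exp_mean / batch_mean) / k_s_true
    retention = 1.0 - truth.depletion_per_read
    j = np.arange(n_reads)
    counts = base * retention**j * truth._noise(rng, truth.read_noise_rel, n_reads)
    seq = RawReadingSequence(dosimeter_id, batch, tuple(float(c) for c in counts))
    sens = ElementSensitivity(dosimeter_id, k_s_assigned, batch, batch_mean)
    return seq, sens


def _corrected(truth: ScannerTruthModel, seq: RawReadingSequence,
               sens: ElementSensitivity) -> CorrectedSignal:
    return correct_reading_sequence(
        seq, DepletionModel(truth.depletion_per_read), sens
    )


@dataclass(frozen=True)
class CalibrationSession:
    """Inputs a calibration protocol would see, generated from known truth."""

    protocol: str
    truth_nd: float
    signals: tuple[CorrectedSignal, ...] = ()
    chamber_doses: tuple[UncertainQuantity, ...] = ()
    delivered: UncertainQuantity | None = None
    vendor_set: VendorStandardSet | None = None

    def recover(self) -> CalibrationCoefficient:
        """Run the matching calibration operation on the simulated inputs."""
        if self.protocol == "vendor":
            return calibrate_vendor(self.vendor_set)
        if self.protocol == "ct_air":
            return calibrate_ct_air(list(self.signals), list(self.chamber_doses))
        return calibrate_megavoltage(list(self.signals), self.delivered)


def simulate_calibration_session(
    truth: ScannerTruthModel,
    protocol: str,
    seed: int | np.random.Generator,
    n_dosimeters: int | None = None,
    n_reads: int = 3,
) -> CalibrationSession:
    """Simulate one calibration session for a protocol.

    Defaults mirror typical practice: 6 dosimeters and 3 chamber readings
    for the free-in-air CT protocol, 4 dosimeters at 45 mGy for the Co-60
    protocol, 3 dosimeters per dose level for the vendor standards.  The
    delivered-dose error is drawn once per session (it is systematic within
    a session) with the protocol's reference-dose relative 2-sigma
    uncertainty.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sys_rel = truth.dose_ref_rel_2sigma_pct[protocol] / 200.0

    if protocol == "megavoltage":
        n = n_dosimeters or 4
        nominal = truth.mv_cal_dose_mGy
        actual = nominal * float(truth._noise(rng, sys_rel))
        s_true = actual / truth.true_nd["megavoltage"]
        signals = tuple(
            _corrected(truth, *simulate_reading_sequence(
                truth, s_true, f"mv-{i}", rng, n_reads=n_reads))
            for i in range(n)
        )
        delivered = UncertainQuantity.from_relative(
            nominal, truth.dose_ref_rel_2sigma_pct[protocol], "D_Co60"
        )
        return CalibrationSession(
            "megavoltage", truth.true_nd["megavoltage"], signals=signals,
            delivered=delivered,
        )

    if protocol == "ct_air":
        n = n_dosimeters or 6
        actual = truth.ct_cal_dose_mGy  # the chamber defines the dose; its
        # systematic error applies to the *measured* dose, not the delivery
        s_true = actual / truth.true_nd["ct_air"]
        signals = tuple(
            _corrected(truth, *simulate_reading_sequence(
                truth, s_true, f"ct-{i}", rng, n_reads=n_reads))
            for i in range(n)
        )
        chamber_sys = float(truth._noise(rng, sys_rel))
        cal = ChamberCalibration(N_k=1.0, P_elec=1.0, muen_ratio_water_air=1.06)
        ref = ReferenceConditions()
        doses = []
        for i in range(3):
            t = float(rng.uniform(20.0, 24.0))
            p = float(rng.uniform(99.0, 103.0))
            m_target = actual * chamber_sys * float(
                truth._noise(rng, truth.chamber_repeat_rel)
            )
            m = ChamberMeasurement(1.0, t, p)
            q = m_target / (
                pressure_temperature_factor(m, ref)
                * cal.P_elec * cal.N_k * cal.muen_ratio_water_air
            )
            doses.append(chamber_dose_to_water(
                ChamberMeasurement(q, t, p), cal, ref,
                dose_rel_2sigma_pct=truth.dose_ref_rel_2sigma_pct["ct_air"],
            ))
        return CalibrationSession(
            "ct_air", truth.true_nd["ct_air"], signals=signals,
            chamber_doses=tuple(doses),
        )

    if protocol == "vendor":
        n_per_level = n_dosimeters or 3
        sys_err = float(truth._noise(rng, sys_rel))  # one irradiator
        level_signals = []
        for li, d in enumerate(truth.vendor_levels_mGy):
            s_true = d * sys_err / truth.true_nd["vendor"]
            sigs = [
                _corrected(truth, *simulate_reading_sequence(
                    truth, s_true, f"v{li}-{i}", rng,
                    batch=CALIBRATION_BATCH, n_reads=n_reads))
                for i in range(n_per_level)
            ]
            level_signals.append(pool_corrected_signals(sigs))
        vset = VendorStandardSet(
            dose_levels_mGy=tuple(truth.vendor_levels_mGy),
            signals=tuple(level_signals),
            calibration_batch_mean_sensitivity=truth.batch_means[CALIBRATION_BATCH],
            experimental_batch_mean_sensitivity=truth.batch_means[EXPERIMENTAL_BATCH],
        )
        return CalibrationSession("vendor", truth.true_nd["vendor"], vendor_set=vset)

    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass(frozen=True)
class SyntheticSession:
    """A full simulated validation study over the reference conditions."""

    seed: int
    truth: ScannerTruthModel
    readings: dict[int, tuple[RawReadingSequence, ...]]
    sensitivities: dict[str, ElementSensitivity]
    chamber: dict[int, tuple[ChamberMeasurement, ...]]
    chamber_cal: ChamberCalibration

    def pooled_signal(self, condition_id: int) -> CorrectedSignal:
        sigs = [
            _corrected(self.truth, seq, self.sensitivities[seq.dosimeter_id])
            for seq in self.readings[condition_id]
        ]
        return pool_corrected_signals(sigs)

    def chamber_dose(self, condition_id: int) -> UncertainQuantity:
        doses = [
            chamber_dose_to_water(m, self.chamber_cal)
            for m in self.chamber[condition_id]
        ]
        mean = sum(d.expected for d in doses) / len(doses)
        var = sum(d.variance for d in doses) / len(doses)
        return UncertainQuantity(mean, var, "D_chamber")

    def readings_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": cid,
                "dosimeter_id": seq.dosimeter_id,
                "batch_id": seq.batch_id,
                "read_index": j + 1,
                "counts": c,
            }
            for cid, seqs in sorted(self.readings.items())
            for seq in seqs
            for j, c in enumerate(seq.counts)
        ]
        return pd.DataFrame(rows)

    def sensitivity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dosimeter_id": s.dosimeter_id,
                    "k_s": s.k_s,
                    "batch_id": s.batch_id,
                    "batch_mean": s.batch_mean,
                }
                for s in self.sensitivities.values()
            ]
        )

    def chamber_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": cid,
                "reading_q": m.reading_q,
                "temperature_C": m.temperature_C,
                "pressure_kPa": m.pressure_kPa,
                "N_k": self.chamber_cal.N_k,
                "P_elec": self.chamber_cal.P_elec,
                "muen_ratio": self.chamber_cal.muen_ratio_water_air,
            }
            for cid, ms in sorted(self.chamber.items())
            for m in ms
        ]
        return pd.DataFrame(rows)

    def truth_json(self) -> str:
        t = self.truth
        return json.dumps(
            {
                "seed": self.seed,
                "true_nd": t.true_nd,
                "true_dose_mGy": {str(k): v for k, v in t.true_dose_mGy.items()},
                "true_kq": {f"{p}:{c}": v for (p, c), v in t.true_kq.items()},
                "depletion_per_read": t.depletion_per_read,
                "read_noise_rel": t.read_noise_rel,
                "sensitivity_error_rel": t.sensitivity_error_rel,
            },
            indent=2,
        )


def simulate_study(
    truth: ScannerTruthModel,
    seed: int,
    n_dosimeters: int = 6,
    n_reads: int = 3,
    n_chamber: int = 3,
) -> SyntheticSession:
    """Simulate the full validation design over the truth model's conditions.

    For each condition: ``n_dosimeters`` experimental-batch dosimeters read
    ``n_reads`` times, plus ``n_chamber`` ion-chamber measurements of the
    same delivery.  Identical seeds give identical sessions.
    """
    rng = np.random.default_rng(seed)
    cal = ChamberCalibration(N_k=1.0, P_elec=1.0, muen_ratio_water_air=1.06)
    ref = ReferenceConditions()
    readings: dict[int, tuple[RawReadingSequence, ...]] = {}
    sens: dict[str, ElementSensitivity] = {}
    chamber: dict[int, tuple[ChamberMeasurement, ...]] = {}
    for cid in sorted(truth.conditions):
        s_true = truth.signal_counts(cid)
        seqs = []
        for i in range(n_dosimeters):
            seq, s = simulate_reading_sequence(
                truth, s_true, f"c{cid}-d{i}", rng, n_reads=n_reads
            )
            seqs.append(seq)
            sens[seq.dosimeter_id] = s
        readings[cid] = tuple(seqs)

        sys_rel = truth.dose_ref_rel_2sigma_pct["ct_air"] / 200.0
        chamber_sys = float(truth._noise(rng, sys_rel))
        ms = []
        for _ in range(n_chamber):
            t = float(rng.uniform(20.0, 24.0))
            p = float(rng.uniform(99.0, 103.0))
            target = truth.true_dose_mGy[cid] * chamber_sys * float(
                truth._noise(rng, truth.chamber_repeat_rel)
            )
            probe = ChamberMeasurement(1.0, t, p)
            q = target / (
                pressure_temperature_factor(probe, ref)
                * cal.P_elec * cal.N_k * cal.muen_ratio_water_air
            )
            ms.append(ChamberMeasurement(q, t, p))
        chamber[cid] = tuple(ms)
    return SyntheticSession(
        seed=seed, truth=truth, readings=readings, sensitivities=sens,
        chamber=chamber, chamber_cal=cal,
    )
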