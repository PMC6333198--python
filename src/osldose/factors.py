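"""Correction-factor storage, lookup and interpolation.

The dose equation applies five multiplicative corrections to the calibrated
signal: linearity (k_L), fading (k_F), irradiation geometry (k_G), angular
dependence (k_theta) and beam quality (k_Q).  Under the measurement
conventions supported here — dosimeters placed flat in the bore, no
differential fading between standards and experimental dosimeters, doses in
the linear regime — k_L, k_F and k_theta are exactly 1, k_G is 1 for
CT-based protocols and 1.03 for the megavoltage protocol, and the entire
energy dependence is carried by k_Q.

k_Q is strongly energy dependent for Al2O3:C at diagnostic energies (the
factor roughly triples between a CT spectrum and a Co-60 reference), so it
is tabulated per calibration protocol: by mean spectral energy at the
dosimeter when the spectrum is known, or by nominal kVp and measurement
position as the clinical simplification.  Tables ship as versioned package
data because they are scanner-spectrum specific.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import yaml

from .uncertainty import UncertainQuantity

__all__ = [
    "Protocol",
    "MeasurementCondition",
    "CorrectionFactorSet",
    "KqTable",
    "load_factor_tables",
    "lookup_kq",
    "lookup_kq_by_energy",
    "factor_set_for",
]

Protocol = Literal["vendor", "ct_air", "megavoltage"]
PROTOCOLS: tuple[str, ...] = ("vendor", "ct_air", "megavoltage")

_VALID_KVP = (80, 120, 140)
_VALID_POSITIONS = ("center", "periphery", "surface", "free-in-air")


class LookupError_(KeyError):
    """A requested (kVp, position) or energy key is not tabulated."""


@dataclass(frozen=True)
class MeasurementCondition:
    """A CT irradiation condition as relevant to dosimeter response."""

    kvp: int
    position: str
    phantom: str = "none"
    scan_type: str = "axial"
    scan_extent_mm: float = 40.0
    mean_spectral_energy_keV: float | None = None
    condition_id: int | None = None

    def __post_init__(self) -> None:
        if self.kvp not in _VALID_KVP:
            raise ValueError(f"kvp must be one of {_VALID_KVP}, got {self.kvp}")
        if self.position not in _VALID_POSITIONS:
            raise ValueError(
                f"position must be one of {_VALID_POSITIONS}, got {self.position!r}"
            )
        if self.scan_extent_mm <= 0:
            raise ValueError("scan extent must be positive")
        e = self.mean_spectral_energy_keV
        if e is not None and not 20.0 < e < 100.0:
            raise ValueError("mean spectral energy must lie in (20, 100) keV for CT beams")


@dataclass(frozen=True)
class CorrectionFactorSet:
    """The five correction factors of the dose equation, with uncertainties."""

    k_l: UncertainQuantity
    k_f: UncertainQuantity
    k_g: UncertainQuantity
    k_theta: UncertainQuantity
    k_q: UncertainQuantity
    protocol: str

    def as_list(self) -> list[UncertainQuantity]:
        return [self.k_l, self.k_f, self.k_g, self.k_theta, self.k_q]

    @property
    def product(self) -> float:
        p = 1.0
        for f in self.as_list():
            p *= f.expected
        return p


@dataclass(frozen=True)
class KqTable:
    """Beam-quality corrections for one calibration protocol.

    ``by_kvp_position`` holds the clinical table keyed by (kVp, position);
    ``by_energy`` holds (mean spectral energy keV, k_Q) nodes for spectrum-
    specific lookup with linear interpolation between nodes.
    """

    protocol: str
    by_kvp_position: dict[tuple[int, str], float]
    by_energy: tuple[tuple[float, float], ...] = ()
    rel_2sigma_pct: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "by_energy", tuple(sorted((float(e), float(k)) for e, k in self.by_energy))
        )


def lookup_kq(table: KqTable, cond: MeasurementCondition) -> UncertainQuantity:
    """Tabulated k_Q for a (kVp, position) pair; no silent extrapolation.

    A free-in-air condition is the CT calibration geometry itself and maps
    to k_Q = 1 for the ct_air protocol.
    """
    if cond.position == "free-in-air" and table.protocol == "ct_air":
        return UncertainQuantity(1.0, 0.0, label="k_Q")
    key = (cond.kvp, cond.position)
    if key not in table.by_kvp_position:
        raise LookupError_(
            f"no k_Q tabulated for {key} in {table.protocol} table; "
            f"available: {sorted(table.by_kvp_position)}"
        )
    return UncertainQuantity.from_relative(
        table.by_kvp_position[key], table.rel_2sigma_pct, label="k_Q"
    )


def lookup_kq_by_energy(table: KqTable, energy_keV: float) -> UncertainQuantity:
    """k_Q at a mean spectral energy, linearly interpolated between nodes.

    Exact at tabulated nodes; raises outside the tabulated span rather than
    extrapolating, since the energy response is strongly non-linear beyond it.
    """
    if not table.by_energy:
        raise LookupError_(f"{table.protocol} table has no energy axis")
    energies = [e for e, _ in table.by_energy]
    if not energies[0] <= energy_keV <= energies[-1]:
        raise LookupError_(
            f"energy {energy_keV} keV outside tabulated span "
            f"[{energies[0]}, {energies[-1]}] keV (no extrapolation)"
        )
    i = bisect.bisect_left(energies, energy_keV)
    if energies[i] == energy_keV:
        value = table.by_energy[i][1]
    else:
        e0, k0 = table.by_energy[i - 1]
        e1, k1 = table.by_energy[i]
        value = k0 + (k1 - k0) * (energy_keV - e0) / (e1 - e0)
    return UncertainQuantity.from_relative(value, table.rel_2sigma_pct, label="k_Q")


class FactorTables:
    """All shipped correction-factor data for the three protocols."""

    def __init__(self, raw: dict):
        self.raw = raw
        unc = raw.get("uncertainty_rel_2sigma_pct", {})
        kq_unc = unc.get("k_q", {})
        self.kq: dict[str, KqTable] = {}
        energy_rows = raw.get("k_q_by_energy", [])
        for protocol in ("ct_air", "megavoltage"):
            grid = raw["k_q_by_kvp_position"][protocol]
            self.kq[protocol] = KqTable(
                protocol=protocol,
                by_kvp_position={
                    (int(kvp), pos): float(v)
                    for kvp, row in grid.items()
                    for pos, v in row.items()
                },
                by_energy=tuple(
                    (row["energy_keV"], row[protocol]) for row in energy_rows
                ),
                rel_2sigma_pct=float(kq_unc.get(protocol, 0.0)),
            )
        self.vendor_k_q = float(raw["vendor_k_q"])
        self.vendor_k_q_unc = float(kq_unc.get("vendor", 0.0))
        self.k_g = {p: float(v) for p, v in raw["k_g"].items()}
        self.k_g_unc = {p: float(v) for p, v in unc.get("k_g", {}).items()}
        self.unit_unc = {
            name: float(unc.get(name, 0.0)) for name in ("k_l", "k_f", "k_theta")
        }


def load_factor_tables(path: str | None = None) -> FactorTables:
    """Load factor tables from a YAML file (default: the packaged tables)."""
    if path is None:
        text = resources.files("osldose.data").joinpath("factor_tables.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return FactorTables(yaml.safe_load(text))


def factor_set_for(
    protocol: str,
    cond: MeasurementCondition,
    tables: FactorTables | None = None,
    prefer_energy: bool = True,
) -> CorrectionFactorSet:
    """Assemble the full correction-factor set for one measurement.

    k_L = k_F = k_theta = 1 under the supported conventions; k_G comes from
    the protocol; k_Q from the vendor constant (1.19 for all CT conditions),
    or from the energy table when a mean spectral energy is given (falling
    back to the (kVp, position) table when it is not or when
    ``prefer_energy`` is False).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    tables = tables if tables is not None else load_factor_tables()

    if protocol == "vendor":
        k_q = UncertainQuantity.from_relative(
            tables.vendor_k_q, tables.vendor_k_q_unc, label="k_Q"
        )
    else:
        table = tables.kq[protocol]
        if cond.position == "free-in-air" and protocol == "ct_air":
            k_q = UncertainQuantity(1.0, 0.0, label="k_Q")
        elif prefer_energy and cond.mean_spectral_energy_keV is not None:
            k_q = lookup_kq_by_energy(table, cond.mean_spectral_energy_keV)
        else:
            k_q = lookup_kq(table, cond)

    unit = lambda name: UncertainQuantity.from_relative(1.0, tables.unit_unc[name], name)
    return CorrectionFactorSet(
        k_l=unit("k_l"),
        k_f=unit("k_f"),
        k_g=UncertainQuantity.from_relative(
            tables.k_g[protocol], tables.k_g_unc.get(protocol, 0.0), label="k_G"
        ),
        k_theta=unit("k_theta"),
        k_q=k_q,
        protocol=protocol,
    )
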