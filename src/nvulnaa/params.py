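"""Domain types, the nominal kinetic parameter registry, and config I/O.

Units follow the model's internal convention throughout: concentrations in
uM, compartment volumes in ul, maximal transport rates in umol/min, membrane
potential in mV (converted to V where it enters an exponent), temperature in
K.  Time is handled in minutes inside the integrator and in days at every
public interface.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import math

import yaml

logger = logging.getLogger(__name__)


class Species(str, Enum):
    """The two transported species: Phe, and the lumped competing-LNAA pool.

    CL aggregates L-leucine, L-isoleucine, L-tyrosine, L-tryptophan,
    L-valine, L-histidine and L-methionine into a single kinetic entity;
    therapeutically supplemented LNAAs are folded into CL with identical
    kinetics.
    """

    PHE = "Phe"
    CL = "CL"


class Compartment(str, Enum):
    """The four homogeneous compartments of the neurovascular unit."""

    MBEC = "MBEC"
    ISF = "ISF"
    AST = "Ast"
    NEU = "Neu"


SPECIES: Tuple[Species, Species] = (Species.PHE, Species.CL)
COMPARTMENTS: Tuple[Compartment, ...] = (
    Compartment.MBEC,
    Compartment.ISF,
    Compartment.AST,
    Compartment.NEU,
)

#: Faraday constant, C/mol
FARADAY = 96485.0
#: Gas constant, J/(mol K)
GAS_CONSTANT = 8.314
#: Adult rat body temperature, K (not printed with the kinetic constants;
#: configurable)
BODY_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class AntiporterParams:
    """Kinetics of an obligatory 1:1 amino-acid exchanger (LAT1 or LAT2).

    ``km_abs`` holds the absolute Michaelis constant per species on the
    extracellular-equivalent side (plasma/ISF for LAT1, either face for
    LAT2).  ``rk`` is the carrier-asymmetry ratio: the Michaelis constant on
    the intracellular (MBEC) face is ``rk * km_abs``.  LAT1 has distinct
    maximal rates at the luminal and abluminal membranes (``vmax`` and
    ``vmax_abl``); LAT2 sits on a single membrane, for which ``vmax_abl``
    is ``None`` and ``vmax`` applies.
    """

    name: str
    km_abs: Mapping[Species, float]
    rk: float
    vmax: Mapping[Species, float]
    vmax_abl: Optional[Mapping[Species, float]] = None

    @property
    def vmax_abluminal(self) -> Mapping[Species, float]:
        """Abluminal maximal rates; defaults to the luminal values."""
        return self.vmax if self.vmax_abl is None else self.vmax_abl

    def km_cis(self, intracellular: bool) -> Dict[Species, float]:
        """Michaelis constants on one carrier face.

        The asymmetry ratio multiplies the constants on the intracellular
        (MBEC for LAT1) side only.
        """
        scale = self.rk if intracellular else 1.0
        return {s: scale * self.km_abs[s] for s in SPECIES}


@dataclass(frozen=True)
class SymporterParams:
    """Kinetics of the Na+-coupled neuronal symporter B0AT2.

    The membrane potential ``delta_psi_mV`` biases forward (inward) and
    backward (outward) translocation through the Eyring-type factors

        eps  = exp(-beta * Z * F * dPsi / (R * T))
        eps' = exp((1 - beta) * Z * F * dPsi / (R * T))

    so that at dPsi < 0 and Z > 0 inward co-transport is favoured
    (eps > 1 > eps').  Na+ levels in ISF and neurons are fixed model
    parameters, not state variables.
    """

    vmax: Mapping[Species, float]
    km: Mapping[Species, float]
    km_na: float
    delta_psi_mV: float = -70.0
    beta: float = 0.6
    z: int = 1
    faraday: float = FARADAY
    gas_constant: float = GAS_CONSTANT
    temperature_K: float = BODY_TEMPERATURE_K
    na_isf_uM: float = 141_000.0
    na_neu_uM: float = 40_000.0

    def bias(self) -> Tuple[float, float]:
        """Forward and backward voltage-bias factors (eps, eps')."""
        u = self.z * self.faraday * (self.delta_psi_mV * 1e-3) / (
            self.gas_constant * self.temperature_K
        )
        return math.exp(-self.beta * u), math.exp((1.0 - self.beta) * u)


@dataclass(frozen=True)
class ParameterSet:
    """The full model parameterisation: volumes plus three carriers."""

    volumes: Mapping[Compartment, float]
    lat1: AntiporterParams
    lat2: AntiporterParams
    b0at2: SymporterParams

    def to_flat(self) -> Dict[str, float]:
        """Flatten to the ASCII config-key dictionary."""
        p, c = Species.PHE, Species.CL
        d = {
            "Km_abs_LAT1_Phe_P": self.lat1.km_abs[p],
            "Km_abs_LAT1_CL_P": self.lat1.km_abs[c],
            "Vmax_LAT1_lum_Phe": self.lat1.vmax[p],
            "Vmax_LAT1_lum_CL": self.lat1.vmax[c],
            "Vmax_LAT1_abl_Phe": self.lat1.vmax_abluminal[p],
            "Vmax_LAT1_abl_CL": self.lat1.vmax_abluminal[c],
            "RK_LAT1": self.lat1.rk,
            "Km_abs_LAT2_Phe": self.lat2.km_abs[p],
            "Km_abs_LAT2_CL": self.lat2.km_abs[c],
            "Vmax_LAT2_Phe": self.lat2.vmax[p],
            "Vmax_LAT2_CL": self.lat2.vmax[c],
            "Km_B0AT2_Phe": self.b0at2.km[p],
            "Km_B0AT2_CL": self.b0at2.km[c],
            "Vmax_B0AT2_Phe": self.b0at2.vmax[p],
            "Vmax_B0AT2_CL": self.b0at2.vmax[c],
            "Km_B0AT2_Na": self.b0at2.km_na,
            "delta_psi_mV": self.b0at2.delta_psi_mV,
            "beta": self.b0at2.beta,
            "Z_Na": float(self.b0at2.z),
            "F": self.b0at2.faraday,
            "R": self.b0at2.gas_constant,
            "T": self.b0at2.temperature_K,
            "Na_ISF": self.b0at2.na_isf_uM,
            "Na_Neu": self.b0at2.na_neu_uM,
            "V_MBEC": self.volumes[Compartment.MBEC],
            "V_ISF": self.volumes[Compartment.ISF],
            "V_Ast": self.volumes[Compartment.AST],
            "V_Neu": self.volumes[Compartment.NEU],
        }
        return d

    @staticmethod
    def from_flat(d: Mapping[str, float]) -> "ParameterSet":
        p, c = Species.PHE, Species.CL
        lat1 = AntiporterParams(
            name="LAT1",
            km_abs={p: d["Km_abs_LAT1_Phe_P"], c: d["Km_abs_LAT1_CL_P"]},
            rk=d["RK_LAT1"],
            vmax={p: d["Vmax_LAT1_lum_Phe"], c: d["Vmax_LAT1_lum_CL"]},
            vmax_abl={p: d["Vmax_LAT1_abl_Phe"], c: d["Vmax_LAT1_abl_CL"]},
        )
        lat2 = AntiporterParams(
            name="LAT2",
            km_abs={p: d["Km_abs_LAT2_Phe"], c: d["Km_abs_LAT2_CL"]},
            rk=1.0,
            vmax={p: d["Vmax_LAT2_Phe"], c: d["Vmax_LAT2_CL"]},
        )
        b0at2 = SymporterParams(
            vmax={p: d["Vmax_B0AT2_Phe"], c: d["Vmax_B0AT2_CL"]},
            km={p: d["Km_B0AT2_Phe"], c: d["Km_B0AT2_CL"]},
            km_na=d["Km_B0AT2_Na"],
            delta_psi_mV=d["delta_psi_mV"],
            beta=d["beta"],
            z=int(d["Z_Na"]),
            faraday=d["F"],
            gas_constant=d["R"],
            temperature_K=d["T"],
            na_isf_uM=d["Na_ISF"],
            na_neu_uM=d["Na_Neu"],
        )
        volumes = {
            Compartment.MBEC: d["V_MBEC"],
            Compartment.ISF: d["V_ISF"],
            Compartment.AST: d["V_Ast"],
            Compartment.NEU: d["V_Neu"],
        }
        return ParameterSet(volumes=volumes, lat1=lat1, lat2=lat2, b0at2=b0at2)

    def perturbed(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with flat-key values multiplied by ``factors``."""
        d = self.to_flat()
        for key, f in factors.items():
            if key not in d:
                raise KeyError(f"unknown parameter key: {key!r}")
            d[key] = d[key] * f
        return ParameterSet.from_flat(d)


#: Flat keys eligible for random perturbation in sensitivity ensembles
#: (maximal transport rates and Michaelis constants).
KINETIC_KEYS: Tuple[str, ...] = (
    "Km_abs_LAT1_Phe_P",
    "Km_abs_LAT1_CL_P",
    "Vmax_LAT1_lum_Phe",
    "Vmax_LAT1_lum_CL",
    "Vmax_LAT1_abl_Phe",
    "Vmax_LAT1_abl_CL",
    "Km_abs_LAT2_Phe",
    "Km_abs_LAT2_CL",
    "Vmax_LAT2_Phe",
    "Vmax_LAT2_CL",
    "Km_B0AT2_Phe",
    "Km_B0AT2_CL",
    "Vmax_B0AT2_Phe",
    "Vmax_B0AT2_CL",
    "Km_B0AT2_Na",
)

#: Provenance per flat key: "literature" (printed in the source parameter
#: table), "derived" (follows from a printed value plus a stated rule) or
#: "assumed" (fixed by this package's documented conventions).
PROVENANCE: Dict[str, str] = {
    **{k: "literature" for k in KINETIC_KEYS},
    "RK_LAT1": "literature",
    "delta_psi_mV": "literature",
    "beta": "literature",
    "Na_ISF": "literature",
    "Na_Neu": "literature",
    "V_MBEC": "literature",
    "V_ISF": "literature",
    "V_Ast": "literature",
    "V_Neu": "literature",
    "Vmax_LAT1_abl_Phe": "assumed",  # abluminal Vmax not printed; = luminal
    "Vmax_LAT1_abl_CL": "assumed",
    "Z_Na": "assumed",
    "F": "literature",
    "R": "literature",
    "T": "assumed",
}

_NOMINAL_FLAT: Dict[str, float] = {
    "Km_abs_LAT1_Phe_P": 11.0,
    "Km_abs_LAT1_CL_P": 52.9,
    "Vmax_LAT1_lum_Phe": 0.075,
    "Vmax_LAT1_lum_CL": 0.129,
    "Vmax_LAT1_abl_Phe": 0.075,
    "Vmax_LAT1_abl_CL": 0.129,
    "RK_LAT1": 80.0,
    "Km_abs_LAT2_Phe": 110.2,
    "Km_abs_LAT2_CL": 185.9,
    "Vmax_LAT2_Phe": 0.1128,
    "Vmax_LAT2_CL": 0.1494,
    "Km_B0AT2_Phe": 1050.0,
    "Km_B0AT2_CL": 126.2,
    "Vmax_B0AT2_Phe": 0.0086,
    "Vmax_B0AT2_CL": 0.0186,
    "Km_B0AT2_Na": 1050.0,
    "delta_psi_mV": -70.0,
    "beta": 0.6,
    "Z_Na": 1.0,
    "F": FARADAY,
    "R": GAS_CONSTANT,
    "T": BODY_TEMPERATURE_K,
    "Na_ISF": 141_000.0,
    "Na_Neu": 40_000.0,
    "V_MBEC": 3.5,
    "V_ISF": 352.6,
    "V_Ast": 742.0,
    "V_Neu": 441.7,
}


def nominal_parameters() -> ParameterSet:
    """The literature parameter set for the adult-rat NVU.

    Referentially transparent: every call rebuilds an identical object.
    """
    return ParameterSet.from_flat(dict(_NOMINAL_FLAT))


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``level`` is 'error' or 'warning'."""

    level: str
    key: str
    message: str


def validate_parameters(p: ParameterSet) -> List[Violation]:
    """Check type invariants; violations are returned, never raised."""
    out: List[Violation] = []
    flat = p.to_flat()
    signed_ok = {"delta_psi_mV"}
    for key, val in flat.items():
        if key in signed_ok:
            continue
        if key == "beta":
            if not (0.0 < val < 1.0):
                out.append(
                    Violation("warning", key, f"beta={val} outside (0, 1)")
                )
            continue
        if val <= 0:
            out.append(Violation("error", key, f"{key}={val} must be > 0"))
    return out


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = ("parameters", "forcing", "run")


@dataclass
class RunSettings:
    """Non-kinetic run settings with package defaults."""

    span_days: float = 14.0
    output_step_days: float = 0.01
    transition_days: Optional[float] = None  # None -> one forcing period
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-8
    steady_residual_uM_per_min: float = 1e-6
    steady_max_minutes: float = 1e6

    @staticmethod
    def from_dict(d: Mapping[str, object]) -> "RunSettings":
        rs = RunSettings()
        valid = {f.name for f in dataclasses.fields(RunSettings)}
        for key, val in d.items():
            if key not in valid:
                raise KeyError(f"unknown run-settings key: {key!r}")
            setattr(rs, key, val)
        return rs


def load_config(path) -> Tuple[ParameterSet, dict]:
    """Load a YAML config; unspecified parameters fall back to nominal.

    Returns ``(ParameterSet, extras)`` where ``extras`` has keys
    ``"forcing"`` (raw mapping or None) and ``"run"`` (:class:`RunSettings`).
    Every parameter override is logged with its old and new value; unknown
    keys raise ``KeyError`` and invalid values raise ``ValueError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    for section in raw:
        if section not in _CONFIG_SECTIONS:
            raise KeyError(f"unknown config section: {section!r}")

    flat = dict(_NOMINAL_FLAT)
    for key, val in (raw.get("parameters") or {}).items():
        if key not in flat:
            raise KeyError(f"unknown parameter key: {key!r}")
        logger.info("config override %s: %s -> %s", key, flat[key], val)
        flat[key] = float(val)

    pset = ParameterSet.from_flat(flat)
    errors = [v for v in validate_parameters(pset) if v.level == "error"]
    if errors:
        raise ValueError(
            "invalid parameter values: "
            + "; ".join(f"{v.key}: {v.message}" for v in errors)
        )
    extras = {
        "forcing": raw.get("forcing"),
        "run": RunSettings.from_dict(raw.get("run") or {}),
    }
    return pset, extras


def save_config(p: ParameterSet, path, forcing: Optional[Mapping] = None,
                run: Optional[RunSettings] = None) -> None:
    """Write a config that :func:`load_config` round-trips losslessly."""
    doc: Dict[str, object] = {"parameters": p.to_flat()}
    if forcing is not None:
        doc["forcing"] = dict(forcing)
    if run is not None:
        doc["run"] = dataclasses.asdict(run)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
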