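"""Domain types for engineered tumor-microenvironment biosensor circuits.

The strains modeled here are *E. coli* Nissle 1917 chassis carrying one of
three sensing promoters — pLldR (lactate-activated), pCadC (acid/proton-
activated) or pPepT (hypoxia-activated, i.e. repressed by oxygen) — wired in
one of three topologies:

``DIRECT``
    sensing promoter drives the mRFP reporter directly.
``SWITCH``
    sensing promoter drives the serine integrase TP901, which irreversibly
    inverts a terminator (the amplifying "XOR switch") so that the strong
    constitutive promoter pP7 drives the reporter in flipped cells.
``SWITCH_LYSIS``
    as ``SWITCH``, with the phage lysis gene phiX174E co-expressed from the
    sensing promoter, so induction also kills the host.

All rate constants are per hour; cell density is in dimensionless culture
units (carrying capacity ~1); fluorescence is in the arbitrary units (A.U.)
of an OD600-normalized plate-reader readout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "EnvironmentSignal",
    "HillParams",
    "PromoterSpec",
    "SwitchParams",
    "LysisParams",
    "GrowthParams",
    "ReporterParams",
    "MeasurementParams",
    "StrainSpec",
    "CircuitState",
    "TOPOLOGIES",
    "PROMOTER_CHANNELS",
]


class ParameterError(ValueError):
    """A numeric parameter violates its constraint (sign, range, finiteness)."""


class ConfigurationError(ValueError):
    """A structural inconsistency in a strain/promoter configuration."""


TOPOLOGIES = ("DIRECT", "SWITCH", "SWITCH_LYSIS")

#: canonical promoter -> signal channel wiring
PROMOTER_CHANNELS = {
    "pLldR": "lactate",
    "pCadC": "proton",
    "pPepT": "oxygen",
    "constitutive": "none",
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _finite(x: float, name: str) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise ParameterError(f"{name} must be finite, got {x!r}")
    return x


@dataclass(frozen=True)
class EnvironmentSignal:
    """Inducer state of the culture environment.

    Parameters
    ----------
    lactate : float
        L-lactate concentration in mM, >= 0.
    pH : float
        Culture pH, in [0, 14]. The proton channel used by pCadC is the
        derived concentration ``10**(-pH)`` in molar.
    oxygen : float
        Oxygen fraction in percent v/v, in [0, 100]. 20% is normoxia, 0% is
        the anoxic condition realized in anaerobic bags.
    """

    lactate: float = 0.0
    pH: float = 7.3
    oxygen: float = 20.0

    def __post_init__(self):
        _require(_finite(self.lactate, "lactate") >= 0, f"lactate must be >= 0, got {self.lactate}")
        _require(0 <= _finite(self.pH, "pH") <= 14, f"pH must be in [0, 14], got {self.pH}")
        _require(0 <= _finite(self.oxygen, "oxygen") <= 100, f"oxygen must be in [0, 100] %, got {self.oxygen}")

    @property
    def proton(self) -> float:
        """Proton concentration 10**(-pH) in molar; strictly positive."""
        return 10.0 ** (-self.pH)

    def channel_value(self, channel: str) -> float:
        if channel == "lactate":
            return self.lactate
        if channel == "proton":
            return self.proton
        if channel == "oxygen":
            return self.oxygen
        raise ConfigurationError(f"unknown signal channel {channel!r}")

    def to_dict(self) -> dict:
        return {"lactate": self.lactate, "pH": self.pH, "oxygen": self.oxygen}

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSignal":
        return cls(**{k: d[k] for k in ("lactate", "pH", "oxygen") if k in d})


@dataclass(frozen=True)
class HillParams:
    """Hill input function of one promoter.

    ``activating``: basal + span * s^n / (K^n + s^n)
    ``repressing``: basal + span * K^n / (K^n + s^n)

    Output is bounded in [basal, basal + span] for any signal >= 0.
    ``half_max`` (K) carries the units of the signal channel; ``coefficient``
    (n) is the Hill cooperativity.
    """

    basal: float
    span: float
    half_max: float
    coefficient: float
    mode: str = "activating"

    def __post_init__(self):
        _require(_finite(self.basal, "basal") >= 0, f"basal must be >= 0, got {self.basal}")
        _require(_finite(self.span, "span") >= 0, f"span must be >= 0, got {self.span}")
        _require(_finite(self.half_max, "half_max") > 0, f"half_max must be > 0, got {self.half_max}")
        _require(_finite(self.coefficient, "coefficient") > 0, f"coefficient must be > 0, got {self.coefficient}")
        if self.mode not in ("activating", "repressing"):
            raise ParameterError(f"mode must be 'activating' or 'repressing', got {self.mode!r}")


@dataclass(frozen=True)
class PromoterSpec:
    """One promoter: an inducible Hill element or a constitutive element.

    The sensing promoters are hard-wired to their channel: pLldR reads
    lactate (activating), pCadC reads protons (activating), pPepT reads
    oxygen (repressing). ``constitutive`` models the strong pP7 promoter
    downstream of the flipped switch and ignores the environment.
    """

    id: str
    channel: str
    hill: Optional[HillParams] = None
    const_activity: Optional[float] = None

    def __post_init__(self):
        if self.id not in PROMOTER_CHANNELS:
            raise ConfigurationError(f"unknown promoter id {self.id!r}")
        expected = PROMOTER_CHANNELS[self.id]
        if self.channel != expected:
            raise ConfigurationError(
                f"promoter {self.id!r} must read channel {expected!r}, got {self.channel!r}"
            )
        if self.id == "constitutive":
            if self.const_activity is None:
                raise ConfigurationError("constitutive promoter requires const_activity")
            _require(_finite(self.const_activity, "const_activity") >= 0, "const_activity must be >= 0")
        else:
            if self.hill is None:
                raise ConfigurationError(f"inducible promoter {self.id!r} requires Hill parameters")
            if self.id == "pPepT" and self.hill.mode != "repressing":
                raise ConfigurationError("pPepT is oxygen-repressed; hill.mode must be 'repressing'")
            if self.id in ("pLldR", "pCadC") and self.hill.mode != "activating":
                raise ConfigurationError(f"{self.id} is signal-activated; hill.mode must be 'activating'")


@dataclass(frozen=True)
class SwitchParams:
    """Serine-integrase (TP901) switch kinetics.

    The integrase pool is assumed at quasi-steady state, ``I = A(u)/gamma_I``
    with ``A(u)`` the sensing-promoter activity, and the per-cell flip
    propensity is ``flip_rate_constant * I``. Flipping is irreversible.
    """

    integrase_degradation: float = 1.0
    flip_rate_constant: float = 0.1

    def __post_init__(self):
        _require(_finite(self.integrase_degradation, "integrase_degradation") > 0,
                 "integrase_degradation must be > 0")
        _require(_finite(self.flip_rate_constant, "flip_rate_constant") > 0,
                 "flip_rate_constant must be > 0")


@dataclass(frozen=True)
class LysisParams:
    """phiX174E lysis-protein expression and the death rate it induces.

    Death follows a Hill function of the per-cell lysis-protein level E:
    ``delta(E) = max_death_rate * E^h / (death_half_max^h + E^h)``, so the
    death rate is zero at E = 0 and saturates strictly below max_death_rate.
    """

    lysis_expression_rate: float = 1.0
    lysis_protein_decay: float = 0.3
    max_death_rate: float = 0.5
    death_half_max: float = 1.0
    death_coefficient: float = 2.0

    def __post_init__(self):
        _require(_finite(self.lysis_expression_rate, "lysis_expression_rate") >= 0,
                 "lysis_expression_rate must be >= 0")
        _require(_finite(self.lysis_protein_decay, "lysis_protein_decay") > 0,
                 "lysis_protein_decay must be > 0")
        _require(_finite(self.max_death_rate, "max_death_rate") >= 0, "max_death_rate must be >= 0")
        _require(_finite(self.death_half_max, "death_half_max") > 0, "death_half_max must be > 0")
        _require(_finite(self.death_coefficient, "death_coefficient") >= 1, "death_coefficient must be >= 1")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic batch-culture growth: dN/dt = r N (1 - B/K).

    ``B`` is the total biomass competing for the shared resource. In the
    absence of flipping and lysis the live population follows the logistic
    closed form exactly.
    """

    growth_rate: float = 0.35
    carrying_capacity: float = 1.0
    initial_density: float = 0.1

    def __post_init__(self):
        _require(_finite(self.growth_rate, "growth_rate") > 0, "growth_rate must be > 0")
        _require(_finite(self.carrying_capacity, "carrying_capacity") > 0, "carrying_capacity must be > 0")
        _require(_finite(self.initial_density, "initial_density") > 0, "initial_density must be > 0")


@dataclass(frozen=True)
class ReporterParams:
    """mRFP reporter balance parameters.

    ``direct_expression_gain`` converts sensing-promoter activity into
    per-cell reporter synthesis in the DIRECT topology; in SWITCH topologies
    synthesis comes from the constitutive strong promoter instead.
    """

    reporter_decay: float = 0.03
    direct_expression_gain: float = 1.0

    def __post_init__(self):
        _require(_finite(self.reporter_decay, "reporter_decay") > 0, "reporter_decay must be > 0")
        _require(_finite(self.direct_expression_gain, "direct_expression_gain") >= 0,
                 "direct_expression_gain must be >= 0")


@dataclass(frozen=True)
class MeasurementParams:
    """Plate-reader observation model.

    OD600 counts live cells and (partially) cell debris; total fluorescence
    is a flat instrument background plus the live reporter-bearing biomass;
    the normalized readout is ``(total - background) / OD600``, matching the
    background-subtracted, OD-normalized A.U. convention.
    """

    fluor_scale: float = 1.0
    od_scale_cells: float = 1.0
    od_scale_debris: float = 0.5
    background_fluor: float = 50.0
    detection_threshold: float = 10.0

    def __post_init__(self):
        _require(_finite(self.fluor_scale, "fluor_scale") > 0, "fluor_scale must be > 0")
        _require(_finite(self.od_scale_cells, "od_scale_cells") > 0, "od_scale_cells must be > 0")
        _require(_finite(self.od_scale_debris, "od_scale_debris") >= 0, "od_scale_debris must be >= 0")
        _require(_finite(self.background_fluor, "background_fluor") >= 0, "background_fluor must be >= 0")
        _require(_finite(self.detection_threshold, "detection_threshold") > 0, "detection_threshold must be > 0")


@dataclass(frozen=True)
class StrainSpec:
    """Full parameterization of one engineered strain."""

    topology: str
    sensing: PromoterSpec
    strong: PromoterSpec
    growth: GrowthParams = field(default_factory=GrowthParams)
    reporter: ReporterParams = field(default_factory=ReporterParams)
    measurement: MeasurementParams = field(default_factory=MeasurementParams)
    switch: Optional[SwitchParams] = None
    lysis: Optional[LysisParams] = None
    strain_id: str = ""

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if self.strong.id != "constitutive":
            raise ConfigurationError("the strong promoter must be constitutive (pP7)")
        if self.topology in ("SWITCH", "SWITCH_LYSIS") and self.switch is None:
            raise ConfigurationError(f"{self.topology} topology requires switch parameters")
        if self.topology == "SWITCH_LYSIS" and self.lysis is None:
            raise ConfigurationError("SWITCH_LYSIS topology requires lysis parameters")
        if self.topology == "DIRECT" and self.switch is not None:
            raise ConfigurationError("DIRECT topology must not carry switch parameters")
        if self.topology != "SWITCH_LYSIS" and self.lysis is not None:
            raise ConfigurationError("lysis parameters are only valid for SWITCH_LYSIS")

    @property
    def has_switch(self) -> bool:
        return self.topology in ("SWITCH", "SWITCH_LYSIS")

    @property
    def has_lysis(self) -> bool:
        return self.topology == "SWITCH_LYSIS"

    # --- flat key-value serialization -------------------------------------
    def to_flat_dict(self) -> dict:
        """Serialize to a flat key-value mapping (dotted keys)."""
        out: dict = {"topology": self.topology, "strain_id": self.strain_id}
        out["sensing.id"] = self.sensing.id
        out["sensing.channel"] = self.sensing.channel
        if self.sensing.hill is not None:
            for k, v in dataclasses.asdict(self.sensing.hill).items():
                out[f"sensing.hill.{k}"] = v
        if self.sensing.const_activity is not None:
            out["sensing.const_activity"] = self.sensing.const_activity
        out["strong.const_activity"] = self.strong.const_activity
        for block in ("growth", "reporter", "measurement"):
            for k, v in dataclasses.asdict(getattr(self, block)).items():
                out[f"{block}.{k}"] = v
        for block in ("switch", "lysis"):
            val = getattr(self, block)
            if val is not None:
                for k, v in dataclasses.asdict(val).items():
                    out[f"{block}.{k}"] = v
        return out

    @classmethod
    def from_flat_dict(cls, d: dict) -> "StrainSpec":
        def sub(prefix: str) -> dict:
            p = prefix + "."
            return {k[len(p):]: v for k, v in d.items() if k.startswith(p)}

        hill_d = sub("sensing.hill")
        sensing = PromoterSpec(
            id=d["sensing.id"],
            channel=d["sensing.channel"],
            hill=HillParams(**hill_d) if hill_d else None,
            const_activity=d.get("sensing.const_activity"),
        )
        strong = PromoterSpec(id="constitutive", channel="none",
                              const_activity=d["strong.const_activity"])
        switch_d = sub("switch")
        lysis_d = sub("lysis")
        return cls(
            topology=d["topology"],
            sensing=sensing,
            strong=strong,
            growth=GrowthParams(**sub("growth")),
            reporter=ReporterParams(**sub("reporter")),
            measurement=MeasurementParams(**sub("measurement")),
            switch=SwitchParams(**switch_d) if switch_d else None,
            lysis=LysisParams(**lysis_d) if lysis_d else None,
            strain_id=d.get("strain_id", ""),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StrainSpec":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_flat_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "StrainSpec":
        return cls.from_flat_dict(json.loads(s))


# index layout of the packed ODE state vector
STATE_NAMES = ("n_unflipped", "n_flipped", "reporter_per_cell",
               "lysis_protein_per_cell", "debris")


@dataclass
class CircuitState:
    """ODE state of one strain's culture.

    ``n_unflipped`` / ``n_flipped`` are live cell densities before/after the
    integrase has inverted the switch (``n_flipped`` stays 0 for DIRECT);
    ``reporter_per_cell`` and ``lysis_protein_per_cell`` are per-cell protein
    levels; ``debris`` is lysed biomass still scattering in the well.
    """

    n_unflipped: float
    n_flipped: float = 0.0
    reporter_per_cell: float = 0.0
    lysis_protein_per_cell: float = 0.0
    debris: float = 0.0

    def __post_init__(self):
        for name in STATE_NAMES:
            v = _finite(getattr(self, name), name)
            _require(v >= 0, f"{name} must be >= 0, got {v}")

    @property
    def n_live(self) -> float:
        return self.n_unflipped + self.n_flipped

    @property
    def flipped_fraction(self) -> float:
        n = self.n_live
        return self.n_flipped / n if n > 0 else 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr, clip_tol: float = 1e-9) -> "CircuitState":
        """Build from a solver state vector, clipping tiny negatives.

        Components below ``-clip_tol`` are a genuine invariant violation and
        are rejected; values in ``[-clip_tol, 0)`` are solver round-off and
        are clipped to 0.
        """
        arr = np.asarray(arr, dtype=float)
        if np.any(arr < -clip_tol):
            raise ParameterError(f"negative state components beyond tolerance: {arr}")
        arr = np.clip(arr, 0.0, None)
        return cls(**dict(zip(STATE_NAMES, arr)))
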