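"""Synthetic plate-reader datasets with the in-vitro characterization design.

Emulates the measurement workflow: strains grown in 96-well plates across an
inducer grid (lactate 0/0.1/1/5/10 mM, pH 5.3-7.3, O2 0/20%), three
biological replicates, OD600 and raw mRFP read on a plate reader, background
from untransformed host wells, then background subtraction and OD
normalization.

Noise structure: multiplicative lognormal noise on the circuit fluorescence
(plate readers err proportionally), additive Gaussian noise on OD600, and
Gaussian instrument background. The defaults are stipulated, configurable
choices — the characterization reports only replicate means and s.e.m.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .defaults import build_strain
from .params import EnvironmentSignal, ParameterError, StrainSpec
from .simulate import EnvironmentSchedule, simulate_time_course

__all__ = [
    "NoiseModel",
    "PlateDesign",
    "ProcessedPlate",
    "untransformed_host",
    "default_design",
    "recovery_design",
    "generate_plate_dataset",
    "process_plate",
    "supernatant_schedule",
    "PLATE_COLUMNS",
    "LACTATE_GRID",
    "PH_GRID",
    "OXYGEN_GRID",
]

#: inducer grids of the characterization experiments
LACTATE_GRID = (0.0, 0.1, 1.0, 5.0, 10.0)
PH_GRID = (5.3, 5.8, 6.3, 7.3)
OXYGEN_GRID = (0.0, 20.0)

PLATE_COLUMNS = ["strain_id", "topology", "lactate_mM", "pH", "oxygen_pct",
                 "replicate", "read_time_h", "raw_fluor_au", "od600"]


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader noise: lognormal CV on fluorescence, Gaussian on OD."""

    fluor_cv: float = 0.1
    od_sd: float = 0.01
    background_mean: float = 50.0
    background_sd: float = 2.0

    def __post_init__(self):
        for name in ("fluor_cv", "od_sd", "background_mean", "background_sd"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def noiseless(cls, background_mean: float = 50.0) -> "NoiseModel":
        return cls(fluor_cv=0.0, od_sd=0.0, background_mean=background_mean,
                   background_sd=0.0)


def untransformed_host(template: StrainSpec, strain_id: str = "EcN_wt") -> StrainSpec:
    """The background strain: same host growth, no circuit output.

    Modeled as a DIRECT strain whose expression gain is zero, so its wells
    report instrument background only, at the OD of a normally growing
    culture.
    """
    return StrainSpec(
        topology="DIRECT",
        sensing=template.sensing,
        strong=template.strong,
        growth=template.growth,
        reporter=dataclasses.replace(template.reporter, direct_expression_gain=0.0),
        measurement=template.measurement,
        strain_id=strain_id,
    )


@dataclass
class PlateDesign:
    """One plate layout: strains x environment conditions x replicates x reads."""

    strains: list
    conditions: list
    replicates: int = 3
    read_times: tuple = (48.0,)
    background_strain_id: str = "EcN_wt"

    def __post_init__(self):
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if not self.strains:
            raise ParameterError("design must include at least one strain")
        if not self.conditions:
            raise ParameterError("design must include at least one condition")
        ids = [s.strain_id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ParameterError("strain ids must be unique")
        if self.background_strain_id not in ids:
            raise ParameterError(
                f"background strain {self.background_strain_id!r} missing from design")

    @property
    def n_records(self) -> int:
        return (len(self.strains) * len(self.conditions) * self.replicates
                * len(self.read_times))


def default_design(params: dict | None = None, topology: str = "DIRECT",
                   replicates: int = 3, read_times: tuple = (48.0,)) -> PlateDesign:
    """The lactate characterization plate: pLldR strain + background host."""
    sensor = build_strain("pLldR", topology, params)
    background = untransformed_host(sensor)
    conditions = [EnvironmentSignal(lactate=c) for c in LACTATE_GRID]
    return PlateDesign(strains=[sensor, background], conditions=conditions,
                       replicates=replicates, read_times=read_times)


def recovery_design(params: dict | None = None, replicates: int = 3,
                    read_times: tuple = (48.0,)) -> PlateDesign:
    """Plate for parameter-recovery studies: DIRECT + SWITCH lactate sensors.

    Carrying both topologies over the lactate grid makes the DIRECT
    expression gain, the pLldR half-max and the strong-promoter activity
    jointly identifiable, which a single-topology plate does not.
    """
    direct = build_strain("pLldR", "DIRECT", params)
    switch = build_strain("pLldR", "SWITCH", params)
    background = untransformed_host(direct)
    conditions = [EnvironmentSignal(lactate=c) for c in LACTATE_GRID]
    return PlateDesign(strains=[direct, switch, background], conditions=conditions,
                       replicates=replicates, read_times=read_times)


def generate_plate_dataset(design: PlateDesign, noise: NoiseModel,
                           seed: int, params: dict | None = None,
                           replicates: Optional[int] = None,
                           output_step: float = 0.5) -> pd.DataFrame:
    """Simulate a plate and add measurement noise; deterministic per seed.

    ``params`` rebuilds every non-background strain from a calibration
    parameter dictionary (used by the recovery experiment so the generating
    truth is explicit); without it the design's strains are simulated as-is.
    Returns a long-format table with :data:`PLATE_COLUMNS`.
    """
    if seed is None:
        raise ParameterError("a seed is required to generate a plate dataset")
    rng = np.random.default_rng(seed)
    n_rep = replicates if replicates is not None else design.replicates
    if n_rep < 1:
        raise ParameterError("replicates must be >= 1")

    strains = []
    for s in design.strains:
        if params is not None and s.strain_id != design.background_strain_id:
            s = build_strain(s.sensing.id, s.topology, params, strain_id=s.strain_id)
        strains.append(s)

    horizon = max(design.read_times)
    sigma_log = float(np.sqrt(np.log1p(noise.fluor_cv ** 2)))
    rows = []
    for strain in strains:
        for env in design.conditions:
            traj = simulate_time_course(strain, env, horizon=horizon,
                                        output_step=output_step)
            for read_t in design.read_times:
                circuit = traj.value_at(read_t, "total_fluor") \
                    - strain.measurement.background_fluor
                od_true = traj.value_at(read_t, "od600")
                for rep in range(1, n_rep + 1):
                    if sigma_log > 0:
                        fl_noise = float(np.exp(rng.normal(-0.5 * sigma_log ** 2,
                                                           sigma_log)))
                    else:
                        fl_noise = 1.0
                    bg = noise.background_mean
                    if noise.background_sd > 0:
                        bg += float(rng.normal(0.0, noise.background_sd))
                    raw = max(circuit * fl_noise + bg, 0.0)
                    od = od_true
                    if noise.od_sd > 0:
                        od += float(rng.normal(0.0, noise.od_sd))
                    od = max(od, 1e-6)
                    rows.append({
                        "strain_id": strain.strain_id, "topology": strain.topology,
                        "lactate_mM": env.lactate, "pH": env.pH,
                        "oxygen_pct": env.oxygen, "replicate": rep,
                        "read_time_h": read_t, "raw_fluor_au": raw, "od600": od,
                    })
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


_COND_KEYS = ["lactate_mM", "pH", "oxygen_pct", "read_time_h"]


@dataclass
class ProcessedPlate:
    """Background-subtracted, OD-normalized wells plus replicate summaries."""

    wells: pd.DataFrame
    summary: pd.DataFrame


def process_plate(raw: pd.DataFrame, background_strain_id: str = "EcN_wt") -> ProcessedPlate:
    """Apply the characterization normalization to a raw plate table.

    Per well: subtract the mean background-well fluorescence of the same
    condition and read time, floor at zero, divide by the well's OD600.
    Then average replicates per condition and report mean and s.e.m.
    """
    missing = [c for c in PLATE_COLUMNS if c not in raw.columns]
    if missing:
        raise ParameterError(f"raw plate table is missing columns: {missing}")
    bg = raw[raw["strain_id"] == background_strain_id]
    if bg.empty:
        raise ParameterError(
            f"no background records for strain {background_strain_id!r}")
    bg_mean = (bg.groupby(_COND_KEYS)["raw_fluor_au"].mean()
               .rename("background_fluor_au").reset_index())

    wells = raw[raw["strain_id"] != background_strain_id].merge(
        bg_mean, on=_COND_KEYS, how="left", validate="many_to_one")
    if wells["background_fluor_au"].isna().any():
        bad = wells[wells["background_fluor_au"].isna()][_COND_KEYS].drop_duplicates()
        raise ParameterError(
            f"missing background wells for conditions:\n{bad.to_string(index=False)}")
    net = (wells["raw_fluor_au"] - wells["background_fluor_au"]).clip(lower=0.0)
    wells = wells.assign(normalized_fluor_au=net / wells["od600"])

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    summary = (wells.groupby(["strain_id", "topology"] + _COND_KEYS)
               .agg(mean_normalized_fluor_au=("normalized_fluor_au", "mean"),
                    sem_normalized_fluor_au=("normalized_fluor_au", _sem),
                    mean_od600=("od600", "mean"),
                    n=("normalized_fluor_au", "size"))
               .reset_index())
    return ProcessedPlate(wells=wells, summary=summary)


def supernatant_schedule(lactate_series: Sequence, pH_series: Sequence,
                         oxygen: float = 20.0) -> EnvironmentSchedule:
    """Merge sampled lactate and pH series into one piecewise schedule.

    Emulates conditioning medium collected from a growing cancer-cell
    culture at intervals (lactate rises and pH falls over culture days) and
    then presented to the biosensors. Each channel holds its most recent
    sampled value; before its first sample it holds that first value.
    """
    def _check(series, name):
        series = [(float(t), float(v)) for t, v in series]
        if not series:
            raise ParameterError(f"{name} series must be non-empty")
        times = [t for t, _ in series]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError(f"{name} series times must be strictly increasing")
        return series

    lac = _check(lactate_series, "lactate")
    ph = _check(pH_series, "pH")
    breakpoints = sorted({t for t, _ in lac} | {t for t, _ in ph} | {0.0})

    def _hold(series, t):
        val = series[0][1]
        for tt, v in series:
            if tt <= t:
                val = v
            else:
                break
        return val

    segments = [(t, EnvironmentSignal(lactate=_hold(lac, t), pH=_hold(ph, t),
                                      oxygen=oxygen))
                for t in breakpoints]
    return EnvironmentSchedule(segments=tuple(segments))
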