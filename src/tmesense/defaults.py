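"""Shipped default parameterization of the six biosensor strains.

The calibrated values live in ``data/calibrated_params.yaml`` (produced by
multi-start least squares against the in-text characterization anchors; see
``tmesense.calibrate``) and the nine promoter x topology strain files under
``data/strains/`` are their serialized form. :func:`build_strain` assembles
a :class:`~tmesense.params.StrainSpec` from any flat parameter dictionary
with the same keys, which is also the parameter space the calibrator and
the parameter-recovery experiment optimize over.
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml

from .params import (
    GrowthParams,
    HillParams,
    LysisParams,
    MeasurementParams,
    ParameterError,
    PromoterSpec,
    ReporterParams,
    StrainSpec,
    SwitchParams,
)

__all__ = ["default_params", "build_strain", "default_strain", "SENSING_PROMOTERS"]

SENSING_PROMOTERS = ("pLldR", "pCadC", "pPepT")

_PROMOTER_MODE = {"pLldR": "activating", "pCadC": "activating", "pPepT": "repressing"}
_PROMOTER_CHANNEL = {"pLldR": "lactate", "pCadC": "proton", "pPepT": "oxygen"}


@functools.lru_cache(maxsize=1)
def _shipped_params() -> dict:
    text = resources.files("tmesense").joinpath("data/calibrated_params.yaml").read_text()
    return {k: float(v) for k, v in yaml.safe_load(text).items()}


def default_params() -> dict:
    """A fresh copy of the shipped calibrated parameter dictionary."""
    return dict(_shipped_params())


def build_strain(promoter: str, topology: str, params: dict | None = None,
                 strain_id: str | None = None) -> StrainSpec:
    """Assemble a StrainSpec from a flat calibration-parameter dictionary.

    ``params`` may override any subset of the shipped defaults; unknown keys
    are rejected so optimizer parameter vectors cannot silently miss.
    """
    if promoter not in SENSING_PROMOTERS:
        raise ParameterError(f"unknown sensing promoter {promoter!r}")
    p = default_params()
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ParameterError(f"unknown calibration parameters: {sorted(unknown)}")
        p.update(params)

    hill = HillParams(
        basal=p[f"{promoter}_basal"],
        span=p[f"{promoter}_span"],
        half_max=p[f"{promoter}_half_max"],
        coefficient=p[f"{promoter}_coefficient"],
        mode=_PROMOTER_MODE[promoter],
    )
    sensing = PromoterSpec(id=promoter, channel=_PROMOTER_CHANNEL[promoter], hill=hill)
    strong = PromoterSpec(id="constitutive", channel="none", const_activity=p["alpha_P7"])
    growth = GrowthParams(growth_rate=p["growth_rate"],
                          carrying_capacity=p["carrying_capacity"],
                          initial_density=p["initial_density"])
    reporter = ReporterParams(reporter_decay=p["reporter_decay"],
                              direct_expression_gain=p[f"{promoter}_direct_gain"])
    measurement = MeasurementParams(
        fluor_scale=p["fluor_scale"],
        od_scale_cells=p["od_scale_cells"],
        od_scale_debris=p["od_scale_debris"],
        background_fluor=p["background_fluor"],
        detection_threshold=p["detection_threshold"],
    )
    switch = lysis = None
    if topology in ("SWITCH", "SWITCH_LYSIS"):
        switch = SwitchParams(integrase_degradation=p["integrase_degradation"],
                              flip_rate_constant=p["flip_rate_constant"])
    if topology == "SWITCH_LYSIS":
        lysis = LysisParams(
            lysis_expression_rate=p["lysis_expression_rate"],
            lysis_protein_decay=p["lysis_protein_decay"],
            max_death_rate=p["lysis_max_death_rate"],
            death_half_max=p["lysis_death_half_max"],
            death_coefficient=p["lysis_death_coefficient"],
        )
    return StrainSpec(
        topology=topology, sensing=sensing, strong=strong, growth=growth,
        reporter=reporter, measurement=measurement, switch=switch, lysis=lysis,
        strain_id=strain_id or f"{promoter}_{topology}",
    )


def default_strain(promoter: str, topology: str) -> StrainSpec:
    """Load one of the nine shipped promoter x topology strain files."""
    name = f"data/strains/{promoter}_{topology}.yaml"
    try:
        text = resources.files("tmesense").joinpath(name).read_text()
    except FileNotFoundError:
        # strain files are generated from the calibrated parameters; fall
        # back to building directly from them
        return build_strain(promoter, topology)
    return StrainSpec.from_flat_dict(yaml.safe_load(text))
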