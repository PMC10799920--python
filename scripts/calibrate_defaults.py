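"""Regenerate the shipped default parameters from the anchor set.

Runs the staged calibration that produced ``tmesense/data/calibrated_params.yaml``
and the nine strain files under ``tmesense/data/strains/``:

1. fit growth, reporter turnover, switch and pLldR expression scales to the
   lactate-sensor absolute anchors and the peak-time anchor;
2. solve the pCadC/pPepT direct gains against the fold-change anchors
   (the fold is inversely proportional to the direct gain, so one damped
   fixed-point pass suffices);
3. fit the lysis and debris parameters to the lysis dose-response anchors
   under physical bounds (debris scatters less than intact cells);
4. set the detection threshold to the level the switch traces cross at the
   reported persistence time;
5. polish everything jointly against the full anchor set and verify every
   residual sits within its tolerance.

Usage: python scripts/calibrate_defaults.py [--seed 7] [--write]
"""

import argparse
import pathlib
import sys

import numpy as np
import yaml

import tmesense as tm
from tmesense.calibrate import AnchorSet, fit_parameters, fold_change, reference_anchor_set
from tmesense.defaults import SENSING_PROMOTERS

DATA_DIR = pathlib.Path(__file__).resolve().parents[1] / "src" / "tmesense" / "data"

LYSIS_BOUNDS = {
    "lysis_max_death_rate": (0.05, 0.8),
    "lysis_death_half_max": (0.1, 10.0),
    "lysis_expression_rate": (0.2, 5.0),
    "od_scale_debris": (0.05, 0.9),
}

# structural seed: fixed model-shape choices and starting values for the
# staged fit; the calibration always starts here, never from the currently
# shipped file, so regeneration is idempotent
BASE_SEED = {
    "alpha_P7": 80.0,
    "background_fluor": 50.0,
    "carrying_capacity": 1.0,
    "detection_threshold": 10.0,
    "flip_rate_constant": 0.14,
    "fluor_scale": 1.0,
    "growth_rate": 0.17,
    "initial_density": 0.1,
    "integrase_degradation": 1.0,
    "lysis_death_coefficient": 3.0,
    "lysis_death_half_max": 0.6,
    "lysis_expression_rate": 1.2,
    "lysis_max_death_rate": 0.2,
    "lysis_protein_decay": 0.3,
    "od_scale_cells": 1.0,
    "od_scale_debris": 0.4,
    "pCadC_basal": 0.0,
    "pCadC_coefficient": 1.0,
    "pCadC_direct_gain": 25.0,
    "pCadC_half_max": 1.0e-06,
    "pCadC_span": 2.0,
    "pLldR_basal": 0.0,
    "pLldR_coefficient": 1.5,
    "pLldR_direct_gain": 28.0,
    "pLldR_half_max": 2.0,
    "pLldR_span": 2.0,
    "pPepT_basal": 0.0,
    "pPepT_coefficient": 2.0,
    "pPepT_direct_gain": 15.0,
    "pPepT_half_max": 0.5,
    "pPepT_span": 2.0,
    "reporter_decay": 0.04,
}

FREE_ALL = [
    "growth_rate", "reporter_decay", "alpha_P7", "flip_rate_constant",
    "pLldR_direct_gain", "pCadC_direct_gain", "pPepT_direct_gain",
    "lysis_max_death_rate", "lysis_death_half_max", "lysis_expression_rate",
    "od_scale_debris", "detection_threshold",
]


def staged_calibration(seed: int) -> dict:
    anchors = reference_anchor_set()
    base = dict(BASE_SEED)

    # stage 0: the peak-time readout is quantized on the output grid, so a
    # least-squares step sees no gradient from it; pin the growth rate by a
    # coarse scan against the peak-time anchor first
    peak_anchor = next(a for a in anchors if a.kind == "peak_time")
    best = None
    for r in np.geomspace(0.08, 0.6, 40):
        strain = tm.build_strain(peak_anchor.promoter, peak_anchor.topology,
                                 {**base, "growth_rate": float(r)})
        traj = tm.simulate_time_course(strain, peak_anchor.environment,
                                       horizon=peak_anchor.horizon_h, output_step=0.5)
        peak_t = tm.summarize(traj).peak_time
        err = abs(peak_t - peak_anchor.target)
        if best is None or err < best[0]:
            best = (err, float(r), peak_t)
    base["growth_rate"] = best[1]
    print(f"stage 0: growth_rate={best[1]:.5g} (peak time {best[2]:.1f} h)")

    # stage 1: lactate-sensor absolute levels (growth rate stays pinned)
    stage1 = AnchorSet([a for a in anchors
                        if a.promoter == "pLldR" and a.topology in ("DIRECT", "SWITCH")
                        and a.kind == "absolute_fluor"])
    fit1 = fit_parameters(stage1,
                          ["reporter_decay", "alpha_P7",
                           "pLldR_direct_gain", "flip_rate_constant"],
                          n_starts=1, base_params=base)
    base.update({n: float(v) for n, v in zip(fit1.free_names, fit1.estimates)})
    print("stage 1 (growth/expression):", dict(zip(fit1.free_names, np.round(fit1.estimates, 5))))

    # stage 2: fold-change gains (fold is ~inverse in the direct gain)
    for a in anchors:
        if a.kind != "fold_change":
            continue
        key = f"{a.promoter}_direct_gain"
        for _ in range(3):
            pred = fold_change(a.promoter, a.environment, base, read_time=a.read_time_h)
            base[key] = float(base[key] * pred / a.target)
        print(f"stage 2 ({a.promoter}): gain={base[key]:.5g}")

    # stage 3: lysis dose-response anchors under physical bounds
    stage3 = AnchorSet([a for a in anchors if a.topology == "SWITCH_LYSIS"])
    fit3 = fit_parameters(stage3, list(LYSIS_BOUNDS), bounds=LYSIS_BOUNDS,
                          n_starts=6, seed=seed, base_params=base)
    base.update({n: float(v) for n, v in zip(fit3.free_names, fit3.estimates)})
    print("stage 3 (lysis):", dict(zip(fit3.free_names, np.round(fit3.estimates, 5))))

    # stage 4: detection threshold from the reported persistence time
    levels = []
    for a in anchors:
        if a.kind != "persistence_time":
            continue
        strain = tm.build_strain(a.promoter, a.topology, base)
        traj = tm.simulate_time_course(strain, a.environment, horizon=a.horizon_h,
                                       output_step=0.5)
        levels.append(traj.value_at(a.target))
    base["detection_threshold"] = float(np.exp(np.mean(np.log(levels))))
    print(f"stage 4: detection_threshold={base['detection_threshold']:.5g} "
          f"(signal levels at the persistence anchors: {np.round(levels, 3)})")

    # stage 5: joint polish on the full anchor set
    bounds = dict(LYSIS_BOUNDS)
    final = fit_parameters(anchors, FREE_ALL, bounds=bounds, n_starts=1,
                           base_params=base, seed=seed)
    print(final.summary())
    if not final.within_tolerance:
        print("WARNING: final fit leaves residuals outside tolerance", file=sys.stderr)
    return final.params


def write_defaults(params: dict) -> None:
    lines = [
        "# Shipped default parameters, produced by the staged anchor calibration",
        "# (scripts/calibrate_defaults.py) against tmesense/data/anchors.csv --",
        "# the in-text characterization values of the biosensor strains.",
        "# Units: rates 1/h, activities and expression in per-hour activity",
        "# units, densities in culture units (carrying capacity ~1), readouts",
        "# in plate-reader A.U.",
    ]
    body = yaml.safe_dump({k: float(v) for k, v in params.items()}, sort_keys=True)
    (DATA_DIR / "calibrated_params.yaml").write_text("\n".join(lines) + "\n" + body)

    strains_dir = DATA_DIR / "strains"
    strains_dir.mkdir(exist_ok=True)
    for promoter in SENSING_PROMOTERS:
        for topology in ("DIRECT", "SWITCH", "SWITCH_LYSIS"):
            strain = tm.build_strain(promoter, topology, params)
            strain.to_yaml(strains_dir / f"{promoter}_{topology}.yaml")
    print(f"wrote {DATA_DIR / 'calibrated_params.yaml'} and 9 strain files")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--write", action="store_true",
                    help="overwrite the shipped data files with the new fit")
    args = ap.parse_args()
    params = staged_calibration(args.seed)
    if args.write:
        write_defaults(params)


if __name__ == "__main__":
    main()
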