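"""Calibration of circuit parameters to printed characterization anchors.

The in-text characterization of the strains provides a small set of anchor
measurements (end-point normalized fluorescence at specific inducer levels,
switch/direct fold changes, peak and persistence times). This module
represents them as :class:`Anchor` records, evaluates any candidate
parameter dictionary against them by running the simulator, and fits free
parameters by multi-start, bound-constrained weighted least squares on a
log parameter scale (rate constants span orders of magnitude, so the
optimizer works in log space).

The modeling interface follows the model/results convention: build an
:class:`AnchorCalibration` from an :class:`AnchorSet`, call :meth:`fit`,
inspect the returned :class:`CalibrationResult` (parameter estimates,
per-anchor residuals, ``summary()``).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from importlib import resources
from scipy.optimize import least_squares

from .defaults import SENSING_PROMOTERS, build_strain, default_params
from .params import PROMOTER_CHANNELS, EnvironmentSignal, ParameterError
from .simulate import dose_response, simulate_time_course, summarize

__all__ = [
    "Anchor",
    "AnchorSet",
    "AnchorError",
    "FittingError",
    "evaluate_anchor",
    "fold_change",
    "AnchorCalibration",
    "CalibrationResult",
    "fit_parameters",
    "RecoveryReport",
    "parameter_recovery_experiment",
]

ANCHOR_KINDS = ("absolute_fluor", "fold_change", "peak_time",
                "persistence_time", "half_activation_signal")

#: read time (h) of the end-point dose-response characterization
ANCHOR_READ_TIME = 48.0
#: horizon (h) of the time-course characterization
ANCHOR_HORIZON = 150.0


class AnchorError(ValueError):
    """An anchor cannot be evaluated as specified."""


class FittingError(RuntimeError):
    """No optimizer start converged."""


@dataclass(frozen=True)
class Anchor:
    """One printed calibration target.

    ``tolerance`` is the relative tolerance used both to weight the fit
    residual and to judge whether the fitted model reproduces the value.
    """

    kind: str
    promoter: str
    topology: str
    environment: EnvironmentSignal
    target: float
    units: str
    tolerance: float
    read_time_h: float = ANCHOR_READ_TIME
    horizon_h: float = ANCHOR_HORIZON
    quote: str = ""

    def __post_init__(self):
        if self.kind not in ANCHOR_KINDS:
            raise AnchorError(f"unknown anchor kind {self.kind!r}")
        if self.promoter not in SENSING_PROMOTERS:
            raise AnchorError(f"unknown promoter {self.promoter!r}")
        if not (self.target > 0):
            raise AnchorError(f"anchor target must be > 0, got {self.target}")
        if not (0 < self.tolerance < 1):
            raise AnchorError(f"tolerance must be in (0, 1), got {self.tolerance}")


@dataclass
class AnchorSet:
    """A non-empty collection of anchors with provenance notes."""

    anchors: list

    def __post_init__(self):
        if not self.anchors:
            raise AnchorError("anchor set must be non-empty")

    def __iter__(self):
        return iter(self.anchors)

    def __len__(self):
        return len(self.anchors)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.anchors:
            rows.append({
                "kind": a.kind, "promoter": a.promoter, "topology": a.topology,
                "channel": PROMOTER_CHANNELS[a.promoter],
                "signal_value": a.environment.lactate,
                "pH": a.environment.pH, "oxygen_pct": a.environment.oxygen,
                "read_time_h": a.read_time_h, "horizon_h": a.horizon_h,
                "target": a.target, "units": a.units, "tolerance": a.tolerance,
                "quote": a.quote,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnchorSet":
        anchors = []
        for _, r in df.iterrows():
            env = EnvironmentSignal(lactate=float(r["signal_value"]),
                                    pH=float(r["pH"]), oxygen=float(r["oxygen_pct"]))
            anchors.append(Anchor(
                kind=r["kind"], promoter=r["promoter"], topology=r["topology"],
                environment=env, target=float(r["target"]), units=r["units"],
                tolerance=float(r["tolerance"]),
                read_time_h=float(r.get("read_time_h", ANCHOR_READ_TIME)),
                horizon_h=float(r.get("horizon_h", ANCHOR_HORIZON)),
                quote=str(r.get("quote", "")),
            ))
        return cls(anchors=anchors)

    @classmethod
    def from_csv(cls, path) -> "AnchorSet":
        return cls.from_frame(pd.read_csv(path))


def reference_anchor_set() -> AnchorSet:
    """The shipped anchor set assembled from the in-text characterization."""
    text = resources.files("tmesense").joinpath("data/anchors.csv").read_text()
    return AnchorSet.from_csv(io.StringIO(text))


def fold_change(promoter: str, env_on: EnvironmentSignal, params: dict | None = None,
                read_time: float = ANCHOR_READ_TIME, output_step: float = 0.5) -> float:
    """SWITCH / DIRECT normalized-fluorescence ratio at the read time.

    Quantifies the amplification delivered by the integrase switch for one
    promoter under a fully inducing environment.
    """
    vals = {}
    for topology in ("SWITCH", "DIRECT"):
        strain = build_strain(promoter, topology, params)
        traj = simulate_time_course(strain, env_on, horizon=read_time,
                                    output_step=output_step)
        vals[topology] = traj.normalized_fluor[-1]
    if vals["DIRECT"] <= 0:
        raise AnchorError("fold change undefined: DIRECT readout is zero")
    return vals["SWITCH"] / vals["DIRECT"]


def evaluate_anchor(anchor: Anchor, params: dict | None = None,
                    output_step: float = 0.5) -> float:
    """Predicted value of one anchor under a parameter dictionary."""
    if anchor.kind == "half_activation_signal":
        # the half-activation point of a Hill element is its half_max constant
        p = default_params()
        if params:
            p.update(params)
        return p[f"{anchor.promoter}_half_max"]

    if anchor.kind == "fold_change":
        return fold_change(anchor.promoter, anchor.environment, params,
                           read_time=anchor.read_time_h, output_step=output_step)

    strain = build_strain(anchor.promoter, anchor.topology, params)
    if anchor.kind == "absolute_fluor":
        traj = simulate_time_course(strain, anchor.environment,
                                    horizon=anchor.read_time_h,
                                    output_step=output_step)
        return float(traj.normalized_fluor[-1])

    # time-course anchors
    traj = simulate_time_course(strain, anchor.environment,
                                horizon=anchor.horizon_h, output_step=output_step)
    summ = summarize(traj)
    if anchor.kind == "peak_time":
        return summ.peak_time
    if anchor.kind == "persistence_time":
        if summ.persistence_time <= 0:
            raise AnchorError(
                "persistence anchor unevaluable: signal never reaches the "
                f"detection threshold within {anchor.horizon_h} h")
        return summ.persistence_time
    raise AnchorError(f"unsupported anchor kind {anchor.kind!r}")


def _residuals(anchors: AnchorSet, params: dict, output_step: float) -> np.ndarray:
    res = np.empty(len(anchors))
    for i, a in enumerate(anchors):
        pred = evaluate_anchor(a, params, output_step=output_step)
        res[i] = (pred - a.target) / (a.tolerance * max(a.target, 1.0))
    return res


@dataclass
class CalibrationResult:
    """Fit results: estimates, loss, per-anchor residuals, diagnostics."""

    params: dict                      # full parameter dictionary, fitted values merged
    free_names: list
    estimates: np.ndarray             # fitted values of the free parameters
    loss: float
    predicted: np.ndarray
    residual_table: pd.DataFrame
    n_starts: int
    seed: Optional[int]
    converged: bool
    start_losses: list = field(default_factory=list)

    @property
    def within_tolerance(self) -> bool:
        return bool((self.residual_table["abs_rel_error"]
                     <= self.residual_table["tolerance"] + 1e-12).all())

    def summary(self) -> str:
        lines = ["Anchor calibration results",
                 "=" * 60,
                 f"free parameters: {len(self.free_names)}   anchors: {len(self.residual_table)}",
                 f"weighted SSE loss: {self.loss:.6g}   starts: {self.n_starts}"
                 f"   converged: {self.converged}",
                 "-" * 60]
        for name, val in zip(self.free_names, self.estimates):
            lines.append(f"  {name:28s} = {val:12.6g}")
        lines.append("-" * 60)
        with pd.option_context("display.width", 120):
            lines.append(self.residual_table.to_string(index=False))
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "free_parameters": {n: float(v) for n, v in zip(self.free_names, self.estimates)},
            "full_parameters": {k: float(v) for k, v in self.params.items()},
            "loss": float(self.loss),
            "n_starts": self.n_starts,
            "seed": self.seed,
            "converged": self.converged,
            "residuals": self.residual_table.to_dict(orient="records"),
        }
        s = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class AnchorCalibration:
    """Weighted least-squares calibration model over an anchor set.

    Parameters
    ----------
    anchors : AnchorSet
        Targets the model is scored against.
    free_names : sequence of str
        Calibration-parameter names to optimize; the rest stay at
        ``base_params``. An empty list makes :meth:`fit` a pure evaluation
        of the base parameters.
    bounds : dict, optional
        ``name -> (lo, hi)`` box constraints (natural scale, finite, > 0).
        Defaults to a factor-of-30 box around the base value.
    base_params : dict, optional
        Starting/fixed parameter dictionary (shipped defaults if omitted).
    output_step : float
        Output-grid step used in anchor evaluation (h).
    """

    def __init__(self, anchors: AnchorSet, free_names: Sequence[str] = (),
                 bounds: Optional[dict] = None, base_params: Optional[dict] = None,
                 output_step: float = 0.5):
        self.anchors = anchors
        self.free_names = list(free_names)
        self.base_params = dict(base_params) if base_params else default_params()
        unknown = set(self.free_names) - set(self.base_params)
        if unknown:
            raise ParameterError(f"unknown free parameters: {sorted(unknown)}")
        self.output_step = output_step
        self.bounds = {}
        for name in self.free_names:
            base = self.base_params[name]
            if bounds and name in bounds:
                lo, hi = bounds[name]
            else:
                lo, hi = base / 30.0, base * 30.0
            if not (0 < lo < hi and math.isfinite(hi)):
                raise ParameterError(f"invalid bounds for {name}: ({lo}, {hi})")
            self.bounds[name] = (float(lo), float(hi))

    # -- parameter vector mapping (log scale) ------------------------------
    def _to_params(self, x_log: np.ndarray) -> dict:
        p = dict(self.base_params)
        for name, v in zip(self.free_names, np.exp(x_log)):
            p[name] = float(v)
        return p

    def _loss_vector(self, x_log: np.ndarray) -> np.ndarray:
        return _residuals(self.anchors, self._to_params(x_log), self.output_step)

    def fit(self, n_starts: int = 4, seed: Optional[int] = None,
            max_nfev: int = 200) -> CalibrationResult:
        """Run multi-start bounded least squares and return the best fit.

        The first start is the base parameter vector; the remaining starts
        are drawn log-uniformly inside the bounds from ``seed``.
        """
        if n_starts < 1:
            raise ParameterError("n_starts must be >= 1")
        if not self.free_names:
            params = dict(self.base_params)
            res = _residuals(self.anchors, params, self.output_step)
            return self._result(params, np.array([]), res, n_starts=0, seed=seed,
                                converged=True, start_losses=[])
        if n_starts > 1 and seed is None:
            raise ParameterError("multi-start fitting requires a seed")
        rng = np.random.default_rng(seed)
        lo = np.log([self.bounds[n][0] for n in self.free_names])
        hi = np.log([self.bounds[n][1] for n in self.free_names])
        x0_base = np.log([np.clip(self.base_params[n], *self.bounds[n])
                          for n in self.free_names])
        starts = [x0_base]
        for _ in range(n_starts - 1):
            starts.append(lo + rng.random(len(self.free_names)) * (hi - lo))

        best = None
        start_losses = []
        for x0 in starts:
            try:
                sol = least_squares(self._loss_vector, x0, bounds=(lo, hi),
                                    max_nfev=max_nfev, xtol=1e-10, ftol=1e-10)
            except (AnchorError, ParameterError):
                start_losses.append(float("nan"))
                continue
            loss = float(np.sum(sol.fun ** 2))
            start_losses.append(loss)
            if best is None or loss < best[0]:
                best = (loss, sol)
        if best is None:
            raise FittingError("all optimizer starts failed")
        _, sol = best
        params = self._to_params(sol.x)
        res = _residuals(self.anchors, params, self.output_step)
        return self._result(params, np.exp(sol.x), res, n_starts=n_starts,
                            seed=seed, converged=bool(sol.success),
                            start_losses=start_losses)

    def _result(self, params, estimates, scaled_residuals, n_starts, seed,
                converged, start_losses) -> CalibrationResult:
        rows = []
        predicted = []
        for a, r in zip(self.anchors, scaled_residuals):
            pred = a.target + r * a.tolerance * max(a.target, 1.0)
            predicted.append(pred)
            rows.append({
                "kind": a.kind, "promoter": a.promoter, "topology": a.topology,
                "target": a.target, "predicted": pred, "units": a.units,
                "abs_rel_error": abs(pred - a.target) / a.target,
                "tolerance": a.tolerance,
            })
        table = pd.DataFrame(rows)
        return CalibrationResult(
            params=params, free_names=list(self.free_names),
            estimates=np.asarray(estimates, dtype=float),
            loss=float(np.sum(scaled_residuals ** 2)),
            predicted=np.asarray(predicted), residual_table=table,
            n_starts=n_starts, seed=seed, converged=converged,
            start_losses=start_losses,
        )


def fit_parameters(anchors: AnchorSet, free_parameter_names: Sequence[str],
                   bounds: Optional[dict] = None, n_starts: int = 4,
                   seed: Optional[int] = None,
                   base_params: Optional[dict] = None,
                   output_step: float = 0.5) -> CalibrationResult:
    """Functional wrapper: build an :class:`AnchorCalibration` and fit it."""
    model = AnchorCalibration(anchors, free_parameter_names, bounds=bounds,
                              base_params=base_params, output_step=output_step)
    return model.fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# parameter recovery on synthetic data
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Outcome of a generate -> fit -> compare recovery experiment."""

    parameter_names: list
    true_values: dict
    estimates: pd.DataFrame          # one row per dataset x parameter
    n_datasets: int
    n_replicates: int
    n_failed: int
    seed: int
    identifiability_threshold: float = 0.5

    def error_summary(self) -> pd.DataFrame:
        g = self.estimates.groupby("parameter")["rel_error"]
        out = g.agg(median_rel_error="median", max_rel_error="max").reset_index()
        out["identifiable"] = out["median_rel_error"] <= self.identifiability_threshold
        return out

    @property
    def median_rel_error(self) -> float:
        return float(self.estimates["rel_error"].median())

    def non_identifiable(self) -> list:
        s = self.error_summary()
        return s.loc[~s["identifiable"], "parameter"].tolist()

    def to_json(self, path=None) -> str:
        payload = {
            "parameter_names": self.parameter_names,
            "true_values": {k: float(v) for k, v in self.true_values.items()},
            "n_datasets": self.n_datasets,
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "median_rel_error": self.median_rel_error,
            "per_parameter": self.error_summary().to_dict(orient="records"),
            "estimates": self.estimates.to_dict(orient="records"),
        }
        s = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def parameter_recovery_experiment(true_params: dict, design, noise_model,
                                  n_replicates: int, seed: int,
                                  free_parameter_names: Sequence[str] = (
                                      "pLldR_direct_gain", "pLldR_half_max", "alpha_P7"),
                                  n_datasets: int = 3, n_starts: int = 2,
                                  bounds: Optional[dict] = None,
                                  output_step: float = 1.0) -> RecoveryReport:
    """Generate synthetic plates from known parameters, refit, compare.

    For each of ``n_datasets`` independent synthetic datasets: simulate the
    plate design under ``true_params`` with ``n_replicates`` wells per
    condition, add noise, process the plate, turn every processed mean into
    an absolute-fluorescence anchor, and fit the free parameters starting
    from a perturbed parameter vector. Fitting failures are counted, not
    fatal. The report gives the per-parameter relative-error distribution
    and flags parameters whose median error exceeds 50% as non-identifiable.
    """
    from .synthetic import generate_plate_dataset, process_plate  # local: avoid cycle

    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if n_datasets < 1:
        raise ParameterError("n_datasets must be >= 1")
    free_parameter_names = list(free_parameter_names)
    rng = np.random.default_rng(seed)

    rows = []
    n_failed = 0
    for d in range(n_datasets):
        ds_seed = int(rng.integers(0, 2 ** 31 - 1))
        table = generate_plate_dataset(design, params=true_params,
                                       noise=noise_model, seed=ds_seed,
                                       replicates=n_replicates)
        processed = process_plate(table, design.background_strain_id)
        anchors = _anchors_from_processed(processed.summary, design)
        if not anchors:
            raise ParameterError("recovery design produced no usable anchors")
        # start the fit away from the truth so recovery is non-trivial
        base = dict(true_params)
        for name in free_parameter_names:
            base[name] = float(true_params[name] * np.exp(rng.normal(0.0, 0.3)))
        try:
            fit = fit_parameters(AnchorSet(anchors), free_parameter_names,
                                 bounds=bounds, n_starts=n_starts, seed=ds_seed,
                                 base_params=base, output_step=output_step)
        except (FittingError, AnchorError):
            n_failed += 1
            continue
        for name, est in zip(fit.free_names, fit.estimates):
            truth = float(true_params[name])
            rows.append({"dataset": d, "parameter": name, "true": truth,
                         "estimate": float(est),
                         "rel_error": abs(est - truth) / abs(truth)})

    estimates = pd.DataFrame(rows, columns=["dataset", "parameter", "true",
                                            "estimate", "rel_error"])
    return RecoveryReport(
        parameter_names=free_parameter_names,
        true_values={n: float(true_params[n]) for n in free_parameter_names},
        estimates=estimates, n_datasets=n_datasets, n_replicates=n_replicates,
        n_failed=n_failed, seed=seed,
    )


def _anchors_from_processed(summary: pd.DataFrame, design) -> list:
    """Turn processed per-condition means into absolute-fluorescence anchors.

    Conditions whose mean normalized signal is below 0.5 A.U. carry almost
    no information relative to plate noise and are dropped.
    """
    strain_topologies = {s.strain_id: s.topology for s in design.strains}
    promoters = {s.strain_id: s.sensing.id for s in design.strains}
    anchors = []
    for _, r in summary.iterrows():
        sid = r["strain_id"]
        if sid == design.background_strain_id or r["mean_normalized_fluor_au"] < 0.5:
            continue
        env = EnvironmentSignal(lactate=float(r["lactate_mM"]), pH=float(r["pH"]),
                                oxygen=float(r["oxygen_pct"]))
        anchors.append(Anchor(
            kind="absolute_fluor", promoter=promoters[sid],
            topology=strain_topologies[sid], environment=env,
            target=float(r["mean_normalized_fluor_au"]), units="A.U.",
            tolerance=0.1, read_time_h=float(r["read_time_h"]),
            quote="synthetic plate mean",
        ))
    return anchors
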