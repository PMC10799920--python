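"""Anchor evaluation, least-squares calibration, and recovery reporting."""

import numpy as np
import pandas as pd
import pytest

import tmesense as tm
from tmesense.calibrate import (
    Anchor,
    AnchorError,
    AnchorSet,
    reference_anchor_set,
)
from tmesense.params import ParameterError
from tmesense.synthetic import NoiseModel, recovery_design


def make_anchor(**kw):
    base = dict(kind="absolute_fluor", promoter="pLldR", topology="DIRECT",
                environment=tm.EnvironmentSignal(lactate=10.0), target=70.0,
                units="A.U.", tolerance=0.1)
    base.update(kw)
    return Anchor(**base)


class TestAnchors:
    def test_shipped_anchor_set_loads(self):
        anchors = reference_anchor_set()
        assert len(anchors) == 10
        kinds = {a.kind for a in anchors}
        assert {"absolute_fluor", "fold_change", "peak_time",
                "persistence_time", "half_activation_signal"} == kinds

    def test_anchor_validation(self):
        with pytest.raises(AnchorError):
            make_anchor(target=0.0)
        with pytest.raises(AnchorError):
            make_anchor(tolerance=1.5)
        with pytest.raises(AnchorError):
            make_anchor(kind="mystery")
        with pytest.raises(AnchorError):
            AnchorSet([])

    def test_csv_round_trip(self, tmp_path):
        anchors = reference_anchor_set()
        path = tmp_path / "anchors.csv"
        anchors.to_csv(path)
        again = AnchorSet.from_csv(path)
        assert len(again) == len(anchors)
        assert [a.target for a in again] == [a.target for a in anchors]

    def test_self_consistency_oracle(self, params):
        """An anchor built from a simulated value has zero residual there."""
        strain = tm.build_strain("pLldR", "DIRECT", params)
        traj = tm.simulate_time_course(strain, tm.EnvironmentSignal(lactate=5.0),
                                       horizon=48.0)
        anchor = make_anchor(environment=tm.EnvironmentSignal(lactate=5.0),
                             target=float(traj.normalized_fluor[-1]))
        pred = tm.evaluate_anchor(anchor, params)
        assert pred == pytest.approx(anchor.target, rel=1e-9)

    def test_half_activation_anchor_reads_hill_constant(self, params):
        anchor = make_anchor(kind="half_activation_signal", promoter="pPepT",
                             topology="SWITCH", target=0.5, units="% O2")
        assert tm.evaluate_anchor(anchor, params) == params["pPepT_half_max"]


class TestFoldChange:
    def test_fold_matches_ratio_of_absolute_readouts(self, params):
        env = tm.EnvironmentSignal(lactate=10.0)
        direct = tm.simulate_time_course(tm.build_strain("pLldR", "DIRECT", params),
                                         env, horizon=48.0)
        switch = tm.simulate_time_course(tm.build_strain("pLldR", "SWITCH", params),
                                         env, horizon=48.0)
        expected = switch.normalized_fluor[-1] / direct.normalized_fluor[-1]
        assert tm.fold_change("pLldR", env, params) == pytest.approx(expected, rel=1e-9)

    def test_zero_direct_readout_rejected(self, params):
        with pytest.raises(AnchorError):
            tm.fold_change("pLldR", tm.EnvironmentSignal(lactate=0.0), params)


class TestFitParameters:
    def test_empty_free_list_evaluates_defaults(self):
        anchors = AnchorSet([make_anchor()])
        result = tm.fit_parameters(anchors, [], n_starts=1)
        assert result.params == tm.default_params()
        assert result.loss >= 0.0

    def test_loss_zero_iff_anchors_match(self, params):
        matched = AnchorSet([make_anchor(target=tm.evaluate_anchor(make_anchor(), params))])
        r0 = tm.fit_parameters(matched, [], n_starts=1, base_params=params)
        assert r0.loss == pytest.approx(0.0, abs=1e-12)
        off = AnchorSet([make_anchor(target=200.0)])
        r1 = tm.fit_parameters(off, [], n_starts=1, base_params=params)
        assert r1.loss > 0.0

    def test_recovers_perturbed_gain(self, params):
        """1-D noiseless refit lands back on the generating value."""
        truth = params["pLldR_direct_gain"]
        target = tm.evaluate_anchor(make_anchor(), params)
        anchors = AnchorSet([make_anchor(target=target)])
        start = dict(params, pLldR_direct_gain=truth * 1.7)
        fit = tm.fit_parameters(anchors, ["pLldR_direct_gain"], n_starts=1,
                                base_params=start)
        assert fit.estimates[0] == pytest.approx(truth, rel=1e-4)

    def test_seeded_determinism(self, params):
        anchors = AnchorSet([make_anchor()])
        kw = dict(free_parameter_names=["pLldR_direct_gain"], n_starts=2, seed=11,
                  base_params=dict(params, pLldR_direct_gain=50.0))
        a = tm.fit_parameters(anchors, **kw)
        b = tm.fit_parameters(anchors, **kw)
        assert np.array_equal(a.estimates, b.estimates)
        assert a.loss == b.loss

    def test_multistart_requires_seed(self, params):
        anchors = AnchorSet([make_anchor()])
        with pytest.raises(ParameterError):
            tm.fit_parameters(anchors, ["pLldR_direct_gain"], n_starts=3)

    def test_shipped_defaults_reproduce_all_anchors(self):
        """Every shipped anchor is matched within its stated tolerance."""
        result = tm.fit_parameters(reference_anchor_set(), [], n_starts=1)
        assert result.within_tolerance, result.residual_table

    def test_summary_renders(self, params):
        result = tm.fit_parameters(AnchorSet([make_anchor()]), [], n_starts=1)
        text = result.summary()
        assert "loss" in text and "absolute_fluor" in text


class TestRecoveryExperiment:
    def test_invalid_replicates_rejected(self, params):
        with pytest.raises(ParameterError):
            tm.parameter_recovery_experiment(params, recovery_design(params),
                                             NoiseModel.noiseless(),
                                             n_replicates=0, seed=1)

    def test_report_serializes(self, params, tmp_path):
        rep = tm.parameter_recovery_experiment(
            params, recovery_design(params), NoiseModel.noiseless(),
            n_replicates=1, seed=5, n_datasets=1, n_starts=1,
            free_parameter_names=["pLldR_direct_gain"])
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert "median_rel_error" in payload
        assert isinstance(rep.error_summary(), pd.DataFrame)
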