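"""Objective, qualitative constraints and GA behaviour."""

import numpy as np
import pytest

from nfatnet import make_sequential_pulses
from nfatnet.calibration import (
    CalibrationTarget,
    GAConfig,
    QualitativeConstraints,
    check_qualitative_constraints,
    constraint_penalty,
    fit_ga,
    objective,
)
from nfatnet.engine import Trajectory, simulate
from nfatnet.network import KineticLaw, LawForm, NetworkModel, Reaction, Species
from nfatnet.parameters import ParameterSet


def _nfat_like_trajectory(peak1, peak2, peak_time=1.0, decay=3.0):
    """Two-bump NFAT/FasL curve with controllable peaks and transiency."""
    proto = make_sequential_pulses(1.0, 1.0)
    t = np.linspace(0, 96, 961)
    def bump(t0, h):
        x = np.maximum(t - t0, 0.0)
        return h * (x / peak_time) * np.exp(1 - x / peak_time) * np.exp(-x / (decay * 24))
    v = bump(0.0 + 0.0, peak1) * (t >= 0) + bump(48.0, peak2) * (t >= 48)
    states = np.stack([v, v], axis=1)
    return Trajectory(t, states, ("NFATnuc", "FasL"), proto, None, np.zeros(2))


class TestQualitativeConstraints:
    def test_transient_amplified_response_passes(self):
        traj = _nfat_like_trajectory(40.0, 100.0, decay=0.2)
        out = check_qualitative_constraints(traj, QualitativeConstraints(fasl_fold_min=2.0))
        assert all(out.values()), out

    def test_insufficient_fold_fails_the_fold_test(self):
        traj = _nfat_like_trajectory(40.0, 60.0, decay=0.2)  # 1.5-fold
        out = check_qualitative_constraints(traj, QualitativeConstraints(fasl_fold_min=None))
        assert not out["nfat_fold"]
        assert out["transient_primary"] and out["transient_secondary"]

    def test_flat_response_fails_everything(self):
        proto = make_sequential_pulses(1.0, 1.0)
        t = np.linspace(0, 96, 961)
        states = np.full((961, 2), 5.0)
        traj = Trajectory(t, states, ("NFATnuc", "FasL"), proto, None, np.zeros(2))
        out = check_qualitative_constraints(traj, QualitativeConstraints(fasl_fold_min=None))
        assert not out["nfat_fold"]
        assert not out["transient_primary"]

    def test_late_peak_fails_transiency(self):
        traj = _nfat_like_trajectory(40.0, 100.0, peak_time=40.0, decay=0.5)
        out = check_qualitative_constraints(traj, QualitativeConstraints(fasl_fold_min=None))
        assert not out["transient_primary"]

    def test_penalty_is_zero_iff_constraints_met(self):
        good = _nfat_like_trajectory(40.0, 100.0, decay=0.2)
        bad = _nfat_like_trajectory(40.0, 60.0, decay=0.2)
        c = QualitativeConstraints(fasl_fold_min=None)
        assert constraint_penalty(good, c) == 0.0
        assert constraint_penalty(bad, c) > 0.0


# ---------------------------------------------------------------------------
# a three-parameter toy cascade for objective/GA tests
# ---------------------------------------------------------------------------

def _toy_model():
    reactions = (
        Reaction("a", KineticLaw(LawForm.MICHAELIS_MENTEN, {"Vmax": "V_t1", "Km": "Km_t1"}),
                 substrates=(("A", 1),), products=(("B", 1),), driven_by_input=True),
        Reaction("b", KineticLaw(LawForm.MASS_ACTION, {"k": "kd_t2"}),
                 substrates=(("B", 1),), products=(("A", 1),)),
    )
    return NetworkModel(
        name="toy-cascade",
        species=(Species("A", initial_value=100.0), Species("B")),
        reactions=reactions,
    )


TOY_TRUTH = ParameterSet({"V_t1": 5.0, "Km_t1": 40.0, "kd_t2": 0.05})
TOY_PROTOCOL = make_sequential_pulses(1.0, 1.0, interval=4.0, duration=1.0, horizon=8.0)


def _toy_targets(weight=1.0):
    times = np.linspace(0.2, 8.0, 25)
    traj = simulate(_toy_model(), TOY_TRUTH, TOY_PROTOCOL)
    values = np.interp(times, traj.time_h, traj.series("B"))
    return [CalibrationTarget("B", times, values, weight=weight)]


def test_objective_is_zero_for_self_generated_targets():
    # residual limited only by grid interpolation / integrator tolerance
    cost = objective(TOY_TRUTH, _toy_model(), _toy_targets(), None, TOY_PROTOCOL)
    assert cost == pytest.approx(0.0, abs=1e-4)


def test_objective_weights_scale_the_residual_linearly():
    wrong = TOY_TRUTH.scaled({"V_t1": 2.0})
    c1 = objective(wrong, _toy_model(), _toy_targets(1.0), None, TOY_PROTOCOL)
    c2 = objective(wrong, _toy_model(), _toy_targets(2.0), None, TOY_PROTOCOL)
    assert c1 > 0
    assert c2 == pytest.approx(2.0 * c1, rel=1e-9)


def test_objective_is_invariant_under_target_reordering():
    model = _toy_model()
    times = np.linspace(0.2, 8.0, 15)
    traj = simulate(model, TOY_TRUTH, TOY_PROTOCOL)
    tg_a = CalibrationTarget("A", times, np.interp(times, traj.time_h, traj.series("A")))
    tg_b = CalibrationTarget("B", times, np.interp(times, traj.time_h, traj.series("B")))
    wrong = TOY_TRUTH.scaled({"kd_t2": 3.0})
    assert objective(wrong, model, [tg_a, tg_b], None, TOY_PROTOCOL) == pytest.approx(
        objective(wrong, model, [tg_b, tg_a], None, TOY_PROTOCOL), rel=1e-12
    )


class TestGeneticAlgorithm:
    config = GAConfig(population=30, generations=60, mutation_sigma=0.15,
                      init_jitter=0.4, seed=5, early_stop=False)

    def test_recovers_toy_parameters_from_exact_data(self):
        start = TOY_TRUTH.scaled({"V_t1": 3.0, "Km_t1": 0.4, "kd_t2": 2.5})
        res = fit_ga(_toy_model(), _toy_targets(), None, self.config,
                     protocol=TOY_PROTOCOL, start=start)
        assert res.cost < 1e-4
        # V/Km enter the rate jointly; the decay constant is cleanly
        # identifiable from the post-pulse relaxation
        assert res.best["kd_t2"] == pytest.approx(TOY_TRUTH["kd_t2"], rel=0.10)

    def test_cost_history_is_non_increasing(self):
        start = TOY_TRUTH.scaled({"V_t1": 3.0})
        res = fit_ga(_toy_model(), _toy_targets(), None,
                     GAConfig(population=12, generations=10, seed=3, early_stop=False),
                     protocol=TOY_PROTOCOL, start=start)
        assert all(b <= a + 1e-15 for a, b in zip(res.history, res.history[1:]))

    def test_fixed_seed_reproduces_the_best_individual(self):
        start = TOY_TRUTH.scaled({"V_t1": 3.0})
        cfg = GAConfig(population=10, generations=6, seed=11, early_stop=False)
        r1 = fit_ga(_toy_model(), _toy_targets(), None, cfg,
                    protocol=TOY_PROTOCOL, start=start)
        r2 = fit_ga(_toy_model(), _toy_targets(), None, cfg,
                    protocol=TOY_PROTOCOL, start=start)
        assert r1.best.values == r2.best.values
        assert r1.history == r2.history


def test_robustness_envelope_zero_spread_has_zero_sd(full_model, nominal,
                                                     equal_pulse_protocol):
    from nfatnet.calibration import robustness_envelope

    grid = np.linspace(0.0, 96.0, 49)
    env = robustness_envelope(full_model, nominal, equal_pulse_protocol, n=3,
                              spread=0.0, seed=2, grid=grid, species=["NFATnuc"])
    mean, sd = env["NFATnuc"]
    # identical replicates up to integrator warm-up noise at machine precision
    assert np.all(sd <= 1e-9 * (1.0 + np.abs(mean)))
    assert mean.shape == grid.shape


def test_robustness_envelope_is_seed_reproducible(full_model, nominal,
                                                  equal_pulse_protocol):
    from nfatnet.calibration import robustness_envelope

    grid = np.linspace(0.0, 96.0, 25)
    kw = dict(n=4, spread=0.3, seed=7, grid=grid, species=["NFATnuc", "FasL"])
    e1 = robustness_envelope(full_model, nominal, equal_pulse_protocol, **kw)
    e2 = robustness_envelope(full_model, nominal, equal_pulse_protocol, **kw)
    np.testing.assert_array_equal(e1["NFATnuc"][0], e2["NFATnuc"][0])
    np.testing.assert_array_equal(e1["FasL"][1], e2["FasL"][1])
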