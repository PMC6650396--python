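"""Simulation engine: baseline handling, conservation, convergence."""

import numpy as np
import pytest

from nfatnet import find_baseline, make_sequential_pulses, simulate
from nfatnet.engine import BaselineError, SimulationError
from nfatnet.fullmodel import SYNTHESIS_DECAY_RIDS


def test_baseline_is_a_fixed_point_under_zero_input(full_model, nominal, baseline):
    proto = make_sequential_pulses(1e-12, 0.0)  # effectively no stimulus
    traj = simulate(full_model, nominal, proto, baseline=baseline)
    drift = np.abs(traj.states - baseline).max(axis=0)
    assert np.all(drift <= 1e-3 * (1.0 + baseline))


def test_baseline_nuclear_nfat_is_near_zero(baseline, full_model):
    i = full_model.species_index("NFATnuc")
    assert baseline[i] < 0.5  # inactive before stimulation


def test_trajectory_states_stay_essentially_nonnegative(nominal_trajectory):
    assert nominal_trajectory.states.min() > -1e-6


def test_always_closed_moieties_are_conserved(full_model, nominal_trajectory):
    closed = ["CN_total", "TCR_total", "IL2R_total", "TAK1_total", "MEK_total",
              "ERK_total", "PI3K_total", "Akt_total", "PP2A_total", "GSK3_total",
              "Rac1_total", "CnI_total", "Ras_total"]
    for name in closed:
        members = full_model.conserved_moieties[name]
        idx = [full_model.species_index(m) for m in members]
        total = nominal_trajectory.states[:, idx].sum(axis=1)
        scale = max(total[0], 1.0)
        assert np.abs(total - total[0]).max() / scale < 1e-6, name


def test_nfat_moiety_conserved_when_synthesis_and_decay_removed(full_model, nominal):
    closed_model = full_model.without_reactions(SYNTHESIS_DECAY_RIDS)
    params = nominal  # extra constants are ignored by the smaller model
    base = find_baseline(closed_model, params, t_settle_h=200.0, tol=1e-5)
    traj = simulate(closed_model, params, make_sequential_pulses(1.0, 1.0), baseline=base)
    for name in ("NFAT_total", "RCAN_total", "Carabin_total"):
        idx = [closed_model.species_index(m) for m in closed_model.conserved_moieties[name]]
        total = traj.states[:, idx].sum(axis=1)
        assert np.abs(total - total[0]).max() / max(total[0], 1.0) < 1e-6, name


def test_tolerance_refinement_changes_auc_marginally(full_model, nominal, baseline,
                                                     equal_pulse_protocol):
    t1 = simulate(full_model, nominal, equal_pulse_protocol, baseline=baseline,
                  rtol=1e-6, atol=1e-9)
    t2 = simulate(full_model, nominal, equal_pulse_protocol, baseline=baseline,
                  rtol=5e-7, atol=5e-10)
    for sp in ("NFATnuc", "FasL"):
        a1 = np.trapezoid(t1.series(sp), t1.time_h)
        a2 = np.trapezoid(t2.series(sp), t2.time_h)
        assert abs(a1 - a2) / a1 < 1e-3, sp


def test_simulation_is_deterministic(full_model, nominal, baseline, equal_pulse_protocol):
    a = simulate(full_model, nominal, equal_pulse_protocol, baseline=baseline)
    b = simulate(full_model, nominal, equal_pulse_protocol, baseline=baseline)
    np.testing.assert_array_equal(a.states, b.states)


def test_incomplete_parameters_raise_configuration_error(full_model, nominal,
                                                         equal_pulse_protocol):
    from nfatnet.parameters import ParameterSet

    partial = ParameterSet({k: v for k, v in list(nominal.values.items())[:10]})
    with pytest.raises(KeyError, match="incomplete"):
        simulate(full_model, partial, equal_pulse_protocol)


def test_work_budget_failures_carry_last_state(full_model, nominal, baseline,
                                               equal_pulse_protocol):
    with pytest.raises(SimulationError) as err:
        simulate(full_model, nominal, equal_pulse_protocol, baseline=baseline,
                 max_rhs_evals=100)
    assert err.value.last_state is not None
    with pytest.raises(BaselineError):
        find_baseline(full_model, nominal, max_rhs_evals=100)


def test_tidy_frame_export(nominal_trajectory):
    frame = nominal_trajectory.to_frame()
    assert list(frame.columns) == ["time_h", "species", "value"]
    assert len(frame) == len(nominal_trajectory.time_h) * len(nominal_trajectory.species_names)
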