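"""Pattern classification, LSF identities, phenotypes, dosing operations."""

import numpy as np
import pytest

from nfatnet import make_sequential_pulses
from nfatnet.feedback import (
    ImmunePhenotype,
    ScanPattern,
    classify_immune_phenotype,
    classify_scan_pattern,
    link_sensitivity,
    lsf_sensitivity,
    optimal_window,
    perturbation_study,
    significance_band,
)
from nfatnet.network import KineticLaw, LawForm, NetworkModel, Reaction, Species
from nfatnet.parameters import ParameterSet

GRID = np.logspace(-2, 2, 5)


class TestScanPatternClassifier:
    @pytest.mark.parametrize("outputs, pattern", [
        ([1, 2, 3, 4, 5], ScanPattern.MONOTONIC_INCREASE),
        ([5, 4, 3, 2, 1], ScanPattern.MONOTONIC_DECREASE),
        ([1, 3, 5, 3, 1], ScanPattern.BIPHASIC),
        ([5, 3, 1, 3, 5], ScanPattern.REVERSE_BIPHASIC),
        ([1.0, 1.01, 1.02, 1.0, 0.99], ScanPattern.NO_CHANGE),
    ])
    def test_truth_table(self, outputs, pattern):
        assert classify_scan_pattern(GRID, np.array(outputs, float)) is pattern

    @pytest.mark.parametrize("scale", [0.003, 1.0, 1e4])
    def test_invariant_under_positive_rescaling(self, scale):
        y = np.array([1, 3, 5, 3, 1], float)
        assert classify_scan_pattern(GRID, y * scale) is ScanPattern.BIPHASIC

    def test_interior_margin_separates_biphasic_from_monotone(self):
        y = np.array([1.0, 2.0, 3.0, 3.05, 2.99])  # interior max within 5% of ends
        assert classify_scan_pattern(GRID, y) is ScanPattern.MONOTONIC_INCREASE

    def test_preconditions(self):
        with pytest.raises(ValueError):
            classify_scan_pattern(GRID[:4], np.ones(4))
        with pytest.raises(ValueError):
            classify_scan_pattern(GRID[::-1], np.ones(5))


class TestLogSensitivity:
    """Closed-form checks on scalar toy systems (no ODEs involved)."""

    @staticmethod
    def _model_with(powerlaw):
        model = NetworkModel(
            name="lsf-toy",
            species=(Species("X"),),
            reactions=(Reaction("r", KineticLaw(LawForm.MASS_ACTION, {"k": "kc_p"}),
                                products=(("X", 1),)),),
        )
        params = ParameterSet({"kc_p": 2.0})

        def output(model, ps, protocol):
            return powerlaw(ps["kc_p"])

        return model, params, output

    def test_linear_output_scores_exactly_one(self):
        model, params, output = self._model_with(lambda p: 7.0 * p)
        for delta in (0.01, 0.3, 0.5):
            (score,) = lsf_sensitivity(model, params, output, ["kc_p"], delta)
            assert score.score == pytest.approx(1.0)

    def test_quadratic_output_approaches_two_as_delta_shrinks(self):
        model, params, output = self._model_with(lambda p: p**2)
        scores = [lsf_sensitivity(model, params, output, ["kc_p"], d)[0].score
                  for d in (0.5, 0.1, 0.01, 0.001)]
        assert scores[0] == pytest.approx(2.5)  # one-sided FD at delta = 0.5
        assert scores[-1] == pytest.approx(2.0, abs=0.01)
        assert abs(scores[2] - 2.0) < abs(scores[0] - 2.0)

    def test_constant_output_scores_zero(self):
        model, params, output = self._model_with(lambda p: 42.0)
        (score,) = lsf_sensitivity(model, params, output, ["kc_p"], 0.25)
        assert score.score == 0.0

    def test_zero_output_gives_nan_sentinel(self):
        model, params, output = self._model_with(lambda p: 0.0)
        (score,) = lsf_sensitivity(model, params, output, ["kc_p"], 0.25)
        assert not score.defined

    def test_zero_delta_scores_zero_without_simulation(self):
        model, params, output = self._model_with(lambda p: p**3)
        (score,) = lsf_sensitivity(model, params, output, ["kc_p"], 0.0)
        assert score.score == 0.0


class TestImmunePhenotype:
    REF = 100.0  # reference primary FasL AUC

    def classify(self, primary, secondary):
        return classify_immune_phenotype(primary, secondary,
                                         silence_threshold=0.1 * self.REF,
                                         induction_threshold=2.0 * self.REF).phenotype

    def test_silenced_primary_with_induced_secondary_is_aicd(self):
        assert self.classify(1.0, 2000.0) is ImmunePhenotype.AICD

    def test_strong_primary_is_immune_deficiency_regardless_of_secondary(self):
        assert self.classify(1500.0, 0.0) is ImmunePhenotype.ID
        assert self.classify(1500.0, 5000.0) is ImmunePhenotype.ID

    def test_both_silenced_is_autoimmunity(self):
        assert self.classify(0.5, 0.5) is ImmunePhenotype.AU

    def test_intermediate_cases_are_other(self):
        assert self.classify(50.0, 50.0) is ImmunePhenotype.OTHER

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            classify_immune_phenotype(1.0, 1.0, silence_threshold=5.0,
                                      induction_threshold=2.0)


class TestOptimalWindow:
    def test_flat_curves_give_empty_window(self):
        doses = np.linspace(0, 10, 11)
        assert optimal_window(doses, np.ones(11), np.ones(11)) is None

    def test_matches_brute_force_on_analytic_curves(self):
        doses = np.linspace(0.0, 10.0, 101)
        il2 = np.exp(-doses)
        fasl = doses * np.exp(-doses / 2.0)
        window = optimal_window(doses, il2, fasl, 0.5, 0.8)
        ok = (il2 < 0.5 * il2[0]) & (fasl > 0.8 * fasl.max())
        runs, i = [], 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j + 1 < len(ok) and ok[j + 1]:
                    j += 1
                runs.append((doses[i], doses[j]))
                i = j + 1
            else:
                i += 1
        expected = max(runs, key=lambda r: r[1] - r[0])
        assert window == pytest.approx(expected)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            optimal_window(np.arange(5), np.ones(5), np.ones(4))


def test_significance_bands():
    assert significance_band(0.5) == "ns"
    assert significance_band(0.03) == "p<0.05"
    assert significance_band(0.005) == "p<0.01"
    assert significance_band(1e-5) == "p<0.001"


def test_null_perturbation_study_finds_nothing(full_model, nominal):
    """delta = 0 makes perturbed and control arms identical sample-by-sample."""
    results = perturbation_study(full_model, nominal, links=["NFAT/NFAT"],
                                 delta=0.0, n=4, seed=3)
    for res in results:
        np.testing.assert_array_equal(res.ai_samples, res.control_samples)
        assert res.p_value == 1.0
        assert res.significance_band == "ns"


def test_perturbation_study_is_seed_deterministic(full_model, nominal):
    kw = dict(links=["Carabin/CN"], delta=0.3, n=4, seed=9)
    r1 = perturbation_study(full_model, nominal, **kw)
    r2 = perturbation_study(full_model, nominal, **kw)
    for a, b in zip(r1, r2):
        np.testing.assert_array_equal(a.ai_samples, b.ai_samples)
        assert a.p_value == b.p_value


def test_link_sensitivity_suppression_sign_convention(full_model, nominal):
    """Suppressing the NFAT auto-induction loop lowers AI: positive score."""
    from nfatnet.feedback import secondary_auc_output

    score = link_sensitivity(full_model, nominal, "NFAT/NFAT",
                             secondary_auc_output("NFATnuc"), delta_fraction=-0.5)
    assert score.score > 0
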