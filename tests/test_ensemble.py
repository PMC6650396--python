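"""Ensemble machinery: tallies against brute force, seeding, small builds."""

import numpy as np
import pytest

from nfatnet.calibration import GAConfig
from nfatnet.ensemble import (
    EnsembleModel,
    EnsembleResult,
    SensitivityMatrix,
    build_ensemble,
    ensemble_sensitivity,
    tally_strong_effects,
)


class TestStrongEffectTally:
    def test_matches_exhaustive_enumeration_on_a_small_matrix(self):
        scores = np.array([
            [2.0, -1.0],
            [0.5, -0.2],
            [1.5, 0.3],
            [-0.1, -2.0],
        ])
        matrix = SensitivityMatrix(scores=scores, links=["a", "b"])
        out = tally_strong_effects(matrix, quantile_axis="pooled")
        pooled = scores.ravel()
        hi, lo = np.quantile(pooled, 0.75), np.quantile(pooled, 0.25)
        for j, link in enumerate(["a", "b"]):
            col = scores[:, j]
            assert out[link].n_enhancing == int(np.sum((col > hi) & (col > 0)))
            assert out[link].n_inhibiting == int(np.sum((col < lo) & (col < 0)))
            assert out[link].n_scored == 4

    def test_constant_column_counts_nothing_per_link(self):
        scores = np.column_stack([np.full(6, 3.0), np.linspace(-1, 1, 6)])
        matrix = SensitivityMatrix(scores=scores, links=["const", "varied"])
        out = tally_strong_effects(matrix, quantile_axis="per_link")
        assert out["const"].n_enhancing == 0
        assert out["const"].n_inhibiting == 0

    def test_enhancing_and_inhibiting_sets_are_disjoint_fractions(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(40, 3))
        matrix = SensitivityMatrix(scores=scores, links=["x", "y", "z"])
        for tally in tally_strong_effects(matrix).values():
            assert 0.0 <= tally.enhancing_fraction <= 1.0
            assert 0.0 <= tally.inhibiting_fraction <= 1.0
            assert tally.n_enhancing + tally.n_inhibiting <= tally.n_scored

    def test_nan_sentinels_are_excluded(self):
        scores = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan], [4.0, np.nan]])
        matrix = SensitivityMatrix(scores=scores, links=["ok", "dead"])
        out = tally_strong_effects(matrix)
        assert "dead" not in out
        assert out["ok"].n_scored == 4

    def test_degenerate_matrix_rejected(self):
        matrix = SensitivityMatrix(scores=np.full((3, 2), np.nan), links=["a", "b"])
        with pytest.raises(ValueError):
            tally_strong_effects(matrix)


def test_cluster_order_is_a_permutation():
    rng = np.random.default_rng(3)
    matrix = SensitivityMatrix(scores=rng.normal(size=(12, 5)),
                               links=list("abcde"))
    order = matrix.cluster_order()
    assert sorted(order) == list(range(12))


class TestSmallEnsembleBuild:
    """End-to-end on the reduced network (cheap simulations)."""

    @pytest.fixture(scope="class")
    def small_ensemble(self):
        from nfatnet.reduced import build_reduced_network, reduced_nominal_parameters

        model = build_reduced_network()
        ens = build_ensemble(
            model, n=2, seed=5, reference=reduced_nominal_parameters(),
            ga_config=GAConfig(population=10, generations=25, mutation_sigma=0.45,
                               mutation_rate=0.3, init_jitter=0.5),
        )
        return model, ens

    def test_members_satisfy_every_constraint(self, small_ensemble):
        _, ens = small_ensemble
        assert len(ens) == 2
        for m in ens.members:
            assert all(m.constraint_report.values()), m.constraint_report

    def test_ensemble_minimum_ai_is_positive_and_finite(self, small_ensemble):
        _, ens = small_ensemble
        assert np.isfinite(ens.ai_ratios).all()
        assert ens.ai_ratios.min() > 1.0

    def test_same_seed_reproduces_members(self, small_ensemble):
        from nfatnet.reduced import build_reduced_network, reduced_nominal_parameters

        model, ens = small_ensemble
        again = build_ensemble(
            model, n=2, seed=5, reference=reduced_nominal_parameters(),
            ga_config=GAConfig(population=10, generations=25, mutation_sigma=0.45,
                               mutation_rate=0.3, init_jitter=0.5),
        )
        for a, b in zip(ens.members, again.members):
            assert a.params.values == b.params.values

    def test_sensitivity_matrix_shape_and_scores(self, small_ensemble):
        model, ens = small_ensemble
        matrix = ensemble_sensitivity(ens, model)
        assert matrix.scores.shape == (2, len(model.feedback_links))
        assert np.isfinite(matrix.scores).any()


def test_empty_ensemble_rejected():
    from nfatnet.reduced import build_reduced_network

    with pytest.raises(ValueError):
        ensemble_sensitivity(EnsembleResult([], 0, 0), build_reduced_network())
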