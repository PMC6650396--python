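"""Structural and rate-law unit tests for the network domain types."""

import numpy as np
import pytest

from nfatnet import (
    KineticLaw,
    LawForm,
    Reaction,
    apply_link_perturbation,
    evaluate_rate,
)
from nfatnet.network import CANONICAL_LINKS, FeedbackSign, NetworkError
from nfatnet._codegen import compile_rhs


def test_full_network_has_eleven_feedback_links(full_model):
    assert len(full_model.feedback_links) == 11
    assert {l.name for l in full_model.feedback_links} == set(CANONICAL_LINKS)


def test_link_signs_match_their_regulatory_direction(full_model):
    positive = {"NFAT/NFAT", "pRCAN/CN", "TNFa/TAK1", "PI3K/Akt", "Akt/GSK3", "PI3K/Rac1"}
    for link in full_model.feedback_links:
        expected = FeedbackSign.POSITIVE if link.name in positive else FeedbackSign.NEGATIVE
        assert link.sign is expected, link.name


def test_controlled_parameter_sets_are_disjoint_and_nonempty(full_model):
    seen = set()
    for link in full_model.feedback_links:
        assert link.controlled_parameters
        assert not (seen & link.controlled_parameters)
        seen |= link.controlled_parameters


def test_amplification_group_species_are_present(full_model):
    required = {"NFATnuc", "NFATcyt", "FasL", "CN_RCAN", "RCAN", "pRCAN", "IL2",
                "Carabin", "pTCR", "CaCN", "aRas", "pERK", "aPI3K", "pAkt",
                "CTLA4", "TNFa", "pMEK", "GSK3b", "TAK1", "Rac1", "IL2mRNA",
                "CnI", "aPP2A", "aRas_Carabin", "CN_Carabin", "CN_pRCAN", "pIL2R"}
    assert required <= set(full_model.species_names)


# ---------------------------------------------------------------------------
# kinetic-law identities (evaluate_rate is the slow reference path)
# ---------------------------------------------------------------------------

def test_michaelis_menten_half_saturation_identity():
    rxn = Reaction("x", KineticLaw(LawForm.MICHAELIS_MENTEN, {"Vmax": "V", "Km": "K"}),
                   substrates=(("S", 1),), products=(("P", 1),))
    rate = evaluate_rate(rxn, {"S": 5.0, "P": 0.0}, {"V": 8.0, "K": 5.0})
    assert rate == pytest.approx(4.0)


@pytest.mark.parametrize("s", [0.1, 1.0, 5.0, 50.0])
def test_hill_with_unit_exponent_equals_michaelis_menten(s):
    hill = Reaction("h", KineticLaw(LawForm.HILL, {"Vmax": "V", "Km": "K"}, hill_n=1.0),
                    products=(("P", 1),), regulator="S")
    mm = Reaction("m", KineticLaw(LawForm.MICHAELIS_MENTEN, {"Vmax": "V", "Km": "K"}),
                  substrates=(("S", 1),), products=(("P", 1),))
    params = {"V": 3.0, "K": 2.0}
    assert evaluate_rate(hill, {"S": s, "P": 0.0}, params) == pytest.approx(
        evaluate_rate(mm, {"S": s, "P": 0.0}, params)
    )


def test_mass_action_rate_is_product_of_substrates():
    rxn = Reaction("b", KineticLaw(LawForm.MASS_ACTION, {"k": "ka"}),
                   substrates=(("A", 1), ("B", 1)), products=(("C", 1),))
    assert evaluate_rate(rxn, {"A": 3.0, "B": 4.0, "C": 0.0}, {"ka": 2.0}) == 24.0


def test_negative_concentration_is_a_precondition_violation():
    rxn = Reaction("b", KineticLaw(LawForm.MASS_ACTION, {"k": "ka"}),
                   substrates=(("A", 1),))
    with pytest.raises(ValueError, match="negative"):
        evaluate_rate(rxn, {"A": -1.0}, {"ka": 2.0})


def test_missing_parameter_names_the_parameter():
    rxn = Reaction("b", KineticLaw(LawForm.MASS_ACTION, {"k": "ka_77"}),
                   substrates=(("A", 1),))
    with pytest.raises(KeyError, match="ka_77"):
        evaluate_rate(rxn, {"A": 1.0}, {})


def test_compiled_rhs_matches_reference_rates(full_model, nominal, rng):
    """The generated ODE right-hand side equals the sum of reference rates."""
    state = {n: float(rng.uniform(0, 50)) for n in full_model.species_names}
    y = np.array([state[n] for n in full_model.species_names])
    p = nominal.as_array(full_model.parameter_names)
    dy = compile_rhs(full_model)(0.0, y, p, 1.0)
    expected = np.zeros_like(y)
    for rxn in full_model.reactions:
        rate = evaluate_rate(rxn, state, nominal.values, input_value=1.0)
        for sp, st in rxn.substrates:
            expected[full_model.species_index(sp)] -= st * rate
        for sp, st in rxn.products:
            expected[full_model.species_index(sp)] += st * rate
    np.testing.assert_allclose(dy, expected, rtol=1e-12, atol=1e-12)


# ---------------------------------------------------------------------------
# link perturbation
# ---------------------------------------------------------------------------

def test_unit_factor_perturbation_is_identity(full_model, nominal):
    ps = apply_link_perturbation(full_model, "NFAT/NFAT", 1.0, params=nominal)
    assert ps.values == nominal.values


def test_perturbation_scales_only_controlled_parameters(full_model, nominal):
    link = full_model.link("NFAT/NFAT")
    ps = apply_link_perturbation(full_model, link, 1.3, params=nominal)
    for name in nominal.names:
        if name in link.controlled_parameters:
            assert ps[name] == pytest.approx(1.3 * nominal[name])
        else:
            assert ps[name] == nominal[name]


def test_perturbation_locality_in_the_rhs(full_model, nominal, rng):
    """Scaling one link changes only rate terms referencing its parameters."""
    y = rng.uniform(0, 50, size=len(full_model.species))
    p0 = nominal.as_array(full_model.parameter_names)
    rhs = compile_rhs(full_model)
    ps = apply_link_perturbation(full_model, "TNFa/TAK1", 2.0, params=nominal)
    p1 = ps.as_array(full_model.parameter_names)
    d0, d1 = rhs(0.0, y, p0, 1.0), rhs(0.0, y, p1, 1.0)
    link_params = full_model.link("TNFa/TAK1").controlled_parameters
    touched = {
        full_model.species_index(s)
        for r in full_model.reactions
        if set(r.parameter_names) & link_params
        for s in r.species_names()
    }
    for i in range(len(y)):
        if i not in touched:
            assert d0[i] == pytest.approx(d1[i], rel=1e-12), full_model.species_names[i]


def test_scan_bracket_factors_are_admissible(full_model, nominal):
    for factor in (0.01, 100.0):
        ps = apply_link_perturbation(full_model, "NFAT/NFAT", factor, params=nominal)
        (name,) = full_model.link("NFAT/NFAT").controlled_parameters
        assert ps[name] == pytest.approx(factor * nominal[name])


def test_zero_or_negative_factor_rejected(full_model, nominal):
    with pytest.raises(ValueError):
        apply_link_perturbation(full_model, "NFAT/NFAT", 0.0, params=nominal)


def test_unknown_link_name_raises_lookup_error(full_model, nominal):
    with pytest.raises(NetworkError, match="unknown feedback link"):
        apply_link_perturbation(full_model, "Foo/Bar", 1.3, params=nominal)
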