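"""Elasticities, control coefficients and the partitioned response."""

import math

import pytest

import gsda
from gsda.mca import (
    SingularJacobianError,
    connectivity_residuals,
    elasticity,
    elasticities,
    finite_difference_response,
)
from gsda.model import KineticModel, Reaction, Species


def reversible_unit():
    return KineticModel(
        [Species("S", "variable", 1.0), Species("P", "variable", 1.0)],
        {"kf": 2.0, "kr": 1.0},
        [Reaction.create("R1", {"S": -1, "P": 1}, "kf*S - kr*P")],
    )


class TestElasticities:
    def test_reversible_mass_action_closed_form(self):
        # eps_S = kf*S/v = 2/(2-1), eps_P = -kr*P/v = -1/(2-1)
        m = reversible_unit()
        st = m.initial_state()
        assert elasticity(m, "R1", "S", st) == pytest.approx(2.0)
        assert elasticity(m, "R1", "P", st) == pytest.approx(-1.0)

    def test_mass_action_log_linear(self):
        m = KineticModel(
            [Species("S", "variable", 1.0), Species("P", "variable", 1.0)],
            {"k": 3.0},
            [Reaction.create("R1", {"S": -1, "P": 1}, "k*S")],
        )
        for s in (0.01, 1.0, 250.0):
            assert elasticity(m, "R1", "S", {"S": s, "P": 1.0}) == pytest.approx(1.0)

    def test_elasticity_diverges_near_equilibrium(self):
        m = reversible_unit()
        values = [abs(elasticity(m, "R1", "S", {"S": 0.5 + d, "P": 1.0}))
                  for d in (0.1, 0.01, 0.001)]
        assert values[0] < values[1] < values[2]
        # at exact equilibrium the scaled elasticity is flagged non-finite
        em = elasticities(m, {"S": 0.5, "P": 1.0})
        assert math.isnan(em.get("R1", "S"))
        assert ("R1", "S") in em.near_equilibrium

    def test_structural_zero(self):
        m = reversible_unit()
        em = elasticities(m, m.initial_state())
        assert em.get("R1", "nonexistent") == 0.0

    def test_symbolic_numeric_agreement(self, all_models):
        for m in all_models:
            ss = gsda.steady_state(m, raise_on_failure=True)
            for r in m.reactions:
                for x in sorted(r.free_symbols & set(m.species_ids)):
                    a = elasticity(m, r.id, x, ss.concentrations, "symbolic")
                    b = elasticity(m, r.id, x, ss.concentrations, "numeric")
                    assert a == pytest.approx(b, rel=1e-6, abs=1e-9), (m.name, r.id, x)


class TestControlCoefficients:
    def test_two_step_closed_form(self):
        # eps1_S = -1, eps2_S = 1 at the root of 2 - s = s:
        # C^J_v1 = eps2/(eps2 - eps1) = 0.5
        m = KineticModel(
            [Species("X0", "clamped", 1.0), Species("S", "variable", 0.5),
             Species("X1", "clamped", 0.0)],
            {},
            [Reaction.create("R1", {"X0": -1, "S": 1}, "2*X0 - S"),
             Reaction.create("R2", {"S": -1, "X1": 1}, "S")],
        )
        ss = gsda.steady_state(m, raise_on_failure=True)
        cm = gsda.control_coefficients(m, ss)
        assert cm.C_J("R1", "R1") == pytest.approx(0.5, abs=1e-9)
        assert cm.C_J("R1", "R2") == pytest.approx(0.5, abs=1e-9)

    def test_single_reaction_full_control(self):
        # one reaction between clamped pools: summation forces C^J_v1 = 1
        m = KineticModel(
            [Species("X0", "clamped", 1.0), Species("S", "variable", 0.5),
             Species("X1", "clamped", 0.0)],
            {"k": 1.0},
            [Reaction.create("R1", {"X0": -1, "X1": 1}, "k*X0")],
        )
        ss = gsda.steady_state(m, raise_on_failure=True)
        cm = gsda.control_coefficients(m, ss)
        assert cm.C_J("R1", "R1") == pytest.approx(1.0, abs=1e-12)

    def test_summation_theorems_all_fixtures(self, all_models):
        for m in all_models:
            ss = gsda.steady_state(m, raise_on_failure=True)
            cm = gsda.control_coefficients(m, ss)
            assert cm.theorems["flux_summation_max_abs_error"] <= 1e-6
            assert cm.theorems["conc_summation_max_abs_error"] <= 1e-6

    def test_connectivity_theorem_all_fixtures(self, all_models):
        for m in all_models:
            ss = gsda.steady_state(m, raise_on_failure=True)
            res = connectivity_residuals(m, ss)
            assert res.abs().max().max() <= 1e-6

    def test_singular_jacobian_refused(self):
        # rate independent of S: dv/ds = 0, reduced Jacobian singular
        m = KineticModel(
            [Species("X0", "clamped", 1.0), Species("S", "variable", 1.0),
             Species("X1", "clamped", 0.0)],
            {"k": 1.0},
            [Reaction.create("R1", {"X0": -1, "S": 1}, "k*X0"),
             Reaction.create("R2", {"S": -1, "X1": 1}, "k*X0")],
        )
        ss = gsda.SteadyStateResult(m.initial_state(),
                                    {"R1": 1.0, "R2": 1.0}, 0.0, 1.0, True, m)
        with pytest.raises(SingularJacobianError, match="condition"):
            gsda.control_coefficients(m, ss)


class TestResponseCoefficients:
    def test_single_channel_is_c_times_eps(self, chain_model, chain_ss):
        cm = gsda.control_coefficients(chain_model, chain_ss)
        R = gsda.response_coefficient(chain_model, chain_ss, "X0",
                                      ("flux", "R3"), cm=cm)
        assert list(R.decomposition) == ["R1"]
        C, eps = R.factors["R1"]
        assert R.value == pytest.approx(C * eps, rel=1e-12)

    def test_partition_identity(self, all_models):
        for m in all_models:
            ss = gsda.steady_state(m, raise_on_failure=True)
            for p in m.clamped_ids:
                R = gsda.response_coefficient(m, ss, p, ("flux", m.reaction_ids[0]))
                assert R.value == pytest.approx(sum(R.decomposition.values()),
                                                rel=1e-6, abs=1e-12)

    def test_matches_resolve_finite_difference(self, chain_model):
        R = gsda.response_coefficient(
            chain_model, gsda.steady_state(chain_model, raise_on_failure=True),
            "X0", ("flux", "R3"))
        fd = finite_difference_response(chain_model, "X0", ("flux", "R3"))
        assert R.value == pytest.approx(fd, rel=1e-4)

    def test_parameter_with_no_effect_gives_zero(self, chain_model, chain_ss):
        m = chain_model.with_parameters({"unused": 1.0})
        ss = gsda.steady_state(m, raise_on_failure=True)
        R = gsda.response_coefficient(m, ss, "unused", ("flux", "R1"))
        assert R.value == 0.0 and R.decomposition == {}

    def test_indirect_route_chain_identity(self, chain_fb_internal):
        """With feedback from the demand-side intermediate, the supply-block
        partial via the demand reaction factorises as
        C^Jsup_v1 * eps^v1_S2 * C^S2_v3 * eps^v3_P in the clamped system."""
        m = chain_fb_internal
        ss = gsda.steady_state(m, raise_on_failure=True)
        clamped = gsda.clamp(m, "P", ss.concentrations["P"])
        css = gsda.steady_state(clamped, init=ss.concentrations,
                                raise_on_failure=True)
        cm = gsda.control_coefficients(clamped, css)
        em = gsda.elasticities(clamped, css.concentrations)
        R = gsda.response_coefficient(clamped, css, "P", ("flux", "R2"), cm=cm)
        expanded = (cm.C_J("R2", "R1") * em.get("R1", "S2")
                    * cm.C_s("S2", "R3") * em.get("R3", "P"))
        assert R.decomposition["R3"] == pytest.approx(expanded, rel=1e-6)
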