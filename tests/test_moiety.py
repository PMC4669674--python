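"""Moiety-ratio variables: reconstruction, elasticity chain rule, oracle
equivalence with explicit member clamping."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gsda
from gsda.mca import elasticity
from gsda.model import KineticModel, ModelDefinitionError, Reaction, Species
from gsda.moiety import MoietyRatio, introduce_ratio, ratio_elasticity, set_ratio


class TestReconstruction:
    @pytest.mark.parametrize("phi,total,expected", [
        (1.0, 2.0, (1.0, 1.0)),
        (3.0, 4.0, (3.0, 1.0)),
    ])
    def test_symmetric_and_asymmetric_cases(self, phi, total, expected):
        r = MoietyRatio("phi", "ATP", "ADP", total, phi)
        assert r.member_values(phi) == pytest.approx(expected)

    @given(phi=st.floats(1e-6, 1e6), total=st.floats(1e-9, 1e9))
    @settings(max_examples=200, derandomize=True)
    def test_sum_exact_and_monotone(self, phi, total):
        r = MoietyRatio("phi", "up", "down", total, 1.0)
        num, den = r.member_values(phi)
        assert num + den == total          # exact, by construction
        num2, den2 = r.member_values(phi * 1.5)
        assert num2 > num and den2 < den   # strict monotonicity in phi

    def test_nonpositive_phi_rejected(self):
        r = MoietyRatio("phi", "a", "b", 1.0, 1.0)
        with pytest.raises(ValueError):
            r.member_values(0.0)


class TestIntroduceRatio:
    def test_reference_state_reproduced(self, moiety_model):
        ref = gsda.steady_state(moiety_model, raise_on_failure=True)
        clamped, ratio = introduce_ratio(moiety_model, "Mp", "M", symbol="phi",
                                         reference=ref)
        assert ratio.total == pytest.approx(
            ref.concentrations["M"] + ref.concentrations["Mp"], rel=1e-12)
        assert clamped.species_by_id("Mp").role == "clamped"
        num, den = ratio.member_values(ratio.value)
        assert num == pytest.approx(ref.concentrations["Mp"], rel=1e-9)
        assert den == pytest.approx(ref.concentrations["M"], rel=1e-9)

    def test_unconserved_pair_rejected(self, chain_model):
        with pytest.raises(ModelDefinitionError, match="conserved"):
            introduce_ratio(chain_model, "S1", "P")

    def test_non_unit_coefficients_rejected(self):
        # 2A + B conserved: row (1, 2) is not a unit-coefficient pair
        m = KineticModel(
            [Species("A", "variable", 1.0), Species("B", "variable", 1.0)],
            {"k": 1.0},
            [Reaction.create("R1", {"A": -1, "B": 2}, "k*A - k*B")],
        )
        with pytest.raises(ModelDefinitionError, match="coefficient"):
            introduce_ratio(m, "B", "A",
                            reference=gsda.SteadyStateResult(
                                m.initial_state(), {"R1": 0.0}, 0, 1, True, m))


class TestRatioElasticity:
    def _single_member_model(self):
        return KineticModel(
            [Species("U", "variable", 1.0), Species("V", "variable", 1.0),
             Species("W", "variable", 1.0)],
            {"k": 2.0, "k2": 1.0},
            [Reaction.create("R1", {"U": -1, "V": 1}, "k*U"),
             Reaction.create("R2", {"V": -1, "U": 1}, "k2*V"),
             Reaction.create("R3", {"W": -1, "U": 1, "V": -1},
                             "k*W - k2*U*V/(10)")],
            validate=True,
        )

    def test_numerator_only_dependence(self):
        # eps_num = 1 at phi = 1 gives eps_phi = 1/(1+phi) = 0.5
        m = self._single_member_model()
        r = MoietyRatio("phi", "U", "V", 2.0, 1.0)
        st_ = {"U": 1.0, "V": 1.0, "W": 1.0}
        assert elasticity(m, "R1", "U", st_) == pytest.approx(1.0)
        assert ratio_elasticity(m, "R1", r, st_) == pytest.approx(0.5)

    def test_reaction_referencing_neither_member(self, moiety_model):
        r = MoietyRatio("phi", "Mp", "M", 2.0, 1.0)
        st_ = gsda.steady_state(moiety_model).concentrations
        assert ratio_elasticity(moiety_model, "R2", r, st_) == 0.0

    def test_matches_log_space_finite_difference(self, moiety_model):
        ref = gsda.steady_state(moiety_model, raise_on_failure=True)
        _, ratio = introduce_ratio(moiety_model, "Mp", "M", symbol="phi",
                                   reference=ref)
        h = 1e-6
        for rxn in ("R1", "R3"):
            for phi in (0.2, ratio.value, 3.0):
                st_ = dict(ref.concentrations)
                num, den = ratio.member_values(phi)
                st_.update({"Mp": num, "M": den})
                analytic = ratio_elasticity(moiety_model, rxn, ratio, st_)

                def rate_at(ph):
                    n, d = ratio.member_values(ph)
                    s2 = dict(st_)
                    s2.update({"Mp": n, "M": d})
                    return gsda.evaluate_rates(moiety_model, s2)[rxn]

                v0 = rate_at(phi)
                fd = (rate_at(phi * math.exp(h)) - rate_at(phi * math.exp(-h))) \
                    / (2 * h * v0)
                assert analytic == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestOracleEquivalence:
    def test_phi_quantities_equal_member_clamping(self, moiety_model):
        """Block responses over phi agree with an explicit member-clamped
        computation where the ratio elasticity is assembled by hand from the
        member elasticities."""
        ref = gsda.steady_state(moiety_model, raise_on_failure=True)
        _, ratio = introduce_ratio(moiety_model, "Mp", "M", symbol="phi",
                                   reference=ref)
        for phi in (0.1, ratio.value, 2.5):
            via_ratio = gsda.block_responses(
                set_ratio(moiety_model, ratio, phi), ratio,
                gsda.steady_state(set_ratio(moiety_model, ratio, phi),
                                  raise_on_failure=True))

            # independent route: clamp members through the generic species
            # machinery and combine member elasticities with the chain rule
            num, den = ratio.member_values(phi)
            members_clamped = moiety_model.with_species([
                Species(s.id, "clamped", {"Mp": num, "M": den}[s.id])
                if s.id in ("Mp", "M") else s for s in moiety_model.species
            ])
            ss = gsda.steady_state(members_clamped, raise_on_failure=True)
            cm = gsda.control_coefficients(members_clamped, ss)
            for bname, resp in via_ratio.items():
                manual = 0.0
                for rxn in members_clamped.reaction_ids:
                    e_num = elasticity(members_clamped, rxn, "Mp", ss.concentrations)
                    e_den = elasticity(members_clamped, rxn, "M", ss.concentrations)
                    eps_phi = e_num / (1 + phi) - e_den * phi / (1 + phi)
                    if eps_phi:
                        manual += cm.C_J(bname, rxn) * eps_phi
                assert resp.value == pytest.approx(manual, abs=1e-8)

    def test_supply_demand_orientation_follows_numerator(self, moiety_model):
        ref = gsda.steady_state(moiety_model, raise_on_failure=True)
        clamped, ratio = introduce_ratio(moiety_model, "Mp", "M", symbol="phi",
                                         reference=ref)
        blocks = {b.name: b.kind for b in gsda.partition_blocks(clamped, ratio)}
        # R3 produces Mp (the numerator) -> supply; R1 consumes it -> demand
        assert blocks == {"R3": "supply", "R1": "demand"}
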