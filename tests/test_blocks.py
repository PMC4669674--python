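"""Supply-demand partitioning, scans and block comparisons."""

import math

import numpy as np
import pytest

import gsda
from gsda.blocks import (
    BlockComparison,
    compare_block_responses,
    partition_blocks,
    rate_characteristic_scan,
)
from gsda.model import ModelDefinitionError


class TestPartition:
    def test_chain_blocks_around_central_intermediate(self, chain_model, chain_ss):
        clamped = gsda.clamp(chain_model, "P", chain_ss.concentrations["P"])
        blocks = {b.name: b for b in partition_blocks(clamped, "P", chain_ss.fluxes)}
        assert set(blocks) == {"R2", "R3"}
        assert blocks["R2"].kind == "supply"
        assert blocks["R2"].members == {"R1", "R2"}
        assert blocks["R3"].kind == "demand"
        assert blocks["R3"].members == {"R3", "R4"}

    def test_isoenzyme_model_blocks(self, iso_model):
        ss = gsda.steady_state(iso_model, raise_on_failure=True)
        clamped = gsda.clamp(iso_model, "A", ss.concentrations["A"])
        blocks = {b.name: b for b in partition_blocks(clamped, "A", ss.fluxes)}
        assert blocks["R3"].kind == "supply"
        assert blocks["R3"].members == {"R1", "R2", "R3"}
        assert blocks["R4"].kind == "demand"
        assert blocks["R4"].members == {"R4", "R5"}

    def test_species_without_adjacent_reactions_is_error(self, chain_model):
        m = chain_model.with_species(list(chain_model.species))
        with pytest.raises(ModelDefinitionError):
            partition_blocks(m, "nosuch")

    def test_allosteric_link_does_not_confer_membership(self, chain_fb_internal):
        """S2 inhibits R1 allosterically; R1 still belongs only to the supply
        side once P is clamped."""
        ss = gsda.steady_state(chain_fb_internal, raise_on_failure=True)
        clamped = gsda.clamp(chain_fb_internal, "P", ss.concentrations["P"])
        blocks = {b.name: b for b in partition_blocks(clamped, "P", ss.fluxes)}
        assert blocks["R3"].members == {"R3", "R4"}
        assert "R1" not in blocks["R3"].members


class TestScan:
    def test_reference_point_reproduces_full_model(self, chain_model, chain_ss):
        scan = rate_characteristic_scan(chain_model, "P", n_points=33)
        rec = scan.reference_record
        assert rec.value == pytest.approx(chain_ss.concentrations["P"], rel=1e-12)
        for r in chain_model.reaction_ids:
            assert rec.fluxes[r] == pytest.approx(chain_ss.fluxes[r], rel=1e-6)

    def test_grid_contains_reference_exactly(self, chain_model, chain_ss):
        scan = rate_characteristic_scan(chain_model, "P", n_points=16)
        assert chain_ss.concentrations["P"] in scan.grid

    def test_partial_sum_identity_every_converged_point(self, chain_fb_internal):
        scan = rate_characteristic_scan(chain_fb_internal, "P", n_points=21)
        checked = 0
        for rec in scan.records:
            if not rec.converged:
                continue
            for resp in rec.responses.values():
                if math.isnan(resp.value):
                    continue
                assert resp.value == pytest.approx(
                    sum(resp.decomposition.values()), rel=1e-6, abs=1e-12)
                checked += 1
        assert checked > 30

    def test_supply_falls_demand_rises_with_clamp_value(self, chain_model):
        scan = rate_characteristic_scan(chain_model, "P", n_points=25)
        sup = scan.block_flux_curve("R2")
        dem = scan.block_flux_curve("R3")
        assert np.all(np.diff(sup) < 0)
        assert np.all(np.diff(dem) > 0)

    def test_curves_intersect_at_reference(self, chain_model):
        scan = rate_characteristic_scan(chain_model, "P", n_points=25)
        rec = scan.reference_record
        assert rec.block_flux(scan.blocks[0]) == pytest.approx(
            rec.block_flux(scan.blocks[1]), rel=1e-9)

    def test_feedback_steepens_supply_response(self, chain_model,
                                               chain_fb_product,
                                               chain_fb_internal):
        """Allosteric feedback on enzyme 1 makes the supply block respond
        more negatively to the clamped intermediate at the same clamp value."""
        at = 1.0
        values = {}
        for name, m in [("none", chain_model), ("product", chain_fb_product),
                        ("internal", chain_fb_internal)]:
            clamped = gsda.clamp(m, "P", at)
            ss = gsda.steady_state(clamped, raise_on_failure=True)
            resp = gsda.block_responses(clamped, "P", ss)
            values[name] = resp["R2"].value
        assert values["product"] < values["none"]
        assert values["internal"] < values["none"]

    def test_internal_feedback_creates_partial_via_demand_reaction(
            self, chain_model, chain_fb_internal):
        def supply_partials(m):
            ss = gsda.steady_state(m, raise_on_failure=True)
            clamped = gsda.clamp(m, "P", ss.concentrations["P"])
            css = gsda.steady_state(clamped, raise_on_failure=True)
            return gsda.block_responses(clamped, "P", css)["R2"].decomposition

    # without feedback the R3 term is structurally absent or zero
        assert supply_partials(chain_model).get("R3", 0.0) == 0.0
        assert supply_partials(chain_fb_internal)["R3"] < 0

    def test_nonconverged_points_flagged_not_dropped(self, chain_model):
        scan = rate_characteristic_scan(chain_model, "P", n_points=12)
        assert len(scan.records) == len(scan.grid)
        assert all(r.converged in (True, False) for r in scan.records)


class TestCompare:
    def test_equal_and_opposite_gives_unit_ratio(self):
        c = BlockComparison(supply_response=-0.7, demand_response=0.7)
        assert c.flux_control_ratio == pytest.approx(1.0)
        assert c.homeostasis_index == pytest.approx(1.4)

    def test_zero_demand_response_reported_infinite(self):
        c = BlockComparison(supply_response=-0.5, demand_response=0.0)
        assert math.isinf(c.flux_control_ratio)

    def test_aggregate_is_flux_weighted(self, iso_model):
        ss = gsda.steady_state(iso_model, raise_on_failure=True)
        clamped = gsda.clamp(iso_model, "B", ss.concentrations["B"])
        css = gsda.steady_state(clamped, raise_on_failure=True)
        blocks = partition_blocks(clamped, "B", css.fluxes)
        responses = gsda.block_responses(clamped, "B", css, blocks=blocks)
        out = compare_block_responses(blocks, responses, css.fluxes)
        sup = [b for b in blocks if b.kind == "supply"]
        J = sum(css.fluxes[b.adjacent_reaction] for b in sup)
        expected = sum(css.fluxes[b.adjacent_reaction] / J * responses[b.name].value
                       for b in sup)
        assert out["aggregate"].supply_response == pytest.approx(expected, rel=1e-12)

    def test_scan_level_comparison(self, chain_model):
        scan = rate_characteristic_scan(chain_model, "P", n_points=15)
        out = gsda.compare_blocks(scan)
        assert ("R2", "R3") in out
        assert out[("R2", "R3")].supply_response < 0
        assert out[("R2", "R3")].demand_response > 0
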