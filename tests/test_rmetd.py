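"""The expression-integration contract: direction mapping, floors, scaling.

Hand-solved reference for the epithelium fixture (fatty-acid uptake 5,
three per lipid particle): chylomicron and HDL maxima are both 5/3, so the
20% floors pin each secretion at 1/3; the lipid-assembly range under both
floors is [2/3, 5/3]; down-scaling it by 20% caps assembly at 4/3, leaving
1.0 for chylomicrons after the HDL floor — versus 4/3 in the reference.
"""

import numpy as np
import pytest

from gutflux import lp_engine as lp
from gutflux import rmetd
from gutflux.synthetic_data import EPITHELIUM_DIET


def de_table(*entries):
    return rmetd.DETable(entries=[rmetd.DEGene(*e) for e in entries])


@pytest.fixture
def config():
    return rmetd.RMetDConfig(objective_products=["EX_chylo", "EX_hdl"])


class TestDirectionMapping:
    def test_concordant_up_via_isoenzymes(self, epithelium_model):
        m = epithelium_model.copy()
        m.reactions["TAG_SYN"].gpr = "g1 or g2"
        dmap = rmetd.map_de_to_reactions(
            m, de_table(("g1", "up", 0.01), ("g2", "up", 0.02)))
        assert dmap.calls["TAG_SYN"].direction == "up"
        assert dmap.calls["TAG_SYN"].reason == "all-concordant"

    def test_mixed_directions_become_unchanged(self, epithelium_model):
        """Disagreeing significant genes neutralize the reaction call."""
        dmap = rmetd.map_de_to_reactions(
            epithelium_model,
            de_table(("g_gclc", "up", 0.01), ("g_gclm", "down", 0.01)))
        assert dmap.calls["GCL"].direction == "unchanged"
        assert dmap.calls["GCL"].reason == "mixed-directions"

    def test_insignificant_gene_leaves_reaction_unmapped(self, epithelium_model):
        dmap = rmetd.map_de_to_reactions(
            epithelium_model, de_table(("g_dgat", "up", 0.20)), q_threshold=0.05)
        assert "TAG_SYN" not in dmap

    def test_unknown_genes_counted_not_raised(self, epithelium_model):
        dmap = rmetd.map_de_to_reactions(
            epithelium_model,
            de_table(("g_nowhere", "up", 0.01), ("g_dgat", "down", 0.01)))
        assert dmap.coverage["de_genes_ignored"] == 1
        assert dmap.coverage["de_genes_in_model"] == 1


class TestScaling:
    @pytest.mark.parametrize("lo,hi,direction,alpha,expected", [
        (2.0, 4.0, "up", 0.2, (2.4, 4.8)),
        (2.0, 4.0, "down", 0.2, (1.6, 3.2)),
        (2.0, 4.0, "unchanged", 0.2, (2.0, 4.0)),
        (-5.0, 10.0, "up", 0.2, (-6.0, 12.0)),
        (-5.0, 10.0, "down", 0.2, (-4.0, 8.0)),
    ])
    def test_multiplicative_bound_push(self, lo, hi, direction, alpha, expected):
        assert rmetd.scale_range(lo, hi, direction, alpha) == pytest.approx(expected)

    def test_scaling_preserves_ordering(self):
        for lo, hi in [(-3, -1), (-1, 2), (0, 5)]:
            for d in ("up", "down"):
                slo, shi = rmetd.scale_range(lo, hi, d, 0.3)
                assert slo <= shi


class TestRunRmetd:
    def test_product_floor_is_20pct_of_maximum(self, epithelium_model, config):
        result = rmetd.run_rmetd(epithelium_model, rmetd.DETable(),
                                 EPITHELIUM_DIET, config)
        assert result.product_maxima["EX_chylo"] == pytest.approx(5 / 3, abs=1e-6)
        assert result.reference_model.reactions["EX_hdl"].lower_bound == \
            pytest.approx(0.2 * 5 / 3, abs=1e-6)
        assert result.condition_model.reactions["EX_chylo"].lower_bound == \
            pytest.approx(0.2 * 5 / 3, abs=1e-6)

    def test_empty_de_identity(self, epithelium_model, config):
        result = rmetd.run_rmetd(epithelium_model, rmetd.DETable(),
                                 EPITHELIUM_DIET, config)
        assert result.feasible
        assert result.reference_solution.objective_value == pytest.approx(
            result.condition_solution.objective_value, abs=1e-6)
        for comp in result.product_comparison:
            assert comp.ratio == pytest.approx(1.0, abs=1e-6)

    def test_condition_bounds_are_scaled_reference_fva(self, epithelium_model,
                                                       config):
        de = de_table(("g_dgat", "down", 0.01))
        result = rmetd.run_rmetd(epithelium_model, de, EPITHELIUM_DIET, config)
        lo, hi = result.reference_bounds["TAG_SYN"]
        assert (lo, hi) == pytest.approx((2 / 3, 5 / 3), abs=1e-6)
        assert result.condition_bounds["TAG_SYN"] == pytest.approx(
            (0.8 * lo, 0.8 * hi), abs=1e-6)

    def test_downregulated_lipid_chain_lowers_chylomicron(self, epithelium_model,
                                                          config, lp_oracle):
        """Direction must match the hand-solved instance (1.0 vs 4/3)."""
        de = de_table(("g_dgat", "down", 0.01))
        result = rmetd.run_rmetd(epithelium_model, de, EPITHELIUM_DIET, config)
        chylo = result.product_comparison[0]
        assert chylo.reference_flux == pytest.approx(4 / 3, abs=1e-6)
        assert chylo.condition_flux == pytest.approx(1.0, abs=1e-6)
        assert chylo.condition_flux < chylo.reference_flux
        # cross-check the condition optimum against the brute LP oracle
        expected, _ = lp_oracle["fba"](
            result.condition_model, "EX_chylo", "max")
        assert abs(result.condition_solution.objective_value - expected) < 1e-6

    def test_all_down_never_raises_product_maximum(self, epithelium_model,
                                                   config, lp_oracle):
        de = de_table(("g_dgat", "down", 0.01), ("g_mttp", "down", 0.01),
                      ("g_gclc", "down", 0.01), ("g_gclm", "down", 0.01),
                      ("g_gss", "down", 0.01), ("g_abca1", "down", 0.01))
        result = rmetd.run_rmetd(epithelium_model, de, EPITHELIUM_DIET, config)
        ref_max, _ = lp_oracle["fba"](result.reference_model, "EX_chylo", "max")
        cond_max, _ = lp_oracle["fba"](result.condition_model, "EX_chylo", "max")
        assert cond_max <= ref_max + 1e-6

    def test_monotone_floor_total_flux(self, epithelium_model):
        """A larger forced secretion cannot shrink the parsimonious total."""
        sums = []
        for frac in (0.1, 0.2, 0.4):
            cfg = rmetd.RMetDConfig(objective_products=["EX_chylo", "EX_hdl"],
                                    product_floor_fraction=frac)
            result = rmetd.run_rmetd(epithelium_model, rmetd.DETable(),
                                     EPITHELIUM_DIET, cfg)
            sums.append(sum(abs(v) for v in
                            result.reference_solution.fluxes.values()))
        assert sums[0] <= sums[1] + 1e-6 <= sums[2] + 2e-6

    def test_infeasible_conflict_diagnosed_not_relaxed(self, epithelium_model,
                                                       config):
        """A floor above what the scaled bounds allow must surface in the
        elastic diagnostics instead of being silently repaired."""
        m = epithelium_model.copy()
        m.reactions["EX_chylo"].lower_bound = 1.5   # near the 5/3 maximum
        de = de_table(("g_dgat", "down", 0.01))
        result = rmetd.run_rmetd(m, de, EPITHELIUM_DIET, config)
        assert not result.condition_solution.ok
        diag = result.diagnostics["condition"]
        assert diag["elastic_status"] == "optimal"
        assert "TAG_SYN" in diag["violated_bounds"]


class TestSensitivityScan:
    def test_direction_stable_across_alphas(self, epithelium_model, config):
        de = de_table(("g_dgat", "down", 0.01))
        table = rmetd.sensitivity_scan(epithelium_model, de, EPITHELIUM_DIET,
                                       config, [0.1, 0.2, 0.3])
        assert table.attrs["stable"]
        chylo = table[table["product"] == "EX_chylo"]
        assert (chylo.condition_flux < chylo.reference_flux).all()

    def test_singleton_scan_matches_single_run(self, epithelium_model, config):
        de = de_table(("g_dgat", "down", 0.01))
        table = rmetd.sensitivity_scan(epithelium_model, de, EPITHELIUM_DIET,
                                       config, [0.2])
        single = rmetd.run_rmetd(epithelium_model, de, EPITHELIUM_DIET, config)
        for comp in single.product_comparison:
            row = table[table["product"] == comp.product].iloc[0]
            assert row.condition_flux == pytest.approx(comp.condition_flux,
                                                       abs=1e-9)

    def test_empty_de_all_ratios_one(self, epithelium_model, config):
        table = rmetd.sensitivity_scan(epithelium_model, rmetd.DETable(),
                                       EPITHELIUM_DIET, config, [0.1, 0.2, 0.3])
        assert np.allclose(table.ratio, 1.0, atol=1e-6)


class TestInputValidation:
    def test_inconsistent_direction_fold_change(self):
        with pytest.raises(ValueError, match="inconsistent"):
            rmetd.DEGene("g1", "up", 0.01, log2fc=-2.0)

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            de_table(("g1", "up", 0.01), ("g1", "down", 0.02))

    def test_alpha_outside_unit_interval(self):
        with pytest.raises(ValueError):
            rmetd.RMetDConfig(alpha=1.0, objective_products=["EX_P"])

    def test_de_tsv_round_trip(self, tmp_path):
        de = de_table(("g1", "up", 0.01, 2.0), ("g2", "down", 0.5, -0.1))
        path = tmp_path / "de.tsv"
        de.to_tsv(str(path))
        back = rmetd.DETable.from_tsv(str(path))
        assert [(e.gene_id, e.direction, e.q_value) for e in back] == \
            [(e.gene_id, e.direction, e.q_value) for e in de]
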