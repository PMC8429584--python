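import numpy as np
import pytest
from scipy.integrate import quad

from soccf.characterization import (ImpactValue, background_initial_impact,
                                    characterize_region, occupation_cf,
                                    regeneration_impact, select_pnv,
                                    transformation_cf_background,
                                    transformation_cf_foreground)
from soccf.exceptions import ConfigurationError
from soccf.soc_curves import SOCCurve


def _exp_curve(asoc=100.0, d0=40.0, k=0.05, years=300, lu_from="x"):
    t = np.arange(12 * years + 1) / 12.0
    soc = asoc - d0 * np.exp(-k * t)
    return SOCCurve(times=t, soc=soc, asoc=asoc, k=k, t_reg=None,
                    lu_from=lu_from)


class TestOccupation:
    @pytest.mark.parametrize("pnv,lu2,expected", [
        (120.0, 80.0, 40.0), (80.0, 120.0, -40.0), (90.0, 90.0, 0.0)])
    def test_difference_and_sign_convention(self, pnv, lu2, expected):
        assert occupation_cf(pnv, lu2) == expected

    def test_negative_stock_rejected(self):
        with pytest.raises(ValueError):
            occupation_cf(-1.0, 10.0)


class TestPNVSelection:
    def test_argmax_over_forest_and_grassland(self, world6):
        region = world6.regions[0]
        asoc = {cid: 10.0 for cid in region.feasible_classes}
        grass_or_forest = [cid for cid in region.feasible_classes
                           if world6.registry[cid].category in
                           ("forest", "grassland")]
        asoc[grass_or_forest[0]] = 99.0
        asoc["urban"] = 500.0  # not a PNV candidate, must be ignored
        pnv = select_pnv(region, world6.registry, asoc_by_class=asoc)
        assert pnv.pnv_class_id == grass_or_forest[0]
        assert pnv.asoc_pnv == 99.0

    def test_tie_breaks_lexicographically(self, world25):
        region = next(r for r in world25.regions
                      if sum(c.startswith("forest")
                             for c in r.feasible_classes) >= 2)
        forests = sorted(c for c in region.feasible_classes
                         if c.startswith("forest"))
        asoc = {cid: 50.0 for cid in region.feasible_classes}
        pnv = select_pnv(region, world25.registry, asoc_by_class=asoc)
        candidates = sorted(c for c in region.feasible_classes
                            if world25.registry[c].category in
                            ("forest", "grassland"))
        assert pnv.pnv_class_id == candidates[0]
        assert forests[0] in candidates

    def test_no_candidate_is_configuration_error(self, world6):
        region = world6.regions[0].replace(
            feasible_classes=("urban", "crop_wheat_rainfed_left"))
        with pytest.raises(ConfigurationError):
            select_pnv(region, world6.registry)


class TestRegenerationImpact:
    def test_constant_curve_is_zero(self):
        t = np.arange(25) / 12.0
        curve = SOCCurve(times=t, soc=np.full(25, 100.0), asoc=100.0, k=None,
                         t_reg=0.0)
        assert regeneration_impact(curve, 100.0).value == pytest.approx(0.0,
                                                                        abs=1e-9)

    def test_pure_exponential_closed_form(self):
        """Deficit 40 t C/ha decaying at 0.05/yr accumulates 40/0.05 = 800
        t C·yr/ha; cross-checked against adaptive quadrature."""
        curve = _exp_curve()
        impact = regeneration_impact(curve, 100.0)
        assert impact.value == pytest.approx(800.0, rel=1e-5)
        oracle, _ = quad(lambda t: 40.0 * np.exp(-0.05 * t), 0, np.inf)
        assert impact.value == pytest.approx(oracle, rel=1e-5)

    def test_piecewise_matches_fine_quadrature(self, world6):
        """The simulated-window trapezoid plus analytic tail agrees with a
        dense quadrature of the same sampled curve plus the same tail."""
        from soccf.soc_curves import simulate_transition
        region = world6.regions[1]
        rc = characterize_region(region, world6.registry)
        curve = simulate_transition(region, "urban", rc.pnv.pnv_class_id,
                                    world6.registry)
        impact = regeneration_impact(curve, rc.pnv.asoc_pnv)
        dense = np.trapezoid(rc.pnv.asoc_pnv - curve.soc, curve.times)
        assert impact.simulated == pytest.approx(dense, rel=1e-9)
        assert impact.value == pytest.approx(dense + impact.tail, rel=1e-12)

    def test_mismatched_pnv_rejected(self):
        curve = _exp_curve(asoc=90.0)
        with pytest.raises(ValueError):
            regeneration_impact(curve, 100.0)

    def test_missing_rate_with_residual_deficit_rejected(self):
        curve = _exp_curve(years=3)
        curve.k = None
        with pytest.raises(ValueError):
            regeneration_impact(curve, 100.0)


class TestTransformationForeground:
    def test_same_class_is_zero(self):
        imp = ImpactValue(value=500.0, simulated=400.0, tail=100.0,
                          asoc_pnv=100.0)
        assert transformation_cf_foreground(imp, imp) == 0.0

    def test_pnv_to_class_equals_class_impact(self):
        imp_pnv = ImpactValue(value=0.0, simulated=0.0, tail=0.0,
                              asoc_pnv=100.0)
        imp_lu = ImpactValue(value=800.0, simulated=700.0, tail=100.0,
                             asoc_pnv=100.0)
        assert transformation_cf_foreground(imp_pnv, imp_lu) == 800.0

    def test_antisymmetry_is_exact(self, world6):
        rc = characterize_region(world6.regions[2], world6.registry)
        for lu1 in rc.class_ids:
            for lu2 in rc.class_ids:
                assert (rc.transformation(lu1, lu2)
                        + rc.transformation(lu2, lu1)) == 0.0

    def test_different_pnv_references_rejected(self):
        a = ImpactValue(value=1.0, simulated=1.0, tail=0.0, asoc_pnv=100.0)
        b = ImpactValue(value=1.0, simulated=1.0, tail=0.0, asoc_pnv=90.0)
        with pytest.raises(ValueError):
            transformation_cf_foreground(a, b)


class TestTransformationBackground:
    @staticmethod
    def _impacts(region, values):
        return {cid: ImpactValue(value=v, simulated=v, tail=0.0,
                                 asoc_pnv=100.0, class_id=cid)
                for cid, v in values.items()}

    def test_share_weighted_average(self, world6):
        """50 % cropland / 50 % forestry: the unknown-origin impact is the
        plain mean of the two category means, recomputed by hand."""
        registry = world6.registry
        region = world6.regions[2]
        crops = [c for c in region.feasible_classes
                 if registry[c].category == "cropland"]
        forests = [c for c in region.feasible_classes
                   if registry[c].category == "forest"]
        if not forests:
            pytest.skip("region draw has no feasible forest")
        values = {cid: float(10 * (i + 1))
                  for i, cid in enumerate(region.feasible_classes)}
        impacts = self._impacts(region, values)
        region = region.replace(lu_shares=dict(cropland=0.5, forestry=0.5,
                                               grazing=0.0, urban=0.0))
        expected = 0.5 * np.mean([values[c] for c in crops]) + \
            0.5 * np.mean([values[c] for c in forests])
        assert background_initial_impact(region, registry, impacts) == \
            pytest.approx(expected, rel=1e-12)

    def test_degenerate_single_category_matches_foreground(self, world6,
                                                          grass_region):
        """A region that is 100 % grazing with one grassland class gives the
        same CF as the foreground transformation from that class."""
        registry = world6.registry
        region = grass_region.replace(
            lu_shares=dict(cropland=0.0, forestry=0.0, grazing=1.0,
                           urban=0.0))
        values = {cid: float(7 * (i + 1))
                  for i, cid in enumerate(region.feasible_classes)}
        impacts = self._impacts(region, values)
        lu_to = region.feasible_classes[0]
        cf_bg = transformation_cf_background(region, lu_to, impacts, registry)
        cf_fg = transformation_cf_foreground(impacts["grassland"],
                                             impacts[lu_to])
        assert cf_bg == pytest.approx(cf_fg, rel=1e-12)

    def test_all_zero_shares_rejected(self, world6):
        region = world6.regions[0].replace(
            lu_shares=dict(cropland=0.0, forestry=0.0, grazing=0.0,
                           urban=0.0))
        values = {cid: 1.0 for cid in region.feasible_classes}
        with pytest.raises(ConfigurationError):
            background_initial_impact(region, world6.registry,
                                      self._impacts(region, values))

    def test_bounded_by_foreground_extremes(self, world6):
        """The background CF to a class is a convex combination of the
        foreground CFs into it, hence lies between their extremes."""
        registry = world6.registry
        rc = characterize_region(world6.regions[1], registry)
        region = world6.regions[1]
        for lu_to in rc.class_ids:
            cf_bg = transformation_cf_background(region, lu_to, rc.impacts,
                                                 registry)
            fg = [rc.transformation(lu1, lu_to) for lu1 in rc.class_ids]
            assert min(fg) - 1e-9 <= cf_bg <= max(fg) + 1e-9
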