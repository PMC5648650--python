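"""Heating, power, current division, and liana protection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import treestrike as ts
from treestrike.errors import CalibrationError, InvalidInputError


class TestScalarFormulas:
    def test_heating_is_bilinear_and_zero_at_zero(self):
        assert ts.heating(2.0e6, 0.0) == 0.0
        assert ts.heating(2.0e6, 1.5e4) == pytest.approx(3.0e10)
        assert ts.heating(4.0e6, 1.5e4) == pytest.approx(2 * ts.heating(2.0e6, 1.5e4))

    def test_max_power_is_quadratic_in_current(self):
        assert ts.max_power(1e6, 0.0) == 0.0
        assert ts.max_power(1e6, 3e4) == pytest.approx(9e14)
        assert ts.max_power(1e6, 6e4) == pytest.approx(4 * ts.max_power(1e6, 3e4))

    def test_heating_density_unit_conversion(self):
        # 1 GJ over 1 m^3 is 1 kJ/cm^3
        assert ts.heating_density(1e9, 1.0) == pytest.approx(1e3)
        assert ts.heating_density(0.0, 0.5) == 0.0
        with pytest.raises(InvalidInputError):
            ts.heating_density(1.0, 0.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            ts.heating(-1.0, 1.0)
        with pytest.raises(InvalidInputError):
            ts.max_power(1.0, -1.0)


class TestParallelAndDivider:
    def test_parallel_resistance_identities(self):
        assert ts.parallel_resistance([7.0]) == pytest.approx(7.0)
        assert ts.parallel_resistance([5.0, 5.0, 5.0]) == pytest.approx(5.0 / 3)
        assert ts.parallel_resistance([2.0, 2.0]) == pytest.approx(1.0)
        with pytest.raises(InvalidInputError):
            ts.parallel_resistance([])
        with pytest.raises(InvalidInputError):
            ts.parallel_resistance([1.0, -2.0])

    def test_symmetric_divider_splits_evenly(self):
        assert ts.tree_current_fraction(1e6, 1e6) == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        f = ts.tree_current_fraction(1.3e6, 2.9e6)
        assert f + (1 - f) == pytest.approx(1.0)
        assert 0 < f < 1

    @given(r_tree=st.floats(1e3, 1e8), r_liana=st.floats(1e3, 1e8))
    def test_divider_in_open_interval_and_monotone(self, r_tree, r_liana):
        f = ts.tree_current_fraction(r_tree, r_liana)
        assert 0 < f < 1
        # a more resistive liana bundle leaves more current in the tree
        assert ts.tree_current_fraction(r_tree, r_liana * 2) > f

    def test_infinite_liana_resistance_limit(self):
        assert ts.tree_current_fraction(1e6, 1e15) == pytest.approx(1.0, abs=1e-8)


class TestLianaCalibration:
    def test_regional_resistances_match_inversion_oracle(self, liana_calibration):
        # frozen from inverting the published one-liana reductions with
        # this package's computed 20 m tree resistances
        assert liana_calibration["tropical"] == pytest.approx(2.98e6, rel=0.01)
        assert liana_calibration["temperate"] == pytest.approx(3.98e6, rel=0.01)

    def test_override_wins(self, liana_calibration):
        spec = ts.LianaSpec(host_height=20.0, resistance_override=1e6)
        assert ts.liana_resistance(spec, liana_calibration) == 1e6

    def test_resistance_scales_linearly_with_length(self, liana_calibration):
        short = ts.LianaSpec(host_height=20.0, region="tropical")
        tall = ts.LianaSpec(host_height=40.0, region="tropical")
        assert short.length == pytest.approx(25.0)
        assert ts.liana_resistance(tall, liana_calibration) == pytest.approx(
            2 * ts.liana_resistance(short, liana_calibration)
        )

    def test_unknown_region_without_override_rejected(self):
        spec = ts.LianaSpec(host_height=20.0, region="boreal")
        with pytest.raises(CalibrationError):
            ts.liana_resistance(spec, {"tropical": 3e6})

    def test_liana_must_outreach_host(self):
        with pytest.raises(InvalidInputError):
            ts.LianaSpec(host_height=20.0, length=18.0)


class TestStrikeComplex:
    def test_liana_free_tree_takes_everything(self, models, constants):
        rep = ts.strike_complex(
            ts.build_complex(models["Jacaranda copaia"]), constants
        )
        assert rep.tree.current_fraction == 1.0
        assert rep.percent_diverted == 0.0
        assert rep.tree.heating == pytest.approx(
            constants.action_integral_d1 * rep.tree.resistance
        )

    def test_current_fractions_sum_to_one(self, models, constants, liana_calibration):
        rep = ts.strike_complex(
            ts.build_complex(models["Alseis blackiana"], n_lianas=3),
            constants,
            liana_calibration=liana_calibration,
        )
        total = sum(c.current_fraction for c in rep.conductors)
        assert total == pytest.approx(1.0)

    def test_heating_and_power_reduced_by_identical_factor(
        self, models, constants, liana_calibration
    ):
        bare = ts.strike_complex(ts.build_complex(models["Quercus rubra"]), constants)
        laden = ts.strike_complex(
            ts.build_complex(models["Quercus rubra"], n_lianas=2),
            constants,
            liana_calibration=liana_calibration,
        )
        heat_factor = laden.tree.heating / bare.tree.heating
        power_factor = laden.tree.max_power / bare.tree.max_power
        assert heat_factor == pytest.approx(power_factor, rel=1e-12)
        assert heat_factor == pytest.approx(laden.tree.current_fraction**2, rel=1e-12)

    def test_protection_grows_with_liana_count_and_conductivity(
        self, models, constants, liana_calibration
    ):
        jac = models["Jacaranda copaia"]
        pcts = [
            ts.strike_complex(
                ts.build_complex(jac, n_lianas=n),
                constants,
                liana_calibration=liana_calibration,
            ).percent_diverted
            for n in (1, 2, 3, 5)
        ]
        assert all(b > a for a, b in zip(pcts, pcts[1:]))
        better_liana = ts.strike_complex(
            ts.build_complex(jac, n_lianas=1, liana_resistance_override=1e6),
            constants,
        )
        worse_liana = ts.strike_complex(
            ts.build_complex(jac, n_lianas=1, liana_resistance_override=5e6),
            constants,
        )
        assert better_liana.percent_diverted > worse_liana.percent_diverted

    def test_more_resistant_trees_gain_more_protection(
        self, models, constants, liana_calibration
    ):
        reports = {
            name: ts.strike_complex(
                ts.build_complex(model, n_lianas=1),
                constants,
                liana_calibration=liana_calibration,
            )
            for name, model in models.items()
        }
        # the liana resistance is shared within a region, so percent diverted
        # must be strictly ordered by tree resistance within each region
        for region in ("tropical", "temperate"):
            names = [n for n in reports if models[n].region == region]
            by_resistance = sorted(names, key=lambda n: reports[n].tree.resistance)
            diverted = [reports[n].percent_diverted for n in by_resistance]
            assert all(b > a for a, b in zip(diverted, diverted[1:]))


class TestProtectionSummary:
    def test_single_species_has_zero_spread(self, models, constants, liana_calibration):
        s = ts.protection_summary(
            [models["Tsuga canadensis"]], constants, liana_calibration=liana_calibration
        )
        assert s.sd_percent == 0.0

    def test_empty_species_list_rejected(self, constants):
        with pytest.raises(InvalidInputError):
            ts.protection_summary([], constants)
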