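"""Screening: rate scaling, equivalent rates, solubility flag, KD*, batches."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import runoffscreen as rs
from runoffscreen.screening import (
    LabelUsePattern,
    decay_fraction,
    ei_from_relationship,
    kd_star,
    max_rate_eq,
    rate_eq_series,
    sol_check,
)


@pytest.fixture(scope="module")
def cotton_dissolved():
    return rs.shipped_relationship("cotton", "dissolved")


class TestEiFromRelationship:
    def test_base_rate_returns_ei_base(self, cotton_dissolved):
        ei = ei_from_relationship(cotton_dissolved, 226.01, 1000.0, 0.1)
        expected = math.exp(cotton_dissolved.b1
                            + cotton_dissolved.b2 * math.log(226.01)
                            + cotton_dissolved.b3 * math.log(1000.0))
        assert ei == pytest.approx(expected, rel=1e-12)

    def test_linear_in_rate(self, cotton_dissolved):
        e1 = ei_from_relationship(cotton_dissolved, 50.0, 500.0, 1.0)
        e2 = ei_from_relationship(cotton_dissolved, 50.0, 500.0, 2.0)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_published_cotton_value(self, cotton_dissolved):
        """KOC=100 clamps to lnKOC*=5.5:
        EI = exp(6.3173 + 0.1467 ln 226.01 - 0.7662*5.5), hand-evaluated."""
        ei = ei_from_relationship(cotton_dissolved, 226.01, 100.0, 0.1)
        assert ei == pytest.approx(18.145071395907912, rel=1e-9)

    def test_continuous_across_breakpoint(self, cotton_dissolved):
        koc_star = math.exp(cotton_dissolved.ln_koc_star)
        below = ei_from_relationship(cotton_dissolved, 30.0,
                                     koc_star * (1 - 1e-9), 0.1)
        above = ei_from_relationship(cotton_dissolved, 30.0,
                                     koc_star * (1 + 1e-9), 0.1)
        assert below == pytest.approx(above, rel=1e-6)
        assert abs(below - above) / below < 1e-6

    def test_constant_below_decreasing_above(self, cotton_dissolved):
        koc_star = cotton_dissolved.koc_star
        low = [ei_from_relationship(cotton_dissolved, 30.0, k, 0.1)
               for k in (koc_star / 100, koc_star / 10, koc_star)]
        assert low[0] == pytest.approx(low[2], rel=1e-12)
        high = [ei_from_relationship(cotton_dissolved, 30.0, k, 0.1)
                for k in np.geomspace(koc_star, koc_star * 1e3, 6)]
        assert np.all(np.diff(high) < 0)

    def test_invalid_inputs_rejected(self, cotton_dissolved):
        with pytest.raises(ValueError):
            ei_from_relationship(cotton_dissolved, -1.0, 100.0, 0.1)


class TestEquivalentRate:
    def test_single_application_identity(self):
        assert rate_eq_series([(0, 2.24)], fd_days=7.0, t=0) == 2.24

    def test_no_decay_limit_is_cumulative(self):
        sched = [(0, 1.0), (7, 2.0), (14, 3.0)]
        assert rate_eq_series(sched, math.inf, 14) == 6.0
        assert rate_eq_series(sched, math.inf, 7) == 3.0

    def test_before_first_application_is_zero(self):
        assert rate_eq_series([(10, 1.0)], 7.0, 3) == 0.0

    def test_carbaryl_pattern_geometric_series(self):
        """4 x 2.24 kg/ha at 7-day intervals, FD=7: each prior application
        halves once per interval -> 2.24 * (1 + 1/2 + 1/4 + 1/8) = 4.20."""
        sched = [(7 * m, 2.24) for m in range(4)]
        assert rate_eq_series(sched, 7.0, 21) == pytest.approx(4.20)
        pattern = LabelUsePattern(single_rate_kg_per_ha=2.24,
                                  interval_days=7, max_applications=4,
                                  fd_days=7.0)
        assert max_rate_eq(pattern) == pytest.approx(4.20)

    def test_accepts_calendar_dates(self):
        sched = [(pd.Timestamp("2001-06-01") + pd.Timedelta(days=7 * m), 2.24)
                 for m in range(4)]
        got = rate_eq_series(sched, 7.0, pd.Timestamp("2001-06-22"))
        assert got == pytest.approx(4.20)

    def test_single_application_pattern(self):
        assert max_rate_eq(LabelUsePattern(2.24)) == 2.24

    def test_no_decay_limit_pattern(self):
        pattern = LabelUsePattern(2.24, interval_days=7, max_applications=4,
                                  fd_days=math.inf)
        assert max_rate_eq(pattern) == pytest.approx(8.96)

    @given(rate=st.floats(0.01, 10.0), interval=st.integers(1, 30),
           m=st.integers(1, 8), fd=st.floats(0.5, 200.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_closed_form_equals_convolution_and_sandwich(self, rate, interval,
                                                         m, fd):
        """Closed-form maximum == convolution at the last application,
        and RATE <= max_rate_eq <= M*RATE."""
        pattern = LabelUsePattern(rate, interval_days=interval,
                                  max_applications=m, fd_days=fd)
        closed = max_rate_eq(pattern)
        sched = [(interval * j, rate) for j in range(m)]
        conv = rate_eq_series(sched, fd, interval * (m - 1))
        assert closed == pytest.approx(conv, rel=1e-12)
        assert rate - 1e-12 <= closed <= m * rate + 1e-9

    def test_invalid_patterns_rejected(self):
        with pytest.raises(ValueError):
            LabelUsePattern(0.0)
        with pytest.raises(ValueError):
            LabelUsePattern(1.0, interval_days=0, max_applications=3)
        with pytest.raises(ValueError):
            decay_fraction(1.0, 0.0)


class TestSolCheck:
    @pytest.mark.parametrize("ei, sol, expected", [
        (50.0, 1.0, False),
        (2000.0, 1.0, True),
        (1000.0, 1.0, False),   # boundary: strict inequality
    ])
    def test_flag(self, ei, sol, expected):
        assert sol_check(ei, sol) is expected

    def test_absent_solubility_gives_none(self):
        assert sol_check(50.0, None) is None


class TestKdStar:
    def test_alfalfa_dissolved_in_published_band(self):
        rel = rs.shipped_relationship("alfalfa", "dissolved")
        scen = rs.get_scenario("alfalfa")
        value = kd_star(rel, scen)
        assert value == pytest.approx(math.exp(3.5) * 0.0177, rel=1e-12)
        assert 0.5 <= value <= 0.7

    def test_cotton_adsorbed_in_published_band(self):
        rel = rs.shipped_relationship("cotton", "adsorbed")
        scen = rs.get_scenario("cotton")
        value = kd_star(rel, scen)
        assert value == pytest.approx(math.exp(11.0) * 0.0029, rel=1e-12)
        assert 160 <= value <= 240

    def test_linear_in_oc1(self):
        rel = rs.shipped_relationship("cotton", "adsorbed")
        scen = rs.get_scenario("cotton")
        halved = dataclasses.replace(scen, oc1=scen.oc1 / 2)
        assert kd_star(rel, halved) == pytest.approx(kd_star(rel, scen) / 2)


class TestScreenBatch:
    def chems(self, rows):
        df = pd.DataFrame(rows)
        for col in rs.chem.CHEMICAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        return df

    def test_empty_input_gives_empty_table_with_headers(self):
        out = rs.screen_batch(self.chems([]), rs.load_scenarios())
        assert len(out) == 0
        assert {"chemical", "scenario", "phase", "ei"} <= set(out.columns)

    def test_rows_reproducible_from_single_relationship_calls(self):
        chems = self.chems([dict(name="x", aero_days=30.0, koc=400.0,
                                 rate_kg_per_ha=1.5)])
        out = rs.screen_batch(chems, rs.load_scenarios(),
                              phases=("dissolved",))
        assert len(out) == 8
        for _, row in out.iterrows():
            rel = rs.shipped_relationship(row["scenario"], "dissolved")
            assert row["ei"] == pytest.approx(
                float(ei_from_relationship(rel, 30.0, 400.0, 1.5)), rel=1e-12)

    def test_multiple_applications_use_equivalent_rate(self):
        chems = self.chems([dict(name="multi", aero_days=30.0, koc=400.0,
                                 rate_kg_per_ha=2.24, interval_days=7,
                                 max_applications=4, fd_days=7.0)])
        out = rs.screen_batch(chems, {"cotton": rs.get_scenario("cotton")},
                              phases=("dissolved",))
        rate_eq = max_rate_eq(LabelUsePattern(2.24, 7, 4, 7.0))
        rel = rs.shipped_relationship("cotton", "dissolved")
        assert out.loc[0, "rate_used_kg_per_ha"] == pytest.approx(rate_eq)
        assert out.loc[0, "ei"] == pytest.approx(
            float(ei_from_relationship(rel, 30.0, 400.0, rate_eq)), rel=1e-12)

    def test_missing_fd_with_multiple_applications_raises(self):
        chems = self.chems([dict(name="multi", aero_days=30.0, koc=400.0,
                                 rate_kg_per_ha=2.24, interval_days=7,
                                 max_applications=4)])
        with pytest.raises(ValueError, match="fd_days"):
            rs.screen_batch(chems, {"cotton": rs.get_scenario("cotton")})

    def test_solubility_flagging(self):
        chems = self.chems([dict(name="soluble", aero_days=30.0, koc=10.0,
                                 rate_kg_per_ha=5.0, sol_mg_per_l=1e-4)])
        out = rs.screen_batch(chems, {"cotton": rs.get_scenario("cotton")},
                              phases=("dissolved",))
        assert out.loc[0, "sol_exceeded"]

    def test_unknown_scenario_relationship_raises(self):
        chems = self.chems([dict(name="x", aero_days=30.0, koc=400.0,
                                 rate_kg_per_ha=1.0)])
        scen = dataclasses.replace(rs.get_scenario("cotton"), name="maize")
        with pytest.raises(KeyError, match="available"):
            rs.screen_batch(chems, {"maize": scen})
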