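"""Value polynomials, published fixtures, crossings, statics, conclusions."""

import numpy as np
import pytest

from shrimpgame import (
    Mode,
    Player,
    Variant,
    comparative_static_sign,
    compare_modes,
    conclusion_report,
    crossing_points,
    preferred_mode,
    printed_fixture,
    reproduction_report,
    statics_report,
    value_polynomial_in_f,
)
from shrimpgame.analysis import DegenerateComparison, ValuePolynomial


class TestValuePolynomial:
    def test_feed_mode_us_coefficients(self, baseline):
        pol = value_polynomial_in_f(Mode.FEED, Player.US, baseline)
        assert pol.k2 == pytest.approx(0.1235, abs=1e-4)
        assert pol.k1 == pytest.approx(1.9753, abs=1e-4)
        assert pol.k0 == pytest.approx(8.901, abs=1e-3)
        assert (round(pol.k2, 2), round(pol.k1, 2)) == (0.12, 1.98)

    def test_us_natural_enemy_as_printed_is_linear(self, baseline):
        pol = value_polynomial_in_f(Mode.NATURAL_ENEMY, Player.US, baseline, Variant.AS_PRINTED_B1)
        assert pol.k2 == 0.0
        assert pol.k1 == pytest.approx(2.667, abs=1e-3)
        assert pol.k0 == pytest.approx(6.333, abs=1e-3)

    def test_partner_natural_enemy_squared_form(self, baseline):
        """Derived (B,2) value expands 1 + (9.493 + f2)^2 / 5.4."""
        pol = value_polynomial_in_f(Mode.NATURAL_ENEMY, Player.PARTNER, baseline)
        inner0 = 5.0 * (1 + np.log(3.0)) - 1.0  # = 9.4931
        coef = 1.0 / 5.4
        f = np.linspace(0, 10, 7)
        assert pol(f) == pytest.approx(1.0 + coef * (inner0 + f) ** 2)

    def test_own_f_does_not_shift_polynomial(self, baseline):
        """f1/f2 are the free variable: their stored value is irrelevant."""
        a = value_polynomial_in_f(Mode.TABLE, Player.PARTNER, baseline)
        b = value_polynomial_in_f(Mode.TABLE, Player.PARTNER, baseline.replace(f2=3.3))
        assert (a.k0, a.k1, a.k2) == (b.k0, b.k1, b.k2)

    def test_b_and_m_polynomials_independent_of_shrimp_price(self, baseline):
        for mode in (Mode.NATURAL_ENEMY, Mode.FEED):
            lo = value_polynomial_in_f(mode, Player.US, baseline.replace(q_E1=1.0))
            hi = value_polynomial_in_f(mode, Player.US, baseline.replace(q_E1=4.0))
            assert (lo.k0, lo.k1, lo.k2) == (hi.k0, hi.k1, hi.k2)


class TestPrintedFixtures:
    @pytest.mark.parametrize(
        "mode,player,scenario,f,expected",
        [
            (Mode.TABLE, Player.US, 1.0, 0.0, 1 + 0.22 * 36),
            (Mode.TABLE, Player.US, 4.0, 1.0, 1 + 0.22 * 100),
            (Mode.FEED, Player.PARTNER, None, 2.0, 1 + 0.28 * 25),
            (Mode.TABLE, Player.PARTNER, 4.0, 0.0, 1 + 1.39 * 2.2**2),
            (Mode.TABLE, Player.PARTNER, 1.0, 5.0, 1 + 1.39 * 9.0),
            (Mode.NATURAL_ENEMY, Player.US, None, 2.0, 6.33 + 2.67 * 2),
            (Mode.FEED, Player.US, None, 1.0, 0.12 + 1.98 + 9.16),
        ],
    )
    def test_fixture_values(self, mode, player, scenario, f, expected):
        assert printed_fixture(mode, player, scenario)(f) == pytest.approx(expected)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            printed_fixture(Mode.TABLE, Player.PARTNER, 2.0)
        with pytest.raises(ValueError, match="scenario"):
            printed_fixture(Mode.TABLE, Player.US, None)


class TestCrossings:
    def test_feed_vs_table_crossing_at_low_price(self):
        m = printed_fixture(Mode.FEED, Player.US)
        e = printed_fixture(Mode.TABLE, Player.US, 1.0)
        crossings = crossing_points(m, e, (0.0, 10.0))
        assert len(crossings) == 1
        assert crossings[0] == pytest.approx(0.3455, abs=1e-3)
        assert float(m(0.0)) > float(e(0.0))
        assert float(m(10.0)) < float(e(10.0))

    def test_identical_polynomials_degenerate(self):
        p = ValuePolynomial(1.0, 2.0, 3.0)
        with pytest.raises(DegenerateComparison):
            crossing_points(p, ValuePolynomial(1.0, 2.0, 3.0), (0.0, 1.0))

    def test_partner_natural_enemy_dominates_feed_in_domain(self, baseline):
        b = value_polynomial_in_f(Mode.NATURAL_ENEMY, Player.PARTNER, baseline)
        m = value_polynomial_in_f(Mode.FEED, Player.PARTNER, baseline)
        assert crossing_points(b, m, (0.0, 10.0)) == []

    def test_bad_domain_rejected(self):
        p = ValuePolynomial(1.0, 0.0, 0.0)
        q = ValuePolynomial(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            crossing_points(p, q, (3.0, 3.0))

    @pytest.mark.parametrize("pair", [("B", "M"), ("B", "E"), ("M", "E")])
    @pytest.mark.parametrize("player,scenario", [(1, 1.0), (1, 4.0), (2, 1.0), (2, 4.0)])
    def test_crossings_match_brute_force_sign_scan(self, pair, player, scenario):
        """Root finding agrees with a dense sign-change scan for every
        printed fixture pair."""
        pa = printed_fixture(Mode(pair[0]), Player(player), scenario)
        pb = printed_fixture(Mode(pair[1]), Player(player), scenario)
        crossings = crossing_points(pa, pb, (0.0, 10.0))
        grid = np.linspace(0.0, 10.0, 10_001)
        diff = np.asarray(pa(grid)) - np.asarray(pb(grid))
        sign_changes = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        assert len(sign_changes) == len(crossings)
        for idx, root in zip(sign_changes, crossings):
            assert grid[idx] - 1e-9 <= root <= grid[idx + 1] + 1e-9


class TestPreferredMode:
    def test_partner_prefers_natural_enemy_derived(self, baseline):
        ordering = preferred_mode(
            Player.PARTNER, baseline.replace(f2=0.0), f=0.0, scenario=1.0, source="derived"
        )
        assert ordering.order == (Mode.NATURAL_ENEMY, Mode.FEED, Mode.TABLE)
        assert ordering.values[Mode.NATURAL_ENEMY] == pytest.approx(17.68, abs=0.01)
        assert ordering.values[Mode.FEED] == pytest.approx(3.50, abs=0.01)
        assert ordering.values[Mode.TABLE] == pytest.approx(2.39, abs=0.01)

    def test_us_prefers_feed_at_low_price_printed(self):
        ordering = preferred_mode(Player.US, None, f=0.0, scenario=1.0, source="printed")
        assert ordering.values[Mode.FEED] == pytest.approx(9.16)
        assert ordering.values[Mode.TABLE] == pytest.approx(8.92)
        assert ordering.order[0] == Mode.FEED

    def test_us_prefers_table_at_high_price_printed(self):
        ordering = preferred_mode(Player.US, None, f=0.0, scenario=4.0, source="printed")
        assert ordering.order[0] == Mode.TABLE

    def test_tie_reported(self):
        # identical B/M fixtures would tie; construct via equal evaluation point
        ordering = preferred_mode(Player.US, None, f=0.0, scenario=1.0, source="printed")
        assert ordering.ties == ()


class TestComparativeStatics:
    @pytest.mark.parametrize(
        "mode,player,parameter,expected",
        [
            (Mode.NATURAL_ENEMY, Player.PARTNER, "h_B", +1),
            (Mode.NATURAL_ENEMY, Player.PARTNER, "c_B", -1),
            (Mode.NATURAL_ENEMY, Player.PARTNER, "f_B", -1),
            (Mode.FEED, Player.US, "q_M1", +1),
            (Mode.FEED, Player.PARTNER, "q_M2", +1),
            (Mode.FEED, Player.US, "c_M1", -1),
            (Mode.FEED, Player.PARTNER, "c_M2", -1),
            (Mode.TABLE, Player.US, "q_E1", +1),
            (Mode.TABLE, Player.PARTNER, "q_E2", +1),
            (Mode.TABLE, Player.PARTNER, "f_E", +1),
        ],
    )
    def test_baseline_signs(self, baseline, mode, player, parameter, expected):
        assert comparative_static_sign(mode, player, parameter, baseline) == expected

    def test_out_of_scope_parameter_rejected(self, baseline):
        with pytest.raises(ValueError, match="does not enter"):
            comparative_static_sign(Mode.FEED, Player.US, "c_T", baseline)

    def test_statics_report_all_pass(self, baseline):
        report = statics_report(baseline)
        assert report["pass"].all()
        assert len(report) == 10


class TestReproduction:
    def test_all_rows_behave_as_documented(self, baseline):
        report = reproduction_report(baseline)
        assert report.ok.all()

    def test_exactly_two_documented_discrepancies(self, baseline):
        report = reproduction_report(baseline)
        mismatches = set(report[~report.expected_match]["item"])
        assert mismatches == {"M1 constant", "B2 inner constant"}
        m1 = report[report.item == "M1 constant"].iloc[0]
        assert m1.derived == pytest.approx(8.90, abs=0.005)
        b2 = report[report.item == "B2 inner constant"].iloc[0]
        assert b2.derived == pytest.approx(9.49, abs=0.005)

    def test_tampered_fixture_detected(self, baseline, monkeypatch):
        """Negative control: corrupting a published coefficient flips the
        corresponding reproduction row to a failure."""
        from shrimpgame import analysis

        monkeypatch.setitem(
            analysis._PRINTED_SQUARED[(Mode.TABLE, Player.US)], 1.0, (1.0, 0.32, 6.0, 1.0)
        )
        report = reproduction_report(baseline)
        row = report[report.item == "E1 leading coefficient"].iloc[0]
        assert not row.match and not row.ok


class TestConclusions:
    def test_all_conclusions_pass_at_baseline(self, baseline):
        report = conclusion_report(baseline)
        assert report.all_pass
        assert set(report.results) == {f"conclusion_{i}" for i in range(1, 6)}

    def test_partner_natural_enemy_dominates_everywhere(self, baseline):
        for source in ("printed", "derived"):
            for q in (1.0, 4.0):
                comp = compare_modes(Player.PARTNER, baseline, scenario=q, source=source)
                assert all(m == Mode.NATURAL_ENEMY for m in comp.preferred)

    def test_preferred_changes_only_at_crossings(self, baseline):
        comp = compare_modes(Player.US, None, scenario=1.0, source="printed", n=2001)
        switches = [
            (comp.f_grid[i], comp.f_grid[i + 1])
            for i in range(len(comp.preferred) - 1)
            if comp.preferred[i] != comp.preferred[i + 1]
        ]
        assert len(switches) == len(comp.crossings)
        for (lo, hi), root in zip(switches, comp.crossings):
            assert lo - 1e-9 <= root <= hi + 1e-9
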