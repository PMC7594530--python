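"""Count-notation parsing, decomposition, summaries and the generation test."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import karyosort as ks
from karyosort.counts import (
    CountNotation,
    InfeasibleCountsError,
    ObservedCountRecord,
    round_half_up,
)


class TestParseCountNotation:
    @pytest.mark.parametrize(
        "token,value,approx,high,s",
        [
            ("ca82", 82, True, None, 0),
            ("29 + 2s", 29, False, None, 2),
            ("53", 53, False, None, 0),
            ("ca106–108", 106, True, 108, 0),
            ("29 + s", 29, False, None, 1),
            ("29+2s", 29, False, None, 2),  # whitespace-tolerant
            ("ca29 + 3s", 29, True, None, 3),
            ("106-108", 106, False, 108, 0),  # ASCII hyphen range
        ],
    )
    def test_grammar(self, token, value, approx, high, s):
        obs = ks.parse_count_notation(token)
        assert (obs.value, obs.approximate, obs.range_high, obs.s_count) == (
            value,
            approx,
            high,
            s,
        )

    def test_parenthetical_note_preserved(self):
        obs = ks.parse_count_notation("53 (at MII)")
        assert obs.value == 53 and obs.note == "at MII"
        assert obs.render() == "53 (at MII)"

    @pytest.mark.parametrize("bad", ["", "abc", "29 ++ s", "s29", "ca", "29s2"])
    def test_unparseable_token_named_in_error(self, bad):
        with pytest.raises(ks.CountParseError, match="token"):
            ks.parse_count_notation(bad)

    @given(
        st.integers(0, 200),
        st.booleans(),
        st.one_of(st.none(), st.integers(0, 50)),
        st.integers(0, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_render_parse_round_trip(self, value, approx, extra, s):
        high = None if extra is None else value + extra
        obs = CountNotation(value, approximate=approx, range_high=high, s_count=s)
        assert ks.parse_count_notation(obs.render()) == obs


class TestDecompose:
    @pytest.mark.parametrize(
        "n,m,x,y",
        [(28, 81, 3, 25), (53, 106, 53, 0), (29, 87, 0, 29), (29, 82, 5, 24)],
    )
    def test_worked_examples(self, n, m, x, y):
        res = ks.decompose(n, m)
        assert (res.x, res.y) == (x, y)

    def test_infeasible_reports_which_bound(self):
        with pytest.raises(InfeasibleCountsError) as err:
            ks.decompose(10, 35)  # x = -5
        assert err.value.bound == "m>3n"
        with pytest.raises(InfeasibleCountsError) as err:
            ks.decompose(10, 19)  # y = -1
        assert err.value.bound == "m<2n"

    def test_exhaustive_inversion(self):
        """decompose(x + y, 2x + 3y) == (x, y) for all x, y <= 60."""
        for x in range(61):
            for y in range(61):
                if x + y == 0:
                    continue
                res = ks.decompose(x + y, 2 * x + 3 * y)
                assert (res.x, res.y) == (x, y)

    def test_feasibility_band(self):
        """Succeeds exactly when 2n <= m <= 3n."""
        for n in range(1, 15):
            for m in range(2, 50):
                feasible = 2 * n <= m <= 3 * n
                if feasible:
                    ks.decompose(n, m)
                else:
                    with pytest.raises(InfeasibleCountsError):
                        ks.decompose(n, m)


class TestHomozygosityProportion:
    @pytest.mark.parametrize(
        "x,m,expected", [(3, 81, 7.4), (53, 106, 100.0), (23, 82, 56.1), (5, 82, 12.2)]
    )
    def test_examples(self, x, m, expected):
        assert ks.homozygosity_proportion(x, m) == expected

    def test_bounds_error(self):
        with pytest.raises(ValueError):
            ks.homozygosity_proportion(60, 106)

    def test_rounding_is_half_up(self):
        assert round_half_up(Fraction(125, 1000), 2) == 0.13
        assert round_half_up(Fraction(135, 10), 0) == 14.0


def _record(sample_id, line, n, m, printed=(None, None)):
    return ObservedCountRecord(
        sample_id=sample_id,
        line=line,
        mi_observations=(CountNotation(n),) if n else (),
        m_observation=CountNotation(m) if m else None,
        printed_x=printed[0],
        printed_y=printed[1],
    )


class TestModalCount:
    def test_modal_value_ignores_univalents(self):
        rec = ObservedCountRecord(
            "12Z066",
            "F1",
            tuple(CountNotation(29, s_count=s) for s in (0, 1, 2, 3)),
            CountNotation(82, approximate=True),
        )
        assert rec.modal_n == 29

    def test_ties_break_to_smallest(self):
        rec = ObservedCountRecord(
            "X", "F2", (CountNotation(32), CountNotation(31)), CountNotation(77)
        )
        assert rec.modal_n == 31


class TestSummaries:
    def test_single_record_has_undefined_sd(self):
        summary = ks.summarize_generation([_record("a", "F1", 28, 81)], "F1")
        assert summary.k == 1
        assert summary.prop_range == (7.4, 7.4)
        assert summary.prop_sd is None

    def test_no_eligible_records_is_an_error(self):
        with pytest.raises(ValueError, match="no decomposable"):
            ks.summarize_generation([_record("a", "F1", 29, None)], "F1")

    def test_printed_inconsistency_warns_but_keeps_computation(self):
        rec = _record("12Z051", "F1", 29, 82, printed=("5", "25"))
        with pytest.warns(ks.CountInconsistencyWarning, match="12Z051"):
            res = ks.decompose_record(rec)
        assert (res.x, res.y) == (5, 24)

    def test_range_low_endpoint_of_m_used(self):
        rec = ObservedCountRecord(
            "L", "Spain", (CountNotation(53),), CountNotation(106, True, 108)
        )
        res = ks.decompose_record(rec)
        assert (res.x, res.y) == (53, 0)
        assert res.approximate


class TestGenerationEffectTest:
    def test_two_groups_equal_squared_t(self):
        """With two groups the ANOVA F must equal the pooled-variance t^2."""
        f2 = [(31, 82), (32, 82), (32, 77), (34, 83), (35, 87)]
        f4 = [(32, 79), (33, 78), (34, 83), (37, 86), (38, 89)]
        records = [_record(f"a{i}", "F2", n, m) for i, (n, m) in enumerate(f2)]
        records += [_record(f"b{i}", "F4", n, m) for i, (n, m) in enumerate(f4)]
        res = ks.generation_effect_test(records, n_perm=200, seed=0)
        props = {
            g: [float(ks.decompose(n, m).proportion) for n, m in pairs]
            for g, pairs in (("F2", f2), ("F4", f4))
        }
        t_stat = scipy.stats.ttest_ind(props["F2"], props["F4"], equal_var=True).statistic
        assert res.F_statistic == pytest.approx(t_stat**2, rel=1e-10)

    def test_identical_groups_give_zero_f(self):
        records = [_record(f"a{i}", "F2", 30, 70) for i in range(3)]
        records += [_record(f"b{i}", "F3", 30, 70) for i in range(3)]
        res = ks.generation_effect_test(records, n_perm=500, seed=0)
        assert res.F_statistic == 0.0
        assert res.p_value > 0.5

    def test_degenerate_grouping_is_an_error(self):
        with pytest.raises(ValueError, match="two generations"):
            ks.generation_effect_test([_record("a", "F2", 30, 70)])

    def test_matches_scipy_f_oneway_on_fixture(self, table1_records):
        res = ks.generation_effect_test(table1_records, n_perm=100, seed=0)
        groups = [
            [
                float(ks.decompose_record(r, warn=False).proportion)
                for r in table1_records
                if r.line == g and ks.decompose_record(r, warn=False) is not None
            ]
            for g in ("F1", "F2", "F3", "F4")
        ]
        expected = scipy.stats.f_oneway(*groups).statistic
        assert res.F_statistic == pytest.approx(expected, rel=1e-10)

    def test_permutation_p_converges_across_seeds(self, table1_records):
        p = [
            ks.generation_effect_test(table1_records, n_perm=100_000, seed=s).p_value
            for s in (1, 2)
        ]
        assert abs(p[0] - p[1]) <= 0.005
        assert max(p) < 0.001
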