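"""Climate-zone and national weighting, yield ratio, stability, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropshift.aggregate import (
    build_report,
    current_yield_summary,
    cz_weighted_yield,
    national_weighted_yield,
    national_yield_ratio,
    yield_stability_cv,
)
from cropshift.cropsim import SiteYield


def make_site(yield_mean, balance, cz=0, flag="contracting", intensity=1.0, cv=5.0, irr=1.0):
    series = np.array([yield_mean * 0.95, yield_mean * 1.05])
    return SiteYield(
        yearly_annual_yield=series,
        mean_annual_yield=yield_mean,
        cv_percent=cv,
        crop_intensity=intensity,
        buffer_id=0,
        cz_id=cz,
        irrigated_share=irr,
        net_balance_ha=balance,
        flag=flag,
    )


class TestCzWeightedYield:
    def test_single_site_identity(self):
        assert cz_weighted_yield([make_site(9.4, -5000.0)]) == pytest.approx(9.4)

    def test_hand_weighted_two_sites(self):
        sites = [make_site(10.0, -3000.0), make_site(14.0, -1000.0)]
        assert cz_weighted_yield(sites) == pytest.approx(11.0)

    def test_random_sites_match_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(1, 8))
            yields = rng.uniform(2, 20, k)
            balances = -rng.uniform(100, 50_000, k)
            sites = [make_site(float(y), float(b)) for y, b in zip(yields, balances)]
            oracle = sum(abs(b) * y for y, b in zip(yields, balances)) / sum(abs(b) for b in balances)
            assert cz_weighted_yield(sites) == pytest.approx(oracle, rel=1e-9)

    def test_mixed_flags_rejected(self):
        sites = [make_site(10.0, -100.0, flag="contracting"), make_site(9.0, 100.0, flag="expanding")]
        with pytest.raises(ValueError):
            cz_weighted_yield(sites)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            cz_weighted_yield([make_site(10.0, 0.0)])


class TestNationalWeightedYield:
    def test_single_zone_identity(self):
        assert national_weighted_yield({3: 11.5}, {3: 0.4}) == pytest.approx(11.5)

    def test_equal_shares_average(self):
        assert national_weighted_yield({0: 12.0, 1: 16.0}, {0: 0.3, 1: 0.3}) == pytest.approx(14.0)

    def test_random_cases_match_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = int(rng.integers(1, 9))
            values = {cz: float(v) for cz, v in enumerate(rng.uniform(1, 20, k))}
            shares = {cz: float(s) for cz, s in enumerate(rng.uniform(0.01, 1.0, k))}
            total = sum(shares.values())
            oracle = sum(values[cz] * shares[cz] / total for cz in values)
            assert national_weighted_yield(values, shares) == pytest.approx(oracle, rel=1e-9)

    def test_empty_zone_set_rejected(self):
        with pytest.raises(ValueError):
            national_weighted_yield({}, {})

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_weight_rescaling(self, factor):
        values = {0: 8.0, 1: 14.0, 2: 11.0}
        shares = {0: 0.2, 1: 0.5, 2: 0.3}
        scaled = {cz: s * factor for cz, s in shares.items()}
        assert national_weighted_yield(values, scaled) == pytest.approx(
            national_weighted_yield(values, shares), rel=1e-12
        )


class TestNationalYieldRatio:
    @pytest.mark.parametrize(
        "converted,new,expected",
        [(15.2, 11.8, 1.3), (16.9, 13.4, 1.3), (11.6, 8.5, 1.4), (10.0, 10.0, 1.0)],
    )
    def test_country_worked_examples_at_one_decimal(self, converted, new, expected):
        assert round(national_yield_ratio(converted, new), 1) == pytest.approx(expected)

    def test_rejects_nonpositive_expanding_yield(self):
        with pytest.raises(ValueError):
            national_yield_ratio(10.0, 0.0)

    @given(st.floats(1.0, 30.0), st.floats(1.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_side_swap(self, a, b):
        assert national_yield_ratio(a, b) == pytest.approx(1.0 / national_yield_ratio(b, a), rel=1e-12)


class TestYieldStability:
    def test_constant_series_zero_cv(self):
        assert yield_stability_cv(np.full(10, 7.7)) == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        # SD = 2*sqrt(2), mean 10 -> 28.28%
        assert yield_stability_cv(np.array([8.0, 12.0])) == pytest.approx(28.284271, abs=1e-5)

    def test_random_series_matches_formula(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(5, 15, size=12)
        oracle = np.sqrt(((s - s.mean()) ** 2).sum() / (len(s) - 1)) / s.mean() * 100
        assert yield_stability_cv(s) == pytest.approx(oracle, rel=1e-12)

    def test_rejects_short_or_nonpositive_series(self):
        with pytest.raises(ValueError):
            yield_stability_cv(np.array([5.0]))
        with pytest.raises(ValueError):
            yield_stability_cv(np.array([1.0, -3.0]))


class TestCurrentYields:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["buffer_id", "admin_unit", "year", "yield_t_ha", "area_ha"])

    def test_constant_unit_returns_its_mean(self):
        rows = [(0, "a", y, 1.8, 100.0) for y in range(2006, 2011)]
        out = current_yield_summary(self.table(rows))
        assert out[0] == pytest.approx(1.8)

    def test_equal_area_units_average(self):
        rows = [(0, "a", y, 2.0, 100.0) for y in range(5)] + [
            (0, "b", y, 4.0, 100.0) for y in range(5)
        ]
        assert current_yield_summary(self.table(rows))[0] == pytest.approx(3.0)

    def test_window_takes_most_recent_five_years(self):
        rows = [(0, "a", y, float(y), 100.0) for y in range(2000, 2011)]
        # most recent 5 years: 2006..2010 -> mean 2008
        assert current_yield_summary(self.table(rows))[0] == pytest.approx(2008.0)

    def test_random_table_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for buf in range(3):
            for unit in "abc":
                area = float(rng.uniform(10, 500))
                for year in range(2003, 2011):
                    rows.append((buf, unit, year, float(rng.uniform(1, 9)), area))
        table = self.table(rows)
        out = current_yield_summary(table)
        for buf in range(3):
            sub = table[table.buffer_id == buf]
            means, areas = [], []
            for unit in "abc":
                u = sub[sub.admin_unit == unit].sort_values("year").tail(5)
                means.append(u.yield_t_ha.mean())
                areas.append(u.area_ha.iloc[-1])
            oracle = np.average(means, weights=areas)
            assert out[buf] == pytest.approx(oracle, rel=1e-12)


class TestBuildReport:
    def test_symmetric_sides_give_unit_ratio(self):
        sites = [
            make_site(10.0, -20_000.0, cz=0, flag="contracting"),
            make_site(10.0, 20_000.0, cz=0, flag="expanding"),
        ]
        report = build_report(sites, {0: 1.0})
        assert report.yield_ratio == pytest.approx(1.0)
        assert report.contracting.weighted_yield == report.expanding.weighted_yield

    @pytest.mark.parametrize(
        "converted,new,printed",
        [(15.2, 11.8, 1.3), (16.9, 13.4, 1.3), (11.6, 8.5, 1.4)],
    )
    def test_injected_table_values_reproduce_printed_ratios(self, converted, new, printed):
        sites = [
            make_site(converted, -30_000.0, cz=0, flag="contracting"),
            make_site(new, 30_000.0, cz=0, flag="expanding"),
        ]
        report = build_report(sites, {0: 1.0})
        assert report.yield_ratio_1dp == pytest.approx(printed)

    def test_one_empty_side_flags_undefined_ratio(self):
        sites = [make_site(9.0, -20_000.0, flag="contracting")]
        report = build_report(sites, {0: 1.0})
        assert not report.ratio_defined
        assert report.yield_ratio is None
        assert "expanding" in report.note
        assert "undefined" in report.to_text()

    def test_report_fields_match_independent_recomputation(self):
        rng = np.random.default_rng(9)
        sites = []
        for cz in (0, 1):
            for _ in range(3):
                sites.append(
                    make_site(float(rng.uniform(6, 16)), float(-rng.uniform(1e4, 9e4)), cz=cz,
                              flag="contracting", intensity=float(rng.uniform(1, 2)))
                )
                sites.append(
                    make_site(float(rng.uniform(6, 16)), float(rng.uniform(1e4, 9e4)), cz=cz,
                              flag="expanding", intensity=float(rng.uniform(1, 2)))
                )
        shares = {0: 0.6, 1: 0.4}
        report = build_report(sites, shares)
        for flag, side in (("contracting", report.contracting), ("expanding", report.expanding)):
            members = [s for s in sites if s.flag == flag]
            cz_vals = {}
            for cz in (0, 1):
                grp = [s for s in members if s.cz_id == cz]
                cz_vals[cz] = sum(abs(s.net_balance_ha) * s.mean_annual_yield for s in grp) / sum(
                    abs(s.net_balance_ha) for s in grp
                )
            national = sum(cz_vals[cz] * shares[cz] for cz in cz_vals) / sum(shares.values())
            assert side.weighted_yield == pytest.approx(national, rel=1e-12)
            w = [abs(s.net_balance_ha) for s in members]
            assert side.crop_intensity == pytest.approx(
                np.average([s.crop_intensity for s in members], weights=w), rel=1e-12
            )
        assert report.yield_ratio == pytest.approx(
            report.contracting.weighted_yield / report.expanding.weighted_yield, rel=1e-12
        )

    def test_weighted_yields_bounded_by_site_extremes(self):
        rng = np.random.default_rng(11)
        sites = [
            make_site(float(rng.uniform(4, 18)), float(-rng.uniform(1e3, 5e4)), cz=0)
            for _ in range(6)
        ]
        value = cz_weighted_yield(sites)
        yields = [s.mean_annual_yield for s in sites]
        assert min(yields) <= value <= max(yields)
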