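"""Outlier flagging, trends, cost-volume quadrants and data quality."""
import math

import numpy as np
import pytest

from rems.config import RunConfig
from rems.ledger_io import OutputVolume
from rems.org_model import Quarter, validate_hierarchy
from rems.ram import AllocatedExpenditure, RAM
from rems.step_down import FacilityInflow
from rems.analytics import (
    MAD_CONSISTENCY,
    cost_volume_view,
    data_quality_report,
    flag_outliers,
    trend,
)
from rems.unit_expenditure import compute_unit_expenditure
from conftest import make_units

Q1, Q2 = Quarter(2016, 1), Quarter(2016, 2)


def units_for(values, hierarchy, service="HTC", quarter=Q1, district="P1D1",
              volumes=None):
    """Unit-expenditure records for facilities F1.. in one district."""
    facs = [u.id for u in hierarchy.facilities() if u.id.startswith(district)]
    assert len(values) <= len(facs)
    allocs, vols = [], []
    for fac, val in zip(facs, values):
        v = 10 if volumes is None else volumes[fac]
        allocs.append(AllocatedExpenditure(fac, quarter, service, "personnel", val * v))
        vols.append(OutputVolume(fac, service, quarter, v))
    return compute_unit_expenditure(allocs, vols)


@pytest.fixture
def hierarchy6():
    """One district with 6 facilities (big enough for outlier groups)."""
    return validate_hierarchy(make_units(1, 1, 6))


class TestFlagOutliers:
    def test_extreme_value_flagged_high(self, hierarchy6):
        """{100, 110, 105, 1000}: median 107.5, MAD 5 -> z(1000) ≈ 120.4;
        frozen from a hand median/MAD computation."""
        cfg = RunConfig(outlier_min_group=4)
        units = units_for([100, 110, 105, 1000], hierarchy6)
        flags, _ = flag_outliers(units, hierarchy6, cfg)
        (flag,) = flags
        assert flag.direction == "high"
        assert flag.unit_total == 1000
        assert flag.center == 107.5
        assert flag.spread == pytest.approx(MAD_CONSISTENCY * 5.0)
        assert flag.score == pytest.approx((1000 - 107.5) / (MAD_CONSISTENCY * 5.0))

    def test_degenerate_spread_yields_note_not_flags(self, hierarchy6):
        cfg = RunConfig(outlier_min_group=4)
        units = units_for([50, 50, 50, 50, 50], hierarchy6)
        flags, notes = flag_outliers(units, hierarchy6, cfg)
        assert flags == []
        assert any("degenerate spread" in n for n in notes)

    def test_small_group_not_flagged(self, hierarchy6):
        units = units_for([1, 2, 1000], hierarchy6)
        flags, notes = flag_outliers(units, hierarchy6, RunConfig(outlier_min_group=5))
        assert flags == []
        assert any("too small" in n for n in notes)

    def test_invariant_to_currency_rescaling(self, hierarchy6):
        cfg = RunConfig(outlier_min_group=4)
        base_vals = [100, 110, 105, 1000, 95]
        flags1, _ = flag_outliers(units_for(base_vals, hierarchy6), hierarchy6, cfg)
        flags2, _ = flag_outliers(
            units_for([v * 1000 for v in base_vals], hierarchy6), hierarchy6, cfg)
        assert [(f.facility, f.direction) for f in flags1] == [
            (f.facility, f.direction) for f in flags2]
        for f1, f2 in zip(flags1, flags2):
            assert f1.score == pytest.approx(f2.score, rel=1e-9)

    def test_facility_at_group_median_never_flagged(self, hierarchy6):
        cfg = RunConfig(outlier_min_group=4)
        vals = [10, 20, 30, 40, 20]  # last facility repeats the median
        units = units_for(vals, hierarchy6)
        flags, _ = flag_outliers(units, hierarchy6, cfg)
        median_fac = units[4].facility
        assert median_fac not in {f.facility for f in flags}

    def test_deterministic(self, hierarchy6):
        cfg = RunConfig(outlier_min_group=4)
        units = units_for([100, 110, 105, 1000], hierarchy6)
        a = flag_outliers(units, hierarchy6, cfg)
        b = flag_outliers(list(units), hierarchy6, cfg)
        assert a == b


class TestTrend:
    def test_quarter_over_quarter_change(self, hierarchy6):
        units = units_for([100], hierarchy6, quarter=Q1) + units_for(
            [120], hierarchy6, quarter=Q2)
        fac = units[0].facility
        out = trend(units, fac, "HTC")
        assert list(out["quarter"]) == ["2016Q1", "2016Q2"]
        assert math.isnan(out.loc[0, "change"])
        assert out.loc[1, "change"] == pytest.approx(0.20)

    def test_single_quarter_no_change(self, hierarchy6):
        units = units_for([100], hierarchy6)
        out = trend(units, units[0].facility, "HTC")
        assert len(out) == 1 and math.isnan(out.loc[0, "change"])

    def test_zero_previous_flagged_undefined(self, hierarchy6):
        fac = "P1D1F1"
        units = compute_unit_expenditure(
            [AllocatedExpenditure(fac, Q2, "HTC", "personnel", 100.0)],
            [OutputVolume(fac, "HTC", Q1, 10), OutputVolume(fac, "HTC", Q2, 10)],
        )
        out = trend(units, fac, "HTC")
        # Q1 has volume but no money (zero_expenditure): Q2 change undefined
        assert out.loc[1, "note"] == "undefined_change"
        assert math.isnan(out.loc[1, "change"])


class TestCostVolumeView:
    def test_one_facility_per_quadrant(self, hierarchy6):
        vals = {"P1D1F1": (10, 100), "P1D1F2": (20, 100),
                "P1D1F3": (10, 400), "P1D1F4": (20, 400)}
        # medians: cost 15, volume 250 -> all four proper quadrants
        allocs, vols = [], []
        for fac, (unit_cost, volume) in vals.items():
            allocs.append(
                AllocatedExpenditure(fac, Q1, "HTC", "personnel", unit_cost * volume))
            vols.append(OutputVolume(fac, "HTC", Q1, volume))
        units = compute_unit_expenditure(allocs, vols)
        out = cost_volume_view(units, "HTC", Q1).set_index("facility_id")
        assert out.loc["P1D1F1", "quadrant"] == "low_volume_low_cost"
        assert out.loc["P1D1F2", "quadrant"] == "low_volume_high_cost"
        assert out.loc["P1D1F3", "quadrant"] == "high_volume_low_cost"
        assert out.loc["P1D1F4", "quadrant"] == "high_volume_high_cost"

    def test_single_facility_all_boundary(self, hierarchy6):
        units = units_for([100], hierarchy6)
        out = cost_volume_view(units, "HTC", Q1)
        assert list(out["quadrant"]) == ["boundary"]

    def test_ordered_by_unit_cost_descending(self, hierarchy6):
        units = units_for([10, 50, 30], hierarchy6)
        out = cost_volume_view(units, "HTC", Q1)
        assert list(out["unit_total"]) == sorted(out["unit_total"], reverse=True)


class TestDataQualityReport:
    def test_missing_volume_surfaces(self, hierarchy6):
        fac = "P1D1F1"
        units = compute_unit_expenditure(
            [AllocatedExpenditure(fac, Q1, "HTC", "personnel", 100.0)], [])
        rams = {fac: RAM(fac, ((("HTC", "personnel"), 1.0),))}
        inflows = [FacilityInflow(fac, Q1, 100.0)]
        report = data_quality_report(units, inflows, rams, hierarchy6)
        assert list(report["issue"]) == ["missing_volume"]
        assert report.loc[0, "district"] == "P1D1"

    def test_clean_run_empty_report(self, hierarchy6):
        fac = "P1D1F1"
        units = compute_unit_expenditure(
            [AllocatedExpenditure(fac, Q1, "HTC", "personnel", 100.0)],
            [OutputVolume(fac, "HTC", Q1, 10)])
        rams = {fac: RAM(fac, ((("HTC", "personnel"), 1.0),))}
        report = data_quality_report(units, [FacilityInflow(fac, Q1, 100.0)], rams, hierarchy6)
        assert len(report) == 0

    def test_volume_without_expenditure_surfaces(self, hierarchy6):
        units = compute_unit_expenditure([], [OutputVolume("P1D1F2", "ART", Q1, 5)])
        report = data_quality_report(units, [], {}, hierarchy6)
        assert list(report["issue"]) == ["zero_expenditure"]

    def test_ram_missing_facility_listed(self, hierarchy6):
        report = data_quality_report([], [FacilityInflow("P1D1F3", Q1, 9.0)], {}, hierarchy6)
        assert list(report["issue"]) == ["ram_missing"]
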