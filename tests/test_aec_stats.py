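"""Repeatability, median/IQR summaries, thickness curves and ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecphantom import StudyTable
from aecphantom.aec_stats import (
    intermodality_ratios,
    modality_summaries,
    repeatability,
    repeatability_maxima,
    study_level,
    thickness_curves,
)


def dm_table(values_by_cell, system="SysA", mode="M"):
    """Minimal DM StudyTable: {pmma: [repeat values]} for mgd (kvp/mas fixed)."""
    rows = []
    for pmma, values in values_by_cell.items():
        for r, v in enumerate(values, start=1):
            rows.append(dict(
                system=system, modality="DM", aec_mode=mode, pmma_mm=pmma,
                repeat=r, sub_kind="DM", angle_deg=0.0, anode="Mo",
                filter="Mo", kvp=28.0, mas=v, entrance_kerma_mgy=1.0,
                mgd_mgy=v, cnr=np.nan,
            ))
    return StudyTable(pd.DataFrame(rows))


class TestRepeatability:
    def test_identical_repeats_give_zero_error(self):
        rep = repeatability(dm_table({45.0: [100.0, 100.0, 100.0]}),
                            parameters=("mas",))
        assert rep["relative_error"].iloc[0] == 0.0
        assert rep["half_dispersion"].iloc[0] == 0.0

    def test_hand_arithmetic_90_100_110(self):
        """Repeats {90,100,110}: half-dispersion 10, mean 100, error 10%."""
        rep = repeatability(dm_table({45.0: [90.0, 100.0, 110.0]}),
                            parameters=("mas",))
        assert rep["mean"].iloc[0] == pytest.approx(100.0)
        assert rep["half_dispersion"].iloc[0] == pytest.approx(10.0)
        assert rep["relative_error"].iloc[0] == pytest.approx(0.10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 1e4), min_size=2, max_size=5),
        scale=st.floats(0.01, 100.0),
    )
    def test_relative_error_scale_invariant(self, values, scale):
        """Multiplying all repeats by k>0 leaves the relative error unchanged."""
        rep1 = repeatability(dm_table({45.0: values}), parameters=("mas",))
        rep2 = repeatability(dm_table({45.0: [v * scale for v in values]}),
                             parameters=("mas",))
        assert rep2["relative_error"].iloc[0] == pytest.approx(
            rep1["relative_error"].iloc[0], rel=1e-9)

    def test_single_repeat_raises(self):
        with pytest.raises(ValueError, match="<2 repeats"):
            repeatability(dm_table({45.0: [100.0]}), parameters=("mas",))

    def test_zero_mean_flagged_undefined_and_excluded_from_maxima(self):
        table = dm_table({45.0: [-1.0, 1.0]})
        rep = repeatability(table, parameters=("mas",))
        assert bool(rep["undefined"].iloc[0])
        assert np.isnan(rep["relative_error"].iloc[0])
        maxima = repeatability_maxima(table)
        mas_rows = maxima[maxima["parameter"] == "mas"]
        assert mas_rows.empty or np.isfinite(mas_rows["max_relative_error"]).all()

    def test_maxima_take_worst_thickness(self):
        table = dm_table({40.0: [99.0, 101.0], 50.0: [90.0, 110.0]})
        maxima = repeatability_maxima(table)
        val = maxima.loc[maxima["parameter"] == "mas", "max_relative_error"]
        assert val.iloc[0] == pytest.approx(0.10)


def sort_based_quartiles(values):
    """Independent oracle: order statistics with linear interpolation."""
    xs = sorted(values)
    n = len(xs)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.5), q(0.75)


class TestSummaries:
    def test_median_iqr_match_sort_oracle_on_random_groups(self):
        rng = np.random.default_rng(2024)
        from aecphantom.aec_stats import _quartiles
        for _ in range(1000):
            vals = rng.lognormal(0, 1, size=rng.integers(1, 40))
            q1, med, q3 = _quartiles(vals)
            oq1, omed, oq3 = sort_based_quartiles(vals.tolist())
            assert med == pytest.approx(omed, rel=1e-12)
            assert q1 == pytest.approx(oq1, rel=1e-12)
            assert q3 == pytest.approx(oq3, rel=1e-12)

    def test_five_point_group_median(self):
        table = dm_table({45.0: [1.0, 2.0, 3.0, 4.0, 5.0]})
        summ = modality_summaries(table)
        row = summ[(summ["modality"] == "DM") & (summ["parameter"] == "mgd")]
        assert row["median"].iloc[0] == 3.0
        assert row["q1"].iloc[0] <= row["median"].iloc[0] <= row["q3"].iloc[0]

    def test_single_record_group_degenerate_iqr(self):
        table = dm_table({45.0: [2.5, 2.5]})
        summ = modality_summaries(table)
        row = summ[(summ["modality"] == "DM") & (summ["parameter"] == "mgd")]
        assert row["median"].iloc[0] == row["q1"].iloc[0] == row["q3"].iloc[0]


class TestStudyLevel:
    def test_dbt_rows_become_scan_totals(self):
        rows = []
        for r in (1, 2, 3):
            for angle in (-12.5, 0.0, 12.5):
                rows.append(dict(
                    system="S", modality="DBT", aec_mode="M", pmma_mm=45.0,
                    repeat=r, sub_kind="DBT_PROJECTION", angle_deg=angle,
                    anode="Mo", filter="Mo", kvp=26.0, mas=10.0,
                    entrance_kerma_mgy=1.0, mgd_mgy=0.15,
                    cnr=3.0 if angle == 0.0 else np.nan,
                ))
        sl = study_level(StudyTable(pd.DataFrame(rows)))
        assert (sl["mas"] == 30.0).all()
        assert np.allclose(sl["mgd"], 0.45)
        assert np.allclose(sl["mgd_basis"], 0.15)
        assert np.allclose(sl["cnr"], 3.0)  # 0-degree projection only
        assert np.allclose(sl["fom"], 9.0 / 0.15)

    def test_cem_pairs_expose_total_mgd(self):
        rows = []
        for sub, mgd in (("CEM_LE", 1.2), ("CEM_HE", 0.6)):
            rows.append(dict(
                system="S", modality="CEM", aec_mode="M", pmma_mm=45.0,
                repeat=1, sub_kind=sub, angle_deg=0.0, anode="Rh",
                filter="Cu" if sub == "CEM_HE" else "Ag",
                kvp=49.0 if sub == "CEM_HE" else 34.0, mas=50.0,
                entrance_kerma_mgy=1.0, mgd_mgy=mgd, cnr=np.nan,
            ))
        sl = study_level(StudyTable(pd.DataFrame(rows)))
        assert set(sl["sub_label"]) == {"CEM_LE", "CEM_HE"}
        assert np.allclose(sl["cem_total_mgd"], 1.8)

    def test_fom_identity_on_all_outputs(self, full_study):
        """fom * mgd_basis reproduces cnr^2 on every pipeline output row."""
        sl = study_level(full_study)
        ok = sl[np.isfinite(sl["fom"])]
        assert len(ok) > 300
        assert np.allclose(ok["fom"] * ok["mgd_basis"], ok["cnr"] ** 2,
                           rtol=1e-12)


class TestThicknessCurves:
    def test_constant_repeats_zero_error_bars(self):
        table = dm_table({40.0: [5.0, 5.0, 5.0], 50.0: [7.0, 7.0, 7.0]})
        curves = thickness_curves(table, parameters=("mas",))
        assert (curves["half_dispersion"] == 0.0).all()
        assert sorted(curves["mean"]) == [5.0, 7.0]


class TestIntermodalityRatios:
    @staticmethod
    def _paired_table(dbt_factor):
        rows = []
        for pmma in (40.0, 50.0):
            dm_mgd = 1.0 + pmma / 100.0
            for r in (1, 2):
                rows.append(dict(
                    system="S", modality="DM", aec_mode="M", pmma_mm=pmma,
                    repeat=r, sub_kind="DM", angle_deg=0.0, anode="Mo",
                    filter="Mo", kvp=28.0, mas=10.0, entrance_kerma_mgy=1.0,
                    mgd_mgy=dm_mgd, cnr=10.0,
                ))
                rows.append(dict(
                    system="S", modality="DBT", aec_mode="M", pmma_mm=pmma,
                    repeat=r, sub_kind="DBT_PROJECTION", angle_deg=0.0,
                    anode="Mo", filter="Mo", kvp=28.0, mas=10.0,
                    entrance_kerma_mgy=1.0, mgd_mgy=dbt_factor * dm_mgd,
                    cnr=10.0,
                ))
        return StudyTable(pd.DataFrame(rows))

    def test_identical_doses_give_unit_ratio(self):
        ratios, means = intermodality_ratios(self._paired_table(1.0))
        mgd = means[(means["comparison"] == "DBT_vs_DM")
                    & (means["quantity"] == "MGD")]
        assert mgd["mean_ratio"].iloc[0] == pytest.approx(1.0)

    def test_constructed_1p2_dose_ratio_recovered(self):
        """DBT dose planted at 1.2x DM at every thickness: mean ratio 1.2."""
        ratios, means = intermodality_ratios(self._paired_table(1.2))
        mgd = means[(means["comparison"] == "DBT_vs_DM")
                    & (means["quantity"] == "MGD")]
        assert mgd["mean_ratio"].iloc[0] == pytest.approx(1.2)
        per_thickness = ratios[(ratios["comparison"] == "DBT_vs_DM")
                               & (ratios["quantity"] == "MGD")]
        assert np.allclose(per_thickness["ratio"], 1.2)

    def test_missing_dm_reference_raises(self):
        table = self._paired_table(1.0)
        df = table.df
        dbt_only = StudyTable(df[df["modality"] == "DBT"].copy())
        with pytest.raises(ValueError, match="DM reference"):
            intermodality_ratios(dbt_only)

    def test_ge_reference_mode_is_aop_std(self, full_study):
        """GE ratios use the AOP/STD mode on both sides of the division."""
        ratios, means = intermodality_ratios(full_study)
        ge = means[means["system"] == "GE Pristina"]
        assert not ge.empty  # computed despite GE's multiple modes
        dbt_mgd = ge[(ge["comparison"] == "DBT_vs_DM")
                     & (ge["quantity"] == "MGD")]["mean_ratio"].iloc[0]
        assert 0.5 < dbt_mgd < 1.5
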