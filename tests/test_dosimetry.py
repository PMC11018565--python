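"""Dance-model dosimetry: equivalence ladder, factor lookups, MGD identities."""

import numpy as np
import pandas as pd
import pytest

from aecphantom import (
    Acquisition,
    HvlModel,
    PhantomSpec,
    SpectrumKey,
    cem_total_mgd,
    compute_mgd,
    dance_factors,
    lookup_hvl,
    pmma_to_breast,
    scan_mgd,
)
from aecphantom.dosimetry import DoseResult, TubeOutputModel, load_tables, _read_resource


def constant_hvl_model(anode: str, filt: str, hvl: float) -> HvlModel:
    return HvlModel(pd.DataFrame({
        "anode": [anode] * 2, "filter": [filt] * 2,
        "kvp": [10.0, 60.0], "hvl_mm_al": [hvl, hvl],
    }))


class TestPmmaEquivalence:
    def test_thickest_stack_maps_to_90mm_breast(self):
        breast, gland = pmma_to_breast(70.0)
        assert breast == 90.0
        assert gland == pytest.approx(0.04)

    def test_node_identity(self):
        eq = _read_resource("pmma_equivalence.csv")
        for row in eq.itertuples(index=False):
            breast, gland = pmma_to_breast(row.pmma_mm)
            assert breast == row.breast_mm
            assert gland == pytest.approx(row.glandularity)

    def test_interpolation_matches_hand_calculation(self):
        # 22.5 mm sits a quarter of the way between the 20- and 30-mm rows
        eq = _read_resource("pmma_equivalence.csv").set_index("pmma_mm")
        breast, gland = pmma_to_breast(22.5)
        assert breast == pytest.approx(
            0.75 * eq.loc[20, "breast_mm"] + 0.25 * eq.loc[30, "breast_mm"])
        assert gland == pytest.approx(
            0.75 * eq.loc[20, "glandularity"] + 0.25 * eq.loc[30, "glandularity"])

    def test_monotone_thickness_and_glandularity(self):
        pts = [pmma_to_breast(t) for t in np.arange(20, 70.5, 2.5)]
        breasts = [p[0] for p in pts]
        glands = [p[1] for p in pts]
        assert all(b2 > b1 for b1, b2 in zip(breasts, breasts[1:]))
        assert all(g2 < g1 for g1, g2 in zip(glands, glands[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            pmma_to_breast(15.0)
        with pytest.raises(ValueError):
            pmma_to_breast(75.0)


class TestHvlModel:
    def test_node_and_midpoint_lookup(self):
        model = HvlModel(pd.DataFrame({
            "anode": ["Mo"] * 3, "filter": ["Mo"] * 3,
            "kvp": [24.0, 26.0, 28.0], "hvl_mm_al": [0.31, 0.33, 0.35],
        }))
        assert lookup_hvl(SpectrumKey("Mo", "Mo", 26.0), model) == 0.33
        assert lookup_hvl(SpectrumKey("Mo", "Mo", 25.0), model) == pytest.approx(
            (0.31 + 0.33) / 2)

    def test_edge_clamping(self):
        model = HvlModel.default()
        edge = lookup_hvl(SpectrumKey("Mo", "Mo", 30.0), model)
        beyond = lookup_hvl(SpectrumKey("Mo", "Mo", 35.0), model)
        assert beyond == edge

    def test_unknown_track_names_the_pair(self):
        with pytest.raises(KeyError, match="Mo/Cu"):
            HvlModel.default().lookup(SpectrumKey("Mo", "Cu", 30.0))


class TestDanceFactors:
    def test_two_dimensional_exposures_have_t_one(self):
        f = dance_factors(SpectrumKey("Mo", "Mo", 26.0), 45.0, hvl=0.35)
        assert f.t == 1.0

    def test_central_projection_t_is_one(self):
        f = dance_factors(SpectrumKey("Mo", "Mo", 26.0), 45.0, hvl=0.35,
                          projection_angle_deg=0.0, is_tomo_projection=True)
        assert f.t == 1.0

    def test_oblique_projection_t_below_one(self):
        f = dance_factors(SpectrumKey("Mo", "Mo", 26.0), 45.0, hvl=0.35,
                          projection_angle_deg=12.5, is_tomo_projection=True)
        assert 0.9 < f.t < 1.0

    def test_node_lookup_equals_direct_table_cells(self):
        """At a (thickness, HVL) grid node the factors are raw table reads."""
        g_df = _read_resource("g_factors.csv").set_index("breast_mm")
        c_df = _read_resource("c_factors.csv").set_index("glandularity")
        f = dance_factors(SpectrumKey("Mo", "Mo", 26.0), 40.0, hvl=0.40)
        assert f.g == pytest.approx(g_df.loc[45, "0.40"], rel=1e-12)
        assert f.c == pytest.approx(c_df.loc[0.41, "0.40"], rel=1e-12)
        assert f.s == 1.000

    def test_g_decreases_with_equivalent_thickness(self):
        """Thicker breasts absorb a smaller fraction: g falls monotonically."""
        tables = load_tables()
        g = tables.g.values
        assert np.all(np.diff(g, axis=0) < 0)  # down each HVL column
        assert np.all(np.diff(g, axis=1) > 0)  # harder beams convert more

    def test_interpolated_value_within_bracketing_cells(self):
        # 45 mm PMMA -> 53 mm breast (a row node); HVL 0.42 between columns
        g_df = _read_resource("g_factors.csv").set_index("breast_mm")
        f = dance_factors(SpectrumKey("Mo", "Mo", 26.0), 45.0, hvl=0.42)
        assert g_df.loc[53, "0.40"] <= f.g <= g_df.loc[53, "0.45"]


def make_acq(kvp=26.0, mas=50.0, kerma=2.0, anode="Mo", filt="Mo",
             sub_kind="DM", angle=0.0, pmma=40.0):
    return Acquisition(
        sub_kind=sub_kind, anode=anode, filter=filt, kvp=kvp, mas=mas,
        pmma_mm=pmma, projection_angle_deg=angle, entrance_kerma_mgy=kerma,
        plan_key=("GE Pristina", "DM", "AOP/STD", pmma, 1),
    )


class TestComputeMgd:
    def test_zero_kerma_gives_zero_dose(self):
        model = constant_hvl_model("Mo", "Mo", 0.40)
        res = compute_mgd(make_acq(kerma=0.0), PhantomSpec(40.0), hvl_model=model)
        assert res.mgd_mgy == 0.0

    def test_mgd_linear_in_entrance_kerma(self):
        model = constant_hvl_model("Mo", "Mo", 0.40)
        r1 = compute_mgd(make_acq(kerma=1.5), PhantomSpec(40.0), hvl_model=model)
        r2 = compute_mgd(make_acq(kerma=3.0), PhantomSpec(40.0), hvl_model=model)
        assert r2.mgd_mgy == pytest.approx(2.0 * r1.mgd_mgy, rel=1e-12)

    def test_node_aligned_mgd_equals_hand_product(self):
        """K*g*c*s at a table node, with all cells read directly."""
        g_df = _read_resource("g_factors.csv").set_index("breast_mm")
        c_df = _read_resource("c_factors.csv").set_index("glandularity")
        s_df = _read_resource("s_factors.csv").set_index(["anode", "filter"])
        model = constant_hvl_model("Rh", "Ag", 0.50)
        res = compute_mgd(
            make_acq(kvp=34.0, kerma=4.0, anode="Rh", filt="Ag", pmma=50.0),
            PhantomSpec(50.0), hvl_model=model,
        )
        expected = (
            4.0 * g_df.loc[60, "0.50"] * c_df.loc[0.20, "0.50"]
            * s_df.loc[("Rh", "Ag"), "s"]
        )
        assert res.mgd_mgy == pytest.approx(expected, rel=1e-12)
        assert res.mgd_mgy == pytest.approx(
            res.entrance_kerma_mgy * res.factors.product, rel=1e-12)

    def test_kerma_fallback_uses_tube_output_model(self):
        model = constant_hvl_model("Mo", "Mo", 0.40)
        tube = TubeOutputModel(y0_mgy_per_mas={("Mo", "Mo"): 0.05})
        acq = make_acq(kerma=None)
        res = compute_mgd(acq, PhantomSpec(40.0), hvl_model=model, tube_output=tube)
        assert res.kerma_source == "tube-output-model"
        assert res.entrance_kerma_mgy > 0
        with pytest.raises(ValueError):
            compute_mgd(acq, PhantomSpec(40.0), hvl_model=model)


class TestScanAndCemTotals:
    def _proj(self, mgd, key=("a",)):
        f = dance_factors(SpectrumKey("Mo", "Mo", 26.0), 40.0, hvl=0.40)
        return DoseResult(mgd_mgy=mgd, factors=f, entrance_kerma_mgy=1.0,
                          kerma_source="dicom", scan_key=key)

    def test_nine_equal_projections(self):
        scan = scan_mgd([self._proj(0.15)] * 9)
        assert scan.total_mgy == pytest.approx(1.35)
        assert scan.per_projection_mgy == pytest.approx(0.15)
        assert scan.per_projection_mgy == scan.total_mgy / scan.n_projections

    def test_single_projection_total(self):
        scan = scan_mgd([self._proj(0.2)])
        assert scan.total_mgy == 0.2

    def test_mixed_scan_rejected(self):
        with pytest.raises(ValueError):
            scan_mgd([self._proj(0.1, key=("a",)), self._proj(0.1, key=("b",))])
        with pytest.raises(ValueError):
            scan_mgd([])

    def test_cem_total_is_le_plus_he(self):
        le = self._proj(1.285)
        he = self._proj(0.611)
        assert cem_total_mgd(le, he) == pytest.approx(1.896)
        assert cem_total_mgd(self._proj(1.683), self._proj(0.596)) == pytest.approx(2.279)
        assert cem_total_mgd(le, self._proj(0.0)) == le.mgd_mgy

    def test_cem_series_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cem_total_mgd(self._proj(1.0, key=("a",)), self._proj(0.5, key=("b",)))


def test_apply_dosimetry_appends_consistent_columns(small_dm_study):
    df = small_dm_study.df
    for col in ("mgd_mgy", "g", "c", "s", "t", "hvl_mm_al"):
        assert col in df.columns
    product = df.entrance_kerma_mgy * df.g * df.c * df.s * df.t
    assert np.allclose(df.mgd_mgy, product, rtol=1e-12)
    assert (df.t == 1.0).all()  # DM only
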