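import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relacbp.itc import (BindingRecord, ITCParams, ITCSchedule,
                         OneSiteBindingModel, check_table_consistency,
                         default_schedule, delta_g, fit_one_site, fold_change,
                         load_binding_table, predict_heats, tds_from)


class TestLinkage:
    def test_one_molar_kd_gives_zero_free_energy(self):
        assert delta_g(1e9, 310.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kd_nm, expected", [(57.0, -9.88), (244.4, -9.02)])
    def test_free_energy_closed_form(self, kd_nm, expected):
        # frozen from independent evaluation of RT·ln(Kd·1e-9) at 298.15 K
        assert delta_g(kd_nm) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("kd_nm, dh, expected", [
        (244.4, -7.2, 1.8),      # wild type at physiological salt
        (1706.8, -2.4, 5.5),     # the L465A hydrophobic-anchor mutant
    ])
    def test_tds_reproduces_tabulated_values(self, kd_nm, dh, expected):
        assert round(tds_from(kd_nm, dh), 1) == expected

    def test_tds_zero_when_enthalpy_equals_free_energy(self):
        dg = delta_g(500.0)
        assert tds_from(500.0, dg) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            delta_g(0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(kd=st.floats(1e-3, 1e9), dh=st.floats(-50, 50),
           temp=st.floats(270, 350))
    def test_linkage_identity_exact(self, kd, dh, temp):
        assert delta_g(kd, temp) + tds_from(kd, dh, temp) - dh == \
            pytest.approx(0.0, abs=1e-12)


class TestBindingTable:
    def test_packaged_table_has_seven_quantified_rows(self):
        records = load_binding_table()
        assert len(records) == 7
        assert {r.salt_mm for r in records} == {50.0, 150.0}

    def test_all_rows_thermodynamically_consistent(self):
        df = check_table_consistency(load_binding_table(), tolerance=0.1)
        assert df.attrs["all_passed"]
        assert df["residual"].max() <= 0.1

    def test_corrupted_record_fails(self):
        rec = BindingRecord(label="bad", salt_mm=150, kd_nm=244.4, kd_err=11.3,
                            dh_kcal=-7.2, dh_err=0.1, tds_kcal=2.8, tds_err=0.1)
        df = check_table_consistency([rec], tolerance=0.1)
        assert not df.attrs["all_passed"]
        assert df["residual"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_empty_set_passes_vacuously_with_warning(self):
        df = check_table_consistency([])
        assert df.attrs["all_passed"]
        assert "warning" in df.attrs

    def test_salt_weakens_binding_for_both_measured_constructs(self):
        records = load_binding_table()
        by = {(r.label, r.salt_mm): r.kd_nm for r in records}
        assert by[("wt_425-508", 150.0)] > by[("wt_425-508", 50.0)]
        assert by[("S467D_425-508", 150.0)] > by[("S467D_425-508", 50.0)]


class TestFoldChange:
    @pytest.mark.parametrize("num, den, rounding, expected", [
        (244.4, 57.0, "nearest-integer", 4.0),
        (1604.5, 244.4, "nearest-integer", 7.0),
        (386.8, 244.4, "one-decimal", 1.6),
        (100.0, 100.0, "none", 1.0),
    ])
    def test_rounding_conventions(self, num, den, rounding, expected):
        assert fold_change(num, den, rounding) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(10.0, 0.0)


class TestForwardModel:
    def test_zero_enthalpy_gives_zero_heats(self):
        sch = default_schedule()
        heats = predict_heats(ITCParams(n=1.0, kd_nm=100.0, dh_kcal=0.0), sch)
        np.testing.assert_allclose(heats, 0.0, atol=1e-12)

    def test_saturating_first_injection_releases_all_heat(self):
        # one huge injection saturates the cell; later heats are ~0
        sch = ITCSchedule(cell_volume_ml=1.4, cell_conc_um=5.0,
                          syringe_conc_um=50000.0,
                          injection_volumes_ul=np.array([20.0, 10.0, 10.0,
                                                         10.0, 10.0, 10.0]))
        p = ITCParams(n=1.0, kd_nm=1.0, dh_kcal=-8.0)
        heats = predict_heats(p, sch)
        expected_total = 1.0 * 5.0 * 1.4 * -8.0    # n·M0·V0·ΔH in µcal
        assert heats[0] == pytest.approx(expected_total, rel=0.02)
        assert np.abs(heats[1:]).max() < 0.01 * abs(expected_total)

    def test_total_heat_at_saturation_matches_closed_form(self):
        sch = default_schedule()
        p = ITCParams(n=1.0, kd_nm=57.0, dh_kcal=-5.9)
        total = predict_heats(p, sch).sum()
        # displaced-volume bookkeeping: compare against the cumulative-heat
        # closed form at the final composition, not the naive n·M0·V0·ΔH
        assert total == pytest.approx(1.0 * sch.cell_conc_um * sch.cell_volume_ml
                                      * -5.9, rel=0.06)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            ITCSchedule(cell_volume_ml=1.4, cell_conc_um=15.0,
                        syringe_conc_um=175.0,
                        injection_volumes_ul=np.array([5.0]))


class TestFit:
    @pytest.mark.parametrize("kd_nm", [30.0, 300.0, 3000.0])
    def test_noiseless_round_trip_across_c_range(self, kd_nm):
        """Wiseman c from 5 to 500: parameters recovered to better than 1%."""
        sch = default_schedule()
        truth = ITCParams(n=1.0, kd_nm=kd_nm, dh_kcal=-6.0)
        fit = fit_one_site(predict_heats(truth, sch), sch)
        assert fit.n == pytest.approx(1.0, rel=0.01)
        assert fit.kd_nm == pytest.approx(kd_nm, rel=0.01)
        assert fit.dh_kcal == pytest.approx(-6.0, rel=0.01)

    def test_results_object_reports_errors_and_summary(self):
        from relacbp.synthetic import gen_itc
        sch = default_schedule()
        truth = ITCParams(n=1.0, kd_nm=57.0, dh_kcal=-5.9)
        res = OneSiteBindingModel(gen_itc(truth, sch, 0.02, seed=3), sch).fit()
        assert res.params.kd_nm == pytest.approx(57.0, rel=0.3)
        assert np.isfinite(res.bse["kd_nm"]) and res.bse["kd_nm"] > 0
        assert res.c_parameter > 5
        assert "Kd" in res.summary()
        assert res.resid.size == sch.n_injections

    def test_flat_heats_rejected(self):
        sch = default_schedule()
        with pytest.raises(ValueError, match="degenerate"):
            OneSiteBindingModel(np.zeros(sch.n_injections), sch).fit()

    def test_first_injection_excluded_by_default(self):
        sch = default_schedule()
        model = OneSiteBindingModel(np.ones(sch.n_injections), sch)
        assert not model._mask[0] and model._mask[1:].all()
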