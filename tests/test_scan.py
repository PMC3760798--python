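import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from relacbp.scan import (FitResult, ScaleSelectionModel, TimeCourseData,
                          combined_rmsd, load_timecourse_data,
                          normalize_activation, normalize_depletion,
                          save_timecourse_data, scan_total_nfkb,
                          select_best_scale)


class TestNormalization:
    def test_activation_affine_map(self):
        out = normalize_activation([0.2, 0.2, 1.0, 0.6])
        np.testing.assert_allclose(out, [0.0, 0.0, 1.0, 0.5])

    def test_activation_flat_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_activation([0.4, 0.4, 0.4])

    def test_depletion_affine_map(self):
        out = normalize_depletion([1.0, 0.1, 0.55])
        np.testing.assert_allclose(out, [1.0, 0.0, 0.5])

    def test_depletion_without_drop_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_depletion([0.2, 0.5, 0.9])

    def test_depletion_overshoot_above_resting_allowed(self):
        out = normalize_depletion([1.0, 0.0, 1.5])
        assert out[2] == pytest.approx(1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=30))
    def test_activation_idempotent_and_unit_range(self, values):
        x = np.asarray(values)
        if x.max() - x[0] <= 1e-6:
            return
        once = normalize_activation(x)
        np.testing.assert_allclose(normalize_activation(once), once, atol=1e-12)
        assert once[0] == 0.0 and once.max() == pytest.approx(1.0)


class TestCombinedRMSD:
    def test_self_consistency_zero(self, wt_trajectory):
        times = np.array([0.0, 15.0, 30.0, 60.0, 120.0])
        data = []
        for obs, norm in (("nuclear_nfkb", normalize_activation),
                          ("total_ikba", normalize_depletion)):
            series = norm(getattr(wt_trajectory, obs))
            data.append(TimeCourseData(
                observable=obs, times=times,
                values=np.interp(times, wt_trajectory.times, series)))
        assert combined_rmsd(wt_trajectory, data) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_residual_is_the_rmsd(self, wt_trajectory):
        series = normalize_activation(wt_trajectory.nuclear_nfkb)
        d = TimeCourseData(observable="nuclear_nfkb", times=np.array([30.0]),
                           values=np.array([np.interp(30.0, wt_trajectory.times,
                                                      series) + 0.3]))
        assert combined_rmsd(wt_trajectory, [d]) == pytest.approx(0.3)

    def test_pooling_over_both_observables(self, wt_trajectory):
        """Two 3-point series with residuals {0,0,0} and {0.1,0.1,0.1} pool to
        sqrt(3*0.01/6) = 0.0707…"""
        times = np.array([10.0, 40.0, 80.0])
        nf = normalize_activation(wt_trajectory.nuclear_nfkb)
        ik = normalize_depletion(wt_trajectory.total_ikba)
        exact = TimeCourseData(observable="nuclear_nfkb", times=times,
                               values=np.interp(times, wt_trajectory.times, nf))
        off = TimeCourseData(observable="total_ikba", times=times,
                             values=np.interp(times, wt_trajectory.times, ik) + 0.1)
        assert combined_rmsd(wt_trajectory, [exact, off]) == \
            pytest.approx(np.sqrt(0.03 / 6.0), rel=1e-9)

    def test_data_outside_span_rejected(self, wt_trajectory):
        d = TimeCourseData(observable="nuclear_nfkb",
                           times=np.array([1e4]), values=np.array([0.5]))
        with pytest.raises(ValueError, match="span"):
            combined_rmsd(wt_trajectory, [d])


class TestScans:
    def test_identity_scale_matches_plain_simulation(self, kmrna_scan_120,
                                                     params, tnf_curve):
        from relacbp import simulate
        plain = simulate(params, tnf_curve, t_end=120.0, dt_out=1.0)
        np.testing.assert_allclose(
            kmrna_scan_120.trajectories[1.0].states, plain.states,
            rtol=1e-6, atol=1e-12)

    def test_resting_totals_proportional_to_abundance_scale(self, params,
                                                            tnf_curve):
        from relacbp.ode import weighted_nfkb_total
        scan = scan_total_nfkb(params, tnf_curve, scales=(1.0, 0.5),
                               t_end=10.0, dt_out=5.0)
        kv = params.volume_ratio
        w1 = weighted_nfkb_total(scan.trajectories[1.0].states[0], kv)
        w05 = weighted_nfkb_total(scan.trajectories[0.5].states[0], kv)
        assert w05 == pytest.approx(0.5 * w1, rel=1e-6)

    def test_invalid_kmrna_scale_rejected(self, params, tnf_curve):
        from relacbp.scan import scan_kmrna
        with pytest.raises(ValueError):
            scan_kmrna(params, tnf_curve, scales=(1.5,), t_end=10.0)


class TestSelection:
    def test_noiseless_self_recovery(self, kmrna_scan_120, params, tnf_curve):
        from relacbp.synthetic import gen_timecourse
        data = gen_timecourse(params, tnf_curve, 0.25, sigma=0.0,
                              trajectory=kmrna_scan_120.trajectories[0.25])
        fr = select_best_scale(kmrna_scan_120, data)
        assert fr.best_scale == 0.25
        assert fr.rmsd[0.25] == pytest.approx(0.0, abs=1e-9)
        assert not fr.tie

    def test_tie_broken_toward_larger_scale(self, kmrna_scan_120):
        # duplicate the 1.0 trajectory under a second scale label
        from relacbp.scan import ScanResult
        from relacbp.synthetic import gen_timecourse
        t1 = kmrna_scan_120.trajectories[1.0]
        scan = ScanResult(trajectories={0.5: t1, 1.0: t1}, kind="kmrna_scale")
        data = [TimeCourseData(observable="nuclear_nfkb",
                               times=np.array([30.0, 60.0]),
                               values=np.array([0.5, 0.2]))]
        fr = select_best_scale(scan, data)
        assert fr.best_scale == 1.0
        assert fr.tie

    def test_fitresult_rejects_inconsistent_argmin(self):
        with pytest.raises(ValueError):
            FitResult(rmsd={1.0: 0.2, 0.5: 0.1}, best_scale=1.0)

    def test_model_results_object(self, kmrna_scan_120, params, tnf_curve):
        from relacbp.synthetic import gen_timecourse
        data = gen_timecourse(params, tnf_curve, 0.0625, sigma=0.02, seed=5,
                              trajectory=kmrna_scan_120.trajectories[0.0625])
        model = ScaleSelectionModel(data, params, tnf_curve)
        res = model.fit(scan=kmrna_scan_120)
        assert res.best_scale == 0.0625
        assert set(res.rmsd) == {1.0, 0.25, 0.125, 0.0625}
        text = res.summary()
        assert "best" in text and "RMSD" in text
        rep = res.to_report()
        assert rep["best_scale"] == 0.0625


def test_timecourse_file_round_trip(tmp_path):
    data = [TimeCourseData(observable="nuclear_nfkb",
                           times=np.array([0.0, 10.0]),
                           values=np.array([0.0, 0.8])),
            TimeCourseData(observable="total_ikba",
                           times=np.array([0.0, 10.0]),
                           values=np.array([1.0, 0.2]))]
    path = tmp_path / "tc.tsv"
    save_timecourse_data(data, path)
    back = load_timecourse_data(path)
    assert {d.observable for d in back} == {"nuclear_nfkb", "total_ikba"}
    np.testing.assert_allclose(back[0].values, data[0].values)
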