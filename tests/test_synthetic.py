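import numpy as np
import pandas as pd
import pytest

from placentabold.bold_signal import TimeActivityCurve, amplitude_summary, curve_slope, delta_r2star
from placentabold.errors import GeometryError, ValidationError
from placentabold.io import VolumeSeries
from placentabold.synthetic import (
    CohortSpec,
    CompartmentParams,
    VoxelTruth,
    delta_r2star_model,
    generate_cohort,
    generate_phantom,
    response_fraction,
    simulate_dhb,
    simulate_voxel_series,
)


class TestCompartmentModel:
    def test_pre_arrival_dhb_is_zero(self, paradigm):
        out = simulate_dhb(paradigm, CompartmentParams(), VoxelTruth(delta=2.0))
        pre = out["t"] < paradigm.hyperoxia_start + 2.0
        np.testing.assert_array_equal(out["dhb_m"][pre], 0.0)
        np.testing.assert_array_equal(out["dhb_f"][pre], 0.0)

    def test_dhb_falls_during_hyperoxia(self, paradigm):
        out = simulate_dhb(paradigm, CompartmentParams(), VoxelTruth())
        hyper = (out["t"] > paradigm.hyperoxia_start + 1) & (out["t"] < paradigm.hyperoxia_end)
        assert np.all(out["dhb_m"][hyper] < 0) and np.all(out["dhb_f"][hyper] < 0)

    def test_calibration_identity(self, paradigm):
        comp = CompartmentParams()
        truth = VoxelTruth(alpha=1.5, beta=1.2, delta=0.0, c2=9.83)
        out = simulate_dhb(paradigm, comp, truth)
        # compartment-weighted sum reproduces c2 * g(t) everywhere ...
        weighted = -comp.r2star_relaxivity * (comp.v_f * out["dhb_f"] + comp.v_m * out["dhb_m"])
        g = response_fraction(truth, out["t"], paradigm)
        np.testing.assert_allclose(weighted, truth.c2 * g, atol=1e-12)
        # ... and equals c2 at plateau (fast kinetics reach g ~ 1)
        assert weighted.max() == pytest.approx(truth.c2, rel=1e-3)

    def test_zero_fetal_volume_contributes_nothing(self, paradigm):
        comp = CompartmentParams(v_f=0.0)
        out = simulate_dhb(paradigm, comp, VoxelTruth())
        maternal_only = -comp.r2star_relaxivity * comp.v_m * out["dhb_m"]
        np.testing.assert_allclose(out["delta_r2star"], maternal_only, atol=1e-12)

    def test_plateau_below_baseline_rejected(self):
        with pytest.raises(ValidationError):
            CompartmentParams(sat_m_plateau=0.5)


class TestVoxelSeries:
    def test_noiseless_roundtrip_through_delta_r2star(self, paradigm):
        truth = VoxelTruth(alpha=2.0, beta=2.0, delta=1.0, c2=9.83)
        sim = simulate_voxel_series(truth, paradigm, te=0.035, s_baseline=100.0)
        vs = VolumeSeries(data=sim["signal"][None, None, None, :], tr=6.0, te=0.035)
        d = delta_r2star(vs, np.full((1, 1, 1), 100.0), paradigm=paradigm)
        np.testing.assert_allclose(d.data[0, 0, 0], sim["model_delta_r2star"], atol=1e-12)

    def test_zero_amplitude_is_constant_baseline(self, paradigm):
        sim = simulate_voxel_series(VoxelTruth(c2=0.0), paradigm, s_baseline=77.0)
        np.testing.assert_array_equal(sim["signal"], 77.0)

    def test_seeded_determinism(self, paradigm):
        a = simulate_voxel_series(VoxelTruth(), paradigm, noise_sd=2.0, seed=9)
        b = simulate_voxel_series(VoxelTruth(), paradigm, noise_sd=2.0, seed=9)
        np.testing.assert_array_equal(a["signal"], b["signal"])

    def test_floor_clipping_flagged(self, paradigm):
        sim = simulate_voxel_series(VoxelTruth(c2=0.0), paradigm, s_baseline=1.0, noise_sd=50.0, seed=0)
        assert sim["clipped"].any()
        assert np.all(sim["signal"] > 0)


class TestPhantom:
    def test_uniform_truth_constant_over_placenta(self):
        _, rois, truth = generate_phantom(shape=(16, 16, 8), spatial_ttp_field="uniform", seed=1)
        placenta = (rois.labels == 1) | (rois.labels == 2)
        assert np.nanstd(truth["ttp"][placenta]) == 0.0

    def test_pathological_patch_offset_by_construction(self):
        _, rois, truth = generate_phantom(
            shape=(32, 32, 8), spatial_ttp_field="pathological_patch", seed=1, patch_offset=3.0
        )
        placenta = (rois.labels == 1) | (rois.labels == 2)
        patch = truth["patch"]
        bg = placenta & ~patch
        assert truth["ttp"][patch].mean() - truth["ttp"][bg].mean() == pytest.approx(3.0)

    def test_cotyledon_field_varies_smoothly(self):
        _, rois, truth = generate_phantom(shape=(24, 24, 8), spatial_ttp_field="cotyledon", seed=2)
        placenta = (rois.labels == 1) | (rois.labels == 2)
        vals = truth["ttp"][placenta]
        assert vals.std() > 0.1 and np.all(vals > 0)

    def test_seeded_determinism(self):
        s1, _, t1 = generate_phantom(shape=(12, 12, 8), seed=3, noise_sd=1.0)
        s2, _, t2 = generate_phantom(shape=(12, 12, 8), seed=3, noise_sd=1.0)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(t1["ttp"], t2["ttp"])

    def test_too_small_grid_rejected(self):
        with pytest.raises(GeometryError):
            generate_phantom(shape=(6, 6, 6))


class TestCohort:
    def test_exact_plateau_amplitude_with_zero_sd(self, paradigm):
        spec = CohortSpec(n_pairs=2, amp_sd_aga=0.0, amp_sd_sga=0.0, slope_sd=0.0, noise_sd=0.0)
        co = generate_cohort(spec, paradigm, seed=0)
        for sid in co.records[co.records.group == "AGA"].subject_id:
            y = co.curves[(sid, "placenta")]
            c = TimeActivityCurve("placenta_twinA", co.t, y, np.zeros_like(y), 1)
            assert amplitude_summary(c, paradigm)["last2min_mean"] == pytest.approx(9.83, abs=1e-9)

    def test_organ_amplitude_ratio(self, paradigm):
        spec = CohortSpec(n_pairs=1, amp_sd_aga=0.0, amp_sd_sga=0.0, slope_sd=0.0, noise_sd=0.0)
        co = generate_cohort(spec, paradigm, seed=0)
        pl = np.max(np.abs(co.curves[("P01A", "placenta")]))
        liver = np.max(np.abs(co.curves[("P01A", "liver")]))
        brain = np.max(np.abs(co.curves[("P01A", "brain")]))
        assert liver == pytest.approx(pl / 2, rel=1e-9)
        assert brain == pytest.approx(pl / 6, rel=1e-9)

    def test_operational_slope_matches_drawn_slope(self, paradigm):
        spec = CohortSpec(n_pairs=2, amp_sd_aga=0.0, amp_sd_sga=0.0, slope_sd=0.0, noise_sd=0.0)
        co = generate_cohort(spec, paradigm, seed=0)
        for sid, group in zip(co.records.subject_id, co.records.group):
            y = co.curves[(sid, "placenta")]
            c = TimeActivityCurve("placenta_twinA", co.t, y, np.zeros_like(y), 1)
            target = 1.89 if group == "AGA" else 0.88
            assert curve_slope(c, paradigm.hyperoxia_start) == pytest.approx(target, rel=1e-3)

    def test_seeded_determinism(self, paradigm):
        a = generate_cohort(CohortSpec(n_pairs=7), paradigm, seed=4)
        b = generate_cohort(CohortSpec(n_pairs=7), paradigm, seed=4)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_sampled_parameters_respect_invariants(self, paradigm):
        co = generate_cohort(CohortSpec(n_pairs=10), paradigm, seed=6)
        assert (co.truth.alpha >= 1).all()
        assert (co.truth.beta >= 1).all()
        assert (co.truth.delta >= 0).all()
        assert (co.truth.c2 > 0).all()
        assert (co.records.birth_weight > 0).all()
        assert co.records.weight_percentile.between(0, 100).all()

    def test_birth_weight_decreases_with_ttp(self, paradigm):
        co = generate_cohort(CohortSpec(n_pairs=20), paradigm, seed=7)
        r = np.corrcoef(co.records.ttp_true, co.records.birth_weight)[0, 1]
        assert r < -0.3

    def test_longer_ttp_more_moderate_findings(self, paradigm):
        co = generate_cohort(CohortSpec(n_pairs=40), paradigm, seed=8)
        n_mod = co.records.findings.fillna("").str.count("moderate")
        long = co.records.ttp_true > co.records.ttp_true.median()
        assert n_mod[long].mean() > n_mod[~long].mean()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_pairs=0)
        with pytest.raises(ValidationError):
            CohortSpec(noise_sd=-1.0)
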