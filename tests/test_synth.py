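"""Synthetic phantom and cohort generator: determinism, noise, design."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from dceus.bolus import derived_params, lognormal_model
from dceus.synth import (
    CohortSpec,
    apply_necrosis,
    generate_cohorts,
    generate_phantom,
    simulate_bolus_4d,
    truth_for_day,
)


class TestPhantom:
    def test_same_seed_bit_identical(self):
        a = generate_phantom(seed=42, shape_zyx=(12, 12, 12))
        b = generate_phantom(seed=42, shape_zyx=(12, 12, 12))
        np.testing.assert_array_equal(a.auc_field, b.auc_field)
        np.testing.assert_array_equal(a.t0_field, b.t0_field)
        assert a.mvd_truth == b.mvd_truth

    def test_large_heterogeneity_scale_flattens_fields(self):
        rough = generate_phantom(seed=1, shape_zyx=(16, 16, 16),
                                 heterogeneity_scale=2.0)
        flat = generate_phantom(seed=1, shape_zyx=(16, 16, 16),
                                heterogeneity_scale=200.0)
        assert (flat.auc_field[flat.mask].var()
                < 0.01 * rough.auc_field[rough.mask].var())

    def test_field_invariants(self, small_phantom):
        p = small_phantom
        assert p.mask.any()
        assert np.all(p.sigma_field[p.mask] > 0)
        assert np.all(p.auc_field >= 0) and np.all(p.t0_field >= 0)

    @pytest.mark.parametrize("kwargs", [
        {"shape_zyx": (4, 12, 12)},
        {"heterogeneity_scale": 0.0},
        {"heterogeneity_scale": -1.0},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_phantom(**kwargs)

    def test_mvd_tracks_mean_perfusion_across_phantoms(self):
        """The synthetic histology link: MVD rank-correlates with mean AUC."""
        mvd, mean_auc = [], []
        for seed in range(200):
            p = generate_phantom(seed=seed, shape_zyx=(12, 12, 12))
            mvd.append(p.mvd_truth)
            mean_auc.append(p.auc_field[p.mask].mean())
        rho = sps.spearmanr(mvd, mean_auc).statistic
        assert rho > 0.7

    def test_necrosis_zeroes_auc(self, small_phantom):
        nec = apply_necrosis(small_phantom, 0.3)
        assert nec.necrosis_mask.sum() > 0
        assert np.all(nec.auc_field[nec.necrosis_mask] == 0.0)
        frac = nec.necrosis_mask.sum() / nec.mask.sum()
        assert frac == pytest.approx(0.3, abs=0.1)


class TestSimulate:
    def test_noiseless_voxel_equals_analytic_model(self, noiseless_dataset):
        vol, truth, spec = noiseless_dataset
        idx = np.argwhere(truth.mask)[5]
        z, y, x = idx
        expected = lognormal_model(spec.frame_times_s,
                                   truth.auc_field[z, y, x],
                                   truth.mu_field[z, y, x],
                                   truth.sigma_field[z, y, x],
                                   truth.t0_field[z, y, x])
        np.testing.assert_allclose(vol[:, z, y, x], expected, atol=1e-12)

    def test_necrotic_voxels_at_background_level(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12), noise_level=0.05,
                          scale_jitter_sigma=0.0, duration_s=60.0)
        nec_truth = apply_necrosis(small_phantom, 0.2)
        vol = simulate_bolus_4d(nec_truth, spec, seed=5)
        perfused = nec_truth.mask & ~nec_truth.necrosis_mask
        background = np.abs(vol[:, ~nec_truth.mask]).mean()
        nec_mean = vol[:, nec_truth.necrosis_mask].mean()
        assert nec_mean <= 3 * background + 1e-12
        assert vol[:, perfused].mean() > 10 * nec_mean

    def test_gaussian_noise_has_nominal_amplitude(self, small_phantom):
        """Empirical noise SD within 20% of the injected sigma per voxel."""
        spec = CohortSpec(shape_zyx=(12, 12, 12), noise_level=0.05,
                          scale_jitter_sigma=0.0, duration_s=60.0)
        clean = simulate_bolus_4d(small_phantom, replace(spec, noise_level=0.0),
                                  seed=9)
        noisy = simulate_bolus_4d(small_phantom, spec, seed=9)
        m = small_phantom.mask
        pe, _, _ = derived_params(small_phantom.auc_field[m],
                                  small_phantom.mu_field[m],
                                  small_phantom.sigma_field[m],
                                  small_phantom.t0_field[m])
        resid = (noisy - clean)[:, m]
        cl = clean[:, m]
        ratios = []
        for i in range(min(100, cl.shape[1])):
            # avoid clipped samples: use frames with strong clean signal
            frames = cl[:, i] > 3 * 0.05 * pe[i]
            if frames.sum() < 20:
                continue
            nominal = 0.05 * pe[i] + 0.02 * float(np.median(pe))
            ratios.append(resid[frames, i].std() / nominal)
        ratios = np.array(ratios)
        assert np.mean(np.abs(ratios - 1.0) < 0.2) > 0.8

    def test_intensities_nonnegative(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12), noise_level=0.2,
                          duration_s=60.0)
        vol = simulate_bolus_4d(small_phantom, spec, seed=2)
        assert np.all(vol >= 0)

    def test_gamma_speckle_model_runs(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12), duration_s=60.0,
                          noise_model="multiplicative_gamma", noise_level=0.1)
        vol = simulate_bolus_4d(small_phantom, spec, seed=2)
        assert np.all(np.isfinite(vol)) and vol.max() > 0


class TestTreatmentModel:
    def test_attenuation_monotone_in_effect(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12))
        means = []
        for e in (0.1, 0.3, 0.5):
            t1 = truth_for_day(small_phantom, replace(spec, responder_effect=e),
                               "treated", True, 1)
            means.append(t1.auc_field[t1.mask].mean())
        assert means[0] > means[1] > means[2]

    def test_control_and_nonresponder_unchanged(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12))
        ctrl = truth_for_day(small_phantom, spec, "control", True, 10)
        np.testing.assert_array_equal(ctrl.auc_field, small_phantom.auc_field)
        nr = truth_for_day(small_phantom, spec, "treated", False, 10)
        np.testing.assert_array_equal(nr.auc_field, small_phantom.auc_field)

    def test_rim_attenuated_more_than_core(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12), necrosis_growth=0.0)
        t1 = truth_for_day(small_phantom, spec, "treated", True, 1)
        ratio = t1.auc_field / np.where(small_phantom.auc_field > 0,
                                        small_phantom.auc_field, 1.0)
        from dceus.synth import _radius_field

        r = _radius_field(small_phantom.shape_zyx)
        core = small_phantom.mask & (r < 0.4)
        rim = small_phantom.mask & (r > 0.8)
        assert ratio[core].mean() > ratio[rim].mean()

    def test_late_day_necrosis_only_in_treated_responders(self, small_phantom):
        spec = CohortSpec(shape_zyx=(12, 12, 12), necrosis_growth=0.1)
        late = truth_for_day(small_phantom, spec, "treated", True, 10)
        assert late.necrosis_mask.sum() > 0
        ctrl = truth_for_day(small_phantom, spec, "control", True, 10)
        assert ctrl.necrosis_mask.sum() == 0


@pytest.fixture(scope="module")
def tiny_spec():
    return CohortSpec(n_per_group=2, shape_zyx=(12, 12, 12),
                      days=(0, 1, 3), duration_s=60.0, frame_rate_hz=1.0,
                      seed=3)


class TestCohorts:
    def test_manifest_counts(self):
        spec = CohortSpec(n_per_group=10)
        man = generate_cohorts(spec).manifest
        a = man[man.cohort == "A"]
        assert len(a) == 10 * 2 * 5  # n x {treated,control} x days
        assert len(man[man.cohort == "C"]) == 2 * 10 * 2  # subjects x replicates
        assert set(man.columns) >= {"subject", "day", "cohort", "arm",
                                    "replicate", "mvd"}

    def test_generation_is_deterministic(self, tiny_spec):
        c1 = generate_cohorts(tiny_spec)
        c2 = generate_cohorts(tiny_spec)
        d1 = next(c1.datasets("A"))
        d2 = next(c2.datasets("A"))
        np.testing.assert_array_equal(d1.volume4d, d2.volume4d)

    def test_retest_pair_shares_truth_differs_in_noise(self, tiny_spec):
        it = generate_cohorts(tiny_spec).datasets("C")
        r1, r2 = next(it), next(it)
        assert r1.subject_id == r2.subject_id
        assert (r1.replicate, r2.replicate) == (1, 2)
        np.testing.assert_array_equal(r1.truth.auc_field, r2.truth.auc_field)
        assert not np.array_equal(r1.volume4d, r2.volume4d)

    def test_null_effects_make_arms_exchangeable(self):
        """With no treatment effect, treated and control day-1 mean AUC
        distributions coincide (two-sample KS at the truth level)."""
        spec = CohortSpec(n_per_group=10, shape_zyx=(12, 12, 12),
                          responder_effect=0.0, necrosis_growth=0.0, seed=5)
        man = generate_cohorts(spec).manifest
        means = {"treated": [], "control": []}
        from dceus.synth import _subject_truth

        sub = man[(man.cohort == "A") & (man.day == 1)]
        for _, row in sub.iterrows():
            truth = _subject_truth(spec, "A", row.subject_index)
            t1 = truth_for_day(truth, spec, row.arm, True, 1)
            means[row.arm].append(t1.auc_field[t1.mask].mean())
        p = sps.ks_2samp(means["treated"], means["control"]).pvalue
        assert p > 0.01

    def test_mvd_lower_in_treated_cohort_d(self, tiny_spec):
        spec = replace(tiny_spec, n_per_group=10)
        man = generate_cohorts(spec).manifest
        d1 = man[(man.cohort == "D") & (man.day == 1)]
        treated = d1[d1.arm == "treated"]["mvd"].to_numpy(float)
        control = d1[d1.arm == "control"]["mvd"].to_numpy(float)
        assert np.median(treated) < np.median(control)

    def test_write_round_trip(self, tiny_spec, tmp_path):
        import json

        import nibabel as nib

        spec = replace(tiny_spec, days=(0, 1), n_per_group=2)
        coll = generate_cohorts(spec)
        out = coll.write(tmp_path / "study")
        man_path = out / "manifest.csv"
        assert man_path.exists()
        ds = next(coll.datasets("A"))
        stem = f"A_{ds.subject_id}_d{ds.day}_r1"
        img = nib.load(out / f"{stem}_vol.nii.gz")
        assert img.shape[3] == ds.frame_times_s.size
        times = json.loads((out / f"{stem}_times.json").read_text())
        assert len(times["frame_times_s"]) == ds.frame_times_s.size

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(responder_effect=1.5)
        with pytest.raises(ValueError):
            CohortSpec(noise_model="poisson")
        with pytest.raises(ValueError):
            generate_cohorts(CohortSpec(n_per_group=1))
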