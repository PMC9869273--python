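"""Minimum-norm inverse and ROI-level effect recovery."""

import numpy as np
import pytest

from olfactomap.atlas import ROI, SourceAtlas
from olfactomap.forward import default_sensor_array
from olfactomap.paradigm import ConditionLabel, EpochProvenance, EpochSet, build_schedule, extract_epochs
from olfactomap.simulate import (
    BandComponent,
    ModulationSpec,
    NoiseSpec,
    simulate_recording,
)
from olfactomap.sourcemap import (
    apply_inverse_epochs,
    compute_inverse,
    roi_band_power,
    roi_change_map,
)

P, A, R = ConditionLabel.PEA, ConditionLabel.AMYL_ACETATE, ConditionLabel.REST


def make_epochs(data3d, rate=100.0, condition=P):
    prov = [EpochProvenance(0, i, 0.0) for i in range(data3d.shape[0])]
    return EpochSet(condition, data3d.shape[2] / rate, rate, np.asarray(data3d, float), prov)


class TestComputeInverse:
    def test_identity_leadfield_small_lambda(self):
        inv = compute_inverse(np.eye(4), 1e-12)
        np.testing.assert_allclose(inv.matrix, np.eye(4), atol=1e-10)

    def test_orthogonal_leadfield_zero_lambda(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        inv = compute_inverse(q, 0.0)
        np.testing.assert_allclose(inv.matrix, q.T, atol=1e-12)

    def test_well_conditioned_inverse_times_leadfield_near_identity(self, rng):
        lf = rng.normal(size=(12, 6))
        inv = compute_inverse(lf, 1e-6)
        resolution = inv.matrix @ lf
        pinv_oracle = np.linalg.pinv(lf) @ lf
        np.testing.assert_allclose(resolution, pinv_oracle, atol=1e-3)
        np.testing.assert_allclose(resolution, np.eye(6), atol=1e-3)

    def test_rank_deficient_zero_lambda_advises_regularization(self):
        lf = np.zeros((4, 3))
        lf[:2, :] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="λ > 0"):
            compute_inverse(lf, 0.0)

    def test_non_finite_leadfield_rejected(self):
        lf = np.ones((3, 2))
        lf[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            compute_inverse(lf)


class TestApplyInverse:
    def test_identity_inverse_keeps_epochs(self, rng):
        eps = make_epochs(rng.normal(size=(3, 4, 50)))
        inv = compute_inverse(np.eye(4), 1e-12)
        out = apply_inverse_epochs(eps, inv)
        np.testing.assert_allclose(out.epochs, eps.epochs, atol=1e-9)
        assert out.provenance == eps.provenance

    def test_zero_epochs_in_zero_out(self):
        eps = make_epochs(np.empty((0, 4, 50)))
        inv = compute_inverse(np.eye(4), 1e-12)
        assert len(apply_inverse_epochs(eps, inv)) == 0

    def test_linearity(self, rng):
        eps = make_epochs(rng.normal(size=(2, 4, 30)))
        scaled = make_epochs(5.0 * eps.epochs)
        inv = compute_inverse(rng.normal(size=(4, 3)), 1e-6)
        np.testing.assert_allclose(
            apply_inverse_epochs(scaled, inv).epochs,
            5.0 * apply_inverse_epochs(eps, inv).epochs,
            rtol=1e-12,
        )

    def test_channel_mismatch_rejected(self, rng):
        eps = make_epochs(rng.normal(size=(2, 5, 30)))
        inv = compute_inverse(np.eye(4), 1e-12)
        with pytest.raises(ValueError, match="channels"):
            apply_inverse_epochs(eps, inv)


class TestRoiBandPower:
    def atlas(self):
        return SourceAtlas(
            (
                ROI("one", np.array([[0.0, 0.03, 0.05]]), np.array([[1.0, 0, 0]])),
                ROI("two", np.array([[0.0, -0.03, 0.05], [0.005, -0.03, 0.05]]),
                    np.array([[1.0, 0, 0], [1.0, 0, 0]])),
            )
        )

    def test_single_point_roi_equals_source_band_power(self, rng):
        atlas = self.atlas()
        data = rng.normal(size=(6, 3, 100))
        eps = {R: make_epochs(data, condition=R)}
        maps = roi_band_power(eps, atlas)
        from olfactomap.spectral import DEFAULT_BANDS, band_power, condition_spectrum

        spec = condition_spectrum(eps[R])
        alpha = band_power(spec, DEFAULT_BANDS[2])
        assert maps["REST"].absolute[0, 2] == pytest.approx(alpha[0])
        assert maps["REST"].absolute[1, 2] == pytest.approx(alpha[1:].mean())

    def test_duplicated_point_leaves_mean_unchanged(self, rng):
        data = rng.normal(size=(4, 1, 100))
        single = SourceAtlas(
            (ROI("r", np.array([[0.0, 0.03, 0.05]]), np.array([[1.0, 0, 0]])),)
        )
        double = SourceAtlas(
            (ROI("r", np.tile([0.0, 0.03, 0.05], (2, 1)), np.tile([1.0, 0, 0], (2, 1))),)
        )
        m1 = roi_band_power({R: make_epochs(data, condition=R)}, single)
        m2 = roi_band_power(
            {R: make_epochs(np.repeat(data, 2, axis=1), condition=R)}, double
        )
        np.testing.assert_allclose(m1["REST"].absolute, m2["REST"].absolute, rtol=1e-12)

    def test_source_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="sources"):
            roi_band_power(
                {R: make_epochs(rng.normal(size=(2, 7, 100)), condition=R)}, self.atlas()
            )


def spaced_single_source_atlas():
    """One tangential source per ROI, well separated."""
    positions = {
        "olfactory_L": (-0.02, 0.03, -0.02),
        "somatosensory_R": (0.04, -0.02, 0.07),
        "precentral_L": (-0.04, 0.01, 0.065),
    }
    rois = []
    for label, pos in positions.items():
        pos = np.asarray(pos)
        t = np.cross(pos, [0, 0, 1.0])
        t = t / np.linalg.norm(t)
        rois.append(ROI(label, pos[None, :], t[None, :]))
    return SourceAtlas(tuple(rois))


def alpha_spec(labels, mods):
    comps = {}
    for label in labels:
        comps[label] = (BandComponent("alpha", 10.0, 4.0, 1e-8, mods.get(label, {})),)
    return ModulationSpec(comps)


class TestEndToEndRecovery:
    def test_noiseless_single_sources_recover_injected_ratio_within_1pct(self):
        """With the true leadfield, no noise, and one source per ROI, the
        recovered stimulation/rest source-power ratio matches the injected
        modulation to 1% relative."""
        atlas = spaced_single_source_atlas()
        schedule = build_schedule(n_runs=4)
        array = default_sensor_array(32)
        mods = {
            "olfactory_L": {P: 40.0, A: 40.0},
            "somatosensory_R": {P: -30.0, A: -30.0},
        }
        spec = alpha_spec(atlas.labels, mods)
        quiet = NoiseSpec(std_by_type={"magnetometer": 0.0})
        rec, lf = simulate_recording(
            schedule, atlas, spec, array, noise=quiet, sampling_rate=250.0, seed=4
        )
        inv = compute_inverse(lf, 1e-10)
        src = {
            c: apply_inverse_epochs(extract_epochs(rec, schedule, c), inv)
            for c in (P, A, R)
        }
        maps = roi_band_power(src, atlas)
        # oracle: band power of the raw source timecourses, epoch for epoch
        from olfactomap.simulate import simulate_source_timecourses
        from olfactomap.forward import SensorArray
        from olfactomap.recording import SensorRecording

        seeds = np.random.SeedSequence(4).spawn(2)
        truth = simulate_source_timecourses(atlas, spec, schedule, 250.0, seeds[0])
        n = truth.shape[0]
        stub = SensorArray(
            np.tile([0, 0, 0.2], (n, 1)) + np.arange(n)[:, None] * [1e-3, 0, 0],
            np.tile([0, 0, 1.0], (n, 1)), ["magnetometer"] * n,
        )
        truth_rec = SensorRecording(truth, 250.0, stub)
        truth_src = {
            c: extract_epochs(truth_rec, schedule, c) for c in (P, A, R)
        }
        truth_maps = roi_band_power(truth_src, atlas)
        for roi_idx in range(3):
            got = maps["PEA"].absolute[roi_idx, 2] / maps["REST"].absolute[roi_idx, 2]
            want = (
                truth_maps["PEA"].absolute[roi_idx, 2]
                / truth_maps["REST"].absolute[roi_idx, 2]
            )
            assert got == pytest.approx(want, rel=0.01)

    def test_roi_change_map_flags_injected_effects(self):
        atlas = spaced_single_source_atlas()
        schedule = build_schedule(n_runs=4)
        array = default_sensor_array(32)
        mods = {"olfactory_L": {P: 60.0, A: 60.0}}
        spec = alpha_spec(atlas.labels, mods)
        quiet = NoiseSpec(std_by_type={"magnetometer": 0.0})
        rec, lf = simulate_recording(
            schedule, atlas, spec, array, noise=quiet, sampling_rate=250.0, seed=9
        )
        inv = compute_inverse(lf, 1e-10)
        src = {
            c: apply_inverse_epochs(extract_epochs(rec, schedule, c), inv)
            for c in (P, A, R)
        }
        cmap = roi_change_map(roi_band_power(src, atlas))
        change, sig = cmap.entry("olfactory_L", "alpha", "PEA")
        assert sig and change > 20
        # the unmodulated ROIs stay quiet in a noiseless matched setting
        for roi in ("somatosensory_R", "precentral_L"):
            _, other_sig = cmap.entry(roi, "alpha", "PEA")
            assert not other_sig

    def test_recovered_change_invariant_to_global_sensor_gain(self):
        atlas = spaced_single_source_atlas()
        schedule = build_schedule(n_runs=1)
        array = default_sensor_array(32)
        spec = alpha_spec(atlas.labels, {"olfactory_L": {P: 40.0}})
        quiet = NoiseSpec(std_by_type={"magnetometer": 0.0})
        rec, lf = simulate_recording(
            schedule, atlas, spec, array, noise=quiet, sampling_rate=250.0, seed=5
        )
        inv = compute_inverse(lf, 1e-10)

        def recovered(gain):
            scaled = type(rec)(gain * rec.data, rec.sampling_rate, rec.array)
            src = {
                c: apply_inverse_epochs(extract_epochs(scaled, schedule, c), inv)
                for c in (P, A, R)
            }
            return roi_change_map(roi_band_power(src, atlas)).changes["PEA"]

        np.testing.assert_allclose(recovered(1.0), recovered(250.0), rtol=1e-9)
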