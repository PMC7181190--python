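import dataclasses

import numpy as np
import pytest

from nervect.phantom import (PIG_PROFILE, RAT_PROFILE, FascicleEvent, FascicleSpec,
                             PhantomSpec, TissueClass, add_movement_artefact,
                             build_phantom, example_nerve_spec, parallel_tubes_spec,
                             staining_contrast_model)
from nervect.phantom import _translate_slice
from nervect.volume import Volume


class TestGeometry:
    def test_four_straight_tubes_give_four_full_tracks(self):
        spec = parallel_tubes_spec(n_tubes=4, noise_sd=0.0, shape=(96, 96, 20))
        res = build_phantom(spec)
        ids = set(np.unique(res.instance_labels)) - {0}
        assert ids == {1, 2, 3, 4}
        for t in res.truth_tracks:
            assert [r.z for r in t.records] == list(range(20))

    def test_truth_area_matches_instance_label_count(self, example_result):
        vox_area = example_result.spec_echo.voxel_size_um ** 2
        for t in example_result.truth_tracks:
            for rec in t.records[::37]:
                n = int((example_result.instance_labels[rec.z] == t.id).sum())
                assert rec.area_um2 == pytest.approx(n * vox_area)

    def test_label_intensity_consistency_when_noise_free(self, noise_free_result):
        res = noise_free_result
        means = res.spec_echo.tissue_means
        for tc in TissueClass:
            sel = res.tissue_labels == int(tc)
            if sel.any():
                assert np.all(res.volume.data[sel] == means[tc])

    def test_all_five_tissue_classes_present(self, example_result):
        present = set(np.unique(example_result.tissue_labels))
        assert present == {int(tc) for tc in TissueClass}

    def test_seed_determinism_bit_identical(self):
        spec = parallel_tubes_spec(noise_sd=0.02, rng_seed=5, shape=(64, 64, 8))
        a, b = build_phantom(spec), build_phantom(spec)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.instance_labels, b.instance_labels)

    def test_resolution_scaling_doubles_voxel_diameter(self):
        # same physical tube rasterized at 4 um and 2 um voxels
        diam = {}
        for vox in (4.0, 2.0):
            shape = (int(96 * 4 / vox), int(96 * 4 / vox), 4)
            spec = parallel_tubes_spec(n_tubes=1, radius_um=32.0, shape=shape,
                                       voxel_size_um=vox, noise_sd=0.0)
            res = build_phantom(spec)
            row = (res.instance_labels[2] == 1).sum(axis=1).max()
            diam[vox] = int(row)
        assert abs(diam[2.0] - 2 * diam[4.0]) <= 2

    def test_undeclared_overlap_rejected(self):
        fs = (FascicleSpec(1, 30.0, (0.0, 0.0)), FascicleSpec(2, 30.0, (20.0, 0.0)))
        spec = PhantomSpec(shape=(96, 96, 6), fascicles=fs, noise_sd=0.0)
        with pytest.raises(ValueError, match="overlap.*without a declared"):
            build_phantom(spec)

    def test_fascicle_outside_epineurium_rejected(self):
        fs = (FascicleSpec(1, 30.0, (200.0, 0.0)),)
        spec = PhantomSpec(shape=(96, 96, 6), fascicles=fs, noise_sd=0.0)
        with pytest.raises(ValueError, match="epineurium"):
            build_phantom(spec)

    def test_unresolvable_radius_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            PhantomSpec(shape=(64, 64, 6), fascicles=(FascicleSpec(1, 6.0),))

    def test_event_z_outside_volume_rejected(self):
        fs = (FascicleSpec(1, 20.0, (0.0, 0.0),
                           events=(FascicleEvent("branch", 9999.0, (2, 3)),)),
              FascicleSpec(2, 16.0, (-40.0, 0.0)), FascicleSpec(3, 16.0, (40.0, 0.0)))
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(shape=(96, 96, 10), fascicles=fs)


class TestGreyStatistics:
    def test_reported_class_means_recovered(self):
        # adipocytes 0.92 +- 0.03 and sponge/air 0.18 +- 0.04 on the 0-1 scale
        spec = parallel_tubes_spec(noise_sd=0.0, rng_seed=3, shape=(96, 96, 30))
        spec = dataclasses.replace(spec, n_adipocytes=10, adipocyte_radius_um=32.0)
        res = build_phantom(spec)
        for tc, mean in ((TissueClass.ADIPOCYTE, 0.92), (TissueClass.SPONGE_AIR, 0.18)):
            vals = res.volume.data[res.tissue_labels == int(tc)]
            assert vals.size >= 10_000
            assert vals.mean() == pytest.approx(mean, abs=0.01)


class TestStainingModel:
    @pytest.mark.parametrize("profile", [RAT_PROFILE, PIG_PROFILE])
    def test_day_zero_anchor(self, profile):
        means = staining_contrast_model(0.0, profile)
        assert abs(means[TissueClass.FASCICLE] - means[TissueClass.EPINEURIUM]) <= 0.05

    @pytest.mark.parametrize("profile", [RAT_PROFILE, PIG_PROFILE])
    def test_spread_peaks_at_optimum_day(self, profile):
        soft = (TissueClass.FASCICLE, TissueClass.EPINEURIUM, TissueClass.ADIPOCYTE)

        def spread(day):
            m = staining_contrast_model(day, profile)
            vals = [m[t] for t in soft]
            return max(vals) - min(vals)

        days = list(range(14))
        spreads = [spread(d) for d in days]
        assert days[int(np.argmax(spreads))] == profile.optimum_day

    def test_spread_decays_toward_plateau_after_optimum(self):
        soft = (TissueClass.FASCICLE, TissueClass.EPINEURIUM, TissueClass.ADIPOCYTE)
        prev = None
        for day in (1, 3, 6, 12, 24, 48):
            m = staining_contrast_model(day, RAT_PROFILE)
            vals = [m[t] for t in soft]
            s = max(vals) - min(vals)
            if prev is not None:
                assert s < prev
            prev = s
        assert prev == pytest.approx(0.04, abs=0.01)  # baseline spread

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            staining_contrast_model(-1.0)


class TestMovementArtefact:
    def test_zero_shift_is_identity(self):
        vol = Volume(np.random.default_rng(0).random((10, 16, 16)))
        out = add_movement_artefact(vol, 0, 0.5, seed=1)
        assert np.array_equal(out.data, vol.data)

    def test_zero_fraction_is_identity(self):
        vol = Volume(np.random.default_rng(0).random((10, 16, 16)))
        out = add_movement_artefact(vol, 3, 0.0, seed=1)
        assert np.array_equal(out.data, vol.data)

    def test_constructed_shift_recovered_by_phase_correlation(self):
        rng = np.random.default_rng(2)
        base = rng.random((16, 16))
        shifted = _translate_slice(base, 2, 0, fill=0.18)
        # phase-correlation oracle on the unvacated interior
        f = np.fft.fft2(base) * np.conj(np.fft.fft2(shifted))
        corr = np.fft.ifft2(f / np.abs(f)).real
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        assert peak == (14, 0)  # -2 mod 16 in y, 0 in x

    def test_affected_run_is_contiguous(self):
        vol = Volume(np.random.default_rng(3).random((40, 12, 12)))
        out = add_movement_artefact(vol, 2, 0.25, seed=9)
        changed = [z for z in range(40) if not np.array_equal(out.data[z], vol.data[z])]
        assert changed == list(range(min(changed), max(changed) + 1))
        assert len(changed) <= 10

    def test_shift_exceeding_extent_rejected(self):
        vol = Volume(np.zeros((4, 8, 8)))
        with pytest.raises(ValueError, match="extent"):
            add_movement_artefact(vol, 8, 0.5, seed=0)


class TestSaveLoad:
    def test_save_phantom_roundtrips_spec(self, tmp_path):
        import yaml

        from nervect.phantom import save_phantom, spec_from_config
        spec = parallel_tubes_spec(n_tubes=2, shape=(48, 48, 8), noise_sd=0.01)
        res = build_phantom(spec)
        save_phantom(res, tmp_path)
        assert (tmp_path / "volume.tiff").exists()
        assert (tmp_path / "truth_tracks.json").exists()
        with open(tmp_path / "spec.yaml") as fh:
            cfg = yaml.safe_load(fh)
        spec2 = spec_from_config(cfg)
        assert spec2.shape == spec.shape
        assert spec2.tissue_means[TissueClass.ADIPOCYTE] == pytest.approx(0.92)
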