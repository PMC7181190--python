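import numpy as np
import pytest

from conftest import flood_fill_oracle
from nervect.preprocess import GreyRange
from nervect.tracking import (EventKind, FascicleTrack, SeedPoint, SliceRecord,
                              TrackEvent, assess_acceptance, detect_boundary_gain,
                              detect_boundary_loss, neighborhood_connected,
                              smooth_mask, track_fascicles)
from nervect.volume import Mask, Volume


def _tube_mask(nz=30, ny=24, nx=24, cy=12, cx=12, r=5, voxel=4.0):
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return Mask(np.broadcast_to(disc, (nz, ny, nx)).copy(), voxel_size_um=voxel)


class TestNeighborhoodConnected:
    def test_column_broken_by_out_of_range_voxel(self):
        data = np.array([0.5, 0.5, 0.9, 0.5]).reshape(4, 1, 1)
        mask = neighborhood_connected(Volume(data), [SeedPoint(0, 0, 0)],
                                      GreyRange(0.4, 0.6))
        assert mask.data.ravel().tolist() == [True, True, False, False]

    def test_only_seeded_blob_marked(self):
        data = np.full((1, 8, 8), 0.9)
        data[0, 1:3, 1:3] = 0.5
        data[0, 5:7, 5:7] = 0.5
        mask = neighborhood_connected(Volume(data), [SeedPoint(0, 1, 1)],
                                      GreyRange(0.4, 0.6))
        assert mask.data[0, 1:3, 1:3].all()
        assert not mask.data[0, 5:7, 5:7].any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(10):
            data = rng.random((10, 12, 12))
            in_range = (data >= 0.3) & (data <= 0.7)
            zs, ys, xs = np.nonzero(in_range)
            seed = (int(zs[0]), int(ys[0]), int(xs[0]))
            mask = neighborhood_connected(Volume(data), [SeedPoint(*seed)],
                                          GreyRange(0.3, 0.7), connectivity)
            assert np.array_equal(mask.data,
                                  flood_fill_oracle(in_range, [seed], connectivity))

    def test_output_is_subset_of_threshold_and_contains_seed(self):
        rng = np.random.default_rng(18)
        data = rng.random((8, 10, 10))
        in_range = (data >= 0.2) & (data <= 0.8)
        zs, ys, xs = np.nonzero(in_range)
        seed = SeedPoint(int(zs[5]), int(ys[5]), int(xs[5]))
        mask = neighborhood_connected(Volume(data), [seed], GreyRange(0.2, 0.8))
        assert not (mask.data & ~in_range).any()
        assert mask.data[seed.z, seed.y, seed.x]

    def test_seed_outside_range_rejected(self):
        data = np.full((2, 2, 2), 0.9)
        with pytest.raises(ValueError, match="outside range"):
            neighborhood_connected(Volume(data), [SeedPoint(0, 0, 0)],
                                   GreyRange(0.4, 0.6))

    def test_seed_outside_volume_rejected(self):
        with pytest.raises(ValueError, match="outside the volume"):
            neighborhood_connected(Volume(np.full((2, 2, 2), 0.5)),
                                   [SeedPoint(5, 0, 0)], GreyRange(0.4, 0.6))


class TestSmoothMask:
    def test_radius_zero_identity(self):
        m = _tube_mask()
        out = smooth_mask(m, 0)
        assert np.array_equal(out.data, m.data)

    def test_closing_fills_interior_gap(self):
        m = _tube_mask()
        m.data[15, 12, 12] = False  # 1-voxel pore inside the tube
        out = smooth_mask(m, 1)
        assert out.data[15, 12, 12]

    def test_closing_is_idempotent(self):
        rng = np.random.default_rng(19)
        m = Mask(rng.random((8, 10, 10)) < 0.4)
        once = smooth_mask(m, 1)
        twice = smooth_mask(once, 1)
        assert np.array_equal(once.data, twice.data)


class TestTrackFascicles:
    def test_two_disjoint_tubes_two_tracks_no_events(self):
        m = _tube_mask(cy=6, cx=6, r=3)
        m2 = _tube_mask(cy=17, cx=17, r=3)
        mask = Mask(m.data | m2.data, voxel_size_um=4.0)
        tracks = track_fascicles(mask)
        assert len(tracks) == 2
        assert all(t.events == [] for t in tracks)
        assert all(t.z_start == 0 and t.z_end == 29 for t in tracks)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            track_fascicles(Mask(np.zeros((4, 4, 4), dtype=bool)))

    def test_seed_position_invariance_within_a_tube(self, example_result):
        import nervect as nv
        res = example_result
        cfg = nv.PipelineConfig(min_fascicles=4)
        base = nv.seeds_from_truth(res)
        moved = [SeedPoint(s.z, s.y + 1, s.x, s.fascicle_id) for s in base]
        out1 = nv.run_pipeline(res.volume, base, cfg, annotation=res)
        out2 = nv.run_pipeline(res.volume, moved, cfg, annotation=res)
        assert len(out1.tracks) == len(out2.tracks)
        assert np.array_equal(out1.mask.data, out2.mask.data)

    def test_tracked_area_close_to_analytic_circle(self, example_result,
                                                   example_pipeline):
        # the plain straight tube (truth id 4) has radius 40 um
        areas = []
        for t in example_pipeline.tracks:
            rec = t.records[len(t.records) // 2]
            labels = example_result.instance_labels[rec.z, rec.footprint[0],
                                                    rec.footprint[1]]
            if labels.size and np.bincount(labels[labels > 0]).argmax() == 4:
                areas = [r.area_um2 for r in t.records]
                break
        assert areas, "tube 4 was not tracked"
        analytic = np.pi * 40.0 ** 2
        assert np.all(np.abs(np.asarray(areas) - analytic) <= 0.15 * analytic)


class TestBoundaryLoss:
    def test_straight_tube_has_no_loss(self):
        mask = _tube_mask()
        track = track_fascicles(mask)[0]
        assert detect_boundary_loss(track, mask) == []

    def test_truncated_tube_confirms_loss_at_truncation(self):
        mask = _tube_mask()
        mask.data[20:] = False
        track = track_fascicles(mask)[0]
        events = detect_boundary_loss(track, mask)
        assert len(events) == 1
        assert events[0].kind is EventKind.BOUNDARY_LOSS
        assert events[0].z_um == pytest.approx(20 * 4.0)

    def test_sixty_percent_continuation_is_not_loss(self):
        data = np.zeros((10, 8, 20), dtype=bool)
        data[:5, 2:7, 0:10] = True   # 50 voxels per slice
        data[5:, 2:7, 4:14] = True   # overlap 30 of 50 -> 60% continues
        mask = Mask(data, voxel_size_um=4.0)
        tracks = track_fascicles(mask)
        events = [e for t in tracks for e in detect_boundary_loss(t, mask)]
        assert events == []

    def test_forty_percent_continuation_is_loss(self):
        data = np.zeros((10, 8, 20), dtype=bool)
        data[:5, 2:7, 0:10] = True
        data[5:, 2:7, 7:17] = True   # overlap 15 of 50 -> 30% continues
        mask = Mask(data, voxel_size_um=4.0)
        tracks = track_fascicles(mask)
        events = [e for t in tracks for e in detect_boundary_loss(t, mask)]
        assert any(e.kind is EventKind.BOUNDARY_LOSS for e in events)


def _fusion_tracks(voxel=20.0, merge_z=10, nz=24):
    """Two tubes that fuse at merge_z and stay fused (no re-split)."""
    data = np.zeros((nz, 20, 40), dtype=bool)
    yy, xx = np.mgrid[0:20, 0:40]
    d1 = (yy - 10) ** 2 + (xx - 12) ** 2 <= 16
    d2 = (yy - 10) ** 2 + (xx - 27) ** 2 <= 16
    blob = ((yy - 10) / 6.0) ** 2 + ((xx - 19.5) / 14.0) ** 2 <= 1
    data[:merge_z] = d1 | d2
    data[merge_z:] = blob
    mask = Mask(data, voxel_size_um=voxel)
    return track_fascicles(mask), mask


class TestBoundaryGain:
    def test_fusion_without_plexus_is_gain(self):
        tracks, mask = _fusion_tracks()
        gains = detect_boundary_gain(tracks, None, voxel_size_um=20.0)
        assert len(gains) == 1
        assert gains[0].kind is EventKind.BOUNDARY_GAIN
        assert len(gains[0].partners) >= 2

    def test_plexus_two_mm_away_excuses_gain(self):
        tracks, mask = _fusion_tracks()
        merge_z_um = 10 * 20.0
        gains = detect_boundary_gain(tracks, [merge_z_um + 2000.0],
                                     voxel_size_um=20.0)
        assert gains == []

    def test_plexus_five_mm_away_does_not_excuse(self):
        tracks, mask = _fusion_tracks()
        merge_z_um = 10 * 20.0
        gains = detect_boundary_gain(tracks, [merge_z_um + 5000.0],
                                     voxel_size_um=20.0)
        assert len(gains) == 1

    def test_observed_plexus_resolves_merge(self, example_pipeline):
        kinds = [e.kind for t in example_pipeline.tracks for e in t.events]
        assert EventKind.PLEXUS in kinds
        assert EventKind.BOUNDARY_GAIN not in kinds


def _synthetic_track(z0, z1, full_span, tid=1):
    t = FascicleTrack(id=tid, roots=frozenset({tid}))
    for z in range(z0, z1 + 1):
        t.records.append(SliceRecord(z, (1.0, 1.0), 16.0))
    return t


class TestAcceptanceRule:
    def test_four_tracks_one_branch_min_three_acceptable(self):
        tracks = [_synthetic_track(0, 99, True, tid=i) for i in range(1, 5)]
        tracks[0].events.append(TrackEvent(EventKind.BRANCH, 200.0, (5, 6)))
        report = assess_acceptance(tracks, {"min_fascicles": 3})
        assert report.acceptable
        assert report.n_tracked == 4

    def test_ten_tracks_min_ten_acceptable(self):
        tracks = [_synthetic_track(0, 49, True, tid=i) for i in range(1, 11)]
        report = assess_acceptance(tracks, {"min_fascicles": 10})
        assert report.acceptable

    def test_confirmed_gain_disqualifies(self):
        tracks = [_synthetic_track(0, 99, True, tid=i) for i in range(1, 4)]
        gain = TrackEvent(EventKind.BOUNDARY_GAIN, 120.0, (1, 2))
        report = assess_acceptance(tracks, {"min_fascicles": 3},
                                   confirmed_loss=[], confirmed_gain=[gain])
        assert not report.acceptable
        assert any("gain" in r for r in report.reasons)

    def test_plexus_does_not_disqualify(self):
        tracks = [_synthetic_track(0, 99, True, tid=i) for i in range(1, 4)]
        tracks[0].events.append(TrackEvent(EventKind.PLEXUS, 100.0, (1, 2)))
        report = assess_acceptance(tracks, {"min_fascicles": 3},
                                   confirmed_loss=[], confirmed_gain=[])
        assert report.acceptable

    def test_short_track_not_counted_full_length(self):
        tracks = [_synthetic_track(0, 99, True, tid=1),
                  _synthetic_track(0, 99, True, tid=2),
                  _synthetic_track(0, 40, False, tid=3)]
        report = assess_acceptance(tracks, {"min_fascicles": 3},
                                   confirmed_loss=[], confirmed_gain=[])
        assert not report.acceptable
        assert report.n_tracked == 2

    def test_min_fascicles_below_one_rejected(self):
        with pytest.raises(ValueError):
            assess_acceptance([_synthetic_track(0, 9, True)], {"min_fascicles": 0})

    def test_branch_event_partner_arity_enforced(self):
        with pytest.raises(ValueError, match="partners"):
            TrackEvent(EventKind.BRANCH, 10.0, (2,))
        with pytest.raises(ValueError, match="exactly 2"):
            TrackEvent(EventKind.PLEXUS, 10.0, (1, 2, 3))
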