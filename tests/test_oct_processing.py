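import numpy as np
import pytest

from foveapredict import oct, synth
from foveapredict.errors import AlignmentError, FoveolaNotFoundError, UnsegmentableScanError

from conftest import make_flat_retina


def toy_scan(values, depth_step=2.0, lateral_step=0.1, aligned=False):
    values = np.asarray(values, dtype=float)
    nd, nl = values.shape
    return oct.BScan(
        reflectivity=values,
        depth_axis=depth_step * np.arange(nd),
        lateral_axis=lateral_step * np.arange(nl),
        aligned=aligned,
    )


class TestDownsample:
    def test_4091_to_512_per_15deg(self):
        scan = oct.BScan(
            reflectivity=np.zeros((4, 4091)),
            depth_axis=np.arange(4.0),
            lateral_axis=np.linspace(0, 15, 4091, endpoint=False),
        )
        out = oct.downsample_lrps(scan, 512)
        assert out.n_lateral == 512

    def test_constant_scan_unchanged(self):
        scan = toy_scan(np.full((6, 40), 3.5))
        out = oct.downsample_lrps(scan, int(round(10 * 15 / (40 * 0.1))))
        assert np.allclose(out.reflectivity, 3.5)

    def test_toy_block_means(self):
        # 8 A-scans averaged in blocks of 2; hand-computed column means
        vals = np.array([[1, 3, 5, 7, 2, 4, 6, 8],
                         [2, 4, 6, 8, 3, 5, 7, 9]], dtype=float)
        scan = toy_scan(vals)
        out = oct.downsample_lrps(scan, int(round(4 * 15 / (8 * 0.1))))
        assert out.n_lateral == 4
        assert np.allclose(out.reflectivity, [[2, 6, 3, 7], [3, 7, 4, 8]])
        assert np.allclose(out.lateral_axis, [0.05, 0.25, 0.45, 0.65])

    def test_target_exceeding_density(self):
        scan = toy_scan(np.zeros((4, 10)))
        with pytest.raises(ValueError, match="exceeds"):
            oct.downsample_lrps(scan, 10000)

    def test_mean_preserved_per_block(self):
        rng = np.random.default_rng(0)
        scan = toy_scan(rng.random((5, 12)))
        out = oct.downsample_lrps(scan, int(round(3 * 15 / 1.2)))
        assert out.reflectivity.mean() == pytest.approx(scan.reflectivity.mean())


class TestAlign:
    def test_idempotence(self, noiseless_scan):
        again = oct.align_to_brm(noiseless_scan)
        assert np.all(np.abs(again.truth["RPE2_BrM"]) <= again.axial_step + 1e-9)

    def test_tilted_brm_straightened(self, default_retina):
        params = synth.RenderParams(brm_tilt=30.0)  # 30 um/deg linear tilt
        scan = synth.render_bscan(default_retina, noise_sd=0.0, seed=0, params=params)
        aligned = oct.align_to_brm(scan)
        assert aligned.aligned
        assert np.all(np.abs(aligned.truth["RPE2_BrM"]) <= aligned.axial_step + 1e-9)

    def test_flat_zero_scan_rejected(self):
        with pytest.raises(AlignmentError, match="no detectable band"):
            oct.align_to_brm(toy_scan(np.zeros((50, 70))))

    def test_border_maxima_flagged(self):
        vals = np.zeros((30, 70))
        vals[15, :] = 1.0
        vals[29, 3] = 5.0  # truncated band in one LRP
        aligned = oct.align_to_brm(toy_scan(vals))
        assert aligned.meta["alignment_flagged"][3]
        assert aligned.meta["alignment_flagged"].sum() == 1


class TestFoveola:
    def test_symmetric_pit_centred(self, noiseless_scan):
        assert oct.locate_foveola(noiseless_scan) == pytest.approx(
            0.0, abs=noiseless_scan.lateral_step
        )

    def test_shifted_pit(self):
        retina = synth.build_retina("x", "IRD", 100, 20, 27, 18, pit_center=0.3)
        scan = oct.align_to_brm(synth.render_bscan(retina, noise_sd=0.0, seed=0))
        assert oct.locate_foveola(scan) == pytest.approx(0.3, abs=scan.lateral_step)

    def test_override_wins(self, noiseless_scan):
        assert oct.locate_foveola(noiseless_scan, override=-0.1) == -0.1

    def test_monotone_surface_rejected(self):
        scan = synth.render_bscan(make_flat_retina(), noise_sd=0.0, seed=0)
        scan = oct.align_to_brm(scan)
        with pytest.raises(FoveolaNotFoundError, match="override"):
            oct.locate_foveola(scan)

    def test_unaligned_rejected(self, default_retina):
        scan = synth.render_bscan(default_retina, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="aligned"):
            oct.locate_foveola(scan)


class TestSegmentation:
    def test_noiseless_recovery_everywhere(self, noiseless_scan, noiseless_segmentation):
        scan, seg = noiseless_scan, noiseless_segmentation
        step = scan.axial_step
        for role in oct.BOUNDARIES:
            ok = seg.valid(role)
            assert ok.mean() > 0.9, role
            err = np.abs(seg.depths[role][ok] - scan.truth[role][ok])
            assert err.max() <= step + 1e-6, role

    def test_missing_ez_cost_flagged(self, default_retina):
        # BCM-like IS/OS defect: EZ and COST bands removed
        amps = dict(synth.DEFAULT_BAND_AMPS)
        amps["EZ"] = 0.0
        amps["COST"] = 0.0
        scan = synth.render_bscan(
            default_retina, noise_sd=0.0, seed=0, params=synth.RenderParams(amps=amps)
        )
        scan = oct.align_to_brm(oct.downsample_lrps(scan, 512))
        seg = oct.segment_layers(scan)
        assert seg.flags["EZ"].all() and seg.flags["COST"].all()
        for role in ("ELM", "RPE1", "RPE2_BrM", "OPL"):
            ok = seg.valid(role)
            assert ok.mean() > 0.8, role
            err = np.abs(seg.depths[role][ok] - scan.truth[role][ok])
            assert np.median(err) <= scan.axial_step + 1e-6, role

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(0)
        scan = toy_scan(rng.normal(0, 1, size=(220, 80)), aligned=True)
        with pytest.raises(UnsegmentableScanError, match="detectable bands"):
            oct.segment_layers(scan)

    def test_unaligned_rejected(self, default_retina):
        scan = synth.render_bscan(default_retina, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="aligned"):
            oct.segment_layers(scan)

    def test_manual_override_applied(self, noiseless_scan):
        seg = oct.segment_layers(noiseless_scan, overrides={"ELM": {5: 77.0}})
        assert seg.depths["ELM"][5] == pytest.approx(77.0, abs=1e-9)

    def test_ordering_invariant(self, noiseless_segmentation):
        seg = noiseless_segmentation
        all_ok = np.ones(seg.lateral_axis.size, dtype=bool)
        for role in oct.BOUNDARIES:
            all_ok &= seg.valid(role)
        assert all_ok.any()
        d = seg.depths
        for hi, lo in zip(oct.BOUNDARIES[:-1], oct.BOUNDARIES[1:]):
            assert np.all(d[hi][all_ok] > d[lo][all_ok]), (hi, lo)


class TestThicknesses:
    @staticmethod
    def seg_from_depths(opl=180.0, elm=80.0, ez=55.0, cost=30.0, rpe1=18.0, brm=0.0, n=3):
        depths = {
            "OPL": np.full(n, opl), "ELM": np.full(n, elm), "EZ": np.full(n, ez),
            "COST": np.full(n, cost), "RPE1": np.full(n, rpe1), "RPE2_BrM": np.full(n, brm),
        }
        flags = {r: ~np.isfinite(depths[r]) for r in depths}
        return oct.LayerSegmentation(depths=depths, flags=flags,
                                     lateral_axis=np.arange(n, dtype=float))

    def test_subtraction_by_definition(self):
        th = oct.thicknesses_from_segmentation(self.seg_from_depths())
        row = th.iloc[0]
        assert row["onl"] == 100.0 and row["is_len"] == 25.0
        assert row["cos_len"] == 25.0 and row["rpe"] == 18.0

    def test_flag_propagation(self):
        seg = self.seg_from_depths()
        seg.depths["EZ"][:] = np.nan
        seg.flags["EZ"][:] = True
        th = oct.thicknesses_from_segmentation(seg)
        assert th["is_len"].isna().all() and th["cos_len"].isna().all()
        assert th["onl"].notna().all() and th["rpe"].notna().all()

    def test_negative_flagged_not_clipped(self):
        seg = self.seg_from_depths(ez=90.0)  # EZ above ELM: IS negative
        th = oct.thicknesses_from_segmentation(seg)
        assert th["is_len"].isna().all()
        assert th["cos_len"].notna().all()


class TestCountExtrema:
    depth = np.arange(0.0, 200.0, 2.0)

    def test_constant_zero(self):
        assert oct.count_extrema(self.depth, np.ones_like(self.depth), 150.0, 0.0, 0.01) == 0

    def test_single_gaussian_two(self):
        # analytic: a Gaussian's derivative has one max and one min
        lrp = np.exp(-((self.depth - 75.0) ** 2) / (2 * 9.0))
        assert oct.count_extrema(self.depth, lrp, 150.0, 0.0, 0.01) == 2

    def test_four_bands_eight(self):
        lrp = sum(np.exp(-((self.depth - c) ** 2) / (2 * 9.0)) for c in (30, 60, 90, 120))
        assert oct.count_extrema(self.depth, lrp, 150.0, 0.0, 0.01) == 8

    def test_band_outside_window_ignored(self):
        lrp = np.exp(-((self.depth - 180.0) ** 2) / (2 * 9.0))
        assert oct.count_extrema(self.depth, lrp, 150.0, 0.0, 0.01) == 0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            oct.count_extrema(self.depth, np.ones_like(self.depth), 4.0, 0.0, 0.01)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            oct.count_extrema(self.depth, np.ones_like(self.depth), 0.0, 150.0, 0.01)


class TestExtractSamples:
    def test_grid_eccentricities(self, noiseless_scan, noiseless_segmentation):
        samples = oct.extract_samples(noiseless_scan, noiseless_segmentation, 0.0)
        assert [s.eccentricity for s in samples] == [-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75]

    def test_laterally_constant_scan_identical_samples(self):
        retina = make_flat_retina()
        scan = oct.align_to_brm(synth.render_bscan(retina, noise_sd=0.0, seed=0))
        seg = oct.segment_layers(scan)
        samples = oct.extract_samples(scan, seg, 0.0)
        ref = samples[0]
        for s in samples[1:]:
            assert s.onl == pytest.approx(ref.onl, abs=1e-6)
            assert s.cos_len == pytest.approx(ref.cos_len, abs=1e-6)
            assert s.n_extrema == ref.n_extrema
            assert np.allclose(s.reflectivity_vec, ref.reflectivity_vec, atol=1e-9)

    def test_reflectivity_vec_peaks_at_band_centres(self, noiseless_scan, noiseless_segmentation):
        samples = oct.extract_samples(noiseless_scan, noiseless_segmentation, 0.0)
        vec_depths = oct.DEFAULT_VEC_DEPTHS
        resample_step = vec_depths[1] - vec_depths[0]
        for s in samples:
            j = int(np.argmin(np.abs(noiseless_scan.lateral_axis - s.eccentricity)))
            vec = s.reflectivity_vec
            peaks = [
                i for i in range(1, vec.size - 1) if vec[i] > vec[i - 1] and vec[i] >= vec[i + 1]
            ]
            peak_depths = vec_depths[peaks]
            for role in ("RPE1", "COST", "EZ", "ELM"):
                true_d = noiseless_scan.truth[role][j]
                if vec_depths[0] < true_d < vec_depths[-1]:
                    assert np.min(np.abs(peak_depths - true_d)) <= resample_step + 1e-9, role

    def test_outside_extent_rejected(self, noiseless_scan, noiseless_segmentation):
        with pytest.raises(ValueError, match="outside scan extent"):
            oct.extract_samples(noiseless_scan, noiseless_segmentation, 5.0)

    def test_vec_length_contract(self, noiseless_scan, noiseless_segmentation):
        samples = oct.extract_samples(noiseless_scan, noiseless_segmentation, 0.0)
        assert {s.reflectivity_vec.size for s in samples} == {oct.DEFAULT_VEC_DEPTHS.size}


class TestPipelineProperties:
    def test_lateral_shift_equivariance(self, default_retina):
        scan = synth.render_bscan(default_retina, noise_sd=0.0, seed=0)
        shifted = oct.BScan(
            reflectivity=scan.reflectivity.copy(),
            depth_axis=scan.depth_axis.copy(),
            lateral_axis=scan.lateral_axis + 0.5,
            truth={k: v.copy() for k, v in scan.truth.items()},
        )
        a, b = oct.align_to_brm(scan), oct.align_to_brm(shifted)
        fa, fb = oct.locate_foveola(a), oct.locate_foveola(b)
        assert fb - fa == pytest.approx(0.5, abs=1e-9)
        sa = oct.extract_samples(a, oct.segment_layers(a), fa)
        sb = oct.extract_samples(b, oct.segment_layers(b), fb)
        for x, y in zip(sa, sb):
            assert x.onl == pytest.approx(y.onl, nan_ok=True)
            assert np.allclose(x.reflectivity_vec, y.reflectivity_vec)

    def test_downsample_align_commute(self, default_retina):
        params = synth.RenderParams(brm_tilt=20.0)
        scan = synth.render_bscan(default_retina, noise_sd=0.0, seed=0, params=params)
        a = oct.align_to_brm(oct.downsample_lrps(scan, 512))
        b = oct.downsample_lrps(oct.align_to_brm(scan), 512)
        step = scan.axial_step
        for s in (a, b):
            assert np.all(np.abs(s.truth["RPE2_BrM"]) <= step + 1e-9)
        assert np.all(np.abs(a.truth["EZ"] - b.truth["EZ"]) <= step + 1e-9)

    def test_median_foveal_onl_error_under_default_noise(self):
        errs = []
        cohort = synth.generate_training_cohort(47, 3, 1.5, 0.08, 0.814, seed=123)
        for i, row in enumerate(cohort.rows[:50]):
            scan = synth.render_bscan(row.retina, noise_sd=0.03, n_ascans=192, seed=i)
            scan = oct.align_to_brm(oct.downsample_lrps(scan, 512))
            fov = oct.locate_foveola(scan)
            seg = oct.segment_layers(scan)
            samples = oct.extract_samples(scan, seg, fov)
            onl_hat = [s.onl for s in samples if s.eccentricity == 0.0][0]
            onl_true = float(row.retina.thickness_profiles(fov)[0])
            if np.isfinite(onl_hat):
                errs.append(abs(onl_hat - onl_true))
        assert len(errs) >= 45  # almost all foveae measurable
        assert np.median(errs) <= 3.0
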