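import numpy as np
import pytest

from biofilmflow.growth_model import GrowthParams, equilibrium_height
from biofilmflow.phantom import (
    ColonySpec,
    NoiseSpec,
    TimeSeriesSpec,
    add_colony,
    add_substratum,
    generate_time_series,
    make_noise_volume,
    sample_arrivals,
    substratum_depth_map,
)
from biofilmflow.volume import DEFAULT_VOXEL_AXIAL, DEFAULT_VOXEL_LATERAL


class TestNoiseVolume:
    def test_histogram_mode_near_mean(self):
        vol = make_noise_volume((64, 64, 64), NoiseSpec(30.0, 5.0, seed=1))
        counts = np.bincount(vol.data.ravel(), minlength=256)
        assert abs(int(np.argmax(counts)) - 30) <= 2

    def test_degenerate_sigma_limit(self):
        vol = make_noise_volume((8, 8, 8), NoiseSpec(30.0, 1e-9, seed=0))
        assert np.all(vol.data == 30)

    def test_deterministic_under_seed(self):
        a = make_noise_volume((16, 16, 16), NoiseSpec(30.0, 5.0, seed=9))
        b = make_noise_volume((16, 16, 16), NoiseSpec(30.0, 5.0, seed=9))
        assert np.array_equal(a.data, b.data)
        c = make_noise_volume((16, 16, 16), NoiseSpec(30.0, 5.0, seed=10))
        assert not np.array_equal(a.data, c.data)

    def test_three_sigma_tail_fraction(self):
        # P(X > mean + 3 sigma) = 0.00135 for a Gaussian; binomial error
        # bounds on 64^3 draws (pre-quantisation to avoid grid effects)
        raw = make_noise_volume((64, 64, 64), NoiseSpec(30.0, 5.0, seed=2), quantise=False)
        frac = np.mean(raw > 30.0 + 3 * 5.0)
        n = raw.size
        se = np.sqrt(0.00135 * (1 - 0.00135) / n)
        assert abs(frac - 0.00135) < 5 * se

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            make_noise_volume((0, 4, 4), NoiseSpec(30.0, 5.0, 0))

    def test_noise_spec_invariants(self):
        with pytest.raises(ValueError):
            NoiseSpec(mean_level=30.0, sigma=0.0)
        with pytest.raises(ValueError):
            NoiseSpec(mean_level=300.0, sigma=5.0)


class TestSubstratum:
    def test_zero_tilt_constant_depth(self):
        vol = make_noise_volume((32, 24, 24), NoiseSpec(30, 5, 1))
        _, depth = add_substratum(vol, 0.0, 255, base_depth=7)
        assert np.all(depth == 7)

    def test_five_degree_slope(self):
        # tan(5 deg) * 12 um / 2.1 um ~ 0.5 axial voxels per lateral voxel
        depth = substratum_depth_map(
            (8, 64), 5.0, 2, DEFAULT_VOXEL_LATERAL, DEFAULT_VOXEL_AXIAL
        )
        slope = np.polyfit(np.arange(64), depth[0], 1)[0]
        assert slope == pytest.approx(
            np.tan(np.radians(5.0)) * 12.0 / 2.1, abs=0.02
        )

    def test_brightness_makes_plane_argmax(self):
        vol = make_noise_volume((48, 32, 32), NoiseSpec(30, 5, 3))
        vol, depth = add_substratum(vol, 3.0, 255, 2)
        assert np.array_equal(np.argmax(vol.data, axis=0), depth)

    def test_plane_exiting_volume_rejected(self):
        vol = make_noise_volume((10, 8, 64), NoiseSpec(30, 5, 0))
        with pytest.raises(ValueError):
            add_substratum(vol, 10.0, 255, 2)


class TestColony:
    def test_vertical_solid_cylinder_full_solidity(self):
        vol = make_noise_volume((32, 40, 40), NoiseSpec(30, 5, 4))
        spec = ColonySpec((20.0, 20.0), 5, 15, lean_angle=0.0, streamer_length=0)
        _, truth = add_colony(vol, spec, NoiseSpec(30, 5, 4), -1)
        b = truth.true_binary.data
        footprint = b[0]
        assert footprint.sum() > 0
        heights = b.sum(axis=0)
        tops = np.where(b.any(axis=0), b.shape[0] - 1 - np.argmax(b[::-1], axis=0), -1)
        occ = footprint
        # solid from the base: thickness equals height index + 1 everywhere
        assert np.array_equal(heights[occ], tops[occ] + 1)

    def test_thin_streamer_solidity_is_one_over_h(self):
        vol = make_noise_volume((32, 40, 40), NoiseSpec(30, 5, 5))
        h = 10
        spec = ColonySpec(
            (12.0, 20.0), 2, h, lean_angle=0.0,
            streamer_length=6, streamer_thickness=1,
        )
        _, truth = add_colony(vol, spec, NoiseSpec(30, 5, 5), -1)
        b = truth.true_binary.data
        col = b[:, 20, 18]  # streamer-only column, past the pillar footprint
        assert col.sum() == 1
        assert int(np.nonzero(col)[0][0]) == h - 1
        # solidity 1/h <= 2/3 for h >= 2
        assert 1.0 / h <= 2.0 / 3.0
        # beneath the filament the voxels stay background
        assert not col[: h - 1].any()

    def test_disjoint_footprints_additive(self):
        vol = make_noise_volume((32, 48, 48), NoiseSpec(30, 5, 6))
        s1 = ColonySpec((12.0, 12.0), 4, 8)
        s2 = ColonySpec((34.0, 34.0), 5, 8)
        vol, truth = add_colony(vol, s1, NoiseSpec(30, 5, 6), -1)
        a1 = truth.true_footprint_area
        _, truth = add_colony(vol, s2, NoiseSpec(30, 5, 6), -1, truth)
        a2 = truth.true_footprint_area
        single2 = add_colony(
            make_noise_volume((32, 48, 48), NoiseSpec(30, 5, 6)),
            s2, NoiseSpec(30, 5, 6), -1,
        )[1].true_footprint_area
        assert a2 == a1 + single2

    def test_out_of_bounds_rejected(self):
        vol = make_noise_volume((32, 40, 40), NoiseSpec(30, 5, 7))
        with pytest.raises(ValueError):
            add_colony(vol, ColonySpec((38.0, 20.0), 5, 10), NoiseSpec(30, 5, 7), -1)
        with pytest.raises(ValueError):
            add_colony(vol, ColonySpec((20.0, 20.0), 5, 40), NoiseSpec(30, 5, 7), -1)

    def test_ground_truth_consistency(self):
        vol = make_noise_volume((32, 40, 40), NoiseSpec(30, 5, 8))
        spec = ColonySpec((20.0, 20.0), 6, 12, lean_angle=10.0, streamer_length=5)
        _, truth = add_colony(vol, spec, NoiseSpec(30, 5, 8), -1)
        b = truth.true_binary.data
        derived = np.where(b.any(axis=0), b.shape[0] - np.argmax(b[::-1], axis=0), 0)
        assert np.array_equal(truth.true_height_map, derived)

    def test_biofilm_brighter_than_noise_mode(self):
        vol = make_noise_volume((32, 40, 40), NoiseSpec(30, 5, 9))
        spec = ColonySpec((20.0, 20.0), 5, 10)
        out, truth = add_colony(vol, spec, NoiseSpec(30, 5, 9), -1)
        # with scalar depth -1 the volume z-index equals the truth layer index
        zs, ys, xs = np.nonzero(truth.true_binary.data)
        vals = out.data[zs, ys, xs]
        assert vals.mean() > 30 + 5 * 5


def _series_params(A_fp=7238.0, beta=0.05, A=48 * 48 * 144.0) -> GrowthParams:
    return GrowthParams.with_si_viscosity(
        g=45.4, C=1.0, mu_b_pa_s=1000.0, beta=beta, A_fp=A_fp, A=A
    )


class TestTimeSeries:
    def test_beta_zero_only_noise_and_plane(self):
        p = GrowthParams.with_si_viscosity(
            g=45.4, C=1.0, mu_b_pa_s=1000.0, beta=1e-12, A_fp=7238.0, A=48 * 48 * 144.0
        )
        spec = TimeSeriesSpec(
            growth_params=p, tau_w=0.2, times=(24.0,), shape=(40, 48, 48),
            tilt_deg=0.0, seed=5,
        )
        series = generate_time_series(spec)
        (t, vol, truth) = series[0]
        assert truth.true_binary.count() == 0
        ref = make_noise_volume(
            (40, 48, 48),
            spec.noise,
            rng=np.random.default_rng(np.random.SeedSequence(5).spawn(3)[2]),
        )
        ref, _ = add_substratum(ref, spec.tilt_deg, spec.substratum_brightness, 2)
        assert np.array_equal(vol.data, ref.data)

    def test_deterministic(self):
        spec = TimeSeriesSpec(
            growth_params=_series_params(), tau_w=0.2, times=(30.0, 60.0),
            shape=(40, 48, 48), tilt_deg=0.0, seed=11,
        )
        s1 = generate_time_series(spec)
        s2 = generate_time_series(spec)
        for (t1, v1, g1), (t2, v2, g2) in zip(s1, s2):
            assert t1 == t2
            assert np.array_equal(v1.data, v2.data)
            assert np.array_equal(g1.true_binary.data, g2.true_binary.data)

    def test_expected_colony_count_is_beta_t(self):
        beta, t_max = 0.2, 50.0
        counts = [
            len(sample_arrivals(beta, t_max, np.random.default_rng(seed)))
            for seed in range(400)
        ]
        mean = np.mean(counts)
        se = np.sqrt(beta * t_max / 400)
        assert abs(mean - beta * t_max) < 5 * se

    def test_doubling_shear_halves_saturated_height(self):
        p = _series_params(beta=0.02)
        tau = 0.2
        for factor in (1.0, 2.0):
            h_vox = equilibrium_height(p, factor * tau) / DEFAULT_VOXEL_AXIAL
            spec = TimeSeriesSpec(
                growth_params=p, tau_w=factor * tau, times=(80.0,),
                shape=(40, 48, 48), tilt_deg=0.0, seed=21,
            )
            _, _, truth = generate_time_series(spec)[0]
            if truth.true_binary.count():
                assert abs(truth.true_height_map.max() - round(h_vox)) <= 1

    def test_ensemble_mean_thickness_tracks_model(self):
        # calibrated Monte-Carlo check: the voxelised ground truth carries a
        # systematic ~15% deficit (rounded caps, integer heights) but is
        # linear in time; 100 seeds
        p = _series_params()
        tau, times = 0.2, (30.0, 60.0)
        sums = {t: [] for t in times}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(100):
                spec = TimeSeriesSpec(
                    growth_params=p, tau_w=tau, times=times, shape=(40, 48, 48),
                    tilt_deg=0.0, streamer_length=6, streamer_thickness=2, seed=seed,
                )
                for t, _vol, truth in generate_time_series(spec):
                    sums[t].append(truth.mean_thickness())
        h_max = equilibrium_height(p, tau)
        ratios = {}
        for t in times:
            predicted = p.beta * t * p.A_fp * h_max / p.A
            ratios[t] = np.mean(sums[t]) / predicted
            assert 0.75 <= ratios[t] <= 1.0
        assert ratios[60.0] / ratios[30.0] == pytest.approx(1.0, abs=0.05)

    def test_rejects_shallow_volume(self):
        spec_kwargs = dict(
            growth_params=_series_params(), tau_w=0.05, times=(60.0,), seed=0
        )
        with pytest.raises(ValueError, match="too shallow"):
            generate_time_series(TimeSeriesSpec(shape=(20, 48, 48), **spec_kwargs))

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            TimeSeriesSpec(
                growth_params=_series_params(), tau_w=0.2, times=(10.0, 5.0), seed=0
            )

    def test_field_area(self):
        spec = TimeSeriesSpec(
            growth_params=_series_params(), tau_w=0.2, times=(30.0,),
            shape=(40, 48, 48), seed=0,
        )
        assert spec.field_area == pytest.approx(48 * 48 * 144.0)
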