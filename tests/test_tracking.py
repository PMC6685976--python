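"""DoG spot detection, nearest-neighbor linking and MSD diffusion fitting."""

import numpy as np
import pytest
from oracles import brute_optimal_matching

from flickermap.errors import DegenerateInputError, ParameterError
from flickermap.tracking import (
    Localization,
    Track,
    dog_detect,
    ensemble_msd,
    fit_diffusion,
    link_tracks,
)


def psf_frame(positions, shape=(48, 48), amp=100.0, sigma=1.3, noise=0.0, seed=0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, float)
    for x, y in positions:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    if noise > 0:
        img = img + np.random.default_rng(seed).normal(0, noise, shape)
    return img


class TestDogDetect:
    def test_blank_frame_yields_nothing(self, rng):
        frame = rng.normal(100, 3, size=(48, 48))
        assert dog_detect(frame, threshold=50.0) == []

    def test_single_psf_localized_to_fiftieth_pixel(self):
        frame = psf_frame([(20.40, 11.25)])
        locs = dog_detect(frame, threshold=5.0)
        assert len(locs) == 1
        assert locs[0].x == pytest.approx(20.40, abs=0.02)
        assert locs[0].y == pytest.approx(11.25, abs=0.02)
        assert locs[0].fit_ok

    def test_two_psfs_10px_apart_not_merged(self):
        frame = psf_frame([(15.0, 24.0), (25.0, 24.0)])
        locs = dog_detect(frame, threshold=5.0)
        assert len(locs) == 2
        xs = sorted(l.x for l in locs)
        assert xs[0] == pytest.approx(15.0, abs=0.1)
        assert xs[1] == pytest.approx(25.0, abs=0.1)

    def test_min_pixels_filters_specks(self):
        frame = np.zeros((32, 32))
        frame[10, 10] = 1000.0  # single hot pixel
        locs = dog_detect(frame, threshold=5.0, min_pixels=5)
        # a delta spike spreads under the DoG; just require consistency
        # between thresholds: a huge min_pixels kills everything
        assert dog_detect(frame, threshold=5.0, min_pixels=500) == []
        assert isinstance(locs, list)

    def test_auto_threshold_from_robust_noise(self, rng):
        frame = psf_frame([(24.0, 24.0)], amp=200.0, noise=5.0, seed=1)
        locs = dog_detect(frame, threshold=None, threshold_nsigma=5.0)
        assert len(locs) == 1


class TestLinking:
    def loc(self, frame, x, y):
        return Localization(frame=frame, x=x, y=y, n_pixels=5, fit_ok=True)

    def test_within_three_pixels_linked(self):
        tracks = link_tracks([[self.loc(0, 0, 0)], [self.loc(1, 2, 0)]])
        assert len(tracks) == 1
        assert len(tracks[0]) == 2

    def test_beyond_three_pixels_not_linked(self):
        tracks = link_tracks([[self.loc(0, 0, 0)], [self.loc(1, 4, 0)]])
        assert len(tracks) == 2
        assert all(len(t) == 1 for t in tracks)

    def test_exactly_three_pixels_is_linked(self):
        tracks = link_tracks([[self.loc(0, 0, 0)], [self.loc(1, 3, 0)]])
        assert len(tracks) == 1

    def test_no_gap_closing(self):
        tracks = link_tracks(
            [[self.loc(0, 5, 5)], [], [self.loc(2, 5, 5)]]
        )
        assert len(tracks) == 2

    def test_step_never_exceeds_limit_and_no_merging(self, rng):
        locs_per_frame = []
        for f in range(20):
            locs_per_frame.append(
                [self.loc(f, x, y)
                 for x, y in rng.uniform(0, 60, size=(8, 2))]
            )
        tracks = link_tracks(locs_per_frame, max_link_dist=3.0)
        used = set()
        for tr in tracks:
            assert np.all(np.diff(tr.frames) == 1)
            steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
            assert np.all(steps <= 3.0 + 1e-12)
            for f, x, y in zip(tr.frames, tr.x, tr.y):
                assert (f, x, y) not in used
                used.add((f, x, y))

    def test_well_separated_particles_match_optimal_oracle(self, rng):
        # 3 particles, spacing 10 px, steps <= 1 px: greedy == optimal
        base = np.array([(10.0, 10.0), (30.0, 10.0), (20.0, 30.0)])
        pos = [base]
        for _ in range(49):
            pos.append(pos[-1] + rng.uniform(-0.7, 0.7, size=base.shape))
        locs_per_frame = [
            [self.loc(f, x, y) for x, y in frame_pos]
            for f, frame_pos in enumerate(pos)
        ]
        tracks = link_tracks(locs_per_frame)
        assert len(tracks) == 3
        assert all(len(t) == 50 for t in tracks)
        for f in range(49):
            prev = [(x, y) for x, y in pos[f]]
            cur = [(x, y) for x, y in pos[f + 1]]
            pairs = brute_optimal_matching(prev, cur, max_dist=3.0)
            assert sorted(pairs) == [(0, 0), (1, 1), (2, 2)]


class TestMSD:
    def make_track(self, xs, ys, tid=0):
        n = len(xs)
        return Track(id=tid, frames=np.arange(n),
                     x=np.asarray(xs, float), y=np.asarray(ys, float))

    def test_ballistic_closed_form(self):
        s = 0.5  # um per frame with pixel_size=1
        tr = self.make_track(np.arange(20) * s, np.zeros(20))
        msd = ensemble_msd([tr], pixel_size=1.0, frame_interval=0.1, max_lag=10)
        np.testing.assert_allclose(msd.msd, (np.arange(1, 11) * s) ** 2, rtol=1e-12)

    def test_stationary_particles_have_zero_msd(self):
        trs = [self.make_track(np.full(15, 3.0), np.full(15, 7.0), tid=i)
               for i in range(4)]
        msd = ensemble_msd(trs, pixel_size=0.16, frame_interval=0.1, max_lag=5)
        np.testing.assert_allclose(msd.msd, 0.0)

    def test_brownian_tracks_follow_4dt(self, rng):
        D, dt = 0.05, 0.1
        sigma = np.sqrt(2 * D * dt)
        tracks = []
        for i in range(5000):
            steps = rng.normal(0, sigma, size=(12, 2))
            pos = np.cumsum(steps, axis=0)
            tracks.append(self.make_track(pos[:, 0], pos[:, 1], tid=i))
        msd = ensemble_msd(tracks, pixel_size=1.0, frame_interval=dt, max_lag=10)
        expected = 4 * D * msd.lags
        assert np.all(np.abs(msd.msd - expected) <= 3 * msd.sem)

    def test_nonoverlapping_mode_agrees_in_expectation(self, rng):
        D, dt = 0.05, 0.1
        tracks = []
        for i in range(2000):
            pos = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), size=(21, 2)), axis=0)
            tracks.append(self.make_track(pos[:, 0], pos[:, 1], tid=i))
        m_all = ensemble_msd(tracks, 1.0, dt, max_lag=5, overlapping=True)
        m_ind = ensemble_msd(tracks, 1.0, dt, max_lag=5, overlapping=False)
        # at lag 1 the two modes coincide; beyond it fewer pairs remain
        assert np.all(m_ind.n_pairs[1:] < m_all.n_pairs[1:])
        assert np.all(np.abs(m_all.msd - m_ind.msd) <= 4 * m_ind.sem)

    def test_translation_invariance(self, rng):
        tracks = []
        for i in range(10):
            pos = np.cumsum(rng.normal(0, 0.3, size=(20, 2)), axis=0)
            tracks.append(self.make_track(pos[:, 0], pos[:, 1], tid=i))
        shifted = [self.make_track(t.x + 100.0, t.y - 55.0, tid=t.id)
                   for t in tracks]
        m1 = ensemble_msd(tracks, 0.16, 0.1, max_lag=8)
        m2 = ensemble_msd(shifted, 0.16, 0.1, max_lag=8)
        np.testing.assert_allclose(m1.msd, m2.msd, rtol=1e-9)

    def test_no_usable_tracks_is_degenerate(self):
        short = self.make_track([1.0], [1.0])
        with pytest.raises(DegenerateInputError):
            ensemble_msd([short], 0.16, 0.1)


class TestDiffusionFit:
    def test_exact_line_recovers_slope_over_four(self):
        lags = np.arange(1, 11) * 0.1
        msd = type("M", (), {})()
        from flickermap.tracking import MSDResult

        res = MSDResult(lags=lags, msd=4 * 0.1 * lags,
                        sem=np.zeros(10), n_pairs=np.full(10, 100))
        res = fit_diffusion(res, fit_lags=10)
        assert res.D == pytest.approx(0.1, rel=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_offset_absorbed_by_intercept(self):
        from flickermap.tracking import MSDResult

        lags = np.arange(1, 11) * 0.1
        res = MSDResult(lags=lags, msd=4 * 0.07 * lags + 0.02,
                        sem=np.zeros(10), n_pairs=np.full(10, 100))
        res = fit_diffusion(res, fit_lags=10)
        assert res.D == pytest.approx(0.07, rel=1e-9)
        assert res.intercept == pytest.approx(0.02, rel=1e-9)

    def test_too_few_lags_rejected(self):
        from flickermap.tracking import MSDResult

        res = MSDResult(lags=np.array([0.1]), msd=np.array([0.01]),
                        sem=np.array([0.0]), n_pairs=np.array([5]))
        with pytest.raises(ParameterError):
            fit_diffusion(res, fit_lags=1)
        with pytest.raises(ParameterError):
            fit_diffusion(res, fit_lags=5)


def test_estimator_unbiased_across_seeds():
    """Truth-track MSD fit recovers D without systematic bias (20 seeds)."""
    from flickermap.synthetic import DiffusionMovieParams, generate_diffusion_movie

    ds = []
    for seed in range(20):
        params = DiffusionMovieParams(n_particles=30, n_frames=25, noise_sigma=0.0,
                                      snr=10.0)
        _, truth = generate_diffusion_movie(params, seed=seed)
        tracks = [Track(id=t["id"], frames=t["frames"], x=t["x"], y=t["y"])
                  for t in truth.tracks if len(t["frames"]) >= 2]
        msd = ensemble_msd(tracks, params.pixel_size, params.frame_interval,
                           max_lag=10)
        ds.append(fit_diffusion(msd, fit_lags=10).D)
    ds = np.asarray(ds)
    sem = ds.std(ddof=1) / np.sqrt(len(ds))
    assert abs(ds.mean() - 0.067) <= 3 * sem + 0.003
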