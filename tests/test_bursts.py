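"""ALEX burst search, corrections, filtering and BVA."""

import numpy as np
import pandas as pd
import pytest

from interdom.bursts import (
    BurstSet,
    CorrectionFactors,
    PhotonStream,
    alex_2cde,
    bva,
    correct_bursts,
    filter_bursts,
    fit_efret_distribution,
    read_photon_csv,
    read_photon_hdf5,
    search_bursts,
    shot_noise_sd,
    write_photon_csv,
    write_photon_hdf5,
)
from interdom.synthetic import AlexSpec, Population, StreamConfig, simulate_photon_stream

LOW_BG = {"dd": 50.0, "ad": 50.0, "aa": 80.0, "da": 20.0}


@pytest.fixture(scope="module")
def static_stream():
    cfg = StreamConfig(populations=[Population(E=0.5)], burst_rate=20.0, background=LOW_BG)
    d, truth = simulate_photon_stream(cfg, duration=30.0, seed=0)
    return PhotonStream.from_dict(d), truth


class TestContainerIO:
    def test_photon_hdf5_roundtrip(self, static_stream, tmp_path):
        stream, _ = static_stream
        path = str(tmp_path / "s.h5")
        write_photon_hdf5(stream, path)
        again = read_photon_hdf5(path)
        assert np.array_equal(again.timestamps, stream.timestamps)
        assert np.array_equal(again.detectors, stream.detectors)
        assert again.alex.period_s == pytest.approx(stream.alex.period_s)

    def test_csv_roundtrip(self, static_stream, tmp_path):
        stream, _ = static_stream
        path = str(tmp_path / "s.csv")
        write_photon_csv(stream, path)
        again = read_photon_csv(path)
        assert np.array_equal(again.timestamps, stream.timestamps)
        assert again.clock_rate == stream.clock_rate


class TestStreams:
    def test_four_stream_partition(self, static_stream):
        stream, _ = static_stream
        labels = stream.stream_labels()
        exc = stream.excitation()
        assert set(np.unique(labels)) <= {"dd", "ad", "da", "aa", ""}
        # every non-dark photon belongs to exactly one stream
        assert ((labels != "") == (exc >= 0)).all()

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            PhotonStream(timestamps=[5, 1], detectors=[0, 1], clock_rate=1e8)


class TestBurstSearch:
    def test_isolated_planted_bursts_recovered_exactly(self):
        # 50 bright, well-separated bursts: recovery must be exact
        rng = np.random.default_rng(5)
        alex = AlexSpec()
        times, chans = [], []
        for k in range(50):
            t0 = 0.1 + k * 0.2  # 200 ms spacing: no merging possible
            n = 80
            t = np.sort(t0 + rng.uniform(0, 1e-3, n))
            period_start = np.floor(t / alex.period_s) * alex.period_s
            dw = alex.donor_window
            t = period_start + (dw[0] + rng.uniform(0, 1, n) * (dw[1] - dw[0])) * alex.period_s
            times.append(t)
            chans.append((rng.random(n) < 0.5).astype(np.int8))
        # sparse background so rates are estimable
        n_bg = 3000
        t_bg = np.sort(rng.uniform(0, 10.2, n_bg))
        period_start = np.floor(t_bg / alex.period_s) * alex.period_s
        t_bg = period_start + (0.0 + rng.uniform(0, 1, n_bg) * 0.4) * alex.period_s
        times.append(t_bg)
        chans.append((rng.random(n_bg) < 0.5).astype(np.int8))
        t = np.concatenate(times)
        c = np.concatenate(chans)
        order = np.argsort(t)
        stream = PhotonStream(
            timestamps=np.round(t[order] * 1e8).astype(np.int64),
            detectors=c[order], clock_rate=1e8, alex=alex,
        )
        bset = search_bursts(stream, background={"all": 300.0, "dd": 150.0,
                                                 "ad": 150.0, "da": 0.0, "aa": 0.0})
        assert len(bset) == 50

    def test_most_planted_bursts_detected_in_realistic_stream(self, static_stream):
        stream, truth = static_stream
        bset = search_bursts(stream)
        n_true = len(truth)
        # nearby bursts can merge at the permissive rate factor, so detected
        # counts fall a little below the planted count but never far
        assert 0.6 * n_true <= len(bset) <= 1.05 * n_true

    def test_small_bursts_dropped(self, static_stream):
        stream, _ = static_stream
        bset = search_bursts(stream, min_size=20)
        assert (bset.bursts["size"] >= 20).all()

    def test_pure_background_yields_no_bursts(self):
        rng = np.random.default_rng(0)
        alex = AlexSpec()
        duration = 600.0
        times = []
        chans = []
        for rate, (chan, window) in zip(
            (350.0, 250.0, 500.0, 80.0), ((0, 0), (1, 0), (1, 1), (0, 1))
        ):
            n = rng.poisson(rate * duration)
            t = np.sort(rng.uniform(0, duration, n))
            frac = alex.donor_window if window == 0 else alex.acceptor_window
            period_start = np.floor(t / alex.period_s) * alex.period_s
            t = period_start + (frac[0] + rng.uniform(0, 1, n) * (frac[1] - frac[0])) * alex.period_s
            times.append(t)
            chans.append(np.full(n, chan, dtype=np.int8))
        t = np.concatenate(times)
        c = np.concatenate(chans)
        order = np.argsort(t)
        stream = PhotonStream(
            timestamps=np.round(t[order] * 1e8).astype(np.int64),
            detectors=c[order], clock_rate=1e8, alex=alex,
        )
        bset = search_bursts(stream)
        assert len(bset) <= 1  # < 1 false positive per 10 minutes

    def test_global_time_shift_invariance(self, static_stream):
        stream, _ = static_stream
        bset1 = search_bursts(stream)
        # shift by an integer number of ALEX periods so stream labels persist
        shift = int(round(stream.alex.period_s * stream.clock_rate)) * 1000
        shifted = PhotonStream(
            timestamps=stream.timestamps + shift, detectors=stream.detectors,
            clock_rate=stream.clock_rate, alex=stream.alex,
        )
        bset2 = search_bursts(shifted, background=bset1.background)
        assert len(bset1) == len(bset2)
        assert np.array_equal(bset1.bursts["size"], bset2.bursts["size"])


class TestCorrections:
    def _single_burst_set(self, n_dd, n_ad, n_aa):
        times = np.sort(np.random.default_rng(0).uniform(0, 1e-3, n_dd + n_ad + n_aa))
        det = np.concatenate([np.zeros(n_dd), np.ones(n_ad), np.ones(n_aa)]).astype(np.int8)
        exc = np.concatenate([np.zeros(n_dd + n_ad), np.ones(n_aa)]).astype(np.int8)
        bursts = pd.DataFrame(
            [{
                "istart": 0, "istop": len(times) - 1, "t_start": 0.0, "t_stop": 1e-3,
                "duration": 1e-3, "size": len(times),
                "n_dd": n_dd, "n_ad": n_ad, "n_da": 0, "n_aa": n_aa,
            }]
        )
        bg = {"dd": 0.0, "ad": 0.0, "da": 0.0, "aa": 0.0, "all": 0.0}
        return BurstSet(times=times, detectors=det, excitation=exc, bursts=bursts, background=bg)

    def test_trivial_corrections_reproduce_apparent_values(self):
        bset = self._single_burst_set(25, 75, 100)
        df = correct_bursts(bset, CorrectionFactors())
        assert df.loc[0, "E"] == pytest.approx(0.75)
        assert df.loc[0, "E"] == pytest.approx(df.loc[0, "e_app"])
        assert df.loc[0, "S"] == pytest.approx(df.loc[0, "s_app"])

    def test_leakage_closed_form(self):
        # donor-only population with apparent E of 0.10 implies alpha = 1/9
        e_do = 0.10
        assert e_do / (1 - e_do) == pytest.approx(1 / 9)

    def test_gamma_beta_change_corrected_values(self):
        bset = self._single_burst_set(50, 50, 100)
        plain = correct_bursts(bset, CorrectionFactors())
        adj = correct_bursts(bset, CorrectionFactors(gamma=0.5, beta=2.0))
        assert adj.loc[0, "E"] > plain.loc[0, "E"]  # smaller gamma boosts E
        assert adj.loc[0, "S"] != plain.loc[0, "S"]

    def test_mixture_round_trip_recovers_truth(self):
        cfg = StreamConfig(
            populations=[
                Population(E=0.2, S=0.5, weight=0.35),
                Population(E=0.6, S=0.5, weight=0.35),
                Population(E=0.0, S=1.0, weight=0.15),
                Population(E=0.0, S=0.0, weight=0.15),
            ],
            burst_rate=15.0, alpha=0.05, delta=0.05, gamma=0.8, beta=1.2,
        )
        d, _ = simulate_photon_stream(cfg, duration=120.0, seed=4)
        bset = search_bursts(PhotonStream.from_dict(d))
        from interdom.bursts import estimate_factors

        factors = estimate_factors(bset)
        assert factors.alpha == pytest.approx(0.05, abs=0.015)
        assert factors.delta == pytest.approx(0.05, abs=0.02)
        assert factors.gamma == pytest.approx(0.8, abs=0.1)
        df = correct_bursts(bset, factors)
        kept = filter_bursts(bset, df)
        fit = fit_efret_distribution(kept, force=2)
        means = sorted(fit.modes)
        assert means[0] == pytest.approx(0.2, abs=0.04)
        assert means[1] == pytest.approx(0.6, abs=0.04)


class TestFiltering:
    def _df(self, s_values):
        return pd.DataFrame({"S": s_values, "valid": [True] * len(s_values)})

    def test_s_window_closed_boundaries(self, static_stream):
        stream, _ = static_stream
        bset = search_bursts(stream)
        df = correct_bursts(bset, CorrectionFactors())
        df = df.copy()
        df.loc[df.index[0], "S"] = 0.75
        df.loc[df.index[1], "S"] = 0.95
        kept = filter_bursts(bset, df, alex2cde_max=None)
        assert df.index[0] in kept.index  # boundary inclusive
        assert df.index[1] not in kept.index  # donor-only removed

    def test_alex2cde_separates_single_labelled(self):
        cfg = StreamConfig(
            populations=[Population(E=0.4, S=0.5, weight=0.5), Population(E=0.0, S=1.0, weight=0.5)],
            burst_rate=15.0, background=LOW_BG,
        )
        d, _ = simulate_photon_stream(cfg, duration=60.0, seed=7)
        bset = search_bursts(PhotonStream.from_dict(d))
        scores = alex_2cde(bset)
        df = correct_bursts(bset, CorrectionFactors())
        dual = df["s_app"].between(0.3, 0.7)
        donor_only = df["s_app"] > 0.9
        assert np.median(scores[dual]) < np.median(scores[donor_only])

    def test_invalid_tau_rejected(self, static_stream):
        stream, _ = static_stream
        bset = search_bursts(stream)
        with pytest.raises(ValueError, match="tau"):
            alex_2cde(bset, tau=-1.0)


class TestMixtureFit:
    def test_single_population_selected_and_located(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0.5, 0.05, 2000)
        fit = fit_efret_distribution(e)
        assert fit.n_components == 1
        assert fit.modes[0] == pytest.approx(0.5, abs=0.02)

    def test_balanced_mixture_resolved(self):
        rng = np.random.default_rng(1)
        e = np.concatenate([rng.normal(0.2, 0.05, 1000), rng.normal(0.6, 0.05, 1000)])
        fit = fit_efret_distribution(e)
        assert fit.n_components == 2
        assert fit.modes[0] == pytest.approx(0.2, abs=0.03)
        assert fit.modes[1] == pytest.approx(0.6, abs=0.03)

    def test_forced_single_component_mean_between_modes(self):
        rng = np.random.default_rng(2)
        e = np.concatenate([rng.normal(0.2, 0.05, 1000), rng.normal(0.6, 0.05, 1000)])
        fit = fit_efret_distribution(e, force=1)
        assert 0.2 < fit.modes[0] < 0.6

    def test_too_few_bursts_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_efret_distribution(np.full(50, 0.5))


class TestBva:
    def test_static_population_matches_shot_noise(self):
        cfg = StreamConfig(populations=[Population(E=0.4)], burst_rate=15.0, background=LOW_BG)
        d, _ = simulate_photon_stream(cfg, duration=60.0, seed=2)
        bset = search_bursts(PhotonStream.from_dict(d))
        res = bva(bset, window=5)
        big = res.bins[res.bins["n"] >= 50]
        assert len(big) >= 1
        assert (abs(big["sd_mean"] - big["sd_shot"]) / big["sd_shot"] <= 0.10).all()

    def test_zero_efficiency_windows_have_zero_sd(self):
        cfg = StreamConfig(populations=[Population(E=0.0)], burst_rate=15.0,
                           background={"dd": 0.0, "ad": 0.0, "aa": 0.0, "da": 0.0})
        d, _ = simulate_photon_stream(cfg, duration=20.0, seed=3)
        bset = search_bursts(PhotonStream.from_dict(d), background={"all": 100.0})
        res = bva(bset, window=5)
        assert np.allclose(res.per_burst["sd"], 0.0)

    def test_two_state_dynamics_exceed_shot_noise(self):
        cfg = StreamConfig(
            populations=[Population(E=0.2, E2=0.6, k12=10000.0, k21=10000.0)],
            burst_rate=15.0, background=LOW_BG,
        )
        d, _ = simulate_photon_stream(cfg, duration=60.0, seed=2)
        bset = search_bursts(PhotonStream.from_dict(d))
        res = bva(bset, window=5)
        big = res.bins[res.bins["n"] >= 50]
        excess = (big["sd_mean"] - big["sd_shot"]) / big["sd_se"]
        assert (excess > 3.0).all()

    def test_window_validation(self, static_stream):
        stream, _ = static_stream
        bset = search_bursts(stream)
        with pytest.raises(ValueError, match="window"):
            bva(bset, window=1)


def test_shot_noise_curve_maximal_at_half():
    e = np.linspace(0, 1, 101)
    sd = shot_noise_sd(e, 5)
    assert np.argmax(sd) == 50
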