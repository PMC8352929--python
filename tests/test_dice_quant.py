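import numpy as np
import pytest

from icer.alignment import AlignmentWindows
from icer.dice_quant import (
    DiceWindow,
    compute_kde_map,
    detect_peaks,
    extract_quant,
    filter_outlier_peaks,
    select_window,
)
from icer.io_formats import SampleIonMap
from icer.noise_fdr import NoiseModel

WINDOWS = AlignmentWindows(rt_window=0.3, mz_window=0.001)


def _cluster(rng, rt0, mz0, n=100, rt_sd=0.03, mz_sd=2e-4, intensity=1e4):
    return (rng.normal(rt0, rt_sd, n), rng.normal(mz0, mz_sd, n),
            np.full(n, intensity))


def _map_from_clusters(*clusters):
    rts = np.concatenate([c[0] for c in clusters])
    mzs = np.concatenate([c[1] for c in clusters])
    ints = np.concatenate([c[2] for c in clusters])
    return SampleIonMap("s", rts, mzs, ints)


def _const_noise(mean=0.0, sd=0.0, counts=()):
    return NoiseModel("s", None, 0.0, 0.0, mean, sd,
                      np.asarray(counts, dtype=float), np.zeros(0))


class TestComputeKdeMap:
    def test_zero_ions_zero_grid(self):
        m = SampleIonMap("s", [], [], [])
        kde = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1)
        assert kde.density.shape == (50, 50)
        assert np.all(kde.density == 0)

    def test_density_nonnegative(self, rng):
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0))
        kde = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1)
        assert np.all(kde.density >= 0)

    def test_argmax_matches_bruteforce_oracle(self, rng):
        # oracle: evaluate the same separable kernel density point by point
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0, n=100))
        kde = compute_kde_map(m, 20.05, 500.0002, WINDOWS, 0.1)
        idx = kde.ion_idx
        u = (m.rt[idx] - 20.05) / WINDOWS.rt_window
        v = (m.mz[idx] - 500.0002) / WINDOWS.mz_window

        def bandwidth(x):
            sd = np.std(x)
            iqr = np.subtract(*np.percentile(x, [75, 25]))
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            return max(0.9 * spread * x.size ** -0.2, 0.12) if spread > 0 else 0.2

        hu, hv = bandwidth(u), bandwidth(v)
        dense = np.zeros_like(kde.density)
        for i, gr in enumerate(kde.rt_grid):
            for j, gm in enumerate(kde.mz_grid):
                gu = (gr - 20.05) / WINDOWS.rt_window
                gv = (gm - 500.0002) / WINDOWS.mz_window
                dense[i, j] = np.sum(
                    np.exp(-0.5 * ((gu - u) / hu) ** 2)
                    * np.exp(-0.5 * ((gv - v) / hv) ** 2))
        assert np.unravel_index(np.argmax(dense), dense.shape) == \
            np.unravel_index(np.argmax(kde.density), kde.density.shape)

    def test_tight_cluster_max_within_one_cell(self, rng):
        m = _map_from_clusters(
            _cluster(rng, 20.0, 500.0, n=100, rt_sd=0.005, mz_sd=5e-5))
        kde = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1)
        i, j = np.unravel_index(np.argmax(kde.density), kde.density.shape)
        cell_rt = kde.rt_grid[1] - kde.rt_grid[0]
        cell_mz = kde.mz_grid[1] - kde.mz_grid[0]
        assert abs(kde.rt_grid[i] - 20.0) <= 1.5 * cell_rt
        assert abs(kde.mz_grid[j] - 500.0) <= 1.5 * cell_mz

    def test_resolution_doubling_stable(self, rng):
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0, n=80))
        k50 = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1, resolution=50)
        k100 = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1, resolution=100)
        i50, j50 = np.unravel_index(np.argmax(k50.density), k50.density.shape)
        i100, j100 = np.unravel_index(np.argmax(k100.density), k100.density.shape)
        cell_rt = k50.rt_grid[1] - k50.rt_grid[0]
        cell_mz = k50.mz_grid[1] - k50.mz_grid[0]
        assert abs(k50.rt_grid[i50] - k100.rt_grid[i100]) <= cell_rt
        assert abs(k50.mz_grid[j50] - k100.mz_grid[j100]) <= cell_mz


class TestDetectPeaks:
    def _detect(self, m, exp_rt, exp_mz, min_ions=0, rt_half=0.1,
                mz_half=0.001):
        kde = compute_kde_map(m, exp_rt, exp_mz, WINDOWS, rt_half)
        return detect_peaks(kde, m, exp_rt, exp_mz, rt_half, mz_half,
                            WINDOWS, min_ions)

    def test_single_cluster_single_candidate(self, rng):
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0))
        cands = self._detect(m, 20.0, 500.0)
        assert len(cands) == 1
        assert cands[0].rt == pytest.approx(20.0, abs=0.02)

    def test_two_clusters_nearer_ranked_first(self, rng):
        m = _map_from_clusters(
            _cluster(rng, 20.0, 500.0), _cluster(rng, 20.5, 500.002))
        cands = self._detect(m, 20.05, 500.0, min_ions=10)
        assert len(cands) == 2
        assert abs(cands[0].rt - 20.0) < abs(cands[1].rt - 20.0)
        assert cands[0].rank == 0

    def test_below_min_ions_outside_window_dropped(self, rng):
        m = _map_from_clusters(
            _cluster(rng, 20.4, 500.002, n=5))  # outside expected window
        cands = self._detect(m, 20.0, 500.0, min_ions=50)
        assert cands == []

    def test_inside_expected_window_kept_despite_low_count(self, rng):
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0, n=5))
        cands = self._detect(m, 20.0, 500.0, min_ions=50)
        assert len(cands) == 1
        assert cands[0].in_expected_window

    def test_at_most_five_candidates(self, rng):
        clusters = [_cluster(rng, 19.4 + 0.25 * k, 500.0 + 0.0012 * k, n=40)
                    for k in range(7)]
        m = _map_from_clusters(*clusters)
        cands = self._detect(m, 20.0, 500.0015, min_ions=1)
        assert len(cands) <= 5
        dists = [c.distance for c in cands]
        assert dists == sorted(dists)


class TestSelectWindow:
    def test_known_sample_nearest_valid_candidate(self, rng):
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0))
        kde = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1)
        cands = detect_peaks(kde, m, 20.0, 500.0, 0.1, 0.001, WINDOWS, 0)
        sel = select_window({"A": cands}, {"A": (20.0, 500.0)}, {"A"}, 7,
                            0.1, 0.001, WINDOWS, {"A": 0})
        assert sel["A"].origin == "known"
        assert sel["A"].consensus_id == 7

    def test_transfer_within_limits(self, rng):
        m_known = _map_from_clusters(_cluster(rng, 20.0, 500.0))
        kde_k = compute_kde_map(m_known, 20.0, 500.0, WINDOWS, 0.1)
        cands_k = detect_peaks(kde_k, m_known, 20.0, 500.0, 0.1, 0.001,
                               WINDOWS, 0)
        # unknown sample: cluster offset 2.5 mz windows from expected
        m_unk = _map_from_clusters(_cluster(rng, 20.05, 500.0025))
        kde_u = compute_kde_map(m_unk, 20.0, 500.0, WINDOWS, 0.1)
        cands_u = detect_peaks(kde_u, m_unk, 20.0, 500.0, 0.1, 0.001,
                               WINDOWS, 0)
        sel = select_window(
            {"A": cands_k, "B": cands_u},
            {"A": (20.0, 500.0), "B": (20.0, 500.0)}, {"A"}, 0,
            0.1, 0.001, WINDOWS, {"A": 0, "B": 0})
        assert sel["B"].origin == "transferred"
        assert sel["B"].mz_center == pytest.approx(500.0025, abs=2e-4)

    def test_transfer_beyond_three_mz_windows_falls_back(self, rng):
        m_known = _map_from_clusters(_cluster(rng, 20.0, 500.0))
        kde_k = compute_kde_map(m_known, 20.0, 500.0, WINDOWS, 0.1)
        cands_k = detect_peaks(kde_k, m_known, 20.0, 500.0, 0.1, 0.001,
                               WINDOWS, 0)
        m_unk = _map_from_clusters(_cluster(rng, 20.05, 500.0035))
        kde_u = compute_kde_map(m_unk, 20.0, 500.0, WINDOWS, 0.1)
        cands_u = detect_peaks(kde_u, m_unk, 20.0, 500.0, 0.1, 0.001,
                               WINDOWS, 20)
        sel = select_window(
            {"A": cands_k, "B": cands_u},
            {"A": (20.0, 500.0), "B": (20.0, 500.0)}, {"A"}, 0,
            0.1, 0.001, WINDOWS, {"A": 0, "B": 0})
        assert sel["B"].origin == "expected_fallback"
        assert sel["B"].rt_center == pytest.approx(20.0)

    def test_no_candidates_all_fallback(self):
        sel = select_window(
            {"A": [], "B": []}, {"A": (20.0, 500.0), "B": (20.1, 500.0)},
            {"A"}, 0, 0.1, 0.001, WINDOWS, {"A": 0, "B": 0})
        assert all(w.origin == "expected_fallback" for w in sel.values())

    def test_half_widths_identical_across_samples(self, rng):
        m = _map_from_clusters(_cluster(rng, 20.0, 500.0))
        kde = compute_kde_map(m, 20.0, 500.0, WINDOWS, 0.1)
        cands = detect_peaks(kde, m, 20.0, 500.0, 0.1, 0.001, WINDOWS, 0)
        sel = select_window(
            {"A": cands, "B": [], "C": []},
            {s: (20.0, 500.0) for s in "ABC"}, {"A"}, 0,
            0.12, 0.001, WINDOWS, {s: 0 for s in "ABC"})
        halfs = {(w.rt_half_width, w.mz_half_width) for w in sel.values()}
        assert halfs == {(0.12, 0.001)}


class TestExtractQuant:
    def test_empty_window_missing(self):
        m = SampleIonMap("s", [], [], [])
        w = DiceWindow("s", 0, 20.0, 0.1, 500.0, 0.001, "known")
        ev = extract_quant(m, w, _const_noise())
        assert (ev.ion_count, ev.total_intensity, ev.signal_intensity,
                ev.background_intensity) == (0, 0.0, 0.0, 0.0)
        assert ev.missing

    def test_signal_background_threshold_arithmetic(self):
        # direct threshold oracle: mean 25, sd 5 -> threshold 35
        m = SampleIonMap("s", [20.0] * 5, [500.0] * 5,
                         [10.0, 20.0, 30.0, 40.0, 50.0])
        w = DiceWindow("s", 0, 20.0, 0.1, 500.0, 0.001, "known")
        ev = extract_quant(m, w, _const_noise(mean=25.0, sd=5.0))
        assert ev.total_intensity == pytest.approx(150.0)
        assert ev.signal_intensity == pytest.approx(90.0)
        assert ev.background_intensity == pytest.approx(60.0)
        assert ev.signal_intensity + ev.background_intensity == \
            pytest.approx(ev.total_intensity)

    def test_all_below_threshold(self):
        m = SampleIonMap("s", [20.0] * 3, [500.0] * 3, [1.0, 2.0, 3.0])
        w = DiceWindow("s", 0, 20.0, 0.1, 500.0, 0.001, "known")
        ev = extract_quant(m, w, _const_noise(mean=100.0, sd=10.0))
        assert ev.signal_intensity == 0.0
        assert ev.total_intensity > 0

    def test_equals_bruteforce_on_random_instances(self, rng):
        n = 2000
        m = SampleIonMap("s", rng.uniform(0, 30, n), rng.uniform(400, 900, n),
                         rng.uniform(1, 100, n))
        for _ in range(100):
            rt_c = rng.uniform(2, 28)
            mz_c = rng.uniform(420, 880)
            rt_h = rng.uniform(0.05, 2.0)
            mz_h = rng.uniform(0.001, 5.0)
            w = DiceWindow("s", 0, rt_c, rt_h, mz_c, mz_h, "known")
            ev = extract_quant(m, w)
            mask = ((np.abs(m.rt - rt_c) <= rt_h)
                    & (np.abs(m.mz - mz_c) <= mz_h))
            assert ev.ion_count == int(mask.sum())
            assert ev.total_intensity == pytest.approx(
                float(m.intensity[mask].sum()), rel=1e-12)


def _selection_population(n_features=40, n_samples=5, jitter=0.005, seed=0):
    rng = np.random.default_rng(seed)
    selections, expected = {}, {}
    for fid in range(n_features):
        rt0, mz0 = 20.0 + fid, 500.0 + fid
        sel, exp = {}, {}
        for k in range(n_samples):
            sid = f"S{k}"
            dr = rng.normal(0, jitter)
            dm = rng.normal(0, jitter * WINDOWS.mz_window / WINDOWS.rt_window)
            sel[sid] = DiceWindow(sid, fid, rt0 + dr, 0.1, mz0 + dm, 0.001,
                                  "known")
            exp[sid] = (rt0, mz0)
        selections[fid] = sel
        expected[fid] = exp
    return selections, expected


class TestFilterOutlierPeaks:
    def test_clean_population_nothing_removed(self):
        selections, expected = _selection_population()
        removed, excluded, log = filter_outlier_peaks(
            selections, expected, None, {}, WINDOWS)
        assert not removed and not excluded and len(log) == 0

    def test_shifted_sample_excluded(self):
        selections, expected = _selection_population()
        bad = selections[3]["S2"]
        selections[3]["S2"] = DiceWindow(
            "S2", 3, bad.rt_center + 10 * WINDOWS.rt_window, 0.1,
            bad.mz_center, 0.001, "transferred")
        removed, excluded, log = filter_outlier_peaks(
            selections, expected, None, {}, WINDOWS)
        assert (3, "S2") in excluded
        assert 3 not in removed

    def test_high_iqr_feature_removed(self):
        selections, expected = _selection_population()
        for k, sid in enumerate(selections[7]):
            w = selections[7][sid]
            # scatter peaks over several windows in alternating directions
            shift = (3 + k) * WINDOWS.rt_window * (-1) ** k
            selections[7][sid] = DiceWindow(
                sid, 7, w.rt_center + shift, 0.1, w.mz_center, 0.001, "known")
        removed, excluded, log = filter_outlier_peaks(
            selections, expected, None, {}, WINDOWS)
        assert 7 in removed
        assert "feature_iqr_outlier" in set(log["reason"])

    def test_isotope_disagreement_excludes_cell(self):
        selections, expected = _selection_population(n_features=5)
        iso = {}
        for fid, sel in selections.items():
            iso[fid] = {
                sid: DiceWindow(sid, fid, w.rt_center, 0.1,
                                w.mz_center + 1.002 / 2, 0.001, "transferred")
                for sid, w in sel.items()
            }
        # one isotope peak off by 4 mz windows
        w = iso[2]["S1"]
        iso[2]["S1"] = DiceWindow("S1", 2, w.rt_center, 0.1,
                                  w.mz_center + 4 * WINDOWS.mz_window, 0.001,
                                  "transferred")
        charges = {fid: 2 for fid in selections}
        removed, excluded, log = filter_outlier_peaks(
            selections, expected, iso, charges, WINDOWS)
        assert (2, "S1") in excluded
        assert "isotope_disagreement" in set(log["reason"])

    def test_fallback_isotopes_ignored(self):
        selections, expected = _selection_population(n_features=3)
        iso = {fid: {sid: DiceWindow(sid, fid, 0.0, 0.1, 0.0, 0.001,
                                     "expected_fallback")
                     for sid in sel} for fid, sel in selections.items()}
        removed, excluded, _ = filter_outlier_peaks(
            selections, expected, iso, {fid: 2 for fid in selections}, WINDOWS)
        assert not excluded
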