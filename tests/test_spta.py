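"""Spike-triggered averaging, facilitation acceptance, density mapping."""

import numpy as np
import pytest

import limbdecode as ld
from limbdecode import spta
from limbdecode.synth import EMGRecord, FacilitationEffect, FacilitationSpec, SpikeTrainSet


def _spta_from(values, n_spikes=500):
    return spta.SpTAResult(np.asarray(values, dtype=float), n_spikes, 0)


class TestComputeSpta:
    def test_constant_emg_gives_flat_average(self):
        st = np.array([0.5, 1.0, 1.5])
        res = spta.compute_spta(st, np.full(3000, 2.0), min_spikes=1)
        assert res.values == pytest.approx(2.0)
        feats = spta.characterize_spta(res)
        assert feats.peak_magnitude == pytest.approx(0.0)

    def test_single_spike_average_is_its_window(self, rng):
        emg = np.abs(rng.standard_normal(3000))
        res = spta.compute_spta(np.array([1.0]), emg, min_spikes=1)
        assert np.array_equal(res.values, emg[980:1061])

    def test_window_length_81_samples(self, rng):
        res = spta.compute_spta(np.array([1.0]), np.abs(rng.standard_normal(3000)))
        assert res.values.size == 81

    def test_boundary_spikes_skipped_and_counted(self, rng):
        emg = np.abs(rng.standard_normal(1000))
        res = spta.compute_spta(np.array([0.005, 0.5, 0.995]), emg, min_spikes=1)
        assert res.n_spikes == 1 and res.n_skipped == 2

    def test_matches_bruteforce_averaging_oracle(self, rng):
        n = 400_000
        raw = rng.standard_normal(n) * 15.0
        st = np.sort(rng.uniform(0.5, n / 1000.0 - 0.5, 500))
        rec = EMGRecord(1000.0, ("RS",), raw[:, None])
        sp = SpikeTrainSet([st], ["u000"], np.array([[12.0, 4.0, 1.0]]))
        eff = FacilitationEffect("u000", "RS", 8.0, 30.0, 3.0)
        out = ld.inject_facilitation(rec, sp, FacilitationSpec([eff]))
        rect = np.abs(out.values[:, 0])
        res = spta.compute_spta(st, rect)
        # independent loop-based oracle
        acc = np.zeros(81)
        cnt = 0
        for t in st:
            i = int(round(t * 1000))
            if i - 20 >= 0 and i + 60 < rect.size:
                acc += rect[i - 20 : i + 61]
                cnt += 1
        assert res.n_spikes == cnt
        assert res.values == pytest.approx(acc / cnt)

    def test_insufficient_spikes_flagged(self, rng):
        emg = np.abs(rng.standard_normal(5000))
        res = spta.compute_spta(np.array([1.0, 2.0]), emg, min_spikes=100)
        assert not res.sufficient
        assert not spta.characterize_spta(res).accepted


class TestCharacterize:
    def test_flat_spta_rejected(self):
        feats = spta.characterize_spta(_spta_from(np.full(81, 3.0)))
        assert feats.onset_ms is None
        assert feats.peak_magnitude == pytest.approx(0.0)
        assert not feats.accepted

    def test_triangular_bump_pwhm_from_geometry(self):
        # symmetric triangle, base 4 ms, apex at +10 ms above a flat baseline:
        # at half height the width spans 2 ms
        v = np.zeros(81)
        apex = 20 + 10
        v[apex - 2 : apex + 3] = [0.0, 0.5, 1.0, 0.5, 0.0]
        feats = spta.characterize_spta(_spta_from(v))
        assert feats.pwhm_ms == pytest.approx(2.0)
        assert feats.peak_ms == pytest.approx(10.0)

    def test_noisy_injected_transient_recovered_within_1_ms(self, rng):
        n = 400_000
        raw = rng.standard_normal(n) * 20.0
        st = np.sort(rng.uniform(0.5, n / 1000.0 - 0.5, 500))
        rec = EMGRecord(1000.0, ("RS",), raw[:, None])
        sp = SpikeTrainSet([st], ["u000"], np.array([[12.0, 4.0, 1.0]]))
        eff = FacilitationEffect("u000", "RS", 8.0, 30.0, 3.0)
        out = ld.inject_facilitation(rec, sp, FacilitationSpec([eff]))
        feats = spta.characterize_spta(spta.compute_spta(st, np.abs(out.values[:, 0])))
        assert feats.onset_ms is not None
        assert abs(feats.onset_ms - 8.0) <= 1.0
        assert feats.accepted


class TestAcceptance:
    @pytest.mark.parametrize(
        "onset,pwhm,expected",
        [
            (4.0, 3.0, False),      # onset too early
            (10.0, 3.0, True),
            (10.0, 10.0, False),    # too wide
            (16.0, 3.0, False),     # onset too late
            (5.0, 0.75, True),      # boundaries inclusive
            (15.0, 9.0, True),
            (10.0, 0.5, False),     # too narrow
            (None, 3.0, False),     # no crossing
        ],
    )
    def test_physiological_windows(self, onset, pwhm, expected):
        feats = spta.SpTAFeatures(
            baseline_mean=0.0, baseline_sd=1.0, onset_ms=onset, offset_ms=None,
            peak_ms=10.0, peak_magnitude=5.0, pwhm_ms=pwhm, n_spikes=500,
        )
        assert spta.accept_pair(feats) is expected

    def test_widening_latency_window_is_monotone(self, rng):
        feats = [
            spta.SpTAFeatures(0.0, 1.0, float(o), None, 10.0, 5.0, float(w), 500)
            for o in rng.uniform(0, 30, 50)
            for w in rng.uniform(0, 12, 3)
        ]
        narrow = {i for i, f in enumerate(feats) if spta.accept_pair(f)}
        wide = {
            i for i, f in enumerate(feats)
            if spta.accept_pair(f, onset_window=(2.0, 20.0))
        }
        assert narrow <= wide


class TestDensityMap:
    def test_single_occupied_cell_is_the_maximum(self):
        coords = np.tile([[12.05, 4.05, 1.0]], (5, 1))
        dm = spta.compute_density_map(coords, np.ones(5, dtype=bool))
        assert dm.raw.max() == pytest.approx(1.0)
        assert (dm.raw > 0).sum() == 1
        assert dm.normalized.max() == pytest.approx(1.0)

    def test_no_accepted_units_all_zero(self, rng):
        coords = rng.uniform([8, 0, 0], [22, 16, 5], size=(30, 3))
        dm = spta.compute_density_map(coords, np.zeros(30, dtype=bool))
        assert not dm.raw.any() and not dm.normalized.any() and not dm.filtered.any()

    def test_values_in_unit_interval(self, rng):
        coords = rng.uniform([8, 0, 0], [22, 16, 5], size=(60, 3))
        flags = rng.uniform(size=60) < 0.4
        for view in ("horizontal", "coronal"):
            dm = spta.compute_density_map(coords, flags, view=view)
            for M in (dm.normalized, dm.filtered):
                assert M.min() >= 0.0 and M.max() <= 1.0

    def test_median_filter_matches_bruteforce_oracle(self, rng):
        from scipy import ndimage

        M = rng.uniform(size=(5, 5))
        out = ndimage.median_filter(M, size=3, mode="constant", cval=0.0)
        # brute-force sliding-window median with zero padding
        pad = np.zeros((7, 7))
        pad[1:6, 1:6] = M
        expect = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expect[i, j] = np.median(pad[i : i + 3, j : j + 3])
        assert out == pytest.approx(expect)

    def test_empty_unit_set_rejected(self):
        with pytest.raises(ValueError):
            spta.compute_density_map(np.empty((0, 3)), np.empty(0, dtype=bool))


class TestClustering:
    def _maps(self, mats):
        out = {}
        for name, M in mats.items():
            M = np.asarray(M, dtype=float)
            out[name] = spta.DensityMap(
                "horizontal", np.arange(M.shape[0] + 1), np.arange(M.shape[1] + 1),
                M, M, M,
            )
        return out

    def test_identical_maps_merge_first_at_zero_distance(self, rng):
        base = rng.uniform(size=(4, 4))
        maps = self._maps({"a": base, "b": base, "c": rng.uniform(size=(4, 4)) + 2})
        labels, Z, D = spta.cluster_density_maps(maps, use_filtered=False)
        i, j = labels.index("a"), labels.index("b")
        assert D[i, j] == 0.0
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {i, j}

    def test_distances_match_direct_summation_oracle(self, rng):
        mats = {k: rng.uniform(size=(3, 3)) for k in "abc"}
        maps = self._maps(mats)
        labels, _, D = spta.cluster_density_maps(maps, use_filtered=False)
        for x in "abc":
            for y in "abc":
                acc = 0.0
                for i in range(3):
                    for j in range(3):
                        acc += (mats[x][i, j] - mats[y][i, j]) ** 2
                assert D[labels.index(x), labels.index(y)] == pytest.approx(np.sqrt(acc))

    def test_grid_mismatch_rejected(self, rng):
        maps = self._maps({"a": rng.uniform(size=(3, 3)), "b": rng.uniform(size=(4, 4))})
        with pytest.raises(ValueError):
            spta.cluster_density_maps(maps)

    def test_grouped_session_recovers_muscle_groups(self, fac_session):
        s = fac_session
        rect = s.emg.copy()
        rect.values = np.abs(rect.values)
        table = spta.scan_pairs(s.spikes, rect)
        maps = {}
        for m in ld.MUSCLES:
            flags = (
                table[table["muscle"] == m]
                .set_index("unit")["accepted"]
                .reindex(s.spikes.unit_ids)
                .fillna(False)
                .to_numpy()
            )
            maps[m] = spta.compute_density_map(s.spikes.coords, flags)
        labels, Z, _ = spta.cluster_density_maps(maps)
        assert spta.pair_merge_order_ok(
            labels, Z, groups=[("RRF", "RMG"), ("RFHL", "RFDL"), ("RTA", "REDL")]
        )
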