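import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import microtrait as mt
from conftest import orthogonal_generators
from microtrait.maps import zero_mean
from microtrait.microstates import (
    LabelSequence,
    MicrostateModel,
    aahc,
    backfit,
    cluster_grand_mean,
    compute_stats,
    extract_peak_maps,
    find_gfp_peaks,
    segment_subject,
    sort_maps,
)
from microtrait.preprocess import average_reference, select_condition_and_epoch
from microtrait.synth import FixedRunLength, simulate_eeg, simulate_state_sequence


def _model_from_maps(maps, labels=None):
    maps = np.asarray(maps, dtype=float)
    K = maps.shape[0]
    return MicrostateModel(
        maps=maps,
        labels=labels or tuple("ABCDEFGH"[:K]),
        gev_per_map=np.full(K, 1.0 / K),
        gev_total=1.0,
    )


class TestGfpPeaks:
    def test_monotone_trace_has_no_peaks(self):
        assert find_gfp_peaks(np.arange(10.0)).size == 0

    def test_small_example(self):
        assert find_gfp_peaks(np.array([0.0, 1.0, 0.0, 2.0, 0.0])).tolist() == [1, 3]

    def test_plateau_counts_once(self):
        assert find_gfp_peaks(np.array([0.0, 1.0, 1.0, 0.0])).tolist() == [1]

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            find_gfp_peaks(np.array([]))

    def test_carrier_produces_two_peaks_per_cycle(self, montage16):
        gens = orthogonal_generators(4, 16, np.random.default_rng(0))
        lab = simulate_state_sequence(FixedRunLength(256), 1024, K=4, seed=0)
        rec = simulate_eeg(gens, lab, snr=None, oscillation_hz=10.0, sfreq=512.0, seed=1)
        epochs = average_reference(select_condition_and_epoch(rec))
        trace = mt.gfp(epochs.epochs[0], axis=0)
        n_peaks = find_gfp_peaks(trace).size
        assert abs(n_peaks - 40) <= 1  # 2 GFP maxima per 10 Hz cycle over 2 s


def _partitions_k(items, K):
    if K == 1:
        yield [list(items)]
        return
    if len(items) == K:
        yield [[i] for i in items]
        return
    first, rest = items[0], items[1:]
    for p in _partitions_k(rest, K):
        for b in range(len(p)):
            yield [blk + [first] if i == b else blk for i, blk in enumerate(p)]
    for p in _partitions_k(rest, K - 1):
        yield [[first]] + p


def _partition_gev(partition, maps, weights):
    """Independent oracle: GEV of a partition via each block's top eigenvalue."""
    U = maps - maps.mean(axis=1, keepdims=True)
    U = U / np.linalg.norm(U, axis=1, keepdims=True)
    total = np.sum(weights**2)
    g = 0.0
    for blk in partition:
        S = sum(np.outer(weights[i] * U[i], weights[i] * U[i]) for i in blk)
        g += np.linalg.eigvalsh(S)[-1]
    return g / total


class TestAahc:
    def test_noiseless_two_generator_recovery(self):
        rng = np.random.default_rng(3)
        gens = orthogonal_generators(2, 12, rng)
        assign = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        flips = rng.choice([-1.0, 1.0], size=10)
        X = gens[assign] * flips[:, None]
        model = aahc(X, 2, weights=np.ones(10))
        assert model.gev_total == pytest.approx(1.0, abs=1e-12)
        for g in gens:
            assert max(mt.spatial_correlation(g, m) for m in model.maps) == pytest.approx(1.0)
        got = frozenset(
            frozenset(np.flatnonzero(model.assignment == j).tolist()) for j in range(2)
        )
        want = frozenset(frozenset(np.flatnonzero(assign == k).tolist()) for k in range(2))
        assert got == want

    def test_k_equals_n_is_trivial_partition(self):
        rng = np.random.default_rng(4)
        X = np.stack([zero_mean(rng.normal(size=10)) for _ in range(5)])
        model = aahc(X, 5)
        assert model.n_states == 5
        assert model.gev_total == pytest.approx(1.0, abs=1e-12)

    def test_identical_maps_collapse_with_warning(self):
        base = zero_mean(np.arange(8.0))
        X = np.stack([base, -base, base, 2 * base])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = aahc(X, 2)
        assert model.n_states == 1
        assert model.gev_total == pytest.approx(1.0, abs=1e-9)

    def test_fewer_maps_than_k_raises(self):
        X = np.stack([zero_mean(np.random.default_rng(0).normal(size=6))])
        with pytest.raises(ValueError):
            aahc(X, 2)

    def test_matches_exhaustive_max_gev_on_small_instances(self):
        """Greedy AAHC vs brute-force best partition (balanced, modest noise)."""
        rng = np.random.default_rng(11)
        for _ in range(15):
            K = int(rng.integers(2, 4))
            n = int(rng.integers(6, 11))
            gens = orthogonal_generators(K, 16, rng)
            assign = np.array([i % K for i in range(n)])
            rng.shuffle(assign)
            X = gens[assign] + 0.1 * np.stack(
                [zero_mean(rng.normal(size=16)) for _ in range(n)]
            )
            X *= rng.choice([-1.0, 1.0], size=n)[:, None]
            w = rng.uniform(0.8, 1.2, size=n)
            model = aahc(X, K, weights=w)
            best = max(
                _partition_gev(p, X, w) for p in _partitions_k(list(range(n)), K)
            )
            assert model.gev_total == pytest.approx(best, abs=1e-9)


class TestGrandMean:
    def test_consensus_of_identical_subjects(self):
        gens = orthogonal_generators(4, 16, np.random.default_rng(5))
        models = [_model_from_maps(gens) for _ in range(5)]
        gm = cluster_grand_mean(models, 4)
        for g in gens:
            assert max(mt.spatial_correlation(g, m) for m in gm.maps) == pytest.approx(1.0)

    def test_single_subject_raises(self):
        gens = orthogonal_generators(4, 16, np.random.default_rng(6))
        with pytest.raises(ValueError):
            cluster_grand_mean([_model_from_maps(gens)], 4)

    def test_channel_mismatch_raises(self):
        a = _model_from_maps(orthogonal_generators(2, 16, np.random.default_rng(0)))
        b = _model_from_maps(orthogonal_generators(2, 12, np.random.default_rng(0)))
        with pytest.raises(ValueError):
            cluster_grand_mean([a, b], 2)


class TestSortMaps:
    def test_already_sorted_is_identity(self, proto4):
        model = _model_from_maps(proto4)
        out = sort_maps(model, proto4)
        assert np.array_equal(out.maps, model.maps)
        assert out.labels == ("A", "B", "C", "D")

    def test_known_shuffle_recovered(self, proto4):
        perm = [2, 0, 3, 1]
        model = _model_from_maps(proto4[perm])
        out = sort_maps(model, proto4)
        assert np.allclose(out.maps, proto4)
        assert out.sort_objective == pytest.approx(4.0)

    def test_matches_hungarian_assignment(self, montage16):
        """Exhaustive search vs linear-sum assignment as an independent oracle."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            model = _model_from_maps(orthogonal_generators(4, 16, rng))
            tmpl = np.stack([zero_mean(rng.normal(size=16)) for _ in range(4)])
            out = sort_maps(model, tmpl)
            corr = np.abs(
                np.array(
                    [
                        [mt.spatial_correlation(model.maps[i], tmpl[k]) for k in range(4)]
                        for i in range(4)
                    ]
                )
            )
            rows, cols = linear_sum_assignment(-corr)
            assert out.sort_objective == pytest.approx(corr[rows, cols].sum(), abs=1e-12)


class TestBackfit:
    def _epochs_and_truth(
        self, montage16, snr=None, seconds=20.0, flip=1.0, scale=1.0, am_depth=0.5
    ):
        gens = orthogonal_generators(4, 16, np.random.default_rng(7))
        sfreq, osc = 512.0, 8.0  # half-period of exactly 32 samples
        snap = sfreq / (2 * osc)
        lab = simulate_state_sequence(
            mt.GammaRunLength.from_ms(80.0, 15.0, sfreq),
            int(seconds * sfreq), K=4, seed=8, snap_period=snap,
        )
        rec = simulate_eeg(
            gens, lab, snr=snr, oscillation_hz=osc, sfreq=sfreq, seed=9,
            am_depth=am_depth,
        )
        rec.data *= flip * scale
        epochs = average_reference(select_condition_and_epoch(rec))
        truth = lab[: epochs.n_epochs * epochs.epochs.shape[2]].reshape(
            epochs.n_epochs, -1
        )
        return epochs, truth, gens

    def test_noiseless_labels_match_generating_sequence(self, montage16):
        # pure carrier: state switches sit exactly at carrier zero crossings,
        # where the field is null and a label is undefined in principle
        epochs, truth, gens = self._epochs_and_truth(montage16, am_depth=0.0)
        seq = backfit(epochs, _model_from_maps(gens))
        informative = seq.gfp > 1e-9 * seq.gfp.max()
        agreement = np.mean(seq.labels[informative] == truth[informative])
        assert agreement >= 0.99
        assert np.mean(seq.labels == truth) >= 0.97  # boundary samples only

    def test_polarity_flip_leaves_labels_unchanged(self, montage16):
        epochs, _, gens = self._epochs_and_truth(montage16, snr=5.0)
        flipped, _, _ = self._epochs_and_truth(montage16, snr=5.0, flip=-1.0)
        model = _model_from_maps(gens)
        a = backfit(epochs, model)
        b = backfit(flipped, model)
        assert np.array_equal(a.labels, b.labels)

    def test_scale_invariance(self, montage16):
        epochs, _, gens = self._epochs_and_truth(montage16, snr=5.0)
        scaled, _, _ = self._epochs_and_truth(montage16, snr=5.0, scale=13.7)
        model = _model_from_maps(gens)
        assert np.array_equal(backfit(epochs, model).labels, backfit(scaled, model).labels)

    def test_single_state_model_labels_everything(self, montage16):
        epochs, _, gens = self._epochs_and_truth(montage16)
        seq = backfit(epochs, _model_from_maps(gens[:1]))
        assert np.all(seq.labels == 0)


class TestComputeStats:
    def _sequence(self, labels_2d, sfreq=100.0):
        labels_2d = np.asarray(labels_2d)
        return LabelSequence(
            labels=labels_2d,
            gfp=np.ones_like(labels_2d, dtype=float),
            fit_corr=np.ones_like(labels_2d, dtype=float),
            sfreq=sfreq,
        )

    def test_truncation_rule_hand_trace(self):
        # one 100 Hz epoch: A x10, B x15, A x10, B x15 -> only the interior
        # runs (B 15, A 10) count toward durations
        lab = np.array([[0] * 10 + [1] * 15 + [0] * 10 + [1] * 15])
        seq = self._sequence(lab)
        model = _model_from_maps(orthogonal_generators(2, 8, np.random.default_rng(0)), ("A", "B"))
        stats = compute_stats(seq, model)
        assert stats.duration_ms["A"] == pytest.approx(100.0)
        assert stats.duration_ms["B"] == pytest.approx(150.0)
        # occurrences: runs starting strictly inside the epoch, / 0.5 s
        assert stats.occurrence_hz["A"] == pytest.approx(2.0)
        assert stats.occurrence_hz["B"] == pytest.approx(4.0)

    def test_single_type_covers_everything(self):
        lab = np.zeros((2, 50), dtype=int)
        model = _model_from_maps(orthogonal_generators(4, 8, np.random.default_rng(1)))
        stats = compute_stats(self._sequence(lab), model)
        assert stats.coverage["A"] == pytest.approx(1.0)
        assert stats.coverage["B"] == stats.coverage["C"] == stats.coverage["D"] == 0.0
        assert any("never occurs" in f for f in stats.flags)
        assert np.isnan(stats.duration_ms["B"])
        assert stats.mean_duration == pytest.approx(stats.duration_ms["A"])

    def test_accounting_identity_without_truncation(self):
        rng = np.random.default_rng(13)
        model = _model_from_maps(orthogonal_generators(4, 8, rng))
        for _ in range(10):
            lab = rng.integers(0, 4, size=(3, 200))
            stats = compute_stats(self._sequence(lab), model, exclude_truncated=False)
            total = sum(
                stats.duration_ms[k] * stats.occurrence_hz[k]
                for k in model.labels
                if not np.isnan(stats.duration_ms[k])
            )
            assert total == pytest.approx(1000.0 * sum(stats.coverage.values()), abs=1e-6)

    def test_coverage_sums_to_one(self):
        rng = np.random.default_rng(14)
        model = _model_from_maps(orthogonal_generators(4, 8, rng))
        lab = rng.integers(0, 4, size=(4, 123))
        stats = compute_stats(self._sequence(lab), model)
        assert sum(stats.coverage.values()) == pytest.approx(1.0, abs=1e-9)


class TestSegmentSubject:
    def test_identical_subjects_identical_stats(self, montage64, short_recording):
        epochs = mt.preprocess_recording(short_recording.recording, montage64)
        a = segment_subject(epochs)[2]
        b = segment_subject(epochs)[2]
        assert a.as_dict() == b.as_dict()

    def test_gev_partition_is_valid(self, montage64, short_recording):
        epochs = mt.preprocess_recording(short_recording.recording, montage64)
        model, _seq, stats = segment_subject(epochs)
        assert 0.0 <= stats.gev_total <= 1.0
        assert model.gev_total == pytest.approx(model.gev_per_map.sum())

    def test_high_snr_explains_most_variance(self, montage64):
        sim = mt.simulate_recording(montage64, record_seconds=20.0, snr=10.0, seed=21)
        epochs = mt.preprocess_recording(sim.recording, montage64)
        _model, _seq, stats = segment_subject(epochs)
        assert stats.gev_total >= 0.9

    def test_requires_average_reference(self, montage64, short_recording):
        epochs = select_condition_and_epoch(short_recording.recording)
        with pytest.raises(ValueError, match="average"):
            mt.MicrostateSegmentation(epochs)

    def test_peak_extraction_yields_zero_mean_maps(self, montage64, short_recording):
        epochs = mt.preprocess_recording(short_recording.recording, montage64)
        maps, weights = extract_peak_maps(epochs)
        assert maps.shape[1] == 64
        assert weights.shape == (maps.shape[0],)
        assert np.max(np.abs(maps.mean(axis=1))) < 1e-9
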