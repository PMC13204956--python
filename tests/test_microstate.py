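"""GFP, clustering, alignment, soft backfitting and microstate statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from mscascade.microstate import (
    SoftSequence,
    TemplateSet,
    align_bands,
    backfit_soft,
    detect_gfp_peaks,
    fuse_bands,
    gev,
    gfp,
    label_canonical,
    load_fused_epochs,
    microstate_stats,
    modified_kmeans,
    save_fused_epochs,
    spatial_corr,
)


class TestGfp:
    def test_constant_map_is_zero(self):
        assert gfp(np.full(19, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_two_channel_hand_case(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_offset_invariance(self, rng):
        x = rng.normal(size=12)
        assert gfp(x) == pytest.approx(gfp(x + 5.3))

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.ones((1, 10)))


class TestPeakDetection:
    def test_hand_enumeration(self):
        assert list(detect_gfp_peaks([0, 1, 0, 2, 0])) == [1, 3]

    def test_monotone_series_has_none(self):
        assert detect_gfp_peaks(np.arange(10.0)).size == 0

    def test_endpoints_never_returned(self, rng):
        for _ in range(20):
            s = rng.normal(size=50)
            peaks = detect_gfp_peaks(s)
            assert 0 not in peaks and 49 not in peaks


class TestSpatialCorr:
    def test_identity_and_polarity(self, rng):
        x = rng.normal(size=19)
        assert spatial_corr(x, x) == pytest.approx(1.0)
        assert spatial_corr(x, -x, polarity_invariant=False) == pytest.approx(-1.0)
        assert spatial_corr(x, -x, polarity_invariant=True) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        assert spatial_corr([1, -1, 0, 0], [0, 0, 1, -1]) == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_corr(np.ones(4), np.arange(4.0))


class TestModifiedKmeans:
    def test_recovers_planted_prototypes(self, prototype_maps, rng):
        n = 200
        assign = rng.integers(4, size=n)
        signs = rng.choice([-1.0, 1.0], size=n)
        maps = prototype_maps[assign] * signs[:, None] + rng.normal(0, 0.1, (n, 19))
        ts = modified_kmeans(maps, seed=0)
        # every prototype matched by a distinct recovered template
        corr = np.abs(ts.maps @ prototype_maps.T)
        rows, cols = linear_sum_assignment(1 - corr)
        assert sorted(cols.tolist()) == [0, 1, 2, 3]
        assert corr[rows, cols].min() >= 0.95

    def test_single_cluster_sign_flips(self, rng):
        base = rng.normal(size=19)
        base -= base.mean()
        maps = np.array([base * s for s in (1, -1, 1, -1, 1)])
        ts = modified_kmeans(maps, k=1, seed=0)
        assert spatial_corr(ts.maps[0], base) == pytest.approx(1.0)

    def test_beats_random_template_sets(self, prototype_maps, rng):
        n = 120
        maps = prototype_maps[rng.integers(4, size=n)] + rng.normal(0, 0.2, (n, 19))
        ts = modified_kmeans(maps, seed=1)
        g = gfp(maps.T)
        for _ in range(100):
            rand = rng.normal(size=(4, 19))
            rand -= rand.mean(axis=1, keepdims=True)
            rand /= np.linalg.norm(rand, axis=1, keepdims=True)
            assert ts.gev_total >= gev(rand, maps, g) - 1e-9

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(rng.normal(size=(3, 19)), k=4)

    def test_identical_maps_degenerate(self):
        base = np.linspace(-1, 1, 19)
        with pytest.raises(ValueError):
            modified_kmeans(np.tile(base, (10, 1)), k=4)


class TestGev:
    def test_perfect_fit(self, prototype_maps, rng):
        maps = prototype_maps[rng.integers(4, size=50)] * rng.choice([-1, 1], size=(50, 1))
        assert gev(prototype_maps, maps) == pytest.approx(1.0)

    def test_orthogonal_maps_zero(self):
        templates = np.array([[1.0, -1.0, 0.0, 0.0]])
        maps = np.array([[0.0, 0.0, 1.0, -1.0]] * 5)
        assert gev(templates, maps) == pytest.approx(0.0, abs=1e-12)

    def test_single_map_half_correlation(self):
        # one map correlating 0.5 with its best template -> GEV 0.25
        t = np.array([1.0, -1.0, 1.0, -1.0])
        m = np.array([1.0, 1.0, 0.0, -2.0])
        rho = spatial_corr(t, m)
        templates = (t - t.mean()) / np.linalg.norm(t - t.mean())
        assert gev(templates[None, :], m[None, :]) == pytest.approx(rho**2)

    def test_sign_flip_invariance(self, prototype_maps, rng):
        maps = rng.normal(size=(30, 19))
        flipped = maps * rng.choice([-1, 1], size=(30, 1))
        assert gev(prototype_maps, maps, gfp(maps.T)) == pytest.approx(
            gev(-prototype_maps, flipped, gfp(maps.T))
        )


class TestAlignment:
    def test_identity_labeling(self, ideal_templates, prototype_maps):
        out = label_canonical(ideal_templates, prototype_maps)
        assert out.labels == ("A", "B", "C", "D")

    def test_known_permutation_recovered(self, prototype_maps, rng):
        perm = [2, 0, 3, 1]
        shuffled = TemplateSet("alpha", prototype_maps[perm], ("A", "B", "C", "D"))
        anchor = TemplateSet("broadband", prototype_maps, ("A", "B", "C", "D"))
        out = align_bands(shuffled, anchor)
        assert out.labels == ("C", "A", "D", "B")

    def test_permutation_with_noise_and_sign_flips(self, prototype_maps, rng):
        anchor = TemplateSet("broadband", prototype_maps, ("A", "B", "C", "D"))
        for _ in range(10):
            perm = rng.permutation(4)
            noisy = prototype_maps[perm] * rng.choice([-1, 1], size=(4, 1))
            noisy = noisy + rng.normal(0, 0.05, (4, 19))
            out = align_bands(TemplateSet("delta", noisy, ("A", "B", "C", "D")), anchor)
            expected = tuple("ABCD"[i] for i in perm)
            assert out.labels == expected

    def test_hungarian_equals_exhaustive_search(self, rng):
        for _ in range(120):
            cost = rng.random((4, 4))
            rows, cols = linear_sum_assignment(cost)
            hung = cost[rows, cols].sum()
            brute = min(
                sum(cost[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert hung == pytest.approx(brute)

    def test_montage_mismatch_rejected(self, prototype_maps):
        anchor = TemplateSet("broadband", prototype_maps, ("A", "B", "C", "D"))
        small = TemplateSet("delta", np.eye(4)[:, :4] - 0.25, ("A", "B", "C", "D"))
        with pytest.raises(ValueError):
            align_bands(small, anchor)


class TestBackfitAndFusion:
    def test_template_frame_scores_one(self, ideal_templates, rng):
        data = rng.normal(size=(19, 10))
        data[:, 4] = ideal_templates.map_for("B")
        seq = backfit_soft(data, ideal_templates)
        assert seq.values[1, 4] == pytest.approx(1.0)
        assert np.all(seq.values >= 0) and np.all(seq.values <= 1)

    def test_default_epoch_shape(self, ideal_templates, rng):
        seq = backfit_soft(rng.normal(size=(19, 2560)), ideal_templates)
        assert seq.values.shape == (4, 2560)

    def test_zero_variance_frames_flagged(self, ideal_templates, rng):
        data = rng.normal(size=(19, 8))
        data[:, 3] = 2.5  # flat topography
        seq = backfit_soft(data, ideal_templates)
        assert 3 in seq.flagged
        assert np.all(seq.values[:, 3] == 0)

    def test_fuse_ordering_and_round_trip(self, rng):
        a = SoftSequence("alpha", rng.random((4, 100)), "s1", 0)
        d = SoftSequence("delta", rng.random((4, 100)), "s1", 0)
        fused = fuse_bands(a, d, "stage1")
        assert fused.values.shape == (8, 100)
        assert np.array_equal(fused.values[0], a.values[0])
        assert np.array_equal(fused.values[:4], a.values)
        assert np.array_equal(fused.values[4:], d.values)

    def test_fuse_mismatch_rejected(self, rng):
        a = SoftSequence("alpha", rng.random((4, 100)), "s1", 0)
        b = SoftSequence("delta", rng.random((4, 100)), "s2", 0)
        with pytest.raises(ValueError):
            fuse_bands(a, b, "stage1")

    def test_fused_epoch_serialization(self, tmp_path, rng):
        a = SoftSequence("alpha", rng.random((4, 64)), "s1", 3)
        d = SoftSequence("delta", rng.random((4, 64)), "s1", 3)
        fused = fuse_bands(a, d, "stage1")
        save_fused_epochs(tmp_path / "f.npz", [fused])
        back = load_fused_epochs(tmp_path / "f.npz")[0]
        assert np.allclose(back.values, fused.values)
        assert back.bands == ("alpha", "delta")
        assert back.epoch_index == 3


class TestMicrostateStats:
    def test_worked_example(self):
        # 128 A, 128 B, 256 A at 256 Hz
        labels = np.array([0] * 128 + [1] * 128 + [0] * 256)
        values = np.zeros((4, 512))
        values[labels, np.arange(512)] = 1.0
        stats = microstate_stats(SoftSequence("alpha", values, "s", 0), 256.0)
        assert stats.coverage["A"] == pytest.approx(0.75)
        assert stats.coverage["B"] == pytest.approx(0.25)
        assert stats.occurrence["A"] == pytest.approx(1.0)
        assert stats.occurrence["B"] == pytest.approx(0.5)
        assert stats.mean_dwell["A"] == pytest.approx(750.0)
        assert stats.mean_dwell["B"] == pytest.approx(500.0)
        # transitions between consecutive distinct segments, rows normalized:
        # the only A-exit goes to B and the only B-exit goes to A
        assert stats.transitions[0, 1] == pytest.approx(1.0)
        assert stats.transitions[1, 0] == pytest.approx(1.0)

    def test_degenerate_single_state(self):
        values = np.zeros((4, 100))
        values[0] = 1.0
        stats = microstate_stats(SoftSequence("alpha", values, "s", 0), 256.0)
        assert stats.coverage["A"] == pytest.approx(1.0)
        assert np.all(stats.transitions == 0)
        assert set(stats.empty_rows) == {"A", "B", "C", "D"}

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_coverage_conservation(self, seed):
        r = np.random.default_rng(seed)
        values = r.random((4, 200))
        stats = microstate_stats(SoftSequence("alpha", values, "s", 0), 256.0)
        assert sum(stats.coverage.values()) == pytest.approx(1.0)
        rowsums = stats.transitions.sum(axis=1)
        assert np.all((np.abs(rowsums - 1) < 1e-9) | (rowsums == 0))
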