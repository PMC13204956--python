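"""The planted-ground-truth EEG generator."""

import json

import numpy as np
import pytest
from scipy.signal import welch

from mscascade.io_core import read_recording, rereference_average
from mscascade.microstate import backfit_soft, spatial_corr
from mscascade.synthetic import (
    CohortSpec,
    make_prototypes,
    null_spec,
    simulate_cohort,
    simulate_subject,
    write_cohort,
)


def band_power(data, rate, lo, hi):
    f, p = welch(data, fs=rate, nperseg=1024)
    return p[:, (f >= lo) & (f <= hi)].sum()


class TestPrototypes:
    def test_construction_invariants(self, prototypes):
        for p in prototypes:
            assert abs(p.map.mean()) < 1e-12
            assert abs(np.linalg.norm(p.map) - 1.0) < 1e-12

    def test_pairwise_dissimilarity(self, prototypes):
        for i in range(4):
            for j in range(i + 1, 4):
                assert abs(float(prototypes[i].map @ prototypes[j].map)) < 0.9

    def test_class_a_extrema_locations(self, prototypes, montage):
        a = prototypes[0].map
        right_anterior = {"Fp2", "F4", "F8"}
        left_posterior = {"O1", "T5", "P3"}
        assert montage.names[a.argmax()] in right_anterior
        assert montage.names[a.argmin()] in left_posterior


class TestSimulateSubject:
    def test_seeded_determinism(self):
        a, _ = simulate_subject("HC", 20, 256, seed=5)
        b, _ = simulate_subject("HC", 20, 256, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_hc_alpha_dominates_delta(self):
        rec, _ = simulate_subject("HC", 60, 256, seed=1)
        alpha = band_power(rec.data, 256, 8, 13)
        delta = band_power(rec.data, 256, 0.5, 4)
        assert alpha > delta

    def test_ad_alpha_attenuated_relative_to_hc(self):
        spec = CohortSpec(alpha_attenuation=0.3, delta_burst_rate_per_min=0.0)
        hc, _ = simulate_subject("HC", 60, 256, seed=2, spec=spec)
        ad, _ = simulate_subject("AD", 60, 256, seed=2, spec=spec)
        ratio = band_power(ad.data, 256, 8, 13) / band_power(hc.data, 256, 8, 13)
        assert ratio < 1.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_subject("MCI", 10, 256, seed=0)

    def test_segment_durations_within_bounds(self):
        _, gt = simulate_subject("HC", 30, 256, seed=3)
        inner = gt.segment_durations_ms[1:-1]  # first/last may be clipped
        assert inner.min() >= 55.0  # 60 ms minus one-sample rounding
        assert inner.max() <= 125.0

    def test_ground_truth_covers_recording(self):
        rec, gt = simulate_subject("FTD", 15, 256, seed=4)
        assert gt.state_sequence.size == rec.n_samples
        assert set(np.unique(gt.state_sequence)) <= {0, 1, 2, 3}


class TestCohort:
    def test_counts_labels_and_unique_ids(self):
        spec = CohortSpec(n_per_class={"AD": 2, "FTD": 2, "HC": 2}, duration_s=12.0, seed=9)
        cohort = simulate_cohort(spec)
        assert len(cohort) == 6
        ids = [rec.subject_id for rec, _ in cohort]
        assert len(set(ids)) == 6
        assert sorted(rec.group for rec, _ in cohort) == ["AD", "AD", "FTD", "FTD", "HC", "HC"]

    def test_regeneration_is_identical(self):
        spec = CohortSpec(n_per_class={"AD": 1, "FTD": 1, "HC": 1}, duration_s=12.0, seed=11)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for (ra, ga), (rb, gb) in zip(a, b):
            assert np.array_equal(ra.data, rb.data)
            assert np.array_equal(ga.state_sequence, gb.state_sequence)

    def test_null_spec_disables_class_effects(self):
        spec = null_spec(duration_s=12.0)
        assert spec.alpha_attenuation == 1.0
        assert spec.delta_burst_rate_per_min == 0.0

    def test_write_cohort_round_trip(self, tmp_path):
        spec = CohortSpec(n_per_class={"AD": 1, "FTD": 0, "HC": 1}, duration_s=12.0, seed=2)
        cohort = simulate_cohort(spec)
        write_cohort(cohort, tmp_path)
        rec = read_recording(tmp_path / "sim-000.edf", "edf")
        assert rec.n_samples == cohort[0][0].n_samples
        sidecar = json.loads((tmp_path / "sim-000_truth.json").read_text())
        assert sidecar["class_label"] == "AD"
        total = sum(n for _, n in sidecar["state_sequence_rle"])
        assert total == cohort[0][1].state_sequence.size


class TestPlantedStructureRecovery:
    def test_backfit_recovers_latent_labels_noise_free(self, ideal_templates):
        spec = CohortSpec(noise_sd=0.0)
        rec, gt = simulate_subject("HC", 20, 256, seed=21, spec=spec)
        rec = rereference_average(rec)
        seq = backfit_soft(rec.data, ideal_templates)
        acc = np.mean(seq.values.argmax(axis=0) == gt.state_sequence)
        assert acc >= 0.99

    def test_gfp_peak_clustering_recovers_templates(self, prototype_maps):
        from mscascade.io_core import BANDS, bandpass
        from mscascade.microstate import detect_gfp_peaks, gfp, label_canonical, modified_kmeans

        spec = CohortSpec(noise_sd=0.05)
        rec, _ = simulate_subject("HC", 60, 256, seed=22, spec=spec)
        rec = rereference_average(rec)
        bb = bandpass(rec, BANDS["broadband"])
        peaks = detect_gfp_peaks(gfp(bb.data))
        templates = label_canonical(modified_kmeans(bb.data[:, peaks].T, seed=0))
        for i, label in enumerate("ABCD"):
            assert spatial_corr(templates.map_for(label), prototype_maps[i]) >= 0.95
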