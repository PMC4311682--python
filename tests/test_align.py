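"""Chromatographic centroid, reference selection, and COW alignment."""

import itertools

import numpy as np
import pytest

from mrmflow import (
    Chromatogram,
    CowParams,
    IntensityDrift,
    RTDrift,
    SampleRecord,
    SynthSpec,
    TransitionKey,
    align_study,
    chromatographic_centroid,
    cow_align,
    generate_study,
    select_reference,
)
from mrmflow.align import UndefinedCentroidError, _boundaries, _segment_correlation


class TestCentroid:
    @pytest.mark.parametrize(
        "times,intensities,expected",
        [
            ([1, 2, 3, 4, 5], [0, 1, 2, 1, 0], 3.0),  # symmetric
            ([1.0, 2.5, 4.0], [0, 7, 0], 2.5),  # point mass
            ([10.0, 20.0], [1, 3], 17.5),  # weighted mean: (10+60)/4
        ],
    )
    def test_weighted_mean(self, key, times, intensities, expected):
        c = Chromatogram(key, np.asarray(times, float), np.asarray(intensities, float))
        assert chromatographic_centroid(c) == pytest.approx(expected)

    def test_all_zero_is_undefined(self, key):
        c = Chromatogram(key, [1.0, 2.0], [0.0, 0.0])
        with pytest.raises(UndefinedCentroidError):
            chromatographic_centroid(c)

    def test_within_time_range(self, key):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 30, 50))
        t += np.arange(50) * 1e-6
        y = rng.uniform(0, 100, 50)
        c = Chromatogram(key, t, y)
        assert t[0] <= chromatographic_centroid(c) <= t[-1]


def _study_store(gravity_by_sample, key):
    """One-transition store with a point mass at each sample's target gravity."""
    store = {key: {}}
    for sid, g in gravity_by_sample.items():
        store[key][sid] = Chromatogram(
            key, np.array([g - 1.0, g, g + 1.0]), np.array([0.0, 10.0, 0.0]), sample_id=sid
        )
    return store


class TestSelectReference:
    def test_closest_to_midpoint(self, key):
        qcs = [SampleRecord(s, "", "QC", i + 1, "QC") for i, s in enumerate("ABC")]
        store = _study_store({"A": 10.0, "B": 12.0, "C": 14.1}, key)
        # midpoint (10 + 14.1)/2 = 12.05 -> B
        assert select_reference(qcs, store) == "B"

    def test_single_qc_returned(self, key):
        qcs = [SampleRecord("only", "", "QC", 1, "QC")]
        assert select_reference(qcs, _study_store({"only": 9.0}, key)) == "only"

    def test_tie_breaks_by_injection_order(self, key):
        qcs = [SampleRecord("B", "", "QC", 5, "QC"), SampleRecord("A", "", "QC", 2, "QC")]
        store = _study_store({"A": 10.0, "B": 14.0}, key)
        # both are 2.0 from midpoint 12 -> lower injection order (A) wins
        assert select_reference(qcs, store) == "A"

    def test_no_signal_errors(self, key):
        qcs = [SampleRecord("A", "", "QC", 1, "QC")]
        store = {key: {"A": Chromatogram(key, [1.0, 2.0], [0.0, 0.0], sample_id="A")}}
        with pytest.raises(ValueError, match="manual"):
            select_reference(qcs, store)


def brute_force_cow(query, reference, params):
    """Enumerate every feasible boundary assignment; return the best objective.

    Feasibility mirrors the DP contract: endpoints pinned, each warped
    segment >= 2 scans with length within +/- slack of its nominal length.
    """
    dt = float(np.median(np.diff(reference.times)))
    seg_scans = int(round(params.segment_size / dt))
    n_ref, n_q = len(reference), len(query)
    n_segments = max(1, int(round((n_ref - 1) / seg_scans)))
    ref_b = _boundaries(n_ref, n_segments)
    nominal = np.rint(np.linspace(0, n_q - 1, n_segments + 1)).astype(int)
    best = -np.inf
    interior = []
    for i in range(1, n_segments):
        dev = min(i, n_segments - i) * params.slack
        interior.append(range(nominal[i] - dev, nominal[i] + dev + 1))
    for combo in itertools.product(*interior):
        bounds = (0, *combo, n_q - 1)
        ok = all(
            bounds[i] - bounds[i - 1] >= 1
            and abs((bounds[i] - bounds[i - 1]) - (nominal[i] - nominal[i - 1])) <= params.slack
            for i in range(1, n_segments + 1)
        )
        if not ok:
            continue
        score = sum(
            _segment_correlation(
                reference.intensities[ref_b[i - 1] : ref_b[i] + 1],
                query.intensities,
                bounds[i - 1],
                bounds[i],
            )
            for i in range(1, n_segments + 1)
        )
        best = max(best, score)
    return best


class TestCowAlign:
    def test_self_alignment_is_identity(self, key):
        # baseline slope gives every segment variance, so the optimum is unique
        t = 0.05 * np.arange(81)
        y = 5.0 * t + 100 * np.exp(-0.5 * ((t - 2.0) / 0.2) ** 2)
        ref = Chromatogram(key, t, y)
        aligned, path, score = cow_align(ref, ref, CowParams(0.5, 1))
        assert np.array_equal(path.query_indices, path.ref_indices)
        assert np.array_equal(aligned.intensities, ref.intensities)
        n_segments = len(path.ref_indices) - 1
        assert score == pytest.approx(n_segments, abs=1e-9)

    def test_shifted_gaussian_apex_recovered(self, gaussian_trace):
        ref = gaussian_trace(centers=(10.0,))
        query = gaussian_trace(centers=(10.15,))
        aligned, _, _ = cow_align(query, ref, CowParams(0.5, 2))
        apex = aligned.times[np.argmax(aligned.intensities)]
        assert abs(apex - 10.0) <= 0.05 + 1e-9  # within one scan

    def test_slack_zero_is_identity_boundary_assignment(self, gaussian_trace):
        ref = gaussian_trace(centers=(10.0,))
        query = gaussian_trace(centers=(10.3,))
        _, path, _ = cow_align(query, ref, CowParams(0.5, 0))
        assert np.array_equal(path.query_indices, path.ref_indices)

    def test_segment_under_three_scans_errors(self, key):
        t = np.arange(0, 10.0, 0.5)  # 0.5 min/scan -> 0.5 min segment = 1 scan
        c = Chromatogram(key, t, np.ones_like(t))
        with pytest.raises(ValueError, match="segment_size"):
            cow_align(c, c, CowParams(0.5, 1))

    @pytest.mark.parametrize("shift_scans", [-1, 0, 1, 2])
    def test_dp_matches_brute_force(self, key, shift_scans):
        """On short traces the DP objective equals exhaustive enumeration."""
        rng = np.random.default_rng(42 + shift_scans)
        t = 0.1 * np.arange(41)  # 4 segments of 0.5 min at 0.1 min/scan
        base = np.exp(-0.5 * ((t - 2.0) / 0.35) ** 2) * 50 + rng.uniform(0, 5, t.size)
        ref = Chromatogram(key, t, base)
        q_y = np.interp(t, t + shift_scans * 0.1, base)
        query = Chromatogram(key, t, q_y)
        params = CowParams(0.5, 1)
        _, _, dp_score = cow_align(query, ref, params)
        assert dp_score == pytest.approx(brute_force_cow(query, ref, params), abs=1e-10)

    def test_warp_monotone_and_endpoint_pinned(self, gaussian_trace):
        rng = np.random.default_rng(3)
        for seed in range(5):
            centers = np.sort(rng.uniform(2, 18, 3))
            ref = gaussian_trace(centers=centers, heights=(500, 800, 300), baseline_slope=1.0)
            query = gaussian_trace(
                centers=centers + rng.uniform(-0.2, 0.2, 3),
                heights=(500, 800, 300),
                baseline_slope=1.0,
            )
            _, path, _ = cow_align(query, ref, CowParams(0.5, 2))
            assert path.ref_indices[0] == 0 and path.query_indices[0] == 0
            assert path.ref_indices[-1] == len(ref) - 1
            assert path.query_indices[-1] == len(query) - 1
            assert np.all(np.diff(path.ref_indices) > 0)
            assert np.all(np.diff(path.query_indices) > 0)


class TestAlignStudy:
    @pytest.fixture
    def small_study(self):
        from mrmflow.synth import LibraryEntry, SynthCompound

        compounds = [
            SynthCompound(
                LibraryEntry("cpd1", "C10H20O2", TransitionKey(200.1, 100.1), 4.0),
                {"A": 20000.0, "B": 20000.0},
            ),
            SynthCompound(
                LibraryEntry("cpd2", "C20H30O2", TransitionKey(300.1, 150.1), 9.0),
                {"A": 30000.0, "B": 10000.0},
            ),
        ]
        spec = SynthSpec(
            n_bio=6,
            qc_every=3,
            compounds=compounds,
            rt_drift=RTDrift("shift", 0.3),
            seed=5,
            t_end=15.0,
        )
        return generate_study(spec)

    def test_shift_corrected_against_truth(self, small_study):
        study = small_study
        ref = select_reference(study.qc_samples, study.store)
        aligned, _ = align_study(study.store, ref, CowParams(0.5, 1))
        ref_truth = study.truth[study.truth.sample_id == ref]
        for key, per in aligned.items():
            ref_tops = {
                r.peak: r.true_top_rt
                for r in ref_truth[ref_truth.precursor_mz == key.precursor_mz].itertuples()
            }
            for sid, chrom in per.items():
                apex = chrom.times[np.argmax(chrom.intensities)]
                assert min(abs(apex - v) for v in ref_tops.values()) < 0.051

    def test_reference_run_unchanged(self, small_study):
        study = small_study
        ref = select_reference(study.qc_samples, study.store)
        aligned, _ = align_study(study.store, ref, CowParams(0.5, 1))
        for key, per in aligned.items():
            assert np.array_equal(per[ref].intensities, study.store[key][ref].intensities)

    def test_zero_drift_identity(self):
        from mrmflow.synth import LibraryEntry, SynthCompound

        spec = SynthSpec(
            n_bio=4,
            qc_every=3,
            compounds=[
                SynthCompound(
                    LibraryEntry("cpd1", "C10H20O2", TransitionKey(200.1, 100.1), 4.0),
                    {"A": 20000.0, "B": 20000.0},
                )
            ],
            seed=2,
            t_end=10.0,
        )
        study = generate_study(spec)
        ref = select_reference(study.qc_samples, study.store)
        aligned, _ = align_study(study.store, ref, CowParams(0.5, 1))
        for key, per in aligned.items():
            for sid, chrom in per.items():
                raw_apex = study.store[key][sid].times[
                    np.argmax(study.store[key][sid].intensities)
                ]
                apex = chrom.times[np.argmax(chrom.intensities)]
                assert apex == pytest.approx(raw_apex, abs=1e-9)

    def test_alignment_reduces_apex_error(self, small_study):
        study = small_study
        ref = select_reference(study.qc_samples, study.store)
        aligned, _ = align_study(study.store, ref, CowParams(0.5, 1))

        def total_err(store):
            err = 0.0
            for key, per in store.items():
                ref_apex = per[ref].times[np.argmax(per[ref].intensities)]
                for chrom in per.values():
                    err += abs(chrom.times[np.argmax(chrom.intensities)] - ref_apex)
            return err

        assert total_err(aligned) <= total_err(study.store)

    def test_centroid_reference_not_worse_than_first_injection(self):
        """A mid-drift reference aligns the batch at least as well as an
        extreme (first-injection) one when drift spans the batch."""
        from mrmflow.synth import LibraryEntry, SynthCompound

        compounds = [
            SynthCompound(
                LibraryEntry("cpd1", "C10H20O2", TransitionKey(200.1, 100.1), 4.0),
                {"A": 20000.0, "B": 25000.0},
            ),
            SynthCompound(
                LibraryEntry("cpd2", "C20H30O2", TransitionKey(300.1, 150.1), 9.0),
                {"A": 30000.0, "B": 10000.0},
            ),
        ]
        spec = SynthSpec(
            n_bio=8,
            qc_every=3,
            compounds=compounds,
            rt_drift=RTDrift("shift", 0.3),
            noise_sd=30.0,
            seed=11,
            t_end=15.0,
        )
        study = generate_study(spec)
        centroid_ref = select_reference(study.qc_samples, study.store)
        first = min(study.samples, key=lambda s: s.injection_order).sample_id

        def total_apex_error(reference):
            aligned, _ = align_study(study.store, reference, CowParams(0.5, 1))
            truth_ref = study.truth[study.truth.sample_id == reference]
            err = 0.0
            for key, per in aligned.items():
                tops = truth_ref[truth_ref.precursor_mz == key.precursor_mz]["true_top_rt"]
                for chrom in per.values():
                    apex = chrom.times[np.argmax(chrom.intensities)]
                    err += min(abs(apex - v) for v in tops)
            return err

        assert total_apex_error(centroid_ref) <= total_apex_error(first) + 1e-9
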