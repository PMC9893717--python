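import numpy as np
import pytest

from ensemblepipe import (
    DegenerateSeriesError,
    EnsembleAssignment,
    Raster,
    coactivity_series,
    detect_peaks,
    estimate_error_rates,
    generate_raster,
    runs_test,
    significant_peaks_per_ensemble,
    surrogate_type1,
    surrogate_type2,
)
from ensemblepipe.synth import SynthConfig


class TestCoactivitySeries:
    def test_all_zero_raster_gives_zero_series(self):
        s = coactivity_series(Raster(np.zeros((3, 5)), fps=4.0))
        assert (s.counts == 0).all()

    def test_simultaneous_activation_counted(self):
        mat = np.zeros((3, 5), dtype=int)
        mat[:, 2] = 1
        s = coactivity_series(Raster(mat, fps=4.0))
        assert s.counts.tolist() == [0, 0, 3, 0, 0]

    def test_total_counts_conserve_events(self, control_raster):
        s = coactivity_series(control_raster)
        assert s.counts.sum() == control_raster.n_events


class TestRunsTest:
    def test_alternating_series_closed_form(self):
        # 10 values strictly alternating around the mean: T=10, n1=n2=5
        result = runs_test(np.array([2, 0] * 5))
        assert result.T == 10
        assert result.T_bar == pytest.approx(6.0)
        assert result.s_T == pytest.approx(1.49071, abs=1e-4)
        assert result.Z == pytest.approx(2.68328, abs=1e-4)
        assert result.n1 == result.n2 == 5

    def test_z_zero_when_observed_equals_expected(self):
        # [1,1,0,0,1,1,0,0...]: n1=n2=4, T=4; construct one with T == T_bar
        # T_bar for n1=n2=2 is 3; series + + - - + gives T=3 after drop
        result = runs_test(np.array([2.0, 2.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]))
        # mean=1: values equal to mean dropped -> ++-- : T=2, T_bar=3
        assert result.n1 == result.n2 == 2
        assert result.T == 2

    def test_values_equal_to_mean_are_dropped(self):
        a = runs_test(np.array([2, 0, 2, 0, 2, 0]))
        b = runs_test(np.array([2, 1, 0, 2, 1, 0, 2, 1, 0]))  # 1s sit at the mean
        assert b.n1 == a.n1 and b.n2 == a.n2 and b.T == a.T

    def test_constant_series_raises_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            runs_test(np.array([3, 3, 3, 3]))

    def test_structured_coactivity_strongly_rejects(self, control_raster):
        result = runs_test(coactivity_series(control_raster))
        assert result.p_value < 1e-4
        assert result.Z < 0  # bursty series has far fewer runs than expected


class TestSurrogates:
    def test_type1_preserves_per_neuron_event_counts(self, control_raster):
        surr = surrogate_type1(control_raster, seed=5)
        assert np.array_equal(
            surr.matrix.sum(axis=1), control_raster.matrix.sum(axis=1)
        )
        assert surr.n_events == control_raster.n_events

    def test_type1_always_on_neuron_unchanged(self):
        mat = np.ones((1, 6), dtype=int)
        surr = surrogate_type1(Raster(mat, fps=4.0), seed=0)
        assert surr.matrix.sum() == 6

    def test_type2_preserves_interval_multisets(self, control_raster):
        surr = surrogate_type2(control_raster, seed=5)
        for i in range(control_raster.n_neurons):
            orig = np.flatnonzero(control_raster.matrix[i])
            new = np.flatnonzero(surr.matrix[i])
            assert new.size == orig.size
            if orig.size >= 2:
                assert sorted(np.diff(orig)) == sorted(np.diff(new))

    def test_type2_toy_neuron_permuted_placement_reachable(self):
        # events {2,5,6}: intervals {3,1}; placement {1,2,5} uses order (1,3)
        mat = np.zeros((1, 8), dtype=int)
        mat[0, [2, 5, 6]] = 1
        raster = Raster(mat, fps=4.0)
        seen = set()
        for seed in range(200):
            surr = surrogate_type2(raster, seed=seed)
            seen.add(tuple(np.flatnonzero(surr.matrix[0])))
        assert (1, 2, 5) in seen

    def test_surrogates_deterministic_given_seed(self, control_raster):
        assert surrogate_type1(control_raster, seed=9) == surrogate_type1(
            control_raster, seed=9
        )
        assert surrogate_type2(control_raster, seed=9) == surrogate_type2(
            control_raster, seed=9
        )


class TestErrorRates:
    def test_report_reproducible_and_sane(self, control_raster):
        r1 = estimate_error_rates(control_raster, M=10, seed=21)
        r2 = estimate_error_rates(control_raster, M=10, seed=21)
        assert r1 == r2
        assert 0 <= r1.alpha_hat <= 1 and 0 <= r1.beta_hat <= 1

    def test_zero_surrogates_errors(self, control_raster):
        with pytest.raises(ValueError):
            estimate_error_rates(control_raster, M=0)


class TestDetectPeaks:
    def test_toy_series_flags_only_outlier_at_two_sd(self):
        toy = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 9])
        assert detect_peaks(toy, 1.0, 2.0).flagged_frames.tolist() == [9]
        assert detect_peaks(toy, 1.0, 3.0).n_flagged == 0

    def test_constant_series_has_no_flags(self):
        assert detect_peaks(np.full(50, 4.0), 0.2, 2.0).n_flagged == 0

    def test_flags_cover_planted_epoch_peaks(self, control_raster_truth):
        # each ensemble's own coactivity must flag the peak frame of >= 90%
        # of its planted epochs at the default window and threshold
        from ensemblepipe import subraster

        raster, truth = control_raster_truth
        assignment = EnsembleAssignment(truth.labels, 0.0)
        peaksets = significant_peaks_per_ensemble(raster, assignment)
        hits = total = 0
        for t0, lab in truth.epoch_onsets:
            counts = coactivity_series(
                subraster(raster, assignment.members(lab))
            ).counts
            window = np.arange(t0, min(t0 + 12, raster.n_frames))
            peak = window[np.argmax(counts[window])]
            total += 1
            hits += bool(peaksets[lab].flags[peak])
        assert hits / total >= 0.9

    def test_bad_window_fraction_errors(self):
        with pytest.raises(ValueError):
            detect_peaks(np.arange(10.0), 1.5, 2.0)
        with pytest.raises(ValueError, match="need >= 2"):
            detect_peaks(np.arange(10.0), 0.05, 2.0)


class TestPerEnsemblePeaks:
    def test_every_planted_ensemble_yields_nonempty_peaks(self, control_raster_truth):
        raster, truth = control_raster_truth
        assignment = EnsembleAssignment(truth.labels, 0.0)
        peaksets = significant_peaks_per_ensemble(raster, assignment)
        assert set(peaksets) == set(range(6))
        assert all(ps.n_flagged > 0 for ps in peaksets.values())

    def test_flags_only_where_ensemble_is_active(self, control_raster_truth):
        raster, truth = control_raster_truth
        assignment = EnsembleAssignment(truth.labels, 0.0)
        peaksets = significant_peaks_per_ensemble(raster, assignment)
        from ensemblepipe import subraster

        for cid, ps in peaksets.items():
            counts = coactivity_series(
                subraster(raster, assignment.members(cid))
            ).counts
            assert (counts[ps.flags] > 0).all()

    def test_constant_coactivity_gets_empty_peakset_and_warning(self):
        # all neurons always on -> coactivity constant -> runs test is
        # degenerate and the gate must yield an empty set with a warning
        raster = Raster(np.ones((12, 400), dtype=int), fps=4.0)
        assignment = EnsembleAssignment(np.zeros(12, dtype=int), 0.0)
        with pytest.warns(UserWarning, match="not distinguishable"):
            ps = significant_peaks_per_ensemble(raster, assignment)
        assert ps[0].n_flagged == 0
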