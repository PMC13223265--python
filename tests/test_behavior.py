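"""Rating preprocessing, reliability, consensus, and surrogate-null tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_panel
from narrative_encoding import behavior, synthetic
from narrative_encoding.containers import RatingPanel
from narrative_encoding.errors import (
    EmptyCohortError,
    InsufficientDataError,
    MalformedInputError,
    UndefinedStatisticError,
)


class TestApplyExclusions:
    def _panel(self):
        rng = np.random.default_rng(0)
        base = 50 + 20 * np.sin(np.arange(60) * 0.2)
        values = {f"p{i}": np.clip(base + rng.normal(0, 5, 60), 0, 100) for i in range(6)}
        values["constant"] = np.full(60, 42.0)
        values["dissimilar"] = np.clip(50 - 20 * np.sin(np.arange(60) * 0.2), 0, 100)
        participants = list(values)
        attention = pd.DataFrame(
            {
                "participant": np.repeat(participants, 4),
                "run": np.tile(np.arange(4), len(participants)),
                "passed": True,
            }
        )
        attention.loc[attention["participant"] == "p0", "passed"] = [True, False, False, False]
        return make_panel(values, attention=attention)

    def test_each_rule_fires_with_its_reason(self):
        filtered, log = behavior.apply_exclusions(self._panel(), "social", loo_threshold=0.3)
        reasons = dict(zip(log["participant"], log["reason"]))
        assert reasons["p0"] == "attention"  # failed 3 of 4 checks
        assert reasons["constant"] == "constant"
        assert reasons["dissimilar"] == "loo_similarity"
        kept = set(filtered.ratings["participant"])
        assert kept == {f"p{i}" for i in range(1, 6)}

    def test_all_excluded_raises(self):
        panel = make_panel({"a": np.full(20, 10.0), "b": np.full(20, 90.0)})
        with pytest.raises(EmptyCohortError):
            behavior.apply_exclusions(panel, "social", loo_threshold=0.3)


class TestPreprocessRatings:
    def test_linear_interpolation_onto_grid(self):
        panel = RatingPanel(
            ratings=pd.DataFrame(
                {
                    "participant": "a",
                    "question": "social",
                    "trial": "t0",
                    "time_s": [0.0, 1.0],
                    "value": [0.0, 100.0],
                }
            )
        )
        out = behavior.preprocess_ratings(panel, grid_step=0.5)
        vals = out.ratings["value"].to_numpy()
        assert np.allclose(vals, [0.0, 50.0, 100.0])

    def test_samples_before_first_move_are_missing(self):
        panel = RatingPanel(
            ratings=pd.DataFrame(
                {
                    "participant": "a",
                    "question": "social",
                    "trial": "t0",
                    "time_s": np.arange(0, 6.0, 0.5),
                    "value": 50.0,
                }
            ),
            first_move=pd.DataFrame(
                {"participant": ["a"], "trial": ["t0"], "first_move_s": [2.0]}
            ),
        )
        out = behavior.preprocess_ratings(panel, grid_step=0.5)
        sub = out.ratings
        assert sub.loc[sub["time_s"] < 2.0, "value"].isna().all()
        assert sub.loc[sub["time_s"] >= 2.0, "value"].notna().all()

    def test_grid_point_count_convention(self):
        # a 30 s trial at 230 ms: floor(30 / 0.23) + 1 grid points
        panel = RatingPanel(
            ratings=pd.DataFrame(
                {
                    "participant": "a",
                    "question": "social",
                    "trial": "t0",
                    "time_s": np.arange(0, 31.5, 0.083),
                    "value": 60.0,
                }
            ),
            trials=pd.DataFrame({"trial": ["t0"], "duration_s": [30.0]}),
        )
        out = behavior.preprocess_ratings(panel, grid_step=0.23)
        assert len(out.ratings) == int(np.floor(30.0 / 0.23)) + 1 == 131

    def test_non_monotone_timestamps_raise(self):
        panel = RatingPanel(
            ratings=pd.DataFrame(
                {
                    "participant": "a",
                    "question": "social",
                    "trial": "t0",
                    "time_s": [0.0, 1.0, 0.5],
                    "value": [1.0, 2.0, 3.0],
                }
            )
        )
        with pytest.raises(MalformedInputError):
            behavior.preprocess_ratings(panel)


class TestGroupTimecourse:
    def test_median_mad_and_counts_by_hand(self):
        course = behavior.group_timecourse(
            make_panel({"a": [0.0], "b": [50.0], "c": [100.0]})
        )
        assert course.median[0] == 50.0
        assert course.mad[0] == 50.0
        assert course.n_valid[0] == 3

    def test_low_coverage_timepoint_flagged_invalid(self):
        values = {f"p{i}": [50.0, 50.0] for i in range(10)}
        for i in range(6):  # 6 of 10 missing at timepoint 1 -> 40% coverage
            values[f"p{i}"] = [50.0, np.nan]
        course = behavior.group_timecourse(
            make_panel(values), min_trial_coverage=0.0
        )
        assert bool(course.valid_flag[0]) is True
        assert bool(course.valid_flag[1]) is False

    def test_identical_participants_give_zero_mad(self):
        series = np.linspace(10, 90, 20)
        course = behavior.group_timecourse(
            make_panel({p: series for p in "abcd"})
        )
        assert np.allclose(course.median, series)
        assert np.allclose(course.mad, 0.0)

    def test_permutation_invariance_to_participant_order(self, rng):
        values = {f"p{i}": rng.uniform(0, 100, 30) for i in range(7)}
        a = behavior.group_timecourse(make_panel(values))
        shuffled = {k: values[k] for k in reversed(list(values))}
        b = behavior.group_timecourse(make_panel(shuffled))
        assert np.array_equal(a.median, b.median)
        assert np.array_equal(a.mad, b.mad)


class TestRatingSimilarity:
    def test_spearman_brown_closed_form(self):
        assert behavior.spearman_brown(0.5) == pytest.approx(2 / 3, abs=1e-4)

    @given(st.floats(0.01, 0.99))
    def test_spearman_brown_monotone_and_above_raw(self, r):
        assert behavior.spearman_brown(r) >= r
        assert behavior.spearman_brown(r + 0.005) > behavior.spearman_brown(r)

    def test_identical_participants_are_perfectly_reliable(self):
        series = 50 + 30 * np.sin(np.arange(100) * 0.3)
        panel = make_panel({p: series for p in "abcdef"})
        rep = behavior.rating_similarity(panel, n_permutations=50, seed=0)
        assert np.allclose(rep.corrected, 1.0)
        assert rep.pairwise_median == pytest.approx(1.0)

    def test_reliability_increases_with_cohort_size(self):
        latent, _ = synthetic.make_latent_pair(0.3, 1500, seed=0)
        means = []
        for n_raters in (8, 16, 32):
            panel = synthetic.simulate_raters(latent, n_raters, noise_sd=25.0, seed=3)
            rep = behavior.rating_similarity(panel, n_permutations=200, seed=4)
            means.append(rep.mean)
        assert means[0] < means[1] < means[2]

    def test_small_cohort_rejected(self):
        panel = make_panel({p: np.arange(40.0) for p in "abc"})
        with pytest.raises(InsufficientDataError):
            behavior.rating_similarity(panel)


class TestConsensusAnnotations:
    def test_unanimity_majority_and_tie(self):
        labels = np.array(
            [
                [1, 1, 1, 1],  # unanimous -> 1
                [1, 1, 1, 0],  # 3-1 -> 1
                [1, 1, 0, 0],  # tie -> unresolved
                [0, 0, 0, 1],  # 3-1 -> 0
            ]
        )
        out = behavior.consensus_annotations(labels)
        assert list(out.consensus) == [1, 1, -1, 0]
        resolved = behavior.consensus_annotations(labels, resolution=np.array([9, 9, 1, 9]))
        assert resolved.consensus[2] == 1

    def test_perfect_agreement_has_unit_kappa(self):
        labels = np.tile(np.array([1, 0, 1, 0, 0])[:, None], (1, 4))
        assert behavior.consensus_annotations(labels).kappa == pytest.approx(1.0)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(MalformedInputError):
            behavior.consensus_annotations(np.array([[0, 2], [1, 0]]))


class TestPhaseRandomization:
    def test_surrogates_preserve_amplitude_spectrum_and_mean(self, rng):
        y = rng.standard_normal(257) + 1.5
        sur = behavior.phase_randomize(y, rng, 20)
        assert np.allclose(
            np.abs(np.fft.rfft(sur, axis=1)), np.abs(np.fft.rfft(y)), atol=1e-9
        )
        assert np.allclose(sur.mean(axis=1), y.mean(), atol=1e-9)

    def test_self_correlation_hits_the_p_floor(self):
        x, _ = synthetic.make_latent_pair(0.0, 500, seed=2)
        res = behavior.phase_randomization_corr(x, x, n_surrogates=1000, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] <= 2 / 1000

    def test_degenerate_inputs_raise(self):
        with pytest.raises(InsufficientDataError):
            behavior.phase_randomization_corr(np.arange(10.0), np.arange(10.0))
        x = np.arange(64.0)
        with pytest.raises(UndefinedStatisticError):
            behavior.phase_randomization_corr(x, np.full(64, 3.0))

    def test_missing_timepoints_removed_listwise(self):
        x = np.sin(np.arange(100) * 0.3)
        y = np.cos(np.arange(100) * 0.3)
        x[:5] = np.nan
        res = behavior.phase_randomization_corr(x, y, n_surrogates=100, seed=0)
        assert res["n_timepoints"] == 95
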