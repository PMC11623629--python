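"""Synthetic-data generators: planted models, patterns, behavior, gaze, words."""

import numpy as np
import pytest

import repgeom as rg
from repgeom.errors import GenerationError, InvalidArgumentError
from repgeom.synthetic import blend_similarity


class TestStimulusSet:
    def test_full_design_has_90_stimuli(self):
        s = rg.make_stimulus_set(18, 5)
        assert s.n == 90
        assert len(s.categories) == 18

    def test_minimal_case(self):
        s = rg.make_stimulus_set(1, 1)
        assert s.n == 1

    def test_exemplars_grouped_under_categories(self):
        s = rg.make_stimulus_set(3, 2)
        assert s.n == 6
        from collections import Counter
        assert Counter(s.category) == {"cat00": 2, "cat01": 2, "cat02": 2}

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rg.make_stimulus_set(0, 5)


class TestModelRDMs:
    def test_category_structure_planted(self, small_stimuli, small_truth, small_models):
        cat = small_models[0]
        same = np.equal.outer(small_stimuli.category, small_stimuli.category)
        off = ~np.eye(small_stimuli.n, dtype=bool)
        within = cat.matrix[same & off].mean()
        between = cat.matrix[~same].mean()
        assert within < between

    def test_models_pairwise_distinguishable(self, small_models, small_truth):
        for i in range(len(small_models)):
            for j in range(i + 1, len(small_models)):
                rho = rg.spearman_fit(small_models[i], small_models[j])
                assert abs(rho) <= small_truth.max_model_spearman

    def test_unsatisfiable_distinguishability_fails_generation(self, small_stimuli):
        """Two draws sharing one block structure always correlate well above a
        tight bound, so the distinguishability contract must abort."""
        truth = rg.GroundTruth(
            n_categories=4, n_exemplars=3,
            model_kinds=("category", "category"),
            mixture_weights={"a": (1.0, 0.0)},
            max_model_spearman=0.2, seed=0,
        )
        with pytest.raises(GenerationError):
            rg.simulate_model_rdms(small_stimuli, truth, max_retries=8)

    def test_deterministic_under_seed(self, small_stimuli, small_truth):
        a = rg.simulate_model_rdms(small_stimuli, small_truth)
        b = rg.simulate_model_rdms(small_stimuli, small_truth)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.matrix, y.matrix)


class TestSubjectPatterns:
    def test_zero_weights_plant_identity_similarity(self, small_models):
        s = blend_similarity(small_models, [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(s, np.eye(small_models[0].n))

    def test_blend_is_valid_correlation_matrix(self, small_models):
        s = blend_similarity(small_models, [0.5, 0.3, 0.2])
        np.testing.assert_allclose(np.diag(s), 1.0, atol=1e-12)
        w = np.linalg.eigvalsh((s + s.T) / 2)
        assert w.min() >= -1e-10

    def test_splitdata_correlations_converge_to_generative_law(self, small_models):
        """Small-scale check of the 1/(1+sigma^2) attenuation law.

        The law describes the raw generative draws; the per-unit z-scoring
        applied for analysis re-centers profiles across conditions and shifts
        correlations by the row means of S, so it is bypassed here."""
        truth = rg.GroundTruth(
            n_subjects=1, n_categories=4, n_exemplars=3,
            n_units_per_neighborhood=20_000, noise_sd=1.0,
            mixture_weights={"a": (1.0, 0.0, 0.0)}, seed=5,
        )
        s = blend_similarity(small_models, (1.0, 0.0, 0.0))
        (s1, s2), = rg.simulate_subject_patterns(
            truth, "a", model_rdms=small_models, zscore=False
        )
        observed = 1.0 - rg.splitdata_rdm(s1, s2).matrix  # correlations
        expected = s / 2.0  # sigma = 1
        off = ~np.eye(12, dtype=bool)
        assert np.abs(observed[off] - expected[off]).max() < 0.04

    def test_deterministic_under_seed(self, small_truth, small_models):
        a = rg.simulate_subject_patterns(small_truth, "nbhd00", model_rdms=small_models)
        b = rg.simulate_subject_patterns(small_truth, "nbhd00", model_rdms=small_models)
        np.testing.assert_array_equal(a[0][0].matrix, b[0][0].matrix)
        np.testing.assert_array_equal(a[-1][1].matrix, b[-1][1].matrix)

    def test_unknown_neighborhood_rejected(self, small_truth, small_models):
        with pytest.raises(InvalidArgumentError):
            rg.simulate_subject_patterns(small_truth, "nope", model_rdms=small_models)

    def test_profiles_are_zscored(self, small_truth, small_models):
        (s1, _), *_ = rg.simulate_subject_patterns(
            small_truth, "nbhd00", model_rdms=small_models
        )
        np.testing.assert_allclose(s1.matrix.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(s1.matrix.std(axis=0, ddof=1), 1, atol=1e-9)


class TestArrangementSimulator:
    def test_record_count_and_full_first_set(self, small_models):
        rdm = small_models[0]
        design = rg.design_subsets(list(rdm.labels), 3, 6, n_candidates=5, seed=1)
        recs = rg.simulate_arrangement_session(rdm, design, jitter_sd=0.0, seed=2)
        assert len(recs) == 1 + 3
        assert recs[0].set_index == 0
        assert set(recs[0].stimulus_ids) == set(rdm.labels)

    def test_noiseless_2d_embeddable_round_trip(self, rng):
        """A planted 2-D configuration survives simulate -> aggregate exactly."""
        pts = rng.normal(size=(10, 2)) * 50
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        rdm = rg.RDM(d, tuple(f"s{i}" for i in range(10)))
        design = rg.design_subsets(list(rdm.labels), 2, 5, n_candidates=5, seed=3)
        recs = rg.simulate_arrangement_session(rdm, design, jitter_sd=0.0, seed=4)
        agg = rg.aggregate_arrangements(recs, labels=rdm.labels)
        assert rg.spearman_fit(agg, rdm) == pytest.approx(1.0)

    def test_jitter_degrades_fit_monotonically(self, rng):
        pts = rng.normal(size=(12, 2)) * 50
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        rdm = rg.RDM(d, tuple(f"s{i}" for i in range(12)))
        design = rg.design_subsets(list(rdm.labels), 4, 6, n_candidates=5, seed=5)
        fits = []
        for jitter in (0.0, 20.0, 200.0):
            rhos = [
                rg.spearman_fit(
                    rg.aggregate_arrangements(
                        rg.simulate_arrangement_session(
                            rdm, design, jitter_sd=jitter, seed=100 + rep
                        ),
                        labels=rdm.labels,
                    ),
                    rdm,
                )
                for rep in range(5)
            ]
            fits.append(np.mean(rhos))
        assert fits[0] > fits[1] > fits[2]

    def test_unknown_stimulus_in_subset_rejected(self, small_models):
        design = rg.SubsetDesign(
            subsets=(("zzz", "cat00_ex1", "cat00_ex2"),),
            n_stimuli=12, subset_size=3, n_subsets=1, unique_pair_count=3, seed=0,
        )
        with pytest.raises(InvalidArgumentError, match="zzz"):
            rg.simulate_arrangement_session(small_models[0], design, seed=0)


class TestGazeSimulator:
    def test_sample_count_and_validity(self, small_stimuli):
        trials = rg.simulate_gaze_session(small_stimuli, n_blocks=1,
                                          blink_rate=0.0, seed=0)
        assert len(trials) == small_stimuli.n
        assert all(t.n_samples == 2500 for t in trials)
        assert all(t.valid.all() for t in trials)

    def test_blinks_flagged_when_requested(self, small_stimuli):
        trials = rg.simulate_gaze_session(small_stimuli, n_blocks=1,
                                          blink_rate=1.0, seed=1)
        assert all(not t.valid.all() for t in trials)

    def test_interblock_reliability_exceeds_screening_threshold(self, small_stimuli):
        trials = rg.simulate_gaze_session(small_stimuli, n_blocks=4,
                                          blink_rate=0.0, seed=2)
        by_block = {}
        for t in trials:
            by_block.setdefault(t.block_index, {})[t.stimulus_id] = rg.gaze_preprocess(t)
        rdms = [rg.gaze_rdm(by_block[b]) for b in sorted(by_block)]
        retained, _, rel = rg.gaze_reliability_screen({"p0": rdms}, threshold=0.1)
        assert retained == ["p0"]
        assert rel["p0"] > 0.1

    def test_deterministic_under_seed(self, small_stimuli):
        a = rg.simulate_gaze_session(small_stimuli, n_blocks=1, blink_rate=0.3, seed=9)
        b = rg.simulate_gaze_session(small_stimuli, n_blocks=1, blink_rate=0.3, seed=9)
        np.testing.assert_array_equal(a[0].x_px, b[0].x_px)
        np.testing.assert_array_equal(a[-1].valid, b[-1].valid)


class TestAnnotationSimulator:
    def test_zero_annotator_noise_perfect_agreement(self, small_stimuli):
        a, b = rg.simulate_annotations(small_stimuli, dim=50, seed=0,
                                       annotator_noise_sd=0.0)
        _, mean, _ = rg.annotator_agreement(a, b)
        assert mean == pytest.approx(1.0)

    def test_default_dimension_is_300(self, small_stimuli):
        a, _ = rg.simulate_annotations(small_stimuli, seed=1)
        assert a.dim == 300

    def test_word_counts_match_annotation_ranges(self, small_stimuli):
        a, _ = rg.simulate_annotations(small_stimuli, dim=20, seed=2)
        for stim, rows in a.entries.items():
            n_verbs = sum(1 for _, cls, _ in rows if cls == "verb")
            n_nonverbs = sum(1 for _, cls, _ in rows if cls == "nonverb")
            assert 2 <= n_verbs <= 5
            assert 3 <= n_nonverbs <= 6

    def test_deterministic_under_seed(self, small_stimuli):
        a1, _ = rg.simulate_annotations(small_stimuli, dim=10, seed=3)
        a2, _ = rg.simulate_annotations(small_stimuli, dim=10, seed=3)
        for stim in a1.stimuli:
            for (w1, c1, v1), (w2, c2, v2) in zip(a1.entries[stim], a2.entries[stim]):
                assert (w1, c1) == (w2, c2)
                np.testing.assert_array_equal(v1, v2)
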