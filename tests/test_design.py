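"""Serially balanced sequences, probe repair, sessions, onsets, efficiency."""

from collections import Counter

import numpy as np
import pytest

import repgeom as rg
from repgeom.design import (
    FIXATION,
    PROBE,
    DesignMatrixSpec,
    build_design_matrix,
    default_trial_types,
)
from repgeom.errors import InvalidArgumentError, NumericalError


def cyclic_pairs(seq):
    return Counter(zip(seq, seq[1:] + seq[:1]))


class TestType1Sequence:
    def test_length_is_n_squared(self):
        assert len(rg.generate_type1_sequence(20, seed=1)) == 400

    def test_n2_structure(self):
        seq = rg.generate_type1_sequence(2, seed=0, labels=["A", "B"])
        assert len(seq) == 4
        assert cyclic_pairs(seq) == Counter(
            {("A", "A"): 1, ("A", "B"): 1, ("B", "B"): 1, ("B", "A"): 1}
        )

    @pytest.mark.parametrize("n", range(2, 9))
    def test_every_ordered_pair_exactly_once(self, n):
        seq = rg.generate_type1_sequence(n, seed=n)
        counts = cyclic_pairs(seq)
        labels = sorted(set(seq))
        assert len(labels) == n
        for a in labels:
            for b in labels:
                assert counts[(a, b)] == 1

    def test_run_balanced_variant(self):
        seq = rg.generate_type1_sequence(20, seed=2, balance_runs=4)
        counts = cyclic_pairs(seq)
        assert all(v == 1 for v in counts.values()) and len(counts) == 400
        for r in range(4):
            run = seq[r * 100:(r + 1) * 100]
            assert all(c == 5 for c in Counter(run).values())

    def test_rejects_single_type(self):
        with pytest.raises(InvalidArgumentError):
            rg.generate_type1_sequence(1)

    def test_deterministic_under_seed(self):
        a = rg.generate_type1_sequence(6, seed=9)
        b = rg.generate_type1_sequence(6, seed=9)
        assert a == b


class TestProbeRepair:
    def test_probe_after_fixation_replaced(self):
        seq = ["cat00", FIXATION, PROBE, "cat01"]
        assert rg.repair_probe_constraints(seq) == ["cat00", FIXATION, FIXATION, "cat01"]

    def test_no_violation_is_identity(self):
        seq = ["cat00", PROBE, "cat01", FIXATION, "cat02"]
        assert rg.repair_probe_constraints(seq) == seq

    def test_double_probe_replaced(self):
        assert rg.repair_probe_constraints([PROBE, PROBE]) == [PROBE, FIXATION]

    def test_idempotent(self):
        seq = rg.generate_type1_sequence(
            20, seed=5, labels=default_trial_types(18), balance_runs=4
        )
        once = rg.repair_probe_constraints(seq)
        assert rg.repair_probe_constraints(once) == once

    def test_probe_count_per_run_after_repair(self):
        """<= 5 probes per run; exactly 5 when no violation fell in the run."""
        seq = rg.generate_type1_sequence(
            20, seed=6, labels=default_trial_types(18), balance_runs=4
        )
        repaired = rg.repair_probe_constraints(seq)
        for r in range(4):
            raw = seq[r * 100:(r + 1) * 100]
            rep = repaired[r * 100:(r + 1) * 100]
            assert raw.count(PROBE) == 5
            assert rep.count(PROBE) <= 5
            n_violations = sum(
                1 for i in range(r * 100, (r + 1) * 100)
                if seq[i] == PROBE and i > 0 and seq[i - 1] in (PROBE, FIXATION)
            )
            if n_violations == 0:
                assert rep.count(PROBE) == 5


@pytest.fixture(scope="module")
def session():
    seq = rg.repair_probe_constraints(
        rg.generate_type1_sequence(
            20, seed=3, labels=default_trial_types(18), balance_runs=4
        )
    )
    return rg.build_session(seq, n_exemplars=5, n_runs=4, seed=4,
                            onset_candidates=2)


class TestBuildSession:
    def test_runs_have_100_main_trials(self, session):
        assert len(session) == 4
        assert all(len(r.main_trials) == 100 for r in session)

    def test_each_exemplar_once_per_run(self, session):
        for run in session:
            exemplars = [t.exemplar_id for t in run.main_trials
                         if t.exemplar_id is not None]
            counts = Counter(exemplars)
            assert all(v == 1 for v in counts.values())
            # 18 categories x 5 exemplars all present
            assert len(counts) == 90

    def test_prepended_trials_use_disjoint_pool(self, session):
        main_ids = {t.exemplar_id for r in session for t in r.main_trials
                    if t.exemplar_id}
        prep_ids = {t.exemplar_id for r in session for t in r.trials
                    if t.prepended and t.exemplar_id}
        assert prep_ids and main_ids.isdisjoint(prep_ids)
        assert all(e.endswith("_prep") for e in prep_ids)

    def test_run_duration_535s(self, session):
        for run in session:
            assert rg.run_duration(run) == pytest.approx(535.0)


def test_two_session_build_gives_8_trials_per_stimulus():
    sessions = rg.build_experiment(seed=1, onset_candidates=1)
    counts = Counter(
        t.exemplar_id
        for sess in sessions for run in sess for t in run.main_trials
        if t.exemplar_id is not None
    )
    assert len(counts) == 90
    assert set(counts.values()) == {8}


class TestOnsets:
    def test_isis_respect_floor_and_mean(self):
        res = rg.generate_onsets(100, mean_isi_s=2.5, min_isi_s=2.0,
                                 n_candidates=3, seed=0)
        assert np.all(res.isis_s >= 2.0 - 1e-12)
        assert res.isis_s.mean() == pytest.approx(2.5)
        assert res.isis_s.sum() == pytest.approx(250.0)

    def test_single_candidate_chosen(self):
        res = rg.generate_onsets(10, n_candidates=1, seed=1)
        assert res.chosen_index == 0

    def test_insufficient_null_time_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rg.generate_onsets(10, mean_isi_s=2.5, min_isi_s=2.0, total_null_s=10.0)

    def test_selection_is_monotone(self):
        spec = DesignMatrixSpec(trial_types=tuple(
            f"t{i % 4}" for i in range(20)
        ))
        res = rg.generate_onsets(20, n_candidates=8, spec=spec, seed=2)
        assert res.efficiencies[res.chosen_index] == res.efficiencies.max()


class TestEfficiency:
    def test_orthonormal_design_closed_form(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(30, 4)))
        assert rg.design_efficiency(q, np.eye(4)) == pytest.approx(0.25)

    def test_scaling_design_scales_efficiency(self, rng):
        x = rng.normal(size=(40, 5))
        e1 = rg.design_efficiency(x)
        e2 = rg.design_efficiency(2 * x)
        assert e2 == pytest.approx(4 * e1)

    def test_matches_explicit_inverse_oracle(self, rng):
        x = rng.normal(size=(50, 5))
        c = rng.normal(size=(2, 5))
        expected = 1.0 / np.trace(c @ np.linalg.inv(x.T @ x) @ c.T)
        assert rg.design_efficiency(x, c) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_contrast_row_order(self, rng):
        x = rng.normal(size=(30, 4))
        c = rng.normal(size=(3, 4))
        assert rg.design_efficiency(x, c) == pytest.approx(
            rg.design_efficiency(x, c[::-1])
        )

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(size=(20, 3))
        x = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises(NumericalError, match="rank"):
            rg.design_efficiency(x)

    def test_design_matrix_has_one_column_per_modeled_type(self):
        spec = DesignMatrixSpec(trial_types=("a", "b", FIXATION, "a"))
        x = build_design_matrix(spec, np.array([0.0, 5.0, 10.0, 15.0]))
        assert x.shape[1] == 2  # fixation is baseline


class TestRunDuration:
    def test_empty_run_is_lead_plus_trail(self):
        run = rg.TrialSequence((), 0, 0, 20)
        assert rg.run_duration(run, 5.0, 15.0) == pytest.approx(20.0)

    def test_matches_event_loop_oracle(self, rng):
        trials = []
        t0 = 5.0
        for k in range(7):
            isi = float(rng.uniform(2, 4))
            trials.append(rg.design.Trial(f"t{k}", None, t0, 2.5, isi))
            t0 += 2.5 + isi
        run = rg.TrialSequence(tuple(trials), 0, 0, 7)
        expected = 5.0 + sum(t.stim_duration_s + t.isi_s for t in trials) + 15.0
        assert rg.run_duration(run) == pytest.approx(expected, abs=1e-12)
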