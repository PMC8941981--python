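"""Session structure and pulse-schedule generation."""

import itertools
import json

import numpy as np
import pytest
from scipy import stats

from betarec.task_design import (
    DesignConfig,
    beta_pulse_train,
    build_session,
    random_pulse_train,
    sample_target_schedule,
)


def brute_force_targets(n, k, min_between):
    gap = min_between + 1
    return [
        c
        for c in itertools.combinations(range(n), k)
        if all(b - a >= gap for a, b in zip(c, c[1:]))
    ]


def brute_force_bins(n_bins, k):
    return [
        c
        for c in itertools.combinations(range(n_bins), k)
        if all(b - a >= 2 for a, b in zip(c, c[1:]))
    ]


class TestBetaPulseTrain:
    def test_default_protocol_times(self):
        train = beta_pulse_train(480, 80, 6)
        assert train.times_ms == (0, 80, 160, 240, 320, 400)
        assert train.kind == "beta"

    def test_single_pulse(self):
        assert beta_pulse_train(480, 80, 1).times_ms == (0,)

    def test_implied_rate_is_12_5_hz(self):
        assert beta_pulse_train(480, 80, 6).rate_hz == pytest.approx(12.5)

    def test_train_exceeding_epoch_rejected_with_bound(self):
        with pytest.raises(ValueError, match="480"):
            beta_pulse_train(480, 80, 7)

    @pytest.mark.parametrize("bad", [(0, 80, 6), (480, 0, 6), (480, 80, 0)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            beta_pulse_train(*bad)


class TestRandomPulseTrain:
    def test_constraints_hold_over_seeds(self):
        for seed in range(50):
            train = random_pulse_train(480, 30, 6, np.random.default_rng(seed))
            times = np.array(train.times_ms)
            assert len(times) == 6
            assert np.all(times % 30 == 0)
            assert np.all(np.diff(times) >= 60)
            assert times.min() >= 0 and times.max() < 480

    def test_same_seed_same_train(self):
        a = random_pulse_train(480, 30, 6, np.random.default_rng(7))
        b = random_pulse_train(480, 30, 6, np.random.default_rng(7))
        assert a == b

    def test_valid_bin_subset_count_matches_brute_force(self):
        from betarec.task_design import _nonadjacent_bin_sets

        oracle = brute_force_bins(16, 6)
        assert len(oracle) == 462
        assert set(_nonadjacent_bin_sets(16, 6)) == set(oracle)

    def test_bin_sets_sampled_uniformly(self):
        # chi-square goodness of fit over all 462 admissible bin subsets
        rng = np.random.default_rng(11)
        counts = {}
        n_draws = 462 * 40
        for _ in range(n_draws):
            t = random_pulse_train(480, 30, 6, rng).times_ms
            counts[t] = counts.get(t, 0) + 1
        observed = np.array([counts.get(k, 0) for k in counts])
        assert len(counts) == 462
        chi2 = ((observed - n_draws / 462) ** 2 / (n_draws / 462)).sum()
        assert stats.chi2.sf(chi2, 461) > 1e-3

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            random_pulse_train(480, 30, 9, np.random.default_rng(0))

    def test_indivisible_epoch_rejected(self):
        with pytest.raises(ValueError):
            random_pulse_train(470, 30, 6, np.random.default_rng(0))


class TestTargetSchedule:
    def test_count_matches_brute_force(self):
        oracle = brute_force_targets(12, 4, 2)
        assert len(oracle) == 15

    def test_all_draws_satisfy_gap(self):
        for seed in range(30):
            pos = sorted(sample_target_schedule(12, 4, 2, np.random.default_rng(seed)))
            assert all(b - a >= 3 for a, b in zip(pos, pos[1:]))

    def test_uniform_over_15_schedules(self):
        rng = np.random.default_rng(3)
        n_draws = 15_000
        counts = {}
        for _ in range(n_draws):
            key = tuple(sorted(sample_target_schedule(12, 4, 2, rng)))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        # binomial 99% band around 1/15
        p = 1 / 15
        half = 2.576 * np.sqrt(p * (1 - p) / n_draws)
        for c in counts.values():
            assert abs(c / n_draws - p) < half + 1e-9

    def test_single_target_all_positions_feasible(self):
        seen = set()
        for seed in range(300):
            seen |= sample_target_schedule(12, 1, 2, np.random.default_rng(seed))
        assert seen == set(range(12))

    def test_infeasible_five_targets_rejected(self):
        assert len(brute_force_targets(12, 5, 2)) == 0
        with pytest.raises(ValueError):
            sample_target_schedule(12, 5, 2, np.random.default_rng(0))


class TestBuildSession:
    def test_published_totals(self, session_design):
        table = session_design.trials_table()
        assert len(table) == 540
        for cond in ("beta", "random", "none"):
            sub = table[table.condition == cond]
            assert len(sub[sub.trial_type == "nonmatch"]) == 90
            assert sub.block.nunique() == 15

    def test_block_composition(self, session_design):
        for block in session_design.blocks:
            types = [t.trial_type for t in block.test_trials]
            assert types.count("match") == 6 and types.count("nonmatch") == 6
            sample_set = set(block.sample_ids)
            for t in block.test_trials:
                if t.trial_type == "match":
                    assert t.stimulus_id in sample_set
                else:
                    assert t.stimulus_id not in sample_set

    def test_stimulus_ids_session_unique(self, session_design):
        ids = [s for b in session_design.blocks for s in b.sample_ids]
        ids += [
            t.stimulus_id
            for b in session_design.blocks
            for t in b.test_trials
            if t.trial_type == "nonmatch"
        ]
        assert len(ids) == len(set(ids))

    def test_targeted_flags_match_schedule(self, session_design):
        for block in session_design.blocks:
            for t in block.test_trials:
                if t.trial_type == "match":
                    expected = t.sample_position in block.schedule.targeted_samples
                    assert t.targeted == expected
                else:
                    assert not t.targeted

    def test_conditions_balanced_within_subsession(self, session_design):
        for sub in session_design.subsessions:
            conds = [b.condition for b in sub]
            assert all(conds.count(c) == 5 for c in ("beta", "random", "none"))

    def test_seed_reproducibility_byte_identical(self):
        a = build_session(DesignConfig(), rng=42).to_json()
        b = build_session(DesignConfig(), rng=42).to_json()
        assert a == b

    def test_forced_targeted_match_counts(self, forced_design):
        table = forced_design.trials_table()
        match = table[(table.trial_type == "match") & table.targeted]
        assert len(match[match.condition == "beta"]) == 36
        assert len(match[match.condition == "random"]) == 33

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            build_session(DesignConfig(n_match=13), rng=0)

    def test_json_roundtrip_parses(self, session_design):
        parsed = json.loads(session_design.to_json())
        assert len(parsed["subsessions"]) == 3
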