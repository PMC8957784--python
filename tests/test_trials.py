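"""Run-list balance, staircase bookkeeping, scoring, sessions, observations."""

import numpy as np
import pandas as pd
import pytest

import ssinva
from ssinva.renderer import SpeakerLayout
from ssinva.trials import (
    SESSION_LOG_COLUMNS,
    StaircaseState,
    Trial,
    TrialResponse,
    assign_block_orders,
    block_orders,
    build_run_list,
    derive_geometry,
    run_session,
    run_staircase,
    score_trial,
    srt_from_reversals,
    staircase_step,
    to_observation_table,
)


def _trial(ref="pale", tgt="peel", ra=-90.0, ta=-60.0, idx=0):
    return Trial(index=idx, ref_word=ref, target_word=tgt, ref_azimuth_deg=ra,
                 target_azimuth_deg=ta, group="Vc", snr_condition="SRT")


class TestRunList:
    def test_balance_holds_for_many_seeds(self):
        """96 trials; 8 per ordered pair; each group twice per pair, any seed."""
        layout = SpeakerLayout()
        for seed in range(100):
            rl = build_run_list(layout, "SRT", seed)
            assert len(rl) == 96
            df = rl.to_dataframe()
            per_pair = df.groupby(["ref_azimuth_deg", "target_azimuth_deg"]).size()
            assert len(per_pair) == 12 and (per_pair == 8).all()
            per_pg = df.groupby(["ref_azimuth_deg", "target_azimuth_deg", "group"]).size()
            assert (per_pg == 2).all()
            assert (df.ref_word != df.target_word).all()

    def test_legacy_appends_flagged_97th_trial(self):
        rl = build_run_list(SpeakerLayout(), "SRT", 3, legacy_extra_trial=True)
        assert len(rl) == 97
        assert rl.trials[-1].is_legacy and not any(t.is_legacy for t in rl.trials[:-1])

    def test_deterministic_for_fixed_seed(self):
        a = build_run_list(SpeakerLayout(), "SRT+3", 11)
        b = build_run_list(SpeakerLayout(), "SRT+3", 11)
        assert a.trials == b.trials


class TestGeometry:
    @pytest.mark.parametrize("ra,ta,mean,direction", [
        (-90.0, -60.0, -75.0, "right"),
        (30.0, 0.0, 15.0, "left"),
        (60.0, 90.0, 75.0, "right"),
    ])
    def test_mean_location_and_direction(self, ra, ta, mean, direction):
        g = derive_geometry(_trial(ra=ra, ta=ta))
        assert g.mean_location_deg == mean and g.direction == direction

    def test_all_pairs_cover_six_mean_locations_twice(self):
        geoms = [derive_geometry(_trial(ra=a, ta=b)) for a, b in SpeakerLayout().adjacent_pairs()]
        locs = sorted(g.mean_location_deg for g in geoms)
        assert locs == sorted([-75, -45, -15, 15, 45, 75] * 2)

    def test_invalid_trials_rejected(self):
        with pytest.raises(ValueError):
            _trial(ra=-90.0, ta=-30.0)  # not adjacent
        with pytest.raises(ValueError):
            _trial(ref="pale", tgt="pale")
        with pytest.raises(ValueError):
            Trial(0, "pale", "hoot", -90.0, -60.0, "Vc", "SRT")  # cross-group


class TestStaircase:
    def test_hand_simulated_track_c_c_i(self):
        s = StaircaseState()
        assert s.current_snr_db == 0.0  # first trial at SNR 0
        for correct in (True, True, False):
            s = staircase_step(s, correct)
        assert s.snr_track_db == (0.0, -2.0, -4.0, -2.0)
        assert s.reversal_snrs_db == (-4.0,)

    def test_alternating_responses_stop_after_8_reversals(self):
        s = StaircaseState()
        responses = [True, False] * 20
        i = 0
        while not s.stopped:
            s = staircase_step(s, responses[i])
            i += 1
        assert len(s.reversal_snrs_db) == 8
        assert all(-2.0 <= x <= 0.0 for x in s.snr_track_db)

    def test_step_invariant_for_random_responses(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = StaircaseState()
            while not s.stopped:
                s = staircase_step(s, bool(rng.random() < 0.5))
            diffs = np.abs(np.diff(s.snr_track_db))
            assert np.all(diffs == 2.0)
            assert len(s.reversal_snrs_db) == 8

    def test_stepping_stopped_staircase_rejected(self):
        s = StaircaseState()
        while not s.stopped:
            s = staircase_step(s, True if len(s.snr_track_db) % 2 else False)
        with pytest.raises(RuntimeError):
            staircase_step(s, True)

    def test_srt_is_mean_of_last_six_reversals(self):
        s = StaircaseState(reversal_snrs_db=(-4, -2, -6, -4, -6, -4, -6, -4), stopped=True)
        assert srt_from_reversals(s) == pytest.approx(-5.0)
        s2 = StaircaseState(reversal_snrs_db=(-6.0,) * 8, stopped=True)
        assert srt_from_reversals(s2) == -6.0
        with pytest.raises(ValueError):
            srt_from_reversals(StaircaseState())

    def test_deterministic_threshold_listener_converges(self):
        """A listener correct iff SNR >= t yields SRT within 2 dB of t."""
        for t in (-9.0, -4.0, 1.0):
            srts = []
            for _ in range(10):
                state = run_staircase(lambda snr: snr >= t)
                srts.append(state.srt_db)
            assert abs(np.mean(srts) - t) <= 2.0


class TestScoring:
    def test_order_matched_outcomes(self):
        t = _trial()  # true: pale, peel, right
        assert score_trial(t, TrialResponse(("pale", "peel"), "right")) == (1, 1, 1)
        assert score_trial(t, TrialResponse(("peel", "pale"), "right")) == (1, 0, 0)
        assert score_trial(t, TrialResponse(("pale", "peel"), "left")) == (0, 1, 1)

    def test_invalid_response_yields_no_rows(self):
        assert score_trial(_trial(), TrialResponse(("pale", "peel"), "right", valid=False)) is None


def _always_right_responder(trial, snr_db):
    return TrialResponse((trial.ref_word, trial.target_word),
                         derive_geometry(trial).direction)


class TestSession:
    def test_legacy_session_presents_582_trials(self):
        log = run_session("P01", SpeakerLayout(), -8.0, ("SRT", "SRT+3", "SRT+6"),
                          _always_right_responder, master_seed=1)
        assert len(log.table) == 582  # 97 trials x 6 runs
        assert list(log.table.columns) == list(SESSION_LOG_COLUMNS)

    def test_non_legacy_session_presents_576_trials(self):
        log = run_session("P01", SpeakerLayout(), -8.0, ("SRT+6", "SRT", "SRT+3"),
                          _always_right_responder, master_seed=1,
                          legacy_extra_trial=False)
        assert len(log.table) == 576

    def test_snr_fixed_per_run_and_follows_block_order(self):
        log = run_session("P02", SpeakerLayout(), -6.0, ("SRT+3", "SRT", "SRT+6"),
                          _always_right_responder, master_seed=2,
                          legacy_extra_trial=False)
        per_run = log.table.groupby("run")["snr_db"].unique()
        assert all(len(v) == 1 for v in per_run)
        assert [v[0] for v in per_run] == [-3.0, -3.0, -6.0, -6.0, 0.0, 0.0]

    def test_invalid_block_order_rejected(self):
        with pytest.raises(ValueError):
            run_session("P03", SpeakerLayout(), -8.0, ("SRT", "SRT", "SRT+6"),
                        _always_right_responder, master_seed=3)

    def test_twelve_participants_use_all_six_orders_twice(self):
        pids = [f"P{i:02d}" for i in range(12)]
        orders = assign_block_orders(pids)
        counts = pd.Series(list(orders.values())).value_counts()
        assert len(block_orders()) == 6
        assert set(counts.index) == set(block_orders()) and (counts == 2).all()


class TestObservationTable:
    def test_one_valid_trial_gives_three_rows(self):
        log = run_session("P01", SpeakerLayout(), -8.0, ("SRT", "SRT+3", "SRT+6"),
                          _always_right_responder, master_seed=1,
                          legacy_extra_trial=False)
        obs = to_observation_table([log])
        assert len(obs) == 3 * 576
        assert (obs.task == "word").sum() == 2 * (obs.task == "localization").sum()

    def test_invalid_trials_dropped(self):
        def flaky(trial, snr_db):
            r = _always_right_responder(trial, snr_db)
            if trial.index < 5:
                return TrialResponse(r.clicked_words, r.clicked_direction, valid=False)
            return r

        log = run_session("P01", SpeakerLayout(), -8.0, ("SRT", "SRT+3", "SRT+6"),
                          flaky, master_seed=1, runs_per_block=1,
                          legacy_extra_trial=True)
        obs = to_observation_table([log])
        assert len(obs) == 3 * (97 - 5) * 3  # 3 runs of 97 with 5 invalid each

    def test_session_log_csv_round_trip(self, tmp_path):
        log = run_session("P07", SpeakerLayout(), -8.0, ("SRT", "SRT+3", "SRT+6"),
                          _always_right_responder, master_seed=9, runs_per_block=1,
                          legacy_extra_trial=False)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == list(SESSION_LOG_COLUMNS)
        assert len(back) == len(log.table)
        obs = to_observation_table([back])
        assert len(obs) == 3 * len(back)
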