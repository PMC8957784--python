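"""Experimental design and session logic for the SSiN-VA.

Covers the balanced 96-trial run lists (12 adjacent reference->target
azimuth pairs x 8 trials, each word group twice per pair), the 1-up/1-down
adaptive staircase used to estimate the speech reception threshold (2-dB
steps, stop after 8 reversals, SRT = mean SNR of the last 6), trial
scoring, the validity filter for malformed responses, session execution
against a responder callback, and the long-format observation table the
statistical models consume (1 localization row + 2 word rows per valid
trial).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .assets import WORD_GROUPS, GROUP_OF_WORD
from .calibration import SNR_LABELS, SnrCondition, snr_conditions
from .renderer import SpeakerLayout

#: Documented, bit-stable column order of session logs.
SESSION_LOG_COLUMNS = (
    "participant_id", "block", "run", "trial_index", "is_legacy",
    "snr_condition", "snr_db", "group", "ref_word", "target_word",
    "ref_azimuth_deg", "target_azimuth_deg", "mean_location_deg", "direction",
    "clicked_word1", "clicked_word2", "clicked_direction", "valid",
    "loc_correct", "ref_word_correct", "target_word_correct",
)

#: Documented column order of the long-format observation table.
OBSERVATION_COLUMNS = (
    "participant_id", "task", "outcome", "mean_location_deg", "azimuth_deg",
    "word_order", "snr_condition", "group", "direction",
)


@dataclass(frozen=True)
class Trial:
    """One dual-task trial: reference word then target word from an adjacent azimuth."""

    index: int
    ref_word: str
    target_word: str
    ref_azimuth_deg: float
    target_azimuth_deg: float
    group: str
    snr_condition: str
    is_legacy: bool = False

    def __post_init__(self) -> None:
        if GROUP_OF_WORD.get(self.ref_word) != self.group or GROUP_OF_WORD.get(self.target_word) != self.group:
            raise ValueError("both words must belong to the trial's group")
        if self.ref_word == self.target_word:
            raise ValueError("reference and target words must differ")
        if abs(self.target_azimuth_deg - self.ref_azimuth_deg) != 30.0:
            raise ValueError("reference and target azimuths must be adjacent (30° apart)")


@dataclass(frozen=True)
class DerivedTrialGeometry:
    mean_location_deg: float
    direction: str  # "right" iff target azimuth > reference azimuth


def derive_geometry(trial: Trial) -> DerivedTrialGeometry:
    """Mean location = midpoint of the two source azimuths; direction of the shift."""
    return DerivedTrialGeometry(
        mean_location_deg=(trial.ref_azimuth_deg + trial.target_azimuth_deg) / 2.0,
        direction="right" if trial.target_azimuth_deg > trial.ref_azimuth_deg else "left",
    )


@dataclass(frozen=True)
class RunList:
    trials: tuple[Trial, ...]
    snr_condition: str
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            g = derive_geometry(t)
            rows.append({
                "trial_index": t.index, "is_legacy": t.is_legacy,
                "snr_condition": t.snr_condition, "group": t.group,
                "ref_word": t.ref_word, "target_word": t.target_word,
                "ref_azimuth_deg": t.ref_azimuth_deg,
                "target_azimuth_deg": t.target_azimuth_deg,
                "mean_location_deg": g.mean_location_deg, "direction": g.direction,
            })
        return pd.DataFrame(rows)


def build_run_list(
    layout: SpeakerLayout,
    snr_condition: str | SnrCondition,
    seed: int,
    legacy_extra_trial: bool = False,
) -> RunList:
    """Build one balanced, shuffled 96-trial run list.

    12 ordered adjacent azimuth pairs x 8 trials each; within each pair every
    word group appears exactly twice; the two words of a trial are drawn from
    the group without replacement.  With ``legacy_extra_trial`` one extra
    random trial is appended (the original implementation presented 97 per
    run); it is flagged and excluded from balance accounting.
    """
    label = snr_condition.label if isinstance(snr_condition, SnrCondition) else snr_condition
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    pairs = layout.adjacent_pairs()
    if len(pairs) != 2 * (len(layout.word_azimuths_deg) - 1):
        raise ValueError("layout has no usable adjacency structure")
    protos = []
    for ref_az, tgt_az in pairs:
        for group in WORD_GROUPS:
            for _ in range(2):
                ref_w, tgt_w = rng.choice(WORD_GROUPS[group], size=2, replace=False)
                protos.append((ref_w, tgt_w, ref_az, tgt_az, group))
    rng.shuffle(protos)
    if legacy_extra_trial:
        ref_az, tgt_az = pairs[rng.integers(len(pairs))]
        group = list(WORD_GROUPS)[rng.integers(len(WORD_GROUPS))]
        ref_w, tgt_w = rng.choice(WORD_GROUPS[group], size=2, replace=False)
        protos.append((ref_w, tgt_w, ref_az, tgt_az, group))
    trials = tuple(
        Trial(
            index=i, ref_word=str(rw), target_word=str(tw),
            ref_azimuth_deg=ra, target_azimuth_deg=ta, group=g,
            snr_condition=label, is_legacy=legacy_extra_trial and i == 96,
        )
        for i, (rw, tw, ra, ta, g) in enumerate(protos)
    )
    return RunList(trials=trials, snr_condition=label, seed=int(seed))


# ----------------------------------------------------------------------------
# adaptive staircase
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseState:
    """1-up/1-down track: correct lowers the SNR by 2 dB, incorrect raises it.

    A reversal is recorded at the SNR where the step direction changes sign;
    the track stops once 8 reversals have been collected.
    """

    snr_track_db: tuple[float, ...] = (0.0,)
    step_db: float = 2.0
    stop_reversals: int = 8
    reversal_snrs_db: tuple[float, ...] = ()
    stopped: bool = False
    _last_dir: int = 0  # -1 down, +1 up, 0 before the first step

    @property
    def current_snr_db(self) -> float:
        return self.snr_track_db[-1]

    @property
    def srt_db(self) -> float:
        return srt_from_reversals(self)


def staircase_step(state: StaircaseState, last_response_correct: bool) -> StaircaseState:
    """Advance the staircase by one response."""
    if state.stopped:
        raise RuntimeError("cannot step a stopped staircase")
    step_dir = -1 if last_response_correct else 1
    reversals = state.reversal_snrs_db
    if state._last_dir != 0 and step_dir != state._last_dir:
        reversals = reversals + (state.current_snr_db,)
    stopped = len(reversals) >= state.stop_reversals
    track = state.snr_track_db
    if not stopped:
        track = track + (state.current_snr_db + step_dir * state.step_db,)
    return replace(
        state,
        snr_track_db=track,
        reversal_snrs_db=reversals,
        stopped=stopped,
        _last_dir=step_dir,
    )


def srt_from_reversals(state: StaircaseState) -> float:
    """SRT = arithmetic mean of the SNRs at the last six reversals."""
    if not state.stopped or len(state.reversal_snrs_db) < state.stop_reversals:
        raise ValueError("staircase has not collected its 8 reversals yet")
    return float(np.mean(state.reversal_snrs_db[-6:]))


def run_staircase(
    respond_correct: Callable[[float], bool],
    start_snr_db: float = 0.0,
    step_db: float = 2.0,
    stop_reversals: int = 8,
    max_trials: int = 400,
) -> StaircaseState:
    """Drive a staircase against a responder until 8 reversals (or a cap).

    ``respond_correct(snr_db)`` plays one SRT trial (a single word from 0° in
    babble) and reports whether the response was correct.
    """
    state = StaircaseState(
        snr_track_db=(start_snr_db,), step_db=step_db, stop_reversals=stop_reversals
    )
    for _ in range(max_trials):
        state = staircase_step(state, respond_correct(state.current_snr_db))
        if state.stopped:
            break
    return state


# ----------------------------------------------------------------------------
# responses and scoring
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialResponse:
    """Button presses for one trial: two word clicks plus a direction click.

    ``valid`` is False for malformed logs (repeated or extra presses); such
    trials carry no scored outcomes and are discarded before analysis.
    """

    clicked_words: tuple[str, str]
    clicked_direction: str
    valid: bool = True


def score_trial(trial: Trial, response: TrialResponse) -> tuple[int, int, int] | None:
    """Score one trial: (localization, reference word, target word) correctness.

    Word clicks are matched by order: first click vs the reference word,
    second vs the target.  Invalid responses yield None (no rows).
    """
    if not response.valid:
        return None
    true_dir = derive_geometry(trial).direction
    loc = int(response.clicked_direction == true_dir)
    ref_ok = int(response.clicked_words[0] == trial.ref_word)
    tgt_ok = int(response.clicked_words[1] == trial.target_word)
    return loc, ref_ok, tgt_ok


# ----------------------------------------------------------------------------
# sessions
# ----------------------------------------------------------------------------

def block_orders() -> list[tuple[str, str, str]]:
    """The 6 permutations of the three SNR conditions."""
    return list(itertools.permutations(SNR_LABELS))


def assign_block_orders(participant_ids: Sequence[str]) -> dict[str, tuple[str, str, str]]:
    """Assign block orders cyclically: 12 participants use each of the 6 orders twice."""
    orders = block_orders()
    return {pid: orders[i % len(orders)] for i, pid in enumerate(participant_ids)}


def derive_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Per-run seeds split deterministically from one master seed."""
    rng = np.random.default_rng(int(master_seed) & 0x7FFFFFFF)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_runs)]


@dataclass
class SessionLog:
    """Full per-trial record of one participant's session."""

    participant_id: str
    srt_db: float
    block_order: tuple[str, str, str]
    master_seed: int
    table: pd.DataFrame = field(repr=False)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def read_csv(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path)


def run_session(
    participant_id: str,
    layout: SpeakerLayout,
    srt_db: float,
    block_order: Sequence[str],
    responder: Callable[[Trial, float], TrialResponse],
    master_seed: int,
    runs_per_block: int = 2,
    legacy_extra_trial: bool = True,
) -> SessionLog:
    """Execute one session: 3 blocks x 2 runs, SNR fixed within each run.

    ``responder(trial, snr_db)`` supplies the button presses (a human UI in
    the real test; a simulated listener here).  Each run gets its own seed
    derived from the master seed, so the whole session is reproducible.
    """
    if sorted(block_order) != sorted(SNR_LABELS):
        raise ValueError(f"block order must be a permutation of {SNR_LABELS}")
    conds = {c.label: c for c in snr_conditions()}
    seeds = derive_run_seeds(master_seed, len(block_order) * runs_per_block)
    rows = []
    run_no = 0
    for b, label in enumerate(block_order):
        snr_db = conds[label].snr_db(srt_db)
        for _ in range(runs_per_block):
            run_list = build_run_list(layout, label, seeds[run_no], legacy_extra_trial)
            for t in run_list.trials:
                resp = responder(t, snr_db)
                scored = score_trial(t, resp)
                g = derive_geometry(t)
                rows.append({
                    "participant_id": participant_id, "block": b, "run": run_no,
                    "trial_index": t.index, "is_legacy": t.is_legacy,
                    "snr_condition": label, "snr_db": snr_db, "group": t.group,
                    "ref_word": t.ref_word, "target_word": t.target_word,
                    "ref_azimuth_deg": t.ref_azimuth_deg,
                    "target_azimuth_deg": t.target_azimuth_deg,
                    "mean_location_deg": g.mean_location_deg, "direction": g.direction,
                    "clicked_word1": resp.clicked_words[0],
                    "clicked_word2": resp.clicked_words[1],
                    "clicked_direction": resp.clicked_direction,
                    "valid": resp.valid,
                    "loc_correct": scored[0] if scored else pd.NA,
                    "ref_word_correct": scored[1] if scored else pd.NA,
                    "target_word_correct": scored[2] if scored else pd.NA,
                })
            run_no += 1
    table = pd.DataFrame(rows, columns=list(SESSION_LOG_COLUMNS))
    return SessionLog(
        participant_id=participant_id, srt_db=srt_db,
        block_order=tuple(block_order), master_seed=int(master_seed), table=table,
    )


def to_observation_table(session_logs: Sequence[SessionLog] | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Long-format binary observations: 1 localization + 2 word rows per valid trial.

    Invalid trials are dropped.  Word rows carry the azimuth the word was
    presented from and its order (reference or target); localization rows
    carry the mean location and shift direction.
    """
    frames = [sl.table if isinstance(sl, SessionLog) else sl for sl in session_logs]
    log = pd.concat(frames, ignore_index=True)
    log = log[log["valid"].astype(bool)]
    rows = []
    for r in log.itertuples(index=False):
        base = {
            "participant_id": r.participant_id, "snr_condition": r.snr_condition,
            "group": r.group, "direction": r.direction,
        }
        rows.append({**base, "task": "localization", "outcome": int(r.loc_correct),
                     "mean_location_deg": r.mean_location_deg,
                     "azimuth_deg": np.nan, "word_order": pd.NA})
        rows.append({**base, "task": "word", "outcome": int(r.ref_word_correct),
                     "mean_location_deg": np.nan,
                     "azimuth_deg": r.ref_azimuth_deg, "word_order": "reference"})
        rows.append({**base, "task": "word", "outcome": int(r.target_word_correct),
                     "mean_location_deg": np.nan,
                     "azimuth_deg": r.target_azimuth_deg, "word_order": "target"})
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
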