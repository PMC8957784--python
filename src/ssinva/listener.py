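"""Parameterised probabilistic listeners for end-to-end simulation.

Two flavours:

* **geometry-driven** — closed-form logistic response models on the trial
  geometry (mean location / azimuth, SNR condition, word group, shift
  direction) with a per-participant random intercept.  Fast; used for
  staircase-convergence checks, cohort simulation and GLMM parameter
  recovery.  Guess floors reflect the forced-choice structure (1/4 for the
  closed-set word task, 1/2 for the direction judgement) and can be set to
  0 when the simulation must generate exactly from a logistic model.
* **audio-driven** — identifies words in the rendered stereo mix by
  template correlation and judges the shift direction from the interaural
  level difference of the speech stem; used in renderer integration tests.

Default coefficient magnitudes mirror the effect sizes observed with the
test (localization odds ratios ~1.2-2.7 over mean location, a strong SNR
effect on word discrimination, a weak final-consonant group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .assets import WORD_GROUPS
from .calibration import rms
from .renderer import RenderedTrial, SpeakerLayout
from .trials import (
    SessionLog,
    Trial,
    TrialResponse,
    assign_block_orders,
    derive_geometry,
    run_session,
    run_staircase,
    to_observation_table,
)

#: Inverted-U localization profile over mean location (log-odds vs -75°).
DEFAULT_LOC_MEAN_LOCATION = {
    -75.0: 0.0, -45.0: 0.60, -15.0: 1.00, 15.0: 0.91, 45.0: 0.57, 75.0: 0.24,
}
DEFAULT_LOC_SNR = {"SRT": 0.0, "SRT+3": 0.08, "SRT+6": 0.20}

#: U-shaped word profile over azimuth (log-odds vs -90°).
DEFAULT_WORD_AZIMUTH = {
    -90.0: 0.0, -60.0: -0.04, -30.0: -0.36, 0.0: -0.46,
    30.0: -0.25, 60.0: -0.20, 90.0: -0.29,
}
DEFAULT_WORD_SNR = {"SRT": 0.0, "SRT+3": 1.10, "SRT+6": 1.90}
DEFAULT_WORD_GROUP = {"Vc": 0.0, "Vs": -0.27, "Ci": 0.20, "Cf": -0.99}


@dataclass
class ListenerProfile:
    """Response model of one simulated participant.

    ``*_intercept`` are the fixed intercepts (log-odds at the reference
    cell); ``random_intercept_sd`` is the between-participant SD tau on the
    log-odds scale; ``participant_offset_*`` the realised draw for this
    listener.  Coefficients are per-level log-odds contributions.
    """

    loc_intercept: float = -0.04
    loc_mean_location: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_LOC_MEAN_LOCATION))
    loc_snr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOC_SNR))
    loc_direction: dict[str, float] = field(default_factory=lambda: {"left": 0.0, "right": 0.0})
    word_intercept: float = 1.53
    word_azimuth: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_WORD_AZIMUTH))
    word_snr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WORD_SNR))
    word_group: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WORD_GROUP))
    random_intercept_sd_loc: float = np.sqrt(0.23)
    random_intercept_sd_word: float = np.sqrt(0.47)
    participant_offset_loc: float = 0.0
    participant_offset_word: float = 0.0
    guess_floor_word: float = 0.25
    guess_floor_direction: float = 0.5
    #: single-word psychometric slope/threshold for SRT staircase simulation
    srt_threshold_db: float = -8.0
    srt_slope_per_db: float = 1.0
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(int(self.seed) & 0x7FFFFFFF)

    # -- analytic probabilities -------------------------------------------
    def loc_eta(self, trial: Trial) -> float:
        geom = derive_geometry(trial)
        return (
            self.loc_intercept
            + self.loc_mean_location[geom.mean_location_deg]
            + self.loc_snr[trial.snr_condition]
            + self.loc_direction[geom.direction]
            + self.participant_offset_loc
        )

    def word_eta(self, trial: Trial, azimuth_deg: float) -> float:
        return (
            self.word_intercept
            + self.word_azimuth[azimuth_deg]
            + self.word_snr[trial.snr_condition]
            + self.word_group[trial.group]
            + self.participant_offset_word
        )

    def p_direction_correct(self, trial: Trial) -> float:
        f = self.guess_floor_direction
        return f + (1.0 - f) * float(expit(self.loc_eta(trial)))

    def p_word_correct(self, trial: Trial, azimuth_deg: float) -> float:
        f = self.guess_floor_word
        return f + (1.0 - f) * float(expit(self.word_eta(trial, azimuth_deg)))

    def p_single_word_correct(self, snr_db: float) -> float:
        """Psychometric function for the single-word SRT task (floor 1/4)."""
        f = self.guess_floor_word
        return f + (1.0 - f) * float(
            expit(self.srt_slope_per_db * (snr_db - self.srt_threshold_db))
        )


def respond(profile: ListenerProfile, trial: Trial, snr_db: float = 0.0) -> TrialResponse:
    """Geometry-driven button response for one trial.

    Each word click is correct with the profile's word probability, else a
    uniform within-group foil; the direction click is correct with the
    localization probability.  All draws come from the profile's stream, so
    a fixed profile seed reproduces a session bit-for-bit.
    """
    rng = profile._rng
    words = []
    for true_word, az in (
        (trial.ref_word, trial.ref_azimuth_deg),
        (trial.target_word, trial.target_azimuth_deg),
    ):
        if rng.random() < profile.p_word_correct(trial, az):
            words.append(true_word)
        else:
            foils = [w for w in WORD_GROUPS[trial.group] if w != true_word]
            words.append(foils[rng.integers(len(foils))])
    true_dir = derive_geometry(trial).direction
    if rng.random() < profile.p_direction_correct(trial):
        direction = true_dir
    else:
        direction = "left" if true_dir == "right" else "right"
    return TrialResponse(clicked_words=(words[0], words[1]), clicked_direction=direction)


def make_responder(profile: ListenerProfile):
    """Adapter to the trial-engine responder callback signature."""
    def _respond(trial: Trial, snr_db: float) -> TrialResponse:
        return respond(profile, trial, snr_db)
    return _respond


def simulate_srt(profile: ListenerProfile, seed: int | None = None) -> float:
    """Estimate this listener's SRT with the 1-up/1-down staircase."""
    rng = np.random.default_rng(seed) if seed is not None else profile._rng
    state = run_staircase(lambda snr: rng.random() < profile.p_single_word_correct(snr))
    return state.srt_db


# ----------------------------------------------------------------------------
# audio-driven listener
# ----------------------------------------------------------------------------

def better_ear_snr(rendered: RenderedTrial, word_index: int) -> float:
    """Best per-ear SNR (dB) within one word's time window.

    Per ear: speech-stem RMS minus babble-stem RMS over the window; the
    better ear is the max.  Captures the better-ear-glimpsing advantage a
    lateral source enjoys over the symmetric babble.
    """
    t0, t1 = rendered.word_windows_s[word_index]
    i0, i1 = int(t0 * rendered.sample_rate), int(t1 * rendered.sample_rate)
    snrs = []
    for ch in (0, 1):
        s = rms(rendered.speech_only[ch, i0:i1])
        b = rms(rendered.babble_only[ch, i0:i1])
        snrs.append(20.0 * np.log10(s / b))
    return float(max(snrs))


def _word_ild_db(rendered: RenderedTrial, word_index: int) -> float:
    t0, t1 = rendered.word_windows_s[word_index]
    i0, i1 = int(t0 * rendered.sample_rate), int(t1 * rendered.sample_rate)
    l = rms(rendered.speech_only[0, i0:i1])
    r = rms(rendered.speech_only[1, i0:i1])
    return 20.0 * float(np.log10(r / l))


def respond_from_audio(
    trial: Trial,
    rendered: RenderedTrial,
    templates: dict[str, np.ndarray],
) -> TrialResponse:
    """Audio-driven response: template-correlation word identification on the
    mix (restricted to the 4 within-group candidates) and a direction
    judgement from the change in speech-stem interaural level difference."""
    from .assets import correlate_identify

    fs = rendered.sample_rate
    clicks = []
    for k in range(2):
        t0, t1 = rendered.word_windows_s[k]
        seg = rendered.mix[:, int(t0 * fs): int(t1 * fs)]
        clicks.append(correlate_identify(seg, templates, list(WORD_GROUPS[trial.group])))
    direction = "right" if _word_ild_db(rendered, 1) > _word_ild_db(rendered, 0) else "left"
    return TrialResponse(clicked_words=(clicks[0], clicks[1]), clicked_direction=direction)


# ----------------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------------

def simulate_cohort(
    n_participants: int,
    profile_template: ListenerProfile | None = None,
    layout: SpeakerLayout | None = None,
    seed: int = 0,
    runs_per_block: int = 2,
    legacy_extra_trial: bool = False,
    srt_db: float = -8.0,
    participant_ids: Sequence[str] | None = None,
) -> tuple[list[SessionLog], pd.DataFrame]:
    """Simulate a full cohort and return (session logs, observation table).

    Each participant gets an independent random-intercept draw (loc and
    word, SD from the template) and a block order; all 6 orders are used
    across 12 participants (each twice).  Sessions run through the trial
    engine exactly as a human session would.
    """
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    template = profile_template or ListenerProfile()
    layout = layout or SpeakerLayout()
    master = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    pids = list(participant_ids) if participant_ids is not None else [
        f"P{i + 1:02d}" for i in range(n_participants)
    ]
    orders = assign_block_orders(pids)
    logs = []
    for pid in pids:
        p_seed = int(master.integers(0, 2**31 - 1))
        draw = np.random.default_rng(p_seed)
        profile = replace(
            template,
            participant_offset_loc=float(draw.normal(0.0, template.random_intercept_sd_loc)),
            participant_offset_word=float(draw.normal(0.0, template.random_intercept_sd_word)),
            seed=p_seed,
        )
        logs.append(run_session(
            participant_id=pid, layout=layout, srt_db=srt_db,
            block_order=orders[pid], responder=make_responder(profile),
            master_seed=p_seed, runs_per_block=runs_per_block,
            legacy_extra_trial=legacy_extra_trial,
        ))
    return logs, to_observation_table(logs)
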