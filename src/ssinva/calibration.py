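"""Level calibration chain for the SSiN-VA.

The test fixes the multi-talker babble at 52 dB SPL throughout; word level
is 52 dB SPL at SNR 0 and moves with the requested SNR; the calibration
noise sits 20 dB above the word level (72 dB SPL).  All levels are defined
at the source domain, before spatialisation: the single per-run SNR is a
property of the calibrated source streams, while the SNR at each eardrum
varies with azimuth by design.

Digital levels map to SPL through a single configurable reference:
by default a digital RMS of 1.0 corresponds to 100 dB SPL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assets import WordToken

SNR_OFFSETS_DB = (0, 3, 6)
SNR_LABELS = ("SRT", "SRT+3", "SRT+6")


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(np.asarray(x, dtype=float)))))


def db(ratio: float) -> float:
    return 20.0 * float(np.log10(ratio))


@dataclass(frozen=True)
class LevelMap:
    """dB SPL <-> digital RMS mapping and the test's fixed presentation levels."""

    spl_ref_db: float = 100.0  # SPL assigned to digital RMS 1.0
    word_level_db_spl: float = 52.0  # word level when SNR = 0
    babble_level_db_spl: float = 52.0  # constant across the whole task
    calib_offset_db: float = 20.0

    @property
    def calib_noise_level_db_spl(self) -> float:
        return self.word_level_db_spl + self.calib_offset_db

    def rms_for_spl(self, level_db_spl: float) -> float:
        return float(10.0 ** ((level_db_spl - self.spl_ref_db) / 20.0))

    def spl_for_rms(self, digital_rms: float) -> float:
        if digital_rms <= 0:
            raise ValueError("RMS must be positive")
        return float(self.spl_ref_db + 20.0 * np.log10(digital_rms))


@dataclass(frozen=True)
class SnrCondition:
    """One of the three test conditions: SNR = participant SRT + offset."""

    label: str
    offset_db: int

    def __post_init__(self) -> None:
        if self.offset_db not in SNR_OFFSETS_DB:
            raise ValueError(f"offset must be one of {SNR_OFFSETS_DB}")

    def snr_db(self, srt_db: float) -> float:
        return srt_db + self.offset_db


def snr_conditions() -> tuple[SnrCondition, ...]:
    return tuple(SnrCondition(l, o) for l, o in zip(SNR_LABELS, SNR_OFFSETS_DB))


def equalize_word_levels(
    tokens: dict[str, WordToken], target_rms: float | None = None
) -> tuple[dict[str, WordToken], dict[str, float]]:
    """Equalise the vowel steady-state RMS across all word tokens.

    Each token is rescaled by one gain so that the RMS over its annotated
    steady-state window equals ``target_rms`` (default: geometric mean of the
    input steady-state RMS values, so an already-equal set gets unit gains).
    Returns the rescaled tokens and the per-word gains applied.
    """
    ss_rms = {}
    for word_id, tok in tokens.items():
        r = tok.steady_state_rms()
        if r <= 0 or not np.isfinite(r):
            raise ValueError(f"token {word_id!r} has a degenerate steady state")
        ss_rms[word_id] = r
    if target_rms is None:
        target_rms = float(np.exp(np.mean(np.log(list(ss_rms.values())))))
    gains = {w: target_rms / r for w, r in ss_rms.items()}
    return {w: tok.scaled(gains[w]) for w, tok in tokens.items()}, gains


def scale_babble_sources(
    source_rms: float,
    n_sources: int,
    target_rms: float,
    convention: str = "sum",
) -> float:
    """Per-source gain so the babble matches the word-stimulus RMS.

    With the default ``"sum"`` convention the n independent source streams
    sum incoherently to ``target_rms`` (gain = target / (rms * sqrt(n)));
    with ``"per_source"`` each individual stream is set to ``target_rms``.
    """
    if n_sources < 1:
        raise ValueError("need at least one babble source")
    if source_rms <= 0:
        raise ValueError("source RMS must be positive")
    if convention == "sum":
        return target_rms / (source_rms * np.sqrt(n_sources))
    if convention == "per_source":
        return target_rms / source_rms
    raise ValueError(f"unknown convention {convention!r}")


def make_calibration_noise(
    level_map: LevelMap, duration_s: float, sample_rate: int = 44100, seed: int = 0
) -> np.ndarray:
    """Gaussian calibration noise at word level + 20 dB (72 dB SPL by default)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    x = rng.standard_normal(int(round(duration_s * sample_rate)))
    return x * (level_map.rms_for_spl(level_map.calib_noise_level_db_spl) / rms(x))


@dataclass(frozen=True)
class TrialGains:
    """Source-domain presentation levels for one trial."""

    speech_level_db_spl: float
    babble_level_db_spl: float
    speech_rms: float  # target steady-state RMS for each word token
    babble_rms: float  # target RMS of the summed babble


def set_trial_gains(level_map: LevelMap, snr_db: float) -> TrialGains:
    """Levels realising the requested SNR: babble fixed, speech = babble + SNR."""
    if not np.isfinite(snr_db):
        raise ValueError("SNR must be finite")
    speech_spl = level_map.babble_level_db_spl + snr_db
    return TrialGains(
        speech_level_db_spl=speech_spl,
        babble_level_db_spl=level_map.babble_level_db_spl,
        speech_rms=level_map.rms_for_spl(speech_spl),
        babble_rms=level_map.rms_for_spl(level_map.babble_level_db_spl),
    )
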