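"""Anechoic binaural rendering of SSiN-VA trial scenes.

A trial scene has word sources on a 7-azimuth grid (-90° to 90° in 30°
steps) and four constant babble sources at ±30° and ±60°.  Rendering is
fully anechoic: per 12-ms head-tracking frame, the effective azimuth of
each source (world azimuth minus head yaw) selects an interpolated,
time-aligned HRIR pair whose interaural delay is replaced by a Woodworth
ITD personalised to the listener's head circumference.  Frames are joined
with a linear crossfade so head motion produces no clicks.

Sign convention: negative azimuth = listener's left, 0° = front, and a
positive ITD means the right ear leads.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .assets import (
    HRIRSet,
    WordToken,
    _apply_itd,
    woodworth_itd,
    DEFAULT_HEAD_CIRCUMFERENCE_M,
    HEAD_CIRCUMFERENCE_RANGE_M,
)
from .calibration import LevelMap, rms, scale_babble_sources, set_trial_gains

logger = logging.getLogger("ssinva.renderer")

HEAD_UPDATE_PERIOD_S = 0.012

# re-export: the personalised interaural delay IS the Woodworth model
personalized_itd = woodworth_itd


@dataclass(frozen=True)
class SpeakerLayout:
    """Virtual loudspeaker geometry of the test."""

    word_azimuths_deg: tuple[float, ...] = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)
    babble_azimuths_deg: tuple[float, ...] = (-60.0, -30.0, 30.0, 60.0)

    def __post_init__(self) -> None:
        az = np.asarray(self.word_azimuths_deg)
        if len(az) < 2 or not np.allclose(np.diff(az), 30.0):
            raise ValueError("word grid must be evenly spaced at 30°")
        bz = np.asarray(self.babble_azimuths_deg)
        if not np.allclose(np.sort(bz), np.sort(-bz)):
            raise ValueError("babble azimuths must be symmetric about 0°")

    def adjacent_pairs(self) -> list[tuple[float, float]]:
        """All ordered (reference, target) pairs of adjacent grid azimuths."""
        az = self.word_azimuths_deg
        pairs = []
        for a, b in zip(az[:-1], az[1:]):
            pairs.append((a, b))
            pairs.append((b, a))
        return pairs


@dataclass(frozen=True)
class TrialTimeline:
    """Fixed within-trial event times (seconds)."""

    babble_on_s: float = 0.0
    word1_on_s: float = 0.5
    word2_on_s: float = 2.0
    babble_off_s: float = 3.5

    def __post_init__(self) -> None:
        ts = (self.babble_on_s, self.word1_on_s, self.word2_on_s, self.babble_off_s)
        if not all(a < b for a, b in zip(ts[:-1], ts[1:])):
            raise ValueError("timeline events must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.babble_off_s


@dataclass
class HeadState:
    """Listener head: yaw-over-time track plus the ITD-personalisation measure.

    ``yaw_track`` is None for a static head (the default test condition:
    participants face front), or ``(t_s, yaw_deg)`` sample arrays that are
    linearly interpolated and held at the ends.
    """

    circumference_m: float = DEFAULT_HEAD_CIRCUMFERENCE_M
    yaw_track: tuple[np.ndarray, np.ndarray] | None = None
    update_period_s: float = HEAD_UPDATE_PERIOD_S

    def __post_init__(self) -> None:
        lo, hi = HEAD_CIRCUMFERENCE_RANGE_M
        if not (lo <= self.circumference_m <= hi):
            raise ValueError(f"head circumference outside [{lo}, {hi}] m")

    def yaw_at(self, t_s: float) -> float:
        if self.yaw_track is None:
            return 0.0
        t, y = self.yaw_track
        return float(np.interp(t_s, t, y))

    @property
    def is_static(self) -> bool:
        return self.yaw_track is None or np.ptp(self.yaw_track[1]) == 0.0

    @classmethod
    def from_csv(cls, path: str | Path, circumference_m: float = DEFAULT_HEAD_CIRCUMFERENCE_M) -> "HeadState":
        """Load a head-yaw track from CSV with columns t_s, yaw_deg."""
        ts, ys = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ts.append(float(row["t_s"]))
                ys.append(float(row["yaw_deg"]))
        return cls(circumference_m=circumference_m, yaw_track=(np.asarray(ts), np.asarray(ys)))


def effective_azimuth(source_azimuth_deg: float, head_yaw_deg: float) -> float:
    """World-anchored source azimuth as seen by a rotated head, in (-180, 180]."""
    a = (source_azimuth_deg - head_yaw_deg) % 360.0
    return a - 360.0 if a > 180.0 else a


def fold_to_lateral(azimuth_deg: float) -> float:
    """Fold azimuths beyond ±90° onto the frontal hemifield.

    The synthetic HRIRs carry no front/back cues, so a source behind the
    listener is rendered from the mirror-front direction with the same
    lateral angle.  A structured warning is logged when folding occurs.
    """
    a = azimuth_deg
    if a > 90.0:
        folded = 180.0 - a
    elif a < -90.0:
        folded = -180.0 - a
    else:
        return a
    logger.warning("front_back_fold azimuth_deg=%.1f folded_deg=%.1f", a, folded)
    return folded


def frame_count(duration_s: float, update_period_s: float = HEAD_UPDATE_PERIOD_S) -> int:
    """Number of head-tracking frames covering a render of ``duration_s``."""
    return math.ceil(duration_s / update_period_s)


def interpolate_aligned_ir(hrir_set: HRIRSet, azimuth_deg: float) -> np.ndarray:
    """Time-aligned IR pair at an arbitrary azimuth in [-90, 90].

    Grid IRs are already zero-ITD; linear interpolation between the two
    bracketing grid azimuths is therefore phase-coherent (the personalised
    delay is re-inserted afterwards by the caller).
    """
    az = hrir_set.azimuths_deg
    if len(az) == 0:
        raise ValueError("HRIR grid is empty")
    a = float(np.clip(azimuth_deg, az[0], az[-1]))
    hi = int(np.searchsorted(az, a))
    if hi < len(az) and np.isclose(az[hi], a):
        return hrir_set.aligned_irs[hi]
    if hi == 0:
        return hrir_set.aligned_irs[0]
    if hi >= len(az):
        return hrir_set.aligned_irs[-1]
    lo = hi - 1
    w = (a - az[lo]) / (az[hi] - az[lo])
    return (1.0 - w) * hrir_set.aligned_irs[lo] + w * hrir_set.aligned_irs[hi]


def _ir_for(hrir_set: HRIRSet, eff_azimuth_deg: float, circumference_m: float) -> np.ndarray:
    """Personalised delay-carrying IR pair for one effective azimuth."""
    a = fold_to_lateral(eff_azimuth_deg)
    aligned = interpolate_aligned_ir(hrir_set, a)
    itd = personalized_itd(a, circumference_m)
    return _apply_itd(aligned, itd, hrir_set.sample_rate)


def spatialize(
    waveform: np.ndarray,
    azimuth_deg: float,
    hrir_set: HRIRSet,
    head_state: HeadState | None = None,
) -> np.ndarray:
    """Render a mono source at a world azimuth to a stereo (2, n) signal.

    With a static head the whole signal is convolved once; with a moving
    head the IR pair is updated every 12 ms and successive frames are
    joined by linearly crossfading the framed input between the previous
    and current IRs (exact for a static head, click-free otherwise).
    Output is truncated to the input length.
    """
    head = head_state or HeadState()
    x = np.asarray(waveform, dtype=float)
    n = len(x)
    fs = hrir_set.sample_rate

    if head.is_static:
        yaw = head.yaw_at(0.0)
        ir = _ir_for(hrir_set, effective_azimuth(azimuth_deg, yaw), head.circumference_m)
        out = np.stack([signal.fftconvolve(x, ir[ch])[:n] for ch in (0, 1)])
        return out

    flen = int(round(head.update_period_s * fs))
    n_frames = frame_count(n / fs, head.update_period_s)
    out = np.zeros((2, n + hrir_set.aligned_irs.shape[2]))
    ir_prev: np.ndarray | None = None
    ramp = None
    for i in range(n_frames):
        j0, j1 = i * flen, min((i + 1) * flen, n)
        seg = x[j0:j1]
        yaw = head.yaw_at(j0 / fs)
        ir_cur = _ir_for(hrir_set, effective_azimuth(azimuth_deg, yaw), head.circumference_m)
        if ir_prev is None:
            parts = [(seg, ir_cur)]
        else:
            if ramp is None or len(ramp) != len(seg):
                ramp = np.linspace(0.0, 1.0, len(seg), endpoint=False)
            parts = [(seg * (1.0 - ramp), ir_prev), (seg * ramp, ir_cur)]
        for s, ir in parts:
            for ch in (0, 1):
                y = signal.fftconvolve(s, ir[ch])
                out[ch, j0 : j0 + len(y)] += y
        ir_prev = ir_cur
    return out[:, :n]


@dataclass(frozen=True)
class RenderedTrial:
    """Stereo mix and stems of one rendered trial."""

    mix: np.ndarray
    speech_only: np.ndarray
    babble_only: np.ndarray
    sample_rate: int
    timeline: TrialTimeline
    word_windows_s: tuple[tuple[float, float], tuple[float, float]]
    word_azimuths_deg: tuple[float, float] = field(default=(0.0, 0.0))
    #: realized source-domain SNR: speech steady-state RMS vs summed babble RMS
    source_snr_db: float = float("nan")


def _babble_excerpt(babble_wave: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Seed-chosen excerpt with wraparound."""
    start = int(rng.integers(0, len(babble_wave)))
    idx = (start + np.arange(n)) % len(babble_wave)
    return babble_wave[idx]


def render_trial(
    word1: WordToken,
    word2: WordToken,
    azimuth1_deg: float,
    azimuth2_deg: float,
    babble_wave: np.ndarray,
    hrir_set: HRIRSet,
    level_map: LevelMap,
    snr_db: float,
    head_state: HeadState | None = None,
    seed: int = 0,
    timeline: TrialTimeline = TrialTimeline(),
    layout: SpeakerLayout = SpeakerLayout(),
    babble_convention: str = "sum",
) -> RenderedTrial:
    """Render one full trial: babble 0-3.5 s, words at 0.5 s and 2.0 s.

    Word tokens are scaled so their vowel steady-state RMS sits at the
    speech level (52 dB SPL + SNR); the four babble streams are independent
    seed-chosen excerpts scaled so their sum sits at 52 dB SPL.  Returns the
    stereo mix plus speech-only and babble-only stems; by linearity
    ``mix == speech_only + babble_only`` sample-wise.
    """
    head = head_state or HeadState()
    fs = hrir_set.sample_rate
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    gains = set_trial_gains(level_map, snr_db)
    n_total = int(round(timeline.duration_s * fs))

    # --- speech stem
    speech = np.zeros((2, n_total))
    slots = (
        (timeline.word1_on_s, timeline.word2_on_s),
        (timeline.word2_on_s, timeline.babble_off_s),
    )
    for tok, az, (t_on, t_end) in zip((word1, word2), (azimuth1_deg, azimuth2_deg), slots):
        if tok.sample_rate != fs:
            raise ValueError("token sample rate must match the HRIR set")
        if tok.duration_s > (t_end - t_on) + 1e-9:
            raise ValueError(
                f"token {tok.word_id!r} ({tok.duration_s:.2f} s) exceeds its "
                f"{t_end - t_on:.2f}-s slot"
            )
        scaled = tok.waveform * (gains.speech_rms / tok.steady_state_rms())
        rendered = spatialize(scaled, az, hrir_set, head)
        i0 = int(round(t_on * fs))
        speech[:, i0 : i0 + rendered.shape[1]] += rendered[:, : n_total - i0]

    # --- babble stem: four independent excerpts at the fixed babble azimuths
    n_bab = int(round((timeline.babble_off_s - timeline.babble_on_s) * fs))
    babble = np.zeros((2, n_total))
    n_src = len(layout.babble_azimuths_deg)
    babble_src_sum = np.zeros(n_bab)
    for az in layout.babble_azimuths_deg:
        ex = _babble_excerpt(np.asarray(babble_wave, dtype=float), n_bab, rng)
        g = scale_babble_sources(rms(ex), n_src, gains.babble_rms, babble_convention)
        babble_src_sum += ex * g
        rendered = spatialize(ex * g, az, hrir_set, head)
        i0 = int(round(timeline.babble_on_s * fs))
        babble[:, i0 : i0 + rendered.shape[1]] += rendered[:, : n_total - i0]
    source_snr_db = 20.0 * np.log10(gains.speech_rms / rms(babble_src_sum))

    w1 = (timeline.word1_on_s, timeline.word1_on_s + word1.duration_s)
    w2 = (timeline.word2_on_s, timeline.word2_on_s + word2.duration_s)
    return RenderedTrial(
        mix=speech + babble,
        speech_only=speech,
        babble_only=babble,
        sample_rate=fs,
        timeline=timeline,
        word_windows_s=(w1, w2),
        word_azimuths_deg=(azimuth1_deg, azimuth2_deg),
        source_snr_db=float(source_snr_db),
    )
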