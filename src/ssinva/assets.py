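"""Synthetic stimulus assets for the SSiN-VA test.

The real test uses closed-set children's word recordings, a sixteen-male-talker
babble recording, and a KEMAR HRTF set.  None of those are redistributable,
so this module synthesises stand-ins that preserve the properties the rest
of the pipeline depends on:

* 16 word tokens in 4 phonetic-contrast groups, each ~1 s long, each with an
  annotated vowel steady-state segment, and mutually distinguishable by
  template correlation (so a simulated listener can identify them);
* a 16-stream amplitude-modulated speech-shaped-noise babble surrogate with
  speech-like long-term level statistics;
* a spherical-head HRIR set on the 7-azimuth grid with Woodworth ITDs and a
  monotone ILD.

Real assets remain loadable: mono WAV tokens plus a CSV segment-annotation
sidecar, and SOFA (SimpleFreeFieldHRIR) HRTF sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

SPEED_OF_SOUND_M_S = 343.0
DEFAULT_SAMPLE_RATE = 44100
DEFAULT_HEAD_CIRCUMFERENCE_M = 0.56
HEAD_CIRCUMFERENCE_RANGE_M = (0.40, 0.70)

#: Closed-set word inventory: 4 groups x 4 words, one phonetic contrast per
#: group (complex vowel, simple vowel, initial consonant, final consonant).
WORD_GROUPS: dict[str, tuple[str, ...]] = {
    "Vc": ("pale", "pool", "pile", "peel"),
    "Vs": ("hoot", "heat", "heart", "hurt"),
    "Ci": ("chalk", "talk", "fork", "stork"),
    "Cf": ("cheat", "cheese", "cheap", "cheek"),
}

GROUP_OF_WORD: dict[str, str] = {
    w: g for g, words in WORD_GROUPS.items() for w in words
}
ALL_WORDS: tuple[str, ...] = tuple(w for ws in WORD_GROUPS.values() for w in ws)

# Per-word synthesis parameters: fundamental and two formant-like resonances.
# Chosen distinct so tokens are separable by matched-filter correlation.
_WORD_F0_HZ = {w: 95.0 + 9.0 * i for i, w in enumerate(ALL_WORDS)}
_WORD_FORMANTS_HZ = {
    w: (350.0 + 55.0 * i, 900.0 + 150.0 * ((i * 5) % 16)) for i, w in enumerate(ALL_WORDS)
}
_WORD_MARKER_HZ = {w: 2500.0 + 170.0 * i for i, w in enumerate(ALL_WORDS)}


@dataclass(frozen=True)
class WordToken:
    """A calibrated mono word stimulus with its vowel steady-state annotation."""

    word_id: str
    group: str
    waveform: np.ndarray
    sample_rate: int
    steady_state: tuple[float, float]
    duration_s: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "duration_s", len(self.waveform) / self.sample_rate)
        lo, hi = self.steady_state
        if not (0.0 <= lo < hi <= self.duration_s + 1e-9):
            raise ValueError(
                f"steady state {self.steady_state} outside token of "
                f"{self.duration_s:.3f} s ({self.word_id})"
            )

    def steady_state_slice(self) -> np.ndarray:
        lo, hi = self.steady_state
        i0, i1 = int(round(lo * self.sample_rate)), int(round(hi * self.sample_rate))
        return self.waveform[i0:i1]

    def steady_state_rms(self) -> float:
        seg = self.steady_state_slice()
        return float(np.sqrt(np.mean(np.square(seg))))

    def scaled(self, gain: float) -> "WordToken":
        return replace(self, waveform=self.waveform * gain)


@dataclass(frozen=True)
class BabbleAsset:
    """Multi-talker babble surrogate (sum of modulated speech-shaped streams)."""

    waveform: np.ndarray
    sample_rate: int
    n_talkers: int = 16

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.waveform))))


@dataclass
class HRIRSet:
    """Head-related impulse responses on an azimuth grid.

    IRs are stored time-aligned (zero ITD); the native interaural delay of
    each measurement is kept separately in ``native_itd_s`` so the renderer
    can replace it with a personalised Woodworth delay.  ``irs`` reconstructs
    conventional delay-carrying IR pairs.
    """

    azimuths_deg: np.ndarray
    aligned_irs: np.ndarray  # (n_az, 2, n_taps); channel 0 = left
    native_itd_s: np.ndarray  # positive => right ear leads
    sample_rate: int
    source: str = "synthetic_sphere"

    def __post_init__(self) -> None:
        self.azimuths_deg = np.asarray(self.azimuths_deg, dtype=float)
        self.aligned_irs = np.asarray(self.aligned_irs, dtype=float)
        self.native_itd_s = np.asarray(self.native_itd_s, dtype=float)
        if self.aligned_irs.shape[0] != len(self.azimuths_deg):
            raise ValueError("one IR pair required per grid azimuth")
        if self.aligned_irs.ndim != 3 or self.aligned_irs.shape[1] != 2:
            raise ValueError("aligned_irs must have shape (n_az, 2, n_taps)")
        if not np.all(np.isfinite(self.aligned_irs)):
            raise ValueError("IRs must have finite energy")

    @property
    def irs(self) -> np.ndarray:
        """Conventional IR pairs with the native ITD re-inserted."""
        out = np.empty_like(self.aligned_irs)
        for i, itd in enumerate(self.native_itd_s):
            out[i] = _apply_itd(self.aligned_irs[i], itd, self.sample_rate)
        return out

    def index_of(self, azimuth_deg: float) -> int:
        hits = np.nonzero(np.isclose(self.azimuths_deg, azimuth_deg))[0]
        if len(hits) == 0:
            raise ValueError(
                f"azimuth {azimuth_deg}° not on grid {self.azimuths_deg.tolist()}"
            )
        return int(hits[0])

    def ild_db(self, azimuth_deg: float) -> float:
        """Broadband right-minus-left level difference of the IR pair."""
        ir = self.aligned_irs[self.index_of(azimuth_deg)]
        e_l, e_r = np.sum(ir[0] ** 2), np.sum(ir[1] ** 2)
        return float(10.0 * np.log10(e_r / e_l))


# ----------------------------------------------------------------------------
# word tokens
# ----------------------------------------------------------------------------

def _raised_cosine_ramps(n: int, n_ramp: int) -> np.ndarray:
    win = np.ones(n)
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        win[:n_ramp] = r
        win[-n_ramp:] = r[::-1]
    return win


def generate_word_token(
    word_id: str,
    group: str | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> WordToken:
    """Synthesise one deterministic word token.

    The token is ~1 s long: a harmonic "vowel" core occupying the annotated
    steady state (0.25-0.75 s), flanked by word-specific narrow-band noise
    markers standing in for the consonantal onset/offset.  Fixed
    ``(word_id, seed)`` gives a bit-identical waveform.
    """
    if word_id not in GROUP_OF_WORD:
        raise ValueError(f"unknown word_id {word_id!r}")
    true_group = GROUP_OF_WORD[word_id]
    if group is not None and group != true_group:
        raise ValueError(f"word {word_id!r} belongs to group {true_group!r}, not {group!r}")

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, ALL_WORDS.index(word_id)])
    dur_s = 1.0
    n = int(round(dur_s * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)

    # harmonic vowel core with two formant-like resonances
    f0 = _WORD_F0_HZ[word_id]
    f1, f2 = _WORD_FORMANTS_HZ[word_id]
    core = np.zeros(n)
    for k in range(1, int(4000.0 // f0) + 1):
        fk = k * f0
        amp = 1.0 / k * (
            1.0
            + 2.0 * np.exp(-0.5 * ((fk - f1) / 120.0) ** 2)
            + 1.5 * np.exp(-0.5 * ((fk - f2) / 180.0) ** 2)
        )
        core += amp * np.sin(2.0 * np.pi * fk * t + rng.uniform(0, 2 * np.pi))
    core_win = np.zeros(n)
    i0, i1 = int(0.20 * sample_rate), int(0.80 * sample_rate)
    core_win[i0:i1] = _raised_cosine_ramps(i1 - i0, int(0.05 * sample_rate))
    wave += core * core_win / np.max(np.abs(core))

    # onset / offset markers: band-passed noise bursts at a word-specific band
    fc = _WORD_MARKER_HZ[word_id]
    sos = signal.butter(4, [fc * 0.85, fc * 1.15], btype="band", fs=sample_rate, output="sos")
    for (a, b), gain in (((0.0, 0.18), 0.45), ((0.82, 1.0), 0.35)):
        j0, j1 = int(a * sample_rate), int(b * sample_rate)
        burst = signal.sosfilt(sos, rng.standard_normal(j1 - j0))
        burst /= np.max(np.abs(burst)) + 1e-12
        wave[j0:j1] += gain * burst * _raised_cosine_ramps(j1 - j0, int(0.005 * sample_rate))

    wave *= 0.5 / np.max(np.abs(wave))
    return WordToken(
        word_id=word_id,
        group=true_group,
        waveform=wave,
        sample_rate=sample_rate,
        steady_state=(0.25, 0.75),
    )


def generate_word_set(sample_rate: int = DEFAULT_SAMPLE_RATE, seed: int = 0) -> dict[str, WordToken]:
    """All 16 tokens of the closed-set inventory, keyed by word id."""
    return {
        w: generate_word_token(w, GROUP_OF_WORD[w], sample_rate, seed) for w in ALL_WORDS
    }


def correlate_identify(
    observed: np.ndarray, templates: dict[str, np.ndarray], candidates: list[str] | None = None
) -> str:
    """Matched-filter word identification.

    Returns the candidate whose template attains the largest normalised
    cross-correlation (max over lag) with the observed signal.  Multi-channel
    observations are summed to mono first.  This is the identification oracle
    used by the audio-driven simulated listener.
    """
    x = np.asarray(observed, dtype=float)
    if x.ndim == 2:
        x = x.sum(axis=0 if x.shape[0] <= 2 else 1)
    best, best_score = None, -np.inf
    for word in candidates if candidates is not None else list(templates):
        tpl = np.asarray(templates[word], dtype=float)
        num = signal.fftconvolve(x, tpl[::-1], mode="valid" if len(x) >= len(tpl) else "full")
        score = float(np.max(np.abs(num))) / (
            float(np.linalg.norm(x)) * float(np.linalg.norm(tpl)) + 1e-30
        )
        if score > best_score:
            best, best_score = word, score
    assert best is not None
    return best


# ----------------------------------------------------------------------------
# babble
# ----------------------------------------------------------------------------

def generate_babble(
    duration_s: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    n_talkers: int = 16,
) -> BabbleAsset:
    """Sixteen-talker babble surrogate.

    Each stream is speech-spectrum-shaped Gaussian noise (flat below ~500 Hz,
    falling above) amplitude-modulated by a slow (~4 Hz) envelope, mimicking
    a single talker's syllabic level fluctuation.  Summing 16 independent
    streams yields the near-stationary long-term statistics of real babble:
    any 1-s window RMS is within about 1.5 dB of the global RMS.
    """
    if duration_s < 3.5:
        raise ValueError("babble must cover the 3.5-s trial timeline")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    n = int(round(duration_s * sample_rate))
    sos_spec = signal.butter(1, 500.0, btype="low", fs=sample_rate, output="sos")
    sos_env = signal.butter(2, 4.0, btype="low", fs=sample_rate, output="sos")
    total = np.zeros(n)
    for _ in range(n_talkers):
        stream = signal.sosfilt(sos_spec, rng.standard_normal(n))
        env = signal.sosfilt(sos_env, np.abs(rng.standard_normal(n)))
        env = 1.0 + 0.8 * (env - env.mean()) / (env.std() + 1e-12)
        total += stream * np.clip(env, 0.1, None)
    total *= 0.05 / np.sqrt(np.mean(total**2))
    return BabbleAsset(waveform=total, sample_rate=sample_rate, n_talkers=n_talkers)


# ----------------------------------------------------------------------------
# spherical-head HRIRs
# ----------------------------------------------------------------------------

def woodworth_itd(
    azimuth_deg: float, head_circumference_m: float = DEFAULT_HEAD_CIRCUMFERENCE_M
) -> float:
    """Spherical-head ITD in seconds: (r/c)(theta + sin theta), r = C/(2*pi).

    Positive azimuth (source on the right) gives a positive ITD, meaning the
    right ear leads.
    """
    lo, hi = HEAD_CIRCUMFERENCE_RANGE_M
    if not (lo <= head_circumference_m <= hi):
        raise ValueError(
            f"head circumference {head_circumference_m} m outside [{lo}, {hi}] m"
        )
    if abs(azimuth_deg) > 90.0 + 1e-9:
        raise ValueError("Woodworth model defined for |azimuth| <= 90°")
    r = head_circumference_m / (2.0 * np.pi)
    theta = np.deg2rad(abs(azimuth_deg))
    itd = (r / SPEED_OF_SOUND_M_S) * (theta + np.sin(theta))
    return float(np.sign(azimuth_deg) * itd)


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Causal first-order (linear-interpolation) fractional delay."""
    if delay_samples < 0:
        raise ValueError("delay must be non-negative")
    k = int(np.floor(delay_samples))
    frac = delay_samples - k
    out = np.zeros(len(x) + k + 1)
    out[k : k + len(x)] += (1.0 - frac) * x
    out[k + 1 : k + 1 + len(x)] += frac * x
    return out[: len(x)]


def _apply_itd(aligned_pair: np.ndarray, itd_s: float, sample_rate: int) -> np.ndarray:
    """Delay the lagging ear of a time-aligned IR pair by |itd|."""
    d = abs(itd_s) * sample_rate
    left, right = aligned_pair
    if itd_s > 0:  # right leads -> delay left
        left = _fractional_delay(left, d)
    elif itd_s < 0:
        right = _fractional_delay(right, d)
    return np.stack([left, right])


DEFAULT_AZIMUTH_GRID_DEG = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)
_ILD_MAX_DB = 10.0  # broadband ILD at |azimuth| = 90°
_SHELF_MAX_DB = 8.0  # additional high-frequency shelf depth at 90°


def _shelf_ir(gain_db: float, sample_rate: int, n_taps: int, f_shelf: float = 2000.0) -> np.ndarray:
    """Impulse response of a first-order high shelf (gain above f_shelf)."""
    a = 10.0 ** (gain_db / 40.0)
    w0 = 2.0 * np.pi * f_shelf / sample_rate
    alpha = np.sin(w0) / np.sqrt(2.0)
    cosw = np.cos(w0)
    b = np.array([
        a * ((a + 1) + (a - 1) * cosw + 2 * np.sqrt(a) * alpha),
        -2 * a * ((a - 1) + (a + 1) * cosw),
        a * ((a + 1) + (a - 1) * cosw - 2 * np.sqrt(a) * alpha),
    ])
    aa = np.array([
        (a + 1) - (a - 1) * cosw + 2 * np.sqrt(a) * alpha,
        2 * ((a - 1) - (a + 1) * cosw),
        (a + 1) - (a - 1) * cosw - 2 * np.sqrt(a) * alpha,
    ])
    x = np.zeros(n_taps)
    x[0] = 1.0
    return signal.lfilter(b / aa[0], aa / aa[0], x)


def spherical_aligned_ir_pair(
    azimuth_deg: float, sample_rate: int, n_taps: int = 128
) -> np.ndarray:
    """Time-aligned (zero-ITD) spherical-head IR pair for one azimuth.

    The ipsilateral ear gets a broadband boost plus a high-shelf boost; the
    contralateral ear the mirror cut.  Both grow with sin|azimuth|, so the
    ILD is strictly monotone in |azimuth| on the grid.
    """
    s = np.sin(np.deg2rad(abs(azimuth_deg)))
    half_ild = 0.5 * _ILD_MAX_DB * s
    half_shelf = 0.5 * _SHELF_MAX_DB * s
    ipsi = 10.0 ** (half_ild / 20.0) * _shelf_ir(half_shelf, sample_rate, n_taps)
    contra = 10.0 ** (-half_ild / 20.0) * _shelf_ir(-half_shelf, sample_rate, n_taps)
    if azimuth_deg >= 0:  # source right: right ear ipsilateral
        return np.stack([contra, ipsi])
    return np.stack([ipsi, contra])


def generate_spherical_hrir_set(
    azimuths_deg=DEFAULT_AZIMUTH_GRID_DEG,
    head_circumference_m: float = DEFAULT_HEAD_CIRCUMFERENCE_M,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    n_taps: int = 128,
) -> HRIRSet:
    """Synthetic spherical-head HRIR set on the 7-azimuth grid.

    Native ITDs follow the Woodworth model at the given head circumference;
    ILDs follow a monotone shelving model.  At 0° the two ears are identical.
    """
    az = np.asarray(azimuths_deg, dtype=float)
    if np.any(np.abs(az) > 90.0):
        raise ValueError("grid azimuths must lie in [-90°, 90°]")
    aligned = np.stack([spherical_aligned_ir_pair(a, sample_rate, n_taps) for a in az])
    itds = np.array([woodworth_itd(a, head_circumference_m) for a in az])
    return HRIRSet(
        azimuths_deg=az,
        aligned_irs=aligned,
        native_itd_s=itds,
        sample_rate=sample_rate,
        source="synthetic_sphere",
    )


# ----------------------------------------------------------------------------
# file I/O: WAV, SOFA, segment annotations
# ----------------------------------------------------------------------------

def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write mono or stereo float32 WAV (channels-last on disk)."""
    w = np.asarray(waveform, dtype=np.float32)
    if w.ndim == 2 and w.shape[0] in (1, 2):
        w = w.T
    wavfile.write(str(path), sample_rate, w)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1], channels-first for stereo."""
    sr, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        data = (data.astype(float) - 128.0) / 128.0
    data = data.astype(float)
    if data.ndim == 2:
        data = data.T
    return data, int(sr)


def load_segment_annotations(path: str | Path) -> dict[str, tuple[str, float, float]]:
    """Read a sidecar CSV of vowel steady-state segments.

    Columns: word_id, group, ss_start_s, ss_end_s.
    """
    out: dict[str, tuple[str, float, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["word_id"]] = (
                row["group"],
                float(row["ss_start_s"]),
                float(row["ss_end_s"]),
            )
    return out


def load_word_tokens(
    wav_dir: str | Path, annotations_csv: str | Path
) -> dict[str, WordToken]:
    """Load real word recordings (<word_id>.wav) with their annotations."""
    ann = load_segment_annotations(annotations_csv)
    tokens = {}
    for word_id, (group, lo, hi) in ann.items():
        wave, sr = read_wav(Path(wav_dir) / f"{word_id}.wav")
        if wave.ndim != 1:
            raise ValueError(f"word recordings must be mono: {word_id}")
        tokens[word_id] = WordToken(
            word_id=word_id, group=group, waveform=wave, sample_rate=sr,
            steady_state=(lo, hi),
        )
    return tokens


def _estimate_itd_s(pair: np.ndarray, sample_rate: int) -> float:
    """ITD of an IR pair from the cross-correlation peak (right lead positive)."""
    left, right = pair
    xc = signal.correlate(right, left, mode="full")
    lag = int(np.argmax(np.abs(xc))) - (len(left) - 1)
    # right[n] ~ left[n - lag]; a leading right ear gives negative lag
    return float(-lag) / sample_rate


def load_sofa_hrir_set(
    path: str | Path, azimuths_deg=DEFAULT_AZIMUTH_GRID_DEG, az_tol_deg: float = 2.0
) -> HRIRSet:
    """Load horizontal-plane HRIRs from a SOFA (SimpleFreeFieldHRIR) file.

    SOFA stores azimuth counterclockwise in [0, 360) (90° = listener's left);
    the package convention is clockwise-positive-right in [-90, 90], so the
    sign is flipped on load.  For each requested grid azimuth the nearest
    elevation-0 measurement within ``az_tol_deg`` is taken; its native ITD is
    estimated by cross-correlation and removed so the renderer can substitute
    personalised delays.
    """
    import h5py

    with h5py.File(str(path), "r") as f:
        irs = np.asarray(f["Data.IR"])  # (M, 2, N)
        pos = np.asarray(f["SourcePosition"])  # (M, 3): az, el, dist
        sr = int(np.ravel(f["Data.SamplingRate"])[0])
    sofa_az = pos[:, 0] % 360.0
    our_az = -np.where(sofa_az > 180.0, sofa_az - 360.0, sofa_az)
    elev = pos[:, 1]
    az = np.asarray(azimuths_deg, dtype=float)
    aligned, itds = [], []
    for a in az:
        horiz = np.abs(elev) < 5.0
        err = np.abs(our_az - a)
        err[~horiz] = np.inf
        i = int(np.argmin(err))
        if err[i] > az_tol_deg:
            raise ValueError(f"no horizontal-plane measurement within {az_tol_deg}° of {a}°")
        pair = irs[i].astype(float)
        itd = _estimate_itd_s(pair, sr)
        # remove the integer part of the native delay to time-align
        lag = int(round(abs(itd) * sr))
        left, right = pair
        if itd > 0 and lag:
            left = np.concatenate([left[lag:], np.zeros(lag)])
        elif itd < 0 and lag:
            right = np.concatenate([right[lag:], np.zeros(lag)])
        aligned.append(np.stack([left, right]))
        itds.append(itd)
    return HRIRSet(
        azimuths_deg=az,
        aligned_irs=np.stack(aligned),
        native_itd_s=np.array(itds),
        sample_rate=sr,
        source="sofa_file",
    )
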