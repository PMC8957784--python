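"""Configuration and the reproducible end-to-end demo pipeline.

A run is fully described by a ``RunConfig`` (serialisable to YAML) plus its
master seed: assets, calibration, SRT estimation, cohort simulation and the
statistical models are all derived deterministically from it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assets, calibration, glmm, listener, renderer

logger = logging.getLogger("ssinva.pipeline")


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated study end to end."""

    master_seed: int = 1
    sample_rate: int = 44100
    n_participants: int = 12
    runs_per_block: int = 2
    legacy_extra_trial: bool = False
    spl_ref_db: float = 100.0
    word_level_db_spl: float = 52.0
    babble_level_db_spl: float = 52.0
    head_circumference_m: float = 0.56
    srt_threshold_db: float = -8.0
    n_srt_staircases: int = 1
    output_dir: str = "ssinva_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def level_map(self) -> calibration.LevelMap:
        return calibration.LevelMap(
            spl_ref_db=self.spl_ref_db,
            word_level_db_spl=self.word_level_db_spl,
            babble_level_db_spl=self.babble_level_db_spl,
        )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage=%s status=start", name)
                out = fn(*args, **kwargs)
                logger.info("stage=%s status=done", name)
                return out
            except Exception as exc:  # noqa: BLE001 - re-tagged and re-raised
                raise RuntimeError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


LOC_BASE = glmm.ModelSpec(outcome="localization", fixed_terms=())
WORD_BASE = glmm.ModelSpec(outcome="word", fixed_terms=(), random_slope_snr=True)
LOC_TERMS = ["mean_location", "snr", "direction"]
WORD_TERMS = ["azimuth", "snr", "group"]


@_stage("demo")
def end_to_end_demo(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline on simulated listeners and write its report.

    Stages: synthesise assets -> calibrate word levels -> estimate a
    simulated listener's SRT by staircase -> simulate a cohort through the
    trial engine -> fit both mixed logistic models -> write observation
    tables, odds-ratio tables and accuracy-by-location figures (the
    inverted-U localization curve and U-shaped word curve).
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.master_seed)
    report: dict = {"config": dataclasses.asdict(config)}

    tokens, hrirs, babble = _gen_assets(config, int(rng.integers(2**31 - 1)))
    level_map = config.level_map()
    eq_tokens, gains = _calibrate(tokens, level_map)
    report["calibration"] = {
        "steady_state_rms_spread": float(
            np.ptp([t.steady_state_rms() for t in eq_tokens.values()])
        ),
        "calib_noise_db_spl": level_map.calib_noise_level_db_spl,
    }

    srt = _estimate_srt(config, int(rng.integers(2**31 - 1)))
    report["srt_db"] = srt

    logs, obs = _simulate(config, srt, int(rng.integers(2**31 - 1)))
    obs.to_csv(out / "observations.csv", index=False)
    for log in logs:
        log.to_csv(out / f"session_{log.participant_id}.csv")

    report.update(_analyse(obs, out))
    _render_example(config, eq_tokens, hrirs, babble, level_map, srt, out)
    _figures(obs, out)
    (out / "report.yaml").write_text(yaml.safe_dump(_yamlable(report), sort_keys=False))
    return report


@_stage("gen-assets")
def _gen_assets(config: RunConfig, seed: int):
    tokens = assets.generate_word_set(config.sample_rate, seed)
    hrirs = assets.generate_spherical_hrir_set(
        head_circumference_m=config.head_circumference_m,
        sample_rate=config.sample_rate,
    )
    babble = assets.generate_babble(8.0, config.sample_rate, seed)
    return tokens, hrirs, babble


@_stage("calibrate")
def _calibrate(tokens, level_map):
    return calibration.equalize_word_levels(
        tokens, target_rms=level_map.rms_for_spl(level_map.word_level_db_spl)
    )


@_stage("run-srt")
def _estimate_srt(config: RunConfig, seed: int) -> float:
    profile = listener.ListenerProfile(
        srt_threshold_db=config.srt_threshold_db, seed=seed
    )
    return float(listener.simulate_srt(profile))


@_stage("simulate-cohort")
def _simulate(config: RunConfig, srt_db: float, seed: int):
    return listener.simulate_cohort(
        n_participants=config.n_participants,
        seed=seed,
        runs_per_block=config.runs_per_block,
        legacy_extra_trial=config.legacy_extra_trial,
        srt_db=srt_db,
    )


@_stage("fit")
def _analyse(obs: pd.DataFrame, out: Path) -> dict:
    loc_obs = obs[obs["task"] == "localization"]
    word_obs = obs[obs["task"] == "word"]
    loc_ladder = glmm.model_ladder(loc_obs, LOC_BASE, list(LOC_TERMS))
    loc_fit = loc_ladder.attrs["final_fit"]
    word_ladder = glmm.model_ladder(word_obs, WORD_BASE, list(WORD_TERMS))
    word_fit = word_ladder.attrs["final_fit"]
    for name, fit, ladder in (
        ("localization", loc_fit, loc_ladder),
        ("word", word_fit, word_ladder),
    ):
        glmm.odds_ratios(fit).to_csv(out / f"{name}_odds_ratios.csv", index=False)
        ladder.to_csv(out / f"{name}_lrt_ladder.csv", index=False)
    glmm.posthoc_pairwise(loc_fit, "mean_location").to_csv(
        out / "localization_posthoc_mean_location.csv", index=False
    )
    glmm.posthoc_pairwise(word_fit, "azimuth").to_csv(
        out / "word_posthoc_azimuth.csv", index=False
    )
    r2m_loc, r2c_loc = glmm.r2_nakagawa(loc_fit)
    r2m_w, r2c_w = glmm.r2_nakagawa(word_fit)
    return {
        "localization": {
            "n_obs": int(loc_fit.n_obs), "tau00": loc_fit.tau00,
            "icc": loc_fit.icc, "r2_marginal": r2m_loc, "r2_conditional": r2c_loc,
            "lrt_mean_location_chi2": float(loc_ladder.iloc[0]["chi2"]),
            "lrt_mean_location_p": float(loc_ladder.iloc[0]["p"]),
        },
        "word": {
            "n_obs": int(word_fit.n_obs), "tau00": word_fit.tau00,
            "icc": word_fit.icc, "r2_marginal": r2m_w, "r2_conditional": r2c_w,
            "lrt_azimuth_chi2": float(word_ladder.iloc[0]["chi2"]),
            "lrt_azimuth_p": float(word_ladder.iloc[0]["p"]),
        },
    }


@_stage("render-example")
def _render_example(config, eq_tokens, hrirs, babble, level_map, srt_db, out: Path):
    toks = list(eq_tokens.values())
    rt = renderer.render_trial(
        toks[0], toks[1], -90.0, -60.0, babble.waveform, hrirs, level_map,
        snr_db=srt_db, seed=config.master_seed,
        head_state=renderer.HeadState(circumference_m=config.head_circumference_m),
    )
    assets.write_wav(out / "example_trial_mix.wav", rt.mix, config.sample_rate)
    assets.write_wav(out / "example_trial_speech.wav", rt.speech_only, config.sample_rate)
    assets.write_wav(out / "example_trial_babble.wav", rt.babble_only, config.sample_rate)


@_stage("figures")
def _figures(obs: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    loc = obs[obs["task"] == "localization"]
    for snr, sub in loc.groupby("snr_condition"):
        acc = sub.groupby("mean_location_deg")["outcome"].mean()
        axes[0].plot(acc.index, acc.values, "o-", label=snr)
    axes[0].set_xlabel("mean location (°)")
    axes[0].set_ylabel("proportion correct")
    axes[0].set_title("relative localization")
    word = obs[obs["task"] == "word"]
    for snr, sub in word.groupby("snr_condition"):
        acc = sub.groupby("azimuth_deg")["outcome"].mean()
        axes[1].plot(acc.index, acc.values, "o-", label=snr)
    axes[1].set_xlabel("azimuth (°)")
    axes[1].set_title("word discrimination")
    axes[1].legend(title="SNR", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "accuracy_by_location.png", dpi=120)
    plt.close(fig)


def _yamlable(x):
    if isinstance(x, dict):
        return {k: _yamlable(v) for k, v in x.items()}
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x
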