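"""Configuration and orchestration glue for the whole pipeline.

``run_pipeline`` executes simulate -> preprocess -> features -> choice
models -> onsets -> cpp -> decode at the configured (synthetic) scale and
writes every artifact as TSV/JSON/HDF5 with the config hash and seed
attached, so a fixed config reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import choice_models as cm
from . import cpp as cpp_mod
from . import decode as decode_mod
from . import features as feat
from . import onsets as onsets_mod
from . import preprocess as pp
from . import synth
from .containers import config_hash, write_trial_table


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Single configuration for an end-to-end synthetic run.

    Defaults are a desk-scale session: the study-scale structure (10 blocks
    of 120 trials per deadline and 160-trial easy blocks per participant)
    is available by raising ``trials_per_deadline``/``easy_trials``.
    """

    seed: int = 0
    out_dir: str = "results/run"
    n_participants: int = 3
    n_channels: int = 64
    trials_per_deadline: int = 240
    easy_trials: int = 80
    dc: float = 0.006
    bias: float = 0.0
    easy_dc: float = 0.30
    fs: float = 512.0
    span_ms: tuple[float, float] = (-600.0, 800.0)
    titrate: bool = False
    n_boot: int = 100
    n_shuffles: int = 20
    decode_window_ms: tuple[float, float] = (0.0, 400.0)
    k_per_pole: int = 4
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Global seed + stage-name hash, so stages are independently
        reproducible."""
        return (self.seed + zlib.crc32(stage.encode()) % 100_000) % (2**31)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key in ("span_ms", "decode_window_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def hash(self) -> str:
        # where the artifacts land does not affect what they contain
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        return config_hash(payload)


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df.attrs["config_hash"] = cfg.hash
    return df


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={cfg.hash} seed={cfg.seed}\n")
        df.to_csv(f, sep="\t", index=False)


def simulate_stage(cfg: RunConfig) -> dict:
    """Per participant: titrate (optionally), simulate hard blocks under
    both deadlines plus an easy block, and synthesise EEG for all of it."""
    rng = np.random.default_rng(cfg.stage_seed("simulate"))
    fm = synth.make_forward_model(cfg.n_channels)
    participants = []
    for p in range(cfg.n_participants):
        pseed = int(rng.integers(0, 2**31 - 1))
        params = synth.ObserverParams(seed=pseed)
        dc, bias = cfg.dc, cfg.bias
        if cfg.titrate:
            tit = synth.titrate_difficulty(params)
            dc, bias = tit.dc, tit.bias
        frames = []
        block0 = 0
        for deadline in (400.0, 600.0):
            n_blocks = max(1, cfg.trials_per_deadline // 120)
            stim = synth.make_session_stimuli(
                synth.StimulusConfig(dc=dc, bias=bias), n_blocks,
                cfg.trials_per_deadline // n_blocks,
                rng=np.random.default_rng(pseed + int(deadline)))
            tt = synth.simulate_behaviour(
                params, stim, deadline,
                rng=np.random.default_rng(pseed + int(deadline) + 1))
            tt["block"] += block0
            block0 = int(tt["block"].max()) + 1
            tt["condition"] = "hard"
            frames.append(tt)
        easy_stim = synth.make_session_stimuli(
            synth.StimulusConfig(dc=cfg.easy_dc), 1, cfg.easy_trials,
            rng=np.random.default_rng(pseed + 7))
        easy = synth.simulate_behaviour(
            params, easy_stim, 600.0, rng=np.random.default_rng(pseed + 8))
        easy["block"] = block0
        easy["condition"] = "easy"
        frames.append(easy)
        trials = pd.concat(frames, ignore_index=True)
        trials["participant"] = p
        trials["session"] = 0
        epochs = synth.simulate_eeg(
            fm, trials, params, fs=cfg.fs, span_ms=cfg.span_ms,
            rng=np.random.default_rng(pseed + 9))
        participants.append({"trials": trials, "epochs": epochs,
                             "params": params, "dc": dc, "bias": bias})
    return {"participants": participants, "forward_model": fm}


def preprocess_stage(cfg: RunConfig, sim: dict) -> dict:
    """Average-rereference, baseline-correct and artifact-screen each
    participant's epochs."""
    for part in sim["participants"]:
        ep = part["epochs"]
        flat = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
        ep = ep.copy()
        ep.data = pp.rereference_average(flat).reshape(
            ep.n_channels, ep.n_trials, -1).transpose(1, 0, 2)
        ep = pp.baseline_correct(ep)
        veog = part["epochs"].meta.get("veog")
        report = pp.screen_artifacts(ep, veog=veog)
        part["epochs"] = ep
        part["report"] = report
        part["trials"]["excluded"] = (part["trials"]["excluded"].to_numpy()
                                      | report.full_reject)
    return sim


def features_stage(cfg: RunConfig, sim: dict) -> dict:
    """Per-participant C1 montage from the easy block, single-trial C1 in
    hard blocks, and lateralised pre-target alpha as a covariate."""
    fm = sim["forward_model"]
    montage = fm.montage
    alpha_signal = feat.ChoiceSignal(
        name="alpha_lat", contrast="left_minus_right",
        electrodes=montage.occipital_pool("left")
        + montage.occipital_pool("right"),
        t_start_ms=-400.0, t_end_ms=0.0, f_lo_hz=8.0, f_hi_hz=14.0)
    for part in sim["participants"]:
        trials, epochs = part["trials"], part["epochs"]
        easy = trials["condition"] == "easy"
        easy_ep = _subset_epochs(epochs, easy.to_numpy())
        c1m = feat.select_c1_electrodes(
            easy_ep, trials.loc[easy], k_per_pole=cfg.k_per_pole,
            montage=montage, participant=part["params"].seed)
        c1_meas = feat.measure_c1(epochs, c1m)
        part["c1_montage"] = c1m
        part["trials"]["c1_measured"] = c1_meas
        tf = feat.stft(_subset_epochs(epochs, slice(None),
                                      t_max_ms=0.0))
        cov = feat.extract_covariates(trials, [alpha_signal], tf=tf,
                                      channel_labels=epochs.channel_labels,
                                      montage=montage)
        part["covariates"] = cov
    sim["alpha_signal"] = alpha_signal
    return sim


def _subset_epochs(e, row_sel, t_max_ms: float | None = None):
    from .containers import EpochSet

    sel_t = slice(None) if t_max_ms is None else e.time_ms <= t_max_ms
    data = e.data[row_sel][:, :, sel_t]
    return EpochSet(data, e.time_ms[sel_t], e.fs, list(e.channel_labels))


def choice_model_stage(cfg: RunConfig, sim: dict) -> dict:
    """Pooled choice model with quadratic RT interactions, its vertex, and
    the sliding-window series feeding the onset bootstrap."""
    hard = _pooled_hard_trials(sim)
    cov = pd.concat([p["covariates"].loc[
        (p["trials"]["condition"] == "hard").to_numpy()]
        for p in sim["participants"]], ignore_index=True)
    predictors = ["c1_measured", "target", "prev_choice", "alpha_lat"]
    spec = cm.DesignSpec(predictors=predictors, rt_interactions="quadratic")
    design, y, groups = cm.build_design(hard, cov, spec)
    fit = cm.fit_logistic(design, y,
                          random_intercepts=cfg.n_participants >= 2,
                          groups=groups)
    vertex_ms = None
    try:
        coefs = [fit["c1_measured"]["beta"], fit["c1_measured:rt"]["beta"],
                 fit["c1_measured:rt2"]["beta"]]
        vertex_ms, _ = cm.quadratic_vertex(*coefs)
    except (ValueError, KeyError):
        pass
    series = cm.sliding_rt_models(hard, cov, predictors)
    return {"fit": fit, "vertex_ms": vertex_ms, "window_series": series,
            "trials": hard, "covariates": cov, "predictors": predictors}


def _pooled_hard_trials(sim: dict) -> pd.DataFrame:
    return pd.concat([p["trials"][p["trials"]["condition"] == "hard"]
                      for p in sim["participants"]], ignore_index=True)


def onsets_stage(cfg: RunConfig, choice: dict) -> dict:
    trials = choice["trials"].reset_index(drop=True)
    cov = choice["covariates"].reset_index(drop=True)
    predictors = choice["predictors"]

    def c1_window_model(sample: pd.DataFrame) -> cm.WindowSeries:
        rows = sample["row_id"].to_numpy()
        return cm.sliding_rt_models(sample, cov.iloc[rows].reset_index(
            drop=True), predictors)

    trials = trials.assign(row_id=np.arange(len(trials)))
    est_c1 = onsets_mod.bootstrap_onsets(
        trials, c1_window_model, term="c1_measured", n_boot=cfg.n_boot,
        seed=cfg.stage_seed("onsets"))
    est_acc = onsets_mod.bootstrap_onsets(
        trials, lambda s: cm.accuracy_window_models(s), term="intercept",
        n_boot=cfg.n_boot, seed=cfg.stage_seed("onsets"))
    return {"c1": est_c1, "accuracy": est_acc}


def cpp_stage(cfg: RunConfig, sim: dict) -> dict:
    from .containers import EpochSet

    all_trials, resp_data = [], []
    time_ms = fs = labels = None
    for part in sim["participants"]:
        resp, keep = cpp_mod.response_lock(part["epochs"], part["trials"])
        tr = part["trials"].loc[keep].reset_index(drop=True)
        all_trials.append(tr)
        resp_data.append(resp.data)
        time_ms, fs, labels = resp.time_ms, resp.fs, resp.channel_labels
    trials = pd.concat(all_trials, ignore_index=True)
    resp_epochs = EpochSet(np.concatenate(resp_data), time_ms, fs, labels)
    pool = sim["forward_model"].montage.centroparietal_pool()
    channel = cpp_mod.select_cpp_electrode(resp_epochs, pool)
    estimates = []
    for split in ("all", "fast", "slow"):
        estimates.append(cpp_mod.estimate_onset(
            resp_epochs, trials, channel, rt_split=split,
            n_boot=max(cfg.n_boot // 2, 10),
            seed=cfg.stage_seed(f"cpp-{split}")))
    pooled = cpp_mod.pooled_onset(estimates)
    return {"channel": channel, "estimates": estimates, "pooled": pooled}


def decode_stage(cfg: RunConfig, sim: dict) -> decode_mod.DecodingTimecourse:
    from .containers import EpochSet

    parts = sim["participants"]
    hard_sel = [(p["trials"]["condition"] == "hard").to_numpy()
                for p in parts]
    t_sel = None
    data, trials = [], []
    for p, m in zip(parts, hard_sel):
        e = p["epochs"]
        t_sel = (e.time_ms >= cfg.decode_window_ms[0]) & \
            (e.time_ms < cfg.decode_window_ms[1])
        data.append(e.data[m][:, :, t_sel])
        trials.append(p["trials"].loc[m])
    e0 = parts[0]["epochs"]
    epochs = EpochSet(np.concatenate(data), e0.time_ms[t_sel], e0.fs,
                      list(e0.channel_labels))
    return decode_mod.lda_timecourse(
        epochs, pd.concat(trials, ignore_index=True),
        n_shuffles=cfg.n_shuffles, seed=cfg.stage_seed("decode"))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, writing artifacts under ``cfg.out_dir``.

    A stage failure raises :class:`StageError` tagged with the stage name;
    artifacts from completed stages are preserved."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    bundle: dict = {"config_hash": cfg.hash}
    stages = []

    def run(name, fn, *args):
        try:
            result = fn(cfg, *args)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(name, exc) from exc
        stages.append(name)
        return result

    sim = run("simulate", simulate_stage)
    trials_all = pd.concat([p["trials"] for p in sim["participants"]],
                           ignore_index=True)
    write_trial_table(trials_all[
        [c for c in trials_all.columns
         if c in ("participant", "session", "block", "deadline_ms", "target",
                  "choice", "rt_ms", "correct", "prev_choice", "excluded",
                  "condition")]], out / "trials.csv")
    sim = run("preprocess", preprocess_stage, sim)
    reports = pd.concat([p["report"].to_frame().assign(participant=i)
                         for i, p in enumerate(sim["participants"])],
                        ignore_index=True)
    _write_tsv(reports, out / "artifacts.tsv", cfg)
    sim = run("features", features_stage, sim)
    choice = run("choice_model", choice_model_stage, sim)
    _write_tsv(choice["fit"].to_frame(), out / "choice_model.tsv", cfg)
    _write_tsv(choice["window_series"].to_frame(
        flip_terms=("c1_measured",)), out / "window_series.tsv", cfg)
    bundle["vertex_ms"] = choice["vertex_ms"]
    if cfg.n_boot > 0:
        est = run("onsets", onsets_stage, choice)
        with open(out / "onsets.json", "w") as f:
            json.dump({"config_hash": cfg.hash,
                       "c1": est["c1"].to_dict(),
                       "accuracy": est["accuracy"].to_dict()}, f, indent=2)
        bundle["onsets"] = est
    else:
        stages.append("onsets:skipped")
    cpp_res = run("cpp", cpp_stage, sim)
    with open(out / "cpp_onsets.json", "w") as f:
        json.dump({"config_hash": cfg.hash,
                   "channel": cpp_res["channel"],
                   "pooled": {k: (v if not isinstance(v, list) else v)
                              for k, v in cpp_res["pooled"].items()}},
                  f, indent=2, default=float)
    dec = run("decode", decode_stage, sim)
    _write_tsv(dec.to_frame(), out / "decoding.tsv", cfg)
    bundle.update({"sim": sim, "choice": choice, "cpp": cpp_res,
                   "decoding": dec, "stages": stages})
    return bundle
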