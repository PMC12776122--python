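"""End-to-end orchestration: simulate/load -> behavior filter -> artifact
rejection -> ERP subtraction -> wavelet slope estimation -> smoothing and
censoring -> condition averages -> spatial/temporal PCA -> windowed scores
-> baseline and congruency statistics.

Participants are processed one at a time so memory stays flat in the trial
count; every stage is a pure function of its inputs and the configuration,
and the run manifest records every parameter, the seed, per-participant
retained-epoch counts, and library versions, making reruns reproducible.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavioral_anova, filter_trials
from .preprocess import Epochs, reject_artifacts, select_analysis_trials, subtract_condition_erp
from .reduction import (
    ComponentModel,
    TemporalComponent,
    WindowSet,
    project_scores,
    run_spatial_pca,
    run_temporal_pca,
    segment_windows,
    window_scores,
)
from .slope import (
    FrequencyGrid,
    SlopeMaps,
    condition_average,
    fit_slope_timecourse,
    smooth_and_censor,
    wavelet_power,
)
from .stats import baseline_contrast_table, congruency_table
from .synth import CELLS, SimConfig, generate_behavior_table, iter_participant_epochs


@dataclass
class RunConfig:
    """Stage parameters; the analysis defaults are:
    150 uV / 600 ms / 100 ms artifact rule, 2.5-25 Hz grid with the
    7.5-15 Hz range excluded from the fit, 5-point slope smoothing, +-4
    censor bound, -300..1300 ms crop, 160-ms windows, alpha = 0.05."""

    sim: SimConfig = field(default_factory=SimConfig)
    epochs_path: str | None = None  # load instead of simulate when set
    trials_path: str | None = None
    artifact_threshold_uv: float = 150.0
    artifact_window_ms: float = 600.0
    artifact_step_ms: float = 100.0
    freqs: tuple[float, ...] = (2.5, 5.0, 7.5, 15.0, 25.0)
    fit_exclude_hz: tuple[float, float] = (7.5, 15.0)
    smoothing_points: int = 5
    censor_bound: float = 4.0
    crop_ms: tuple[float, float] = (-300.0, 1300.0)
    window_width_ms: float = 160.0
    temporal_decimation: int = 10
    alpha: float = 0.05
    seed: int | None = None  # overrides sim.rng_seed when set

    def frequency_grid(self) -> FrequencyGrid:
        lo, hi = self.fit_exclude_hz
        mask = tuple(not (lo <= f <= hi) for f in self.freqs)
        return FrequencyGrid(freqs=self.freqs, fit_mask=mask)


@dataclass
class PipelineResult:
    slope_maps: SlopeMaps
    spatial_model: ComponentModel
    temporal_model: ComponentModel
    temporal_components: list[TemporalComponent]
    windows: WindowSet
    window_scores: pd.DataFrame
    baseline_table: pd.DataFrame
    congruency_anova: pd.DataFrame
    congruency_followups: pd.DataFrame
    behavior_rt_anova: pd.DataFrame
    behavior_rt_followups: pd.DataFrame
    behavior_acc_anova: pd.DataFrame
    behavior_acc_followups: pd.DataFrame
    manifest: dict

    def save(self, outdir) -> None:
        from .io import write_component_model, write_stat_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.window_scores.to_csv(
            outdir / "window_scores.tsv", sep="\t", index=False
        )
        write_component_model(outdir / "spatial_components", self.spatial_model)
        write_component_model(outdir / "temporal_components", self.temporal_model)
        for name, tab in [
            ("baseline_contrasts", self.baseline_table),
            ("congruency_anova", self.congruency_anova),
            ("congruency_followups", self.congruency_followups),
            ("behavior_rt_anova", self.behavior_rt_anova),
            ("behavior_rt_followups", self.behavior_rt_followups),
            ("behavior_accuracy_anova", self.behavior_acc_anova),
            ("behavior_accuracy_followups", self.behavior_acc_followups),
        ]:
            write_stat_table(outdir / name, tab)
        with open(outdir / "manifest.json", "w") as f:
            json.dump(self.manifest, f, indent=1, default=str)


def _participant_slope_maps(
    data: np.ndarray,
    trials: pd.DataFrame,
    config: RunConfig,
    sim: SimConfig,
    grid: FrequencyGrid,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run preprocessing + slope estimation for one participant's epochs.

    Returns (cell x channel x sample means, per-cell counts, log record).
    """
    epochs = Epochs(
        data=data,
        fs=sim.fs,
        times=sim.times_ms,
        channel_labels=list(sim.channel_layout.labels),
        trial_link=trials.index.values,
    )
    eeg_keep = filter_trials(trials, purpose="eeg").trials.index
    rejected = reject_artifacts(
        epochs,
        threshold_uv=config.artifact_threshold_uv,
        window_ms=config.artifact_window_ms,
        step_ms=config.artifact_step_ms,
    )
    selected = select_analysis_trials(epochs, eeg_keep, rejected)
    meta = trials.loc[selected.trial_link]
    labels = list(
        zip(meta["participant"], meta["prev_congruency"], meta["curr_congruency"])
    )
    clean = subtract_condition_erp(selected, labels)
    power = wavelet_power(clean, grid, only_fit_freqs=True)
    ss = fit_slope_timecourse(
        power, grid, times=clean.times, fs=clean.fs, trial_link=clean.trial_link
    )
    ss, n_censored = smooth_and_censor(
        ss, k=config.smoothing_points, bound=config.censor_bound
    )
    maps = condition_average(ss, trials)
    log = {
        "n_epochs": int(epochs.n_trials),
        "n_artifact_rejected": int(rejected.sum()),
        "n_behavior_excluded": int(epochs.n_trials - len(eeg_keep)),
        "n_analyzed": int(selected.n_trials),
        "n_slope_censored": int(n_censored),
        "n_retained": int(ss.valid_mask.sum()),
    }
    return maps.values[0], maps.counts[0], log


def _effective_sim(config: RunConfig) -> SimConfig:
    if config.seed is None:
        return config.sim
    from dataclasses import replace

    return replace(config.sim, rng_seed=config.seed)


def compute_slope_maps(config: RunConfig | None = None):
    """Simulate and run the per-participant half of the pipeline (behavior
    filter, artifact rejection, ERP subtraction, wavelet slope estimation,
    smoothing/censoring, condition averaging).

    Returns (SlopeMaps, trial table, per-participant retention logs).
    """
    config = config or RunConfig()
    sim = _effective_sim(config)
    grid = config.frequency_grid()
    trials = generate_behavior_table(sim)
    per_part_values, per_part_counts, logs = [], [], {}
    participants = []
    for pid, data, tr, _ in iter_participant_epochs(sim, trials):
        vals, counts, log = _participant_slope_maps(data, tr, config, sim, grid)
        per_part_values.append(vals)
        per_part_counts.append(counts)
        logs[pid] = log
        participants.append(pid)
    maps = SlopeMaps(
        values=np.stack(per_part_values),
        participants=np.asarray(participants),
        cells=list(CELLS),
        times=sim.times_ms,
        counts=np.stack(per_part_counts),
        channel_labels=list(sim.channel_layout.labels),
    )
    return maps, trials, logs


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Execute every stage on simulated (default) or loaded epochs."""
    config = config or RunConfig()
    grid = config.frequency_grid()
    if config.epochs_path:
        return _run_on_loaded_epochs(config, grid)
    sim = _effective_sim(config)
    maps, trials, logs = compute_slope_maps(config)
    return _reduce_and_test(config, sim, grid, maps, trials, logs)


def _run_on_loaded_epochs(config: RunConfig, grid: FrequencyGrid) -> PipelineResult:
    from .io import read_epochs_h5, read_trial_table

    if not config.trials_path:
        raise ValueError("loading epochs requires a trial table path")
    epochs = read_epochs_h5(config.epochs_path)
    trials = read_trial_table(config.trials_path)
    sim = config.sim
    per_part_values, per_part_counts, logs = [], [], {}
    participants = sorted(trials["participant"].unique())
    for pid in participants:
        tr = trials[(trials["participant"] == pid) & (~trials["is_practice"])]
        mask = np.isin(epochs.trial_link, tr.index.values)
        sub = epochs.select(np.flatnonzero(mask))
        vals, counts, log = _participant_slope_maps(
            sub.data, trials.loc[sub.trial_link], config, _sim_like(epochs, sim), grid
        )
        per_part_values.append(vals)
        per_part_counts.append(counts)
        logs[pid] = log
    maps = SlopeMaps(
        values=np.stack(per_part_values),
        participants=np.asarray(participants),
        cells=list(CELLS),
        times=epochs.times,
        counts=np.stack(per_part_counts),
        channel_labels=list(epochs.channel_labels),
    )
    return _reduce_and_test(config, sim, grid, maps, trials, logs)


def _sim_like(epochs: Epochs, sim: SimConfig) -> SimConfig:
    """A SimConfig whose geometry matches loaded epochs (for stage plumbing)."""
    from dataclasses import replace

    return replace(
        sim,
        fs=epochs.fs,
        epoch_span_ms=(float(epochs.times[0]),
                       float(epochs.times[-1] + 1000.0 / epochs.fs)),
    )


def _reduce_and_test(
    config: RunConfig,
    sim: SimConfig,
    grid: FrequencyGrid,
    maps: SlopeMaps,
    trials: pd.DataFrame,
    logs: dict,
) -> PipelineResult:
    layout = sim.channel_layout
    spatial = run_spatial_pca(maps, crop_ms=config.crop_ms, layout=layout)
    temporal, temporal_comps = run_temporal_pca(
        maps, crop_ms=config.crop_ms, decimate=config.temporal_decimation
    )

    # project condition slope maps onto retained spatial components
    from .reduction import _crop_indices

    idx = _crop_indices(maps.times, config.crop_ms)
    t = maps.times[idx]
    vals = maps.values[..., idx]  # (P, cells, ch, T)
    P, C, ch, T = vals.shape
    X = vals.transpose(0, 1, 3, 2).reshape(-1, ch)
    scores = project_scores(np.nan_to_num(X, nan=0.0), spatial)
    n_comp = scores.shape[1]
    scores = scores.reshape(P, C, T, n_comp).transpose(0, 1, 3, 2)

    windows = segment_windows(crop_ms=config.crop_ms, width_ms=config.window_width_ms)
    wmeans = window_scores(scores, t, windows)  # (P, C, comp, W)

    names = _component_names(spatial)
    rows = []
    for i, p in enumerate(maps.participants):
        for j, (prev, curr) in enumerate(maps.cells):
            for c in range(n_comp):
                for wi, lab in enumerate(windows.labels):
                    rows.append(
                        {
                            "participant": int(p),
                            "component": names[c],
                            "prev": prev,
                            "curr": curr,
                            "window": lab,
                            "score": float(wmeans[i, j, c, wi]),
                        }
                    )
    wscores = pd.DataFrame(rows)

    baseline = baseline_contrast_table(wscores, alpha=config.alpha)
    anova, followups = congruency_table(wscores, alpha=config.alpha)

    rt_filtered = filter_trials(trials, purpose="rt").trials
    acc_filtered = filter_trials(trials, purpose="accuracy").trials
    rt_anova, rt_follow = behavioral_anova(rt_filtered, dv="rt")
    acc_anova, acc_follow = behavioral_anova(acc_filtered, dv="accuracy")

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": sim.rng_seed,
        "config": _config_dict(config),
        "retained_epochs": logs,
        "spatial_components": {
            "n_ekc": int(spatial.n_ekc),
            "retained": [names[c] for c in range(n_comp)],
            "explained_variance": spatial.explained_variance.tolist(),
        },
        "temporal_components": {
            "n_ekc": int(temporal.n_ekc),
            "n_retained": int(temporal.retained.sum()),
            "mean_fwhm_ms": float(
                np.mean([c.fwhm_ms for c in temporal_comps])
            ) if temporal_comps else None,
        },
        "windows": windows.labels,
    }
    return PipelineResult(
        slope_maps=maps,
        spatial_model=spatial,
        temporal_model=temporal,
        temporal_components=temporal_comps,
        windows=windows,
        window_scores=wscores,
        baseline_table=baseline,
        congruency_anova=anova,
        congruency_followups=followups,
        behavior_rt_anova=rt_anova,
        behavior_rt_followups=rt_follow,
        behavior_acc_anova=acc_anova,
        behavior_acc_followups=acc_follow,
        manifest=manifest,
    )


def _component_names(model: ComponentModel) -> list[str]:
    base = model.names or [f"comp{j + 1}" for j in range(model.loadings_rotated.shape[1])]
    retained_idx = np.flatnonzero(model.retained)
    names = []
    seen: dict[str, int] = {}
    for j in retained_idx:
        nm = base[j]
        seen[nm] = seen.get(nm, 0) + 1
        names.append(nm if seen[nm] == 1 else f"{nm}-{seen[nm]}")
    return names


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    sim = d["sim"]
    sim["channel_layout"] = f"{len(config.sim.channel_layout.labels)} channels"
    sim["rt_model"] = {f"{k[0]}/{k[1]}": v for k, v in config.sim.rt_model.items()}
    sim["accuracy_model"] = {
        f"{k[0]}/{k[1]}": v for k, v in config.sim.accuracy_model.items()
    }
    return d
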