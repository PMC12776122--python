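"""Synthetic EEG and behavior with known ground truth.

The generator produces stimulus-locked epochs whose background activity is a
power-law (1/f^x) process with a condition- and time-dependent exponent,
plus an alpha-band oscillation, a phase-locked ERP-like transient, and white
sensor noise, together with a trial table carrying a balanced Previous x
Current congruency sequence and programmed congruency (CE) and congruency-
sequence (CSE) effects on reaction time and accuracy.  Every injected value
is recorded in a :class:`GroundTruth` so downstream estimators can be tested
as parameter-recovery problems.

Colored-noise synthesis is exact in the frequency domain: rFFT amplitudes are
shaped as ``f**(-x/2)`` with random Gaussian spectral coefficients, the DC
bin zeroed, and the series normalized to unit variance.  A time-varying
exponent is realized by overlap-add of 500-ms stationary segments under a
square-root-Hann (cosine) crossfade at 50% overlap, which keeps the summed
variance flat across segment seams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import ChannelLayout, default_layout

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CELLS = [
    (CONGRUENT, CONGRUENT),
    (CONGRUENT, INCONGRUENT),
    (INCONGRUENT, CONGRUENT),
    (INCONGRUENT, INCONGRUENT),
]
SOURCE_GROUPS = ("frontal", "central", "occipital")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentEffect:
    """A programmed shift of the aperiodic exponent x.

    ``delta`` is added to the background exponent of one scalp source group
    (or all groups) for trials matching the given previous/current congruency
    (None = any), inside the ``tmin_ms``..``tmax_ms`` post-stimulus window,
    with raised-cosine onset/offset ramps of ``ramp_ms``.
    """

    delta: float
    group: str | None = None
    prev: str | None = None
    curr: str | None = None
    tmin_ms: float = 0.0
    tmax_ms: float = 600.0
    ramp_ms: float = 100.0

    def matches(self, group: str, prev: str, curr: str) -> bool:
        return (
            (self.group is None or self.group == group)
            and (self.prev is None or self.prev == prev)
            and (self.curr is None or self.curr == curr)
        )

    def time_profile(self, times_ms: np.ndarray) -> np.ndarray:
        """delta(t): raised-cosine ramped plateau inside [tmin, tmax]."""
        t = np.asarray(times_ms, dtype=float)
        prof = np.zeros_like(t)
        up = (t >= self.tmin_ms) & (t < self.tmin_ms + self.ramp_ms)
        flat = (t >= self.tmin_ms + self.ramp_ms) & (t <= self.tmax_ms - self.ramp_ms)
        down = (t > self.tmax_ms - self.ramp_ms) & (t <= self.tmax_ms)
        prof[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - self.tmin_ms) / self.ramp_ms))
        prof[flat] = 1.0
        prof[down] = 0.5 * (1 - np.cos(np.pi * (self.tmax_ms - t[down]) / self.ramp_ms))
        return self.delta * prof


def default_exponent_effects() -> tuple[ExponentEffect, ...]:
    """Stimulus-evoked steepening with region-specific dynamics, plus a
    sequence-dependent conflict effect.

    All conditions steepen post-stimulus (the canonical stimulus-induced
    inhibition shift), but with staggered regional time courses — early
    occipital (sensory), intermediate central, sustained frontal (control) —
    so the three scalp sources carry distinct temporal signatures, as the
    regional components recovered from real data do.  Additionally,
    incongruent trials *preceded by a congruent trial* steepen further over
    frontal sites, producing a CC main effect, a CC x PC interaction, and
    the CSE follow-up pattern (conflict effect present only after congruent
    trials).
    """
    return (
        ExponentEffect(delta=0.35, group="occipital", tmin_ms=0.0, tmax_ms=350.0),
        ExponentEffect(delta=0.30, group="central", tmin_ms=100.0, tmax_ms=550.0),
        ExponentEffect(delta=0.25, group="frontal", tmin_ms=200.0, tmax_ms=800.0),
        ExponentEffect(
            delta=0.15, group="frontal", prev=CONGRUENT, curr=INCONGRUENT,
            tmin_ms=100.0, tmax_ms=500.0,
        ),
    )


def default_rt_model() -> dict[tuple[str, str], tuple[float, float]]:
    """Per-cell (mean, SD) RT in ms: CE after congruent, none after incongruent."""
    return {
        (CONGRUENT, CONGRUENT): (635.0, 120.0),
        (CONGRUENT, INCONGRUENT): (663.0, 120.0),
        (INCONGRUENT, CONGRUENT): (649.0, 120.0),
        (INCONGRUENT, INCONGRUENT): (650.0, 120.0),
    }


def default_accuracy_model() -> dict[tuple[str, str], float]:
    """Per-cell error probability (accuracy CE/CSE pattern)."""
    return {
        (CONGRUENT, CONGRUENT): 0.0237,
        (CONGRUENT, INCONGRUENT): 0.0377,
        (INCONGRUENT, CONGRUENT): 0.0257,
        (INCONGRUENT, INCONGRUENT): 0.0276,
    }


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Defaults describe the emulated experiment: 49 participants, 240 trials
    per Previous x Current cell split over 2 blocks (960 experimental
    trials), 512 Hz sampling, 2000-ms epochs from -500 to +1500 ms, 56
    scalp channels, baseline exponent 1.5.
    """

    n_participants: int = 49
    n_trials_per_cell: int = 240
    n_blocks: int = 2
    n_practice: int = 8
    fs: float = 512.0
    epoch_span_ms: tuple[float, float] = (-500.0, 1500.0)
    channel_layout: ChannelLayout = field(default_factory=default_layout)
    baseline_exponent: float = 1.5
    exponent_effects: tuple[ExponentEffect, ...] = field(
        default_factory=default_exponent_effects
    )
    background_scale_uv: float = 10.0
    source_sigma: float = 0.45
    alpha_amp_uv: float = 3.0
    alpha_freq_hz: float = 10.0
    erp_scale_uv: float = 5.0
    noise_sd_uv: float = 2.0
    participant_exponent_sd: float = 0.15
    participant_rt_sd_ms: float = 40.0
    rt_model: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_rt_model
    )
    accuracy_model: dict[tuple[str, str], float] = field(
        default_factory=default_accuracy_model
    )
    rsi_choices_ms: tuple[float, ...] = (1000.0, 2000.0, 3000.0, 5000.0)
    artifact_rate: float = 0.02
    artifact_amp_uv: float = 250.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_span_ms
        dur_s = (hi - lo) / 1000.0
        n = self.fs * dur_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs x epoch duration must give an integer sample count")
        if self.n_trials_per_cell % self.n_blocks:
            raise ValueError("n_trials_per_cell must divide evenly over blocks")
        if not 0 < self.baseline_exponent < 4:
            raise ValueError("baseline_exponent must lie in (0, 4)")
        for eff in self.exponent_effects:
            x = self.baseline_exponent + eff.delta
            if not 0 < x < 4:
                raise ValueError(
                    "baseline_exponent + every exponent effect must stay in (0, 4) "
                    f"(got {x:.3g})"
                )

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_span_ms
        return round(self.fs * (hi - lo) / 1000.0)

    @property
    def times_ms(self) -> np.ndarray:
        lo, _ = self.epoch_span_ms
        return lo + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass
class GroundTruth:
    """Everything the generator injected, for parameter-recovery tests."""

    baseline_exponent: float
    exponent_effects: tuple[ExponentEffect, ...]
    # per participant, per scalp source group (regional individual differences)
    participant_exponent_offset: dict[int, dict[str, float]]
    erp_map: dict[str, np.ndarray]  # current congruency -> (n_channels, n_samples)
    rt_truth: dict[tuple[str, str], float]
    acc_truth: dict[tuple[str, str], float]
    group_weights: dict[str, np.ndarray]
    times_ms: np.ndarray | None = None

    def true_exponent(
        self, participant: int, prev: str, curr: str, group: str,
        times_ms: np.ndarray,
    ) -> np.ndarray:
        """The exponent time course x(t) actually injected for one cell/group."""
        x = np.full(np.shape(times_ms), float(self.baseline_exponent))
        x += self.participant_exponent_offset.get(participant, {}).get(group, 0.0)
        for eff in self.exponent_effects:
            if eff.matches(group, prev, curr):
                x = x + eff.time_profile(times_ms)
        return x


# --------------------------------------------------------------------------
# colored-noise synthesis
# --------------------------------------------------------------------------

def _stationary_power_law(
    x: float, n_samples: int, fs: float, rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """(size, n_samples) zero-mean unit-variance realizations of a 1/f^x process."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-x / 2.0)
    coefs = rng.standard_normal((size, freqs.size)) + 1j * rng.standard_normal(
        (size, freqs.size)
    )
    sig = np.fft.irfft(amp * coefs, n_samples, axis=-1)
    sd = sig.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def synthesize_power_law_epochs(
    exponent_profile,
    fs: float,
    n_samples: int,
    rng: np.random.Generator,
    size: int = 1,
    segment_ms: float = 500.0,
) -> np.ndarray:
    """Batch of zero-mean, unit-variance 1/f^x series with time-varying x.

    ``exponent_profile`` is a scalar, a per-sample array of length
    ``n_samples``, or a callable mapping time in seconds to x.  Constant
    profiles are synthesized in one shot (exact spectral shaping); varying
    profiles use overlap-add of ``segment_ms`` stationary segments with a
    50% cosine (sqrt-Hann) crossfade.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    t = np.arange(n_samples) / fs
    if callable(exponent_profile):
        prof = np.asarray(exponent_profile(t), dtype=float)
        if prof.ndim == 0:
            prof = np.full(n_samples, float(prof))
    else:
        prof = np.asarray(exponent_profile, dtype=float)
        if prof.ndim == 0:
            prof = np.full(n_samples, float(prof))
    if prof.shape != (n_samples,):
        raise ValueError("exponent_profile must be defined for every sample")
    if prof.min() < 0 or prof.max() >= 4:
        raise ValueError(
            f"exponent must lie in [0, 4); got range "
            f"[{prof.min():.3g}, {prof.max():.3g}]"
        )

    if np.ptp(prof) < 1e-12:
        return _stationary_power_law(prof[0], n_samples, fs, rng, size=size)

    seg = int(round(fs * segment_ms / 1000.0))
    seg += seg % 2  # even length for exact 50% overlap
    seg = min(seg, n_samples)
    hop = seg // 2
    window = np.sin(np.pi * (np.arange(seg) + 0.5) / seg)  # sqrt-Hann

    out = np.zeros((size, n_samples))
    env = np.zeros(n_samples)
    start = -hop  # pad half a segment before t=0 so edges are fully covered
    while start < n_samples:
        sl_lo = max(start, 0)
        sl_hi = min(start + seg, n_samples)
        centre = min(max((start + seg // 2), 0), n_samples - 1)
        x = prof[centre]
        segment = _stationary_power_law(x, seg, fs, rng, size=size)
        w = window[sl_lo - start : sl_hi - start]
        out[:, sl_lo:sl_hi] += segment[:, sl_lo - start : sl_hi - start] * w
        env[sl_lo:sl_hi] += w**2
        start += hop
    out /= np.sqrt(np.maximum(env, 1e-12))
    out -= out.mean(axis=-1, keepdims=True)
    return out


def synthesize_power_law_epoch(
    exponent_profile, fs: float, n_samples: int, rng: np.random.Generator,
    segment_ms: float = 500.0,
) -> np.ndarray:
    """Single-channel version of :func:`synthesize_power_law_epochs`."""
    return synthesize_power_law_epochs(
        exponent_profile, fs, n_samples, rng, size=1, segment_ms=segment_ms
    )[0]


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def _balanced_sequence(m: int, rng: np.random.Generator) -> list[str]:
    """Congruency sequence of 4m+1 trials whose 4m lag-1 transitions hit each
    Previous x Current cell exactly m times (random Eulerian circuit on the
    two-state transition multigraph)."""
    labels = [CONGRUENT, INCONGRUENT]
    # adjacency: m copies of each of the four directed edges
    adj = {a: [b for b in labels for _ in range(m)] for a in labels}
    for a in adj:
        rng.shuffle(adj[a])
    start = labels[int(rng.integers(2))]
    # Hierholzer's algorithm
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == 4 * m + 1
    return circuit


def _participant_rng_streams(config: SimConfig) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(config.rng_seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in seq.spawn(
        config.n_participants + 1
    )]


def generate_behavior_table(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Trial table with balanced sequences and programmed RT/accuracy effects.

    Columns: participant, block, trial_index, is_practice, is_first_of_block,
    prev_congruency, curr_congruency, rt_ms, correct, rsi_ms.
    """
    for cell, (mu, sd) in config.rt_model.items():
        if mu <= 0:
            raise ValueError(f"rt_model mean for {cell} must be positive")
    for cell, p in config.accuracy_model.items():
        if not 0 <= p < 1:
            raise ValueError(f"error probability for {cell} must be in [0, 1)")

    streams = _participant_rng_streams(config)
    behav_rng = rng if rng is not None else streams[0]
    m = config.n_trials_per_cell // config.n_blocks
    rows = []
    part_offsets = {}
    for p in range(1, config.n_participants + 1):
        part_offsets[p] = behav_rng.normal(0.0, config.participant_rt_sd_ms)
        for b in range(1, config.n_blocks + 1):
            practice = [
                (CONGRUENT, INCONGRUENT)[int(behav_rng.integers(2))]
                for _ in range(config.n_practice)
            ]
            experimental = _balanced_sequence(m, behav_rng)
            labels = practice + experimental
            prev_labels = (
                [(CONGRUENT, INCONGRUENT)[int(behav_rng.integers(2))]]
                + labels[:-1]
            )
            for k, (prev, curr) in enumerate(zip(prev_labels, labels)):
                is_practice = k < config.n_practice
                cell = (prev, curr)
                mu, sd = config.rt_model[cell]
                rt = max(
                    150.0, mu + part_offsets[p] + behav_rng.normal(0.0, sd)
                )
                err_p = config.accuracy_model[cell]
                rows.append(
                    {
                        "participant": p,
                        "block": b,
                        "trial_index": k + 1,
                        "is_practice": is_practice,
                        "is_first_of_block": k == config.n_practice,
                        "prev_congruency": prev,
                        "curr_congruency": curr,
                        "rt_ms": rt,
                        "correct": bool(behav_rng.random() >= err_p),
                        "rsi_ms": float(
                            config.rsi_choices_ms[
                                int(behav_rng.integers(len(config.rsi_choices_ms)))
                            ]
                        ),
                    }
                )
    trials = pd.DataFrame(rows)
    # lag-1 bookkeeping must hold within blocks (beyond each block's first row)
    for (_, _), blk in trials.groupby(["participant", "block"]):
        assert (
            blk["prev_congruency"].iloc[1:].values
            == blk["curr_congruency"].iloc[:-1].values
        ).all(), "inconsistent sequence bookkeeping"
    return trials


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------

def default_erp_template(
    layout: ChannelLayout, times_ms: np.ndarray, scale_uv: float = 5.0
) -> dict[str, np.ndarray]:
    """Condition ERP templates: early occipital, mid central-negative, late
    central-positive deflections; the late component is larger/later for
    incongruent trials (conflict-sensitive)."""

    def gauss(mu, sigma):
        return np.exp(-0.5 * ((times_ms - mu) / sigma) ** 2)

    w_occ = layout.gaussian_weights("occipital", 0.4)
    w_cen = layout.gaussian_weights("central", 0.4)
    templates = {}
    for cond, (p3_amp, p3_lat) in {
        CONGRUENT: (1.0, 380.0), INCONGRUENT: (1.2, 420.0)
    }.items():
        wave = (
            np.outer(w_occ, 0.8 * gauss(120.0, 30.0))
            - np.outer(w_cen, 0.6 * gauss(230.0, 45.0))
            + np.outer(w_cen + 0.3 * w_occ, p3_amp * gauss(p3_lat, 90.0))
        )
        templates[cond] = scale_uv * wave
    return templates


def _group_weight_maps(config: SimConfig) -> dict[str, np.ndarray]:
    return {
        g: config.channel_layout.gaussian_weights(g, config.source_sigma)
        for g in SOURCE_GROUPS
    }


def generate_participant_epochs(
    config: SimConfig,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    exponent_offset: dict[str, float],
    erp_map: dict[str, np.ndarray],
    weights: dict[str, np.ndarray],
) -> np.ndarray:
    """Epochs (n_trials, n_channels, n_samples) for one participant's
    non-practice trials, in TrialTable row order."""
    times = config.times_ms
    n_samp = config.n_samples
    n_ch = config.channel_layout.n_channels
    data = np.zeros((len(trials), n_ch, n_samp))
    w_alpha = config.channel_layout.gaussian_weights("occipital", config.source_sigma)

    # batch trials by cell: same exponent profile -> one vectorized synthesis
    for cell, idx in trials.groupby(
        ["prev_congruency", "curr_congruency"], sort=True
    ).indices.items():
        prev, curr = cell
        for g in SOURCE_GROUPS:
            x = np.full(n_samp, config.baseline_exponent + exponent_offset.get(g, 0.0))
            for eff in config.exponent_effects:
                if eff.matches(g, prev, curr):
                    x = x + eff.time_profile(times)
            src = synthesize_power_law_epochs(
                x, config.fs, n_samp, rng, size=len(idx)
            )
            data[idx] += (
                config.background_scale_uv
                * weights[g][None, :, None]
                * src[:, None, :]
            )
        # phase drawn unconditionally so alpha-on/off datasets share the same
        # background realization under one seed
        phase = rng.uniform(0, 2 * np.pi, size=(len(idx), 1))
        if config.alpha_amp_uv > 0:
            alpha = config.alpha_amp_uv * np.sin(
                2 * np.pi * config.alpha_freq_hz * times / 1000.0 + phase
            )
            data[idx] += w_alpha[None, :, None] * alpha[:, None, :]
        data[idx] += erp_map[curr][None, :, :]

    if config.noise_sd_uv > 0:
        data += rng.normal(0.0, config.noise_sd_uv, size=data.shape)

    # occasional high-amplitude slow artifact on one channel
    hit = rng.random(len(trials)) < config.artifact_rate
    if config.artifact_rate > 0:
        for i in np.flatnonzero(hit):
            ch = int(rng.integers(n_ch))
            onset = int(rng.integers(n_samp // 2))
            bump = np.zeros(n_samp)
            bump[onset:] = config.artifact_amp_uv
            width = int(0.05 * config.fs)
            kernel = np.hanning(2 * width + 1)
            bump = np.convolve(bump, kernel / kernel.sum(), mode="same")
            data[i, ch] += bump
    return data


def generate_eeg_dataset(config: SimConfig):
    """Full dataset: (Epochs, TrialTable, GroundTruth).

    Epochs cover all non-practice trials, linked to trial-table rows via
    ``trial_link``.  For large configurations prefer
    :func:`iter_participant_epochs`, which yields one participant at a time.
    """
    from .preprocess import Epochs  # local import to avoid a cycle

    trials = generate_behavior_table(config)
    blocks = []
    links = []
    gt = None
    for pid, ep, tr, gt in iter_participant_epochs(config, trials):
        blocks.append(ep)
        links.append(tr.index.values)
    data = np.concatenate(blocks, axis=0)
    epochs = Epochs(
        data=data,
        fs=config.fs,
        times=config.times_ms,
        channel_labels=list(config.channel_layout.labels),
        trial_link=np.concatenate(links),
    )
    return epochs, trials, gt


def iter_participant_epochs(config: SimConfig, trials: pd.DataFrame | None = None):
    """Yield (participant, data array, participant trial rows, GroundTruth).

    The ground truth is identical across yields (it records the full design).
    """
    if trials is None:
        trials = generate_behavior_table(config)
    streams = _participant_rng_streams(config)
    erp_map = default_erp_template(
        config.channel_layout, config.times_ms, config.erp_scale_uv
    )
    weights = _group_weight_maps(config)
    # participant exponent offsets come from a dedicated deterministic stream
    offs_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.rng_seed, 2**20]))
    )
    offsets = {
        p: {
            g: offs_rng.normal(0.0, config.participant_exponent_sd)
            for g in SOURCE_GROUPS
        }
        for p in range(1, config.n_participants + 1)
    }
    gt = GroundTruth(
        baseline_exponent=config.baseline_exponent,
        exponent_effects=config.exponent_effects,
        participant_exponent_offset=offsets,
        erp_map=erp_map,
        rt_truth={c: mu for c, (mu, _) in config.rt_model.items()},
        acc_truth={c: 1 - p for c, p in config.accuracy_model.items()},
        group_weights=weights,
        times_ms=config.times_ms,
    )
    for p in range(1, config.n_participants + 1):
        tr = trials[(trials["participant"] == p) & (~trials["is_practice"])]
        data = generate_participant_epochs(
            config, tr, streams[p], offsets[p], erp_map, weights
        )
        yield p, data, tr, gt
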