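"""Epoch bookkeeping, artifact rejection, and condition-wise ERP removal.

Inputs are assumed already band-passed and re-referenced; an optional
zero-phase Butterworth band-pass and channel re-reference are provided as
plumbing for raw inputs but are off by default throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal


@dataclass
class Epochs:
    """trials x channels x samples container with time axis and trial links."""

    data: np.ndarray
    fs: float
    times: np.ndarray  # ms
    channel_labels: list[str]
    trial_link: np.ndarray  # TrialTable row index per epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_link = np.asarray(self.trial_link)
        n, ch, s = self.data.shape
        if self.times.shape != (s,):
            raise ValueError("times length must equal the sample dimension")
        if len(self.channel_labels) != ch:
            raise ValueError("channel_labels length must equal channel dimension")
        if self.trial_link.shape != (n,):
            raise ValueError("trial_link must have one entry per epoch")
        step = 1000.0 / self.fs
        if self.times.size > 1 and not np.allclose(np.diff(self.times), step):
            raise ValueError("times must be uniformly spaced at 1000/fs ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, idx: np.ndarray) -> "Epochs":
        return Epochs(
            data=self.data[idx],
            fs=self.fs,
            times=self.times,
            channel_labels=list(self.channel_labels),
            trial_link=self.trial_link[idx],
        )


def reject_artifacts(
    epochs: Epochs,
    threshold_uv: float = 150.0,
    window_ms: float = 600.0,
    step_ms: float = 100.0,
) -> np.ndarray:
    """Peak-to-peak artifact mask: True where a trial is rejected.

    A trial is flagged iff any channel, in any full sliding window (start
    positions 0, step, 2*step, ... while start + window <= epoch duration),
    shows max - min strictly exceeding ``threshold_uv``.  Trailing partial
    windows are not evaluated.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    win = int(round(window_ms * epochs.fs / 1000.0))
    step = int(round(step_ms * epochs.fs / 1000.0))
    if win > epochs.n_samples:
        raise ValueError("window must not exceed the epoch duration")
    views = sliding_window_view(epochs.data, win, axis=-1)[..., ::step, :]
    # restrict to full windows only: sliding_window_view already yields only
    # starts with start+win <= n_samples, so the stride slice is sufficient
    ptp = views.max(axis=-1) - views.min(axis=-1)
    return (ptp > threshold_uv).any(axis=(-2, -1))


def subtract_condition_erp(epochs: Epochs, condition_labels) -> Epochs:
    """Remove the phase-locked average within each condition cell.

    ``condition_labels`` is one hashable key per retained trial (typically a
    (participant, previous congruency, current congruency) tuple).  Within
    each cell the mean across trials of the returned data is zero at every
    channel and sample; non-phase-locked single-trial content is untouched.
    """
    labels = list(condition_labels)
    if len(labels) != epochs.n_trials:
        raise ValueError("need one condition label per retained trial")
    groups: dict = {}
    for i, key in enumerate(labels):
        groups.setdefault(key, []).append(i)
    out = epochs.data.copy()
    for key, idx in groups.items():
        idx = np.asarray(idx)
        out[idx] -= out[idx].mean(axis=0, keepdims=True)
    return replace(epochs, data=out)


def select_analysis_trials(
    epochs: Epochs,
    retained_trial_index,
    artifact_rejected: np.ndarray | None = None,
) -> Epochs:
    """Restrict epochs to trials passing behavioral EEG criteria and the
    artifact mask (logical AND of both retentions)."""
    retained = set(np.asarray(retained_trial_index).tolist())
    keep = np.array([link in retained for link in epochs.trial_link])
    if artifact_rejected is not None:
        artifact_rejected = np.asarray(artifact_rejected, dtype=bool)
        if artifact_rejected.shape != (epochs.n_trials,):
            raise ValueError("artifact mask length must match trial count")
        keep &= ~artifact_rejected
    return epochs.select(np.flatnonzero(keep))


def bandpass_rereference(
    epochs: Epochs,
    l_freq: float | None = 0.1,
    h_freq: float | None = 40.0,
    reference: list[str] | None = None,
    order: int = 4,
) -> Epochs:
    """Optional plumbing: zero-phase Butterworth band-pass and re-reference.

    Off by default in the pipeline; provided for raw inputs that have not
    been filtered/re-referenced upstream.
    """
    data = epochs.data
    nyq = epochs.fs / 2.0
    if l_freq is not None or h_freq is not None:
        if l_freq is not None and h_freq is not None:
            sos = sp_signal.butter(
                order, [l_freq / nyq, h_freq / nyq], btype="band", output="sos"
            )
        elif l_freq is not None:
            sos = sp_signal.butter(order, l_freq / nyq, btype="high", output="sos")
        else:
            sos = sp_signal.butter(order, h_freq / nyq, btype="low", output="sos")
        data = sp_signal.sosfiltfilt(sos, data, axis=-1)
    if reference:
        idx = [epochs.channel_labels.index(ch) for ch in reference]
        data = data - data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=data)
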