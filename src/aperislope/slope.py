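"""Instantaneous aperiodic slope estimation from one-cycle wavelet power.

Each epoch is convolved with untapered single-cycle cosine/sine wavelet
pairs at a sparse frequency grid (default 2.5, 5, 7.5, 15, 25 Hz); the two
quadrature outputs are squared and summed into an instantaneous power
estimate per frequency and time point.  Log power is then regressed on log
frequency at every time point (ordinary least squares over the fit-masked
frequencies, by default excluding the alpha-adjacent 7.5 and 15 Hz points),
giving a per-sample slope (the negated aperiodic exponent) and intercept.
Slope time courses are smoothed with a 5-point moving average and trials
with any |slope| > 4 are censored as outliers.

Power normalization.  ``density`` (default) scales each wavelet's output by
its noise bandwidth (2 fs / L Hz for an L-sample one-cycle pair), so that
broadband input yields power in uV^2/Hz and a 1/f^x process fits a slope of
-x.  ``amplitude`` scales kernels by 2/L so a unit sinusoid at the wavelet's
frequency yields power 1; because one-cycle bandwidth grows with frequency,
amplitude-normalized power of a 1/f^x process falls as f^(1-x) and is not
suitable for slope estimation (the density mode exists precisely for that).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .preprocess import Epochs
from .synth import CELLS

DEFAULT_FREQS = (2.5, 5.0, 7.5, 15.0, 25.0)
LOG_FLOOR = 1e-12  # uV^2 floor before log10, guards log(0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Analysis frequencies and the mask of those entering the log-log fit."""

    freqs: tuple[float, ...] = DEFAULT_FREQS
    fit_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.freqs)
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be positive")
        if any(b >= a for a, b in zip(freqs[1:], freqs[:-1])):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)
        if self.fit_mask is None:
            # exclude the alpha-adjacent 7.5-15 Hz range (inclusive)
            mask = tuple(not (7.5 <= f <= 15.0) for f in freqs)
        else:
            mask = tuple(bool(b) for b in self.fit_mask)
            if len(mask) != len(freqs):
                raise ValueError("fit_mask length must match freqs")
        if sum(mask) < 2:
            raise ValueError("fit_mask must keep at least 2 frequencies")
        object.__setattr__(self, "fit_mask", mask)

    @property
    def fit_freqs(self) -> np.ndarray:
        return np.asarray(
            [f for f, m in zip(self.freqs, self.fit_mask) if m]
        )


@dataclass(frozen=True)
class WaveletPair:
    """One cycle of a cosine and a sine at a nominal frequency.

    Kernels span ``L = round(fs / freq)`` samples with phase 2*pi*k/L, so
    both kernels sum to zero exactly and are numerically in quadrature.
    Scaled by 2/L: the squared quadrature sum of a unit matched sinusoid
    is 1 (amplitude normalization).  ``noise_bandwidth_hz`` (2 fs / L) is
    the white-noise equivalent bandwidth used for density normalization.
    """

    freq: float
    fs: float
    cos_kernel: np.ndarray = field(init=False, repr=False)
    sin_kernel: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        L = round(self.fs / self.freq)
        if L < 2:
            raise ValueError(f"sampling too coarse for {self.freq} Hz wavelet")
        phase = 2.0 * np.pi * np.arange(L) / L
        object.__setattr__(self, "cos_kernel", (2.0 / L) * np.cos(phase))
        object.__setattr__(self, "sin_kernel", (2.0 / L) * np.sin(phase))

    @property
    def n_samples(self) -> int:
        return self.cos_kernel.size

    @property
    def noise_bandwidth_hz(self) -> float:
        return 2.0 * self.fs / self.n_samples


@dataclass
class SlopeSeries:
    """Per-trial slope/intercept time courses with a validity mask.

    ``slope`` and ``intercept`` are (trials, channels, samples); ``slope``
    is the log10-power-on-log10-frequency regression slope (the negated
    aperiodic exponent), ``intercept`` the log10 power offset.  Censored
    trials carry ``valid_mask = False``.
    """

    slope: np.ndarray
    intercept: np.ndarray
    valid_mask: np.ndarray
    times: np.ndarray | None = None
    fs: float | None = None
    trial_link: np.ndarray | None = None


@dataclass
class SlopeMaps:
    """Condition-averaged slope maps: (participant, cell, channel, sample)."""

    values: np.ndarray
    participants: np.ndarray
    cells: list[tuple[str, str]]
    times: np.ndarray
    counts: np.ndarray  # trials per participant x cell
    channel_labels: list[str] | None = None

    @property
    def missing_cells(self) -> list[tuple[int, tuple[str, str]]]:
        out = []
        for i, p in enumerate(self.participants):
            for j, cell in enumerate(self.cells):
                if self.counts[i, j] == 0:
                    out.append((int(p), cell))
        return out


def wavelet_power(
    epochs,
    grid: FrequencyGrid | None = None,
    fs: float | None = None,
    normalization: str = "density",
    only_fit_freqs: bool = False,
) -> np.ndarray:
    """Instantaneous wavelet power (trials x channels x freqs x samples).

    Accepts an :class:`Epochs` or a raw array (then ``fs`` is required).
    Convolution uses 'same' alignment (kernels centred on the output
    sample) with zero-padded edges; edge samples are discarded later by the
    PCA crop.  ``normalization``: 'density' (uV^2/Hz, default) or
    'amplitude' (unit matched sinusoid -> power 1).  With
    ``only_fit_freqs`` the fit-masked-out frequencies are left as zeros — a
    pure compute saving for callers (like the slope pipeline) that never
    read them.
    """
    if isinstance(epochs, Epochs):
        data, fs = epochs.data, epochs.fs
    else:
        data = np.asarray(epochs, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
    if data.ndim == 1:
        data = data[None, None, :]
    elif data.ndim == 2:
        data = data[:, None, :]
    if normalization not in ("density", "amplitude"):
        raise ValueError("normalization must be 'density' or 'amplitude'")
    grid = grid or FrequencyGrid()
    n_samp = data.shape[-1]
    pairs = [WaveletPair(freq=f, fs=fs) for f in grid.freqs]
    for pair in pairs:
        if pair.n_samples > n_samp:
            raise ValueError(
                f"epoch ({n_samp} samples) shorter than the {pair.freq} Hz "
                f"one-cycle kernel ({pair.n_samples} samples)"
            )
    # one shared forward FFT; cos/sin kernels combined into a complex kernel
    # so each frequency needs a single inverse transform
    nfft = sp_fft.next_fast_len(n_samp + max(p.n_samples for p in pairs) - 1)
    X = sp_fft.fft(data, nfft, axis=-1)
    out = np.zeros(data.shape[:-1] + (len(pairs), n_samp))
    for k, pair in enumerate(pairs):
        if only_fit_freqs and not grid.fit_mask[k]:
            continue
        L = pair.n_samples
        H = sp_fft.fft(pair.cos_kernel + 1j * pair.sin_kernel, nfft)
        y = sp_fft.ifft(X * H, axis=-1)
        start = (L - 1) // 2  # 'same' alignment: kernel centred on the output
        seg = y[..., start : start + n_samp]
        p = seg.real**2 + seg.imag**2
        if normalization == "density":
            p /= pair.noise_bandwidth_hz
        out[..., k, :] = p
    return out


def fit_slope_timecourse(
    power: np.ndarray,
    grid: FrequencyGrid | None = None,
    floor: float = LOG_FLOOR,
    relative_floor: float = 0.05,
    times: np.ndarray | None = None,
    fs: float | None = None,
    trial_link: np.ndarray | None = None,
) -> SlopeSeries:
    """Per-timepoint OLS of log10(power) on log10(frequency).

    Only fit-masked frequencies enter the regression.  Before the log, each
    (trial, channel, frequency) power trace is left-clamped at
    ``relative_floor`` times its own epoch-mean power: instantaneous
    single-trial power is exponentially distributed around the true
    spectrum, and its heavy left tail (momentary near-zero quadrature
    power) carries no spectral information while producing extreme spurious
    negative slope excursions.  The clamp is a simple censored-power
    treatment of those samples; it is scale-equivariant and leaves constant-
    in-time power (and hence the exact collinear cases) untouched.  The
    absolute ``floor`` only guards log(0); all-floor power (pathological
    zero input) yields slope 0 and is flagged invalid.
    """
    grid = grid or FrequencyGrid()
    power = np.asarray(power, dtype=float)
    if power.ndim == 2:  # (freqs, samples) single trial/channel
        power = power[None, None, ...]
    if power.shape[-2] != len(grid.freqs):
        raise ValueError("power frequency axis must match the grid")
    if np.any(power < 0):
        raise ValueError("negative power: upstream contract violated")
    mask = np.asarray(grid.fit_mask)
    logf = np.log10(np.asarray(grid.freqs)[mask])
    x_mean = logf.mean()
    xc = logf - x_mean
    w = xc / (xc**2).sum()  # slope = sum_i w_i * y_i (exact OLS weights)

    clamped = power
    if relative_floor > 0:
        lo = relative_floor * power.mean(axis=-1, keepdims=True)
        clamped = np.maximum(power, lo)
    logp = np.log10(clamped[..., mask, :] + floor)
    slope = np.einsum("f,...fs->...s", w, logp)
    y_mean = logp.mean(axis=-2)
    intercept = y_mean - slope * x_mean

    all_floor = (power[..., mask, :] <= floor).all(axis=(-2, -1))
    slope = np.where(all_floor[..., None], 0.0, slope)
    valid = ~all_floor.reshape(power.shape[0], -1).any(axis=-1)
    return SlopeSeries(
        slope=slope, intercept=intercept, valid_mask=valid,
        times=times, fs=fs, trial_link=trial_link,
    )


def moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centered k-point moving average along the last axis with shrinking
    windows at the edges (edge means use only in-range samples)."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k == 1:
        return x.copy()
    kernel = np.ones(k)
    shape = x.shape
    flat = x.reshape(-1, shape[-1])
    sums = sp_signal.fftconvolve(flat, kernel[None, :], mode="same", axes=-1)
    counts = np.convolve(np.ones(shape[-1]), kernel, mode="same")
    return (sums / counts[None, :]).reshape(shape)


def smooth_and_censor(
    slopes: SlopeSeries, k: int = 5, bound: float = 4.0,
    edge_exclude_ms: float = 200.0,
) -> tuple[SlopeSeries, int]:
    """5-point moving-average smoothing, then censor trials with |slope| > bound.

    Returns the new series and the number of newly censored trials.  The
    outlier rule is evaluated on the smoothed slopes (smoothing precedes
    censoring), at every channel and sample — except within
    ``edge_exclude_ms`` of the epoch edges, where 'same'-mode convolution
    against zero padding makes the estimates meaningless (those samples are
    discarded by the analysis crop anyway and must not drive censoring).
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    smoothed = moving_average(slopes.slope, k)
    scan = smoothed
    if edge_exclude_ms > 0 and slopes.fs:
        margin = int(round(edge_exclude_ms * slopes.fs / 1000.0))
        if 2 * margin < smoothed.shape[-1]:
            scan = smoothed[..., margin:-margin]
    exceeded = (np.abs(scan) > bound).reshape(scan.shape[0], -1).any(axis=-1)
    new_valid = slopes.valid_mask & ~exceeded
    n_censored = int((slopes.valid_mask & exceeded).sum())
    out = replace(slopes, slope=smoothed, valid_mask=new_valid)
    return out, n_censored


def condition_average(
    slopes: SlopeSeries,
    trials: pd.DataFrame,
    cells: list[tuple[str, str]] | None = None,
) -> SlopeMaps:
    """Mean slope over retained trials per participant x (prev, curr) cell.

    ``trials`` rows are matched to slope trials via ``slopes.trial_link``
    (or positionally when no link is set).  Cells with zero retained trials
    are NaN and reported via :attr:`SlopeMaps.missing_cells`.
    """
    cells = cells or CELLS
    if slopes.trial_link is not None:
        meta = trials.loc[slopes.trial_link]
    else:
        if len(trials) != slopes.slope.shape[0]:
            raise ValueError("trial table must match slope trials positionally")
        meta = trials
    participants = np.sort(meta["participant"].unique())
    n_ch, n_samp = slopes.slope.shape[1:]
    values = np.full((len(participants), len(cells), n_ch, n_samp), np.nan)
    counts = np.zeros((len(participants), len(cells)), dtype=int)
    valid = slopes.valid_mask
    pvals = meta["participant"].values
    prev = meta["prev_congruency"].values
    curr = meta["curr_congruency"].values
    for i, p in enumerate(participants):
        for j, (pc, cc) in enumerate(cells):
            idx = np.flatnonzero((pvals == p) & (prev == pc) & (curr == cc) & valid)
            counts[i, j] = idx.size
            if idx.size:
                values[i, j] = slopes.slope[idx].mean(axis=0)
    maps = SlopeMaps(
        values=values,
        participants=participants,
        cells=list(cells),
        times=slopes.times if slopes.times is not None else np.arange(n_samp, dtype=float),
        counts=counts,
    )
    if maps.missing_cells:
        warnings.warn(
            f"cells with no retained trials: {maps.missing_cells[:8]}"
            + ("..." if len(maps.missing_cells) > 8 else ""),
            stacklevel=2,
        )
    return maps
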