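"""Spatial/temporal PCA with EKC retention, varimax rotation, regression
scores, FWHM duration estimates, and stimulus-anchored time windows.

Extraction operates on the covariance matrix of the variables (electrodes
for the spatial PCA, decimated timepoints for the temporal PCA), because the
regression score formula (data x unstandardized loadings x inverse
covariance) is covariance-metric; eigenvalues are rescaled to correlation
metric (sum = number of variables) only for the Empirical Kaiser Criterion
retention test.  After varimax rotation, components explaining less than
1/x of the total variance (x = number of EKC-retained components) are
dropped from further analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .layout import ChannelLayout
from .slope import SlopeMaps


# --------------------------------------------------------------------------
# retention and rotation primitives
# --------------------------------------------------------------------------

def ekc_retain(eigenvalues, n_cases: int, n_vars: int) -> int:
    """Empirical Kaiser Criterion: number of components to retain.

    Serial rule on correlation-metric eigenvalues: component j is retained
    while lambda_j exceeds

        l_ref_j = max( (1 + sqrt(n_vars/n_cases))^2
                       * (n_vars - sum_{i<j} lambda_i) / (n_vars - j + 1), 1 )

    stopping at the first failure.  A single variable trivially retains one
    component.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be sorted in non-increasing order")
    if n_vars == 1:
        return 1
    shoulder = (1.0 + np.sqrt(n_vars / n_cases)) ** 2
    retained = 0
    consumed = 0.0
    for j, l in enumerate(lam, start=1):
        l_ref = max(shoulder * (n_vars - consumed) / (n_vars - j + 1), 1.0)
        if l > l_ref:
            retained += 1
            consumed += l
        else:
            break
    return retained


def varimax_criterion(loadings: np.ndarray) -> float:
    """The raw varimax objective: sum over components of the variance of
    squared loadings."""
    sq = np.asarray(loadings) ** 2
    return float(((sq - sq.mean(axis=0)) ** 2).sum())


def varimax_rotate(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser-normalized by default).

    Returns (rotated loadings, rotation matrix R) with ``rotated =
    loadings @ R`` and R orthonormal.  Sign convention: each component's
    largest-magnitude loading is positive.  Single-component input returns
    unchanged; rank-deficient input warns and returns the input.
    """
    A = np.asarray(loadings, dtype=float)
    if A.ndim != 2:
        raise ValueError("loadings must be 2-D")
    p, k = A.shape
    if k < 2:
        return _fix_signs(A.copy())[0], np.eye(k)
    if np.linalg.matrix_rank(A) < k:
        warnings.warn("rank-deficient loadings: returning input unrotated",
                      stacklevel=2)
        return A.copy(), np.eye(k)
    comm = np.sqrt((A**2).sum(axis=1))
    if normalize:
        safe = np.where(comm > 0, comm, 1.0)
        A = A / safe[:, None]
    R = np.eye(k)
    sv_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        U, s, Vt = np.linalg.svd(
            A.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        )
        R = U @ Vt
        sv_new = s.sum()
        if sv_new - sv_old < tol * max(sv_new, 1.0):
            break
        sv_old = sv_new
    rotated = A @ R
    if normalize:
        rotated = rotated * np.where(comm > 0, comm, 1.0)[:, None]
    rotated, signs = _fix_signs(rotated)
    R = R * signs[None, :]
    return rotated, R


def _fix_signs(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns so each component's largest-|loading| entry is positive."""
    idx = np.abs(loadings).argmax(axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs[None, :], signs


# --------------------------------------------------------------------------
# the component model
# --------------------------------------------------------------------------

@dataclass
class ComponentModel:
    """One PCA (spatial or temporal): eigenstructure, rotation, retention."""

    variables: list
    mean: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray            # covariance metric, non-increasing
    eigenvalues_corr: np.ndarray       # rescaled to sum = n_vars (EKC metric)
    loadings_unrotated: np.ndarray     # variables x n_extracted (unstandardized)
    loadings_rotated: np.ndarray       # variables x n_ekc (unstandardized)
    loadings_rotated_std: np.ndarray   # standardized copies
    rotation: np.ndarray
    explained_variance: np.ndarray     # fraction of total variance per rotated comp
    explained_of_solution: np.ndarray  # share of the extracted solution's variance
    retained: np.ndarray               # bool per rotated component (1/x filter)
    n_cases: int
    n_ekc: int
    names: list[str] | None = None

    @property
    def communalities_unrotated(self) -> np.ndarray:
        k = self.loadings_rotated.shape[1]
        return (self.loadings_unrotated[:, :k] ** 2).sum(axis=1)

    @property
    def communalities_rotated(self) -> np.ndarray:
        return (self.loadings_rotated**2).sum(axis=1)


def fit_component_model(data: np.ndarray, variables: list) -> ComponentModel:
    """Covariance PCA of a cases x variables matrix with EKC retention,
    varimax rotation, and the 1/x explained-variance filter."""
    X = np.asarray(data, dtype=float)
    n_cases, n_vars = X.shape
    if n_cases < n_vars:
        warnings.warn(
            "fewer cases than variables: EKC retention is unreliable",
            stacklevel=2,
        )
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0.0, None), vec[:, order]
    total = lam.sum()
    lam_corr = lam * n_vars / total if total > 0 else lam
    n_ekc = ekc_retain(lam_corr, n_cases=n_cases, n_vars=n_vars)
    loadings_unrot = vec * np.sqrt(lam)[None, :]
    if n_ekc > 0:
        rotated, R = varimax_rotate(loadings_unrot[:, :n_ekc])
        # order rotated components by explained variance, descending
        ss = (rotated**2).sum(axis=0)
        order_r = np.argsort(ss)[::-1]
        rotated, R, ss = rotated[:, order_r], R[:, order_r], ss[order_r]
        explained = ss / total
        # the "1/x" filter (x = number of EKC components): drop components
        # carrying less than an equal share of the extracted solution's
        # variance.  Measured against the solution, not the raw total, so a
        # single dominant source is retained even in the presence of noise.
        share = ss / ss.sum()
        retained = share >= 1.0 / n_ekc - 1e-12
    else:
        rotated = np.zeros((n_vars, 0))
        R = np.zeros((0, 0))
        explained = np.zeros(0)
        share = np.zeros(0)
        retained = np.zeros(0, dtype=bool)
    sd = np.sqrt(np.clip(np.diag(cov), 1e-30, None))
    rotated_std = rotated / sd[:, None]
    return ComponentModel(
        variables=list(variables),
        mean=mean,
        covariance=cov,
        eigenvalues=lam,
        eigenvalues_corr=lam_corr,
        loadings_unrotated=loadings_unrot,
        loadings_rotated=rotated,
        loadings_rotated_std=rotated_std,
        rotation=R,
        explained_variance=explained,
        explained_of_solution=share,
        retained=retained,
        n_cases=n_cases,
        n_ekc=n_ekc,
    )


def project_scores(
    data: np.ndarray, model: ComponentModel, components: str = "retained"
) -> np.ndarray:
    """Regression-method factor scores: (data - mean) @ cov^-1 @ loadings.

    ``components`` selects 'retained' (default), 'rotated' (all EKC-rotated)
    or 'all' (every unrotated component).  Uses the pseudo-inverse with a
    warning when the covariance is singular.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[-1] != len(model.variables):
        raise ValueError("data variables do not match the component model")
    if components == "retained":
        load = model.loadings_rotated[:, model.retained]
    elif components == "rotated":
        load = model.loadings_rotated
    elif components == "all":
        load = model.loadings_unrotated
    else:
        raise ValueError("components must be 'retained', 'rotated', or 'all'")
    cov = model.covariance
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance: using pseudo-inverse", stacklevel=2)
        cinv = np.linalg.pinv(cov)
    return (X - model.mean) @ cinv @ load


# --------------------------------------------------------------------------
# spatial and temporal PCA drivers
# --------------------------------------------------------------------------

def _crop_indices(times: np.ndarray, crop_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = crop_ms
    return np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))


def run_spatial_pca(
    maps: SlopeMaps,
    crop_ms: tuple[float, float] = (-300.0, 1300.0),
    layout: ChannelLayout | None = None,
) -> ComponentModel:
    """PCA over electrodes: cases are participant x condition x timepoint
    rows of the condition-averaged slope maps inside the crop.

    Retained components are named after the scalp region of their
    peak-|loading| electrode when a layout is provided.
    """
    idx = _crop_indices(maps.times, crop_ms)
    if idx.size == 0:
        raise ValueError("crop window contains no timepoints")
    vals = maps.values[..., idx]  # (P, cells, ch, T)
    P, C, ch, T = vals.shape
    X = vals.transpose(0, 1, 3, 2).reshape(P * C * T, ch)
    X = X[~np.isnan(X).any(axis=1)]
    labels = maps.channel_labels or [f"ch{i}" for i in range(ch)]
    model = fit_component_model(X, labels)
    if layout is not None:
        names = []
        for j in range(model.loadings_rotated.shape[1]):
            peak = int(np.abs(model.loadings_rotated[:, j]).argmax())
            names.append(layout.region_of(labels[peak]))
        model.names = names
    return model


@dataclass
class TemporalComponent:
    """A temporal PCA component summarized by its loading curve peak."""

    index: int
    peak_time_ms: float
    fwhm_ms: float
    truncated: bool
    times_ms: np.ndarray = field(repr=False)
    loading_curve: np.ndarray = field(repr=False)


def run_temporal_pca(
    maps: SlopeMaps,
    crop_ms: tuple[float, float] = (-300.0, 1300.0),
    decimate: int = 10,
) -> tuple[ComponentModel, list[TemporalComponent]]:
    """PCA over (decimated) timepoints: cases are participant x condition x
    electrode rows.  Each retained component gets an FWHM estimate from its
    loading curve."""
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    idx = _crop_indices(maps.times, crop_ms)[::decimate]
    if idx.size < 2:
        raise ValueError("crop/decimation leaves too few timepoints")
    t = maps.times[idx]
    vals = maps.values[..., idx]  # (P, cells, ch, T)
    P, C, ch, T = vals.shape
    X = vals.reshape(P * C * ch, T)
    X = X[~np.isnan(X).any(axis=1)]
    model = fit_component_model(X, [float(x) for x in t])
    comps = []
    for j in np.flatnonzero(model.retained):
        curve = model.loadings_rotated[:, j]
        fwhm, peak, truncated = estimate_fwhm(t, curve)
        comps.append(
            TemporalComponent(
                index=int(j), peak_time_ms=peak, fwhm_ms=fwhm,
                truncated=truncated, times_ms=t, loading_curve=curve,
            )
        )
    return model, comps


def estimate_fwhm(times, curve) -> tuple[float, float, bool]:
    """Full width at half maximum of a peaked curve.

    Returns (fwhm_ms, peak_time_ms, truncated).  Crossings are linearly
    interpolated nearest the unique global maximum; a side that never drops
    below half maximum is bounded by the curve edge and flags truncation.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(curve, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and curve must be matching 1-D arrays")
    if np.ptp(y) == 0:
        raise ValueError("constant curve has no peak")
    ipk = int(y.argmax())
    half = y[ipk] / 2.0
    truncated = False
    # left crossing
    left = t[0]
    seg = np.flatnonzero(y[:ipk] < half)
    if seg.size:
        i = seg[-1]
        left = t[i] + (t[i + 1] - t[i]) * (half - y[i]) / (y[i + 1] - y[i])
    else:
        truncated = True
    # right crossing
    right = t[-1]
    seg = np.flatnonzero(y[ipk:] < half)
    if seg.size:
        i = ipk + seg[0]
        right = t[i - 1] + (t[i] - t[i - 1]) * (half - y[i - 1]) / (y[i] - y[i - 1])
    else:
        truncated = True
    return float(right - left), float(t[ipk]), truncated


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    lo: float
    hi: float
    pre: bool  # pre-stimulus windows are closed on both sides

    @property
    def label(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"

        if self.pre:
            return f"[{fmt(self.lo)},{fmt(self.hi)}]"
        return f"({fmt(self.lo)},{fmt(self.hi)}]"

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.pre:
            return (t >= self.lo - 1e-9) & (t <= self.hi + 1e-9)
        return (t > self.lo + 1e-9) & (t <= self.hi + 1e-9)


@dataclass
class WindowSet:
    windows: list[Window]
    width_ms: float

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    @property
    def pre_labels(self) -> list[str]:
        return [w.label for w in self.windows if w.pre]


def segment_windows(
    crop_ms: tuple[float, float] = (-300.0, 1300.0), width_ms: float = 160.0
) -> WindowSet:
    """Consecutive width-ms windows anchored at stimulus onset (0 ms).

    Windows extend from 0 in both directions; any window not fully inside
    the crop is dropped.  Convention: pre-stimulus windows are closed
    ([lo, hi]), post-stimulus windows are lower-exclusive ((lo, hi]).
    """
    lo, hi = crop_ms
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    if not lo < 0 < hi:
        raise ValueError("crop must contain stimulus onset (0 ms)")
    windows: list[Window] = []
    j = 1
    while -j * width_ms >= lo - 1e-9:
        windows.insert(0, Window(-j * width_ms, -(j - 1) * width_ms, pre=True))
        j += 1
    k = 0
    while (k + 1) * width_ms <= hi + 1e-9:
        windows.append(Window(k * width_ms, (k + 1) * width_ms, pre=False))
        k += 1
    if not windows:
        raise ValueError("no full window fits inside the crop")
    return WindowSet(windows=windows, width_ms=width_ms)


def window_scores(
    scores: np.ndarray, times: np.ndarray, windows: WindowSet
) -> np.ndarray:
    """Mean of score timepoints falling in each window (stacked on a new
    trailing axis).  ``scores``: (..., n_times)."""
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    if scores.shape[-1] != t.size:
        raise ValueError("score time axis must match times")
    out = []
    for w in windows.windows:
        m = w.contains(t)
        if not m.any():
            raise ValueError(f"window {w.label} contains no timepoints")
        out.append(scores[..., m].mean(axis=-1))
    return np.stack(out, axis=-1)
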