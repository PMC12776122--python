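"""Paired t-tests and 2x2 within-subject ANOVAs on windowed component scores.

For a 2x2 within-subject design every ANOVA effect (two main effects and the
interaction) is exactly the squared paired t-test on the corresponding
within-participant contrast of cell means, with df = (1, n-1).  The
Huynh-Feldt sphericity correction is implemented generally but is trivially
1 for two-level factors.  Effect sizes: partial eta^2 = F / (F + df_error)
for single-df effects, Cohen's d = mean(diff) / SD(diff) = t / sqrt(n) for
paired contrasts.  Alpha defaults to 0.05, two-tailed throughout; no
multiple-testing correction is applied by default (a Benjamini-Hochberg
helper is provided but off by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

ALPHA = 0.05

STAT_COLUMNS = [
    "component", "window", "effect", "statistic", "stat_value", "df1", "df2",
    "p", "epsilon_hf", "eta_p2", "cohens_d", "significant",
]


# --------------------------------------------------------------------------
# array-level primitives (vectorized over leading axes)
# --------------------------------------------------------------------------

def paired_t(a, b, axis: int = -1) -> dict[str, np.ndarray]:
    """Classical paired t-test of a vs b along ``axis``.

    Returns dict with t, df, p (two-tailed), d (Cohen's d of the paired
    differences), and n.  Zero-variance differences give t = 0 (all-equal
    pairs) or signed infinity with p = 0 (constant nonzero shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have identical shapes")
    n = a.shape[axis]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    mean = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        cohens_d = mean / sd
    zero_sd = sd == 0
    if np.any(zero_sd):
        with np.errstate(invalid="ignore"):
            signed_inf = np.sign(mean) * np.inf
        t = np.where(zero_sd & (mean == 0), 0.0, t)
        t = np.where(zero_sd & (mean != 0), signed_inf, t)
        cohens_d = np.where(zero_sd & (mean == 0), 0.0, cohens_d)
        cohens_d = np.where(zero_sd & (mean != 0), signed_inf, cohens_d)
    df = n - 1
    p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    return {
        "t": t, "df": df, "p": p, "d": cohens_d, "n": n, "mean_diff": mean,
    }


def rm_anova_2x2(cells: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """2x2 repeated-measures ANOVA on cell means, via paired contrasts.

    ``cells`` has shape (..., n_participants, 2, 2): axis -2 is factor A
    (previous congruency), axis -1 factor B (current congruency).  Each
    effect's F equals the squared paired t on the corresponding contrast;
    df = (1, n-1); epsilon_HF = 1 (two-level factors satisfy sphericity).
    Vectorized over leading axes.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.shape[-2:] != (2, 2):
        raise ValueError("cells must have trailing shape (n, 2, 2)")
    n = cells.shape[-3]
    a_contrast = cells[..., 1, :].mean(axis=-1) - cells[..., 0, :].mean(axis=-1)
    b_contrast = cells[..., :, 1].mean(axis=-1) - cells[..., :, 0].mean(axis=-1)
    ab_contrast = (
        cells[..., 1, 1] - cells[..., 1, 0] - cells[..., 0, 1] + cells[..., 0, 0]
    )
    out = {}
    for name, contrast in (
        ("A", a_contrast), ("B", b_contrast), ("AxB", ab_contrast)
    ):
        r = paired_t(contrast, np.zeros_like(contrast), axis=-1)
        t = r["t"]
        F = t**2
        df_err = n - 1
        with np.errstate(invalid="ignore"):
            eta = np.where(np.isinf(F), 1.0, F / (F + df_err))
        out[name] = {
            "F": F, "t": t, "df1": 1, "df2": df_err, "p": r["p"],
            "eta_p2": eta, "epsilon_hf": np.ones_like(F), "n": n,
            "mean_contrast": r["mean_diff"],
        }
    return out


def hf_epsilon(data: np.ndarray) -> float:
    """Huynh-Feldt epsilon for a one-way repeated-measures design (n x k).

    Equals 1 (capped) for k = 2; kept general for reuse with multi-level
    factors.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least two levels")
    if k == 2:
        return 1.0
    centered = data - data.mean(axis=0)
    S = centered.T @ centered / (n - 1)
    # Greenhouse-Geisser epsilon from the double-centered covariance
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        (S**2).sum() - 2 * k * (row_means**2).sum() + k**2 * grand**2
    )
    gg = num / den
    hf = (n * (k - 1) * gg - 2) / ((k - 1) * (n - 1 - (k - 1) * gg))
    return float(min(1.0, hf))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# --------------------------------------------------------------------------
# table-level wrappers
# --------------------------------------------------------------------------

def _row(
    component, window, effect, statistic, value, df1, df2, p, eps, eta, d,
    alpha=ALPHA,
) -> dict:
    return {
        "component": component, "window": window, "effect": effect,
        "statistic": statistic, "stat_value": float(value),
        "df1": df1, "df2": df2, "p": float(p),
        "epsilon_hf": eps, "eta_p2": eta, "cohens_d": d,
        "significant": bool(p < alpha),
    }


def rm_anova_2x2_table(
    cells: np.ndarray,
    component: str = "",
    window: str = "",
    factor_a: str = "prev",
    factor_b: str = "curr",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """StatTable (one row per effect) for a single 2x2 design."""
    res = rm_anova_2x2(cells)
    rows = []
    for key, label in (
        ("A", factor_a), ("B", factor_b), ("AxB", f"{factor_a} x {factor_b}")
    ):
        r = res[key]
        rows.append(
            _row(
                component, window, label, "F", r["F"], r["df1"], r["df2"],
                r["p"], 1.0, float(r["eta_p2"]), np.nan, alpha,
            )
        )
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def _paired_row(component, window, effect, a, b, alpha=ALPHA) -> dict:
    r = paired_t(a, b)
    return _row(
        component, window, effect, "t", r["t"], r["df"], np.nan, r["p"],
        1.0, np.nan, float(r["d"]), alpha,
    )


def simple_effects_table(
    cells: np.ndarray, component: str = "", window: str = "", alpha: float = ALPHA
) -> pd.DataFrame:
    """The four follow-up simple-effect paired t-tests of a 2x2 design:
    the previous-congruency effect within each current level, and the
    current-congruency effect within each previous level."""
    cells = np.asarray(cells, dtype=float)
    rows = [
        _paired_row(
            component, window, "prev effect | current congruent",
            cells[:, 1, 0], cells[:, 0, 0], alpha,
        ),
        _paired_row(
            component, window, "prev effect | current incongruent",
            cells[:, 1, 1], cells[:, 0, 1], alpha,
        ),
        _paired_row(
            component, window, "curr effect | previous congruent",
            cells[:, 0, 1], cells[:, 0, 0], alpha,
        ),
        _paired_row(
            component, window, "curr effect | previous incongruent",
            cells[:, 1, 1], cells[:, 1, 0], alpha,
        ),
    ]
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def _score_cells(window_scores: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "component", "prev", "curr", "window", "score"}
    missing = required - set(window_scores.columns)
    if missing:
        raise ValueError(f"windowed scores missing columns: {sorted(missing)}")
    return window_scores


def baseline_contrast_table(
    window_scores: pd.DataFrame, pre_window: str | None = None, alpha: float = ALPHA
) -> pd.DataFrame:
    """Paired t of each post-stimulus window against the pre-stimulus window,
    on condition-averaged scores, per component (global stimulus-induced
    change, independent of condition)."""
    df = _score_cells(window_scores)
    windows = list(pd.unique(df["window"]))
    if pre_window is None:
        pre = [w for w in windows if str(w).startswith("[")]
        if not pre:
            raise ValueError("no pre-stimulus window in the windowed scores")
        pre_window = pre[0]
    elif pre_window not in windows:
        raise ValueError(f"pre-stimulus window {pre_window!r} not present")
    post_windows = [w for w in windows if w != pre_window]
    cond_avg = (
        df.groupby(["participant", "component", "window"])["score"]
        .mean()
        .unstack("window")
    )
    rows = []
    for comp, sub in cond_avg.groupby(level="component"):
        pre_vals = sub[pre_window].values
        for w in post_windows:
            rows.append(
                _paired_row(comp, w, "post vs pre", sub[w].values, pre_vals, alpha)
            )
    table = pd.DataFrame(rows, columns=STAT_COLUMNS)
    if not post_windows:
        import warnings

        warnings.warn("no post-stimulus windows; empty baseline table", stacklevel=2)
    return table


def congruency_table(
    window_scores: pd.DataFrame,
    alpha: float = ALPHA,
    gate_followups: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per component x window 2x2 ANOVA (previous x current congruency) with
    follow-up simple effects where the interaction is significant.

    Returns (anova_table, followup_table).  ``gate_followups=False`` emits
    follow-ups for every window (exploration mode).
    """
    df = _score_cells(window_scores)
    wide = df.pivot_table(
        index=["participant"],
        columns=["component", "window", "prev", "curr"],
        values="score",
    )
    anova_rows, follow_rows = [], []
    components = list(pd.unique(df["component"]))
    windows = list(pd.unique(df["window"]))
    for comp in components:
        for w in windows:
            try:
                block = np.stack(
                    [
                        np.stack(
                            [wide[(comp, w, "congruent", "congruent")].values,
                             wide[(comp, w, "congruent", "incongruent")].values],
                            axis=-1,
                        ),
                        np.stack(
                            [wide[(comp, w, "incongruent", "congruent")].values,
                             wide[(comp, w, "incongruent", "incongruent")].values],
                            axis=-1,
                        ),
                    ],
                    axis=-2,
                )
            except KeyError as exc:
                raise ValueError(
                    f"missing condition cell for component {comp!r}, window {w!r}"
                ) from exc
            ok = ~np.isnan(block).any(axis=(1, 2))
            block = block[ok]
            tab = rm_anova_2x2_table(
                block, component=comp, window=w, factor_a="PC", factor_b="CC",
                alpha=alpha,
            )
            anova_rows.append(tab)
            interaction_p = tab.loc[tab["effect"] == "PC x CC", "p"].iloc[0]
            if (not gate_followups) or interaction_p < alpha:
                follow_rows.append(
                    simple_effects_table(block, component=comp, window=w, alpha=alpha)
                )
    anova = pd.concat(anova_rows, ignore_index=True)
    followups = (
        pd.concat(follow_rows, ignore_index=True)
        if follow_rows
        else pd.DataFrame(columns=STAT_COLUMNS)
    )
    return anova, followups
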