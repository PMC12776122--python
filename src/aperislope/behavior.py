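"""Trial exclusion rules and the CE/CSE behavioral analysis.

Exclusion policy: accuracy analyses drop practice trials and the first trial
of each block; RT and EEG analyses additionally drop error trials, trials
following an error, and trials whose RT deviates more than 2.5 SD from the
participant's mean.  The outlier bounds are computed once per participant,
over all blocks pooled, on the trials that survive the other exclusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as ap_stats

PURPOSES = ("accuracy", "rt", "eeg")
EXCLUSION_REASONS = (
    "practice", "first_of_block", "error", "post_error", "rt_outlier"
)


@dataclass
class FilterResult:
    trials: pd.DataFrame
    counts: dict[str, int]
    flagged_participants: list[int]


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the TrialTable invariants (lag-1 consistency, RT positivity)."""
    for (_, _), blk in trials.groupby(["participant", "block"]):
        if not blk["trial_index"].is_monotonic_increasing:
            raise ValueError("trial_index must increase within participant x block")
        prev = blk["prev_congruency"].iloc[1:].values
        curr = blk["curr_congruency"].iloc[:-1].values
        if not (prev == curr).all():
            raise ValueError(
                "prev_congruency must equal the preceding trial's curr_congruency"
            )
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("rt_ms must be positive for responded trials")


def filter_trials(
    trials: pd.DataFrame, purpose: str = "rt", sd_criterion: float = 2.5
) -> FilterResult:
    """Apply the exclusion rules for a given analysis purpose.

    Rows are removed in rule order (practice, first-of-block, error,
    post-error, RT outlier); ``counts`` records how many rows each reason
    removed, summing to the total removed.  Participants left with fewer
    than 2 retained trials are flagged and should be dropped from downstream
    statistics.
    """
    if purpose not in PURPOSES:
        raise ValueError(f"unknown purpose {purpose!r}; expected one of {PURPOSES}")
    df = trials.copy()
    counts = dict.fromkeys(EXCLUSION_REASONS, 0)

    mask = df["is_practice"].astype(bool)
    counts["practice"] = int(mask.sum())
    df = df[~mask]

    mask = df["is_first_of_block"].astype(bool)
    counts["first_of_block"] = int(mask.sum())
    df = df[~mask]

    if purpose in ("rt", "eeg"):
        mask = ~df["correct"].astype(bool)
        counts["error"] = int(mask.sum())
        # post-error: the trial immediately following an error within a block,
        # evaluated on the original sequence (before any removal)
        post = (
            df.groupby(["participant", "block"])["correct"]
            .transform(lambda s: ~s.shift(1, fill_value=True).astype(bool))
            .astype(bool)
        )
        counts["post_error"] = int((post & ~mask).sum())
        df = df[~mask & ~post]

        def _outlier(rt: pd.Series) -> pd.Series:
            mu, sd = rt.mean(), rt.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                return pd.Series(False, index=rt.index)
            return (rt - mu).abs() > sd_criterion * sd

        mask = df.groupby("participant")["rt_ms"].transform(_outlier).astype(bool)
        counts["rt_outlier"] = int(mask.sum())
        df = df[~mask]

    flagged = [
        int(p) for p, n in df.groupby("participant").size().items() if n < 2
    ]
    for p in set(trials["participant"]) - set(df["participant"]):
        flagged.append(int(p))
    if flagged:
        warnings.warn(
            f"participants with < 2 retained trials: {sorted(flagged)}",
            stacklevel=2,
        )
    return FilterResult(trials=df, counts=counts, flagged_participants=sorted(flagged))


def cell_means(
    trials: pd.DataFrame, dv: str = "rt"
) -> pd.DataFrame:
    """Per-participant Previous x Current cell means of RT (ms) or accuracy (%)."""
    df = trials.copy()
    if dv == "rt":
        df["value"] = df["rt_ms"]
    elif dv == "accuracy":
        df["value"] = df["correct"].astype(float) * 100.0
    else:
        raise ValueError("dv must be 'rt' or 'accuracy'")
    out = (
        df.groupby(["participant", "prev_congruency", "curr_congruency"])["value"]
        .mean()
        .reset_index()
    )
    return out


def behavioral_anova(trials: pd.DataFrame, dv: str = "rt"):
    """2x2 within-subject ANOVA on per-participant cell means, plus the four
    simple-effect paired t-tests.

    RT uses the RT-purpose filtered table; accuracy the accuracy-purpose one.
    Participants missing any of the four cells are dropped with a warning.
    Returns (anova StatTable, follow-up StatTable).
    """
    means = cell_means(trials, dv=dv)
    wide = means.pivot_table(
        index="participant",
        columns=["prev_congruency", "curr_congruency"],
        values="value",
    )
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"participants dropped for incomplete cells: {dropped}", stacklevel=2
        )
    cells = np.stack(
        [
            np.stack(
                [complete[("congruent", "congruent")].values,
                 complete[("congruent", "incongruent")].values], axis=-1
            ),
            np.stack(
                [complete[("incongruent", "congruent")].values,
                 complete[("incongruent", "incongruent")].values], axis=-1
            ),
        ],
        axis=-2,
    )  # (n, prev, curr)
    anova = ap_stats.rm_anova_2x2_table(
        cells, factor_a="prev_congruency", factor_b="curr_congruency"
    )
    followups = ap_stats.simple_effects_table(cells)
    return anova, followups
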