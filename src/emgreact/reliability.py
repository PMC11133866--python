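"""Internal consistency and channel-independence checks.

Per-participant Cronbach's alpha treats the 16 time points of an epoch as
items and trials as observations, quantifying how stable a participant's
temporal profile is from trial to trial. Participant alphas are averaged
via Fisher's r-to-z transform. Channel independence tests whether the two
muscles' overall percent-change levels correlate across participants —
the two-dimensional affective-space analysis assumes they do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_ATANH_CLAMP = 0.999999


def cronbach_alpha(matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an observations x items matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(item sums)),
    with k the number of items. Missing entries are handled through the
    pairwise-complete covariance matrix (the total-score variance is then
    the sum of all covariance entries). Returns NaN with a warning-level
    condition if the total variance is zero.
    """
    df = pd.DataFrame(matrix)
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("cronbach_alpha requires >= 2 items and >= 2 observations")
    cov = df.cov()  # pairwise-complete by construction
    total_var = float(cov.to_numpy().sum())
    if not np.isfinite(total_var) or total_var == 0:
        return float("nan")
    k = df.shape[1]
    item_var = float(np.trace(cov.to_numpy()))
    return k / (k - 1) * (1.0 - item_var / total_var)


@dataclass(frozen=True)
class AlphaSummary:
    per_participant: pd.Series
    mean_alpha: float
    min_alpha: float
    max_alpha: float


def summarize_alpha(alphas: Iterable[float]) -> AlphaSummary:
    """Fisher-z average of per-participant alphas.

    mean = tanh(mean(atanh(alpha))) with alphas clamped into
    (-0.999999, 0.999999) before the transform; min/max are reported on
    the raw values (negative alphas are kept, not truncated).
    """
    series = pd.Series(list(alphas), dtype=float).dropna()
    if series.empty:
        raise ValueError("summarize_alpha: no finite alphas")
    clamped = series.clip(-_ATANH_CLAMP, _ATANH_CLAMP)
    mean = float(np.tanh(np.arctanh(clamped).mean()))
    return AlphaSummary(
        per_participant=series,
        mean_alpha=mean,
        min_alpha=float(series.min()),
        max_alpha=float(series.max()),
    )


def _per_participant_alpha(
    long: pd.DataFrame, value_col: str, items: str = "time"
) -> pd.Series:
    """``items='time'``: the 16 time points are items, trials the
    observations (the default orientation); ``items='trials'`` swaps
    them."""
    if items not in ("time", "trials"):
        raise ValueError("items must be 'time' or 'trials'")
    out = {}
    for participant, grp in long.groupby("participant", sort=True):
        wide = grp.pivot_table(
            index=["condition", "trial"], columns="bin", values=value_col, sort=True
        )
        if items == "trials":
            wide = wide.T
        if wide.shape[0] < 2 or wide.shape[1] < 2:
            out[participant] = np.nan
            continue
        out[participant] = cronbach_alpha(wide)
    return pd.Series(out, name="alpha")


def baseline_alpha(
    baseline_bins: pd.DataFrame,
    muscle: str,
    items: str = "time",
    units: str = "uv",
) -> AlphaSummary:
    """Baseline stability: alpha over all trials' 16 baseline bin means.

    ``baseline_bins`` is the long table from
    :func:`emgreact.preprocess.baseline_bin_table`; all conditions'
    trials pool into one consistency matrix per participant (45 rows in
    the full design). Computed on the microvolt scale by default;
    ``units='percent'`` rescales to percent of the participant's overall
    baseline level. Note that percent relative to each trial's *own*
    mean would be vacuous (every trial sums to the same total), and
    alpha is invariant to a per-participant rescaling, so the two unit
    choices offered here give identical consistency values — which is
    why the microvolt default is safe.
    """
    sub = baseline_bins[baseline_bins["muscle"] == muscle]
    if units == "percent":
        sub = sub.copy()
        level = sub.groupby("participant")["value_uv"].transform("mean")
        sub["value_uv"] = 100.0 * sub["value_uv"] / level
    elif units != "uv":
        raise ValueError("units must be 'uv' or 'percent'")
    return summarize_alpha(_per_participant_alpha(sub, "value_uv", items=items))


def noreg_alpha(
    trial_scores: pd.DataFrame,
    muscle: str,
    condition: str = "no_regulation",
    items: str = "time",
) -> AlphaSummary:
    """Response stability under no regulation: alpha over the 15
    no-regulation trials' percent-change profiles."""
    sub = trial_scores[
        (trial_scores["muscle"] == muscle) & (trial_scores["condition"] == condition)
    ]
    return summarize_alpha(_per_participant_alpha(sub, "score", items=items))


@dataclass(frozen=True)
class IndependenceReport:
    r: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    n: int


def channel_independence(
    cells: pd.DataFrame, muscles: Sequence[str] = ("corrugator", "zygomaticus")
) -> IndependenceReport:
    """Correlation between the muscles' grand-average reactivity.

    Each participant's scores are averaged into one value per muscle
    (across all conditions and bins); the Pearson correlation across
    participants, its t statistic (df = n - 2) and Fisher 95% CI are
    reported. A non-significant r supports treating the channels as
    independent affective dimensions.
    """
    per = (
        cells.groupby(["participant", "muscle"], sort=True)["score"]
        .mean()
        .unstack("muscle")
        .dropna(subset=list(muscles))
    )
    n = len(per)
    if n < 3:
        raise ValueError("channel_independence requires >= 3 participants with both muscles")
    x, y = per[muscles[0]].to_numpy(), per[muscles[1]].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("channel_independence: constant muscle vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r**2))
    ci = res.confidence_interval(0.95)
    return IndependenceReport(
        r=r, t=float(t), df=df, p=float(res.pvalue),
        ci_low=float(ci.low), ci_high=float(ci.high), n=n,
    )
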