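"""Per-bin condition contrasts with effect sizes and within-subject CIs.

Every comparison between two instruction conditions is a dependent-samples
t-test at each of the 16 time bins, with Cohen's dz (mean of paired
differences over their SD) and a normal-approximation 95% CI, under a
Bonferroni-adjusted per-test level (0.05/16 = 0.003125 by default).
Group time courses carry Cousineau-Morey within-subject confidence
intervals: scores are centred on each participant's cross-condition mean
(plus the grand mean) and the half-width is inflated by the Morey factor
sqrt(J/(J-1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import BIN_WIDTH_MS, CONDITIONS, N_BINS
from .synth import load_group_means


def bonferroni_threshold(family_alpha: float = 0.05, m: int = N_BINS) -> float:
    """Per-test significance level controlling the family-wise rate."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def cell_scores(cells: pd.DataFrame, condition: str, muscle: str, bin: int) -> pd.Series:
    """Per-participant scores for one condition x muscle x bin."""
    sub = cells[
        (cells["condition"] == condition)
        & (cells["muscle"] == muscle)
        & (cells["bin"] == bin)
    ]
    return sub.set_index("participant")["score"].sort_index()


def _paired(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
        return joined["a"].to_numpy(), joined["b"].to_numpy()
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    t: float
    df: int
    p: float
    n: int


def paired_t(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> PairedTResult:
    """Dependent-samples t-test on paired per-participant scores.

    Pairs with a missing value on either side are dropped (pairwise
    deletion); two-sided p with df = n_pairs - 1.
    """
    x, y = _paired(a, b)
    n = x.size
    if n < 3:
        raise ValueError("paired_t requires >= 3 complete pairs")
    diff = x - y
    if diff.std(ddof=1) == 0:
        # degenerate case: identical pairs carry no evidence either way
        t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf * np.sign(diff.mean()), 0.0)
    else:
        res = stats.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
    return PairedTResult(mean_diff=float(diff.mean()), t=t, df=n - 1, p=p, n=n)


@dataclass(frozen=True)
class CohensDResult:
    d: float
    ci_low: float
    ci_high: float
    n: int


def cohens_d_paired(
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
    ci_level: float = 0.95,
    variant: str = "dz",
) -> CohensDResult:
    """Cohen's d for paired data with a normal-approximation CI.

    The default ``dz`` = mean(diff) / sd(diff) standardises by the
    paired-difference SD, consistent with the dependent-samples t-test;
    ``dav`` standardises by the average of the two condition SDs instead.
    Var(d) is approximated by 1/n + d^2/(2n) in both cases.
    """
    x, y = _paired(a, b)
    n = x.size
    if n < 3:
        raise ValueError("cohens_d_paired requires >= 3 complete pairs")
    diff = x - y
    if variant == "dz":
        sd = diff.std(ddof=1)
    elif variant == "dav":
        sd = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'dz' or 'dav'")
    if sd == 0:
        raise ValueError("cohens_d_paired: zero SD of differences")
    d = float(diff.mean() / sd)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(1.0 / n + d**2 / (2.0 * n))
    return CohensDResult(d=d, ci_low=d - z * se, ci_high=d + z * se, n=n)


def cousineau_morey_ci(
    cells: pd.DataFrame,
    muscle: str,
    bin: int,
    conditions: Sequence[str] = CONDITIONS,
    ci_level: float = 0.95,
) -> Dict[str, float]:
    """Within-subject CI half-widths for each condition at one bin.

    Only participants observed in all J conditions at this bin enter.
    Each score is normalised by subtracting the participant's
    cross-condition mean and adding the grand mean; the half-width is
    t(1-(1-level)/2, n-1) * SD(normalised)/sqrt(n) * sqrt(J/(J-1)).
    """
    J = len(conditions)
    if J < 2:
        raise ValueError("cousineau_morey_ci requires >= 2 conditions")
    sub = cells[
        (cells["muscle"] == muscle)
        & (cells["bin"] == bin)
        & (cells["condition"].isin(conditions))
    ]
    wide = sub.pivot_table(index="participant", columns="condition", values="score", sort=True)
    wide = wide.reindex(columns=list(conditions)).dropna()
    n = len(wide)
    if n < 2:
        raise ValueError("cousineau_morey_ci: need >= 2 complete participants")
    vals = wide.to_numpy()
    normalised = vals - vals.mean(axis=1, keepdims=True) + vals.mean()
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
    morey = np.sqrt(J / (J - 1))
    half = tcrit * normalised.std(axis=0, ddof=1) / np.sqrt(n) * morey
    return dict(zip(conditions, half.astype(float)))


def group_time_course(
    cells: pd.DataFrame,
    conditions: Sequence[str] = CONDITIONS,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per condition x muscle x bin: group mean, SD and within-subject CI.

    Mirrors the descriptive rows of a per-bin group summary table.
    """
    rows = []
    for muscle in sorted(cells["muscle"].unique()):
        ci_by_bin = {
            b: cousineau_morey_ci(cells, muscle, b, conditions, ci_level)
            for b in sorted(cells["bin"].unique())
        }
        for condition in conditions:
            sub = cells[(cells["muscle"] == muscle) & (cells["condition"] == condition)]
            agg = sub.groupby("bin")["score"].agg(["mean", "std"]).reset_index()
            for _, row in agg.iterrows():
                b = int(row["bin"])
                rows.append(
                    {
                        "condition": condition,
                        "muscle": muscle,
                        "bin": b,
                        "time_ms": b * BIN_WIDTH_MS,
                        "mean": row["mean"],
                        "sd": row["std"],
                        "ci_halfwidth": ci_by_bin[b][condition],
                    }
                )
    return pd.DataFrame(rows)


def contrast_table(
    cells: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    muscle: str,
    family_alpha: float = 0.05,
    m: int = N_BINS,
) -> pd.DataFrame:
    """Full per-bin contrast (A - B) for one condition pair and muscle.

    Columns: bin, time_ms, mean_diff, t, df, p, d, d_ci_low, d_ci_high,
    n_pairs, significant (Bonferroni-adjusted level family_alpha/m).
    """
    alpha_adj = bonferroni_threshold(family_alpha, m)
    rows = []
    for b in range(1, N_BINS + 1):
        a = cell_scores(cells, cond_a, muscle, b)
        bb = cell_scores(cells, cond_b, muscle, b)
        tt = paired_t(a, bb)
        dd = cohens_d_paired(a, bb)
        rows.append(
            {
                "bin": b,
                "time_ms": b * BIN_WIDTH_MS,
                "mean_diff": tt.mean_diff,
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "d": dd.d,
                "d_ci_low": dd.ci_low,
                "d_ci_high": dd.ci_high,
                "n_pairs": tt.n,
                "significant": tt.p < alpha_adj,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["pair"] = (cond_a, cond_b)
    out.attrs["muscle"] = muscle
    out.attrs["alpha_adjusted"] = alpha_adj
    return out


@dataclass(frozen=True)
class OnsetSummary:
    first_significant_bin: Optional[int]
    first_significant_ms: Optional[int]
    peak_bin: int
    peak_ms: int
    peak_difference: float


def contrast_summary(table: pd.DataFrame) -> OnsetSummary:
    """Onset (earliest significant bin) and peak differentiation.

    The peak is the bin with the largest |Cohen's d| (ties break toward
    the earlier bin): effect size, not raw mean difference, is what the
    per-bin SDs make comparable across bins. If the table carries no
    usable ``d`` column the |mean difference| is used instead.
    ``peak_difference`` reports the mean difference (percentage points)
    at the peak bin.
    """
    sig = table[table["significant"]]
    first = int(sig["bin"].iloc[0]) if not sig.empty else None
    metric = "d" if "d" in table.columns and table["d"].notna().all() else "mean_diff"
    peak_idx = table[metric].abs().round(9).idxmax()  # idxmax: first occurrence
    peak_bin = int(table.loc[peak_idx, "bin"])
    return OnsetSummary(
        first_significant_bin=first,
        first_significant_ms=None if first is None else first * BIN_WIDTH_MS,
        peak_bin=peak_bin,
        peak_ms=peak_bin * BIN_WIDTH_MS,
        peak_difference=float(table.loc[peak_idx, "mean_diff"]),
    )


def printed_mean_difference(
    pair: Tuple[str, str],
    muscle: str,
    time_ms: int,
    means: Optional[pd.DataFrame] = None,
) -> float:
    """Difference of packaged group means (A - B) at one time point.

    Reported to one decimal, matching the precision of the packaged
    fixture tables. ``means`` defaults to the packaged fixture for the
    muscle.
    """
    df = means if means is not None else load_group_means(muscle)
    sub = df[df["time_ms"] == time_ms]
    if sub.empty:
        raise KeyError(f"unknown time point {time_ms} ms")
    a = sub.loc[sub["condition"] == pair[0], "mean"].item()
    b = sub.loc[sub["condition"] == pair[1], "mean"].item()
    return round(a - b, 1)


def printed_contrast_course(pair: Tuple[str, str], muscle: str) -> pd.DataFrame:
    """Fixture-driven contrast course: per-bin printed mean differences
    and effect sizes for one condition pair and muscle.

    Columns bin, time_ms, mean_diff, d, significant (the last always
    False: the packaged fixtures carry no p-values). Suitable input for
    :func:`contrast_summary`.
    """
    import importlib.resources

    resource = importlib.resources.files("emgreact.data") / "group_effect_sizes.tsv"
    with importlib.resources.as_file(resource) as path:
        es = pd.read_csv(path, sep="\t")
    sub = es[(es["muscle"] == muscle) & (es["cond_a"] == pair[0]) & (es["cond_b"] == pair[1])]
    if sub.empty:
        # the fixture stores each pair once; the reverse order negates d
        rev = es[(es["muscle"] == muscle) & (es["cond_a"] == pair[1]) & (es["cond_b"] == pair[0])]
        if rev.empty:
            raise KeyError(f"no packaged effect sizes for {pair} / {muscle}")
        sub = rev.assign(d=-rev["d"])
    diffs = mean_difference_course(pair, muscle)
    out = sub.sort_values("bin")[["bin", "time_ms", "d"]].reset_index(drop=True)
    out["mean_diff"] = diffs.to_numpy()
    out["significant"] = False
    return out[["bin", "time_ms", "mean_diff", "d", "significant"]]


def mean_difference_course(
    pair: Tuple[str, str], muscle: str, means: Optional[pd.DataFrame] = None
) -> pd.Series:
    """Per-bin differences of packaged group means (A - B), indexed by ms."""
    df = means if means is not None else load_group_means(muscle)
    wide = df.pivot_table(index="time_ms", columns="condition", values="mean", sort=True)
    return (wide[pair[0]] - wide[pair[1]]).round(1)
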