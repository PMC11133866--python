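"""Signal conditioning and data reduction for trial-level facial EMG.

Two entry levels:

* raw 1,000-Hz records: :func:`condition_signal` (60-Hz notch, 20-499-Hz
  bandpass, full-wave rectification, 10-ms running average — in that
  order, all filters applied zero-phase) then :func:`bin_epoch`;
* binned trials: :func:`censor_outlier_bins` (within-trial 2.5-SD rule,
  single pass, strict inequality), :func:`percent_change` against the
  trial's mean pre-stimulus baseline, and :func:`aggregate_cells` to
  per-participant reactivity cells.

:func:`preprocess_table` runs the binned chain on the long-format table
emitted by :mod:`emgreact.synth` (or any table with the same columns) and
is fully vectorised.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .design import N_BINS

logger = logging.getLogger(__name__)

# The nominal 20-500 Hz passband is clamped below the 1,000-Hz Nyquist
# edge; a digital bandpass cannot reach Nyquist itself.
BANDPASS_LOW_HZ = 20.0
BANDPASS_HIGH_HZ = 499.0
NOTCH_HZ = 60.0
NOTCH_Q = 30.0
FILTER_ORDER = 4
SMOOTH_MS = 10

#: Metadata describing the fixed filter realisation, recorded in outputs.
FILTER_SPEC = {
    "notch_hz": NOTCH_HZ,
    "notch_q": NOTCH_Q,
    "bandpass_hz": [BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ],
    "bandpass_order": FILTER_ORDER,
    "application": "zero-phase (filtfilt)",
    "smoothing_ms": SMOOTH_MS,
}

_MIN_SAMPLES = 100  # filtfilt padding needs headroom beyond 3x filter length


def _check_length(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError(f"{what} expects a 1-D signal")
    if x.size < _MIN_SAMPLES:
        raise ValueError(
            f"{what}: record of {x.size} samples is shorter than the filter "
            f"warm-up ({_MIN_SAMPLES} samples)"
        )
    return x


def notch_filter(x: np.ndarray, fs: float = 1000.0, freq: float = NOTCH_HZ, q: float = NOTCH_Q) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency."""
    x = _check_length(x, "notch_filter")
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, x)


def bandpass_filter(
    x: np.ndarray,
    fs: float = 1000.0,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (EMG band)."""
    x = _check_length(x, "bandpass_filter")
    high = min(high, 0.499 * fs)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def rectify_and_smooth(x: np.ndarray, fs: float = 1000.0, window_ms: float = SMOOTH_MS) -> np.ndarray:
    """Full-wave rectification followed by a centred running average."""
    x = np.abs(np.asarray(x, float))
    window = max(int(round(window_ms * fs / 1000.0)), 1)
    return uniform_filter1d(x, size=window, mode="nearest")


def condition_signal(x: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Full conditioning chain: notch -> bandpass -> rectify -> smooth."""
    x = _check_length(x, "condition_signal")
    return rectify_and_smooth(bandpass_filter(notch_filter(x, fs=fs), fs=fs), fs=fs)


def bin_epoch(
    x: np.ndarray,
    fs: float = 1000.0,
    epoch_ms: int = 8000,
    bin_width_ms: int = 500,
    trial: str | None = None,
) -> np.ndarray:
    """Mean of consecutive half-open ``bin_width_ms`` windows over an epoch.

    The record must span the epoch exactly (e.g. 8,000 samples at 1 kHz
    for an 8,000-ms epoch with 16 bins).
    """
    x = np.asarray(x, float)
    expected = int(round(epoch_ms * fs / 1000.0))
    if x.size != expected:
        who = f" (trial {trial})" if trial else ""
        raise ValueError(
            f"bin_epoch: epoch must span exactly {expected} samples, got {x.size}{who}"
        )
    n_bins = epoch_ms // bin_width_ms
    return x.reshape(n_bins, -1).mean(axis=1)


def censor_outlier_bins(values: np.ndarray, k: float = 2.5) -> np.ndarray:
    """Within-trial outlier censoring: bins beyond ``k`` SDs set to NaN.

    Mean and SD are computed over the non-missing bins of this one
    trial-epoch vector; the rule is applied in a single pass with a strict
    inequality, so values exactly at mean +/- k*SD survive. If the SD is
    zero nothing is censored.
    """
    values = np.asarray(values, float).copy()
    present = np.isfinite(values)
    if present.sum() < 3:
        raise ValueError("censor_outlier_bins requires >= 3 non-missing bins")
    m = values[present].mean()
    sd = values[present].std(ddof=1)
    if sd == 0:
        logger.warning("censor_outlier_bins: zero SD, nothing censored")
        return values
    out = present & (np.abs(values - m) > k * sd)
    values[out] = np.nan
    return values


def percent_change(regulation: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Percent-of-baseline scores: 100 x bin / mean(non-missing baseline).

    100 means no change from the pre-stimulus level. Missing regulation
    bins stay missing.
    """
    regulation = np.asarray(regulation, float)
    baseline = np.asarray(baseline, float)
    present = np.isfinite(baseline)
    if present.sum() < 1:
        raise ValueError("percent_change: baseline has no non-missing bins")
    base = baseline[present].mean()
    if base <= 0:
        raise ValueError(f"percent_change: non-positive baseline mean ({base:.3g})")
    return 100.0 * regulation / base


def _pivot_epoch(df: pd.DataFrame, epoch: str) -> Tuple[pd.DataFrame, np.ndarray]:
    sub = df[df["epoch"] == epoch]
    wide = sub.pivot_table(
        index=["participant", "condition", "trial", "muscle"],
        columns="bin",
        values="value_uv",
        sort=True,
    ).reindex(columns=range(1, N_BINS + 1))
    values = wide.to_numpy()
    if "is_missing" in sub.columns and sub["is_missing"].any():
        miss = (
            sub.pivot_table(
                index=["participant", "condition", "trial", "muscle"],
                columns="bin",
                values="is_missing",
                aggfunc="any",
                sort=True,
            )
            .reindex(index=wide.index, columns=range(1, N_BINS + 1))
            .to_numpy()
        )
        values = np.where(miss.astype(bool), np.nan, values)
    return wide, values


def _censor_rows(values: np.ndarray, k: float) -> np.ndarray:
    """Vectorised single-pass 2.5-SD rule, one row per trial-epoch."""
    present = np.isfinite(values)
    n = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(invalid="ignore"):  # k=inf with sd=0 rows
        out = present & (np.abs(values - m[:, None]) > k * sd[:, None]) & (sd[:, None] > 0)
    out[n < 3] = False  # too few bins to judge; leave untouched
    censored = values.copy()
    censored[out] = np.nan
    return censored


def trial_percent_change_table(
    table: pd.DataFrame,
    outlier_k: float = 2.5,
    censor_baseline: bool = True,
) -> pd.DataFrame:
    """Per-trial percent-of-baseline scores from a long binned table.

    Applies within-trial outlier censoring to the regulation epoch (and,
    by default, the baseline epoch too) before dividing by the trial's
    mean baseline. Trials with a non-positive baseline mean are dropped
    with a logged warning. Returns a long table (participant, condition,
    trial, muscle, bin, score).
    """
    reg_wide, reg = _pivot_epoch(table, "regulation")
    base_wide, base = _pivot_epoch(table, "baseline")
    if not reg_wide.index.equals(base_wide.index):
        base = (
            pd.DataFrame(base, index=base_wide.index).reindex(reg_wide.index).to_numpy()
        )

    reg = _censor_rows(reg, outlier_k)
    if censor_baseline:
        base = _censor_rows(base, outlier_k)

    base_mean = np.nanmean(base, axis=1)
    ok = np.isfinite(base_mean) & (base_mean > 0)
    if not ok.all():
        logger.warning(
            "trial_percent_change_table: dropped %d trials with non-positive baseline",
            int((~ok).sum()),
        )
    scores = 100.0 * reg / base_mean[:, None]
    scores[~ok] = np.nan

    out = pd.DataFrame(scores, index=reg_wide.index, columns=range(1, N_BINS + 1))
    out = out.stack(future_stack=True).rename("score").reset_index()
    out.columns = ["participant", "condition", "trial", "muscle", "bin", "score"]
    return out


def aggregate_cells(trial_scores: pd.DataFrame) -> pd.DataFrame:
    """Average trial scores into participant x condition x muscle cells.

    A bin is missing only if it is missing in every contributing trial;
    ``n_trials`` records how many trials entered each bin mean.
    """
    grouped = trial_scores.groupby(
        ["participant", "condition", "muscle", "bin"], sort=True
    )["score"]
    cells = grouped.agg(score="mean", n_trials="count").reset_index()
    return cells


def baseline_bin_table(
    table: pd.DataFrame, outlier_k: float = 2.5, censor: bool = True
) -> pd.DataFrame:
    """Censored baseline bin means (uV) per trial, long format.

    Used by the reliability analyses, which assess baseline stability on
    the microvolt scale (percent change is 100 at baseline by
    construction).
    """
    base_wide, base = _pivot_epoch(table, "baseline")
    if censor:
        base = _censor_rows(base, outlier_k)
    out = pd.DataFrame(base, index=base_wide.index, columns=range(1, N_BINS + 1))
    out = out.stack(future_stack=True).rename("value_uv").reset_index()
    out.columns = ["participant", "condition", "trial", "muscle", "bin", "value_uv"]
    return out


def preprocess_table(
    table: pd.DataFrame,
    outlier_k: float = 2.5,
    censor_baseline: bool = True,
) -> pd.DataFrame:
    """Full binned-data reduction: censor, percent change, aggregate.

    Returns the cells table (participant, condition, muscle, bin, score,
    n_trials) consumed by the reliability/contrast/trajectory stages.
    """
    trial_scores = trial_percent_change_table(
        table, outlier_k=outlier_k, censor_baseline=censor_baseline
    )
    return aggregate_cells(trial_scores)
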