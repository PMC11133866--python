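"""Synthetic trial-level facial-EMG data with known generating structure.

The generator emulates the repeated-measures layout the analysis modules
expect: participants x conditions x trials x muscles, each trial carrying a
baseline and a regulation epoch of 16 500-ms bins. Regulation activity is
generated directly on the percent-of-baseline scale from per-condition
templates (defaults are the printed group means/SDs packaged as fixtures)
and converted to microvolts against each trial's own baseline level, so the
preprocessing chain recovers the latent percent-change scores exactly in
the noise-free limit.

Variance components
-------------------
* participant offset: one normal deviate per participant x condition x
  muscle, scaled per bin so the across-participant SD of cell means
  matches the template's ``between_participant_sd`` (the trial-average
  noise contribution is subtracted in quadrature);
* trial-level shift: shared by the 16 bins of one trial (SD
  ``trial_level_sd``) — this is what gives trials a consistent profile and
  hence a high Cronbach's alpha across time points;
* per-bin noise: independent per bin (SD ``trial_noise_sd``).

The additive-normal model is deliberately simple; with the large printed
zygomaticus SDs it occasionally produces negative reactivity values that
real rectified EMG cannot show (see docs/methods.md).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    EPOCH_MS,
    MUSCLES,
    N_BINS,
    ConditionTemplate,
    SimulationConfig,
    StudyDesign,
)

#: E|X| for X ~ N(0, sigma) is sigma * sqrt(2/pi); raw-mode noise is scaled
#: by the reciprocal so the rectified mean equals the target amplitude.
RECTIFIED_GAUSSIAN_MEAN_FACTOR = float(np.sqrt(2.0 / np.pi))

TABLE_COLUMNS = [
    "participant",
    "condition",
    "trial",
    "muscle",
    "epoch",
    "bin",
    "value_uv",
    "is_missing",
]

_FIXTURES = {muscle: f"group_means_{muscle}.tsv" for muscle in MUSCLES}


def load_group_means(muscle: str) -> pd.DataFrame:
    """Packaged per-bin group means and SDs for one muscle.

    Columns: condition, bin (1..16), time_ms (500..8000), mean, sd —
    percent-of-baseline units.
    """
    if muscle not in _FIXTURES:
        raise KeyError(f"unknown muscle {muscle!r}; expected one of {MUSCLES}")
    resource = importlib.resources.files("emgreact.data") / _FIXTURES[muscle]
    try:
        with importlib.resources.as_file(resource) as path:
            df = pd.read_csv(path, sep="\t")
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"missing packaged fixture {_FIXTURES[muscle]}") from exc
    expected = {"condition", "bin", "time_ms", "mean", "sd"}
    if set(df.columns) != expected or len(df) != len(CONDITIONS) * N_BINS:
        raise ValueError(f"corrupt fixture {_FIXTURES[muscle]}")
    return df


def default_templates(
    trial_noise_sd: float = 12.0, trial_level_sd: float = 25.0
) -> Dict[Tuple[str, str], ConditionTemplate]:
    """Templates for all 6 condition x muscle cells from packaged fixtures."""
    templates: Dict[Tuple[str, str], ConditionTemplate] = {}
    for muscle in MUSCLES:
        df = load_group_means(muscle)
        for condition in CONDITIONS:
            sub = df[df["condition"] == condition].sort_values("bin")
            templates[(condition, muscle)] = ConditionTemplate(
                condition=condition,
                muscle=muscle,
                mean_trajectory=sub["mean"].to_numpy(),
                between_participant_sd=sub["sd"].to_numpy(),
                trial_noise_sd=trial_noise_sd,
                trial_level_sd=trial_level_sd,
            )
    return templates


def expected_alpha(template: ConditionTemplate, n_items: int = N_BINS) -> float:
    """Spearman-Brown internal consistency implied by the noise split.

    The trial-level shift plays the role of a true score shared by all
    items (time points); per-bin noise is the error term.
    """
    tl2 = template.trial_level_sd**2
    tn2 = template.trial_noise_sd**2
    if tl2 + tn2 == 0:
        return 1.0
    rho = tl2 / (tl2 + tn2)
    return n_items * rho / (1.0 + (n_items - 1) * rho)


def _resolve_templates(config: SimulationConfig) -> Dict[Tuple[str, str], ConditionTemplate]:
    if config.templates is not None:
        return dict(config.templates)
    return default_templates()


def simulate_binned(config: SimulationConfig) -> pd.DataFrame:
    """Long table of binned trial-level EMG (baseline + regulation epochs).

    Returns a DataFrame with columns ``participant, condition, trial,
    muscle, epoch, bin, value_uv, is_missing``. Identical configs
    (including seed) return bit-identical tables.
    """
    design = config.design
    templates = _resolve_templates(config)
    for (cond, muscle), tpl in templates.items():
        if cond not in design.conditions:
            raise ValueError(f"unknown condition label {cond!r}")
        if muscle not in design.muscles:
            raise ValueError(f"unknown muscle label {muscle!r}")

    rng = np.random.default_rng(config.seed)
    P, T, K = design.n_participants, design.n_trials_per_condition, design.n_bins

    # Participant-level resting EMG amplitude, one per participant x muscle,
    # shared across conditions/trials (floor keeps it physically positive).
    base_level = {}
    # One reactivity deviate per participant x muscle, shared across
    # conditions: within-participant condition responses are strongly
    # correlated in a repeated-measures design, which is what gives the
    # paired per-bin contrasts their power. Muscles stay independent.
    participant_effect = {}
    for muscle in design.muscles:
        z = rng.standard_normal(P)
        level = config.baseline_mean_uv * (1.0 + config.between_participant_baseline_cv * z)
        base_level[muscle] = np.maximum(level, 0.1 * config.baseline_mean_uv)
        participant_effect[muscle] = rng.standard_normal(P)

    frames: List[pd.DataFrame] = []
    for condition in design.conditions:
        for muscle in design.muscles:
            tpl = templates[(condition, muscle)]
            sigma_within2 = tpl.trial_level_sd**2 + tpl.trial_noise_sd**2
            # Across-participant SD of a cell mean gains sigma_within^2 / T
            # from trial averaging; subtract in quadrature so cell means
            # spread like the configured between-participant SD.
            sd_p_bin = np.sqrt(np.maximum(tpl.between_participant_sd**2 - sigma_within2 / T, 0.0))

            z_p = participant_effect[muscle]
            trial_shift = rng.normal(0.0, tpl.trial_level_sd, size=(P, T)) if tpl.trial_level_sd else np.zeros((P, T))
            bin_noise = rng.normal(0.0, tpl.trial_noise_sd, size=(P, T, K)) if tpl.trial_noise_sd else np.zeros((P, T, K))
            pct = (
                tpl.mean_trajectory[None, None, :]
                + z_p[:, None, None] * sd_p_bin[None, None, :]
                + trial_shift[:, :, None]
                + bin_noise
            )

            # Baseline epoch in microvolts: participant level x trial drift
            # (shared across bins) x per-bin noise.
            u_t = rng.normal(0.0, config.baseline_cv, size=(P, T))
            w_tb = rng.normal(0.0, config.baseline_bin_cv, size=(P, T, K))
            baseline = base_level[muscle][:, None, None] * (1.0 + u_t[:, :, None] + w_tb)
            baseline = np.maximum(baseline, 0.01 * config.baseline_mean_uv)
            baseline_mean = baseline.mean(axis=2)  # (P, T)

            # Regulation epoch: latent percent-of-baseline converted against
            # the trial's own realised baseline mean, so percent_change
            # recovers `pct` exactly when nothing is censored.
            regulation = baseline_mean[:, :, None] * pct / 100.0

            if config.outlier_rate > 0:
                spikes_b = rng.random(size=baseline.shape) < config.outlier_rate
                spikes_r = rng.random(size=regulation.shape) < config.outlier_rate
                sign_b = rng.choice([-1.0, 1.0], size=baseline.shape)
                sign_r = rng.choice([-1.0, 1.0], size=regulation.shape)
                scale_b = config.outlier_magnitude_sd * config.baseline_bin_cv * base_level[muscle][:, None, None]
                scale_r = (
                    config.outlier_magnitude_sd
                    * np.sqrt(sigma_within2)
                    / 100.0
                    * baseline_mean[:, :, None]
                )
                baseline = baseline + spikes_b * sign_b * scale_b
                regulation = regulation + spikes_r * sign_r * scale_r

            frames.append(_to_long(condition, muscle, baseline, regulation))

    table = pd.concat(frames, ignore_index=True)
    return table[TABLE_COLUMNS]


def _to_long(condition: str, muscle: str, baseline: np.ndarray, regulation: np.ndarray) -> pd.DataFrame:
    P, T, K = baseline.shape
    participants = np.repeat(np.arange(1, P + 1), T * K)
    trials = np.tile(np.repeat(np.arange(1, T + 1), K), P)
    bins = np.tile(np.arange(1, K + 1), P * T)
    parts = []
    for epoch, values in (("baseline", baseline), ("regulation", regulation)):
        parts.append(
            pd.DataFrame(
                {
                    "participant": participants,
                    "condition": condition,
                    "trial": trials,
                    "muscle": muscle,
                    "epoch": epoch,
                    "bin": bins,
                    "value_uv": values.reshape(-1),
                    "is_missing": False,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class RawTrialRecord:
    """One trial x epoch x muscle of 1,000-Hz synthetic EMG.

    ``target_bins`` holds the latent per-bin amplitude (uV) the noise was
    modulated to, for round-trip checks against the preprocessing chain.
    """

    participant: int
    condition: str
    trial: int
    muscle: str
    epoch: str
    sampling_rate_hz: int
    samples: np.ndarray
    target_bins: np.ndarray


def simulate_raw(config: SimulationConfig) -> List[RawTrialRecord]:
    """Per-trial 1,000-Hz records whose rectified, smoothed, binned signal
    has expected value equal to the binned generator's latent bin means.

    The carrier is zero-mean Gaussian noise amplitude-modulated per 500-ms
    bin; the scale ``target / sqrt(2/pi)`` makes the full-wave-rectified
    mean equal the target amplitude.
    """
    if not config.raw_mode:
        raise ValueError("simulate_raw requires raw_mode=True in the config")
    fs = config.design.sampling_rate_hz
    if fs < 200:  # 10-ms smoothing window needs a usable sample grid
        raise ValueError("sampling_rate_hz too low for the 10-ms smoothing model")
    binned = simulate_binned(config)
    samples_per_bin = config.design.bin_width_ms * fs // 1000
    rng = np.random.default_rng(config.seed + 1)

    records: List[RawTrialRecord] = []
    keys = ["participant", "condition", "trial", "muscle", "epoch"]
    for key, grp in binned.groupby(keys, sort=True):
        target = grp.sort_values("bin")["value_uv"].to_numpy()
        amp = np.repeat(np.maximum(target, 0.0), samples_per_bin)
        noise = rng.standard_normal(amp.size)
        samples = amp / RECTIFIED_GAUSSIAN_MEAN_FACTOR * noise
        records.append(
            RawTrialRecord(
                participant=int(key[0]),
                condition=str(key[1]),
                trial=int(key[2]),
                muscle=str(key[3]),
                epoch=str(key[4]),
                sampling_rate_hz=fs,
                samples=samples,
                target_bins=target,
            )
        )
    return records


def noise_free_config(seed: int = 0, **kwargs) -> SimulationConfig:
    """Config with every stochastic component switched off.

    The pipeline run on its output reproduces the template trajectories
    exactly; used by calibration tests.
    """
    templates = {
        key: ConditionTemplate(
            condition=t.condition,
            muscle=t.muscle,
            mean_trajectory=t.mean_trajectory,
            between_participant_sd=np.zeros(N_BINS),
            trial_noise_sd=0.0,
            trial_level_sd=0.0,
        )
        for key, t in default_templates().items()
    }
    defaults = dict(
        templates=templates,
        baseline_cv=0.0,
        baseline_bin_cv=0.0,
        between_participant_baseline_cv=0.0,
        outlier_rate=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)
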