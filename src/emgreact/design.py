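"""Study design and simulation configuration objects.

The design mirrors a within-participant facial-EMG regulation experiment:
each participant completes trials under three instruction conditions
(``no_regulation``, ``neutralize``, ``transform``), with two recorded
muscles (``corrugator`` — negative-affect channel, ``zygomaticus`` —
positive-affect channel). Every trial contributes an 8,000-ms pre-stimulus
baseline epoch and an 8,000-ms regulation epoch, each summarised as 16
consecutive 500-ms bin averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

import numpy as np

CONDITIONS: Tuple[str, ...] = ("no_regulation", "neutralize", "transform")
MUSCLES: Tuple[str, ...] = ("corrugator", "zygomaticus")
EPOCHS: Tuple[str, str] = ("baseline", "regulation")

N_BINS = 16
BIN_WIDTH_MS = 500
EPOCH_MS = 8000


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the repeated-measures experiment.

    Parameters
    ----------
    n_participants
        Number of participants (defaults to the full-study 156).
    n_trials_per_condition
        Trials per instruction condition (15 in the full design).
    n_bins, bin_width_ms
        Epoch summarisation grid; must multiply to the epoch duration.
    sampling_rate_hz
        Raw-signal sampling rate (raw mode only).
    """

    n_participants: int = 156
    n_trials_per_condition: int = 15
    conditions: Tuple[str, ...] = CONDITIONS
    muscles: Tuple[str, ...] = MUSCLES
    n_bins: int = N_BINS
    bin_width_ms: int = BIN_WIDTH_MS
    baseline_duration_ms: int = EPOCH_MS
    sampling_rate_hz: int = 1000

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials_per_condition < 1:
            raise ValueError("design requires >= 1 participant and trial")
        if self.n_bins * self.bin_width_ms != EPOCH_MS:
            raise ValueError(
                f"n_bins * bin_width_ms must equal {EPOCH_MS} ms, got "
                f"{self.n_bins} * {self.bin_width_ms}"
            )
        for name, labels in (("conditions", self.conditions), ("muscles", self.muscles)):
            if len(labels) == 0 or len(set(labels)) != len(labels):
                raise ValueError(f"{name} must be non-empty and unique")

    @property
    def regulation_duration_ms(self) -> int:
        return self.n_bins * self.bin_width_ms

    def bin_times_ms(self) -> np.ndarray:
        """Right edge of each bin in ms after instruction onset (500..8000)."""
        return np.arange(1, self.n_bins + 1) * self.bin_width_ms


@dataclass(frozen=True)
class ConditionTemplate:
    """Generating template for one condition x muscle cell.

    ``mean_trajectory`` and ``between_participant_sd`` are per-bin values in
    percent-of-baseline units (100 = no change from baseline). The printed
    group means and SDs of the reference study ship as package fixtures and
    are the default templates (:func:`emgreact.synth.default_templates`).

    ``trial_level_sd`` is the SD of a trial-level shift shared by all 16
    bins of one trial; ``trial_noise_sd`` is per-bin independent noise.
    The split is what gives simulated trials a realistic internal
    consistency (Cronbach's alpha) across time points.
    """

    condition: str
    muscle: str
    mean_trajectory: np.ndarray
    between_participant_sd: np.ndarray
    trial_noise_sd: float = 12.0
    trial_level_sd: float = 25.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_trajectory", np.asarray(self.mean_trajectory, float))
        object.__setattr__(
            self, "between_participant_sd", np.asarray(self.between_participant_sd, float)
        )
        for name in ("mean_trajectory", "between_participant_sd"):
            arr = getattr(self, name)
            if arr.shape != (N_BINS,):
                raise ValueError(f"{name} must have exactly {N_BINS} entries")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if np.any(self.mean_trajectory <= 0):
            raise ValueError("mean_trajectory must be positive")
        if np.any(self.between_participant_sd < 0):
            raise ValueError("between_participant_sd must be non-negative")
        if self.trial_noise_sd < 0 or self.trial_level_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generator configuration; the seed determines output exactly.

    Baseline EMG level is arbitrary (percent change cancels it); the
    default 5 uV is a typical resting facial-EMG amplitude. ``baseline_cv``
    is trial-to-trial drift of the baseline level (shared across the 16
    baseline bins of a trial); ``baseline_bin_cv`` is per-bin baseline
    noise. Outliers are injected as isolated bin-level spikes at
    ``outlier_magnitude_sd`` generating-SDs so the 2.5-SD censoring rule
    can catch them.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    templates: Mapping[Tuple[str, str], ConditionTemplate] | None = None
    baseline_mean_uv: float = 5.0
    baseline_cv: float = 0.12
    baseline_bin_cv: float = 0.06
    between_participant_baseline_cv: float = 0.25
    outlier_rate: float = 0.01
    outlier_magnitude_sd: float = 6.0
    seed: int = 0
    raw_mode: bool = False

    def __post_init__(self) -> None:
        if self.baseline_mean_uv <= 0:
            raise ValueError("baseline_mean_uv must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.templates is not None:
            for cond in self.design.conditions:
                for muscle in self.design.muscles:
                    if (cond, muscle) not in self.templates:
                        raise ValueError(f"missing template for {(cond, muscle)}")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
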