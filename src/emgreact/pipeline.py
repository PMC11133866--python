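"""End-to-end orchestration: simulate -> preprocess -> analyse -> report.

A single :class:`RunConfig` drives every stage; the seed determines the
whole bundle, and a manifest recording config, seed and package version is
written alongside the outputs so any bundle can be re-created.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

from . import __version__
from .design import CONDITIONS, MUSCLES, SimulationConfig, StudyDesign
from .preprocess import (
    aggregate_cells,
    baseline_bin_table,
    preprocess_table,
    trial_percent_change_table,
)
from .reliability import baseline_alpha, channel_independence, noreg_alpha
from .contrasts import (
    bonferroni_threshold,
    contrast_summary,
    contrast_table,
    group_time_course,
)
from .synth import simulate_binned
from .trajectory import fit_all, observed_transform_path, vertex_time_ms

logger = logging.getLogger(__name__)

CONTRAST_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("neutralize", "no_regulation"),
    ("transform", "no_regulation"),
    ("transform", "neutralize"),
)

_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    output_dir: Path
    seed: int = 0
    n_participants: int = 156
    n_trials_per_condition: int = 15
    input_table: Optional[Path] = None  # read a long binned table instead of simulating
    fixtures_only: bool = False  # trajectory fit from packaged printed means only
    outlier_k: float = 2.5
    censor_baseline: bool = True
    family_alpha: float = 0.05
    m_comparisons: int = 16
    run_reliability: bool = True
    run_contrasts: bool = True
    run_trajectory: bool = True

    def to_manifest(self) -> Dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        if self.input_table is not None:
            d["input_table"] = str(self.input_table)
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        """Build a run configuration from a YAML file.

        Keys are the RunConfig field names; keyword overrides (e.g. from
        CLI flags) win over file values.
        """
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        if "output_dir" in data:
            data["output_dir"] = Path(data["output_dir"])
        if data.get("input_table") is not None:
            data["input_table"] = Path(data["input_table"])
        return cls(**data)


@dataclass
class RunBundle:
    """In-memory results of a pipeline run (also written to output_dir)."""

    config: RunConfig
    cells: Optional[pd.DataFrame] = None
    reliability: Optional[pd.DataFrame] = None
    contrast_tables: Dict[Tuple[Tuple[str, str], str], pd.DataFrame] = field(default_factory=dict)
    onset_summaries: Dict[Tuple[Tuple[str, str], str], object] = field(default_factory=dict)
    time_course: Optional[pd.DataFrame] = None
    trajectory_fit: Optional[object] = None
    independence: Optional[object] = None


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute all enabled stages and write the report bundle.

    Output files: ``cells.tsv``, ``reliability.tsv``,
    ``contrasts_<muscle>.tsv``, ``time_course.tsv``,
    ``trajectory_fits.tsv``, ``summary.txt`` and ``manifest.json``.
    A stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = RunBundle(config=config)

    if not config.fixtures_only:
        try:
            if config.input_table is not None:
                table = pd.read_csv(config.input_table, sep="\t")
            else:
                design = StudyDesign(
                    n_participants=config.n_participants,
                    n_trials_per_condition=config.n_trials_per_condition,
                )
                table = simulate_binned(SimulationConfig(design=design, seed=config.seed))
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

        try:
            trial_scores = trial_percent_change_table(
                table, outlier_k=config.outlier_k, censor_baseline=config.censor_baseline
            )
            bundle.cells = aggregate_cells(trial_scores)
            _write(bundle.cells, out / "cells.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

        if config.run_reliability:
            try:
                base_bins = baseline_bin_table(table, outlier_k=config.outlier_k, censor=config.censor_baseline)
                rows = []
                for muscle in MUSCLES:
                    for analysis, summary in (
                        ("baseline", baseline_alpha(base_bins, muscle)),
                        ("no_regulation", noreg_alpha(trial_scores, muscle)),
                    ):
                        rows.append(
                            {
                                "analysis": analysis,
                                "muscle": muscle,
                                "mean_alpha": summary.mean_alpha,
                                "min_alpha": summary.min_alpha,
                                "max_alpha": summary.max_alpha,
                                "n_participants": len(summary.per_participant),
                            }
                        )
                bundle.reliability = pd.DataFrame(rows)
                bundle.independence = channel_independence(bundle.cells)
                _write(bundle.reliability, out / "reliability.tsv")
            except Exception as exc:
                raise RuntimeError(f"stage 'reliability' failed: {exc}") from exc

        if config.run_contrasts:
            try:
                bundle.time_course = group_time_course(bundle.cells)
                _write(bundle.time_course, out / "time_course.tsv")
                per_muscle = {m: [] for m in MUSCLES}
                for pair in CONTRAST_PAIRS:
                    for muscle in MUSCLES:
                        ct = contrast_table(
                            bundle.cells, pair[0], pair[1], muscle,
                            family_alpha=config.family_alpha, m=config.m_comparisons,
                        )
                        bundle.contrast_tables[(pair, muscle)] = ct
                        bundle.onset_summaries[(pair, muscle)] = contrast_summary(ct)
                        labelled = ct.copy()
                        labelled.insert(0, "pair", f"{pair[0]}_vs_{pair[1]}")
                        per_muscle[muscle].append(labelled)
                for muscle, parts in per_muscle.items():
                    _write(pd.concat(parts, ignore_index=True), out / f"contrasts_{muscle}.tsv")
            except Exception as exc:
                raise RuntimeError(f"stage 'contrasts' failed: {exc}") from exc

    if config.run_trajectory:
        try:
            source_cells = None if config.fixtures_only else bundle.cells
            observed = observed_transform_path(source_cells)
            bundle.trajectory_fit = fit_all(observed)
            _write(bundle.trajectory_fit.table, out / "trajectory_fits.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'trajectory' failed: {exc}") from exc

    report = write_report(bundle)
    (out / "summary.txt").write_text(report)
    (out / "manifest.json").write_text(json.dumps(config.to_manifest(), indent=2, sort_keys=True))
    return bundle


def write_report(bundle: RunBundle) -> str:
    """Plain-text summary of the analyses contained in a bundle."""
    cfg = bundle.config
    lines = [
        "emgreact pipeline summary",
        "=========================",
        f"seed: {cfg.seed}",
        f"Bonferroni-adjusted alpha: {bonferroni_threshold(cfg.family_alpha, cfg.m_comparisons):g} "
        f"({cfg.family_alpha:g}/{cfg.m_comparisons})",
        "",
    ]
    if bundle.reliability is not None:
        lines.append("Internal consistency (Fisher-z mean Cronbach's alpha):")
        for _, row in bundle.reliability.iterrows():
            lines.append(
                f"  {row['analysis']:>13} / {row['muscle']:<11} "
                f"mean {row['mean_alpha']:.3f} (range {row['min_alpha']:.3f} to {row['max_alpha']:.3f})"
            )
        lines.append("")
    if bundle.independence is not None:
        ind = bundle.independence
        lines.append(
            f"Channel independence: r = {ind.r:.2f}, t({ind.df}) = {ind.t:.2f}, "
            f"p = {ind.p:.2g}, 95% CI ({ind.ci_low:.2f}, {ind.ci_high:.2f})"
        )
        lines.append("")
    if bundle.onset_summaries:
        lines.append("Per-bin contrasts (dependent-samples t, Bonferroni-corrected):")
        for (pair, muscle), s in bundle.onset_summaries.items():
            onset = f"{s.first_significant_ms} ms" if s.first_significant_bin else "no significant bins"
            lines.append(
                f"  {pair[0]} vs {pair[1]} / {muscle}: onset {onset}; "
                f"peak {s.peak_difference:+.1f} at {s.peak_ms} ms"
            )
        lines.append("")
    if bundle.trajectory_fit is not None:
        fit = bundle.trajectory_fit
        lines.append("Trajectory model fitting (MSD over interior points):")
        for family in ("neutral", "mixed", "valence"):
            sub = fit.table[fit.table["family"] == family]
            idx = sub["msd"].idxmin()
            v = sub.loc[idx, "vertex"]
            where = f" at vertex {int(v)} ({vertex_time_ms(int(v))} ms)" if pd.notna(v) else ""
            lines.append(f"  {family:>8}: min MSD {sub.loc[idx, 'msd']:.2f}{where}")
        v = fit.best_vertex
        where = f" with vertex at {vertex_time_ms(v)} ms (point #{v})" if v else ""
        lines.append(f"  best fit: {fit.best_family} trajectory{where}, MSD {fit.best_msd:.2f}")
    return "\n".join(lines) + "\n"
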