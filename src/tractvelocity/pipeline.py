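"""Config-driven orchestration: map -> extract -> stats -> report.

A pipeline run takes a YAML/JSON config naming per-participant quantitative
maps (MTsat, NODDI intracellular and isotropic fractions, white-matter
probability), one probabilistic atlas per tract, and a behavioural CSV.
It computes voxelwise MR g-ratio maps, extracts probability-weighted tract
means and ROI voxel counts, joins them to the behavioural table, runs the
ROI-size pre-check and the covariate-adjusted correlation battery, and
attaches microstructural scenario calls.  Everything is reproducible from
the echoed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biophysics import DEFAULT_ALPHA, VoxelMap, gratio_map_from_inputs
from .roi import cohort_to_wide, extract_cohort
from .stats import BatteryReport, precheck_voxelcount, run_association_battery

logger = logging.getLogger("tractvelocity")

MAP_KEYS = ("mtsat", "icvf", "iso", "wm_prob")
DERIVED_METRICS = ("g_ratio", "mvf", "awf", "avf")


class ConfigValidationError(ValueError):
    """Pipeline config failed validation; carries the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(errors))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with study-default thresholds."""

    maps_manifest: str
    atlases: dict[str, str]
    behaviour: str
    out_dir: str = "tractvelocity_out"
    calibration_alpha: float = DEFAULT_ALPHA
    min_prob: float = 0.25
    min_wm: float = 0.90
    alpha: float = 0.05
    m_tracts: int = 3
    n_boot: int = 10_000
    seed: int | None = None
    metrics: tuple[str, ...] = ("g_ratio", "mtsat", "icvf", "iso")
    primary_outcome: str = "internal_details"
    control_outcome: str = "external_details"
    lab_outcomes: tuple[str, ...] = ()
    allow_incomplete: bool = False
    metric_name_map: dict[str, str] = field(
        default_factory=lambda: {"icvf": "neurite_density", "iso": "iso_fraction"}
    )


_KNOWN_KEYS = {
    "maps_manifest", "atlases", "behaviour", "out_dir", "calibration_alpha",
    "min_prob", "min_wm", "alpha", "m_tracts", "n_boot", "seed", "metrics",
    "primary_outcome", "control_outcome", "lab_outcomes", "allow_incomplete",
    "metric_name_map",
}


def validate_config(raw: dict, check_paths: bool = True) -> PipelineConfig:
    """Fill defaults and validate a raw config mapping.

    Unknown keys warn (forward compatibility); missing manifests and
    out-of-range thresholds are collected into one error list.
    """
    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            logger.warning("config: unknown key '%s' ignored", key)
    kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    for req in ("maps_manifest", "atlases", "behaviour"):
        if req not in kwargs:
            errors.append(f"missing required key '{req}'")
    if errors:
        raise ConfigValidationError(errors)
    for seq_key in ("metrics", "lab_outcomes"):
        if seq_key in kwargs:
            kwargs[seq_key] = tuple(kwargs[seq_key])
    cfg = PipelineConfig(**kwargs)

    if not cfg.atlases:
        errors.append("config lists zero tracts")
    if not (0 < cfg.calibration_alpha):
        errors.append(f"calibration_alpha must be positive, got {cfg.calibration_alpha}")
    for name, val in (("min_prob", cfg.min_prob), ("min_wm", cfg.min_wm)):
        if not (0 <= val <= 1):
            errors.append(f"{name} must be in [0, 1], got {val}")
    if not (0 < cfg.alpha < 1):
        errors.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    if cfg.m_tracts < 1:
        errors.append(f"m_tracts must be >= 1, got {cfg.m_tracts}")
    if cfg.n_boot < 0:
        errors.append(f"n_boot must be >= 0, got {cfg.n_boot}")
    if check_paths:
        for label, path in [
            ("maps_manifest", cfg.maps_manifest),
            ("behaviour", cfg.behaviour),
            *[(f"atlas '{t}'", p) for t, p in cfg.atlases.items()],
        ]:
            if not Path(path).exists():
                errors.append(f"{label}: path does not exist: {path}")
    if errors:
        raise ConfigValidationError(errors)
    return cfg


@dataclass
class RunReport:
    """Self-contained result of one pipeline run."""

    tract_means: pd.DataFrame
    battery: BatteryReport
    scenarios: dict
    config: PipelineConfig
    version: str
    seed: int | None
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)


def _load_participant_maps(manifest: pd.DataFrame) -> dict[str, dict[str, VoxelMap]]:
    """Load each participant's maps; an unreadable map is skipped (logged) so
    the participant is later quarantined as missing that input."""
    participants: dict[str, dict[str, VoxelMap]] = {}
    for _, row in manifest.iterrows():
        pid = str(row["participant_id"])
        maps = {}
        for key in MAP_KEYS:
            if key in row and isinstance(row[key], str):
                try:
                    maps[key] = VoxelMap.from_nifti(row[key])
                except (OSError, ValueError) as exc:
                    logger.warning("%s: could not load %s map: %s", pid, key, exc)
        participants[pid] = maps
    return participants


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis on the inputs named by a validated config."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    warnings_list: list[str] = []

    manifest = pd.read_csv(cfg.maps_manifest)
    participants = _load_participant_maps(manifest)
    behaviour = pd.read_csv(cfg.behaviour)
    atlases = [(name, VoxelMap.from_nifti(path)) for name, path in cfg.atlases.items()]
    timings["load"] = time.perf_counter() - t0

    # voxelwise g-ratio chain per participant
    t0 = time.perf_counter()
    quarantined: dict[str, str] = {}
    for pid, maps in participants.items():
        missing = [k for k in MAP_KEYS if k not in maps]
        if missing:
            quarantined[pid] = f"missing maps: {', '.join(missing)}"
            continue
        try:
            derived = gratio_map_from_inputs(
                maps["mtsat"], maps["icvf"], maps["iso"], cfg.calibration_alpha
            )
            maps.update(derived)
        except Exception as exc:  # quarantine, keep going
            quarantined[pid] = str(exc)
    for pid in quarantined:
        participants.pop(pid, None)
        warnings_list.append(f"{pid}: {quarantined[pid]}")
    if quarantined:
        logger.warning("quarantined %d participant(s): %s", len(quarantined), quarantined)
    timings["gratio_maps"] = time.perf_counter() - t0

    # extraction
    t0 = time.perf_counter()
    extract_metrics = [m for m in cfg.metrics if m != "n_voxels"]
    long_df, extract_errors = extract_cohort(
        participants, atlases, extract_metrics, cfg.min_prob, cfg.min_wm
    )
    warnings_list.extend(f"{p}: {m}" for p, m in extract_errors.items())
    wide = cohort_to_wide(long_df)
    rename = {
        f"{t}__{src}": f"{t}__{dst}"
        for t, _ in atlases
        for src, dst in cfg.metric_name_map.items()
    }
    wide = wide.rename(columns=rename)
    timings["extract"] = time.perf_counter() - t0

    # join behaviour; default aborts on incomplete cases
    behaviour["participant_id"] = behaviour["participant_id"].astype(str)
    cohort = wide.merge(behaviour, on="participant_id", how="inner")
    n_expected = len(manifest)
    if len(cohort) < n_expected and not cfg.allow_incomplete:
        raise RuntimeError(
            f"only {len(cohort)}/{n_expected} participants have complete data; "
            "set allow_incomplete to analyse complete cases only"
        )
    if len(cohort) < n_expected:
        warnings_list.append(
            f"complete-case analysis on {len(cohort)}/{n_expected} participants"
        )

    # statistics
    t0 = time.perf_counter()
    tract_names = [t for t, _ in atlases]
    battery_metrics = [cfg.metric_name_map.get(m, m) for m in extract_metrics]
    battery = run_association_battery(
        cohort,
        tract_names,
        battery_metrics,
        primary_outcome=cfg.primary_outcome,
        control_outcome=cfg.control_outcome,
        lab_outcomes=cfg.lab_outcomes,
        alpha=cfg.alpha,
        m_tracts=cfg.m_tracts,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
    )
    timings["stats"] = time.perf_counter() - t0

    return RunReport(
        tract_means=long_df,
        battery=battery,
        scenarios={t: s.scenario.value for t, s in battery.scenarios.items()},
        config=cfg,
        version=__version__,
        seed=cfg.seed,
        warnings=warnings_list,
        timings=timings,
    )


def render_report(
    report: RunReport, formats: tuple[str, ...] = ("tsv", "json"), out_dir=None,
    plots: bool = False,
) -> dict[str, str]:
    """Write the run report as TSV tables, a JSON summary and optional figures.

    Numbers in the tables come straight from the stats result objects; the
    renderer computes nothing.  Correlations are written at full precision
    in JSON and rounded to 2 dp in the human-readable TSV duplicates.
    """
    supported = {"tsv", "json"}
    unknown = set(formats) - supported
    if unknown:
        raise ValueError(f"unknown formats {sorted(unknown)}; supported: {sorted(supported)}")
    out = Path(out_dir or report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if "tsv" in formats:
        p = out / "tract_means.tsv"
        report.tract_means.to_csv(p, sep="\t", index=False)
        written["tract_means"] = str(p)
        p = out / "battery.tsv"
        report.battery.results.to_csv(p, sep="\t", index=False)
        written["battery"] = str(p)
        p = out / "comparisons.tsv"
        report.battery.comparisons.to_csv(p, sep="\t", index=False)
        written["comparisons"] = str(p)
    if "json" in formats:
        summary = {
            "version": report.version,
            "seed": report.seed,
            "alpha": report.battery.alpha,
            "threshold_corrected": report.battery.threshold_corrected,
            "m_tracts": report.battery.m_tracts,
            "n_boot": report.battery.n_boot,
            "scenarios": report.scenarios,
            "precheck": {
                t: ({"r": r.r, "p": r.p, "df": r.df} if hasattr(r, "r") else {"error": str(r)})
                for t, r in report.battery.precheck.items()
            },
            "results": report.battery.results.to_dict(orient="records"),
            "comparisons": report.battery.comparisons.to_dict(orient="records"),
            "warnings": report.warnings,
            "timings": report.timings,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(report.config).items()
            },
        }
        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=2, default=str))
        written["summary"] = str(p)
    if plots:
        written.update(_render_figures(report, out))
    return written


def _render_figures(report: RunReport, out: Path) -> dict[str, str]:
    """Scatter of adjusted variables per significant cell, plus paired bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    comp = report.battery.comparisons
    if not comp.empty:
        fig, ax = plt.subplots(figsize=(5, 4))
        labels = [f"{r.tract}\n{r.metric}" for r in comp.itertuples()]
        xpos = np.arange(len(comp))
        ax.bar(xpos - 0.2, comp["r_primary"], width=0.4, label="primary outcome")
        ax.bar(xpos + 0.2, comp["r_control"], width=0.4, label="control outcome")
        ax.set_xticks(xpos, labels, fontsize=8)
        ax.set_ylabel("partial r")
        ax.axhline(0, color="k", lw=0.8)
        ax.legend()
        fig.tight_layout()
        p = out / "comparison_bars.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written["comparison_bars"] = str(p)
    return written


def load_config_file(path) -> dict:
    """Read a YAML or JSON pipeline config file."""
    import yaml

    text = Path(path).read_text()
    return yaml.safe_load(text)
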