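"""Synthetic cohorts and voxel map sets with known ground truth.

The generator emulates the study design the analysis pipeline assumes: a
cohort of n = 217 young adults (age truncated-normal 29.0 +/- 5.60 on
[20, 41], 109 F / 108 M, three scanners), per-tract microstructure means
with the observed marginals (e.g. MR g-ratio 0.647 +/- 0.043), ROI voxel
counts (129.11 +/- 25.68), and behavioural outcomes (internal details
23.95 +/- 7.25 on [4.60, 44.60]; external details 5.35 +/- 3.20 bounded
below at 0.8) plus eight laboratory memory scores.

Association structure is injected at the *partial* level: standardized
residual variables are drawn from a joint normal whose correlation matrix
carries the configured (metric, outcome) correlations, covariate effects
are added on top, and each column is rescaled to its target mean/SD.
Because the covariates are independent of the residual block, the
population covariate-adjusted correlation of each configured pair equals
its target rho exactly; unconfigured pairs are at 0.

``generate_voxel_cohort`` additionally embeds each participant's latent
tract means in small NIfTI-style map sets (a tubular tract in a 3D grid
with a graded probabilistic atlas profile and per-participant white-matter
probability maps), so the full map -> extract -> stats chain can run with
exact bookkeeping of the weighted means it should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biophysics import DEFAULT_ALPHA, VoxelMap
from .stats import (
    STANDARD_COVARIATES,
    bonferroni_threshold,
    partial_correlation,
    partial_correlation_with_ci,
)

# Marginals of the tract microstructure measures (mean, SD)
DEFAULT_METRICS: dict[str, tuple[float, float]] = {
    "g_ratio": (0.647, 0.043),
    "mtsat": (0.959, 0.007),
    "odi": (0.189, 0.038),
    "neurite_density": (0.480, 0.051),
    "iso_fraction": (0.04, 0.03),
}

# Behavioural outcomes: mean, SD, (lower, upper) truncation bounds or None
DEFAULT_OUTCOMES: dict[str, tuple[float, float, tuple[float, float] | None]] = {
    "internal_details": (23.95, 7.25, (4.60, 44.60)),
    "external_details": (5.35, 3.20, (0.8, 17.40)),
}

# Laboratory memory scores (mean, SD); modelled unbounded-normal
DEFAULT_LAB_OUTCOMES: dict[str, tuple[float, float]] = {
    "logical_memory_immediate": (12.95, 2.09),
    "logical_memory_delayed": (12.58, 2.62),
    "list_recall_immediate": (58.82, 7.42),
    "list_recall_delayed": (12.92, 2.17),
    "complex_figure_delayed": (22.28, 5.71),
    "recognition_words": (12.75, 2.06),
    "recognition_faces": (11.00, 3.33),
    "semantic_accuracy": (81.32, 8.44),
}


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass
class VoxelGridSpec:
    """Geometry of the synthetic tubular tract embedded in a small grid."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    tract_axis_extent: tuple[int, int] = (4, 28)   # slab along axis 0
    atlas_core_radius: float = 2.0                 # probability 1 inside
    atlas_edge_radius: float = 4.0                 # probability 0 outside
    # white-matter probability: participant-level plateau, radial falloff and
    # per-voxel segmentation noise, so the 90% refinement bites stochastically
    wm_plateau_mean: float = 0.95
    wm_plateau_sd: float = 0.009
    wm_falloff_per_voxel: float = 0.12             # decline with radius
    wm_voxel_noise_sd: float = 0.02
    within_tract_sd: dict[str, float] = field(
        default_factory=lambda: {"mtsat": 0.02, "icvf": 0.01, "iso": 0.004, "odi": 0.01}
    )
    background: dict[str, float] = field(
        default_factory=lambda: {"mtsat": 0.4, "icvf": 0.25, "iso": 0.25, "odi": 0.4}
    )


@dataclass
class SyntheticConfig:
    """Study-condition configuration for the synthetic generators."""

    n_participants: int = 217
    seed: int | None = None
    age_mean: float = 29.0
    age_sd: float = 5.60
    age_bounds: tuple[float, float] = (20.0, 41.0)
    p_female: float = 109 / 217
    scanner_proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    n_voxels_mean: float = 129.11
    n_voxels_sd: float = 25.68
    tracts: tuple[str, ...] = ("parahippocampal_cingulum",)
    metrics: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRICS)
    )
    outcomes: dict[str, tuple[float, float, tuple[float, float] | None]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES)
    )
    lab_outcomes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LAB_OUTCOMES)
    )
    #: (tract, metric, outcome, rho): target covariate-adjusted correlation
    target_partial_correlations: tuple[tuple[str, str, str, float], ...] = (
        ("parahippocampal_cingulum", "g_ratio", "internal_details", 0.18),
    )
    #: (outcome_a, outcome_b, rho): residual correlation among outcomes
    outcome_correlations: tuple[tuple[str, str, float], ...] = (
        ("internal_details", "external_details", 0.2),
    )
    #: variable -> {covariate -> beta on standardized covariate}
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    calibration_alpha: float = DEFAULT_ALPHA
    voxel_grid: VoxelGridSpec = field(default_factory=VoxelGridSpec)

    def validate(self) -> None:
        if self.n_participants < 10:
            raise ConfigError("n_participants must be at least 10")
        if abs(sum(self.scanner_proportions) - 1.0) > 1e-9:
            raise ConfigError("scanner proportions must sum to 1")
        for name, (_, sd) in self.metrics.items():
            if sd <= 0:
                raise ConfigError(f"metric '{name}' SD must be positive")
        for name, (_, sd, bounds) in self.outcomes.items():
            if sd <= 0:
                raise ConfigError(f"outcome '{name}' SD must be positive")
            if bounds is not None and bounds[0] >= bounds[1]:
                raise ConfigError(f"outcome '{name}' bounds out of order")
        for tract, metric, outcome, rho in self.target_partial_correlations:
            if abs(rho) > 1:
                raise ConfigError(f"|rho| must be <= 1 for {tract}/{metric}/{outcome}")
            if tract not in self.tracts:
                raise ConfigError(f"target names unknown tract '{tract}'")
            if metric not in self.metrics:
                raise ConfigError(f"target names unknown metric '{metric}'")
            if outcome not in self.outcomes and outcome not in self.lab_outcomes:
                raise ConfigError(f"target names unknown outcome '{outcome}'")


@dataclass
class GroundTruth:
    """Everything needed to score recovery on a generated dataset."""

    target_partial_correlations: tuple[tuple[str, str, str, float], ...]
    outcome_correlations: tuple[tuple[str, str, float], ...]
    covariate_effects: dict[str, dict[str, float]]
    seed: int | None
    latent_tract_means: pd.DataFrame | None = None
    true_weighted_means: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Tabular cohort
# ---------------------------------------------------------------------------

def _variable_order(cfg: SyntheticConfig) -> list[str]:
    cols = [f"{t}__{m}" for t in cfg.tracts for m in cfg.metrics]
    cols += list(cfg.outcomes) + list(cfg.lab_outcomes)
    return cols

def _residual_correlation(cfg: SyntheticConfig) -> np.ndarray:
    names = _variable_order(cfg)
    p = len(names)
    S = np.eye(p)
    pairs = []
    for tract, metric, outcome, rho in cfg.target_partial_correlations:
        pairs.append((f"{tract}__{metric}", outcome, rho))
    for a, b, rho in cfg.outcome_correlations:
        pairs.append((a, b, rho))
    for a, b, rho in pairs:
        i, j = names.index(a), names.index(b)
        S[i, j] = S[j, i] = rho
    if np.linalg.eigvalsh(S).min() < -1e-10:
        raise ConfigError(
            "requested correlation structure is not positive semi-definite; "
            f"offending pairs: {[(a, b, r) for a, b, r in pairs]}"
        )
    return S


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    lo, hi = cfg.age_bounds
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    age = sps.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                            size=n, random_state=rng)
    # fixed counts, shuffled: emulates a recruited (not sampled) cohort
    n_f = int(round(n * cfg.p_female))
    gender = rng.permutation(np.r_[np.ones(n_f), np.zeros(n - n_f)]).astype(int)
    counts = np.floor(np.asarray(cfg.scanner_proportions) * n).astype(int)
    counts[: n - counts.sum()] += 1
    scanner = rng.permutation(np.repeat(np.arange(1, len(counts) + 1), counts))
    return pd.DataFrame({"age": age, "gender": gender, "scanner": scanner})


def _materialize(cfg, Z, cov_std, names):
    """Scale standardized residuals to target marginals, adding covariate effects."""
    out = {}
    for j, name in enumerate(names):
        raw = Z[:, j].copy()
        betas = cfg.covariate_effects.get(name, {})
        for cov_name, beta in betas.items():
            raw = raw + beta * cov_std[cov_name]
        sd_raw = np.sqrt(1.0 + sum(b * b for b in betas.values()))
        bare = name.split("__", 1)[1] if "__" in name else name
        if bare in cfg.metrics:
            mean, sd = cfg.metrics[bare]
        elif name in cfg.outcomes:
            mean, sd, _ = cfg.outcomes[name]
        else:
            mean, sd = cfg.lab_outcomes[name]
        out[name] = mean + sd * raw / sd_raw
    return out


def generate_cohort(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic cohort table with the configured structure.

    Outcome columns with bounds are kept in range by jointly redrawing the
    offending participants' residual rows (truncated multivariate normal),
    so the configured correlations hold pre-truncation; at the default,
    mild bounds the attenuation is negligible.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = cfg.n_participants
    names = _variable_order(cfg)
    S = _residual_correlation(cfg)
    # eigen factor tolerates PSD-but-singular targets (e.g. rho = 1)
    w, V = np.linalg.eigh(S)
    L = V * np.sqrt(np.clip(w, 0.0, None))

    cov = _draw_covariates(cfg, rng)
    for tract in cfg.tracts:
        nv = np.maximum(1, np.round(rng.normal(cfg.n_voxels_mean, cfg.n_voxels_sd, n)))
        cov[f"{tract}__n_voxels"] = nv.astype(int)
    cov_std = {
        c: (cov[c] - cov[c].mean()) / (cov[c].std(ddof=0) or 1.0)
        for c in cov.columns
    }

    Z = rng.standard_normal((n, len(names))) @ L.T
    values = _materialize(cfg, Z, cov_std, names)

    bounded = [(o, b) for o, (_, _, b) in cfg.outcomes.items() if b is not None]
    for _ in range(200):
        bad = np.zeros(n, dtype=bool)
        for o, (lo, hi) in bounded:
            v = values[o]
            bad |= (v < lo) | (v > hi)
        if not bad.any():
            break
        Z[bad] = rng.standard_normal((int(bad.sum()), len(names))) @ L.T
        values = _materialize(cfg, Z, cov_std, names)
    else:
        raise ConfigError("could not satisfy outcome bounds; check means/SDs vs bounds")

    df = pd.DataFrame({"participant_id": [f"p{i + 1:03d}" for i in range(n)]})
    df = pd.concat([df, cov.reset_index(drop=True), pd.DataFrame(values)], axis=1)

    latent = df[["participant_id"] + [f"{t}__{m}" for t in cfg.tracts for m in cfg.metrics]].copy()
    gt = GroundTruth(
        target_partial_correlations=cfg.target_partial_correlations,
        outcome_correlations=cfg.outcome_correlations,
        covariate_effects=dict(cfg.covariate_effects),
        seed=seed,
        latent_tract_means=latent,
    )
    return df, gt


# ---------------------------------------------------------------------------
# Voxel-level cohort
# ---------------------------------------------------------------------------

def _radial_distance(spec: VoxelGridSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    r = np.sqrt((yy - cy) ** 2 + (zz - cz) ** 2)
    return np.broadcast_to(r[None, :, :], spec.shape).copy()


def make_atlas(spec: VoxelGridSpec) -> VoxelMap:
    """Shared probabilistic atlas: a tube with a graded probability profile."""
    r = _radial_distance(spec)
    prob = np.clip(
        (spec.atlas_edge_radius - r)
        / (spec.atlas_edge_radius - spec.atlas_core_radius),
        0.0,
        1.0,
    )
    lo, hi = spec.tract_axis_extent
    slab = np.zeros(spec.shape)
    slab[lo:hi] = 1.0
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return VoxelMap(prob * slab, affine, "atlas probability")


def generate_voxel_cohort(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[dict[str, dict[str, VoxelMap]], VoxelMap, pd.DataFrame, GroundTruth]:
    """Embed a generated cohort's latent tract means in synthetic map sets.

    For each participant the MTsat map carries the participant's latent
    MTsat mean inside the tract; the NODDI maps are constructed by
    inverting the g-ratio chain so that, with zero within-tract noise, the
    voxelwise MR g-ratio inside the tract equals the participant's latent
    g-ratio exactly (the neurite-density map is therefore the value the
    chain implies, not an independent marginal).  White-matter probability
    is high inside a participant-specific core radius and graded beyond it,
    so the 90% refinement produces varying ROI sizes.

    Returns (participant map sets, atlas map, behavioural table, ground
    truth).  Map sets are keyed by participant id and include ``wm_prob``;
    ground truth records the exact probability-weighted tract mean of every
    map under the default 25% / 90% thresholds.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    cohort, gt = generate_cohort(cfg, seed=int(rng.integers(2**31)))
    spec = cfg.voxel_grid
    tract = cfg.tracts[0]
    atlas = make_atlas(spec)
    r = _radial_distance(spec)
    lo, hi = spec.tract_axis_extent
    slab = np.zeros(spec.shape, dtype=bool)
    slab[lo:hi] = True
    in_tract = (atlas.values > 0) & slab
    alpha = cfg.calibration_alpha

    participants: dict[str, dict[str, VoxelMap]] = {}
    truth_rows = []
    for _, row in cohort.iterrows():
        pid = row["participant_id"]
        g_i = float(np.clip(row[f"{tract}__g_ratio"], 0.05, 0.98))
        mt_i = float(max(row[f"{tract}__mtsat"], 1e-3))
        iso_i = float(np.clip(row[f"{tract}__iso_fraction"], 1e-3, 0.5))
        odi_i = float(np.clip(row[f"{tract}__odi"], 1e-3, 0.95))

        noise = spec.within_tract_sd
        mtsat = np.full(spec.shape, spec.background["mtsat"])
        mtsat[in_tract] = mt_i + noise["mtsat"] * rng.standard_normal(in_tract.sum())
        mtsat = np.clip(mtsat, 1e-4, None)
        iso = np.full(spec.shape, spec.background["iso"])
        iso[in_tract] = np.clip(
            iso_i + noise["iso"] * rng.standard_normal(in_tract.sum()), 1e-4, 0.9
        )
        odi = np.full(spec.shape, spec.background["odi"])
        odi[in_tract] = np.clip(
            odi_i + noise["odi"] * rng.standard_normal(in_tract.sum()), 1e-4, 0.99
        )
        # invert the chain: choose icvf so that the voxelwise g equals target
        mvf = np.clip(alpha * mtsat, 0.0, 1 - 1e-9)
        g_target = np.full(spec.shape, 0.7)
        g_target[in_tract] = g_i
        avf = mvf * g_target**2 / (1.0 - g_target**2)
        awf = avf / (1.0 - mvf)
        icvf = awf / (1.0 - iso)
        icvf[in_tract] += noise["icvf"] * rng.standard_normal(in_tract.sum())
        icvf = np.clip(icvf, 1e-4, 1.0)

        # participant-specific plateau plus voxelwise segmentation noise ->
        # smoothly varying ROI sizes after the 90% cut
        plateau = rng.normal(spec.wm_plateau_mean, spec.wm_plateau_sd)
        wm = (
            plateau
            - spec.wm_falloff_per_voxel * np.maximum(r - 1.0, 0.0)
            + spec.wm_voxel_noise_sd * rng.standard_normal(spec.shape)
        )
        wm = np.clip(wm, 0.0, 1.0) * slab

        maps = {
            "mtsat": atlas.with_values(mtsat, "MTsat"),
            "icvf": atlas.with_values(icvf, "nu_icvf"),
            "iso": atlas.with_values(iso, "nu_iso"),
            "odi": atlas.with_values(odi, "ODI"),
            "wm_prob": atlas.with_values(wm, "WM probability"),
        }
        participants[pid] = maps

        # exact bookkeeping of what extraction should recover
        sel = (atlas.values >= 0.25) & (wm >= 0.90)
        w = wm[sel]
        mvf_v, awf_v = mvf[sel], awf[sel]
        icvf_v, iso_v = icvf[sel], iso[sel]
        awf_true = (1.0 - iso_v) * icvf_v
        avf_true = (1.0 - mvf_v) * awf_true
        g_v = np.sqrt(avf_true / (avf_true + mvf_v))
        per_metric = {
            "mtsat": mtsat[sel], "icvf": icvf_v, "iso": iso_v,
            "odi": odi[sel], "g_ratio": g_v,
        }
        for metric, vals in per_metric.items():
            truth_rows.append(
                {
                    "participant_id": pid, "tract": tract, "metric": metric,
                    "true_weighted_mean": float(np.dot(w, vals) / w.sum()),
                    "n_voxels": int(sel.sum()),
                }
            )

    gt = replace(gt, true_weighted_means=pd.DataFrame(truth_rows))
    behavioural = cohort[
        ["participant_id", "age", "gender", "scanner"]
        + list(cfg.outcomes) + list(cfg.lab_outcomes)
    ].copy()
    return participants, atlas, behavioural, gt


def write_voxel_cohort(participants, atlas, behavioural, gt, out_dir) -> dict:
    """Write map sets as NIfTI files plus manifest, behavioural CSV and truth JSON."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas_path = out / "atlas.nii.gz"
    atlas.to_nifti(atlas_path)
    manifest_rows = []
    for pid, maps in participants.items():
        entry = {"participant_id": pid}
        for key, vmap in maps.items():
            p = out / f"{pid}_{key}.nii.gz"
            vmap.to_nifti(p)
            entry[key] = str(p)
        manifest_rows.append(entry)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "maps_manifest.csv", index=False)
    behavioural.to_csv(out / "behaviour.csv", index=False)
    truth = {
        "seed": gt.seed,
        "target_partial_correlations": [list(t) for t in gt.target_partial_correlations],
    }
    if gt.true_weighted_means is not None:
        truth["true_weighted_means"] = gt.true_weighted_means.to_dict(orient="records")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {
        "atlas": str(atlas_path),
        "manifest": str(out / "maps_manifest.csv"),
        "behaviour": str(out / "behaviour.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Monte-Carlo summary of how well the battery recovers configured effects."""

    per_target: pd.DataFrame
    n_replicates: int
    n_boot: int
    alpha: float
    m_tracts: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_boot": self.n_boot,
            "alpha": self.alpha,
            "m_tracts": self.m_tracts,
            "seed": self.seed,
            "targets": self.per_target.to_dict(orient="records"),
        }


def recovery_experiment(
    cfg: SyntheticConfig,
    n_replicates: int = 200,
    seed: int | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
    m_tracts: int = 3,
    ci_level: float = 0.95,
) -> RecoveryReport:
    """Generate-analyse loop: bias, RMSE, CI coverage and power per target.

    Each replicate draws a fresh cohort, estimates every configured target
    partial correlation with its covariate set (age, gender, scanner and
    the tract's ROI voxel count), bootstraps the CI, and records whether
    the CI covers the true rho and whether p falls below the Bonferroni
    threshold alpha / m_tracts.
    """
    if not cfg.target_partial_correlations:
        raise ConfigError("recovery requires at least one configured target correlation")
    rng = np.random.default_rng(seed)
    thr = bonferroni_threshold(alpha, m_tracts)
    targets = cfg.target_partial_correlations
    rec: dict[tuple, dict[str, list]] = {
        t: {"r": [], "cover": [], "reject": []} for t in targets
    }
    for _ in range(n_replicates):
        cohort, _ = generate_cohort(cfg, seed=int(rng.integers(2**31)))
        for t in targets:
            tract, metric, outcome, rho = t
            covs = cohort[
                [*STANDARD_COVARIATES, f"{tract}__n_voxels"]
            ].to_numpy(dtype=float)
            x = cohort[f"{tract}__{metric}"].to_numpy(dtype=float)
            y = cohort[outcome].to_numpy(dtype=float)
            res = partial_correlation_with_ci(
                x, y, covs, n_boot=n_boot, level=ci_level,
                seed=int(rng.integers(2**31)),
            )
            rec[t]["r"].append(res.r)
            rec[t]["cover"].append(res.ci_low <= rho <= res.ci_high)
            rec[t]["reject"].append(res.p < thr)
    rows = []
    for t, d in rec.items():
        tract, metric, outcome, rho = t
        r = np.asarray(d["r"])
        rows.append(
            {
                "tract": tract, "metric": metric, "outcome": outcome, "rho": rho,
                "mean_r": float(r.mean()),
                "bias": float(r.mean() - rho),
                "rmse": float(np.sqrt(np.mean((r - rho) ** 2))),
                "ci_coverage": float(np.mean(d["cover"])),
                "power_bonferroni": float(np.mean(d["reject"])),
            }
        )
    return RecoveryReport(
        per_target=pd.DataFrame(rows),
        n_replicates=n_replicates,
        n_boot=n_boot,
        alpha=alpha,
        m_tracts=m_tracts,
        seed=seed,
    )


def null_rejection_rates(
    n_replicates: int = 1000,
    seed: int | None = None,
    n_participants: int = 217,
    tracts: tuple[str, ...] = ("fornix", "uncinate_fasciculus", "parahippocampal_cingulum"),
    metric: str = "g_ratio",
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the battery on fully null cohorts.

    Returns the per-test uncorrected rejection rate and the family-wise
    error rate across the primary tracts at the Bonferroni threshold.
    """
    cfg = SyntheticConfig(
        n_participants=n_participants,
        tracts=tracts,
        target_partial_correlations=(),
    )
    rng = np.random.default_rng(seed)
    thr = bonferroni_threshold(alpha, len(tracts))
    reject_unc = []
    fwe = []
    for _ in range(n_replicates):
        cohort, _ = generate_cohort(cfg, seed=int(rng.integers(2**31)))
        y = cohort["internal_details"].to_numpy(dtype=float)
        ps = []
        for tract in tracts:
            covs = cohort[[*STANDARD_COVARIATES, f"{tract}__n_voxels"]].to_numpy(dtype=float)
            x = cohort[f"{tract}__{metric}"].to_numpy(dtype=float)
            ps.append(partial_correlation(x, y, covs).p)
        ps = np.asarray(ps)
        reject_unc.extend(ps < alpha)
        fwe.append(bool((ps < thr).any()))
    return {
        "uncorrected_rejection_rate": float(np.mean(reject_unc)),
        "familywise_error_rate": float(np.mean(fwe)),
        "n_replicates": n_replicates,
        "n_tests": len(tracts) * n_replicates,
    }
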