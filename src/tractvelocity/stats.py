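"""Covariate-adjusted correlation battery for tract-metric / behaviour data.

The battery mirrors a standard individual-differences design: for each
tract and microstructure metric, a partial correlation with the primary
behavioural outcome adjusting for age, gender, scanner and the tract's ROI
voxel count, with percentile bootstrap confidence intervals; the same
against a control outcome; Bonferroni correction over the primary tracts;
and, wherever the primary association is significant, a test of the
difference between the two dependent overlapping correlations (both share
the tract metric) using the Meng-Rosenthal-Rubin extension of the Fisher z
transformation.  Inter-rater reliability of the behavioural scoring is
quantified with two-way random-effects absolute-agreement ICCs.

Partial correlations are computed by residualization: x and y are each
regressed on [intercept | covariates] by least squares and the Pearson
correlation of the residuals is reported with df = n - 2 - k.  Scanner is
treated as a single numeric covariate (matching df = n - 2 - 4 = 211 at
n = 217 with four covariates); dummy coding is available via
``dummy_code_scanner`` with df adjusted accordingly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biophysics import Association, ScenarioCall, classify_scenario

logger = logging.getLogger("tractvelocity")


class SingularDesignError(ValueError):
    """The covariate design matrix is rank deficient."""


class UndefinedCorrelationError(ValueError):
    """A residual has zero variance, so the correlation is undefined."""


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrResult:
    """Partial correlation with df accounting and optional bootstrap CI."""

    r: float
    n: int
    k: int
    df: int
    p: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def __str__(self) -> str:  # report-style rendering
        s = f"r({self.df}) = {self.r:.2f}, p = {self.p:.3g}"
        if self.ci_low is not None:
            s += f", 95% CI = {self.ci_low:.2f}, {self.ci_high:.2f}"
        return s


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _residualize(z: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return z - X @ beta


def partial_correlation(
    x, y, covariates=None, *, check_rank: bool = True
) -> PartialCorrResult:
    """Partial correlation of x and y given covariates, via residualization.

    p is two-sided from t = r sqrt(df / (1 - r^2)) on Student-t(df),
    df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    X = _design(np.asarray(covariates, dtype=float) if covariates is not None else None, n)
    k = X.shape[1] - 1
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("covariate design matrix is rank deficient")
    rx = _residualize(x, X)
    ry = _residualize(y, X)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    scale = max(np.linalg.norm(x - x.mean()), np.linalg.norm(y - y.mean()), 1.0)
    if sx <= 1e-12 * scale or sy <= 1e-12 * scale:
        raise UndefinedCorrelationError("zero residual variance after adjustment")
    r = float(np.clip(np.dot(rx, ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, n=n, k=k, df=df, p=p)


def _batch_partial_r(Z: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Partial r of columns 0 and 1 of Z given the rest, for many resamples.

    ``idx`` is (B, n) row indices.  Residualization is solved through the
    normal equations, batched; resamples with a (near-)singular design or
    zero residual variance come back NaN for the caller to redraw.
    """
    B, n = idx.shape
    Zb = Z[idx]                                   # (B, n, p)
    Xb = np.concatenate([np.ones((B, n, 1)), Zb[:, :, 2:]], axis=2)  # (B, n, q)
    Yb = Zb[:, :, :2]                             # (B, n, 2)
    XtX = np.einsum("bij,bik->bjk", Xb, Xb)
    XtY = np.einsum("bij,bik->bjk", Xb, Yb)
    q = XtX.shape[1]
    # tiny ridge only as a singularity detector: solve, then validate
    out = np.full(B, np.nan)
    try:
        beta = np.linalg.solve(XtX, XtY)
        ok = np.ones(B, bool)
    except np.linalg.LinAlgError:
        beta = np.full((B, q, 2), np.nan)
        ok = np.zeros(B, bool)
        for b in range(B):
            try:
                beta[b] = np.linalg.solve(XtX[b], XtY[b])
                ok[b] = True
            except np.linalg.LinAlgError:
                pass
    resid = Yb - np.einsum("bij,bjk->bik", Xb, beta)
    sx = np.linalg.norm(resid[:, :, 0], axis=1)
    sy = np.linalg.norm(resid[:, :, 1], axis=1)
    denom = sx * sy
    good = ok & (denom > 1e-12 * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("bi,bi->b", resid[:, :, 0], resid[:, :, 1]) / denom
    out[good] = np.clip(r[good], -1.0, 1.0)
    # guard against ill-conditioned solves that slipped through
    out[~np.isfinite(out)] = np.nan
    return out


def bootstrap_ci(
    x,
    y,
    covariates=None,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "percentile",
) -> tuple[float, float]:
    """Bootstrap CI for the partial correlation by case resampling.

    Whole participant rows (x, y, covariates jointly) are resampled with
    replacement; resamples with a singular design or zero residual variance
    are redrawn (count logged).  ``method`` is ``"percentile"`` (default)
    or ``"bca"``.
    """
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small for a CI", stacklevel=2)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    Z = np.column_stack([x, y]) if C is None else np.column_stack([x, y, C])

    rng = np.random.default_rng(seed)
    r_boot = np.empty(n_boot)
    pending = np.arange(n_boot)
    n_redraws = 0
    for _ in range(100):
        idx = rng.integers(0, n, size=(pending.size, n))
        r_new = _batch_partial_r(Z, idx)
        bad = ~np.isfinite(r_new)
        r_boot[pending] = r_new
        pending = pending[bad]
        if pending.size == 0:
            break
        n_redraws += pending.size
    else:
        raise UndefinedCorrelationError(
            "bootstrap resamples persistently degenerate; data may be constant"
        )
    if n_redraws:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", n_redraws)

    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.quantile(r_boot, [alpha / 2, 1 - alpha / 2])
    elif method == "bca":
        lo, hi = _bca_interval(x, y, C, r_boot, alpha)
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")
    return float(lo), float(hi)


def _bca_interval(x, y, C, r_boot, alpha):
    """Bias-corrected and accelerated endpoints from the bootstrap sample."""
    n = x.size
    r_hat = partial_correlation(x, y, C).r
    prop = np.mean(r_boot < r_hat)
    prop = min(max(prop, 1.0 / (len(r_boot) + 1)), 1 - 1.0 / (len(r_boot) + 1))
    z0 = sps.norm.ppf(prop)
    # jackknife acceleration
    r_jack = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        r_jack[i] = partial_correlation(
            x[keep], y[keep], None if C is None else C[keep]
        ).r
    d = r_jack.mean() - r_jack
    denom = 6.0 * (np.sum(d**2) ** 1.5)
    a = np.sum(d**3) / denom if denom > 0 else 0.0
    z_lo, z_hi = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    q_lo = sps.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    q_hi = sps.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    return np.quantile(r_boot, q_lo), np.quantile(r_boot, q_hi)


def partial_correlation_with_ci(
    x, y, covariates=None, n_boot: int = 10_000, level: float = 0.95,
    seed: int | None = None, method: str = "percentile",
) -> PartialCorrResult:
    """Point estimate plus bootstrap CI in one result object."""
    res = partial_correlation(x, y, covariates)
    if n_boot > 0:
        res.ci_low, res.ci_high = bootstrap_ci(
            x, y, covariates, n_boot=n_boot, level=level, seed=seed, method=method
        )
        res.n_boot = n_boot
        res.seed = seed
    return res


# ---------------------------------------------------------------------------
# Comparing two dependent overlapping correlations (Meng-Rosenthal-Rubin)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependentCorrComparison:
    """z test of r1 vs r2 where both correlations share one variable."""

    r1: float
    r2: float
    r12: float
    n: int
    z: float
    p: float
    r_difference: float


def compare_dependent_correlations(
    r1: float, r2: float, r12: float, n: int
) -> DependentCorrComparison:
    """Meng-Rosenthal-Rubin z test for two overlapping dependent correlations.

    r1 = cor(x, y1), r2 = cor(x, y2), r12 = cor(y1, y2), all from the same
    n cases.  With z_i = atanh(r_i), rbar2 = (r1^2 + r2^2)/2,
    f = min(1, (1 - r12) / (2 (1 - rbar2))) and
    h = (1 - f rbar2) / (1 - rbar2):

        z = (z1 - z2) sqrt((n - 3) / (2 (1 - r12) h))

    with a two-sided normal p-value.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1 * r1 + r2 * r2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DependentCorrComparison(
        r1=r1, r2=r2, r12=r12, n=n, z=float(z), p=p, r_difference=r1 - r2
    )


def bonferroni_threshold(alpha: float = 0.05, m: int = 3) -> float:
    """Per-test significance threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# Intraclass correlation (two-way random effects, absolute agreement)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc_single: float
    icc_average: float
    n_subjects: int
    k_raters: int
    model: str = "two-way random, absolute agreement"


def icc_absolute_agreement(ratings) -> ICCResult:
    """ICC(A,1) and ICC(A,k) from a complete subjects x raters matrix.

    Two-way random-effects ANOVA decomposition:

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
        ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = R.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n} x {k}")
    if not np.isfinite(R).all():
        raise ValueError("ratings matrix must be complete (no missing values)")
    grand = R.mean()
    ss_total = float(((R - grand) ** 2).sum())
    if ss_total <= 0:
        raise UndefinedCorrelationError("zero total variance in ratings")
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ms_r = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    ms_c = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    ss_e = ss_total - k * float(((row_means - grand) ** 2).sum()) - n * float(
        ((col_means - grand) ** 2).sum()
    )
    ms_e = ss_e / ((n - 1) * (k - 1))
    icc1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    icck = (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)
    return ICCResult(icc_single=float(icc1), icc_average=float(icck),
                     n_subjects=n, k_raters=k)


# ---------------------------------------------------------------------------
# Battery orchestration
# ---------------------------------------------------------------------------

STANDARD_COVARIATES = ("age", "gender", "scanner")


def _covariate_matrix(
    cohort: pd.DataFrame, columns: list[str], dummy_code_scanner: bool = False
) -> np.ndarray:
    """Assemble the covariate matrix, dropping constant columns with a warning."""
    cols = []
    for c in columns:
        v = cohort[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.warning("covariate '%s' is constant; dropped from the design", c)
            continue
        if c == "scanner" and dummy_code_scanner:
            levels = np.unique(v)
            for lv in levels[1:]:
                cols.append((v == lv).astype(float))
        else:
            cols.append(v)
    if not cols:
        return np.empty((len(cohort), 0))
    return np.column_stack(cols)


def precheck_voxelcount(
    cohort: pd.DataFrame,
    tracts: list[str],
    outcome: str = "internal_details",
    report_threshold: float = 0.12,
) -> dict[str, PartialCorrResult]:
    """Partial correlation of each tract's ROI voxel count with the outcome.

    Covariates are age, gender and scanner (k = 3; the voxel count is the
    tested variable here, not a covariate).  Results with |r| above
    ``report_threshold`` are flagged in the log.  A tract whose voxel-count
    column is degenerate maps to the surfaced exception instead of a
    result, and the remaining tracts still run.
    """
    out: dict[str, PartialCorrResult] = {}
    C = _covariate_matrix(cohort, list(STANDARD_COVARIATES))
    y = cohort[outcome].to_numpy(dtype=float)
    for tract in tracts:
        x = cohort[f"{tract}__n_voxels"].to_numpy(dtype=float)
        try:
            res = partial_correlation(x, y, C)
        except (SingularDesignError, UndefinedCorrelationError) as exc:
            logger.warning("precheck: %s: %s", tract, exc)
            out[tract] = exc
            continue
        if abs(res.r) > report_threshold:
            logger.warning(
                "precheck: |r|=%.3f between %s ROI size and %s exceeds %.2f",
                abs(res.r), tract, outcome, report_threshold,
            )
        out[tract] = res
    return out


@dataclass
class BatteryReport:
    """Full output of the association battery."""

    results: pd.DataFrame
    comparisons: pd.DataFrame
    scenarios: dict[str, ScenarioCall]
    precheck: dict[str, PartialCorrResult]
    alpha: float
    threshold_corrected: float
    m_tracts: int
    n_boot: int
    seed: int | None
    errors: list[str] = field(default_factory=list)


def _association_label(res: PartialCorrResult, threshold: float) -> str:
    if res.p < threshold:
        return Association.POSITIVE.value if res.r > 0 else Association.NEGATIVE.value
    return Association.NULL.value


def run_association_battery(
    cohort: pd.DataFrame,
    tracts: list[str],
    metrics: list[str],
    primary_outcome: str = "internal_details",
    control_outcome: str = "external_details",
    lab_outcomes: tuple[str, ...] = (),
    lab_metrics: tuple[str, ...] = ("g_ratio", "mtsat"),
    alpha: float = 0.05,
    m_tracts: int = 3,
    n_boot: int = 10_000,
    seed: int | None = None,
    primary_tracts: list[str] | None = None,
    exploratory_tracts: list[str] | None = None,
    run_precheck: bool = True,
    dummy_code_scanner: bool = False,
    r12_adjusted: bool = True,
    n_adjusted_comparison: bool = False,
) -> BatteryReport:
    """Run the full covariate-adjusted correlation battery.

    For every tract x metric the partial correlation (covariates: age,
    gender, scanner, that tract's ROI voxel count) with bootstrap CI is
    computed against the primary and the control outcome; significance is
    judged at alpha / m_tracts for primary tracts and uncorrected alpha
    (flagged as exploratory) otherwise.  Where the primary association is
    significant, the two dependent correlations are compared with r12 equal
    to the (by default covariate-adjusted) primary-control outcome
    correlation.  Metrics listed in ``lab_metrics`` are additionally tested
    against each laboratory outcome.  A microstructural scenario call is
    attached per tract from its g-ratio and MTsat association labels.
    """
    if cohort["participant_id"].duplicated().any():
        raise ValueError("duplicated participant_id in cohort")
    primary_tracts = list(primary_tracts) if primary_tracts is not None else list(tracts)[:m_tracts]
    exploratory = set(exploratory_tracts or []) | (set(tracts) - set(primary_tracts))
    threshold_corrected = bonferroni_threshold(alpha, m_tracts)
    rng = np.random.default_rng(seed)

    precheck = (
        precheck_voxelcount(cohort, list(tracts), primary_outcome) if run_precheck else {}
    )

    rows: list[dict] = []
    comparisons: list[dict] = []
    errors: list[str] = []
    assoc_labels: dict[tuple[str, str], str] = {}

    for tract in tracts:
        is_primary = tract in primary_tracts and tract not in exploratory
        thr = threshold_corrected if is_primary else alpha
        try:
            C = _covariate_matrix(
                cohort,
                [*STANDARD_COVARIATES, f"{tract}__n_voxels"],
                dummy_code_scanner=dummy_code_scanner,
            )
        except KeyError as exc:
            errors.append(f"{tract}: missing column {exc}")
            continue
        y1 = cohort[primary_outcome].to_numpy(dtype=float)
        y2 = cohort[control_outcome].to_numpy(dtype=float)
        for metric in metrics:
            col = f"{tract}__{metric}"
            if col not in cohort.columns:
                errors.append(f"{tract}: missing column {col}")
                continue
            x = cohort[col].to_numpy(dtype=float)
            try:
                res1 = partial_correlation_with_ci(
                    x, y1, C, n_boot=n_boot,
                    seed=int(rng.integers(2**31)) if seed is not None else None,
                )
                res2 = partial_correlation_with_ci(
                    x, y2, C, n_boot=n_boot,
                    seed=int(rng.integers(2**31)) if seed is not None else None,
                )
            except (SingularDesignError, UndefinedCorrelationError) as exc:
                errors.append(f"{tract} x {metric}: {exc}")
                continue
            for outcome, res in ((primary_outcome, res1), (control_outcome, res2)):
                rows.append(
                    {
                        "tract": tract,
                        "metric": metric,
                        "outcome": outcome,
                        "r": res.r, "df": res.df, "p": res.p,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "threshold": thr,
                        "significant": res.p < thr,
                        "tier": "primary" if is_primary else "exploratory",
                    }
                )
            assoc_labels[(tract, metric)] = _association_label(res1, thr)
            if res1.p < thr:
                try:
                    if r12_adjusted:
                        r12 = partial_correlation(y1, y2, C).r
                    else:
                        r12 = float(np.corrcoef(y1, y2)[0, 1])
                    n_eff = res1.n - res1.k if n_adjusted_comparison else res1.n
                    comp = compare_dependent_correlations(res1.r, res2.r, r12, n_eff)
                    comparisons.append(
                        {
                            "tract": tract, "metric": metric,
                            "r_primary": comp.r1, "r_control": comp.r2,
                            "r12": comp.r12, "n": comp.n, "z": comp.z, "p": comp.p,
                            "r_difference": comp.r_difference,
                            "significant": comp.p < alpha,
                        }
                    )
                except ValueError as exc:
                    errors.append(f"{tract} x {metric} comparison: {exc}")
            # laboratory outcomes for the myelin-informative metrics
            if metric in lab_metrics:
                for lab in lab_outcomes:
                    try:
                        resl = partial_correlation_with_ci(
                            x, cohort[lab].to_numpy(dtype=float), C, n_boot=n_boot,
                            seed=int(rng.integers(2**31)) if seed is not None else None,
                        )
                    except (SingularDesignError, UndefinedCorrelationError) as exc:
                        errors.append(f"{tract} x {metric} x {lab}: {exc}")
                        continue
                    rows.append(
                        {
                            "tract": tract, "metric": metric, "outcome": lab,
                            "r": resl.r, "df": resl.df, "p": resl.p,
                            "ci_low": resl.ci_low, "ci_high": resl.ci_high,
                            "threshold": thr, "significant": resl.p < thr,
                            "tier": "laboratory",
                        }
                    )

    scenarios: dict[str, ScenarioCall] = {}
    for tract in tracts:
        g_lbl = assoc_labels.get((tract, "g_ratio"))
        m_lbl = assoc_labels.get((tract, "mtsat"))
        if g_lbl is not None and m_lbl is not None:
            scenarios[tract] = classify_scenario(g_lbl, m_lbl)

    results = pd.DataFrame(
        rows,
        columns=["tract", "metric", "outcome", "r", "df", "p", "ci_low",
                 "ci_high", "threshold", "significant", "tier"],
    )
    comparisons_df = pd.DataFrame(
        comparisons,
        columns=["tract", "metric", "r_primary", "r_control", "r12", "n",
                 "z", "p", "r_difference", "significant"],
    )
    if errors:
        logger.warning("battery completed with %d cell error(s)", len(errors))
    return BatteryReport(
        results=results,
        comparisons=comparisons_df,
        scenarios=scenarios,
        precheck=precheck,
        alpha=alpha,
        threshold_corrected=threshold_corrected,
        m_tracts=m_tracts,
        n_boot=n_boot,
        seed=seed,
        errors=errors,
    )
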