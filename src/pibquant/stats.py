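"""Summary metrics and agreement statistics for amyloid PET quantification.

Covers the mean cortical binding potential (MCBP, the unweighted mean
BP_ND over the prefrontal, precuneus, gyrus rectus and lateral temporal
composites), dichotomous PiB status (MCBP > 0.18), region-specific
positivity-threshold search, test-retest variability (mean absolute
percent difference over the pair mean), variance-components ICC with
fixed-covariate adjustment, and Pearson/Spearman correlation reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regions import MCBP_COMPOSITES

__all__ = [
    "SubjectReport",
    "TestRetestResult",
    "ICCComponents",
    "mcbp",
    "classify_pib",
    "threshold_search",
    "delta_pct",
    "icc_vc",
    "correlation_report",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 0.18  # MCBP positivity criterion, strict ">"


@dataclass
class SubjectReport:
    """Per-subject quantification summary."""

    subject: str
    regional_bp: dict[str, float]
    mcbp: float
    pib_status: str  # "positive" | "negative"
    pvc_applied: bool
    dilution_factors: dict[str, float] | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "subject": self.subject,
            "mcbp": self.mcbp,
            "pib_status": self.pib_status,
            "pvc_applied": self.pvc_applied,
            "regional_bp": self.regional_bp,
            "dilution_factors": self.dilution_factors,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class TestRetestResult:
    """Test-retest variability of BP_ND and ROI volume for one region."""

    region: str
    delta_bp_pct: float
    delta_vol_pct: float
    icc_bp: float | None
    icc_vol: float | None
    n_subjects: int

    def __post_init__(self):
        if self.delta_bp_pct < 0 or self.delta_vol_pct < 0:
            raise ValueError("delta metrics are non-negative by construction")


@dataclass(frozen=True)
class ICCComponents:
    """Variance components and the agreement ICC they imply."""

    var_subject: float
    var_rater: float
    var_residual: float
    icc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_subjects: int = 0
    n_reps: int = 0

    def __post_init__(self):
        if min(self.var_subject, self.var_rater, self.var_residual) < 0:
            raise ValueError("variance components must be truncated at 0")
        if not (0.0 <= self.icc <= 1.0):
            raise ValueError("icc must lie in [0, 1]")


def mcbp(regional_bp: dict[str, float], members=MCBP_COMPOSITES) -> float:
    """Unweighted mean BP_ND over the four MCBP composite regions."""
    missing = [m for m in members if m not in regional_bp]
    if missing:
        raise KeyError(f"MCBP requires missing regions: {missing}")
    return float(np.mean([regional_bp[m] for m in members]))


def classify_pib(mcbp_value: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """PiB status: 'positive' iff the value strictly exceeds the cutoff."""
    if not np.isfinite(mcbp_value):
        raise ValueError(f"non-finite MCBP value: {mcbp_value}")
    return "positive" if mcbp_value > cutoff else "negative"


def _as_bool_status(status) -> np.ndarray:
    arr = np.asarray(status)
    if arr.dtype.kind == "b":
        return arr
    return np.asarray([s == "positive" if isinstance(s, str) else bool(s) for s in arr])


def threshold_search(regional_values, reference_status) -> tuple[float, int, float]:
    """Best region-specific positivity threshold against a reference labelling.

    Scans candidate thresholds (midpoints of adjacent sorted values, plus
    the extremes that label everyone negative or everyone positive) and
    returns (threshold, NOD, D%) where NOD is the number of subjects whose
    classification ``value > threshold`` disagrees with the reference and
    D% = 100 * NOD / N. Ties are broken toward the smallest threshold.
    """
    values = np.asarray(regional_values, dtype=float)
    ref = _as_bool_status(reference_status)
    if values.size == 0:
        raise ValueError("empty input to threshold_search")
    if values.shape != ref.shape:
        raise ValueError("values and reference status must have equal length")

    uniq = np.unique(values)
    candidates = list((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(float(uniq[-1]))  # all negative under strict ">"
    candidates.append(float(np.nextafter(uniq[0], -np.inf)))  # all positive
    candidates = sorted(candidates)

    best_thr, best_nod = None, None
    for thr in candidates:
        nod = int(np.sum((values > thr) != ref))
        if best_nod is None or nod < best_nod:
            best_thr, best_nod = thr, nod
    d_pct = 100.0 * best_nod / values.size
    return float(best_thr), int(best_nod), float(d_pct)


def delta_pct(pairs) -> float:
    """Mean absolute test-retest percent difference.

    (100/N) * sum_i |x_i1 - x_i2| / ((x_i1 + x_i2)/2). The absolute value
    of the pair mean is used so the metric stays a non-negative percent for
    near-zero (possibly negative) binding values. Subjects with a zero pair
    mean are excluded with a warning.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (N, 2) array of test/retest values")
    if arr.shape[0] == 0:
        raise ValueError("delta_pct requires at least one subject")
    means = arr.mean(axis=1)
    keep = means != 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} subject(s) with zero pair mean", stacklevel=2
        )
    if not keep.any():
        raise ValueError("all subjects have zero pair mean")
    rel = np.abs(arr[keep, 0] - arr[keep, 1]) / np.abs(means[keep])
    return float(100.0 * rel.mean())


def _residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove fixed covariate effects by least squares (intercept included)."""
    x = np.column_stack([np.ones(len(values)), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear covariates in ICC adjustment")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    resid = values - x @ beta
    # keep the grand mean so values stay on their original scale
    return resid + values.mean()


def icc_vc(
    table: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "subject",
    rater_col: str | None = None,
    covariate_cols: list[str] | None = None,
    alpha: float = 0.05,
) -> ICCComponents:
    """Agreement ICC from ANOVA variance components.

    Each subject needs >= 2 observations. Optional fixed covariates (e.g.
    age, ApoE4, CDR status) are removed by least-squares residualization
    before component estimation. With a rater column and a balanced
    design, a two-way random-effects decomposition (subject, rater,
    residual) is used; otherwise a one-way decomposition (subject,
    residual; the unbalanced case uses the standard adjusted replicate
    count). Negative component estimates are truncated to zero and
    icc = var_subject / (var_subject + var_rater + var_residual).

    The confidence interval is the exact F-based interval for the
    balanced one-way layout, reported as an approximation when a rater
    component is present.
    """
    df = table.copy()
    values = df[value_col].to_numpy(float)
    subjects = df[subject_col].to_numpy()

    counts = pd.Series(subjects).value_counts()
    if (counts < 2).any():
        lonely = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects with a single observation: {lonely}")

    if covariate_cols:
        cov = df[list(covariate_cols)].to_numpy(float)
        values = _residualize(values, cov)

    n = counts.size
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())

    subj_means = pd.Series(values).groupby(pd.Series(subjects).values).transform("mean").to_numpy()
    ss_within = float(((values - subj_means) ** 2).sum())
    ss_subject = ss_total - ss_within

    balanced = counts.nunique() == 1
    k = float(counts.iloc[0]) if balanced else float(
        (len(values) - (counts**2).sum() / len(values)) / (n - 1)
    )

    ms_subject = ss_subject / (n - 1)

    var_rater = 0.0
    if rater_col is not None:
        raters = df[rater_col].to_numpy()
        r_levels = pd.unique(raters)
        if balanced and len(r_levels) == int(k):
            # two-way random effects, balanced: subject x rater, one obs per cell
            kk = int(k)
            rater_means = pd.Series(values).groupby(pd.Series(raters).values).transform("mean").to_numpy()
            ss_rater = float(((rater_means - grand) ** 2).sum())
            ss_error = ss_total - ss_subject - ss_rater
            ms_rater = ss_rater / (kk - 1)
            ms_error = ss_error / ((n - 1) * (kk - 1))
            var_resid = max(ms_error, 0.0)
            var_rater = max((ms_rater - ms_error) / n, 0.0)
            var_subj = max((ms_subject - ms_error) / kk, 0.0)
        else:
            raise ValueError(
                "rater-effect ICC requires a balanced subject x rater design; "
                "drop rater_col for the one-way decomposition"
            )
    else:
        ms_within = ss_within / (len(values) - n)
        var_resid = max(ms_within, 0.0)
        var_subj = max((ms_subject - ms_within) / k, 0.0)
        ms_error = ms_within

    denom = var_subj + var_rater + var_resid
    if denom <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    icc = var_subj / denom

    ci_low = ci_high = None
    if balanced and ms_error > 0:
        kk = counts.iloc[0]
        dfn, dfd = n - 1, len(values) - n if rater_col is None else (n - 1) * (int(kk) - 1)
        f_obs = ms_subject / ms_error
        f_l = f_obs / sps.f.ppf(1 - alpha / 2, dfn, dfd)
        f_u = f_obs * sps.f.ppf(1 - alpha / 2, dfd, dfn)
        ci_low = max((f_l - 1) / (f_l + kk - 1), 0.0)
        ci_high = min((f_u - 1) / (f_u + kk - 1), 1.0)

    return ICCComponents(
        var_subject=float(var_subj),
        var_rater=float(var_rater),
        var_residual=float(var_resid),
        icc=float(min(max(icc, 0.0), 1.0)),
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects=int(n),
        n_reps=int(round(k)),
    )


def correlation_report(x, y) -> dict[str, float]:
    """Pearson r, Spearman rho and the least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation_report needs matched samples with N >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    pearson_r, pearson_p = sps.pearsonr(x, y)
    spearman_r, spearman_p = sps.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "pearson_r": float(pearson_r),
        "pearson_p": float(pearson_p),
        "spearman_r": float(spearman_r),
        "spearman_p": float(spearman_p),
        "slope": float(slope),
        "intercept": float(intercept),
    }
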