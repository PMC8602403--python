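"""Group-level inference and robustness analyses.

Repeated measurements (per-cell scores, per-spot frequencies) within a
patient are not independent, so group contrasts use a linear mixed model
with a random intercept per patient, REML-fitted; p-values use
Satterthwaite's degrees-of-freedom approximation. When the four standard
group/timepoint contrasts are tested together they are Holm-Bonferroni
corrected; pre- and post-treatment biomarker contrasts are reported
unadjusted because they address independent questions (prediction vs
treatment effect).

Robustness of a contrast is probed three ways: 100-iteration random
subsampling at a fixed fraction of the observations, leave-one-patient-out
exclusion, and bootstrap-coupled estimation of the mean-difference effect
size (percentile CI over 5,000 resamples). Biomarker performance is an
empirical ROC with the cutoff at maximum Youden's J.

The mixed-model fit itself comes from statsmodels (MixedLM); the
Satterthwaite df — not available there — is computed here via the delta
method on the REML information of the variance components, using the
closed-form block inverses the random-intercept structure allows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# random-intercept model with Satterthwaite df


@dataclass
class GroupComparison:
    contrast: tuple[str, str]
    estimate: float  # mean(first) - mean(second), adjusted for patient effects
    se: float
    df: float
    t: float
    p_value: float
    method: str  # "mixedlm" | "ols_fallback"
    adjustment: str = "none"
    p_adjusted: float | None = None
    n_obs: int = 0


def _block_views(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    _, starts = np.unique(go, return_index=True)
    bounds = list(starts) + [len(go)]
    return [
        (Xo[bounds[i] : bounds[i + 1]], yo[bounds[i] : bounds[i + 1]])
        for i in range(len(starts))
    ]


def _gls_pieces(blocks, tau2: float, sigma2: float):
    """X'V^-1X, X'V^-1y and log|V| using the rank-one block structure."""
    p = blocks[0][0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    for Xi, yi in blocks:
        m = len(yi)
        w = tau2 / (sigma2 + m * tau2)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        XtVX += (Xi.T @ Xi - w * np.outer(sx, sx)) / sigma2
        XtVy += (Xi.T @ yi - w * sx * sy) / sigma2
        logdet += (m - 1) * np.log(sigma2) + np.log(sigma2 + m * tau2)
    return XtVX, XtVy, logdet


def _reml_loglik(theta: np.ndarray, blocks) -> float:
    # tau^2 lives on [0, inf); finite-difference probes below 0 are clamped
    # to the boundary so the numeric Hessian stays finite near singular fits
    tau2, sigma2 = max(float(theta[0]), 0.0), float(theta[1])
    if sigma2 <= 0:
        return -np.inf
    XtVX, XtVy, logdet = _gls_pieces(blocks, tau2, sigma2)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return -np.inf
    quad = 0.0
    for Xi, yi in blocks:
        m = len(yi)
        w = tau2 / (sigma2 + m * tau2)
        ri = yi - Xi @ beta
        quad += (ri @ ri - w * ri.sum() ** 2) / sigma2
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet + logdet_xvx + quad)


def _satterthwaite_df(blocks, tau2: float, sigma2: float, c: np.ndarray) -> float:
    """df = 2 f^2 / (grad f' A grad f), f = c' (X'V^-1X)^-1 c, with A the
    inverse observed REML information of (tau^2, sigma^2)."""

    def f(theta):
        XtVX, _, _ = _gls_pieces(
            blocks, max(theta[0], 0.0), max(theta[1], 1e-300)
        )
        try:
            return float(c @ np.linalg.solve(XtVX, c))
        except np.linalg.LinAlgError:
            return np.nan

    theta = np.array([tau2, sigma2])
    h = np.maximum(np.abs(theta), sigma2) * 1e-5 + 1e-12
    grad = np.array(
        [
            (f(theta + h[i] * np.eye(2)[i]) - f(theta - h[i] * np.eye(2)[i]))
            / (2 * h[i])
            for i in range(2)
        ]
    )
    # numeric Hessian of the REML log-likelihood
    H = np.zeros((2, 2))
    hh = np.maximum(np.abs(theta), sigma2) * 1e-4 + 1e-10
    l0 = _reml_loglik(theta, blocks)
    for i in range(2):
        for j in range(i, 2):
            ei, ej = hh[i] * np.eye(2)[i], hh[j] * np.eye(2)[j]
            if i == j:
                lp = _reml_loglik(theta + ei, blocks)
                lm = _reml_loglik(theta - ei, blocks)
                H[i, i] = (lp - 2 * l0 + lm) / hh[i] ** 2
            else:
                lpp = _reml_loglik(theta + ei + ej, blocks)
                lpm = _reml_loglik(theta + ei - ej, blocks)
                lmp = _reml_loglik(theta - ei + ej, blocks)
                lmm = _reml_loglik(theta - ei - ej, blocks)
                H[i, j] = H[j, i] = (lpp - lpm - lmp + lmm) / (4 * hh[i] * hh[j])
    if not np.all(np.isfinite(H)):
        return np.nan
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.nan
    denom = float(grad @ A @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return np.nan
    return 2.0 * f(theta) ** 2 / denom


def fit_random_intercept_contrast(
    values: np.ndarray, indicator: np.ndarray, patients: np.ndarray
) -> GroupComparison:
    """Two-group contrast with a per-patient random intercept.

    ``indicator`` is 1 for the first contrast level, 0 for the second; the
    estimate is the fixed-effect difference (first minus second). A singular
    fit (no between-patient variance) falls back to pooled OLS, logged.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(indicator, dtype=float)
    X = np.column_stack([np.ones_like(y), g])
    n = len(y)
    if np.var(y) < 1e-30:  # fully degenerate data: no signal, no variance
        return GroupComparison(
            ("1", "0"), 0.0, 0.0, float(n - 2), 0.0, 1.0, "ols_fallback", n_obs=n
        )

    tau2 = sigma2 = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = MixedLM(y, X, groups=np.asarray(patients)).fit(reml=True)
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            sigma2 = float(res.scale)
        except Exception as err:  # singular / non-converged fits
            logger.warning("MixedLM fit failed (%s); falling back to OLS", err)

    degenerate = (
        tau2 is None
        or sigma2 is None
        or not np.isfinite(tau2)
        or not np.isfinite(sigma2)
        or sigma2 <= 0
        or tau2 < 1e-10 * max(sigma2, 1e-300)
    )
    if degenerate:
        if tau2 is not None:
            logger.warning("singular mixed fit (zero patient variance); pooled OLS used")
        slope, icpt, *_ = sps.linregress(g, y) if len(np.unique(g)) > 1 else (np.nan,) * 5
        est = float(slope)
        resid = y - (icpt + slope * g)
        dof = n - 2
        s2 = resid @ resid / dof
        sxx = ((g - g.mean()) ** 2).sum()
        se = float(np.sqrt(s2 / sxx))
        t = est / se if se > 0 else 0.0
        p = float(2 * sps.t.sf(abs(t), dof)) if se > 0 else 1.0
        return GroupComparison(("1", "0"), est, se, dof, t, p, "ols_fallback", n_obs=n)

    blocks = _block_views(X, y, np.asarray(patients))
    c = np.array([0.0, 1.0])
    XtVX, XtVy, _ = _gls_pieces(blocks, tau2, sigma2)
    beta = np.linalg.solve(XtVX, XtVy)
    var = float(c @ np.linalg.solve(XtVX, c))
    se = np.sqrt(var)
    dof = _satterthwaite_df(blocks, tau2, sigma2, c)
    if not np.isfinite(dof) or dof < 1:
        dof = max(len(blocks) - 2, 1)  # between-patient fallback df
    est = float(beta[1])
    t = est / se if se > 0 else 0.0
    p = float(2 * sps.t.sf(abs(t), dof)) if se > 0 else 1.0
    return GroupComparison(("1", "0"), est, se, float(dof), t, p, "mixedlm", n_obs=n)


def lmm_contrast(
    values: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    value_col: str = "value",
    label_col: str = "label",
    patient_col: str = "patient_id",
    adjustment: str = "none",
) -> list[GroupComparison]:
    """Mixed-model contrasts between labelled groups.

    ``values`` has one row per observation with the measurement, a group
    label (e.g. ``responder_pre``) and a patient id. Each contrast
    ``(a, b)`` estimates mean(a) - mean(b) with a patient random intercept.
    ``adjustment`` in {none, holm_bonferroni, benjamini_hochberg} is applied
    across the supplied contrasts.
    """
    if adjustment not in ("none", "holm_bonferroni", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    results = []
    for a, b in contrasts:
        sub = values[values[label_col].isin([a, b])]
        for lab in (a, b):
            pats = sub.loc[sub[label_col] == lab, patient_col].nunique()
            if pats < 2:
                raise ValueError(f"contrast ({a}, {b}): fewer than 2 patients in {lab!r}")
        res = fit_random_intercept_contrast(
            sub[value_col].to_numpy(),
            (sub[label_col] == a).to_numpy(),
            sub[patient_col].to_numpy(),
        )
        res.contrast = (a, b)
        res.adjustment = adjustment
        results.append(res)
    if adjustment != "none" and results:
        method = {"holm_bonferroni": "holm", "benjamini_hochberg": "fdr_bh"}[adjustment]
        adj = multipletests([r.p_value for r in results], method=method)[1]
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results


def holm_bonferroni(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    return list(multipletests(p_values, method="holm")[1])


# ---------------------------------------------------------------------------
# bootstrap estimation


def bootstrap_mean_difference(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Mean(x) - mean(y) with a seeded percentile bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    bx = x[rng.integers(0, len(x), size=(n_boot, len(x)))].mean(axis=1)
    by = y[rng.integers(0, len(y), size=(n_boot, len(y)))].mean(axis=1)
    diffs = bx - by
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return float(x.mean() - y.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# subsampling and exclusion robustness


@dataclass
class RobustnessReport:
    mode: str  # "subsample" | "exclusion"
    fraction: float | None
    iterations: pd.DataFrame  # p_value, effect, ci_low, ci_high per iteration
    proportion_significant: float
    alpha: float = 0.05
    seed: int | None = None


def _contrast_records(
    sub: pd.DataFrame,
    first: str,
    second: str,
    value_col: str,
    label_col: str,
    patient_col: str,
    n_boot: int,
    boot_seed: int,
) -> dict:
    res = fit_random_intercept_contrast(
        sub[value_col].to_numpy(),
        (sub[label_col] == first).to_numpy(),
        sub[patient_col].to_numpy(),
    )
    x = sub.loc[sub[label_col] == first, value_col].to_numpy()
    y = sub.loc[sub[label_col] == second, value_col].to_numpy()
    effect, lo, hi = bootstrap_mean_difference(x, y, n_boot=n_boot, seed=boot_seed)
    return {
        "p_value": res.p_value,
        "effect": effect,
        "ci_low": lo,
        "ci_high": hi,
        "method": res.method,
    }


def subsample_analysis(
    values: pd.DataFrame,
    fraction: float,
    iterations: int = 100,
    seed: int = 0,
    contrast: tuple[str, str] | None = None,
    value_col: str = "value",
    label_col: str = "label",
    patient_col: str = "patient_id",
    n_boot: int = 5000,
    alpha: float = 0.05,
) -> RobustnessReport:
    """Refit the group contrast on random subsamples of the observations.

    Each of ``iterations`` rounds keeps ``floor(fraction * n)`` observations
    (without replacement), refits the mixed-model contrast and records the
    p-value plus the bootstrap-estimated mean difference. An iteration that
    empties one group is drawn again (logged).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = list(pd.unique(values[label_col]))
    if contrast is None:
        if len(labels) != 2:
            raise ValueError("contrast required when more than two labels present")
        contrast = (labels[0], labels[1])
    first, second = contrast
    n_keep = int(np.floor(fraction * len(values)))
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(iterations):
        for _try in range(100):
            idx = rng.choice(len(values), size=n_keep, replace=False)
            sub = values.iloc[idx]
            counts = sub[label_col].value_counts()
            if counts.get(first, 0) >= 2 and counts.get(second, 0) >= 2:
                break
            logger.warning("iteration %d emptied a group; resampling", it)
        rows.append(
            _contrast_records(
                sub, first, second, value_col, label_col, patient_col, n_boot,
                boot_seed=int(rng.integers(2**31)),
            )
        )
    iters = pd.DataFrame(rows)
    return RobustnessReport(
        mode="subsample",
        fraction=fraction,
        iterations=iters,
        proportion_significant=float((iters["p_value"] < alpha).mean()),
        alpha=alpha,
        seed=seed,
    )


def exclusion_analysis(
    values: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    value_col: str = "value",
    label_col: str = "label",
    patient_col: str = "patient_id",
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RobustnessReport:
    """Leave-one-patient-out refits of the group contrast (one iteration per
    patient; excluding a patient with no observations reduces to the full
    fit)."""
    labels = list(pd.unique(values[label_col]))
    if contrast is None:
        if len(labels) != 2:
            raise ValueError("contrast required when more than two labels present")
        contrast = (labels[0], labels[1])
    first, second = contrast
    per_group = values.groupby(label_col)[patient_col].nunique()
    if (per_group.reindex([first, second]) < 3).any():
        raise ValueError("exclusion analysis needs >= 3 patients per group")
    rng = np.random.default_rng(seed)
    rows = []
    for patient in pd.unique(values[patient_col]):
        sub = values[values[patient_col] != patient]
        rec = _contrast_records(
            sub, first, second, value_col, label_col, patient_col, n_boot,
            boot_seed=int(rng.integers(2**31)),
        )
        rec["excluded_patient"] = patient
        rows.append(rec)
    iters = pd.DataFrame(rows)
    return RobustnessReport(
        mode="exclusion",
        fraction=None,
        iterations=iters,
        proportion_significant=float((iters["p_value"] < alpha).mean()),
        alpha=alpha,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ROC cutoff


@dataclass
class RocReport:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str  # "low_predicts_positive" | "high_predicts_positive"


def roc_cutoff(
    scores: pd.Series,
    labels: pd.Series,
    positive_label: str = "responder",
) -> RocReport:
    """Empirical ROC over per-patient scores with a Youden-J cutoff.

    Orientation is auto-detected (if AUC for "high score predicts positive"
    is below 0.5, low scores are taken to predict the positive class, as a
    proximity biomarker would behave). The cutoff is the midpoint between
    the adjacent observed scores the optimal threshold separates, so on
    separable data it lies strictly between the groups.
    """
    common = scores.index.intersection(labels.index)
    s = scores.loc[common].to_numpy(dtype=float)
    y = (labels.loc[common] == positive_label).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    n_pos, n_neg = y.sum(), (~y).sum()
    # AUC via the rank-sum identity; orientation with higher AUC wins
    ranks = sps.rankdata(s)
    u_high = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    auc_high = u_high / (n_pos * n_neg)
    if auc_high >= 0.5:
        direction, auc, oriented = "high_predicts_positive", auc_high, s
    else:
        direction, auc, oriented = "low_predicts_positive", 1 - auc_high, -s

    # candidate cutoffs: midpoints between consecutive unique oriented scores
    uniq = np.unique(oriented)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else uniq
    best = None
    for c in mids:
        pred = oriented > c
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    j, c, sens, spec = best
    cutoff = -c if direction == "low_predicts_positive" else c
    return RocReport(
        auc=float(auc),
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Wilcoxon tests


@dataclass
class WilcoxonResult:
    test: str  # "rank_sum" | "signed_rank"
    statistic: float
    p_value: float
    method: str  # "exact" | "approx"
    degenerate: bool = False


def rank_sum_test(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney); exact for n <= 25/group."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    exact = len(x) <= 25 and len(y) <= 25
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return WilcoxonResult(
        "rank_sum", float(res.statistic), float(res.pvalue),
        "exact" if exact else "approx",
    )


def signed_rank_test(x, y=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank on pairs (or pre-computed differences)."""
    d = np.asarray(x, float) - (np.asarray(y, float) if y is not None else 0.0)
    if np.all(d == 0):
        return WilcoxonResult("signed_rank", 0.0, 1.0, "exact", degenerate=True)
    exact = len(d) <= 25 and not np.any(d == 0)
    res = sps.wilcoxon(
        d, alternative="two-sided", method="exact" if exact else "approx"
    )
    return WilcoxonResult(
        "signed_rank", float(res.statistic), float(res.pvalue),
        "exact" if exact else "approx",
    )
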