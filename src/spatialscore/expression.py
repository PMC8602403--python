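"""Bulk-expression scores and their links to spatial features.

Three analyses live here:

* PCA signature scores — per-spot first-principal-component scores over a
  gene signature's submatrix of the log2-TPM bulk matrix (IFN-gamma,
  TGF-beta, immune activation/suppression, ...). PC1's sign is arbitrary,
  so scores are oriented to correlate positively with the per-spot mean
  signature expression.
* L1-regularised (LASSO) association of per-spot expression with either the
  log tumor-cell percentage or the log per-spot SpatialScore; regularisation
  strength chosen by 6-fold cross-validation, percentages get a 1
  percentage-point pseudo-count before the log.
* Marker fold-change phenotyping of tumor vs reactive CD4+ T cells per
  spot, with the <5-CD4+-cell core exclusion, plus thresholded subset
  frequencies (e.g. Ki-67+ share of tumor cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import GroupKFold, KFold

from .io import CellTable, ExpressionMatrix, GeneSignature, TransformStateError
from .scoring import SpatialScoreResult

logger = logging.getLogger(__name__)


@dataclass
class SignatureScore:
    signature: str
    per_spot: pd.Series  # spot_id -> oriented PC1 score, mean ~ 0
    orientation: int  # +1 or -1 applied to raw PC1
    explained_variance_fraction: float
    genes_used: tuple[str, ...] = ()
    genes_missing: tuple[str, ...] = ()


@dataclass
class LassoResult:
    response: str  # log_tumor_frequency | log_spatial_score
    selected_alpha: float
    coefficients: pd.Series  # gene -> coefficient (mostly exact zeros)
    cv_mse: float
    pseudo_count: float = 1.0
    intercept: float = 0.0
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def selected_genes(self) -> pd.Series:
        nz = self.coefficients[self.coefficients != 0.0]
        return nz.sort_values(key=np.abs, ascending=False)


@dataclass
class MarkerFoldChange:
    per_spot: pd.DataFrame  # spot_id x (markers..., size)
    excluded_spots: list
    summary: pd.DataFrame  # marker x (mean, sem) over spots


# ---------------------------------------------------------------------------
# PCA signature scores


def pca_signature_score(
    expr: ExpressionMatrix, signature: GeneSignature
) -> SignatureScore:
    """PC1 score per spot over the signature genes (genes centred).

    Requires a log2-TPM matrix, at least two signature genes present and at
    least three spots. Missing symbols are reported; fewer than two present
    is an error.
    """
    if expr.transform_state != "log2_TPM":
        raise TransformStateError("signature scoring expects a log2_TPM matrix")
    present = [g for g in signature.genes if g in expr.values.index]
    missing = [g for g in signature.genes if g not in expr.values.index]
    if len(present) < 2:
        raise ValueError(
            f"signature {signature.name!r}: fewer than 2 genes found; "
            f"missing {missing}"
        )
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 spots for a PCA score")

    X = expr.values.loc[present].to_numpy(dtype=float).T  # spots x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[0]
    total_var = (s**2).sum()
    evf = float(s[0] ** 2 / total_var) if total_var > 0 else 0.0

    mean_expr = X.mean(axis=1)
    corr = np.corrcoef(scores, mean_expr)[0, 1] if np.std(scores) > 0 else 0.0
    orientation = -1 if corr < 0 else 1
    return SignatureScore(
        signature=signature.name,
        per_spot=pd.Series(orientation * scores, index=expr.values.columns),
        orientation=orientation,
        explained_variance_fraction=evf,
        genes_used=tuple(present),
        genes_missing=tuple(missing),
    )


# ---------------------------------------------------------------------------
# LASSO association


def _log_pct(p: np.ndarray, pseudo_count: float) -> np.ndarray:
    return np.log(p + pseudo_count)


def tumor_frequency(cells: CellTable, tumor_label: str = "tumor") -> pd.Series:
    """Per-spot tumor-cell percentage (0-100)."""
    return cells.df.groupby("spot_id")["cell_type"].apply(
        lambda s: 100.0 * (s == tumor_label).mean()
    )


def fit_lasso(
    expr: ExpressionMatrix,
    cells: CellTable,
    response: str,
    score: SpatialScoreResult | None = None,
    folds: int = 6,
    seed: int = 0,
    tumor_label: str = "tumor",
    cd4_labels: tuple[str, ...] = ("reactive CD4 T", "PD-1+ CD4 T"),
    pseudo_count: float = 1.0,
    standardize: bool = True,
    patient_folds: bool = False,
    alpha_rule: str = "1se",
    fixed_alpha: float | None = None,
) -> LassoResult:
    """LASSO of a per-spot response on per-spot log expression.

    ``response='log_tumor_frequency'`` regresses the natural-log tumor-cell
    percentage (+pseudo-count) on the genes plus an *unpenalised* log CD4
    frequency covariate (handled by partialling the covariate out of the
    response and every gene before the penalised fit, which leaves the
    penalised coefficients unchanged). ``response='log_spatial_score'``
    regresses the natural-log per-spot SpatialScore on the genes alone.

    The regularisation path is cross-validated over ``folds`` seeded random
    folds (optionally grouped by patient to avoid same-patient leakage).
    ``alpha_rule='1se'`` (default) picks the sparsest alpha whose mean
    validation MSE is within one standard error of the minimum — CV-min
    lasso is known to drag in spurious genes at these spot counts, and the
    1-SE convention restores reliable support recovery. ``'cv_min'``
    reproduces the plain minimum-MSE selection.
    """
    if alpha_rule not in ("1se", "cv_min"):
        raise ValueError(f"unknown alpha_rule {alpha_rule!r}")
    if expr.transform_state != "log2_TPM":
        raise TransformStateError("fit_lasso expects a log2_TPM matrix")
    spots = list(expr.values.columns)
    cell_spots = set(cells.spots)
    missing = [s for s in spots if s not in cell_spots]
    if missing:
        raise ValueError(f"expression spots absent from cell table: {missing[:5]}")
    if len(spots) < folds:
        raise ValueError(f"{len(spots)} spots < {folds} folds")

    unpenalized: dict[str, np.ndarray] = {}
    if response == "log_tumor_frequency":
        tf = tumor_frequency(cells, tumor_label).reindex(spots)
        y = _log_pct(tf.to_numpy(dtype=float), pseudo_count)
        cd4 = cells.df.groupby("spot_id")["cell_type"].apply(
            lambda s: 100.0 * s.isin(cd4_labels).mean()
        ).reindex(spots)
        unpenalized["log_cd4_frequency"] = _log_pct(
            cd4.to_numpy(dtype=float), pseudo_count
        )
    elif response == "log_spatial_score":
        if score is None:
            raise ValueError("log_spatial_score response requires a SpatialScoreResult")
        per_spot = score.per_spot.reindex(spots)
        if per_spot.isna().any():
            bad = list(per_spot.index[per_spot.isna()])[:5]
            raise ValueError(f"no SpatialScore for spots {bad}")
        y = np.log(per_spot.to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown response {response!r}")

    X = expr.values.to_numpy(dtype=float).T.copy()  # spots x genes
    y = y.astype(float).copy()

    # Frisch-Waugh partialling-out of unpenalised covariates (plus intercept)
    if unpenalized:
        Z = np.column_stack([np.ones(len(spots))] + list(unpenalized.values()))
        proj = Z @ np.linalg.lstsq(Z, np.column_stack([y, X]), rcond=None)[0]
        y = y - proj[:, 0]
        X = X - proj[:, 1:]

    sd = X.std(axis=0)
    keep_sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - X.mean(axis=0)) / keep_sd if standardize else X

    if fixed_alpha is not None:
        from sklearn.linear_model import Lasso

        refit = Lasso(alpha=fixed_alpha, max_iter=50_000).fit(Xs, y)
        coefs = refit.coef_ / keep_sd if standardize else refit.coef_
        return LassoResult(
            response=response,
            selected_alpha=float(fixed_alpha),
            coefficients=pd.Series(coefs, index=expr.values.index, name="coefficient"),
            cv_mse=float("nan"),
            pseudo_count=pseudo_count,
            intercept=float(refit.intercept_),
            seed=seed,
        )

    if patient_folds:
        meta = cells.spot_metadata()
        groups = meta.loc[spots, "patient_id"].to_numpy()
        cv = list(GroupKFold(n_splits=folds).split(Xs, y, groups))
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)

    model = LassoCV(cv=cv, random_state=seed, max_iter=50_000).fit(Xs, y)
    mse = model.mse_path_.mean(axis=1)
    if alpha_rule == "1se":
        sem = model.mse_path_.std(axis=1) / np.sqrt(model.mse_path_.shape[1])
        i_min = int(mse.argmin())
        # alphas_ descend, so the smallest admissible index is the sparsest
        i_sel = int(np.flatnonzero(mse <= mse[i_min] + sem[i_min]).min())
        alpha = float(model.alphas_[i_sel])
        from sklearn.linear_model import Lasso

        refit = Lasso(alpha=alpha, max_iter=50_000).fit(Xs, y)
        raw_coef = refit.coef_
        intercept_fit = float(refit.intercept_)
        cv_mse = float(mse[i_sel])
    else:
        alpha = float(model.alpha_)
        raw_coef = model.coef_
        intercept_fit = float(model.intercept_)
        cv_mse = float(mse.min())
    coefs = raw_coef / keep_sd if standardize else raw_coef

    cov_coefs: dict[str, float] = {}
    if unpenalized:
        # recover the unpenalised coefficients from the residual fit
        resid = _log_pct(tf.to_numpy(dtype=float), pseudo_count) - (
            expr.values.to_numpy(dtype=float).T @ coefs
        )
        Z = np.column_stack([np.ones(len(spots))] + list(unpenalized.values()))
        beta = np.linalg.lstsq(Z, resid, rcond=None)[0]
        intercept = float(beta[0])
        cov_coefs = {k: float(b) for k, b in zip(unpenalized, beta[1:])}
    else:
        intercept = intercept_fit

    return LassoResult(
        response=response,
        selected_alpha=alpha,
        coefficients=pd.Series(coefs, index=expr.values.index, name="coefficient"),
        cv_mse=cv_mse,
        pseudo_count=pseudo_count,
        intercept=intercept,
        covariate_coefficients=cov_coefs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# marker fold changes


def marker_fold_change(
    cells: CellTable,
    markers: list[str],
    tumor_label: str = "tumor",
    reactive_label: str = "reactive CD4 T",
    min_cd4_cells: int = 5,
) -> MarkerFoldChange:
    """Per-spot tumor/reactive mean-intensity ratios and the size ratio.

    Spots with fewer than ``min_cd4_cells`` CD4+ T cells (tumor + reactive
    combined) are excluded, as are spots where either population is empty.
    The cohort summary is the mean +/- s.e.m. of per-spot ratios.
    """
    for label in (tumor_label, reactive_label):
        if label not in cells.cell_types:
            raise ValueError(f"unknown cell type {label!r}")
    for m in markers:
        if m not in cells.df.columns:
            raise ValueError(f"marker {m!r} absent from table")

    rows, excluded = [], []
    for spot, sub in cells.df.groupby("spot_id", sort=False):
        tum = sub[sub["cell_type"] == tumor_label]
        rea = sub[sub["cell_type"] == reactive_label]
        if len(tum) + len(rea) < min_cd4_cells or len(tum) == 0 or len(rea) == 0:
            excluded.append(spot)
            continue
        row = {"spot_id": spot}
        for m in markers:
            row[m] = tum[m].mean() / rea[m].mean()
        row["size"] = tum["size"].mean() / rea["size"].mean()
        rows.append(row)
    per_spot = (
        pd.DataFrame(rows).set_index("spot_id")
        if rows
        else pd.DataFrame(columns=markers + ["size"])
    )
    summary = pd.DataFrame({"mean": per_spot.mean(), "sem": per_spot.sem()})
    return MarkerFoldChange(per_spot=per_spot, excluded_spots=excluded, summary=summary)


def subset_frequency(
    cells: CellTable,
    base_type: str,
    marker: str,
    threshold: float,
    denominator: str = "all_cells",
    immune_types: tuple[str, ...] | None = None,
) -> pd.Series:
    """Per-spot frequency of marker-positive base-type cells.

    ``denominator`` is ``all_cells`` or ``all_immune`` (requires
    ``immune_types``). Thresholds stand in for the manual gating that
    defined marker-positive subsets. Spots with an empty denominator yield
    NaN and a warning.
    """
    if base_type not in cells.cell_types:
        raise ValueError(f"unknown cell type {base_type!r}")
    if marker not in cells.df.columns:
        raise ValueError(f"marker {marker!r} absent from table")
    if denominator == "all_immune" and not immune_types:
        raise ValueError("all_immune denominator requires immune_types")

    out = {}
    for spot, sub in cells.df.groupby("spot_id", sort=False):
        if denominator == "all_immune":
            denom = sub["cell_type"].isin(immune_types).sum()
        else:
            denom = len(sub)
        if denom == 0:
            logger.warning("subset_frequency: empty denominator in spot %s", spot)
            out[spot] = np.nan
            continue
        base = sub[sub["cell_type"] == base_type]
        out[spot] = (base[marker] > threshold).sum() / denom
    s = pd.Series(out)
    s.index.name = "spot_id"
    return s
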