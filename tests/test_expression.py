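"""PCA signature scores, LASSO association, marker fold changes and subset
frequencies."""

import numpy as np
import pandas as pd
import pytest

from spatialscore import (
    ExpressionMatrix,
    ExpressionModel,
    GeneSignature,
    ScoreTriplet,
    SimulationConfig,
    fit_lasso,
    marker_fold_change,
    pca_signature_score,
    simulate_cohort,
    simulate_expression,
    simulate_spots,
    spatial_score,
    subset_frequency,
)
from spatialscore.io import TransformStateError
from conftest import make_cells


def _log2_matrix(values: np.ndarray, genes, spots) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=spots), transform_state="log2_TPM"
    )


# -- PCA signature scores ---------------------------------------------------


def test_two_correlated_genes_pc1_explains_everything():
    rng = np.random.default_rng(0)
    base = rng.normal(5, 1, 8)
    vals = np.vstack([base, 2 * base + 3])  # perfectly correlated
    expr = _log2_matrix(vals, ["A", "B"], [f"s{i}" for i in range(8)])
    score = pca_signature_score(expr, GeneSignature("sig", ("A", "B")))
    assert score.explained_variance_fraction == pytest.approx(1.0)
    # score proportional to per-spot mean expression, positively oriented
    mean = vals.mean(axis=0)
    corr = np.corrcoef(score.per_spot, mean)[0, 1]
    assert corr == pytest.approx(1.0)
    assert abs(score.per_spot.mean()) < 1e-9


def test_noise_signature_explained_variance_near_uniform():
    rng = np.random.default_rng(1)
    n_genes, n_spots = 40, 200
    vals = rng.normal(0, 1, (n_genes, n_spots))
    expr = _log2_matrix(vals, [f"G{i}" for i in range(n_genes)],
                        [f"s{j}" for j in range(n_spots)])
    sig = GeneSignature("noise", tuple(f"G{i}" for i in range(n_genes)))
    score = pca_signature_score(expr, sig)
    assert score.explained_variance_fraction < 3.0 / n_genes


def test_pc1_invariant_to_gene_order_and_row_constants():
    rng = np.random.default_rng(2)
    vals = rng.normal(4, 1, (5, 12))
    genes = [f"G{i}" for i in range(5)]
    spots = [f"s{j}" for j in range(12)]
    sig = GeneSignature("sig", tuple(genes))
    a = pca_signature_score(_log2_matrix(vals, genes, spots), sig)
    perm = [3, 0, 4, 1, 2]
    b = pca_signature_score(
        _log2_matrix(vals[perm], [genes[i] for i in perm], spots),
        GeneSignature("sig", tuple(genes[i] for i in perm)),
    )
    shifted = vals.copy()
    shifted[2] += 7.5
    c = pca_signature_score(_log2_matrix(shifted, genes, spots), sig)
    assert np.allclose(a.per_spot, b.per_spot, atol=1e-9)
    assert np.allclose(a.per_spot, c.per_spot, atol=1e-9)


def test_signature_with_missing_genes_errors():
    expr = _log2_matrix(np.ones((2, 4)), ["A", "B"], list("wxyz"))
    with pytest.raises(ValueError, match="MISSING1"):
        pca_signature_score(expr, GeneSignature("s", ("A", "MISSING1", "MISSING2")))
    with pytest.raises(TransformStateError):
        pca_signature_score(
            ExpressionMatrix(pd.DataFrame(np.ones((2, 4)), index=["A", "B"])),
            GeneSignature("s", ("A", "B")),
        )


def test_planted_group_shift_recovered_in_score_direction():
    cfg = SimulationConfig(
        seed=40, cells_per_spot=200, n_patients_per_arm=3, spots_per_patient=2,
        attraction={("PD-1+ CD4 T", "tumor"): (2.0, 10.0)},
    )
    sig_genes = tuple(f"ACT{i}" for i in range(6))
    cfg.expression_model = ExpressionModel(
        n_genes=100,
        noise_sd=0.3,
        signature_shifts={
            "activation": (sig_genes, {("responder", "post"): 2.0})
        },
    )
    cells = simulate_cohort(cfg)
    score = spatial_score(cells, ScoreTriplet("PD-1+ CD4 T", "tumor", "Treg"))
    expr = simulate_expression(cfg, cells, score.per_spot)
    sig_score = pca_signature_score(expr, GeneSignature("activation", sig_genes))
    meta = cells.spot_metadata()
    shifted = [
        s for s in expr.spots
        if meta.loc[s, "group"] == "responder" and meta.loc[s, "timepoint"] == "post"
    ]
    rest = [s for s in expr.spots if s not in shifted]
    assert sig_score.per_spot[shifted].mean() > sig_score.per_spot[rest].mean()


# -- LASSO ------------------------------------------------------------------


@pytest.fixture(scope="module")
def lasso_cohort():
    cfg = SimulationConfig(
        seed=41, cells_per_spot=300, n_patients_per_arm=4, spots_per_patient=2,
        attraction={("PD-1+ CD4 T", "tumor"): (2.0, 10.0)},
    )
    cells = simulate_cohort(cfg)
    score = spatial_score(cells, ScoreTriplet("PD-1+ CD4 T", "tumor", "Treg"))
    cfg.expression_model = ExpressionModel(
        n_genes=60,
        true_support={"SG0": ("log_spatial_score", 2.0)},
        noise_sd=0.05,
    )
    expr = simulate_expression(cfg, cells, score.per_spot)
    return cfg, cells, score, expr


def test_infinite_penalty_zeroes_all_genes(lasso_cohort):
    _, cells, score, expr = lasso_cohort
    res = fit_lasso(expr, cells, "log_spatial_score", score=score,
                    fixed_alpha=1e9)
    assert (res.coefficients == 0).all()


def test_sparsity_monotone_in_alpha(lasso_cohort):
    _, cells, score, expr = lasso_cohort
    counts = []
    for alpha in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
        res = fit_lasso(expr, cells, "log_spatial_score", score=score,
                        fixed_alpha=alpha)
        counts.append(int((res.coefficients != 0).sum()))
    assert counts == sorted(counts, reverse=True)


def test_near_noiseless_gene_selected_with_positive_coefficient(lasso_cohort):
    _, cells, score, expr = lasso_cohort
    res = fit_lasso(expr, cells, "log_spatial_score", score=score, seed=0)
    sel = res.selected_genes
    assert "SG0" in sel.index and sel["SG0"] > 0


def test_lasso_reproducible(lasso_cohort):
    _, cells, score, expr = lasso_cohort
    a = fit_lasso(expr, cells, "log_spatial_score", score=score, seed=3)
    b = fit_lasso(expr, cells, "log_spatial_score", score=score, seed=3)
    assert a.selected_alpha == b.selected_alpha
    assert (a.coefficients == b.coefficients).all()


def test_tumor_response_includes_unpenalized_cd4_covariate(lasso_cohort):
    _, cells, _score, expr = lasso_cohort
    res = fit_lasso(expr, cells, "log_tumor_frequency", seed=0)
    assert "log_cd4_frequency" in res.covariate_coefficients


def test_too_few_spots_for_folds(lasso_cohort):
    cfg, _, _, _ = lasso_cohort
    small_cells = simulate_spots(
        SimulationConfig(seed=42, cells_per_spot=200), 3, label="SM"
    )
    score = spatial_score(small_cells, ScoreTriplet("PD-1+ CD4 T", "tumor", "Treg"))
    cfg.expression_model = ExpressionModel(n_genes=10, noise_sd=0.1)
    expr = simulate_expression(cfg, small_cells, score.per_spot)
    with pytest.raises(ValueError, match="folds"):
        fit_lasso(expr, small_cells, "log_spatial_score", score=score, folds=6)


# -- marker fold changes ----------------------------------------------------


def test_identical_distributions_give_unit_fold_change():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(400):
        rows.append({
            "x": rng.uniform(0, 100), "y": rng.uniform(0, 100),
            "cell_type": "tumor" if i % 2 else "reactive CD4 T",
            "CD25": rng.lognormal(3, 0.4),
        })
    cells = make_cells(rows, markers=("CD25",),
                       cell_types=("tumor", "reactive CD4 T"))
    fc = marker_fold_change(cells, ["CD25"])
    assert fc.summary.loc["CD25", "mean"] == pytest.approx(1.0, rel=0.1)


def test_small_cd4_spots_excluded():
    rows = [
        {"x": 0.0, "y": 0.0, "cell_type": "tumor", "CD25": 1.0},
        {"x": 1.0, "y": 0.0, "cell_type": "tumor", "CD25": 1.0},
        {"x": 2.0, "y": 0.0, "cell_type": "reactive CD4 T", "CD25": 1.0},
        {"x": 3.0, "y": 0.0, "cell_type": "reactive CD4 T", "CD25": 1.0},
        {"x": 4.0, "y": 0.0, "cell_type": "other", "CD25": 1.0},
    ]
    cells = make_cells(rows, markers=("CD25",),
                       cell_types=("tumor", "reactive CD4 T", "other"))
    fc = marker_fold_change(cells, ["CD25"])  # 4 CD4 cells < 5
    assert fc.excluded_spots == ["s1"]
    assert len(fc.per_spot) == 0


def test_missing_marker_errors(random_spots):
    with pytest.raises(ValueError, match="NOPE"):
        marker_fold_change(random_spots, ["NOPE"])


def test_fold_change_estimator_unbiased_on_lognormal():
    """Cohort fold-change estimate within 2% of the generative factor at
    10,000 cells per type."""
    cfg = SimulationConfig(seed=43, cells_per_spot=40000,
                           type_proportions={"tumor": 0.5, "reactive CD4 T": 0.5},
                           size_model={"default": (np.log(80), 0.3)})
    spots = simulate_spots(cfg, 1, label="UB")
    fc = marker_fold_change(spots, list(cfg.fold_change_factors))
    for m, factor in cfg.fold_change_factors.items():
        assert fc.per_spot[m].iloc[0] == pytest.approx(factor, rel=0.02)


# -- subset frequencies -----------------------------------------------------


def test_subset_frequency_threshold_extremes(random_spots):
    low = subset_frequency(random_spots, "tumor", "CD25", threshold=-1.0)
    share = random_spots.df.groupby("spot_id")["cell_type"].apply(
        lambda s: (s == "tumor").mean()
    )
    assert np.allclose(low.sort_index(), share.sort_index())
    high = subset_frequency(random_spots, "tumor", "CD25", threshold=1e12)
    assert (high == 0).all()


def test_subset_frequency_recovers_bimodal_positive_share():
    rng = np.random.default_rng(6)
    rows = []
    n = 2000
    positive = rng.random(n) < 0.3
    for i in range(n):
        rows.append({
            "x": rng.uniform(0, 100), "y": rng.uniform(0, 100),
            "cell_type": "T cell",
            "ICOS": rng.lognormal(5, 0.3) if positive[i] else rng.lognormal(1, 0.3),
        })
    cells = make_cells(rows, markers=("ICOS",), cell_types=("T cell",))
    freq = subset_frequency(cells, "T cell", "ICOS", threshold=np.exp(3))
    tol = 4 * np.sqrt(0.3 * 0.7 / n)
    assert abs(freq.iloc[0] - 0.3) < tol


def test_subset_frequency_immune_denominator_requires_types(random_spots):
    with pytest.raises(ValueError, match="immune_types"):
        subset_frequency(random_spots, "tumor", "CD25", 1.0, denominator="all_immune")
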