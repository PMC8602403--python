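"""Mixed-model contrasts (including the lmerTest cross-check), robustness
analyses, bootstrap estimation, ROC and Wilcoxon tests."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spatialscore import (
    bootstrap_mean_difference,
    exclusion_analysis,
    holm_bonferroni,
    lmm_contrast,
    rank_sum_test,
    roc_cutoff,
    signed_rank_test,
    subsample_analysis,
)


def simulate_scores(seed, n_patients=7, obs=6, effect=0.0, icpt_sd=1.0, noise_sd=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for lab, shift in (("responder", effect), ("nonresponder", 0.0)):
        for p in range(n_patients):
            icpt = rng.normal(0, icpt_sd)
            for _ in range(obs):
                rows.append({
                    "value": shift + icpt + rng.normal(0, noise_sd),
                    "label": lab,
                    "patient_id": f"{lab[:1]}{p}",
                })
    return pd.DataFrame(rows)


# -- mixed model ------------------------------------------------------------


def test_identical_groups_give_null_result():
    df = simulate_scores(0, effect=0.0)
    df["value"] = 1.0  # no variance at all -> degenerate, p = 1
    res = lmm_contrast(df, [("responder", "nonresponder")])[0]
    assert res.estimate == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)


def test_effect_recovery_with_random_intercepts():
    """Fixed effect of 2 on top of patient intercepts (sd 1): the estimate's
    95% CI covers the truth in >= 90% of seeded replicates."""
    hits = 0
    reps = 40
    for rep in range(reps):
        df = simulate_scores(1000 + rep, n_patients=7, obs=6, effect=2.0)
        res = lmm_contrast(df, [("responder", "nonresponder")])[0]
        half = sps.t.ppf(0.975, res.df) * res.se
        hits += abs(res.estimate - 2.0) <= half
    assert hits / reps >= 0.9


def test_matches_lmerTest_reference():
    """Estimate, Satterthwaite df and p-value agree with R lme4/lmerTest."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    df = simulate_scores(42, n_patients=5, obs=5, effect=1.5)
    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        csv = os.path.join(tmp, "d.csv")
        df.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages({{library(lme4); library(lmerTest)}})
        d <- read.csv("{csv}")
        d$ind <- as.numeric(d$label == "responder")
        m <- lmer(value ~ ind + (1|patient_id), data=d, REML=TRUE)
        s <- summary(m)$coefficients
        cat(s[2,1], s[2,2], s[2,3], s[2,5], sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        est_r, se_r, df_r, p_r = map(float, out.stdout.strip().splitlines())
    res = lmm_contrast(df, [("responder", "nonresponder")])[0]
    assert res.estimate == pytest.approx(est_r, rel=1e-4)
    assert res.se == pytest.approx(se_r, rel=1e-3)
    assert res.df == pytest.approx(df_r, rel=1e-2)
    assert res.p_value == pytest.approx(p_r, rel=1e-2)


def test_holm_closed_form():
    adj = holm_bonferroni([0.01, 0.02, 0.04, 0.30])
    assert np.allclose(adj, [0.04, 0.06, 0.08, 0.30])


def test_holm_monotone_and_at_least_raw():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random(6)
        adj = np.array(holm_bonferroni(list(p)))
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def test_adjustment_applied_across_contrasts():
    df = pd.concat([
        simulate_scores(7, effect=1.0),
        simulate_scores(8, effect=0.0).assign(
            label=lambda d: d["label"] + "_post",
            patient_id=lambda d: d["patient_id"] + "x",
        ),
    ])
    contrasts = [
        ("responder", "nonresponder"),
        ("responder_post", "nonresponder_post"),
    ]
    res = lmm_contrast(df, contrasts, adjustment="holm_bonferroni")
    for r in res:
        assert r.p_adjusted is not None and r.p_adjusted >= r.p_value - 1e-12


def test_too_few_patients_rejected():
    df = simulate_scores(9, n_patients=1)
    with pytest.raises(ValueError, match="fewer than 2 patients"):
        lmm_contrast(df, [("responder", "nonresponder")])


# -- bootstrap --------------------------------------------------------------


def test_bootstrap_ci_brackets_estimate():
    rng = np.random.default_rng(4)
    x, y = rng.normal(2, 1, 60), rng.normal(0, 1, 60)
    est, lo, hi = bootstrap_mean_difference(x, y, seed=0)
    assert lo <= est <= hi
    assert est == pytest.approx(x.mean() - y.mean())


def test_bootstrap_deterministic():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
    assert bootstrap_mean_difference(x, y, seed=9) == bootstrap_mean_difference(
        x, y, seed=9
    )


# -- subsampling / exclusion ------------------------------------------------


def test_subsample_fraction_one_reproduces_full_fit():
    df = simulate_scores(10, effect=2.0)
    rep = subsample_analysis(df, fraction=1.0, iterations=3, seed=0, n_boot=200)
    full = lmm_contrast(df, [("responder", "nonresponder")])[0]
    assert np.allclose(rep.iterations["p_value"], full.p_value)
    assert np.allclose(rep.iterations["effect"], rep.iterations["effect"].iloc[0])


def test_subsample_deterministic():
    df = simulate_scores(11, effect=1.0)
    a = subsample_analysis(df, 0.5, iterations=5, seed=2, n_boot=100)
    b = subsample_analysis(df, 0.5, iterations=5, seed=2, n_boot=100)
    pd.testing.assert_frame_equal(a.iterations, b.iterations)


def test_subsample_fraction_validated():
    df = simulate_scores(12)
    with pytest.raises(ValueError, match="fraction"):
        subsample_analysis(df, fraction=1.5)


def test_exclusion_iterates_once_per_patient():
    df = simulate_scores(13, n_patients=4, effect=3.0)
    rep = exclusion_analysis(df, n_boot=100)
    assert len(rep.iterations) == df["patient_id"].nunique()
    assert set(rep.iterations["excluded_patient"]) == set(df["patient_id"])


def test_exclusion_needs_three_patients_per_group():
    df = simulate_scores(14, n_patients=2)
    with pytest.raises(ValueError, match="3 patients"):
        exclusion_analysis(df)


# -- ROC --------------------------------------------------------------------


def test_roc_perfect_separation():
    scores = pd.Series(
        [0.2, 0.3, 0.4, 1.1, 1.5, 2.0],
        index=[f"p{i}" for i in range(6)],
    )
    labels = pd.Series(
        ["responder"] * 3 + ["nonresponder"] * 3, index=scores.index
    )
    rep = roc_cutoff(scores, labels)
    assert rep.auc == 1.0
    assert 0.4 < rep.cutoff < 1.1  # strictly between the group extremes
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.direction == "low_predicts_positive"


def test_roc_auc_equals_rank_sum_identity():
    rng = np.random.default_rng(15)
    scores = pd.Series(rng.normal(0, 1, 40), index=[f"p{i}" for i in range(40)])
    labels = pd.Series(
        ["responder"] * 18 + ["nonresponder"] * 22, index=scores.index
    )
    rep = roc_cutoff(scores, labels)
    x = scores[labels == "responder"]
    y = scores[labels == "nonresponder"]
    u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    auc_high = u / (len(x) * len(y))
    assert rep.auc == pytest.approx(max(auc_high, 1 - auc_high), abs=1e-12)


def test_roc_null_labels_auc_near_half():
    rng = np.random.default_rng(16)
    n = 2000
    scores = pd.Series(rng.normal(0, 1, n), index=[f"p{i}" for i in range(n)])
    labels = pd.Series(
        rng.permutation(["responder"] * (n // 2) + ["nonresponder"] * (n // 2)),
        index=scores.index,
    )
    rep = roc_cutoff(scores, labels)
    assert rep.auc == pytest.approx(0.5, abs=0.05)


def test_roc_single_class_rejected():
    s = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError, match="both classes"):
        roc_cutoff(s, pd.Series(["responder", "responder"], index=s.index))


# -- Wilcoxon ---------------------------------------------------------------


def test_rank_sum_exact_small_sample_vs_enumeration():
    """(1,2,3) vs (4,5,6): the most extreme of the C(6,3)=20 assignments,
    exact two-sided p = 2/20 = 0.1, checked by full enumeration."""
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    pooled = [1, 2, 3, 4, 5, 6]
    observed = sum([1, 2, 3])
    sums = [sum(c) for c in itertools.combinations(pooled, 3)]
    lo = sum(s <= observed for s in sums)
    hi = sum(s >= sum(pooled) - observed + 0 for s in sums)
    p_enum = 2 * min(lo, len(sums) - lo + sums.count(observed)) / len(sums)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.1)
    assert p_enum == pytest.approx(0.1)


def test_identical_samples_p_one():
    res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0)
    deg = signed_rank_test([1.0, 1.0], [1.0, 1.0])
    assert deg.degenerate and deg.p_value == 1.0


def test_signed_rank_sign_flip_symmetry():
    rng = np.random.default_rng(17)
    d = rng.normal(0.3, 1, 15)
    a = signed_rank_test(d)
    b = signed_rank_test(-d)
    assert a.p_value == pytest.approx(b.p_value)
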