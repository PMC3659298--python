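"""Leave-one-subject-out cross-validation and predictive accuracy.

The evaluation design: for each subject i, every one of their repeated
observations is removed, the model family is refit on the remaining
subjects, and subject i's visits are predicted from fixed (population)
effects only.  Concatenating all held-out predictions, predictive
accuracy is the square of the Pearson correlation between observed and
predicted values — "R2" throughout — and a genomic model's gain is
``delta R2`` relative to the covariate-only (non-genetic) baseline.

Leakage contract: nothing a fold's model sees — covariates, age-transform
anchors, genotype-imputation means, shrinkage priors, MCMC seeds —
derives from the held-out subject's observations.  Mutation tests in the
test suite assert this for every model family.

Eight model families are provided (labels as used in the results
tables): ``non-genetic``, ``NCBI``, ``BHS-A``, ``BHS-R``, ``BLR-A``,
``BLR-R``, ``BRR-A``, ``BRR-R``.

Confidence intervals for R2 are subject-level (cluster) percentile
bootstrap: visits within a subject are dependent, so subjects — not
observations — are resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agetrans import AgeTransform
from .datamodel import LongCohort, ValidationError
from .lmm import LMMSpec, coef_test, fit_lmm, predict_fixed
from .scores import (
    RiskScoreVector,
    _ModelArrays,
    batched_marker_gls,
    cohort_arrays,
    covariate_design,
    dedup_largest_study,
    fold_subject_dosages,
    marker_set_ids,
)
from .wgr import MCMCSettings, default_priors, fit_wgr, ms_x, predict_wgr

_log = logging.getLogger(__name__)

MODEL_LABELS = (
    "non-genetic",
    "NCBI",
    "BHS-A",
    "BHS-R",
    "BLR-A",
    "BLR-R",
    "BRR-A",
    "BRR-R",
)

#: MCMC settings used inside cross-validation folds (short chains: one
#: posterior-mean fit per subject, thousands of fits per experiment).
CV_MCMC = MCMCSettings(n_iter=600, burnin=200, thin=2, seed=0)

#: assumed lipid heritability entering the shrinkage-prior elicitation
H2_PRIOR = 0.5


@dataclass
class CVResult:
    """Pooled out-of-sample predictions and accuracy for one model."""

    records: pd.DataFrame          # subject_id, age, observed, predicted
    model_label: str
    r2: float
    r2_ci: tuple[float, float] | None
    delta_r2_vs_baseline: float | None
    p_value: float | None
    n_subjects: int
    n_observations: int


@dataclass
class AgeWindowResult:
    """Score gain for a single age cross-section (one visit per subject)."""

    target_age: float
    window: float
    use_previous: bool
    delta_r2: float
    p_value: float
    n_included: int
    r2_with: float
    r2_without: float


# ---------------------------------------------------------------------------
# Accuracy measures
# ---------------------------------------------------------------------------


def r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValidationError("observed/predicted must be equal-length vectors")
    if len(observed) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise ValidationError("constant input: correlation undefined (degenerate)")
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r * r)


def bootstrap_ci_r2(
    result: CVResult, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI for R2 from a subject-level cluster bootstrap."""
    if n_boot < 200:
        raise ValidationError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    groups = [g[["observed", "predicted"]].to_numpy()
              for _, g in result.records.groupby("subject_id", sort=False)]
    n = len(groups)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            take = rng.integers(0, n, size=n)
            pool = np.concatenate([groups[t] for t in take])
            if np.ptp(pool[:, 0]) > 0 and np.ptp(pool[:, 1]) > 0:
                break
        else:
            raise ValidationError("degenerate bootstrap resamples")
        vals[b] = r2(pool[:, 0], pool[:, 1])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Fold plumbing
# ---------------------------------------------------------------------------


@dataclass
class FoldData:
    """Everything a model builder may use for one fold.

    All fields are training-derived except the test-row covariates, whose
    age transform is anchored on training ages (out-of-range test ages are
    clamped).
    """

    arr: _ModelArrays
    heldout: int                   # subject index within arr.subject_ids
    train_mask: np.ndarray         # observation-level
    test_mask: np.ndarray
    train_subjects: np.ndarray     # subject indices
    W_train: np.ndarray
    W_test: np.ndarray
    transform: AgeTransform
    seed: int

    @property
    def y_train(self) -> np.ndarray:
        return self.arr.y[self.train_mask]

    @property
    def groups_train(self) -> np.ndarray:
        return self.arr.subj_of_obs[self.train_mask]


FoldFn = Callable[[FoldData], np.ndarray]
ModelBuilder = Callable[[LongCohort, str], FoldFn]


def _fold_seed(base_seed: int, i: int) -> int:
    return (base_seed * 1000003 + 7919 * (i + 1)) % (2**31)


def loso_cv(
    cohort: LongCohort,
    model_builder: ModelBuilder,
    trait: str,
    base_seed: int = 0,
) -> CVResult:
    """Leave-one-subject-out CV of one model family.

    ``model_builder(cohort, trait)`` is called once and returns a fold
    function mapping :class:`FoldData` to predictions for the held-out
    observations; the fold function must use training data only.
    """
    arr = cohort_arrays(cohort, trait)
    fold_fn = model_builder(cohort, trait)
    n = len(arr.subject_ids)
    preds = np.empty(len(arr.y))
    for i in range(n):
        test = arr.subj_of_obs == i
        train = ~test
        W_train, t = covariate_design(arr, train)
        W_test, _ = covariate_design(arr, test, transform=t)
        fold = FoldData(
            arr=arr,
            heldout=i,
            train_mask=train,
            test_mask=test,
            train_subjects=np.setdiff1d(np.arange(n), [i]),
            W_train=W_train,
            W_test=W_test,
            transform=t,
            seed=_fold_seed(base_seed, i),
        )
        try:
            preds[test] = fold_fn(fold)
        except Exception as exc:
            raise RuntimeError(
                f"model fit failed on fold for subject {arr.subject_ids[i]!r}: {exc}"
            ) from exc
    records = pd.DataFrame(
        {
            "subject_id": np.asarray(arr.subject_ids)[arr.subj_of_obs],
            "age": arr.age,
            "observed": arr.y,
            "predicted": preds,
        }
    )
    return CVResult(
        records=records,
        model_label="",
        r2=r2(arr.y, preds),
        r2_ci=None,
        delta_r2_vs_baseline=None,
        p_value=None,
        n_subjects=n,
        n_observations=len(arr.y),
    )


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def _aligned_subject_dosage(cohort: LongCohort, arr: _ModelArrays,
                            marker_set: str, trait: str) -> np.ndarray:
    ids = marker_set_ids(cohort.catalog, marker_set, trait)
    if not ids:
        raise ValidationError(f"empty {marker_set} marker set for trait {trait!r}")
    geno = cohort.genotypes.subset_markers(ids)
    gidx = cohort.genotypes.subject_index()
    rows = np.array([gidx[s] for s in arr.subject_ids])
    return geno.dosage[rows]


def _fit_predict_lmm(fold: FoldData, extra_train=None, extra_test=None):
    W_tr, W_te = fold.W_train, fold.W_test
    if extra_train is not None:
        W_tr = np.column_stack([W_tr, extra_train])
        W_te = np.column_stack([W_te, extra_test])
    fit = fit_lmm(LMMSpec(fold.y_train, W_tr, fold.groups_train), method="REML")
    return predict_fixed(fit, W_te)


def nongenetic_builder(cohort: LongCohort, trait: str) -> FoldFn:
    """Covariate-only mixed model: intercept, f(age), sex, BMI."""
    return lambda fold: _fit_predict_lmm(fold)


def ncbi_builder(cohort: LongCohort, trait: str) -> FoldFn:
    """Published-weight score added as a fifth fixed covariate."""
    entries = dedup_largest_study([e for e in cohort.catalog if e.trait == trait])
    if not entries:
        raise ValidationError(f"no catalog entries for trait {trait!r}")
    arr = cohort_arrays(cohort, trait)
    ids = [e.marker_id for e in entries]
    w = np.array([e.weight for e in entries])
    geno = cohort.genotypes.subset_markers(ids)
    gidx = cohort.genotypes.subject_index()
    raw = geno.dosage[np.array([gidx[s] for s in arr.subject_ids])]

    def fold_fn(fold: FoldData) -> np.ndarray:
        Xs = fold_subject_dosages(raw, fold.train_subjects)
        scores = Xs @ w
        return _fit_predict_lmm(
            fold,
            scores[fold.arr.subj_of_obs[fold.train_mask]],
            scores[fold.arr.subj_of_obs[fold.test_mask]],
        )

    return fold_fn


def bhs_builder(marker_set: str) -> ModelBuilder:
    """Within-cohort score: fold weights are training-only single-marker
    mixed-model estimates (the fast leave-one-out path); every subject in
    the fold — training and held-out — is scored with the fold's weights."""

    def build(cohort: LongCohort, trait: str) -> FoldFn:
        arr = cohort_arrays(cohort, trait)
        raw = _aligned_subject_dosage(cohort, arr, marker_set, trait)

        def fold_fn(fold: FoldData) -> np.ndarray:
            Xs = fold_subject_dosages(raw, fold.train_subjects)
            base = fit_lmm(
                LMMSpec(fold.y_train, fold.W_train, fold.groups_train),
                method="REML",
            )
            gamma = base.var_subject / base.var_residual
            beta = batched_marker_gls(
                fold.y_train, fold.W_train, fold.groups_train, Xs, gamma
            )
            scores = Xs @ beta
            return _fit_predict_lmm(
                fold,
                scores[fold.arr.subj_of_obs[fold.train_mask]],
                scores[fold.arr.subj_of_obs[fold.test_mask]],
            )

        return fold_fn

    return build


def wgr_builder(
    penalty: str,
    marker_set: str,
    mcmc: MCMCSettings = CV_MCMC,
    h2: float = H2_PRIOR,
) -> ModelBuilder:
    """Bayesian lasso/ridge with all set markers fit simultaneously.

    Priors are re-elicited per fold from the training phenotype variance
    and training genotype sum of squares; the fold's MCMC seed comes from
    the fold, so reruns are bit-identical.
    """

    def build(cohort: LongCohort, trait: str) -> FoldFn:
        arr = cohort_arrays(cohort, trait)
        raw = _aligned_subject_dosage(cohort, arr, marker_set, trait)

        def fold_fn(fold: FoldData) -> np.ndarray:
            Xs = fold_subject_dosages(raw, fold.train_subjects)
            Xs_train = Xs[fold.train_subjects]
            remap = -np.ones(len(arr.subject_ids), dtype=int)
            remap[fold.train_subjects] = np.arange(len(fold.train_subjects))
            sub_tr = remap[fold.groups_train]
            y_tr = fold.y_train
            priors = default_priors(
                float(np.var(y_tr)), h2,
                ms_x(Xs_train[sub_tr]), penalty,
            )
            post = fit_wgr(
                y_tr, fold.W_train, Xs_train, sub_tr, priors,
                replace(mcmc, seed=fold.seed),
            )
            X_test = Xs[fold.arr.subj_of_obs[fold.test_mask]]
            return predict_wgr(post, X_test, fold.W_test)

        return fold_fn

    return build


def get_builder(label: str, mcmc: MCMCSettings = CV_MCMC) -> ModelBuilder:
    """Model builder for a results-table label."""
    if label == "non-genetic":
        return nongenetic_builder
    if label == "NCBI":
        return ncbi_builder
    if label.startswith("BHS-"):
        return bhs_builder(label[-1])
    if label.startswith(("BLR-", "BRR-")):
        penalty = "lasso" if label.startswith("BLR") else "ridge"
        return wgr_builder(penalty, label[-1], mcmc=mcmc)
    raise ValidationError(f"unknown model label {label!r}")


# ---------------------------------------------------------------------------
# Score significance and age-window analysis
# ---------------------------------------------------------------------------


def score_significance(
    cohort: LongCohort, scores: RiskScoreVector, trait: str
) -> float:
    """Wald p of the score coefficient in the full-cohort mixed model
    (covariates intercept, f(age), sex, BMI; random subject intercept)."""
    arr = cohort_arrays(cohort, trait)
    index = {s: i for i, s in enumerate(scores.subject_ids)}
    try:
        sc = scores.scores[np.array([index[s] for s in arr.subject_ids])]
    except KeyError as exc:
        raise ValidationError(f"score missing for subject {exc.args[0]!r}")
    if np.ptp(sc) == 0:
        raise ValidationError("constant scores: association test undefined")
    W, _ = covariate_design(arr)
    design = np.column_stack([W, sc[arr.subj_of_obs]])
    fit = fit_lmm(LMMSpec(arr.y, design, arr.subj_of_obs), method="REML")
    _, _, p = coef_test(fit, design.shape[1] - 1)
    return p


def _ols_fit(y, X):
    """OLS via the mixed-model machinery with each row its own group
    (variance ratio collapses to the boundary)."""
    groups = np.arange(len(y))
    return fit_lmm(LMMSpec(y, X, groups), method="REML")


def select_window_observations(
    cohort: LongCohort,
    trait: str,
    target_age: float,
    window: float = 2.5,
    use_previous: bool = False,
) -> pd.DataFrame:
    """One observation per subject near a target age.

    Keeps, for each subject, the visit closest to ``target_age`` among
    those within ``target_age +- window`` years; subjects with no visit in
    the window are excluded.  With ``use_previous``, the value of the
    subject's most recent measurement strictly before the selected visit
    (at any age) is attached, and subjects lacking one are dropped with a
    logged count.  Returns columns ``subject_id, age, value, previous``.
    """
    arr = cohort_arrays(cohort, trait)
    rows = []
    dropped_prev = 0
    for i in range(len(arr.subject_ids)):
        obs = np.where(arr.subj_of_obs == i)[0]
        dist = np.abs(arr.age[obs] - target_age)
        in_win = dist <= window
        if not in_win.any():
            continue
        sel = obs[in_win][np.argmin(dist[in_win])]
        prev = np.nan
        if use_previous:
            earlier = obs[arr.age[obs] < arr.age[sel]]
            if len(earlier) == 0:
                dropped_prev += 1
                continue
            prev = arr.y[earlier[np.argmax(arr.age[earlier])]]
        rows.append((arr.subject_ids[i], arr.age[sel], arr.y[sel], prev))
    if dropped_prev:
        _log.info("age %g window: dropped %d subject(s) without a previous "
                  "measurement", target_age, dropped_prev)
    return pd.DataFrame(rows, columns=["subject_id", "age", "value", "previous"])


def age_window_analysis(
    cohort: LongCohort,
    scores: RiskScoreVector,
    target_age: float,
    use_previous: bool,
    trait: str,
    window: float = 2.5,
) -> AgeWindowResult:
    """Score gain for lipid levels near one target age.

    One observation per subject (see :func:`select_window_observations`);
    since no subject repeats, the models are ordinary linear regressions.
    ``delta_r2`` is the difference in leave-one-out CV R2 between the
    model with and without the score; the p-value is the full-data Wald
    test of the score term.
    """
    sel = select_window_observations(cohort, trait, target_age, window,
                                     use_previous)
    if len(sel) < 30:
        raise ValidationError(
            f"window underpowered: {len(sel)} subjects within "
            f"{target_age}+-{window} years (need >= 30)"
        )
    index = {s: i for i, s in enumerate(scores.subject_ids)}
    arr = cohort_arrays(cohort, trait)
    aidx = {s: i for i, s in enumerate(arr.subject_ids)}
    sidx = [aidx[s] for s in sel["subject_id"]]
    # recover sex/BMI of the selected visits
    obs_of = {}
    for k, (i, a) in enumerate(zip(arr.subj_of_obs, arr.age)):
        obs_of[(i, a)] = k
    obs_idx = np.array(
        [obs_of[(i, a)] for i, a in zip(sidx, sel["age"])]
    )
    y = sel["value"].to_numpy(dtype=float)
    t = AgeTransform.from_ages(sel["age"])
    cols = [np.ones(len(sel)), t(sel["age"].to_numpy()),
            arr.sex[obs_idx], arr.bmi[obs_idx]]
    if use_previous:
        cols.append(sel["previous"].to_numpy(dtype=float))
    W = np.column_stack(cols)
    sc = scores.scores[np.array([index[s] for s in sel["subject_id"]])]
    X_full = np.column_stack([W, sc])

    # leave-one-out CV predictions (one subject = one row here)
    pred_without = np.empty(len(y))
    pred_with = np.empty(len(y))
    for k in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[k] = False
        f0 = fit_lmm(LMMSpec(y[mask], W[mask], np.arange(mask.sum())),
                     method="REML", fixed_variance=(0.0, 1.0))
        f1 = fit_lmm(LMMSpec(y[mask], X_full[mask], np.arange(mask.sum())),
                     method="REML", fixed_variance=(0.0, 1.0))
        pred_without[k] = predict_fixed(f0, W[k:k + 1])[0]
        pred_with[k] = predict_fixed(f1, X_full[k:k + 1])[0]
    r2_without = r2(y, pred_without)
    r2_with = r2(y, pred_with)
    _, _, p = coef_test(_ols_fit(y, X_full), X_full.shape[1] - 1)
    return AgeWindowResult(
        target_age=float(target_age),
        window=float(window),
        use_previous=use_previous,
        delta_r2=r2_with - r2_without,
        p_value=p,
        n_included=len(y),
        r2_with=r2_with,
        r2_without=r2_without,
    )


# ---------------------------------------------------------------------------
# Full results-table experiment
# ---------------------------------------------------------------------------


def run_accuracy_table(
    cohort: LongCohort,
    trait: str,
    models: Sequence[str] = MODEL_LABELS,
    cv_mcmc: MCMCSettings = CV_MCMC,
    n_boot: int = 0,
    base_seed: int = 0,
    significance: bool = False,
) -> pd.DataFrame:
    """Cross-validated accuracy of every model family on one trait.

    Returns one row per model with R2, optional bootstrap CI, delta R2
    against the non-genetic baseline, and (optionally, for the scalar
    score models) the full-cohort Wald p of the score.
    """
    from .scores import bhs_score, loo_marker_effects, ncbi_score
    from .datamodel import impute_missing_dosages

    results: dict[str, CVResult] = {}
    labels = list(models)
    if "non-genetic" not in labels:
        labels = ["non-genetic"] + labels
    for label in labels:
        res = loso_cv(cohort, get_builder(label, mcmc=cv_mcmc), trait,
                      base_seed=base_seed)
        res.model_label = label
        results[label] = res
        _log.info("%s: CV R2 = %.4f", label, res.r2)
    base = results["non-genetic"].r2

    rows = []
    for label in labels:
        res = results[label]
        res.delta_r2_vs_baseline = None if label == "non-genetic" else res.r2 - base
        if n_boot:
            res.r2_ci = bootstrap_ci_r2(res, n_boot=n_boot, seed=base_seed)
        if significance and label in ("NCBI", "BHS-A", "BHS-R"):
            g_imp = impute_missing_dosages(
                cohort.genotypes, cohort.genotypes.subject_ids
            )
            if label == "NCBI":
                sc = ncbi_score(g_imp, cohort.catalog, trait)
            else:
                eff = loo_marker_effects(cohort, label[-1], trait, mode="fast")
                sc = bhs_score(eff, g_imp, trait=trait, marker_set=label[-1])
            res.p_value = score_significance(cohort, sc, trait)
        rows.append(
            {
                "model": label,
                "r2": res.r2,
                "ci_low": res.r2_ci[0] if res.r2_ci else np.nan,
                "ci_high": res.r2_ci[1] if res.r2_ci else np.nan,
                "delta_r2": (np.nan if res.delta_r2_vs_baseline is None
                             else res.delta_r2_vs_baseline),
                "p_value": np.nan if res.p_value is None else res.p_value,
                "n_subjects": res.n_subjects,
                "n_observations": res.n_observations,
            }
        )
    return pd.DataFrame(rows)
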