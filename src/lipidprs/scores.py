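"""Polygenic risk scores and the single-marker association scan.

Two score families:

* **NCBI score** — classical weighted allele counting with published
  per-allele weights: ``score_i = sum_j dosage_ij * w_j`` over the markers
  previously reported for the trait (the "R" set), keeping the
  largest-study estimate when several studies report the same marker.

* **BHS scores** — within-cohort weighted allele counting where the
  weights are single-marker mixed-model estimates computed by
  leave-one-subject-out cross-validation: subject i's weights
  ``beta_hat_{-i,j}`` come from fits that exclude every observation of
  subject i.  The "A" variant uses all catalog markers, the "R" variant
  only those reported for the trait being scored.

The single-marker model behind both the LOO effects and the association
scan is ``y = x_j b_j + W theta + Z v + e`` with fixed covariates
W = (intercept, f(age), sex, BMI) and a random subject intercept —
the same covariate set as the non-genetic prediction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .agetrans import AgeTransform, f_age
from .datamodel import (
    GenotypeMatrix,
    LongCohort,
    MarkerCatalogEntry,
    ValidationError,
)
from .lmm import LMMError, LMMSpec, coef_test, fit_lmm

_log = logging.getLogger(__name__)

_MONO_TOL = 1e-10


@dataclass
class RiskScoreVector:
    """Per-subject scalar genomic score with its provenance."""

    subject_ids: list[str]
    scores: np.ndarray
    marker_set: str            # "A" or "R"
    method: str                # "NCBI" or "BHS"
    trait: str
    weight_provenance: str     # e.g. "catalog (largest study)" / "LOO per subject"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.subject_ids):
            raise ValidationError("one score per subject required")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite risk score")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "score": self.scores,
                "method": self.method,
                "marker_set": self.marker_set,
                "trait": self.trait,
            }
        )


@dataclass
class LooMarkerEffects:
    """Matrix of beta_hat_{-i,j}: row i excludes subject i's data entirely."""

    subject_ids: list[str]
    marker_ids: list[str]
    effects: np.ndarray        # (n_subjects, n_markers), mg/dL per allele
    mode: str = "fast"

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (len(self.subject_ids), len(self.marker_ids)):
            raise ValidationError("effects shape does not match id lists")


# ---------------------------------------------------------------------------
# Catalog handling
# ---------------------------------------------------------------------------


def dedup_largest_study(
    entries: Sequence[MarkerCatalogEntry],
) -> list[MarkerCatalogEntry]:
    """One entry per marker id: the one from the largest study.

    Ties in study size keep the first occurrence, with a logged warning.
    """
    best: dict[str, MarkerCatalogEntry] = {}
    for e in entries:
        cur = best.get(e.marker_id)
        if cur is None:
            best[e.marker_id] = e
        elif e.study_n > cur.study_n:
            best[e.marker_id] = e
        elif e.study_n == cur.study_n:
            _log.warning(
                "marker %s: tied study_n=%d; keeping first entry",
                e.marker_id, e.study_n,
            )
    return list(best.values())


def marker_set_ids(
    catalog: Sequence[MarkerCatalogEntry], marker_set: str, trait: str
) -> list[str]:
    """Marker ids of the A (all entries) or R (trait-reported) set."""
    if marker_set == "A":
        pool = catalog
    elif marker_set == "R":
        pool = [e for e in catalog if e.trait == trait]
    else:
        raise ValidationError(f"marker_set must be 'A' or 'R', got {marker_set!r}")
    return list(dict.fromkeys(e.marker_id for e in pool))


# ---------------------------------------------------------------------------
# NCBI (published-weight) score
# ---------------------------------------------------------------------------


def ncbi_score(
    g: GenotypeMatrix,
    catalog: Sequence[MarkerCatalogEntry],
    trait: str,
) -> RiskScoreVector:
    """Weighted allele counting with published trait-specific weights."""
    trait_entries = [e for e in catalog if e.trait == trait]
    entries = dedup_largest_study(trait_entries)
    known = set(g.marker_ids)
    entries = [e for e in entries if e.marker_id in known]
    if not entries:
        raise ValidationError(
            f"no catalog markers for trait {trait!r} resolvable in the "
            "genotype matrix"
        )
    ids = [e.marker_id for e in entries]
    w = np.array([e.weight for e in entries])
    sub = g.subset_markers(ids)
    if np.isnan(sub.dosage).any():
        raise ValidationError(
            "missing dosages present; impute before scoring "
            "(see impute_missing_dosages)"
        )
    return RiskScoreVector(
        subject_ids=list(g.subject_ids),
        scores=sub.dosage @ w,
        marker_set="R",
        method="NCBI",
        trait=trait,
        weight_provenance="catalog (largest study per marker)",
    )


# ---------------------------------------------------------------------------
# Cohort -> model arrays
# ---------------------------------------------------------------------------


@dataclass
class _ModelArrays:
    """Observation-level arrays for one trait, NaN outcomes dropped."""

    y: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    bmi: np.ndarray
    subj_of_obs: np.ndarray     # index into subject_ids per observation
    subject_ids: list[str]
    k_s: np.ndarray             # observations per subject


def cohort_arrays(cohort: LongCohort, trait: str) -> _ModelArrays:
    df = cohort.phenotypes.df
    y = cohort.phenotypes.trait_values(trait).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if not keep.any():
        raise ValidationError(f"no observations with {trait} values")
    sids = df["subject_id"].to_numpy()[keep]
    uniq = list(dict.fromkeys(sids))
    index = {s: i for i, s in enumerate(uniq)}
    inv = np.array([index[s] for s in sids])
    return _ModelArrays(
        y=y[keep],
        age=df["age"].to_numpy(dtype=float)[keep],
        sex=df["sex"].to_numpy(dtype=float)[keep],
        bmi=df["bmi"].to_numpy(dtype=float)[keep],
        subj_of_obs=inv,
        subject_ids=uniq,
        k_s=np.bincount(inv, minlength=len(uniq)).astype(float),
    )


def covariate_design(arr: _ModelArrays, mask: np.ndarray | None = None,
                     transform: AgeTransform | None = None):
    """(W, transform) for (a subset of) the observations.

    The age transform is anchored on the ages actually included (the
    training split inside cross-validation), unless one is supplied.
    """
    if mask is None:
        mask = np.ones(len(arr.y), dtype=bool)
    age = arr.age[mask]
    t = AgeTransform.from_ages(age) if transform is None else transform
    W = np.column_stack(
        [np.ones(mask.sum()), f_age(age, t), arr.sex[mask], arr.bmi[mask]]
    )
    return W, t


def fold_subject_dosages(
    dosage: np.ndarray, train_subjects: np.ndarray
) -> np.ndarray:
    """Fill missing subject-level dosages with training-side marker means."""
    ref = dosage[train_subjects]
    counts = (~np.isnan(ref)).sum(axis=0)
    if np.any(counts == 0):
        raise ValidationError("marker entirely missing in training subjects")
    means = np.nanmean(ref, axis=0)
    out = dosage.copy()
    miss = np.isnan(out)
    out[miss] = np.broadcast_to(means, out.shape)[miss]
    return out


# ---------------------------------------------------------------------------
# Batched single-marker GLS (the fast LOO path)
# ---------------------------------------------------------------------------


def batched_marker_gls(
    y: np.ndarray,
    W: np.ndarray,
    subj_of_obs: np.ndarray,
    Xs: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Single-marker GLS coefficients for every marker at a fixed
    variance ratio.

    Solves, for each marker j, the coefficient of x_j in the model
    ``y = x_j b_j + W theta`` under the random-intercept marginal
    covariance with ratio ``gamma``, by partitioned (Frisch-Waugh)
    regression.  Dosages are constant within subject, so every
    cross-product reduces to subject-level aggregates; cost is
    O(K p^2 + n m p) for all markers together.

    Monomorphic markers (zero within-training dosage variance after
    projection) get coefficient 0.
    """
    n_sub = Xs.shape[0]
    k_s = np.bincount(subj_of_obs, minlength=n_sub).astype(float)
    c = np.where(k_s > 0, gamma / (1.0 + gamma * k_s), 0.0)
    SW = np.zeros((n_sub, W.shape[1]))
    np.add.at(SW, subj_of_obs, W)
    sy = np.bincount(subj_of_obs, weights=y, minlength=n_sub)

    WtOW = W.T @ W - SW.T @ (c[:, None] * SW)
    WtOy = W.T @ y - SW.T @ (c * sy)
    shrink = 1.0 - c * k_s                        # 1/(1 + gamma k_s)
    WtOx = SW.T @ (shrink[:, None] * Xs)          # (p, m)
    xtOx = (k_s * shrink) @ (Xs**2)               # (m,)
    xtOy = Xs.T @ (sy * shrink)                   # (m,)

    alpha = np.linalg.solve(WtOW, WtOy)
    B = np.linalg.solve(WtOW, WtOx)
    num = xtOy - WtOx.T @ alpha
    den = xtOx - np.einsum("pm,pm->m", WtOx, B)
    beta = np.zeros(Xs.shape[1])
    ok = den > _MONO_TOL
    if not ok.all():
        _log.warning("%d marker(s) monomorphic in training split; effect set to 0",
                     int((~ok).sum()))
    beta[ok] = num[ok] / den[ok]
    return beta


# ---------------------------------------------------------------------------
# BHS leave-one-subject-out marker effects and score
# ---------------------------------------------------------------------------


def loo_marker_effects(
    cohort: LongCohort,
    marker_set: str,
    trait: str,
    mode: str = "fast",
) -> LooMarkerEffects:
    """beta_hat_{-i,j} for every subject i and marker j in the set.

    ``mode="exact"`` refits the single-marker mixed model by REML on the
    training split for every (i, j) pair — the reference but
    O(n_subjects * n_markers) full fits.  ``mode="fast"`` estimates the
    variance ratio once per fold from the training-only covariate model
    (single markers barely move the variance components) and then solves
    every marker's GLS coefficient at that ratio in one batched pass.
    Both modes use only training data within each fold.
    """
    if mode not in ("fast", "exact"):
        raise ValidationError(f"mode must be 'fast' or 'exact', got {mode!r}")
    arr = cohort_arrays(cohort, trait)
    ids = marker_set_ids(cohort.catalog, marker_set, trait)
    if not ids:
        raise ValidationError(f"empty {marker_set} marker set for trait {trait!r}")
    geno = cohort.genotypes.subset_markers(ids)
    gidx = cohort.genotypes.subject_index()
    rows = np.array([gidx[s] for s in arr.subject_ids])
    Xs_raw = geno.dosage[rows]                     # (n, m) aligned to arr subjects

    n, m = Xs_raw.shape
    effects = np.empty((n, m))
    for i in range(n):
        train = arr.subj_of_obs != i
        train_subjects = np.setdiff1d(np.arange(n), [i])
        Xs = fold_subject_dosages(Xs_raw, train_subjects)
        W, _ = covariate_design(arr, train)
        y_tr = arr.y[train]
        sub_tr = arr.subj_of_obs[train]
        if mode == "fast":
            base = fit_lmm(LMMSpec(y_tr, W, sub_tr), method="REML")
            gamma = base.var_subject / base.var_residual
            x_sub = Xs.copy()
            x_sub[i] = 0.0                        # row unused by training obs
            effects[i] = batched_marker_gls(y_tr, W, sub_tr, x_sub, gamma)
        else:
            x_obs = Xs[sub_tr]
            for j in range(m):
                xj = x_obs[:, j]
                if np.ptp(xj) < _MONO_TOL:
                    _log.warning("marker %s monomorphic in fold %s; effect 0",
                                 ids[j], arr.subject_ids[i])
                    effects[i, j] = 0.0
                    continue
                design = np.column_stack([xj, W])
                fit = fit_lmm(LMMSpec(y_tr, design, sub_tr), method="REML")
                effects[i, j] = fit.fixed_estimates[0]
    return LooMarkerEffects(list(arr.subject_ids), list(ids), effects, mode=mode)


def bhs_score(effects: LooMarkerEffects, g: GenotypeMatrix,
              trait: str = "", marker_set: str = "") -> RiskScoreVector:
    """Score each subject with their own LOO weights:
    ``phi_i = sum_j dosage_ij * beta_hat_{-i,j}``."""
    gidx = g.subject_index()
    try:
        rows = np.array([gidx[s] for s in effects.subject_ids])
    except KeyError as exc:
        raise ValidationError(f"subject {exc.args[0]!r} missing from genotypes")
    sub = g.subset_markers(effects.marker_ids)
    dosage = sub.dosage[rows]
    if np.isnan(dosage).any():
        dosage = fold_subject_dosages(dosage, np.arange(len(rows)))
    if dosage.shape != effects.effects.shape:
        raise ValidationError("genotype/effects dimension mismatch")
    scores = np.einsum("ij,ij->i", dosage, effects.effects)
    return RiskScoreVector(
        subject_ids=list(effects.subject_ids),
        scores=scores,
        marker_set=marker_set or "?",
        method="BHS",
        trait=trait,
        weight_provenance=f"per-subject LOO single-marker LMM ({effects.mode} mode)",
    )


# ---------------------------------------------------------------------------
# Single-marker association scan
# ---------------------------------------------------------------------------


def single_marker_scan(cohort: LongCohort, trait: str) -> pd.DataFrame:
    """Per-marker mixed-model association on the full cohort.

    Fits ``y = x_j b_j + W theta + Z v + e`` by REML for every distinct
    catalog marker present in the genotypes and reports the Wald test of
    b_j.  Zero-variance markers are skipped with a warning.
    """
    arr = cohort_arrays(cohort, trait)
    ids = marker_set_ids(cohort.catalog, "A", trait)
    geno = cohort.genotypes.subset_markers(ids)
    gidx = cohort.genotypes.subject_index()
    rows = np.array([gidx[s] for s in arr.subject_ids])
    Xs = fold_subject_dosages(geno.dosage[rows], np.arange(len(rows)))
    W, _ = covariate_design(arr)

    records = []
    for j, mid in enumerate(ids):
        xj = Xs[arr.subj_of_obs, j]
        if np.ptp(xj) < _MONO_TOL:
            _log.warning("marker %s has zero dosage variance; skipped", mid)
            continue
        design = np.column_stack([xj, W])
        try:
            fit = fit_lmm(LMMSpec(arr.y, design, arr.subj_of_obs), method="REML")
        except LMMError as exc:
            _log.warning("marker %s: fit failed (%s); skipped", mid, exc)
            continue
        est, se, p = coef_test(fit, 0)
        records.append((mid, est, se, p))
    return pd.DataFrame(records, columns=["marker_id", "estimate", "se", "p"])


def qq_coordinates(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})


def qq_plot(pvalues: np.ndarray, path: str) -> None:
    """Write a QQ plot of scan p-values (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = qq_coordinates(pvalues)
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = max(coords["expected"].max(), coords["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.scatter(coords["expected"], coords["observed"], s=8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
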