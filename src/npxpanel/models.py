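"""Forced-core logistic models and model-vs-reference evaluation.

The clinical anchor is a reference logistic model on HE4 (``WFDC2``),
CA125 (``MUC-16``) and age — the information content of the established
risk algorithms built on those two markers. Candidate markers are judged
by what they add to that reference: each is added in turn, the augmented
model's apparent AUC is compared to the reference's with DeLong's paired
test, and the operating points the clinic cares about (sensitivity at 95%
specificity, specificity at 95% sensitivity, the Youden point) are read
off the predicted probabilities.

Reported AUCs are apparent (in-sample), matching how small discovery
cohorts are conventionally summarized; :func:`cross_validated_auc` is the
honest alternative when optimism matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import NpxMatrix
from . import roc

logger = logging.getLogger(__name__)

HE4 = "WFDC2"
CA125 = "MUC-16"
AGE = "age"
CORE_PREDICTORS = (HE4, CA125, AGE)

#: |standardized coefficient| beyond which a fit is flagged as separated.
_SEPARATION_COEF = 25.0


@dataclass
class LogisticModel:
    """A fitted maximum-likelihood logistic model.

    Coefficients are on the original predictor scale (log-odds per unit).
    Samples with a missing value in any predictor are excluded before
    fitting and their count recorded; ``separation_flag`` marks fits where
    the optimizer ran against (quasi-)separation — the coefficient scale is
    then meaningless but the score ranking, which is all the downstream
    ROC machinery uses, is still valid.
    """

    predictors: list[str]
    coef: np.ndarray
    intercept: float
    sample_ids: list[str]
    labels: np.ndarray
    linear_predictor: np.ndarray
    prob: np.ndarray
    converged: bool
    separation_flag: bool
    n_excluded: int
    dropped_predictors: list[str] = field(default_factory=list)


@dataclass
class ModelEvaluation:
    """ROC summary of one model: AUC with CI plus operating points."""

    auc: roc.AucEstimate
    sens_at_spec: roc.OperatingPoint
    spec_at_sens: roc.OperatingPoint
    youden: roc.OperatingPoint | None = None


@dataclass
class ModelComparison:
    """One candidate model against the forced-core reference."""

    label: str
    evaluation: ModelEvaluation
    delong: roc.DelongComparison
    rank: int | None = None
    significant: bool = False


def design_matrix(m: NpxMatrix, predictors: list[str]) -> pd.DataFrame:
    """Assemble a design matrix from NPX columns plus the ``age`` metadata."""

    cols = {}
    for name in predictors:
        if name == AGE:
            cols[name] = m.meta["age"].astype(float)
        elif name in m.values.columns:
            cols[name] = m.values[name]
        else:
            raise KeyError(f"predictor {name!r} not present in cohort")
    return pd.DataFrame(cols, index=m.meta.index)


def fit_logistic(m: NpxMatrix, labels: np.ndarray, predictors: list[str]) -> LogisticModel:
    """Maximum-likelihood logistic fit on the named predictors.

    Predictors are standardized internally (so the fit is invariant to
    affine rescaling of any input) and the coefficients mapped back to the
    original scale. Constant predictors are dropped with a warning; rows
    with missing values are excluded listwise.
    """

    if not predictors:
        raise ValueError("empty predictor list")
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictors")
    X = design_matrix(m, list(predictors))
    y = np.asarray(labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("labels length does not match cohort")

    keep = X.notna().all(axis=1).to_numpy()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "fit_logistic: excluded %d samples with missing predictor values", n_excluded
        )
    X = X.loc[keep]
    y = y[keep]
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class after exclusions")

    sd = X.std(ddof=0)
    dropped = [c for c in X.columns if sd[c] == 0]
    if dropped:
        logger.warning("dropping constant predictors: %s", dropped)
        X = X.drop(columns=dropped)
        if X.shape[1] == 0:
            raise ValueError("all predictors are constant")
    mean = X.mean()
    sd = X.std(ddof=0)
    Z = (X - mean) / sd

    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
    lr.fit(Z.to_numpy(), y)
    coef_std = lr.coef_.ravel()
    converged = bool(lr.n_iter_[0] < 5000)
    separation = (not converged) or bool(np.abs(coef_std).max() > _SEPARATION_COEF)

    coef = coef_std / sd.to_numpy()
    intercept = float(lr.intercept_[0] - np.sum(coef_std * mean.to_numpy() / sd.to_numpy()))
    eta = intercept + X.to_numpy() @ coef
    prob = 1.0 / (1.0 + np.exp(-eta))
    return LogisticModel(
        predictors=list(X.columns),
        coef=coef,
        intercept=intercept,
        sample_ids=[str(i) for i in X.index],
        labels=y,
        linear_predictor=eta,
        prob=prob,
        converged=converged,
        separation_flag=separation,
        n_excluded=n_excluded,
        dropped_predictors=dropped,
    )


def reference_model(m: NpxMatrix, labels: np.ndarray) -> LogisticModel:
    """The forced-core HE4 + CA125 + age reference model.

    Samples with missing age are excluded (listwise) and the count logged.
    """

    for name in (HE4, CA125):
        if name not in m.values.columns:
            raise KeyError(f"required biomarker column {name!r} missing from cohort")
    return fit_logistic(m, labels, list(CORE_PREDICTORS))


def evaluate_model(
    model: LogisticModel,
    n_boot: int = 2000,
    seed: int = 0,
    target_spec: float = 0.95,
    target_sens: float = 0.95,
    include_youden: bool = False,
) -> ModelEvaluation:
    """AUC with bootstrap CI and operating points on predicted probabilities."""

    scores, y = model.prob, model.labels
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31 - 1, size=3)
    auc = roc.bootstrap_auc_ci(scores, y, n_boot=n_boot, seed=int(seeds[0]))
    se = roc.sensitivity_at_specificity(
        scores, y, target_spec, n_boot=n_boot, seed=int(seeds[1])
    )
    sp = roc.specificity_at_sensitivity(
        scores, y, target_sens, n_boot=n_boot, seed=int(seeds[2])
    )
    yj = roc.youden_point(scores, y) if include_youden else None
    return ModelEvaluation(auc=auc, sens_at_spec=se, spec_at_sens=sp, youden=yj)


def _align_pair(model: LogisticModel, reference: LogisticModel):
    """Scores of both models restricted to their common sample set."""

    common = [sid for sid in reference.sample_ids if sid in set(model.sample_ids)]
    ref_pos = {sid: i for i, sid in enumerate(reference.sample_ids)}
    mod_pos = {sid: i for i, sid in enumerate(model.sample_ids)}
    ri = [ref_pos[s] for s in common]
    mi = [mod_pos[s] for s in common]
    y = reference.labels[ri]
    if not np.array_equal(y, model.labels[mi]):
        raise ValueError("label mismatch between paired models")
    return model.prob[mi], reference.prob[ri], y


def compare_to_reference(
    model: LogisticModel, reference: LogisticModel
) -> roc.DelongComparison:
    """DeLong paired test of a model against the reference on the samples
    both were fitted on."""

    a, b, y = _align_pair(model, reference)
    return roc.delong_paired_test(a, b, y)


def add_one_scan(
    m: NpxMatrix,
    labels: np.ndarray,
    candidates: list[str],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[ModelComparison, list[ModelComparison]]:
    """Add each candidate marker to the reference model in turn.

    Returns ``(reference comparison, ranked candidate comparisons)``; rows
    are ranked by apparent model AUC, descending, and flagged significant
    when the DeLong p against the reference is below ``alpha``. Candidates
    equal to a core predictor are skipped with a warning.
    """

    ref = reference_model(m, labels)
    rng = np.random.default_rng(seed)
    ref_eval = evaluate_model(ref, n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))
    ref_row = ModelComparison(
        label="+".join(CORE_PREDICTORS),
        evaluation=ref_eval,
        delong=roc.delong_paired_test(ref.prob, ref.prob, ref.labels),
    )
    rows: list[ModelComparison] = []
    for cand in candidates:
        if cand in CORE_PREDICTORS:
            logger.warning("candidate %r is a core predictor; skipped", cand)
            continue
        model = fit_logistic(m, labels, list(CORE_PREDICTORS) + [cand])
        comparison = compare_to_reference(model, ref)
        ev = evaluate_model(model, n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))
        rows.append(
            ModelComparison(
                label=cand,
                evaluation=ev,
                delong=comparison,
                significant=comparison.p < alpha,
            )
        )
    rows.sort(key=lambda r: (-r.evaluation.auc.auc, r.label))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return ref_row, rows


def cross_validated_auc(
    m: NpxMatrix,
    labels: np.ndarray,
    predictors: list[str],
    k: int = 5,
    seed: int = 0,
) -> float:
    """Out-of-fold AUC of a logistic model under stratified k-fold CV."""

    X = design_matrix(m, list(predictors))
    keep = X.notna().all(axis=1).to_numpy()
    X = X.loc[keep].to_numpy()
    y = np.asarray(labels, dtype=int)[keep]
    oof = np.empty(len(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        mean, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        lr.fit((X[tr] - mean) / sd, y[tr])
        oof[te] = lr.predict_proba((X[te] - mean) / sd)[:, 1]
    return roc.empirical_auc(oof, y)


def comparison_table(
    ref_row: ModelComparison, rows: list[ModelComparison], label_header: str = "model"
) -> pd.DataFrame:
    """Flatten comparisons into the published add-one table layout."""

    def fmt(r: ModelComparison, is_ref: bool) -> dict:
        e = r.evaluation
        out = {
            label_header: r.label,
            "auc": e.auc.auc,
            "auc_ci_low": e.auc.ci_low,
            "auc_ci_high": e.auc.ci_high,
            "rank": r.rank if not is_ref else None,
            "delong_p": None if is_ref else r.delong.p,
            "sens_at_95spec": e.sens_at_spec.sensitivity,
            "sens_ci_low": e.sens_at_spec.ci_low,
            "sens_ci_high": e.sens_at_spec.ci_high,
            "spec_at_95sens": e.spec_at_sens.specificity,
            "spec_ci_low": e.spec_at_sens.ci_low,
            "spec_ci_high": e.spec_at_sens.ci_high,
        }
        if e.youden is not None:
            out["spec_at_best"] = e.youden.specificity
            out["sens_at_best"] = e.youden.sensitivity
        return out

    records = [fmt(ref_row, True)] + [fmt(r, False) for r in rows]
    return pd.DataFrame(records)
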