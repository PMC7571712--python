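"""Empirical ROC/AUC estimation, bootstrap CIs, DeLong tests, operating points.

Scores follow the convention higher = more case-like; the empirical AUC is
the Mann-Whitney estimator (fraction of case/control pairs the case wins,
ties counted one half). Confidence intervals are stratified percentile
bootstrap — cases and controls are resampled separately so no resample can
lose a class. Correlated AUCs measured on the same samples are compared
with DeLong's placement-value estimator of the variance of the AUC
difference.

Operating points are taken over empirically achievable thresholds only (a
sample classifies as a case when its score is >= the threshold); no ROC
interpolation is performed, so every reported sensitivity/specificity pair
is attainable on the data at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import ContrastSpec, NpxMatrix, make_contrast


@dataclass(frozen=True)
class AucEstimate:
    """AUC point estimate with a stratified percentile-bootstrap CI."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_pos: int
    n_neg: int
    flipped: bool = False


@dataclass(frozen=True)
class DelongComparison:
    """Paired comparison of two AUCs measured on the same samples."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


@dataclass(frozen=True)
class OperatingPoint:
    """One achievable (threshold, sensitivity, specificity) triple.

    ``criterion`` records how the threshold was chosen; for the constrained
    criteria the bootstrap CI applies to the unconstrained quantity (the
    sensitivity for ``sens_at_spec``, the specificity for ``spec_at_sens``).
    """

    threshold: float
    sensitivity: float
    specificity: float
    criterion: str
    target: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def _check_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    return scores, labels


def empirical_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 0.5 P(tie)."""

    scores, labels = _check_scores(scores, labels)
    return float(roc_auc_score(labels, scores))


def _auc_rows(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for matched matrices of resampled scores."""

    n1, n0 = pos.shape[1], neg.shape[1]
    both = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> AucEstimate:
    """Stratified percentile-bootstrap CI around the empirical AUC."""

    scores, labels = _check_scores(scores, labels)
    if n_boot < 0:
        raise ValueError("n_boot must be nonnegative")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if n_boot == 0:  # point estimate only
        return AucEstimate(
            auc=empirical_auc(scores, labels),
            ci_low=float("nan"),
            ci_high=float("nan"),
            n_boot=0,
            n_pos=len(pos),
            n_neg=len(neg),
        )
    rng = np.random.default_rng(seed)
    bpos = rng.choice(pos, size=(n_boot, len(pos)), replace=True)
    bneg = rng.choice(neg, size=(n_boot, len(neg)), replace=True)
    aucs = _auc_rows(bpos, bneg)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return AucEstimate(
        auc=empirical_auc(scores, labels),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    ``v10[i]`` is the fraction of controls the i-th case beats (ties half);
    ``v01[j]`` the fraction of cases the j-th control loses to (ties half).
    """

    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_auc_variance(scores, labels) -> float:
    """DeLong variance of a single empirical AUC."""

    scores, labels = _check_scores(scores, labels)
    v10, v01 = _placements(scores[labels == 1], scores[labels == 0])
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_paired_test(scores_a, scores_b, labels) -> DelongComparison:
    """DeLong z-test for two AUCs measured on the same samples.

    The variance of the AUC difference is estimated from the paired
    placement values, which accounts for the correlation induced by scoring
    the same cases and controls twice. Zero variance with equal AUCs gives
    p = 1 by convention.
    """

    scores_a, labels = _check_scores(scores_a, labels)
    scores_b, _ = _check_scores(scores_b, labels)
    pos_mask = labels == 1
    v10a, v01a = _placements(scores_a[pos_mask], scores_a[~pos_mask])
    v10b, v01b = _placements(scores_b[pos_mask], scores_b[~pos_mask])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n1, n0 = len(v10a), len(v01a)
    var = float(
        np.var(v10a - v10b, ddof=1) / n1 + np.var(v01a - v01b, ddof=1) / n0
    )
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return DelongComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
        z = float("inf") if diff > 0 else float("-inf")
        return DelongComparison(auc_a, auc_b, 0.0, z, 0.0)
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongComparison(auc_a, auc_b, var, float(z), p)


def _threshold_stats(scores: np.ndarray, labels: np.ndarray):
    """Sensitivity and specificity at every achievable threshold.

    Thresholds are the unique observed scores plus +inf (the all-negative
    rule); a sample is called a case when score >= threshold.
    """

    thr = np.append(np.unique(scores), np.inf)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    sens = 1.0 - np.searchsorted(pos, thr, side="left") / len(pos)
    spec = np.searchsorted(neg, thr, side="left") / len(neg)
    return thr, sens, spec


def _sens_at_spec(scores, labels, target):
    thr, sens, spec = _threshold_stats(scores, labels)
    ok = spec >= target
    best_sens = sens[ok].max()
    cand = ok & (sens == best_sens)
    best_spec = spec[cand].max()
    i = int(np.flatnonzero(cand & (spec == best_spec))[0])
    return thr[i], sens[i], spec[i]


def _spec_at_sens(scores, labels, target):
    thr, sens, spec = _threshold_stats(scores, labels)
    ok = sens >= target
    best_spec = spec[ok].max()
    cand = ok & (spec == best_spec)
    best_sens = sens[cand].max()
    i = int(np.flatnonzero(cand & (sens == best_sens))[-1])
    return thr[i], sens[i], spec[i]


def _bootstrap_operating(scores, labels, stat_fn, n_boot, seed, which):
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        _, se, sp = stat_fn(scores[idx], labels[idx])
        vals[b] = se if which == "sens" else sp
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return float(lo), float(hi)


def sensitivity_at_specificity(
    scores, labels, target_spec: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> OperatingPoint:
    """Maximum sensitivity over thresholds with specificity >= target.

    Always achievable: the +inf threshold classifies everyone negative
    (specificity 1, sensitivity 0). The bootstrap CI covers the attained
    sensitivity under stratified resampling.
    """

    scores, labels = _check_scores(scores, labels)
    if not 0.0 < target_spec < 1.0:
        raise ValueError("target specificity must be in (0, 1)")
    thr, se, sp = _sens_at_spec(scores, labels, target_spec)
    lo = hi = None
    if n_boot:
        lo, hi = _bootstrap_operating(
            scores, labels, lambda s, l: _sens_at_spec(s, l, target_spec), n_boot, seed, "sens"
        )
    return OperatingPoint(float(thr), float(se), float(sp), "sens_at_spec", target_spec, lo, hi)


def specificity_at_sensitivity(
    scores, labels, target_sens: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> OperatingPoint:
    """Maximum specificity over thresholds with sensitivity >= target."""

    scores, labels = _check_scores(scores, labels)
    if not 0.0 < target_sens < 1.0:
        raise ValueError("target sensitivity must be in (0, 1)")
    thr, se, sp = _spec_at_sens(scores, labels, target_sens)
    lo = hi = None
    if n_boot:
        lo, hi = _bootstrap_operating(
            scores, labels, lambda s, l: _spec_at_sens(s, l, target_sens), n_boot, seed, "spec"
        )
    return OperatingPoint(float(thr), float(se), float(sp), "spec_at_sens", target_sens, lo, hi)


def youden_point(scores, labels) -> OperatingPoint:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (the more conservative rule
    for a rule-in diagnostic), then toward the higher threshold.
    """

    scores, labels = _check_scores(scores, labels)
    thr, sens, spec = _threshold_stats(scores, labels)
    j = sens + spec - 1.0
    best = j.max()
    cand = j == best
    best_spec = spec[cand].max()
    i = int(np.flatnonzero(cand & (spec == best_spec))[-1])
    return OperatingPoint(float(thr[i]), float(sens[i]), float(spec[i]), "youden")


def roc_curve_table(scores, labels) -> pd.DataFrame:
    """ROC points at every achievable threshold: (threshold, fpr, tpr)."""

    scores, labels = _check_scores(scores, labels)
    thr, sens, spec = _threshold_stats(scores, labels)
    return pd.DataFrame({"threshold": thr, "fpr": 1.0 - spec, "tpr": sens})


def rank_univariate_auc(
    m: NpxMatrix,
    contrast: ContrastSpec,
    auc_threshold: float = 0.7,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank every protein by discrimination AUC for one contrast.

    Markers that run lower in cases discriminate just as well as markers
    that run higher, so the reported AUC is orientation-corrected:
    ``max(a, 1 - a)``, with ``flipped`` recording when the raw scores were
    negated. Rows are filtered at ``auc_threshold`` and sorted descending;
    the CI is bootstrapped on the oriented scores.
    """

    sub, labels = make_contrast(m, contrast)
    rng = np.random.default_rng(seed)
    rows = []
    for prot in sub.proteins:
        scores = sub.values[prot].to_numpy()
        a = empirical_auc(scores, labels)
        flipped = a < 0.5
        oriented = -scores if flipped else scores
        est = bootstrap_auc_ci(
            oriented, labels, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
        )
        rows.append(
            {
                "protein": prot,
                "auc": max(a, 1.0 - a),
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flipped": flipped,
                "n_pos": est.n_pos,
                "n_neg": est.n_neg,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["auc", "protein"], ascending=[False, True], kind="mergesort")
    df = df.loc[df["auc"] > auc_threshold].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
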