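"""Repeated-split lasso stability selection with backward elimination.

The variable-selection procedure behind the multi-marker panels works on a
candidate pool of markers competing alongside a forced, unpenalized core
(HE4, CA125, age):

1. *Round*: stratified 50/50 split of the contrast samples. On the
   training half, the lasso shrinkage parameter ``lambda`` is tuned by
   stratified k-fold cross-validation (minimum mean binomial deviance over
   a geometric path). That ``lambda_CV`` is then applied to the held-out
   half, where an L1-penalized logistic fit performs the actual variable
   selection; the selected pool variables and their absolute standardized
   coefficients are saved.
2. *Repeat*: R such rounds (default 10) with independent splits.
3. *Rank*: pool variables are ordered by how often they were selected,
   then by the sum of their saved absolute coefficients, then by name.
4. *Eliminate*: the lowest-ranked variable is removed and the whole loop
   repeats, shrinking the pool by one per cycle down to ``stop_size``.
5. *Report*: the last few nested pools are refit as ordinary logistic
   models on the full contrast (forced core + pool) and each is compared
   to the forced-core reference with DeLong's paired test; the "final"
   model is the reported row with the highest AUC whose DeLong p clears
   the significance level.

Everything is a pure function of (data, configuration, master seed): round
seeds, cycle seeds, split and fold assignments all derive deterministically
from the seed given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _l1, models, roc
from .cohort import NpxMatrix

logger = logging.getLogger(__name__)

_SELECT_TOL = 1e-8  # |standardized coef| above this counts as selected
_MAX_REFOLD = 5


@dataclass(frozen=True)
class SelectionRound:
    """Record of one split/tune/select round."""

    index: int
    seed: int
    lambda_cv: float
    selected: tuple[str, ...]
    coef: dict  # selected variable -> |standardized coefficient|


@dataclass(frozen=True)
class VariableRanking:
    """Aggregated ranking of the candidate pool across rounds.

    ``table`` columns: ``variable, times_selected, coef_sum, rank`` with
    rank 1 the strongest candidate. Ordering: selection count descending,
    coefficient sum descending, name ascending.
    """

    table: pd.DataFrame
    n_rounds: int

    @property
    def ordered(self) -> list[str]:
        return list(self.table["variable"])

    @property
    def lowest(self) -> str:
        return str(self.table["variable"].iloc[-1])


@dataclass(frozen=True)
class EliminationCycle:
    pool: tuple[str, ...]
    ranking: VariableRanking
    eliminated: str


@dataclass(frozen=True)
class EliminationTrace:
    """Full record of the backward-elimination run."""

    initial_pool: tuple[str, ...]
    cycles: tuple[EliminationCycle, ...]
    terminal_pool: tuple[str, ...]

    def pool_sequence(self) -> list[tuple[str, ...]]:
        return [c.pool for c in self.cycles] + [self.terminal_pool]

    def nested_pools(self, depth: int) -> list[tuple[str, ...]]:
        seq = self.pool_sequence()
        if depth > len(seq):
            logger.warning(
                "depth %d exceeds trace length %d; truncating", depth, len(seq)
            )
            depth = len(seq)
        return seq[-depth:]

    def to_json_dict(self) -> dict:
        return {
            "initial_pool": list(self.initial_pool),
            "terminal_pool": list(self.terminal_pool),
            "cycles": [
                {
                    "pool": list(c.pool),
                    "eliminated": c.eliminated,
                    "ranking": c.ranking.table.to_dict(orient="records"),
                }
                for c in self.cycles
            ],
        }


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def _stratified_half_split(y: np.ndarray, rng: np.random.Generator):
    """Index split into training/test halves, stratified by outcome."""

    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        train.extend(idx[:half])
        test.extend(idx[half:])
    train, test = np.sort(np.array(train)), np.sort(np.array(test))
    if min(len(train), len(test)) == 0:
        raise ValueError("empty half in 50/50 split")
    return train, test


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Stratified k-fold assignment; every fold keeps both classes."""

    for _attempt in range(_MAX_REFOLD):
        fold = np.empty(len(y), dtype=int)
        for cls in (0, 1):
            idx = rng.permutation(np.flatnonzero(y == cls))
            fold[idx] = np.arange(len(idx)) % k
        ok = all(
            len(np.unique(y[fold != f])) == 2 and (fold == f).sum() > 0
            for f in range(k)
        )
        if ok:
            return fold
    raise ValueError(
        f"could not build {k} stratified folds with both classes present"
    )


def cv_choose_lambda(
    X: np.ndarray,
    y: np.ndarray,
    pf: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 30,
    rule: str = "min",
) -> float:
    """Pick lambda by stratified k-fold CV of the binomial deviance.

    ``rule='min'`` takes the deviance minimizer; ``rule='1se'`` the largest
    lambda within one standard error of the minimum.
    """

    rng = np.random.default_rng(seed)
    Z, _, _ = _l1.standardize(X)
    lambdas = _l1.lambda_grid(Z, y, pf, n_lambda=n_lambda)
    fold = _stratified_folds(y, k, rng)
    dev = np.empty((k, len(lambdas)))
    for f in range(k):
        tr = fold != f
        te = ~tr
        # looser tolerance than the selection fit: the deviance curve is
        # flat at the scale of the last CD digits
        b0s, betas, mean, sd = _l1.fit_l1_path(
            X[tr], y[tr], lambdas, pf, max_outer=5, tol=1e-3
        )
        Zte = (X[te] - mean) / sd
        eta = np.clip(b0s[None, :] + Zte @ betas.T, -30.0, 30.0)
        ll = y[te][:, None] * eta - np.log1p(np.exp(eta))
        dev[f] = -2.0 * ll.mean(axis=0)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    if rule == "min":
        return float(lambdas[best])
    if rule == "1se":
        se = dev.std(axis=0, ddof=1)[best] / np.sqrt(k)
        ok = np.flatnonzero(mean_dev <= mean_dev[best] + se)
        return float(lambdas[ok[0]])  # lambdas descend: first ok is largest
    raise ValueError(f"unknown lambda rule {rule!r}")


def single_selection_round(
    m: NpxMatrix,
    labels: np.ndarray,
    pool: list[str],
    forced: list[str],
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_rule: str = "min",
    round_index: int = 0,
    lambda_override: float | None = None,
) -> SelectionRound:
    """One 50/50-split selection round.

    The shrinkage parameter tuned on the training half is applied unchanged
    on the held-out half, where the penalized fit (forced variables
    unpenalized) does the selecting. Standardization is per fit, as
    penalized fits conventionally standardize internally.
    """

    if not pool:
        raise ValueError("candidate pool is empty")
    overlap = set(pool) & set(forced)
    if overlap:
        raise ValueError(f"pool and forced sets overlap: {sorted(overlap)}")
    names = list(forced) + list(pool)
    X = models.design_matrix(m, names)
    keep = X.notna().all(axis=1).to_numpy()
    X = X.loc[keep].to_numpy()
    y = np.asarray(labels, dtype=float)[keep]
    pf = np.array([0.0] * len(forced) + [1.0] * len(pool))

    rng = np.random.default_rng(seed)
    tr, te = _stratified_half_split(y.astype(int), rng)
    if lambda_override is None:
        lam = cv_choose_lambda(
            X[tr],
            y[tr],
            pf,
            k=k,
            seed=int(rng.integers(2**31 - 1)),
            n_lambda=n_lambda,
            rule=lambda_rule,
        )
    else:
        lam = float(lambda_override)
    _, beta, _, _ = _l1.fit_at_lambda(X[te], y[te], lam, pf)
    coefs = {}
    for j, name in enumerate(pool):
        b = beta[len(forced) + j]
        if abs(b) > _SELECT_TOL:
            coefs[name] = float(abs(b))
    return SelectionRound(
        index=round_index,
        seed=seed,
        lambda_cv=lam,
        selected=tuple(n for n in pool if n in coefs),
        coef=coefs,
    )


def aggregate_ranking(rounds: list[SelectionRound], pool: list[str]) -> VariableRanking:
    """Order pool variables by selection count, then coefficient sum, then
    name."""

    times = {v: 0 for v in pool}
    coef_sum = {v: 0.0 for v in pool}
    for r in rounds:
        for v, c in r.coef.items():
            times[v] += 1
            coef_sum[v] += c
    df = pd.DataFrame(
        {
            "variable": pool,
            "times_selected": [times[v] for v in pool],
            "coef_sum": [coef_sum[v] for v in pool],
        }
    )
    df = df.sort_values(
        ["times_selected", "coef_sum", "variable"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return VariableRanking(table=df, n_rounds=len(rounds))


def repeated_selection(
    m: NpxMatrix,
    labels: np.ndarray,
    pool: list[str],
    forced: list[str],
    R: int = 10,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_rule: str = "min",
    lambda_override: float | None = None,
) -> tuple[list[SelectionRound], VariableRanking]:
    """R independent selection rounds plus the aggregated ranking."""

    if R < 1:
        raise ValueError("R must be >= 1")
    seeds = _child_seeds(seed, R)
    rounds = [
        single_selection_round(
            m,
            labels,
            pool,
            forced,
            k=k,
            seed=s,
            n_lambda=n_lambda,
            lambda_rule=lambda_rule,
            round_index=i,
            lambda_override=lambda_override,
        )
        for i, s in enumerate(seeds)
    ]
    return rounds, aggregate_ranking(rounds, pool)


def eliminate_and_iterate(
    m: NpxMatrix,
    labels: np.ndarray,
    initial_pool: list[str],
    forced: list[str],
    R: int = 10,
    k: int = 10,
    seed: int = 0,
    stop_size: int = 2,
    n_lambda: int = 30,
    lambda_rule: str = "min",
) -> EliminationTrace:
    """Backward elimination: drop the lowest-ranked variable per cycle
    until the pool reaches ``stop_size``."""

    if stop_size < 0:
        raise ValueError("stop_size must be >= 0")
    pool = list(initial_pool)
    n_cycles = max(0, len(pool) - stop_size)
    cycle_seeds = _child_seeds(seed, n_cycles) if n_cycles else []
    cycles: list[EliminationCycle] = []
    for c in range(n_cycles):
        _, ranking = repeated_selection(
            m,
            labels,
            pool,
            forced,
            R=R,
            k=k,
            seed=cycle_seeds[c],
            n_lambda=n_lambda,
            lambda_rule=lambda_rule,
        )
        out = ranking.lowest
        cycles.append(EliminationCycle(pool=tuple(pool), ranking=ranking, eliminated=out))
        pool.remove(out)
        logger.info("cycle %d: eliminated %s (pool now %d)", c, out, len(pool))
    return EliminationTrace(
        initial_pool=tuple(initial_pool),
        cycles=tuple(cycles),
        terminal_pool=tuple(pool),
    )


@dataclass
class NestedModelReport:
    """The last few nested panels, each compared to the forced-core
    reference; ``final`` is the highest-AUC row with a significant DeLong
    comparison (None when nothing clears the level)."""

    reference: models.ModelComparison
    rows: list[models.ModelComparison] = field(default_factory=list)
    final: models.ModelComparison | None = None

    def to_frame(self) -> pd.DataFrame:
        return models.comparison_table(self.reference, self.rows)


def build_nested_models(
    m: NpxMatrix,
    labels: np.ndarray,
    trace: EliminationTrace,
    forced: list[str],
    depth: int = 3,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> NestedModelReport:
    """Fit and evaluate the last ``depth`` nested pools from a trace.

    Each model is the forced core plus one pool, fitted by ordinary
    logistic regression on the full contrast and compared to the
    forced-core reference with DeLong's paired test. Rows are reported
    largest pool first, as in the published panel tables.
    """

    pools = trace.nested_pools(depth)
    pools = sorted(pools, key=len, reverse=True)
    rng = np.random.default_rng(seed)
    ref = models.fit_logistic(m, labels, list(forced))
    ref_eval = models.evaluate_model(
        ref, n_boot=n_boot, seed=int(rng.integers(2**31 - 1)), include_youden=True
    )
    ref_row = models.ModelComparison(
        label="+".join(forced),
        evaluation=ref_eval,
        delong=roc.delong_paired_test(ref.prob, ref.prob, ref.labels),
    )
    rows = []
    for pool in pools:
        model = models.fit_logistic(m, labels, list(forced) + list(pool))
        delong = models.compare_to_reference(model, ref)
        ev = models.evaluate_model(
            model, n_boot=n_boot, seed=int(rng.integers(2**31 - 1)), include_youden=True
        )
        rows.append(
            models.ModelComparison(
                label="+".join(pool),
                evaluation=ev,
                delong=delong,
                significant=delong.p < alpha,
            )
        )
    significant = [r for r in rows if r.significant]
    final = max(significant, key=lambda r: r.evaluation.auc.auc) if significant else None
    return NestedModelReport(reference=ref_row, rows=rows, final=final)
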