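"""Synthetic NPX cohorts with the statistical structure the pipeline assumes.

The real plasma cohort behind this pipeline was never deposited; what is
public are group-level summaries: per-protein NPX mean and SD in each
contrast group, the cohort composition by tumor category, and per-category
age mean/range. This module turns exactly those published marginals into a
generative model so every downstream stage can be exercised and calibrated
at desk scale:

* per-protein, per-group Gaussian NPX on the log2 scale (the minimal model
  consistent with a printed mean/SD pair), optionally with an exchangeable
  within-sample correlation ``rho`` induced by a shared latent factor;
* "noise" proteins drawn with identical parameters in both groups, standing
  in for the assayed-but-non-significant remainder of the panels;
* ages drawn from a per-category truncated normal matching the printed
  mean, truncated to the printed range, with SD set to range/4;
* QC-failure flags reproducing the published exclusion bookkeeping
  (180 enrolled, 8 failures — 2 borderline, 6 advanced — 172 analyzed).

The closed-form binormal AUC, ``Phi((mu1-mu0)/sqrt(sd0^2+sd1^2))``, is the
independent oracle every empirical ROC estimate is checked against.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORIES, NpxMatrix

#: Fixture key -> (file name, sha256). The parameter tables are transcribed
#: verbatim from the published per-group summary tables; the checksum guards
#: against accidental edits.
_FIXTURES = {
    "group_params_benign_vs_cancer": (
        "group_params_benign_vs_cancer.tsv",
        "190a87f4e5d9fcf04c04d808d58fbc76db2b97a7afbb1e49467f12543e95c21b",
    ),
    "group_params_benign_vs_borderline_cancer": (
        "group_params_benign_vs_borderline_cancer.tsv",
        "109f2f339485809728c18df979bd8c81e2e2cc8c3d8f607022c78f76406583bf",
    ),
    "univariate_auc_benign_vs_cancer": (
        "univariate_auc_benign_vs_cancer.tsv",
        "af5dba5aae2e0215d676c5ffc31f2fea3d5303c67ef3018522a0cd9a9142fa59",
    ),
    "univariate_auc_benign_vs_borderline_cancer": (
        "univariate_auc_benign_vs_borderline_cancer.tsv",
        "5076cd61b8f74bda5898973e19a0ed00162a8b2ec2ad34d563ce5fb34a25e79a",
    ),
}

#: Enrolled cohort composition by tumor category.
PRE_QC_SIZES = {"benign": 30, "borderline": 28, "eoc_I": 25, "eoc_II_IV": 97}

#: Assay-QC failures by category (8 of 180 samples).
QC_FAIL_COUNTS = {"borderline": 2, "eoc_II_IV": 6}

#: Cohort composition after QC exclusion (172 samples).
POST_QC_SIZES = {"benign": 30, "borderline": 26, "eoc_I": 25, "eoc_II_IV": 91}

#: Per-category age model: (mean, low, high) in years. Only the mean and the
#: range are published, so ages are drawn from a normal with SD = range/4
#: truncated to [low, high].
AGE_MODEL = {
    "benign": (54.0, 24.0, 87.0),
    "borderline": (51.0, 26.0, 84.0),
    "eoc_I": (61.0, 27.0, 87.0),
    "eoc_II_IV": (66.0, 35.0, 88.0),
}

#: Histology counts by category, used as sampling weights.
HISTOLOGY_COUNTS = {
    "benign": {"serous": 13, "mucinous": 6, "endometrioid": 7, "teratoma": 4},
    "borderline": {"serous": 13, "mucinous": 12, "endometrioid": 3},
    "eoc_I": {"serous": 8, "mucinous": 5, "endometrioid": 10, "clear_cell": 2},
    "eoc_II_IV": {"serous": 88, "mucinous": 3, "endometrioid": 5, "clear_cell": 1},
}

#: Total number of assayed proteins across the two panels.
N_PANEL_PROTEINS = 177


class FixtureError(RuntimeError):
    """A packaged fixture is missing or does not match its checksum."""


def _fixture_frame(key: str) -> pd.DataFrame:
    fname, want = _FIXTURES[key]
    ref = resources.files("npxpanel.fixtures").joinpath(fname)
    data = ref.read_bytes()
    got = hashlib.sha256(data).hexdigest()
    if got != want:
        raise FixtureError(f"checksum mismatch for fixture {fname}: {got}")
    from io import BytesIO

    return pd.read_csv(BytesIO(data), sep="\t", dtype={"protein": str})


@dataclass(frozen=True)
class GroupParamTable:
    """Per-protein NPX mean/SD in the two groups of one contrast.

    ``group0`` is the benign (control) side, ``group1`` the case side of the
    contrast named by ``contrast``. ``table`` carries columns ``protein,
    mean0, sd0, mean1, sd1, adj_p, adj_p_bound, adj_p_is_upper, rank``; the
    published adjusted p-values are kept as printed (``"<0.001"`` entries
    become an upper bound with ``adj_p_is_upper=True``).
    """

    contrast: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["protein"].duplicated().any():
            raise ValueError("duplicate protein rows in parameter table")
        if (t[["sd0", "sd1"]] <= 0).any().any():
            raise ValueError("group SDs must be strictly positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def proteins(self) -> list[str]:
        return list(self.table["protein"])

    def row(self, protein: str) -> pd.Series:
        hit = self.table.loc[self.table["protein"] == protein]
        if hit.empty:
            raise KeyError(f"protein {protein!r} not in parameter table")
        return hit.iloc[0]

    def count_significant(self, threshold: float) -> int:
        """Number of proteins with adjusted p strictly below ``threshold``.

        A censored entry printed as ``"<b"`` counts when ``b <= threshold``.
        """

        t = self.table
        upper = t["adj_p_is_upper"].to_numpy(dtype=bool)
        bound = t["adj_p_bound"].to_numpy(dtype=float)
        return int(((upper & (bound <= threshold)) | (~upper & (bound < threshold))).sum())


def load_fixture_params(contrast: str) -> GroupParamTable:
    """Load the packaged per-group NPX parameter table for one contrast.

    ``contrast`` is ``"benign_vs_cancer"`` or
    ``"benign_vs_borderline_cancer"``.
    """

    key = f"group_params_{contrast}"
    if key not in _FIXTURES:
        raise KeyError(f"no parameter fixture for contrast {contrast!r}")
    df = _fixture_frame(key)
    adj = df["adj_p"].astype(str)
    df["adj_p_is_upper"] = adj.str.startswith("<")
    df["adj_p_bound"] = adj.str.lstrip("<").astype(float)
    for c in ("mean0", "sd0", "mean1", "sd1"):
        df[c] = df[c].astype(float)
    df["rank"] = df["rank"].astype(int)
    return GroupParamTable(contrast=contrast, table=df)


def load_fixture_auc(contrast: str) -> pd.DataFrame:
    """Published univariate discrimination AUCs (point and 95% CI) for one
    contrast, already restricted to AUC > 0.7 as printed."""

    key = f"univariate_auc_{contrast}"
    if key not in _FIXTURES:
        raise KeyError(f"no AUC fixture for contrast {contrast!r}")
    df = _fixture_frame(key)
    for c in ("auc", "ci_low", "ci_high"):
        df[c] = df[c].astype(float)
    df["rank"] = df["rank"].astype(int)
    return df


def binormal_auc(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """Closed-form AUC of a two-group Gaussian marker.

    Under ``X0 ~ N(mu0, sd0^2)`` and ``X1 ~ N(mu1, sd1^2)``,
    ``P(X1 > X0) = Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2))``. Values above
    0.5 mean the case group scores higher.
    """

    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("group SDs must be strictly positive")
    return float(stats.norm.cdf((mu1 - mu0) / math.hypot(sd0, sd1)))


@dataclass
class CohortConfig:
    """Knobs of the cohort generator.

    ``group_sizes`` defaults to the enrolled composition (30/28/25/97) with
    QC failures flagged per ``qc_fail``, so that QC filtering reproduces the
    published 172-sample analysis set. ``rho`` is an exchangeable
    within-sample correlation among proteins, induced by a single shared
    latent factor; the published tables carry no covariance information, so
    one knob is all the generator offers. ``n_noise_proteins=None`` pads the
    panel to 177 proteins with null markers.
    """

    group_sizes: dict = field(default_factory=lambda: dict(PRE_QC_SIZES))
    qc_fail: dict = field(default_factory=lambda: dict(QC_FAIL_COUNTS))
    missing_age: dict = field(default_factory=lambda: {"benign": 1})
    n_noise_proteins: int | None = None
    rho: float = 0.0
    seed: int = 0
    noise_mean: float = 5.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 0.9:
            raise ValueError("rho must be in [0, 0.9]")
        for cat, n in self.group_sizes.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if n < 0:
                raise ValueError("group sizes must be nonnegative")
        for cat, n in self.qc_fail.items():
            if n > self.group_sizes.get(cat, 0):
                raise ValueError(f"more QC failures than samples in {cat!r}")


def _case_categories(contrast: str) -> set[str]:
    if contrast == "benign_vs_cancer":
        return {"eoc_I", "eoc_II_IV"}
    if contrast == "benign_vs_borderline_cancer":
        return {"borderline", "eoc_I", "eoc_II_IV"}
    raise ValueError(f"unknown contrast parameterization {contrast!r}")


def _truncnorm_ages(cat: str, n: int, rng: np.random.Generator) -> np.ndarray:
    mean, lo, hi = AGE_MODEL[cat]
    sd = (hi - lo) / 4.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(params: GroupParamTable, cfg: CohortConfig) -> NpxMatrix:
    """Draw a synthetic cohort whose marginals match ``params``.

    Each sample's NPX for protein ``p`` is Gaussian with the mean/SD of the
    sample's group under the contrast parameterization carried by
    ``params``; for the benign-vs-cancer parameterization, borderline
    samples (excluded from that contrast) are drawn with the benign-side
    parameters. Deterministic under a fixed ``cfg.seed``.
    """

    rng = np.random.default_rng(cfg.seed)
    case_cats = _case_categories(params.contrast)

    cats: list[str] = []
    for cat in CATEGORIES:
        cats.extend([cat] * cfg.group_sizes.get(cat, 0))
    n = len(cats)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    meta["category"] = cats

    hist = []
    for cat in CATEGORIES:
        k = cfg.group_sizes.get(cat, 0)
        if k == 0:
            continue
        names = list(HISTOLOGY_COUNTS[cat])
        w = np.array([HISTOLOGY_COUNTS[cat][h] for h in names], dtype=float)
        hist.extend(rng.choice(names, size=k, p=w / w.sum()))
    meta["histology"] = hist

    age = np.concatenate(
        [
            _truncnorm_ages(cat, cfg.group_sizes.get(cat, 0), rng)
            for cat in CATEGORIES
            if cfg.group_sizes.get(cat, 0)
        ]
    )
    meta["age"] = age
    cat_arr = meta["category"].to_numpy()
    for cat, k in cfg.missing_age.items():
        idx = np.flatnonzero(cat_arr == cat)[:k]
        meta.iloc[idx, meta.columns.get_loc("age")] = np.nan

    qc = np.ones(n, dtype=bool)
    for cat, k in cfg.qc_fail.items():
        idx = np.flatnonzero(cat_arr == cat)[-k:] if k else []
        qc[idx] = False
    meta["qc_pass"] = qc

    n_noise = cfg.n_noise_proteins
    if n_noise is None:
        n_noise = max(0, N_PANEL_PROTEINS - len(params))
    names = params.proteins + [f"NOISE_{i + 1:03d}" for i in range(n_noise)]
    p = len(names)

    is_case = np.isin(cat_arr, sorted(case_cats))
    mu = np.empty((n, p))
    sd = np.empty((n, p))
    t = params.table
    mu[:, : len(t)] = np.where(
        is_case[:, None], t["mean1"].to_numpy()[None, :], t["mean0"].to_numpy()[None, :]
    )
    sd[:, : len(t)] = np.where(
        is_case[:, None], t["sd1"].to_numpy()[None, :], t["sd0"].to_numpy()[None, :]
    )
    mu[:, len(t):] = cfg.noise_mean
    sd[:, len(t):] = cfg.noise_sd

    eps = rng.standard_normal((n, p))
    if cfg.rho > 0:
        z = rng.standard_normal(n)
        eps = math.sqrt(cfg.rho) * z[:, None] + math.sqrt(1.0 - cfg.rho) * eps
    values = pd.DataFrame(mu + sd * eps, index=meta.index, columns=names)
    return NpxMatrix(meta, values)


def simulate_two_group(
    mean0: float,
    sd0: float,
    mean1: float,
    sd1: float,
    n0: int,
    n1: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one marker for ``n0`` controls and ``n1`` cases.

    Returns ``(scores, labels)`` with controls first. This is the light
    harness used to re-derive published univariate AUCs from the printed
    group means and SDs.
    """

    scores = np.concatenate(
        [rng.normal(mean0, sd0, size=n0), rng.normal(mean1, sd1, size=n1)]
    )
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return scores, labels


def simulate_planted_cohort(
    n_control: int = 30,
    n_case: int = 142,
    n_planted: int = 3,
    effect: float = 1.0,
    n_noise: int = 17,
    seed: int = 0,
    include_core: bool = True,
    core_informative: bool = True,
) -> NpxMatrix:
    """Two-group cohort with planted standardized effects, for calibration.

    Controls are ``benign``, cases ``eoc_II_IV``. When ``include_core`` is
    set, HE4 (``WFDC2``) and CA125 (``MUC-16``) columns are present so the
    forced-core machinery can run; with ``core_informative`` they are drawn
    from the benign-vs-cancer parameter fixture (a realistic reference
    model, for incremental-value experiments), otherwise they are null
    markers (support-recovery experiments, where the only marker signal is
    the planted one). ``n_planted`` markers named ``SIG_##`` are standard
    normal in controls and shifted by ``effect`` SDs in cases; ``n_noise``
    markers named ``NOISE_##`` are standard normal in both groups.
    """

    rng = np.random.default_rng(seed)
    n = n_control + n_case
    ids = [f"S{i + 1:04d}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    meta["category"] = ["benign"] * n_control + ["eoc_II_IV"] * n_case
    meta["histology"] = "other"
    meta["age"] = np.concatenate(
        [_truncnorm_ages("benign", n_control, rng), _truncnorm_ages("eoc_II_IV", n_case, rng)]
    )
    meta["qc_pass"] = True

    is_case = np.array([0] * n_control + [1] * n_case, dtype=float)
    cols: dict[str, np.ndarray] = {}
    if include_core:
        core = load_fixture_params("benign_vs_cancer")
        for name in ("WFDC2", "MUC-16"):
            r = core.row(name)
            if core_informative:
                mu = np.where(is_case > 0, r["mean1"], r["mean0"])
                s = np.where(is_case > 0, r["sd1"], r["sd0"])
            else:
                mu, s = r["mean0"], r["sd0"]
            cols[name] = rng.normal(mu, s)
    for i in range(n_planted):
        cols[f"SIG_{i + 1:02d}"] = rng.standard_normal(n) + effect * is_case
    for i in range(n_noise):
        cols[f"NOISE_{i + 1:02d}"] = rng.standard_normal(n)
    values = pd.DataFrame(cols, index=meta.index)
    return NpxMatrix(meta, values)
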