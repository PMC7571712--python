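"""Cohort container, I/O, QC filtering and case/control contrast construction.

The single substrate of every analysis stage is the :class:`NpxMatrix`: a
samples x proteins table of NPX values (Olink's Normalized Protein
eXpression, an arbitrary unit on a log2 scale, relative within each protein
and not comparable across proteins) together with per-sample clinical
metadata (tumor category, histology, age, QC-pass flag).

Cohort files are plain wide-format CSV/TSV: one row per sample, a declared
set of metadata columns, and every remaining column interpreted as a
protein. Metadata column names are configurable because vendor exports
vary; silent misparsing of a protein named e.g. ``AGE`` would be worse than
asking the caller to declare the mapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tumor categories, in clinical severity order. ``eoc_I`` is early-stage
#: (FIGO I) epithelial ovarian cancer, ``eoc_II_IV`` advanced (FIGO II-IV).
CATEGORIES = ("benign", "borderline", "eoc_I", "eoc_II_IV")

HISTOLOGIES = ("serous", "mucinous", "endometrioid", "clear_cell", "teratoma", "other")

_TRUTHY = {"1", "true", "yes", "pass", "t", "y"}
_FALSY = {"0", "false", "no", "fail", "f", "n"}


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one plasma sample.

    ``age`` is in years; ``math.nan`` encodes a missing age (allowed:
    downstream models apply listwise deletion per model rather than
    imputing). ``qc_pass`` marks whether the sample passed the assay's
    internal quality control.
    """

    sample_id: str
    category: str
    histology: str = "other"
    age: float = math.nan
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown tumor category {self.category!r} for sample "
                f"{self.sample_id!r}; expected one of {CATEGORIES}"
            )
        if not math.isnan(self.age) and self.age < 0:
            raise ValueError(f"negative age for sample {self.sample_id!r}")


@dataclass(frozen=True)
class MetaColumns:
    """Declared names of the metadata columns in a cohort file.

    Every column not named here is treated as a protein.
    """

    sample_id: str = "sample_id"
    category: str = "category"
    histology: str = "histology"
    age: str = "age"
    qc_pass: str = "qc_pass"

    def names(self) -> tuple[str, ...]:
        return (self.sample_id, self.category, self.histology, self.age, self.qc_pass)


class NpxMatrix:
    """Samples x proteins NPX table plus per-sample metadata.

    Parameters
    ----------
    meta
        DataFrame indexed by sample id with columns ``category``,
        ``histology``, ``age`` and ``qc_pass``.
    values
        DataFrame of NPX values with the same index as ``meta`` and one
        column per protein.
    """

    def __init__(self, meta: pd.DataFrame, values: pd.DataFrame):
        meta = meta.copy()
        values = values.copy()
        if meta.index.has_duplicates:
            dups = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not meta.index.equals(values.index):
            raise ValueError("metadata and NPX tables index different samples")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein names: {dups}")
        bad_cat = set(meta["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown tumor categories: {sorted(bad_cat)}")
        vals = values.to_numpy(dtype=float)
        qc = meta["qc_pass"].to_numpy(dtype=bool)
        bad = ~np.isfinite(vals[qc])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            sid = meta.index[np.flatnonzero(qc)[i]]
            raise ValueError(
                f"non-finite NPX for QC-passing sample {sid!r}, "
                f"protein {values.columns[j]!r}"
            )
        self.meta = meta
        self.values = values.astype(float)

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def samples(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                sample_id=str(sid),
                category=row["category"],
                histology=row["histology"],
                age=float(row["age"]) if pd.notna(row["age"]) else math.nan,
                qc_pass=bool(row["qc_pass"]),
            )
            for sid, row in self.meta.iterrows()
        ]

    def subset(self, sample_ids: Sequence[str]) -> "NpxMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.meta.index)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return NpxMatrix(self.meta.loc[ids], self.values.loc[ids])

    def category_counts(self) -> dict[str, int]:
        counts = self.meta["category"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES if counts.get(c, 0)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NpxMatrix({self.n_samples} samples x {self.n_proteins} proteins)"


@dataclass(frozen=True)
class ContrastSpec:
    """A binary case/control labeling of tumor categories.

    ``positive`` categories are coded 1 (the cancer side), ``negative``
    categories 0 (the benign side); samples in neither set are dropped from
    the contrast entirely.
    """

    name: str
    positive: frozenset = field(default_factory=frozenset)
    negative: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pos, neg = frozenset(self.positive), frozenset(self.negative)
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)
        if not pos or not neg:
            raise ValueError("both sides of a contrast must be non-empty")
        if pos & neg:
            raise ValueError(f"overlapping categories: {sorted(pos & neg)}")
        bad = (pos | neg) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories in contrast: {sorted(bad)}")


#: Benign tumors (controls) vs invasive cancer (cases); borderline excluded.
BENIGN_VS_CANCER = ContrastSpec(
    "benign_vs_cancer",
    positive=frozenset({"eoc_I", "eoc_II_IV"}),
    negative=frozenset({"benign"}),
)

#: Benign tumors (controls) vs borderline tumors plus invasive cancer.
BENIGN_VS_BORDERLINE_CANCER = ContrastSpec(
    "benign_vs_borderline_cancer",
    positive=frozenset({"borderline", "eoc_I", "eoc_II_IV"}),
    negative=frozenset({"benign"}),
)

CONTRASTS = {c.name: c for c in (BENIGN_VS_CANCER, BENIGN_VS_BORDERLINE_CANCER)}


def _parse_float_or_nan(text: str) -> float:
    try:
        return float(text)
    except ValueError:
        return math.nan


def _parse_bool(x: object, column: str, sid: str) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse {column}={x!r} for sample {sid!r} as boolean")


def read_cohort(
    path,
    *,
    delimiter: str | None = None,
    columns: MetaColumns = MetaColumns(),
) -> NpxMatrix:
    """Read and validate a wide-format cohort table.

    The delimiter defaults to tab for ``.tsv`` files and comma otherwise.
    Unparseable or empty age cells are recorded as missing; a non-numeric
    NPX value in a QC-passing row is a hard error naming the offending
    row and column.
    """

    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in (columns.sample_id, columns.category, columns.qc_pass) if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")

    sid = raw[columns.sample_id].astype(str)
    if sid.duplicated().any():
        dups = sid[sid.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")

    meta = pd.DataFrame(index=pd.Index(sid, name="sample_id"))
    meta["category"] = raw[columns.category].to_numpy()
    if columns.histology in raw.columns:
        hist = raw[columns.histology].replace("", "other")
        meta["histology"] = hist.to_numpy()
    else:
        meta["histology"] = "other"
    if columns.age in raw.columns:
        meta["age"] = [_parse_float_or_nan(v) for v in raw[columns.age]]
    else:
        meta["age"] = math.nan
    meta["qc_pass"] = [
        _parse_bool(v, columns.qc_pass, s) for v, s in zip(raw[columns.qc_pass], sid)
    ]

    protein_cols = [c for c in raw.columns if c not in set(columns.names())]
    qc = meta["qc_pass"].to_numpy()
    data = {}
    for col in protein_cols:
        parsed = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            text = cell.strip()
            if not text:
                if qc[i]:
                    raise ValueError(
                        f"missing NPX value for QC-passing sample "
                        f"{sid.iloc[i]!r}, column {col!r}"
                    )
                parsed[i] = np.nan
                continue
            try:
                # float() round-trips shortest-repr values exactly, which
                # pandas' fast CSV float parser does not guarantee
                parsed[i] = float(text)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric NPX value {cell!r} in row {sid.iloc[i]!r}, "
                    f"column {col!r}"
                ) from exc
        data[col] = parsed
    values = pd.DataFrame(data, index=meta.index)
    return NpxMatrix(meta, values)


def write_cohort(m: NpxMatrix, path, *, delimiter: str | None = None) -> None:
    """Write a cohort in the same wide format :func:`read_cohort` accepts.

    Floats are written with Python's shortest round-tripping repr, so a
    read/write cycle reproduces finite values bit-identically.
    """

    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = m.meta.reset_index()
    out = pd.concat([out, m.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=delimiter, index=False)


def qc_actions(m: NpxMatrix) -> list[dict]:
    """One JSON-serializable record per QC-excluded sample."""

    failed = m.meta.loc[~m.meta["qc_pass"]]
    return [
        {"action": "exclude", "sample_id": str(sid), "category": row["category"], "reason": "qc_fail"}
        for sid, row in failed.iterrows()
    ]


def apply_qc(m: NpxMatrix) -> NpxMatrix:
    """Drop samples that failed the assay's internal quality control.

    NPX values of retained samples are untouched. Zero exclusions is fine;
    an empty result is allowed but logged as a warning.
    """

    keep = m.meta["qc_pass"].to_numpy(dtype=bool)
    n_out = int((~keep).sum())
    excluded = m.meta.loc[~keep, "category"].value_counts().to_dict()
    result = NpxMatrix(m.meta.loc[keep], m.values.loc[keep])
    if n_out:
        logger.info("QC excluded %d samples: %s", n_out, excluded)
    if result.n_samples == 0:
        logger.warning("all %d samples failed QC; cohort is empty", m.n_samples)
    return result


def make_contrast(m: NpxMatrix, spec: ContrastSpec) -> tuple[NpxMatrix, np.ndarray]:
    """Subset a cohort to one binary contrast.

    Returns the samples whose category is on either side of ``spec`` (in
    the original sample order) and an int array of labels, 1 for the
    positive (case) side and 0 for the negative (control) side.
    """

    cat = m.meta["category"]
    mask = cat.isin(spec.positive | spec.negative).to_numpy()
    sub = NpxMatrix(m.meta.loc[mask], m.values.loc[mask])
    labels = sub.meta["category"].isin(spec.positive).to_numpy().astype(int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"contrast {spec.name!r} has an empty class "
            f"(cases={n_pos}, controls={n_neg})"
        )
    logger.info("contrast %s: %d cases, %d controls", spec.name, n_pos, n_neg)
    return sub, labels
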