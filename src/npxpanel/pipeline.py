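"""End-to-end orchestration: QC -> contrasts -> tables, reproducibly.

A run is described by a declarative config (YAML on disk, plain dict in
memory) and one master seed. Stage seeds are derived deterministically from
the master seed and the stage name, so any stage can be re-run in isolation
and the full pipeline is byte-identical under a fixed seed. Every output
table carries the run's manifest hash — a digest of the config, seed and
package version — in a header comment, and the manifest records a checksum
of every file written.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, diffexp, models, roc, selection, synthetic
from .cohort import CONTRASTS, NpxMatrix, apply_qc, make_contrast, qc_actions, read_cohort, write_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "cohort": None,  # path to a cohort CSV/TSV, or null to simulate
    "simulate": {
        "parameterization": "benign_vs_cancer",
        "n_noise_proteins": None,  # null pads panel to 177 proteins
        "rho": 0.0,
        "pre_qc": True,  # enrolled composition with QC failures flagged
    },
    "contrasts": ["benign_vs_cancer", "benign_vs_borderline_cancer"],
    "report_threshold": 0.05,  # adjusted-p cut for the expression table
    "strict_threshold": 0.001,  # the conservative significance call
    "auc_threshold": 0.7,  # univariate AUC cut feeding the add-one scan
    "target_spec": 0.95,
    "target_sens": 0.95,
    "n_boot": 2000,
    "addone": {"enabled": True},
    "selection": {
        "enabled": True,
        "R": 10,
        "k": 10,
        "n_lambda": 30,
        "lambda_rule": "min",
        "stop_size": 2,
        "depth": 3,
        "pool": None,  # null = all proteins minus the forced core
    },
    "seed": 0,
}


class ConfigError(ValueError):
    pass


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(base[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by a YAML file, overlaid by explicit overrides."""

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""

    import numpy as np

    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def manifest_hash(config: dict) -> str:
    payload = json.dumps(
        {"config": config, "version": __version__}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, mhash: str, note: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# npxpanel manifest {mhash}\n")
        if note:
            fh.write(f"# {note}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _obtain_cohort(config: dict) -> NpxMatrix:
    if config["cohort"]:
        return read_cohort(config["cohort"])
    sim = config["simulate"]
    if sim is None:
        raise ConfigError("config must provide either a cohort path or a simulation spec")
    params = synthetic.load_fixture_params(sim["parameterization"])
    sizes = synthetic.PRE_QC_SIZES if sim.get("pre_qc", True) else synthetic.POST_QC_SIZES
    qc_fail = synthetic.QC_FAIL_COUNTS if sim.get("pre_qc", True) else {}
    cfg = synthetic.CohortConfig(
        group_sizes=dict(sizes),
        qc_fail=dict(qc_fail),
        n_noise_proteins=sim.get("n_noise_proteins"),
        rho=sim.get("rho", 0.0),
        seed=stage_seed(config["seed"], "simulate"),
    )
    return synthetic.simulate_cohort(params, cfg)


def run_pipeline(config: dict, out_dir, include_timestamps: bool = False) -> dict:
    """Execute the full analysis and write the report bundle.

    Stages: cohort acquisition (file or simulation), QC exclusion, then per
    contrast: differential expression, univariate ROC ranking, the add-one
    scan against the HE4+CA125+age reference, and the stability-selection /
    nested-model report. Returns the manifest dict (also written as
    ``manifest.json``).
    """

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mhash = manifest_hash(config)
    files: dict[str, str] = {}

    cohort = _obtain_cohort(config)
    write_cohort(cohort, out / "cohort.csv")
    files["cohort.csv"] = _sha256(out / "cohort.csv")

    actions = qc_actions(cohort)
    with open(out / "qc_log.jsonl", "w") as fh:
        for rec in actions:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    files["qc_log.jsonl"] = _sha256(out / "qc_log.jsonl")
    clean = apply_qc(cohort)
    logger.info(
        "cohort: %d samples pre-QC, %d post-QC, %d proteins",
        cohort.n_samples,
        clean.n_samples,
        clean.n_proteins,
    )

    sel_cfg = config["selection"]
    for cname in config["contrasts"]:
        try:
            contrast = CONTRASTS[cname]
        except KeyError as exc:
            raise ConfigError(f"unknown contrast {cname!r}") from exc
        try:
            _run_contrast(config, clean, contrast, out, mhash, files, sel_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage failed for contrast {cname!r}: {exc}") from exc

    manifest = {
        "config": config,
        "seed": config["seed"],
        "package_version": __version__,
        "manifest_hash": mhash,
        "files": files,
        "timestamp": datetime.now(timezone.utc).isoformat() if include_timestamps else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_contrast(config, clean, contrast, out, mhash, files, sel_cfg):
    cname = contrast.name
    n_boot = config["n_boot"]

    expr = diffexp.summarize_expression(clean, contrast, config["report_threshold"])
    path = out / f"diffexp_{cname}.tsv"
    _write_table(
        diffexp.format_expression_table(expr),
        path,
        mhash,
        note=f"differential NPX expression, adjusted p < {config['report_threshold']}",
    )
    files[path.name] = _sha256(path)

    auc_table = roc.rank_univariate_auc(
        clean,
        contrast,
        auc_threshold=config["auc_threshold"],
        n_boot=n_boot,
        seed=stage_seed(config["seed"], f"roc:{cname}"),
    )
    path = out / f"univariate_auc_{cname}.tsv"
    _write_table(auc_table, path, mhash, note=f"univariate AUC > {config['auc_threshold']}")
    files[path.name] = _sha256(path)

    sub, labels = make_contrast(clean, contrast)

    if config["addone"]["enabled"]:
        candidates = [
            p for p in auc_table["protein"] if p not in (models.HE4, models.CA125)
        ]
        ref_row, rows = models.add_one_scan(
            sub,
            labels,
            candidates,
            n_boot=n_boot,
            seed=stage_seed(config["seed"], f"addone:{cname}"),
        )
        path = out / f"addone_{cname}.tsv"
        _write_table(
            models.comparison_table(ref_row, rows, label_header="added_marker"),
            path,
            mhash,
            note="reference model HE4+CA125+age plus one marker",
        )
        files[path.name] = _sha256(path)

    if sel_cfg["enabled"]:
        pool = sel_cfg["pool"]
        if pool is None:
            pool = [p for p in sub.proteins if p not in (models.HE4, models.CA125)]
        trace = selection.eliminate_and_iterate(
            sub,
            labels,
            initial_pool=list(pool),
            forced=list(models.CORE_PREDICTORS),
            R=sel_cfg["R"],
            k=sel_cfg["k"],
            seed=stage_seed(config["seed"], f"select:{cname}"),
            stop_size=sel_cfg["stop_size"],
            n_lambda=sel_cfg["n_lambda"],
            lambda_rule=sel_cfg["lambda_rule"],
        )
        path = out / f"selection_trace_{cname}.json"
        with open(path, "w") as fh:
            json.dump(trace.to_json_dict(), fh, indent=2, sort_keys=True)
        files[path.name] = _sha256(path)

        report = selection.build_nested_models(
            sub,
            labels,
            trace,
            forced=list(models.CORE_PREDICTORS),
            depth=sel_cfg["depth"],
            n_boot=n_boot,
            seed=stage_seed(config["seed"], f"nested:{cname}"),
        )
        path = out / f"nested_models_{cname}.tsv"
        _write_table(
            report.to_frame(),
            path,
            mhash,
            note="nested panels from lasso stability selection vs reference model",
        )
        files[path.name] = _sha256(path)
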