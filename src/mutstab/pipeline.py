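"""Config-driven end-to-end runs: curate -> featurize -> (augment) ->
split -> train -> evaluate -> (rfe)."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from .augment import AUGMENT_MODES
from .datasets import build_dataset
from .metrics import baseline_single_feature
from .model import ALGORITHMS, SplitScheme, StabilityModel
from .records import CurationConfig, curate, read_mutation_table
from . import synth

log = logging.getLogger("mutstab")

_REQUIRED = ("target", "task", "algorithms", "seed")


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> dict:
    for key in _REQUIRED:
        if key not in cfg:
            raise ConfigError(f"missing required config field: {key}")
    if cfg["target"] not in ("ddg", "dtm"):
        raise ConfigError("target: must be 'ddg' or 'dtm'")
    if cfg["task"] not in ("binary", "ternary", "regression"):
        raise ConfigError("task: must be binary, ternary or regression")
    algos = cfg["algorithms"]
    if isinstance(algos, str):
        algos = [algos]
    for a in algos:
        if a not in ALGORITHMS:
            raise ConfigError(f"algorithms: unknown algorithm {a!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed: an integer seed is mandatory")
    augment = cfg.get("augment", "none")
    if augment not in AUGMENT_MODES:
        raise ConfigError(f"augment: must be one of {AUGMENT_MODES}")
    split_kind = cfg.get("split", {}).get("kind", "random_row")
    if split_kind not in ("random_row", "by_protein"):
        raise ConfigError("split.kind: must be random_row or by_protein")
    if "dataset" not in cfg and "synth" not in cfg:
        raise ConfigError("config needs either dataset: <csv path> or synth: {...}")
    out = dict(cfg)
    out["algorithms"] = list(algos)
    out["augment"] = augment
    return out


def _dataset_from_config(cfg: dict):
    curation = CurationConfig(**cfg.get("curation", {}))
    target, task = cfg["target"], cfg["task"]
    if "dataset" in cfg:
        records = read_mutation_table(
            cfg["dataset"], column_map=cfg.get("columns"), sep=cfg.get("sep")
        )
        n_raw = len(records)
        records = curate(records, curation, target=target)
        log.info("curated %d of %d records", len(records), n_raw)
    else:
        spec = dict(cfg["synth"])
        if spec.pop("benchmark", False):
            records = synth.synthetic_benchmark(target, seed=cfg["seed"])
        else:
            spec.setdefault("seed", cfg["seed"])
            spec.setdefault("target_name", target)
            records = synth.generate(**spec)
        records = curate(records, curation, target=target)
    return build_dataset(records, curation, target=target, task=task)


def run_pipeline(config_path, out_dir=None) -> dict:
    """Run the full pipeline described by a YAML/JSON config file.

    Writes one JSON report per algorithm (plus a summary) when
    ``out_dir`` is given, and returns {algorithm: EvalReport}.
    """
    cfg = validate_config(load_config(config_path))
    seed = cfg["seed"]
    ds = _dataset_from_config(cfg)
    log.info(
        "dataset: %d rows, %d proteins, classes %s",
        len(ds),
        ds.n_proteins,
        ds.class_counts(),
    )
    scheme = SplitScheme(
        kind=cfg.get("split", {}).get("kind", "random_row"),
        train_fraction=cfg.get("split", {}).get("train_fraction", 0.8),
        seed=seed,
    )
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    reports = {}
    for algorithm in cfg["algorithms"]:
        res = StabilityModel(
            ds,
            algorithm,
            cv_folds=cfg.get("cv_folds", 10),
            seed=seed,
            split_scheme=scheme,
            augment=cfg["augment"],
        ).fit()
        report = res.report
        if cfg.get("rfe", False):
            report.rfe_ranks = res.rfe_ranks()
        if cfg.get("baseline_feature"):
            report_extra = baseline_single_feature(
                ds, cfg["baseline_feature"], seed=seed
            )
            log.info("single-feature baseline R^2 = %.3f", report_extra)
        reports[algorithm] = report
        log.info("%s: %s", algorithm, json.dumps(report.to_dict(), default=str))
        if out_dir:
            report.to_json(out_dir / f"report_{algorithm}.json")
            (out_dir / f"summary_{algorithm}.txt").write_text(res.summary() + "\n")
            res.fitted.save(out_dir / f"model_{algorithm}.pkl")
            if cfg["task"] == "binary":
                from .metrics import roc_points
                from .model import predict as _predict

                preds = _predict(res.fitted, res.test_ds)
                roc_points(preds.scores, res.test_ds.labels).to_csv(
                    out_dir / f"roc_{algorithm}.csv", index=False
                )
    return reports
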