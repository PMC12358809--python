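"""End-to-end experiment driver: config, seeds, manifest, results directory.

A single experiment reproduces the study design on synthetic data: generate
a multi-site cohort, preprocess volumes, label trajectories, match the
diagnostic groups per scanner, draw k repeated nested splits, pretrain a
brain-age model on a separate healthy cohort, run the configured
approaches, and summarize with corrected resampled t-tests and FDR flags.

One global seed expands deterministically into per-stage seeds via
``numpy.random.SeedSequence`` so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .approaches import (
    AD_APPROACHES,
    MCI_APPROACHES,
    ApproachConfigs,
    RidgeConfig,
    TaskData,
    run_ad_approach,
    run_learning_curve,
    run_mci_approach,
)
from .cohort_prep import TrajectoryLabel, label_trajectory, make_splits, match_groups
from .errors import ConfigurationError
from .preprocess import CropWindow, crop_volume, normalize_intensity
from .sfcn import (
    DESK_FILTERS,
    HEAD_REGRESSION,
    SFCNConfig,
    TrainConfig,
    pretrain_brainage,
)
from .synthetic_data import GeneratorConfig, generate_cohort, phenotype_table

log = logging.getLogger(__name__)

# Desk-scale demo defaults.  Reference-scale training hyperparameters (lr 0.1,
# 150 epochs, batch 6, finetune lr 0.01) are the TrainConfig defaults; the
# desk presets below are CPU-feasible while exercising the same code paths.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "k": 5,
    "generator": {},
    "pretrain_generator": {
        # healthy out-of-sample cohort for brain-age pretraining
        "n_per_group": {"CN": 64, "AD": 0, "sMCI": 0, "pMCI": 0},
        "datasets": [["PRE", ["pre1", "pre2"]]],
    },
    "model": {"filters": list(DESK_FILTERS), "input_shape": [32, 40, 32],
              "dropout_rate": 0.25},
    "train": {"initial_lr": 0.1, "epochs": 20, "batch_size": 8},
    "finetune": {"initial_lr": 0.1, "epochs": 20, "batch_size": 8,
                 "update_bn_stats": False},
    "pretrain": {"initial_lr": 0.03, "epochs": 30, "batch_size": 8,
                 "lr_decay_every": 20},
    "crop": None,
    "tasks": {"AD_CN": list(AD_APPROACHES), "MCI_PROG": []},
    "dev_sizes": {},
    "fdr_q": 0.05,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    return _merge(DEFAULT_CONFIG, raw)


def validate_config(config: dict | str | Path) -> list[str]:
    """Schema check; returns a list of warning strings (empty = clean).

    Raises ConfigurationError for hard errors (missing/invalid fields)."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    report: list[str] = []
    if "seed" not in config or config["seed"] is None:
        raise ConfigurationError("missing required field: seed")
    if not isinstance(config["seed"], int):
        raise ConfigurationError(f"seed: must be an integer, got {config['seed']!r}")
    k = config.get("k", 0)
    if not isinstance(k, int) or k < 1:
        raise ConfigurationError(f"k: must be a positive integer, got {k!r}")
    if k < 2:
        report.append("k < 2: corrected resampled t-test comparisons are disabled")
    GeneratorConfig(**config.get("generator", {}), seed=config["seed"])  # field validation
    SFCNConfig(**config["model"])
    for block in ("train", "finetune", "pretrain"):
        TrainConfig(**config.get(block, {}))
    for task, names in config.get("tasks", {}).items():
        valid = AD_APPROACHES if task == "AD_CN" else MCI_APPROACHES
        for n in names:
            if n not in valid:
                raise ConfigurationError(f"tasks.{task}: unknown approach {n!r}")
    gen = config.get("generator", {})
    n_min = min(gen.get("n_per_group", {"CN": 20}).values() or [20])
    if n_min < 5:
        report.append("a group has fewer than 5 subjects per scanner; "
                      "80:20 split rounding will be coarse")
    return report


def _stage_seed(seed: int, stage: str) -> int:
    h = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
    return int(np.random.SeedSequence([seed, h]).generate_state(1)[0] % (2**31))


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _preprocess_volumes(volumes, crop_cfg) -> dict[str, np.ndarray]:
    window = CropWindow(tuple(tuple(b) for b in crop_cfg)) if crop_cfg else None
    out = {}
    for sid, vol in volumes.items():
        v = crop_volume(vol, window) if window else vol
        out[sid] = normalize_intensity(v)
    return out


def build_task_data(records, volumes, matched) -> TaskData:
    labels = matched.labels()
    recs = {r.subject_id: r for r in records}
    ids = list(labels)
    return TaskData(volumes={i: volumes[i] for i in ids},
                    labels=labels,
                    ages={i: recs[i].age for i in ids})


def run_experiment(config: dict | str | Path, out_dir) -> Path:
    """Drive the full synthetic-data experiment; returns the results dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    t0 = time.time()

    # --- cohort ----------------------------------------------------------
    gen_cfg = GeneratorConfig(**config["generator"], seed=_stage_seed(seed, "cohort"))
    records, volumes = generate_cohort(gen_cfg)
    phenotype_table(records).to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    x = _preprocess_volumes(volumes, config["crop"])
    log.info("cohort: %d subjects (%.1fs)", len(records), time.time() - t0)

    # --- trajectory labels ------------------------------------------------
    traj = {r.subject_id: label_trajectory(r.visits).value for r in records}

    # --- pretrained brain-age model --------------------------------------
    model_cfg = SFCNConfig(**config["model"])
    pretrained = None
    needs_pretrain = any(n != "direct" for n in config["tasks"].get("AD_CN", [])) or \
        "brainage64d_finetune_ad2prog" in config["tasks"].get("MCI_PROG", [])
    if needs_pretrain:
        pre_gen = GeneratorConfig(**_merge(config["generator"],
                                           config["pretrain_generator"]),
                                  seed=_stage_seed(seed, "pretrain-cohort"))
        pre_records, pre_vols = generate_cohort(pre_gen)
        pre_records = [r for r in pre_records if r.group == "CN"]
        pre_x = _preprocess_volumes(pre_vols, config["crop"])
        reg_cfg = dataclasses.replace(model_cfg, head=HEAD_REGRESSION)
        pretrained, _ = pretrain_brainage(
            reg_cfg, pre_records, pre_x,
            TrainConfig(**config["pretrain"], seed=_stage_seed(seed, "pretrain")))
        log.info("pretraining done (%.1fs)", time.time() - t0)

    all_results = []
    manifest_tasks = {}
    for task, names in config["tasks"].items():
        if not names:
            continue
        if task == "AD_CN":
            matched = match_groups(records, "CN", "AD", task=task)
        else:
            matched = match_groups(
                [r for r in records if traj[r.subject_id] in ("sMCI", "pMCI")],
                "sMCI", "pMCI",
                labels={i: v for i, v in traj.items()}, task=task)
        plan = make_splits(matched, k=config["k"], seed=_stage_seed(seed, f"split-{task}"))
        data = build_task_data(records, x, matched)
        cfgs = ApproachConfigs(
            model=model_cfg,
            train=TrainConfig(**config["train"], seed=0),
            finetune=TrainConfig(**config["finetune"], seed=0),
            ridge=RidgeConfig(),
            pretrained=pretrained,
            seed=_stage_seed(seed, f"approaches-{task}"))
        ad_models: dict = {}
        if task == "AD_CN":
            for name in names:
                res = run_ad_approach(name, data, plan, cfgs,
                                      return_models=name in ("direct", "brainage64d_finetune"))
                if isinstance(res, tuple):
                    res, models = res
                    ad_models[name] = models
                all_results.extend(res)
                log.info("%s/%s done (%.1fs)", task, name, time.time() - t0)
            manifest_tasks[task] = {"n_matched_pairs": len(matched.pairs),
                                    "n_dev": plan.n_dev, "n_test": plan.n_test}
            config.setdefault("_ad_models", ad_models)  # reused by MCI task below
        else:
            prior = config.get("_ad_models", {})
            for name in names:
                source = {"direct_ad2prog": "direct",
                          "brainage64d_finetune_ad2prog": "brainage64d_finetune"}.get(name)
                models = prior.get(source) if source else None
                all_results.extend(
                    run_mci_approach(name, data, plan, cfgs, ad_models=models))
                log.info("%s/%s done (%.1fs)", task, name, time.time() - t0)
            manifest_tasks[task] = {"n_matched_pairs": len(matched.pairs),
                                    "n_dev": plan.n_dev, "n_test": plan.n_test}
        sizes = config["dev_sizes"].get(task, [])
        if sizes:
            curve_names = [n for n in names if n != "bag"]
            src = None
            if task != "AD_CN":
                src = config.get("_ad_models", {}).get("direct")
            all_results.extend(run_learning_curve(
                task, curve_names, data, plan, cfgs, sizes, ad_models=src))

    # --- results + summaries ---------------------------------------------
    import pandas as pd

    from .stats import summarize

    rows = [{k: v for k, v in dataclasses.asdict(r).items()
             if k not in ("train_ids", "val_ids", "test_ids", "selected")}
            for r in all_results]
    pd.DataFrame(rows).to_csv(out / "approach_results.tsv", sep="\t", index=False)
    if config["k"] >= 2 and all_results:
        tables = summarize(all_results, q=config["fdr_q"])
        tables["descriptives"].to_csv(out / "descriptives.tsv", sep="\t", index=False)
        tables["comparisons"].to_csv(out / "comparisons.tsv", sep="\t", index=False)
        tables["box"].to_csv(out / "box_summaries.tsv", sep="\t", index=False)
        comp = tables["comparisons"]
        if len(comp):
            comp = comp.assign(neglog10_p=-np.log10(comp["p"].clip(lower=1e-300)))
            for task, g in comp.groupby("task"):
                mat = g.pivot_table(index="approach_a", columns="approach_b",
                                    values="neglog10_p")
                mat.to_csv(out / f"neglog10p_{task}.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash({k: v for k, v in config.items()
                                     if not k.startswith("_")}),
        "tasks": manifest_tasks,
        "n_results": len(all_results),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
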